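"""Independent brute-force oracles used by the test suite only."""

import itertools


def brute_force_consistent_pairs(off, mothers, fathers, allele_universe=range(10)):
    """Exhaustively enumerate Mendelian-admissible (mother, father) pairs.

    A pair is admissible when at every locus called in the offspring the
    unordered offspring genotype can be formed from one allele of each
    parent; with one parent uncalled the free allele ranges over the whole
    allele universe.
    """
    ok = set()
    for (mi, m), (fi, f) in itertools.product(enumerate(mothers), enumerate(fathers)):
        good = True
        for locus, opair in off.calls.items():
            mp, fp = m.calls.get(locus), f.calls.get(locus)
            if opair is None or (mp is None and fp is None):
                continue
            if mp is not None and fp is not None:
                combos = {tuple(sorted((a, b))) for a in mp for b in fp}
            elif mp is not None:
                combos = {tuple(sorted((a, x))) for a in mp for x in allele_universe}
            else:
                combos = {tuple(sorted((b, x))) for b in fp for x in allele_universe}
            if opair not in combos:
                good = False
                break
        if good:
            ok.add((mi, fi))
    return ok
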