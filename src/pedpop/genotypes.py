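"""Core genetic data structures for codominant microsatellite panels.

A genotype is a map from locus name to an unordered diploid allele pair;
allele labels are opaque non-negative integers (fragment sizes are never
interpreted).  Missing data are explicit: a locus is either fully called
(two alleles) or marked missing — single-allele calls are not represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

AllelePair = Tuple[int, int]

#: sentinel used in array representations for a missing call
MISSING = -1


@dataclass(frozen=True)
class LocusPanel:
    """An ordered set of microsatellite loci with a screening subset.

    The screening subset is the small first-pass panel used for individual
    identification; samples failing any screening locus are discarded before
    full-panel typing.
    """

    loci: Tuple[str, ...]
    screening_subset: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.loci) < 1:
            raise ValueError("panel needs at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        unknown = set(self.screening_subset) - set(self.loci)
        if unknown:
            raise ValueError(f"screening loci not in panel: {sorted(unknown)}")
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "screening_subset", tuple(self.screening_subset))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index(self, locus: str) -> int:
        return self.loci.index(locus)


class Genotype:
    """Multilocus diploid genotype with explicit missingness.

    Parameters
    ----------
    calls
        Mapping locus -> (a, b) allele pair or ``None`` for missing.
        Pairs are stored sorted so (a, b) and (b, a) compare equal.
    """

    __slots__ = ("calls",)

    def __init__(self, calls: Mapping[str, Optional[AllelePair]]):
        normalised: Dict[str, Optional[AllelePair]] = {}
        for locus, pair in calls.items():
            if pair is None:
                normalised[locus] = None
            else:
                a, b = int(pair[0]), int(pair[1])
                if a < 0 or b < 0:
                    raise ValueError(f"negative allele label at {locus}")
                normalised[locus] = (a, b) if a <= b else (b, a)
        self.calls = normalised

    def __getitem__(self, locus: str) -> Optional[AllelePair]:
        return self.calls.get(locus)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genotype) and self.calls == other.calls

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Genotype({self.calls!r})"

    def is_missing(self, locus: str) -> bool:
        return self.calls.get(locus) is None

    def non_missing_loci(self) -> Tuple[str, ...]:
        return tuple(l for l, p in self.calls.items() if p is not None)

    def matches_exactly(self, other: "Genotype", loci: Iterable[str]) -> bool:
        """True when both genotypes are called and identical at every locus."""
        for locus in loci:
            a, b = self.calls.get(locus), other.calls.get(locus)
            if a is None or b is None or a != b:
                return False
        return True

    def consistent_with(self, other: "Genotype", loci: Iterable[str]) -> bool:
        """Identical wherever both are called (missing loci are ignored)."""
        for locus in loci:
            a, b = self.calls.get(locus), other.calls.get(locus)
            if a is not None and b is not None and a != b:
                return False
        return True


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequency estimates used by every likelihood."""

    freqs: Dict[str, Dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if table and abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")
            if any(p <= 0 for p in table.values()):
                raise ValueError(f"non-positive frequency at {locus}")

    def loci(self) -> Tuple[str, ...]:
        return tuple(self.freqs)

    def freq(self, locus: str, allele: int) -> float:
        return self.freqs[locus].get(allele, 0.0)

    def alleles(self, locus: str) -> Tuple[int, ...]:
        return tuple(self.freqs[locus])

    def hwe_genotype_prob(self, locus: str, pair: AllelePair) -> float:
        """Hardy–Weinberg probability of an unordered genotype."""
        a, b = pair
        pa = self.freq(locus, a)
        if a == b:
            return pa * pa
        return 2.0 * pa * self.freq(locus, b)

    def freq_matrix(self, panel_loci: Sequence[str]) -> np.ndarray:
        """Dense (n_loci, max_allele+1) lookup matrix, zeros where absent."""
        max_allele = 0
        for locus in panel_loci:
            table = self.freqs.get(locus, {})
            if table:
                max_allele = max(max_allele, max(table))
        mat = np.zeros((len(panel_loci), max_allele + 1))
        for i, locus in enumerate(panel_loci):
            for allele, p in self.freqs.get(locus, {}).items():
                mat[i, allele] = p
        return mat


def estimate_allele_frequencies(genotypes: Iterable[Genotype]) -> AlleleFrequencyTable:
    """Estimate allele frequencies by direct allele counting.

    Loci with zero observed alleles are simply absent from the table.
    """
    counts: Dict[str, Dict[int, int]] = {}
    n_obs = 0
    for g in genotypes:
        for locus, pair in g.calls.items():
            if pair is None:
                continue
            n_obs += 1
            table = counts.setdefault(locus, {})
            for allele in pair:
                table[allele] = table.get(allele, 0) + 1
    if n_obs == 0:
        raise ValueError("no genotypes with called loci supplied")
    freqs = {
        locus: {a: c / sum(t.values()) for a, c in sorted(t.items())}
        for locus, t in counts.items()
    }
    return AlleleFrequencyTable(freqs)


def pair_mismatches(offspring: Genotype, parent: Genotype) -> int:
    """Loci where parent and offspring share no allele (missing loci skipped)."""
    n = 0
    for locus, opair in offspring.calls.items():
        if opair is None:
            continue
        ppair = parent.calls.get(locus)
        if ppair is None:
            continue
        if opair[0] not in ppair and opair[1] not in ppair:
            n += 1
    return n


def _trio_locus_ok(opair: AllelePair, mpair: AllelePair, fpair: AllelePair) -> bool:
    o1, o2 = opair
    # offspring takes one allele from each parent, in either order
    if o1 == o2:
        return o1 in mpair and o1 in fpair
    return (o1 in mpair and o2 in fpair) or (o2 in mpair and o1 in fpair)


def trio_mismatches(offspring: Genotype, mother: Genotype, father: Genotype) -> int:
    """Loci where the offspring cannot be explained by one allele per parent.

    Loci where the offspring or both parents are missing are skipped; with one
    parent missing the locus degrades to a pairwise check against the other.
    """
    n = 0
    for locus, opair in offspring.calls.items():
        if opair is None:
            continue
        mpair = mother.calls.get(locus)
        fpair = father.calls.get(locus)
        if mpair is None and fpair is None:
            continue
        if mpair is None:
            if opair[0] not in fpair and opair[1] not in fpair:
                n += 1
            continue
        if fpair is None:
            if opair[0] not in mpair and opair[1] not in mpair:
                n += 1
            continue
        if not _trio_locus_ok(opair, mpair, fpair):
            n += 1
    return n


def probability_of_identity(
    freqs: AlleleFrequencyTable, loci: Sequence[str]
) -> float:
    """Probability two random individuals share a multilocus genotype (HWE).

    Per locus: sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2, multiplied over loci.
    """
    if not loci:
        raise ValueError("empty locus set")
    pi = 1.0
    for locus in loci:
        ps = list(freqs.freqs[locus].values())
        term = sum(p**4 for p in ps)
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                term += (2.0 * ps[i] * ps[j]) ** 2
        pi *= term
    return pi


def genotypes_to_array(
    genotypes: Sequence[Genotype], panel: LocusPanel
) -> np.ndarray:
    """Pack genotypes into an (n, n_loci, 2) int array, MISSING = -1."""
    arr = np.full((len(genotypes), panel.n_loci, 2), MISSING, dtype=np.int64)
    for i, g in enumerate(genotypes):
        for j, locus in enumerate(panel.loci):
            pair = g.calls.get(locus)
            if pair is not None:
                arr[i, j, 0], arr[i, j, 1] = pair
    return arr


def array_to_genotype(row: np.ndarray, panel: LocusPanel) -> Genotype:
    """Inverse of :func:`genotypes_to_array` for a single row."""
    calls: Dict[str, Optional[AllelePair]] = {}
    for j, locus in enumerate(panel.loci):
        a, b = int(row[j, 0]), int(row[j, 1])
        calls[locus] = None if a == MISSING or b == MISSING else (a, b)
    return Genotype(calls)
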