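"""Likelihood-based parentage assignment with Monte-Carlo Δ calibration.

The cascade mirrors the classic two-step likelihood workflow for codominant
markers: a parent-pair (trio) assignment first, then single-parent (dyad)
assignment for the remainder.  Candidate parents are pre-filtered on
uniparental haplotypes (mtDNA for mothers, Y for father–son) and on
age/liveness compatibility.  Assignment confidence is calibrated on
Δ = LOD(best) − LOD(second best) by simulating offspring–candidate panels
from the observed allele frequencies.

Genotyping error enters the likelihood as per-genotype replacement by a
Hardy–Weinberg random genotype at rate ``e``: with probability (1−e)^k all k
genotypes in a comparison are correct and the Mendelian transition applies,
otherwise the offspring genotype is treated as uninformative (its HWE
probability), which absorbs exclusions caused by mistyping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .genotypes import (
    MISSING,
    AlleleFrequencyTable,
    Genotype,
    LocusPanel,
    estimate_allele_frequencies,
    genotypes_to_array,
    pair_mismatches,
    trio_mismatches,
)
from .individuals import Individual, Sex


@dataclass
class AssignmentConfig:
    """Tunable parameters of the parentage cascade."""

    error_rate: float = 0.01
    n_simulation_cycles: int = 10_000
    n_candidates_per_offspring: int = 150
    prop_candidates_sampled: float = 0.40
    confidence_strict: float = 0.95
    confidence_relaxed: float = 0.80
    trio_mismatch_max_strict: int = 0
    trio_mismatch_max_relaxed: int = 1
    dyad_mismatch_max: int = 0
    min_maternal_age: int = 4
    min_paternal_age: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 < self.prop_candidates_sampled <= 1.0:
            raise ValueError("prop_candidates_sampled must be in (0, 1]")
        if self.confidence_relaxed >= self.confidence_strict:
            raise ValueError("relaxed confidence must be below strict")


@dataclass
class DeltaThresholds:
    """Calibrated Δ acceptance thresholds per analysis type."""

    trio_relaxed: float
    trio_strict: float
    dyad_relaxed: float
    dyad_strict: float


@dataclass
class ParentageAssignment:
    offspring_id: str
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    route: str = "unassigned"  # trio-strict|trio-relaxed|dyad-mother|dyad-father|sibship|unassigned
    lod: float = 0.0
    delta: float = 0.0
    mismatch_count: int = 0


# ---------------------------------------------------------------------------
# scalar likelihood reference implementation
# ---------------------------------------------------------------------------


def _share(parent_pair: Tuple[int, int], allele: int) -> float:
    """Probability the parent transmits `allele` under Mendelian segregation."""
    return (int(parent_pair[0] == allele) + int(parent_pair[1] == allele)) / 2.0


def transition_prob(
    locus: str,
    offspring_pair: Tuple[int, int],
    parent_pair: Optional[Tuple[int, int]],
    freqs: AlleleFrequencyTable,
    e: float,
    second_parent_pair: Optional[Tuple[int, int]] = None,
) -> float:
    """Probability of the offspring genotype given one or two parents.

    The unknown parent of a single-parent comparison is integrated over HWE.
    """
    o1, o2 = offspring_pair
    h = freqs.hwe_genotype_prob(locus, offspring_pair)
    if parent_pair is None and second_parent_pair is None:
        return h
    if parent_pair is None:
        parent_pair, second_parent_pair = second_parent_pair, None

    if second_parent_pair is None:
        t, u = _share(parent_pair, o1), _share(parent_pair, o2)
        if o1 == o2:
            mendel = t * freqs.freq(locus, o1)
        else:
            mendel = t * freqs.freq(locus, o2) + u * freqs.freq(locus, o1)
        k = 2
    else:
        tm, um = _share(parent_pair, o1), _share(parent_pair, o2)
        tf, uf = _share(second_parent_pair, o1), _share(second_parent_pair, o2)
        mendel = tm * tf if o1 == o2 else tm * uf + um * tf
        k = 3
    w = (1.0 - e) ** k
    return w * mendel + (1.0 - w) * h


def lod_score(
    offspring: Genotype,
    freqs: AlleleFrequencyTable,
    e: float,
    mother: Optional[Genotype] = None,
    father: Optional[Genotype] = None,
) -> float:
    """Log-likelihood ratio of candidate parentage vs an unrelated pairing.

    Loci missing in the offspring or in every supplied candidate contribute
    nothing; a candidate with all loci missing therefore scores 0.
    """
    total = 0.0
    for locus, opair in offspring.calls.items():
        if opair is None or locus not in freqs.freqs:
            continue
        mpair = mother.calls.get(locus) if mother is not None else None
        fpair = father.calls.get(locus) if father is not None else None
        if mpair is None and fpair is None:
            continue
        h = freqs.hwe_genotype_prob(locus, opair)
        num = transition_prob(locus, opair, mpair, freqs, e, fpair)
        if num <= 0.0:
            return -math.inf
        total += math.log(num / h)
    return total


# ---------------------------------------------------------------------------
# vectorised kernels (array layout: (n, n_loci, 2), MISSING = -1)
# ---------------------------------------------------------------------------


def _offspring_locus_terms(o_row: np.ndarray, fmat: np.ndarray):
    """Per-locus HWE probs and presence mask for one offspring row (L, 2)."""
    present = o_row[:, 0] != MISSING
    o1 = np.where(present, o_row[:, 0], 0).clip(0, fmat.shape[1] - 1)
    o2 = np.where(present, o_row[:, 1], 0).clip(0, fmat.shape[1] - 1)
    L = o_row.shape[0]
    p1 = fmat[np.arange(L), o1]
    p2 = fmat[np.arange(L), o2]
    hom = o1 == o2
    h = np.where(hom, p1 * p1, 2.0 * p1 * p2)
    h = np.where(present, h, 1.0)
    h = np.where(h <= 0.0, 1e-30, h)  # guard: alleles absent from the table
    return present, o1, o2, p1, p2, hom, h


def dyad_lod_vector(
    o_row: np.ndarray, cands: np.ndarray, fmat: np.ndarray, e: float
) -> Tuple[np.ndarray, np.ndarray]:
    """LOD and mismatch count of one offspring against n candidates.

    Returns (lod[n], mismatches[n]).
    """
    present, o1, o2, p1, p2, hom, h = _offspring_locus_terms(o_row, fmat)
    cpresent = cands[:, :, 0] != MISSING
    t = (cands == o1[None, :, None]).sum(axis=2) / 2.0
    u = (cands == o2[None, :, None]).sum(axis=2) / 2.0
    mendel = np.where(hom[None, :], t * p1[None, :], t * p2[None, :] + u * p1[None, :])
    w = (1.0 - e) ** 2
    lik = w * mendel + (1.0 - w) * h[None, :]
    both = present[None, :] & cpresent
    ratio = np.where(both, lik / h[None, :], 1.0)
    with np.errstate(divide="ignore"):
        lod = np.log(np.where(ratio > 0, ratio, 1e-300)).sum(axis=1)
    lod = np.where((ratio == 0).any(axis=1), -np.inf, lod)
    mism = (both & (t == 0.0) & (u == 0.0)).sum(axis=1)
    return lod, mism


def trio_lod_matrix(
    o_row: np.ndarray,
    mothers: np.ndarray,
    fathers: np.ndarray,
    fmat: np.ndarray,
    e: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """LOD and mismatch matrices (n_mothers, n_fathers) for one offspring.

    Loci with one missing parent degrade to the single-parent kernel against
    the present parent; loci missing in both parents (or the offspring)
    contribute nothing.
    """
    present, o1, o2, p1, p2, hom, h = _offspring_locus_terms(o_row, fmat)
    nm, nf = mothers.shape[0], fathers.shape[0]
    mp = mothers[:, :, 0] != MISSING
    fp = fathers[:, :, 0] != MISSING
    tm = (mothers == o1[None, :, None]).sum(axis=2) / 2.0
    um = (mothers == o2[None, :, None]).sum(axis=2) / 2.0
    tf = (fathers == o1[None, :, None]).sum(axis=2) / 2.0
    uf = (fathers == o2[None, :, None]).sum(axis=2) / 2.0

    w3 = (1.0 - e) ** 3
    w2 = (1.0 - e) ** 2
    # single-parent likelihood ratios, shape (n, L)
    m_single = np.where(hom, tm * p1, tm * p2 + um * p1)
    f_single = np.where(hom, tf * p1, tf * p2 + uf * p1)
    m_ratio = (w2 * m_single + (1.0 - w2) * h) / h
    f_ratio = (w2 * f_single + (1.0 - w2) * h) / h

    log_ratio = np.zeros((nm, nf))
    exclusion = np.zeros((nm, nf), dtype=bool)
    mism = np.zeros((nm, nf), dtype=np.int64)
    m_mism = (tm == 0.0) & (um == 0.0)
    f_mism = (tf == 0.0) & (uf == 0.0)
    for l in range(o_row.shape[0]):
        if not present[l]:
            continue
        both = np.outer(mp[:, l], fp[:, l])
        only_m = np.outer(mp[:, l], ~fp[:, l])
        only_f = np.outer(~mp[:, l], fp[:, l])
        if hom[l]:
            mendel = np.outer(tm[:, l], tf[:, l])
        else:
            mendel = np.outer(tm[:, l], uf[:, l]) + np.outer(um[:, l], tf[:, l])
        lik = w3 * mendel + (1.0 - w3) * h[l]
        ratio = np.where(both, lik / h[l], 1.0)
        ratio = np.where(only_m, m_ratio[:, l][:, None], ratio)
        ratio = np.where(only_f, f_ratio[None, :, l], ratio)
        zero = ratio <= 0.0
        exclusion |= zero
        with np.errstate(divide="ignore"):
            log_ratio += np.where(zero, 0.0, np.log(np.where(zero, 1.0, ratio)))
        # trio mismatch: jointly unexplainable when both present, pairwise otherwise
        if hom[l]:
            joint_ok = np.outer(tm[:, l] > 0, tf[:, l] > 0)
        else:
            joint_ok = np.outer(tm[:, l] > 0, uf[:, l] > 0) | np.outer(
                um[:, l] > 0, tf[:, l] > 0
            )
        mism += (both & ~joint_ok).astype(np.int64)
        mism += (only_m & m_mism[:, l][:, None]).astype(np.int64)
        mism += (only_f & f_mism[None, :, l]).astype(np.int64)
    log_ratio = np.where(exclusion, -np.inf, log_ratio)
    return log_ratio, mism


# ---------------------------------------------------------------------------
# Monte-Carlo Δ calibration
# ---------------------------------------------------------------------------


def _draw_hwe_genotypes(
    rng: np.random.Generator,
    alleles: List[np.ndarray],
    probs: List[np.ndarray],
    n: int,
) -> np.ndarray:
    """Draw n multilocus genotypes from HWE: (n, L, 2) array."""
    L = len(alleles)
    out = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        out[:, l, :] = rng.choice(alleles[l], size=(n, 2), p=probs[l])
    return out


def _mendelian_offspring(
    rng: np.random.Generator, mothers: np.ndarray, fathers: np.ndarray
) -> np.ndarray:
    n, L, _ = mothers.shape
    pick_m = rng.integers(0, 2, size=(n, L))
    pick_f = rng.integers(0, 2, size=(n, L))
    out = np.empty((n, L, 2), dtype=np.int64)
    out[:, :, 0] = np.take_along_axis(mothers, pick_m[:, :, None], axis=2)[:, :, 0]
    out[:, :, 1] = np.take_along_axis(fathers, pick_f[:, :, None], axis=2)[:, :, 0]
    return out


def _mistype(
    rng: np.random.Generator,
    genos: np.ndarray,
    alleles: List[np.ndarray],
    probs: List[np.ndarray],
    e: float,
) -> np.ndarray:
    """Replace each locus genotype with an HWE redraw at rate e."""
    if e <= 0:
        return genos
    n, L, _ = genos.shape
    hit = rng.random((n, L)) < e
    if not hit.any():
        return genos
    out = genos.copy()
    for l in range(L):
        idx = np.nonzero(hit[:, l])[0]
        if idx.size:
            out[idx, l, :] = rng.choice(alleles[l], size=(idx.size, 2), p=probs[l])
    return out


def _threshold_from_deltas(
    deltas: np.ndarray, correct: np.ndarray, confidence: float
) -> float:
    """Smallest Δ whose ≥-cutoff set attains the requested correct fraction."""
    order = np.argsort(-deltas)
    d_sorted = deltas[order]
    c_sorted = correct[order].astype(float)
    cum_correct = np.cumsum(c_sorted)
    counts = np.arange(1, len(deltas) + 1)
    frac = cum_correct / counts
    ok = frac >= confidence
    if not ok.any():
        return math.inf
    # the largest prefix that still satisfies the confidence requirement
    last = np.nonzero(ok)[0].max()
    return float(d_sorted[last])


def calibrate_delta(
    config: AssignmentConfig,
    freqs: AlleleFrequencyTable,
    panel: LocusPanel,
    seed: int,
) -> DeltaThresholds:
    """Monte-Carlo calibration of Δ thresholds for trio and dyad analyses.

    Each cycle simulates a true family from the observed allele frequencies,
    builds a candidate panel in which the true parent(s) appear with
    probability ``prop_candidates_sampled``, mistypes all genotypes at rate
    ``e``, and records Δ together with whether the top candidate was correct.
    """
    rng = np.random.default_rng(seed)
    loci = [l for l in panel.loci if l in freqs.freqs]
    if not loci:
        raise ValueError("no usable loci for calibration")
    alleles = [np.array(freqs.alleles(l)) for l in loci]
    probs = [
        np.array([freqs.freq(l, a) for a in freqs.alleles(l)]) for l in loci
    ]
    sub_panel = LocusPanel(tuple(loci))
    fmat = freqs.freq_matrix(loci)
    n_cyc = config.n_simulation_cycles
    n_cand = config.n_candidates_per_offspring
    e = config.error_rate

    mothers = _draw_hwe_genotypes(rng, alleles, probs, n_cyc)
    fathers = _draw_hwe_genotypes(rng, alleles, probs, n_cyc)
    offspring = _mendelian_offspring(rng, mothers, fathers)
    offspring = _mistype(rng, offspring, alleles, probs, e)
    mothers_obs = _mistype(rng, mothers, alleles, probs, e)
    fathers_obs = _mistype(rng, fathers, alleles, probs, e)
    m_in = rng.random(n_cyc) < config.prop_candidates_sampled
    f_in = rng.random(n_cyc) < config.prop_candidates_sampled

    dyad_deltas = np.empty(n_cyc)
    dyad_correct = np.empty(n_cyc, dtype=bool)
    trio_deltas = np.empty(n_cyc)
    trio_correct = np.empty(n_cyc, dtype=bool)
    for c in range(n_cyc):
        cand_m = _draw_hwe_genotypes(rng, alleles, probs, n_cand)
        cand_f = _draw_hwe_genotypes(rng, alleles, probs, n_cand)
        if m_in[c]:
            cand_m[0] = mothers_obs[c]
        if f_in[c]:
            cand_f[0] = fathers_obs[c]
        # dyad (maternity) analysis
        lod, _ = dyad_lod_vector(offspring[c], cand_m, fmat, e)
        best_i, delta = _top_two(lod)
        dyad_deltas[c] = delta if math.isfinite(lod[best_i]) else 0.0
        dyad_correct[c] = (
            bool(m_in[c]) and best_i == 0 and math.isfinite(lod[best_i])
        )
        # trio analysis
        tl, _ = trio_lod_matrix(offspring[c], cand_m, cand_f, fmat, e)
        flat = tl.ravel()
        best_i, delta = _top_two(flat)
        trio_deltas[c] = delta if math.isfinite(flat[best_i]) else 0.0
        bi, bj = np.unravel_index(best_i, tl.shape)
        trio_correct[c] = (
            bool(m_in[c])
            and bool(f_in[c])
            and bi == 0
            and bj == 0
            and math.isfinite(flat[best_i])
        )
    # +inf deltas (a single compatible candidate) sort above every finite one,
    # so thresholds derived below remain well defined

    thresholds = DeltaThresholds(
        trio_relaxed=_threshold_from_deltas(
            trio_deltas, trio_correct, config.confidence_relaxed
        ),
        trio_strict=_threshold_from_deltas(
            trio_deltas, trio_correct, config.confidence_strict
        ),
        dyad_relaxed=_threshold_from_deltas(
            dyad_deltas, dyad_correct, config.confidence_relaxed
        ),
        dyad_strict=_threshold_from_deltas(
            dyad_deltas, dyad_correct, config.confidence_strict
        ),
    )
    for name in ("trio_relaxed", "trio_strict", "dyad_relaxed", "dyad_strict"):
        if not math.isfinite(getattr(thresholds, name)):
            warnings.warn(
                f"Δ calibration for {name} did not reach the requested "
                "confidence; threshold set to +inf (no assignments accepted)",
                stacklevel=2,
            )
    return thresholds


# ---------------------------------------------------------------------------
# candidate filtering and the cascade
# ---------------------------------------------------------------------------


def _age_compatible(parent: Individual, off: Individual, min_age: int) -> bool:
    if parent.birth_year is not None and off.birth_year is not None:
        return parent.birth_year + min_age <= off.birth_year
    return True


def _mother_alive_compatible(parent: Individual, off: Individual) -> bool:
    # a mother must survive to the offspring's birth
    if parent.death_year is not None and off.birth_year is not None:
        return parent.death_year >= off.birth_year
    return True


def _father_alive_compatible(parent: Individual, off: Individual) -> bool:
    # a father must be alive at conception, the year before birth
    if parent.death_year is not None and off.birth_year is not None:
        return parent.death_year >= off.birth_year - 1
    return True


def candidate_mothers(
    off: Individual, pool: Sequence[Individual], config: AssignmentConfig
) -> List[Individual]:
    out = []
    for ind in pool:
        if ind.id == off.id or ind.sex is not Sex.FEMALE or ind.genotype is None:
            continue
        if (
            off.mt_haplotype is not None
            and ind.mt_haplotype is not None
            and off.mt_haplotype != ind.mt_haplotype
        ):
            continue
        if not _mother_alive_compatible(ind, off):
            continue
        if not _age_compatible(ind, off, config.min_maternal_age):
            continue
        out.append(ind)
    return out


def candidate_fathers(
    off: Individual, pool: Sequence[Individual], config: AssignmentConfig
) -> List[Individual]:
    out = []
    for ind in pool:
        if ind.id == off.id or ind.sex is not Sex.MALE or ind.genotype is None:
            continue
        if (
            off.sex is Sex.MALE
            and off.y_haplotype is not None
            and ind.y_haplotype is not None
            and off.y_haplotype != ind.y_haplotype
        ):
            continue
        if not _father_alive_compatible(ind, off):
            continue
        if not _age_compatible(ind, off, config.min_paternal_age):
            continue
        out.append(ind)
    return out


def _top_two(values: np.ndarray) -> Tuple[int, float]:
    """Index of the best value and Δ to the runner-up (0 when alone)."""
    if values.size == 1:
        return 0, math.inf if math.isfinite(values[0]) else 0.0
    order = np.argsort(-values)
    best, second = values[order[0]], values[order[1]]
    if not math.isfinite(best):
        return int(order[0]), 0.0
    delta = best - second if math.isfinite(second) else math.inf
    return int(order[0]), float(delta)


def assign_parent_pair(
    off: Individual,
    mothers: Sequence[Individual],
    fathers: Sequence[Individual],
    thresholds: DeltaThresholds,
    config: AssignmentConfig,
    freqs: AlleleFrequencyTable,
    panel: LocusPanel,
) -> Optional[ParentageAssignment]:
    """Trio step: accept the best parent pair at 80% with 0 mismatches, or at
    95% with ≤1 mismatch when maternity- and paternity-only analyses agree."""
    if not mothers or not fathers or off.genotype is None:
        return None
    # deterministic candidate order for reproducible tie-breaks
    mothers = sorted(mothers, key=lambda i: i.id)
    fathers = sorted(fathers, key=lambda i: i.id)
    o_row = genotypes_to_array([off.genotype], panel)[0]
    m_arr = genotypes_to_array([m.genotype for m in mothers], panel)
    f_arr = genotypes_to_array([f.genotype for f in fathers], panel)
    fmat = freqs.freq_matrix(panel.loci)
    e = config.error_rate

    lods, mism = trio_lod_matrix(o_row, m_arr, f_arr, fmat, e)
    flat = lods.ravel()
    idx, delta = _top_two(flat)
    bi, bj = np.unravel_index(idx, lods.shape)
    best_lod = float(lods[bi, bj])
    best_mism = int(mism[bi, bj])
    if not math.isfinite(best_lod):
        return None

    if best_mism <= config.trio_mismatch_max_strict and delta >= thresholds.trio_relaxed:
        return ParentageAssignment(
            off.id, mothers[bi].id, fathers[bj].id, "trio-strict",
            best_lod, delta, best_mism,
        )
    if best_mism <= config.trio_mismatch_max_relaxed and delta >= thresholds.trio_strict:
        # require the same individuals to top separate single-parent analyses
        m_lod, m_mism = dyad_lod_vector(o_row, m_arr, fmat, e)
        f_lod, f_mism = dyad_lod_vector(o_row, f_arr, fmat, e)
        mi, _ = _top_two(m_lod)
        fi, _ = _top_two(f_lod)
        if (
            mi == bi
            and fi == bj
            and m_mism[mi] <= config.trio_mismatch_max_relaxed
            and f_mism[fi] <= config.trio_mismatch_max_relaxed
        ):
            return ParentageAssignment(
                off.id, mothers[bi].id, fathers[bj].id, "trio-relaxed",
                best_lod, delta, best_mism,
            )
    return None


def assign_single_parent(
    off: Individual,
    candidates: Sequence[Individual],
    thresholds: DeltaThresholds,
    config: AssignmentConfig,
    freqs: AlleleFrequencyTable,
    panel: LocusPanel,
) -> Optional[Tuple[Individual, float, float]]:
    """Dyad step: best candidate at 80% confidence with zero mismatches."""
    if not candidates or off.genotype is None:
        return None
    candidates = sorted(candidates, key=lambda i: i.id)
    o_row = genotypes_to_array([off.genotype], panel)[0]
    c_arr = genotypes_to_array([c.genotype for c in candidates], panel)
    fmat = freqs.freq_matrix(panel.loci)
    lod, mism = dyad_lod_vector(o_row, c_arr, fmat, config.error_rate)
    idx, delta = _top_two(lod)
    if (
        math.isfinite(lod[idx])
        and mism[idx] <= config.dyad_mismatch_max
        and delta >= thresholds.dyad_relaxed
    ):
        return candidates[idx], float(lod[idx]), float(delta)
    return None


def run_cascade(
    individuals: Sequence[Individual],
    config: AssignmentConfig,
    seed: int,
    panel: LocusPanel,
    thresholds: Optional[DeltaThresholds] = None,
    freqs: Optional[AlleleFrequencyTable] = None,
) -> List[ParentageAssignment]:
    """Run trio-then-dyad parentage over every individual.

    Immigrant-flagged individuals stay out of the candidate-offspring pool but
    remain candidate fathers.  Every individual receives exactly one
    assignment record; deterministic given the seed.
    """
    ids = [ind.id for ind in individuals]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids")
    if freqs is None:
        freqs = estimate_allele_frequencies(
            [i.genotype for i in individuals if i.genotype is not None]
        )
    if thresholds is None:
        thresholds = calibrate_delta(config, freqs, panel, seed)

    assignments: List[ParentageAssignment] = []
    for off in sorted(individuals, key=lambda i: i.id):
        if off.immigrant or off.genotype is None:
            assignments.append(ParentageAssignment(off.id))
            continue
        moms = candidate_mothers(off, individuals, config)
        dads = candidate_fathers(off, individuals, config)
        trio = assign_parent_pair(
            off, moms, dads, thresholds, config, freqs, panel
        )
        if trio is not None:
            assignments.append(trio)
            continue
        m_hit = assign_single_parent(off, moms, thresholds, config, freqs, panel)
        f_hit = assign_single_parent(off, dads, thresholds, config, freqs, panel)
        if m_hit is not None and f_hit is not None:
            # keep exactly one dyad parent: the better-supported slot
            if m_hit[2] >= f_hit[2]:
                f_hit = None
            else:
                m_hit = None
        if m_hit is not None:
            assignments.append(
                ParentageAssignment(
                    off.id, mother_id=m_hit[0].id, route="dyad-mother",
                    lod=m_hit[1], delta=m_hit[2],
                )
            )
        elif f_hit is not None:
            assignments.append(
                ParentageAssignment(
                    off.id, father_id=f_hit[0].id, route="dyad-father",
                    lod=f_hit[1], delta=f_hit[2],
                )
            )
        else:
            assignments.append(ParentageAssignment(off.id))
    _break_pedigree_cycles(assignments)
    return assignments


def _break_pedigree_cycles(assignments: List[ParentageAssignment]) -> None:
    """Drop the weakest links until the accepted pedigree is acyclic.

    With unknown ages a parent–offspring pair is genetically symmetric, so
    the cascade can occasionally accept a reversed link; a true pedigree can
    never contain a directed cycle, and the lowest-Δ link in any cycle is
    the least trustworthy.
    """
    import networkx as nx

    by_id = {a.offspring_id: a for a in assignments}
    while True:
        g = nx.DiGraph()
        for a in assignments:
            for pid in (a.mother_id, a.father_id):
                if pid is not None:
                    g.add_edge(pid, a.offspring_id, delta=a.delta)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        parent, child = min(
            ((e[0], e[1]) for e in cycle),
            key=lambda uv: (g.edges[uv]["delta"], uv),
        )
        assignment = by_id[child]
        if assignment.mother_id == parent:
            assignment.mother_id = None
        if assignment.father_id == parent:
            assignment.father_id = None
        if assignment.mother_id is None and assignment.father_id is None:
            assignment.route = "unassigned"
        elif assignment.route.startswith("trio"):
            assignment.route = (
                "dyad-mother" if assignment.mother_id is not None else "dyad-father"
            )


class ParentageAssigner(BaseEstimator):
    """Scikit-learn style front end to the parentage cascade.

    ``fit`` estimates allele frequencies from the supplied individuals and
    calibrates the Δ thresholds; ``predict`` runs the cascade and returns one
    :class:`ParentageAssignment` per individual.

    Attributes
    ----------
    frequencies_ : AlleleFrequencyTable
    thresholds_ : DeltaThresholds
    assignments_ : list of ParentageAssignment
    """

    def __init__(
        self,
        panel: Optional[LocusPanel] = None,
        config: Optional[AssignmentConfig] = None,
        seed: int = 0,
    ):
        self.panel = panel
        self.config = config
        self.seed = seed

    def fit(self, individuals: Sequence[Individual], y=None) -> "ParentageAssigner":
        if self.panel is None:
            raise ValueError("panel is required")
        cfg = self.config or AssignmentConfig()
        self.config_ = cfg
        self.frequencies_ = estimate_allele_frequencies(
            [i.genotype for i in individuals if i.genotype is not None]
        )
        self.thresholds_ = calibrate_delta(cfg, self.frequencies_, self.panel, self.seed)
        return self

    def predict(self, individuals: Sequence[Individual]) -> List[ParentageAssignment]:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("call fit before predict")
        self.assignments_ = run_cascade(
            individuals,
            self.config_,
            self.seed,
            self.panel,
            thresholds=self.thresholds_,
            freqs=self.frequencies_,
        )
        return self.assignments_
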