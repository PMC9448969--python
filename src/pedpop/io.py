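"""Readers and writers for the pipeline's plain-text formats.

Genotype tables are TSV with two columns per locus (``locus.A1``,
``locus.A2``); 0 or blank means missing.  Individual metadata travel as CSV
with free-text haplotype labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .demography import PopulationEstimate
from .genotypes import Genotype, LocusPanel
from .individuals import (
    AgeEvidence,
    DeathCause,
    Individual,
    SampleMethod,
    SampleRecord,
    Sex,
)
from .parentage import ParentageAssignment
from .sibship import HypotheticalParent


def genotype_frame(
    records: Sequence[Tuple[str, Genotype]], panel: LocusPanel
) -> pd.DataFrame:
    rows = []
    for rid, g in records:
        row: Dict[str, object] = {"id": rid}
        for locus in panel.loci:
            pair = g.calls.get(locus)
            row[f"{locus}.A1"] = 0 if pair is None else pair[0] + 1
            row[f"{locus}.A2"] = 0 if pair is None else pair[1] + 1
        rows.append(row)
    return pd.DataFrame(rows)


def write_genotypes(
    path: Path, records: Sequence[Tuple[str, Genotype]], panel: LocusPanel
) -> None:
    genotype_frame(records, panel).to_csv(path, sep="\t", index=False)


def read_genotypes(path: Path, panel: LocusPanel) -> List[Tuple[str, Genotype]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        calls: Dict[str, Optional[Tuple[int, int]]] = {}
        for locus in panel.loci:
            a = int(row.get(f"{locus}.A1", 0) or 0)
            b = int(row.get(f"{locus}.A2", 0) or 0)
            calls[locus] = None if a == 0 or b == 0 else (a - 1, b - 1)
        out.append((str(row["id"]), Genotype(calls)))
    return out


_IND_COLS = [
    "id", "sex", "mt_haplotype", "y_haplotype", "birth_year", "min_birth_year",
    "max_birth_year", "death_year", "death_cause", "first_id_year",
    "last_id_year", "id_years", "age_evidence", "immigrant",
]


def write_individuals(path: Path, individuals: Sequence[Individual]) -> None:
    rows = []
    for ind in individuals:
        rows.append(
            {
                "id": ind.id,
                "sex": ind.sex.value,
                "mt_haplotype": ind.mt_haplotype or "",
                "y_haplotype": ind.y_haplotype or "",
                "birth_year": ind.birth_year,
                "min_birth_year": ind.min_birth_year,
                "max_birth_year": ind.max_birth_year,
                "death_year": ind.death_year,
                "death_cause": ind.death_cause.value,
                "first_id_year": ind.first_id_year,
                "last_id_year": ind.last_id_year,
                "id_years": ";".join(str(y) for y in sorted(ind.id_years)),
                "age_evidence": ind.age_evidence.value,
                "immigrant": int(ind.immigrant),
            }
        )
    pd.DataFrame(rows, columns=_IND_COLS).to_csv(path, index=False)


def _opt_int(value) -> Optional[int]:
    return None if value is None or pd.isna(value) or value == "" else int(value)


def read_individuals(path: Path) -> List[Individual]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        years = {
            int(y) for y in str(row.get("id_years", "") or "").split(";") if y
        }
        out.append(
            Individual(
                id=str(row["id"]),
                sex=Sex(row["sex"]),
                mt_haplotype=(row.get("mt_haplotype") or None)
                if not pd.isna(row.get("mt_haplotype"))
                else None,
                y_haplotype=(row.get("y_haplotype") or None)
                if not pd.isna(row.get("y_haplotype"))
                else None,
                birth_year=_opt_int(row.get("birth_year")),
                min_birth_year=_opt_int(row.get("min_birth_year")),
                max_birth_year=_opt_int(row.get("max_birth_year")),
                death_year=_opt_int(row.get("death_year")),
                death_cause=DeathCause(row.get("death_cause", "none")),
                first_id_year=_opt_int(row.get("first_id_year")),
                last_id_year=_opt_int(row.get("last_id_year")),
                id_years=years,
                identified_2019_20=bool(years & {2019, 2020}),
                age_evidence=AgeEvidence(row.get("age_evidence", "none")),
                immigrant=bool(int(row.get("immigrant", 0) or 0)),
            )
        )
    return out


def write_assignments(path: Path, assignments: Sequence[ParentageAssignment]) -> None:
    pd.DataFrame(
        [
            {
                "offspring_id": a.offspring_id,
                "mother_id": a.mother_id or "",
                "father_id": a.father_id or "",
                "route": a.route,
                "lod": round(a.lod, 4),
                "delta": round(a.delta, 4) if a.delta != float("inf") else "inf",
                "mismatches": a.mismatch_count,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path: Path) -> List[ParentageAssignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        ParentageAssignment(
            offspring_id=str(r["offspring_id"]),
            mother_id=str(r["mother_id"]) or None,
            father_id=str(r["father_id"]) or None,
            route=str(r["route"]),
            lod=float(r["lod"]),
            delta=float(r["delta"]) if r["delta"] != "inf" else float("inf"),
            mismatch_count=int(r["mismatches"]),
        )
        for _, r in df.iterrows()
    ]


def write_hypotheticals(path: Path, hyps: Sequence[HypotheticalParent]) -> None:
    pd.DataFrame(
        [
            {
                "id": h.id,
                "sex": h.sex.value,
                "offspring": ";".join(h.offspring_ids),
                "anchor_birth_year": h.anchor_offspring_birth_year,
                "haplotype": h.haplotype or "",
                "liveness": h.liveness,
            }
            for h in hyps
        ]
    ).to_csv(path, sep="\t", index=False)


def estimate_to_dict(est: PopulationEstimate) -> dict:
    return {
        "breeding": {
            s.value: {"min": b.min, "max": b.max} for s, b in est.breeding.items()
        },
        "adult": {
            s.value: {"min": b.min, "max": b.max} for s, b in est.adult.items()
        },
        "minimum_population": {
            s.value: n for s, n in est.minimum_population.items()
        },
        "minimum_population_total": est.minimum_population_total,
        "age_breakdown": {
            s.value: dict(classes) for s, classes in est.age_breakdown.items()
        },
        "density_per_100km2": {
            "study_area": round(est.density_study_area, 1),
            "forest": round(est.density_forest, 1),
        },
    }


def write_estimate(path: Path, est: PopulationEstimate, header: dict) -> None:
    payload = {"run": header, "estimate": estimate_to_dict(est)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_audit(path: Path, est: PopulationEstimate) -> None:
    pd.DataFrame(est.audit).to_csv(path, index=False)
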