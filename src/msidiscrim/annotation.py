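"""Mass-based annotation of discriminatory components.

Peptide components match candidate observed MH+ masses at a relative
tolerance (+-0.05%); lipid components match candidate neutral masses
expanded to [M+H]+, [M+Na]+ and [M+K]+ adducts at an absolute tolerance
(default 0.5 Da).  All matches are kept; the best hit per component is the
lowest |delta| (ties: lighter adduct, then candidate id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CandidateMassList, ValidationError

PEPTIDE_REL_TOL = 0.0005  # +-0.05%

# cation mass minus one electron, Da
ADDUCT_SHIFTS = {
    "H": 1.007276,
    "Na": 22.989218,
    "K": 38.963158,
}
_ADDUCT_ORDER = {"H": 0, "Na": 1, "K": 2, "none": 3}


@dataclass(frozen=True)
class AnnotationRecord:
    component_mz: float
    candidate_id: str
    adduct: str  # "none" for peptides
    theoretical_mz: float
    delta: float
    is_best_hit: bool


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Observed m/z of a singly charged adduct of a neutral molecule."""
    if neutral_mass <= 0:
        raise ValidationError("neutral mass must be > 0")
    if adduct not in ADDUCT_SHIFTS:
        raise ValidationError(f"unknown adduct {adduct!r}")
    return neutral_mass + ADDUCT_SHIFTS[adduct]


def _flag_best_hits(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    by_comp: dict[float, list[int]] = {}
    for i, rec in enumerate(records):
        by_comp.setdefault(rec.component_mz, []).append(i)
    out = list(records)
    for idxs in by_comp.values():
        best = min(
            idxs,
            key=lambda i: (
                abs(out[i].delta),
                _ADDUCT_ORDER[out[i].adduct],
                out[i].candidate_id,
            ),
        )
        for i in idxs:
            rec = out[i]
            out[i] = AnnotationRecord(
                rec.component_mz, rec.candidate_id, rec.adduct,
                rec.theoretical_mz, rec.delta, i == best,
            )
    return out


def match_peptide_masses(
    components: np.ndarray, candidates: CandidateMassList
) -> list[AnnotationRecord]:
    """Match at +-0.05% of the component m/z (closed window)."""
    if candidates.kind != "peptide":
        raise ValidationError("peptide matching requires peptide candidates")
    records: list[AnnotationRecord] = []
    for mz in np.asarray(components, dtype=float):
        tol = PEPTIDE_REL_TOL * mz
        for cid, mass in zip(candidates.ids, candidates.masses):
            delta = mass - mz
            if abs(delta) <= tol:
                records.append(
                    AnnotationRecord(mz, str(cid), "none", float(mass), float(delta), False)
                )
    return _flag_best_hits(records)


def match_lipid_masses(
    components: np.ndarray, candidates: CandidateMassList, tol: float = 0.5
) -> list[AnnotationRecord]:
    """Expand each neutral candidate mass to three adducts and match at an
    absolute tolerance (closed window)."""
    if candidates.kind != "lipid":
        raise ValidationError("lipid matching requires lipid candidates")
    records: list[AnnotationRecord] = []
    for mz in np.asarray(components, dtype=float):
        for cid, mass in zip(candidates.ids, candidates.masses):
            for adduct in ("H", "Na", "K"):
                theo = adduct_mz(float(mass), adduct)
                delta = theo - mz
                if abs(delta) <= tol:
                    records.append(
                        AnnotationRecord(mz, str(cid), adduct, theo, float(delta), False)
                    )
    return _flag_best_hits(records)


def annotation_table(records: list[AnnotationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component_mz": r.component_mz,
                "candidate_id": r.candidate_id,
                "adduct": r.adduct,
                "theoretical_mz": r.theoretical_mz,
                "delta": r.delta,
                "is_best_hit": r.is_best_hit,
            }
            for r in records
        ]
    )
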