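"""Ensemble-disagreement uncertainty and review-stratum selection.

A segmentation ensemble (e.g. the five folds of a cross-validated model)
produces m candidate masks per structure. Their volumetric disagreement is
summarized as

    U = 1 − (1/k) Σ_{i<j} Dice(i, j),        k = m(m−1)/2,

i.e. one minus the mean pairwise Dice overlap: U = 0 means all members
agree perfectly, larger U means more disagreement. Cases for visual review
are then drawn from three strata — the n cases with the highest U, the n
with the lowest, and the n whose U lies nearest the sample median — so a
reviewer sees both likely-erroneous and typical segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .volume_io import LEFT_LUNG, RIGHT_LUNG, BinaryMask, LabelVolume, extract_binary_mask


@dataclass(frozen=True)
class EnsembleRecord:
    """Per-case ensemble uncertainty U derived from m candidate masks."""

    case_id: str
    uncertainty: float
    n_models: int
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.uncertainty <= 1.0 + 1e-12:
            raise ValueError(f"U must lie in [0, 1], got {self.uncertainty}")
        if self.n_models < 2 or self.k != self.n_models * (self.n_models - 1) // 2:
            raise ValueError("need m >= 2 with k = m(m-1)/2")


def _voxels(mask) -> np.ndarray:
    return mask.voxels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks.

    Two empty masks agree perfectly (Dice 1); one empty against one
    non-empty gives 0.
    """
    va, vb = _voxels(a), _voxels(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    denom = int(va.sum()) + int(vb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((va & vb).sum()) / denom


def ensemble_uncertainty(masks: Sequence, case_id: str = "") -> EnsembleRecord:
    """U = 1 − mean pairwise Dice over the ensemble's unordered mask pairs."""
    m = len(masks)
    if m < 2:
        raise ValueError(f"need at least 2 ensemble members, got {m}")
    pair_dice = [dice(a, b) for a, b in combinations(masks, 2)]
    k = len(pair_dice)
    u = 1.0 - float(np.mean(pair_dice))
    return EnsembleRecord(case_id=case_id, uncertainty=max(0.0, min(1.0, u)), n_models=m, k=k)


def label_uncertainty(vols: Sequence[LabelVolume], case_id: str = "") -> dict:
    """Per-case uncertainty of a two-label ensemble.

    U is computed separately on the right-lung and left-lung binary masks
    and combined as their unweighted mean, which is symmetric in the two
    lungs; all three values are reported.
    """
    if len(vols) < 2:
        raise ValueError("need at least 2 ensemble members")
    u_right = ensemble_uncertainty(
        [extract_binary_mask(v, RIGHT_LUNG) for v in vols], case_id
    ).uncertainty
    u_left = ensemble_uncertainty(
        [extract_binary_mask(v, LEFT_LUNG) for v in vols], case_id
    ).uncertainty
    return {
        "case_id": case_id,
        "U_right": u_right,
        "U_left": u_left,
        "U_mean": 0.5 * (u_right + u_left),
        "n_models": len(vols),
    }


def stratified_sample(
    records: Sequence[EnsembleRecord], n_per_stratum: int
) -> dict[str, list[str]]:
    """Select three pairwise-disjoint review strata of ``n_per_stratum``
    cases each: the highest-U cases, the lowest-U cases, and the cases with
    U nearest the sample median (computed over all records) among those not
    already taken. Ties are broken by case_id so the selection is
    deterministic across runs.
    """
    n = n_per_stratum
    if n < 1:
        raise ValueError("n_per_stratum must be positive")
    if len(records) < 3 * n:
        raise ValueError(f"need at least {3 * n} records, got {len(records)}")
    if len({r.case_id for r in records}) != len(records):
        raise ValueError("case_ids must be unique")

    max_stratum = sorted(records, key=lambda r: (-r.uncertainty, r.case_id))[:n]
    taken = {r.case_id for r in max_stratum}
    rest = [r for r in records if r.case_id not in taken]
    min_stratum = sorted(rest, key=lambda r: (r.uncertainty, r.case_id))[:n]
    taken |= {r.case_id for r in min_stratum}
    rest = [r for r in records if r.case_id not in taken]
    med = float(np.median([r.uncertainty for r in records]))
    median_stratum = sorted(rest, key=lambda r: (abs(r.uncertainty - med), r.case_id))[:n]

    return {
        "max": [r.case_id for r in max_stratum],
        "min": [r.case_id for r in min_stratum],
        "median": [r.case_id for r in median_stratum],
    }
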