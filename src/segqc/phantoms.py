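"""Synthetic lung phantoms, error injection, and simulated ensembles/raters.

The real cohort data behind a segmentation-QC study cannot ship with a
library, so this module generates stand-ins that exercise every code path:
paired quasi-ellipsoidal "lungs" on an anisotropic grid (default
128×128×64 voxels at 1.4×1.4×3.0 mm), the six error categories observed in
such cohorts (left–right mislabeling, over-/under-segmentation, exclusion
of pathology, off-target stitching, inclusion of a distant organ, failed
lung separation), randomly perturbed segmentation ensembles for the
uncertainty metric, and conditionally independent binary raters with
configurable sensitivity/specificity.

The phantoms are smoothed ellipsoids, not anatomical atlases: the
projection and statistics logic is shape-agnostic, and simple shapes keep
test suites fast. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .rater_stats import RatingTable
from .volume_io import LEFT_LUNG, RIGHT_LUNG, LabelVolume

ERROR_CATEGORIES = (
    "lr_mislabel",
    "over_under_segmentation",
    "exclude_pathology",
    "off_target_stitching",
    "include_distant_organ",
    "failed_separation",
)

#: observed marginal frequency of each category among error cases
#: (co-occurrence allowed, so the values sum to more than 1)
DEFAULT_CATEGORY_FREQUENCIES: dict[str, float] = {
    "lr_mislabel": 61 / 76,
    "over_under_segmentation": 34 / 76,
    "exclude_pathology": 5 / 76,
    "off_target_stitching": 4 / 76,
    "include_distant_organ": 3 / 76,
    "failed_separation": 1 / 76,
}

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# phantom generation


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a two-lung phantom.

    Semi-axes and centers are in mm on the canonical L-R/P-A/I-S grid; the
    right lung (label 1) sits at high L-R coordinate, matching the RAS
    convention. ``boundary_noise`` modulates the ellipsoid level set with a
    smooth random field of that relative amplitude.
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (1.4, 1.4, 3.0)
    #: None -> scale with the grid (28, 42, 68 mm on the default grid)
    semi_axes: tuple[float, float, float] | None = None
    right_center_frac: tuple[float, float, float] = (0.70, 0.5, 0.5)
    left_center_frac: tuple[float, float, float] = (0.30, 0.5, 0.5)
    boundary_noise: float = 0.05
    noise_sigma_vox: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("all grid dimensions must be >= 16")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if self.semi_axes is not None and min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def resolved_semi_axes(self) -> tuple[float, float, float]:
        if self.semi_axes is not None:
            return self.semi_axes
        ex, ey, ez = self.extent_mm
        return (ex * 28.0 / 179.2, ey * 42.0 / 179.2, ez * 68.0 / 192.0)

    def center_mm(self, side: str) -> tuple[float, float, float]:
        frac = self.right_center_frac if side == "right" else self.left_center_frac
        return tuple(f * e for f, e in zip(frac, self.extent_mm))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _lung_mask(spec: PhantomSpec, side: str, rng: np.random.Generator) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spec.spacing)],
        indexing="ij",
    )
    center = spec.center_mm(side)
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, spec.resolved_semi_axes))
    noise = _smooth_field(rng, spec.shape, spec.noise_sigma_vox)
    return q <= 1.0 + spec.boundary_noise * noise


def generate_lung_phantom(spec: PhantomSpec | None = None) -> LabelVolume:
    """Two disjoint smooth quasi-ellipsoidal lungs, deterministic per seed."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    right = _lung_mask(spec, "right", rng)
    left = _lung_mask(spec, "left", rng)
    if (right & left).any():
        raise ValueError("phantom spec produces overlapping lungs; increase separation")
    if not right.any() or not left.any():
        raise ValueError("phantom spec produces an empty lung; check geometry")
    voxels = np.zeros(spec.shape, dtype=np.int16)
    voxels[right] = RIGHT_LUNG
    voxels[left] = LEFT_LUNG
    return LabelVolume(voxels=voxels, spacing=spec.spacing)


# ---------------------------------------------------------------------------
# error injection


@dataclass(frozen=True)
class ErrorRecord:
    """One injected segmentation error and its magnitude descriptors."""

    case_id: str
    category: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in ERROR_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _ball(shape, spacing, center_vox, radius_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center_vox, spacing))
    return d2 <= radius_mm**2


def _pick_voxel(rng: np.random.Generator, mask: np.ndarray) -> tuple[int, ...]:
    idx = np.argwhere(mask)
    return tuple(idx[rng.integers(len(idx))])


def inject_error(
    vol: LabelVolume, category: str, magnitude: float, seed: int = 0, case_id: str = ""
) -> tuple[LabelVolume, ErrorRecord]:
    """Inject one segmentation error of the given category.

    Magnitude semantics per category: ``lr_mislabel`` — fraction of the
    lung extent relabeled (>= 1 swaps the labels globally);
    ``over_under_segmentation`` — morphological dilation/erosion depth in
    voxels; ``exclude_pathology`` / ``include_distant_organ`` /
    ``failed_separation`` — carved-ball / added-ball / bridge radius in mm;
    ``off_target_stitching`` — in-plane shift in voxels of the sub-volume
    below a random axial cut.
    """
    if category not in ERROR_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    rng = np.random.default_rng(seed)
    vox = vol.voxels.copy()
    right = vox == RIGHT_LUNG
    left = vox == LEFT_LUNG
    params: dict[str, object] = {"magnitude": magnitude, "seed": seed}

    if category == "lr_mislabel":
        if magnitude >= 1.0:
            vox[right] = LEFT_LUNG
            vox[left] = RIGHT_LUNG
            params["mode"] = "complete"
        else:
            lung_label = int(rng.choice((RIGHT_LUNG, LEFT_LUNG)))
            other = LEFT_LUNG if lung_label == RIGHT_LUNG else RIGHT_LUNG
            lung = vox == lung_label
            bbox = [(int(a.min()), int(a.max())) for a in np.nonzero(lung)]
            extent = max((hi - lo + 1) * s for (lo, hi), s in zip(bbox, vol.spacing))
            radius = 0.5 * magnitude * extent
            center = _pick_voxel(rng, lung)
            region = lung & _ball(vox.shape, vol.spacing, center, radius)
            if not region.any():
                raise ValueError("mislabel region is empty; increase magnitude")
            vox[region] = other
            params.update(mode="partial", lung=lung_label, radius_mm=radius)

    elif category == "over_under_segmentation":
        iters = max(1, int(round(magnitude)))
        lung_label = int(rng.choice((RIGHT_LUNG, LEFT_LUNG)))
        lung = vox == lung_label
        other = vox == (LEFT_LUNG if lung_label == RIGHT_LUNG else RIGHT_LUNG)
        direction = str(rng.choice(("dilate", "erode")))
        if direction == "dilate":
            grown = ndimage.binary_dilation(lung, _STRUCT6, iterations=iters) & ~other
            vox[grown] = lung_label
        else:
            shrunk = ndimage.binary_erosion(lung, _STRUCT6, iterations=iters, border_value=0)
            if not shrunk.any():
                raise ValueError("erosion magnitude removes the whole lung")
            vox[lung & ~shrunk] = 0
        params.update(lung=lung_label, direction=direction, iterations=iters)

    elif category == "exclude_pathology":
        lung_label = int(rng.choice((RIGHT_LUNG, LEFT_LUNG)))
        lung = vox == lung_label
        interior = ndimage.binary_erosion(lung, _STRUCT6, iterations=2, border_value=0)
        target = interior if interior.any() else lung
        center = _pick_voxel(rng, target)
        carved = lung & _ball(vox.shape, vol.spacing, center, magnitude)
        if carved.sum() == lung.sum():
            raise ValueError("carve radius removes the whole lung; reduce magnitude")
        vox[carved] = 0
        params.update(lung=lung_label, radius_mm=magnitude, center=tuple(map(int, center)))

    elif category == "off_target_stitching":
        shift = max(1, int(round(magnitude)))
        nz = vox.shape[2]
        cut = int(rng.integers(nz // 3, 2 * nz // 3))
        axis = int(rng.choice((0, 1)))
        sign = int(rng.choice((-1, 1)))
        if shift >= vox.shape[axis]:
            raise ValueError("stitching shift exceeds the volume extent")
        slab = vox[:, :, :cut]
        shifted = np.zeros_like(slab)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if sign > 0:
            dst[axis], src[axis] = slice(shift, None), slice(None, -shift)
        else:
            dst[axis], src[axis] = slice(None, -shift), slice(shift, None)
        shifted[tuple(dst)] = slab[tuple(src)]
        vox[:, :, :cut] = shifted
        params.update(cut_slice=cut, axis=axis, shift_vox=sign * shift)

    elif category == "include_distant_organ":
        fg = vox > 0
        # keep the blob clear of the lungs and the volume border
        dist_mm = ndimage.distance_transform_edt(~fg, sampling=vol.spacing)
        margin = magnitude + 2 * max(vol.spacing)
        candidates = dist_mm > margin
        candidates[:2], candidates[-2:] = False, False
        candidates[:, :2], candidates[:, -2:] = False, False
        candidates[:, :, :2], candidates[:, :, -2:] = False, False
        if not candidates.any():
            raise ValueError("no room for a distant organ of this radius")
        center = _pick_voxel(rng, candidates)
        blob = _ball(vox.shape, vol.spacing, center, magnitude)
        label = int(rng.choice((RIGHT_LUNG, LEFT_LUNG)))
        vox[blob] = label
        params.update(radius_mm=magnitude, label=label, center=tuple(map(int, center)))

    elif category == "failed_separation":
        if not right.any() or not left.any():
            raise ValueError("failed_separation needs both lungs present")
        c_r = np.array(ndimage.center_of_mass(right))
        c_l = np.array(ndimage.center_of_mass(left))
        mid = np.rint(0.5 * (c_r + c_l)).astype(int)
        x_lo, x_hi = sorted((int(round(c_l[0])), int(round(c_r[0]))))
        bridge = np.zeros_like(vox, dtype=bool)
        ry = max(1, int(round(magnitude / vol.spacing[1])))
        rz = max(1, int(round(magnitude / vol.spacing[2])))
        bridge[
            x_lo : x_hi + 1,
            max(0, mid[1] - ry) : mid[1] + ry + 1,
            max(0, mid[2] - rz) : mid[2] + rz + 1,
        ] = True
        label = int(rng.choice((RIGHT_LUNG, LEFT_LUNG)))
        vox[bridge | right | left] = label
        params.update(label=label, radius_mm=magnitude)

    new = LabelVolume(voxels=vox, spacing=vol.spacing, axis_order=vol.axis_order)
    return new, ErrorRecord(case_id=case_id, category=category, params=params)


# ---------------------------------------------------------------------------
# simulated ensembles


def simulate_ensemble(
    vol: LabelVolume, m: int, magnitude: float, seed: int = 0
) -> list[LabelVolume]:
    """m independently perturbed copies of a label volume.

    Each member perturbs each lung's signed-distance level set with a
    smooth random field of strength ``magnitude`` (in voxels), emulating an
    ensemble of segmentation models that disagree at the boundary.
    Magnitude 0 returns m identical copies. Where the two perturbed lungs
    would overlap, the lung with the larger perturbed level-set value wins.
    """
    if m < 2:
        raise ValueError("need m >= 2 ensemble members")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return [vol.with_voxels(vol.voxels.copy()) for _ in range(m)]
    rng = np.random.default_rng(seed)
    levels = {}
    for label in (RIGHT_LUNG, LEFT_LUNG):
        mask = vol.voxels == label
        if mask.any():
            levels[label] = ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(
                ~mask
            )
    members = []
    for _ in range(m):
        vox = np.zeros(vol.shape, dtype=np.int16)
        best = np.full(vol.shape, -np.inf)
        for label, phi in levels.items():
            noise = _smooth_field(rng, vol.shape, sigma=3.0)
            perturbed = phi + magnitude * noise
            inside = perturbed > 0
            claim = inside & (perturbed > best)
            vox[claim] = label
            best = np.where(claim, perturbed, best)
        members.append(vol.with_voxels(vox))
    return members


# ---------------------------------------------------------------------------
# cohorts and truth tables


#: default injection magnitude sampler per category (rng -> magnitude)
def _default_magnitude(category: str, rng: np.random.Generator) -> float:
    if category == "lr_mislabel":
        return 1.0 if rng.random() < 0.5 else float(rng.uniform(0.25, 0.5))
    if category == "over_under_segmentation":
        return float(rng.integers(1, 3))
    if category == "exclude_pathology":
        return float(rng.uniform(8.0, 15.0))
    if category == "off_target_stitching":
        return float(rng.integers(3, 9))
    if category == "include_distant_organ":
        return float(rng.uniform(6.0, 12.0))
    return float(rng.uniform(5.0, 10.0))  # failed_separation bridge radius


@dataclass(frozen=True)
class CohortCase:
    """Plan for one cohort case: phantom seed plus any error injections.

    Volumes are materialized on demand with :meth:`build`, so truth-table
    work (rater simulation, parameter recovery) never pays for voxel
    synthesis.
    """

    case_id: str
    spec: PhantomSpec
    errors: tuple[tuple[str, float, int], ...] = ()  # (category, magnitude, seed)

    def build(self) -> LabelVolume:
        vol = generate_lung_phantom(self.spec)
        for category, magnitude, seed in self.errors:
            vol, _ = inject_error(vol, category, magnitude, seed, case_id=self.case_id)
        return vol


@dataclass(eq=False)
class CohortTruth:
    """Reference standard for a synthetic cohort."""

    table: pd.DataFrame  # columns: case_id, reference, categories (';'-joined)
    records: dict[str, list[ErrorRecord]]

    @property
    def reference(self) -> np.ndarray:
        return self.table["reference"].to_numpy()

    @property
    def case_ids(self) -> list[str]:
        return self.table["case_id"].tolist()

    def categories_by_case(self) -> dict[str, list[str]]:
        return {cid: [r.category for r in recs] for cid, recs in self.records.items()}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTruth":
        table = pd.read_csv(Path(path), keep_default_na=False)
        records: dict[str, list[ErrorRecord]] = {}
        for _, row in table.iterrows():
            cats = [c for c in str(row["categories"]).split(";") if c]
            if cats:
                records[str(row["case_id"])] = [
                    ErrorRecord(case_id=str(row["case_id"]), category=c) for c in cats
                ]
        return cls(table=table, records=records)


def _draw_categories(
    rng: np.random.Generator, frequencies: Mapping[str, float]
) -> list[str]:
    """Draw >= 1 categories whose unconditional marginals match ``frequencies``.

    A primary category is drawn from the normalized frequencies; each
    category c is then added independently with the top-up probability
    e_c = (p_c − π_c)/(1 − π_c), which makes the overall marginal exactly
    p_c while guaranteeing a non-empty draw.
    """
    cats = list(frequencies)
    p = np.array([frequencies[c] for c in cats], dtype=float)
    pi = p / p.sum()
    primary = rng.choice(len(cats), p=pi)
    chosen = {cats[primary]}
    extra = np.clip((p - pi) / (1.0 - pi), 0.0, 1.0)
    for i, c in enumerate(cats):
        if i != primary and rng.random() < extra[i]:
            chosen.add(c)
    # keep a stable, frequency-ordered injection order
    return [c for c in cats if c in chosen]


def generate_cohort(
    n: int,
    prevalence: float,
    category_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    spec: PhantomSpec | None = None,
) -> tuple[list[CohortCase], CohortTruth]:
    """Plan a cohort of n phantom cases with a fixed error prevalence.

    Exactly ``round(prevalence * n)`` cases receive at least one injected
    error, with categories drawn so their marginal frequencies among error
    cases match ``category_weights`` (default: the observed cohort
    frequencies, co-occurrence included). Deterministic given ``seed``.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    freqs = dict(category_weights or DEFAULT_CATEGORY_FREQUENCIES)
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_pos = int(round(prevalence * n))
    positives = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()

    width = max(4, len(str(max(n - 1, 1))))
    cases: list[CohortCase] = []
    rows = []
    records: dict[str, list[ErrorRecord]] = {}
    for i in range(n):
        cid = f"case_{i:0{width}d}"
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        errors: tuple[tuple[str, float, int], ...] = ()
        cats: list[str] = []
        if i in positives:
            cats = _draw_categories(rng, freqs)
            errors = tuple(
                (c, _default_magnitude(c, rng), int(rng.integers(0, 2**31 - 1))) for c in cats
            )
            records[cid] = [
                ErrorRecord(case_id=cid, category=c, params={"magnitude": m, "seed": s})
                for c, m, s in errors
            ]
        cases.append(CohortCase(case_id=cid, spec=replace(base, seed=phantom_seed), errors=errors))
        rows.append({"case_id": cid, "reference": int(i in positives), "categories": ";".join(cats)})
    truth = CohortTruth(table=pd.DataFrame(rows), records=records)
    return cases, truth


# ---------------------------------------------------------------------------
# simulated raters


def simulate_raters(
    truth: CohortTruth,
    n_raters: int = 5,
    sens: float | Sequence[float] = 0.88,
    spec: float | Sequence[float] = 0.97,
    seed: int = 0,
) -> RatingTable:
    """Conditionally independent binary raters.

    Each rater flags an error case with probability ``sens`` and a clean
    case with probability ``1 − spec``, independently across cases and
    raters (no shared difficulty covariate).
    """
    sens_arr = np.broadcast_to(np.asarray(sens, dtype=float), (n_raters,))
    spec_arr = np.broadcast_to(np.asarray(spec, dtype=float), (n_raters,))
    if ((sens_arr < 0) | (sens_arr > 1) | (spec_arr < 0) | (spec_arr > 1)).any():
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = truth.reference
    p_flag = np.where(ref[:, None] == 1, sens_arr[None, :], 1.0 - spec_arr[None, :])
    ratings = (rng.random((len(ref), n_raters)) < p_flag).astype(int)
    return RatingTable(case_ids=truth.case_ids, reference=ref, ratings=ratings)
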