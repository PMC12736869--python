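"""Diagnostic-accuracy and agreement statistics for rater studies.

Implements the evaluation battery for a QC study in which R raters each
give a binary verdict (error / no error) per case and a reference standard
says whether the segmentation truly contains an error:

* majority rating (flag a case when more than R/2 raters flag it),
* sensitivity/specificity/accuracy/PPV/NPV with exact Clopper–Pearson 95%
  confidence intervals, plus the F1 score,
* ROC analysis over the sum of the R binary ratings with a trapezoid AUC,
  a DeLong confidence interval and Youden-index threshold selection,
* Cochran's Q and pairwise McNemar tests (Bonferroni-adjusted) to compare
  methods' sensitivities/specificities,
* Fleiss' kappa (inter-rater) and Cohen's kappa (intra-rater) with the
  customary Landis–Koch interpretation bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats import inter_rater
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

# ---------------------------------------------------------------------------
# rating tables


@dataclass(eq=False)
class RatingTable:
    """Case × rater binary verdicts plus the reference-standard column."""

    case_ids: list[str]
    reference: np.ndarray  # (n,) 0/1; 1 = error per reference standard
    ratings: np.ndarray  # (n, R) 0/1; 1 = rater flagged an error
    rater_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=int)
        self.ratings = np.asarray(self.ratings, dtype=int)
        n = len(self.case_ids)
        if self.reference.shape != (n,):
            raise ValueError("reference must have one entry per case")
        if self.ratings.ndim != 2 or self.ratings.shape[0] != n or self.ratings.shape[1] < 1:
            raise ValueError("ratings must be a case x rater matrix with R >= 1")
        for name, arr in (("reference", self.reference), ("ratings", self.ratings)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary 0/1 with no missing entries")
        if not self.rater_names:
            self.rater_names = [f"rater{i + 1}" for i in range(self.n_raters)]
        if len(self.rater_names) != self.n_raters:
            raise ValueError("rater_names length must match the rating matrix")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    @property
    def rating_sums(self) -> np.ndarray:
        return self.ratings.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"case_id": self.case_ids, "reference": self.reference})
        for j, name in enumerate(self.rater_names):
            df[name] = self.ratings[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingTable":
        if "case_id" not in df or "reference" not in df:
            raise ValueError("need 'case_id' and 'reference' columns")
        rater_cols = [c for c in df.columns if c not in ("case_id", "reference")]
        if not rater_cols:
            raise ValueError("need at least one rater column")
        if df[rater_cols + ["reference"]].isna().any().any():
            raise ValueError("rating table has missing entries")
        return cls(
            case_ids=df["case_id"].astype(str).tolist(),
            reference=df["reference"].to_numpy(),
            ratings=df[rater_cols].to_numpy(),
            rater_names=rater_cols,
        )

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls.from_dataframe(pd.read_csv(Path(path)))


def majority_rating(t: RatingTable, tie_rule: str | None = None) -> np.ndarray:
    """Flag a case iff more than half of the raters flagged it.

    With an even number of raters exact ties are possible; ``tie_rule``
    must then be ``"positive"`` or ``"negative"``.
    """
    r = t.n_raters
    sums = t.rating_sums
    if r % 2 == 0:
        if tie_rule not in ("positive", "negative"):
            raise ValueError("even rater count: set tie_rule='positive' or 'negative'")
        if tie_rule == "positive":
            return (sums >= r / 2).astype(int)
    return (sums > r / 2).astype(int)


# ---------------------------------------------------------------------------
# confusion counts and diagnostic accuracy


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: Sequence[int], ref: Sequence[int]) -> ConfusionCounts:
    """Standard 2×2 cross-tabulation of predictions against the reference."""
    pred = np.asarray(pred, dtype=int)
    ref = np.asarray(ref, dtype=int)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {ref.shape}")
    return ConfusionCounts(
        tp=int(((pred == 1) & (ref == 1)).sum()),
        fp=int(((pred == 1) & (ref == 0)).sum()),
        fn=int(((pred == 0) & (ref == 1)).sum()),
        tn=int(((pred == 0) & (ref == 0)).sum()),
    )


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta-distribution quantiles."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"need 0 <= successes <= n with n >= 1, got {successes}/{n}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


@dataclass(frozen=True)
class Metric:
    """Proportion with its exact binomial confidence interval."""

    value: float
    ci: tuple[float, float]
    numerator: int
    denominator: int


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: Metric | None
    specificity: Metric | None
    accuracy: Metric | None
    ppv: Metric | None
    npv: Metric | None
    f1: float | None


def _metric(k: int, n: int, level: float) -> Metric | None:
    if n == 0:
        return None
    return Metric(value=k / n, ci=clopper_pearson(k, n, level), numerator=k, denominator=n)


def diagnostic_summary(c: ConfusionCounts, level: float = 0.95) -> DiagnosticSummary:
    """Sensitivity, specificity, accuracy, PPV, NPV (each with an exact CI)
    and F1. Metrics with a zero denominator are reported as ``None``."""
    f1_denom = 2 * c.tp + c.fp + c.fn
    return DiagnosticSummary(
        sensitivity=_metric(c.tp, c.tp + c.fn, level),
        specificity=_metric(c.tn, c.tn + c.fp, level),
        accuracy=_metric(c.tp + c.tn, c.total, level) if c.total else None,
        ppv=_metric(c.tp, c.tp + c.fp, level),
        npv=_metric(c.tn, c.tn + c.fn, level),
        f1=2 * c.tp / f1_denom if f1_denom else None,
    )


# ---------------------------------------------------------------------------
# ROC over rating sums and the DeLong interval


def _delong_auc_variance(scores: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    pos = scores[ref == 1]
    neg = scores[ref == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp_.mean())
    v10 = cmp_.mean(axis=1)  # per-positive placement
    v01 = cmp_.mean(axis=0)  # per-negative placement
    s10 = float(np.var(v10, ddof=1)) if pos.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if neg.size > 1 else 0.0
    return auc, s10 / pos.size + s01 / neg.size


def delong_ci(
    scores: Sequence[float], ref: Sequence[int], level: float = 0.95
) -> tuple[float, float, float]:
    """AUC with a DeLong normal-approximation interval, truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    ref = np.asarray(ref, dtype=int)
    auc, var = _delong_auc_variance(scores, ref)
    z = float(stats.norm.ppf(0.5 + level / 2))
    half = z * math.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


@dataclass(eq=False)
class ROCResult:
    thresholds: np.ndarray  # rating-sum cutoffs c (predict positive when sum > c)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden: np.ndarray  # J = sens + spec - 1 per threshold
    youden_pct: np.ndarray  # sens% + spec% per threshold
    best_threshold: float


def roc_over_rating_sums(t: RatingTable, level: float = 0.95) -> ROCResult:
    """ROC analysis over the per-case sum of the R binary ratings.

    Operating points sit at half-integer cutoffs c = −0.5, 0.5, …, R+0.5
    (predict "error" when the rating sum exceeds c); the AUC is the
    trapezoid area over (1−specificity, sensitivity) and its CI comes from
    the DeLong variance of the underlying rating-sum scores.
    """
    ref = t.reference
    if ref.min() == ref.max():
        raise ValueError("reference must contain both classes for an ROC analysis")
    sums = t.rating_sums
    r = t.n_raters
    thresholds = np.arange(-0.5, r + 1.0)  # -0.5, 0.5, ..., R+0.5
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    n_pos = int((ref == 1).sum())
    n_neg = int((ref == 0).sum())
    for i, c in enumerate(thresholds):
        pred = sums > c
        sens[i] = (pred & (ref == 1)).sum() / n_pos
        spec[i] = (~pred & (ref == 0)).sum() / n_neg
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # walk the staircase from (0,0) to (1,1)
    auc = float(np.trapezoid(sens[order], fpr[order]))
    _, lo, hi = delong_ci(sums, ref, level)
    youden = sens + spec - 1.0
    youden_pct = 100.0 * sens + 100.0 * spec
    best = float(thresholds[int(np.argmax(youden))])  # ties -> lowest cutoff
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=(lo, hi),
        youden=youden,
        youden_pct=youden_pct,
        best_threshold=best,
    )


# ---------------------------------------------------------------------------
# multi-classifier comparisons


def cochran_q(correct: np.ndarray) -> tuple[float, float]:
    """Cochran's Q over a case × method binary matrix (1 = method correct).

    Returns (Q, p) against the chi-squared distribution with
    ``methods − 1`` degrees of freedom. When every case is answered
    identically by all methods there is no discordance to test and
    (0, 1) is returned.
    """
    correct = np.asarray(correct, dtype=int)
    if correct.ndim != 2 or correct.shape[1] < 2:
        raise ValueError("need a case x method matrix with >= 2 methods")
    k = correct.shape[1]
    row_sums = correct.sum(axis=1)
    if int((row_sums * (k - row_sums)).sum()) == 0:  # all rows unanimous
        return 0.0, 1.0
    res = _sm_cochrans_q(correct, return_object=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class McNemarPair:
    i: int
    j: int
    b: int  # i correct, j wrong
    c: int  # i wrong, j correct
    p_raw: float
    p_adjusted: float


def mcnemar_pairwise(
    correct: np.ndarray, adjust: str = "bonferroni", exact_threshold: int = 25
) -> list[McNemarPair]:
    """Pairwise McNemar tests between methods on their discordant counts.

    The exact binomial test is used when the number of discordant pairs is
    below ``exact_threshold``, otherwise the chi-squared form with
    continuity correction. Bonferroni adjustment multiplies each p-value by
    the number of method pairs, capped at 1.
    """
    correct = np.asarray(correct, dtype=int)
    if correct.ndim != 2 or correct.shape[1] < 2:
        raise ValueError("need a case x method matrix with >= 2 methods")
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    pairs = list(combinations(range(correct.shape[1]), 2))
    out = []
    for i, j in pairs:
        b = int(((correct[:, i] == 1) & (correct[:, j] == 0)).sum())
        c = int(((correct[:, i] == 0) & (correct[:, j] == 1)).sum())
        if b + c == 0:
            p = 1.0
        else:
            both = int(((correct[:, i] == 1) & (correct[:, j] == 1)).sum())
            neither = int(((correct[:, i] == 0) & (correct[:, j] == 0)).sum())
            table = [[both, b], [c, neither]]
            exact = (b + c) < exact_threshold
            p = float(_sm_mcnemar(table, exact=exact, correction=True).pvalue)
        p_adj = min(1.0, p * len(pairs)) if adjust == "bonferroni" else p
        out.append(McNemarPair(i=i, j=j, b=b, c=c, p_raw=p, p_adjusted=p_adj))
    return out


# ---------------------------------------------------------------------------
# agreement coefficients


KAPPA_BANDS = (
    (0.00, "poor"),
    (0.21, "slight"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (1.01, "almost perfect"),
)


def kappa_interpretation(kappa: float) -> str:
    """Landis–Koch band: <0 poor, 0–0.20 slight, 0.21–0.40 fair,
    0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect."""
    if kappa < 0.0:
        return "poor"
    for upper, name in KAPPA_BANDS[1:]:
        if kappa < upper:
            return name
    return "almost perfect"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    interpretation: str


def fleiss_kappa(ratings: np.ndarray) -> KappaResult:
    """Fleiss' kappa for R ≥ 2 raters over two categories (flag / no flag)."""
    ratings = np.asarray(ratings, dtype=int)
    if ratings.ndim != 2 or ratings.shape[1] < 2 or ratings.shape[0] < 2:
        raise ValueError("need >= 2 cases and >= 2 raters")
    if not np.isin(ratings, (0, 1)).all():
        raise ValueError("ratings must be binary")
    r = ratings.shape[1]
    sums = ratings.sum(axis=1)
    counts = np.column_stack([r - sums, sums])
    p_cat = counts.sum(axis=0) / counts.sum()
    if float((p_cat**2).sum()) >= 1.0:  # every rating in one category
        raise ValueError("expected agreement is 1 (single category used); kappa undefined")
    k = float(inter_rater.fleiss_kappa(counts, method="fleiss"))
    return KappaResult(kappa=k, interpretation=kappa_interpretation(k))


def cohen_kappa(r1: Sequence[int], r2: Sequence[int]) -> KappaResult:
    """Cohen's kappa between two binary rating vectors (e.g. read/re-read)."""
    r1 = np.asarray(r1, dtype=int)
    r2 = np.asarray(r2, dtype=int)
    if r1.shape != r2.shape or r1.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    p1, p2 = r1.mean(), r2.mean()
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1 (constant ratings); kappa undefined")
    k = float(cohen_kappa_score(r1, r2))
    return KappaResult(kappa=k, interpretation=kappa_interpretation(k))


# ---------------------------------------------------------------------------
# study-level evaluation


def _metric_dict(m: Metric | None) -> dict | None:
    if m is None:
        return None
    return {
        "value": m.value,
        "ci": list(m.ci),
        "numerator": m.numerator,
        "denominator": m.denominator,
    }


def evaluate_method(t: RatingTable, level: float = 0.95) -> dict:
    """Full single-method battery: per-rater accuracy, majority-rating
    diagnostic summary, ROC over rating sums, and Fleiss' kappa."""
    per_rater = {}
    for j, name in enumerate(t.rater_names):
        s = diagnostic_summary(confusion(t.ratings[:, j], t.reference), level)
        per_rater[name] = summary_dict(s)
    pred = majority_rating(t) if t.n_raters % 2 == 1 else majority_rating(t, tie_rule="negative")
    counts = confusion(pred, t.reference)
    majority = summary_dict(diagnostic_summary(counts, level))
    roc = roc_over_rating_sums(t, level)
    try:
        kappa = fleiss_kappa(t.ratings)
        kappa_out = {"kappa": kappa.kappa, "interpretation": kappa.interpretation}
    except ValueError as exc:
        kappa_out = {"kappa": None, "interpretation": str(exc)}
    return {
        "n_cases": t.n_cases,
        "n_raters": t.n_raters,
        "per_rater": per_rater,
        "majority": majority,
        "confusion": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn},
        "roc": {
            "thresholds": roc.thresholds.tolist(),
            "sensitivity": roc.sensitivity.tolist(),
            "specificity": roc.specificity.tolist(),
            "auc": roc.auc,
            "auc_ci": list(roc.auc_ci),
            "youden": roc.youden.tolist(),
            "youden_pct": roc.youden_pct.tolist(),
            "best_threshold": roc.best_threshold,
        },
        "fleiss": kappa_out,
    }


def summary_dict(s: DiagnosticSummary) -> dict:
    return {
        "sensitivity": _metric_dict(s.sensitivity),
        "specificity": _metric_dict(s.specificity),
        "accuracy": _metric_dict(s.accuracy),
        "ppv": _metric_dict(s.ppv),
        "npv": _metric_dict(s.npv),
        "f1": s.f1,
    }


def compare_methods(tables: Mapping[str, RatingTable], level: float = 0.95) -> dict:
    """Compare methods' sensitivities and specificities.

    Cochran's Q runs on the correctness indicators (majority rating equals
    reference) separately within reference-positive cases (a sensitivity
    comparison) and reference-negative cases (specificity), followed by
    Bonferroni-adjusted pairwise McNemar tests.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need >= 2 methods to compare")
    ref = None
    correct_cols = []
    for name in names:
        t = tables[name]
        if ref is None:
            ref = t.reference
        elif not np.array_equal(ref, t.reference):
            raise ValueError("all methods must share the same reference standard")
        pred = majority_rating(t) if t.n_raters % 2 == 1 else majority_rating(t, tie_rule="negative")
        correct_cols.append((pred == ref).astype(int))
    correct = np.column_stack(correct_cols)
    out = {}
    for key, mask in (("sensitivity", ref == 1), ("specificity", ref == 0)):
        sub = correct[mask]
        q, p = cochran_q(sub)
        pairs = [
            {
                "methods": [names[pr.i], names[pr.j]],
                "b": pr.b,
                "c": pr.c,
                "p_raw": pr.p_raw,
                "p_adjusted": pr.p_adjusted,
            }
            for pr in mcnemar_pairwise(sub)
        ]
        out[key] = {"cochran_q": q, "p": p, "pairwise_mcnemar": pairs}
    return out


def subgroup_sensitivity(
    t: RatingTable, categories: Mapping[str, Sequence[str]], level: float = 0.95
) -> dict:
    """Sensitivity of the majority rating within each error category.

    ``categories`` maps case_id -> list of category names; a case may carry
    several. Only reference-positive cases enter the per-category counts.
    """
    pred = majority_rating(t) if t.n_raters % 2 == 1 else majority_rating(t, tie_rule="negative")
    by_cat: dict[str, list[int]] = {}
    for idx, cid in enumerate(t.case_ids):
        if t.reference[idx] != 1:
            continue
        for cat in categories.get(cid, []):
            by_cat.setdefault(cat, []).append(idx)
    out = {}
    for cat, idxs in sorted(by_cat.items()):
        hits = int(pred[idxs].sum())
        out[cat] = _metric_dict(_metric(hits, len(idxs), level))
    return out


def stratified_summary(
    t: RatingTable, strata: Mapping[str, str], level: float = 0.95
) -> dict:
    """Per-stratum sensitivity and specificity of the majority rating.

    ``strata`` maps case_id -> stratum label (e.g. min/median/max
    uncertainty). Pooling the per-stratum counts reproduces the overall
    confusion counts exactly.
    """
    pred = majority_rating(t) if t.n_raters % 2 == 1 else majority_rating(t, tie_rule="negative")
    out = {}
    for stratum in sorted(set(strata.values())):
        idxs = [i for i, cid in enumerate(t.case_ids) if strata.get(cid) == stratum]
        if not idxs:
            continue
        c = confusion(pred[idxs], t.reference[idxs])
        out[stratum] = {
            "sensitivity": _metric_dict(_metric(c.tp, c.tp + c.fn, level)),
            "specificity": _metric_dict(_metric(c.tn, c.tn + c.fp, level)),
            "confusion": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
        }
    return out


def render_report_markdown(results: Mapping[str, dict], comparison: dict | None = None) -> str:
    """Markdown report: one diagnostic-accuracy block per method plus the
    optional method comparison."""

    def pct(m: dict | None) -> str:
        if m is None:
            return "n/a"
        lo, hi = m["ci"]
        return f"{100 * m['value']:.1f}% [{100 * lo:.1f}%; {100 * hi:.1f}%]"

    lines = ["# Segmentation QC rating report", ""]
    for name, res in results.items():
        maj = res["majority"]
        roc = res["roc"]
        lines += [
            f"## {name}",
            "",
            f"Cases: {res['n_cases']}, raters: {res['n_raters']}",
            "",
            "| Metric | Majority rating |",
            "|---|---|",
            f"| Sensitivity | {pct(maj['sensitivity'])} |",
            f"| Specificity | {pct(maj['specificity'])} |",
            f"| Accuracy | {pct(maj['accuracy'])} |",
            f"| PPV | {pct(maj['ppv'])} |",
            f"| NPV | {pct(maj['npv'])} |",
            f"| F1-score | {maj['f1']:.3f} |" if maj["f1"] is not None else "| F1-score | n/a |",
            "",
            f"AUC over rating sums: {roc['auc']:.3f} "
            f"[{roc['auc_ci'][0]:.3f}; {roc['auc_ci'][1]:.3f}], "
            f"best threshold > {roc['best_threshold']:g} positive ratings",
        ]
        if res["fleiss"]["kappa"] is not None:
            lines.append(
                f"Fleiss' kappa: {res['fleiss']['kappa']:.2f} ({res['fleiss']['interpretation']})"
            )
        lines.append("")
    if comparison:
        lines += ["## Method comparison", ""]
        for key in ("sensitivity", "specificity"):
            blk = comparison[key]
            lines.append(f"Cochran's Q ({key}): Q = {blk['cochran_q']:.2f}, p = {blk['p']:.3g}")
            for pr in blk["pairwise_mcnemar"]:
                a, b = pr["methods"]
                lines.append(f"  - {a} vs {b}: adjusted p = {pr['p_adjusted']:.3g}")
            lines.append("")
    return "\n".join(lines)
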