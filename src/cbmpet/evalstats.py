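"""Concordance classification and diagnostic agreement statistics.

Localization calls are graded against the surgical field: conclusive
concordance (CC) when the top-ranked cluster's peak lies inside the
field; partial concordance (PC) when only a lower-ranked or overlapping
cluster matches and a secondary modality supports it; discordance (DC)
otherwise.  For the 2x2 analysis only CC counts as "surgically removed"
— an unaided correct localization — which, crossed with seizure outcome
(Engel IA = seizure-free), yields TP/FP/FN/TN and the derived
sensitivity, specificity, PPV, NPV (Clopper-Pearson 95% CIs), Cohen's
kappa with its large-sample z-test, and McNemar's exact test between
method pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import AmbiguityError, UndefinedStatisticError, ValidationError

__all__ = [
    "CC",
    "PC",
    "DC",
    "LocalizationCall",
    "ConfusionTable",
    "classify_concordance",
    "engel_seizure_free",
    "build_confusion",
    "diagnostics",
    "cohens_kappa",
    "mcnemar",
    "mcnemar_from_calls",
    "recover_confusion_from_rates",
    "diagnostic_report",
]

CC = "CC"
PC = "PC"
DC = "DC"


@dataclass
class LocalizationCall:
    subject_id: str
    method: str  # "cbm" | "tmap" | "visual"
    concordance: str  # CC | PC | DC

    def __post_init__(self) -> None:
        if self.concordance not in (CC, PC, DC):
            raise ValidationError(f"concordance must be CC/PC/DC, got {self.concordance}")


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for k in ("tp", "fp", "fn", "tn"):
            if getattr(self, k) < 0:
                raise ValidationError(f"{k} must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion table must count at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


def _cluster_vertices(cluster) -> np.ndarray:
    if hasattr(cluster, "vertex_ids"):
        return np.asarray(cluster.vertex_ids)
    return np.asarray(cluster.voxels)


def _peak_inside(cluster, mask: np.ndarray) -> bool:
    if mask.ndim == 1:
        return bool(mask[int(cluster.peak_vertex)])
    return bool(mask[tuple(cluster.peak_voxel)])


def _overlaps(cluster, mask: np.ndarray) -> bool:
    members = _cluster_vertices(cluster)
    if mask.ndim == 1:
        return bool(mask[members].any())
    return bool(mask[tuple(members.T)].any())


def classify_concordance(clusters, surgical_mask: np.ndarray, secondary_supported: bool = False) -> str:
    """CC / PC / DC for a ranked cluster list against the surgical field.

    ``clusters`` must be sorted most hypometabolic first (as produced by
    the pipelines).  Works for surface clusters (1-D vertex mask) and
    voxel clusters (3-D mask) alike.
    """
    surgical_mask = np.asarray(surgical_mask, dtype=bool)
    if not surgical_mask.any():
        raise ValidationError("surgical mask is empty")
    if clusters and _peak_inside(clusters[0], surgical_mask):
        return CC
    if secondary_supported and any(_overlaps(c, surgical_mask) for c in clusters):
        return PC
    return DC


def engel_seizure_free(engel: str) -> tuple[bool, bool]:
    """Map an Engel class to (seizure_free, flagged).

    Only Engel IA counts as seizure-free; IB-ID are treated as not
    seizure-free (they are excluded from the IA definition) and flagged
    for transparency.
    """
    grade = engel.strip().upper()
    if grade == "IA":
        return True, False
    flagged = grade in ("IB", "IC", "ID")
    return False, flagged


def build_confusion(calls, outcomes) -> ConfusionTable:
    """Cross CC-vs-not localization with seizure outcome.

    ``calls``: per-subject concordance (CC/PC/DC strings or
    :class:`LocalizationCall`); ``outcomes``: per-subject seizure-free
    booleans.  Only CC counts as "PET result surgically removed"; PC
    needs a secondary modality and maps to not-removed in this primary
    analysis.
    """
    if len(calls) == 0:
        raise ValidationError("no subjects")
    if len(calls) != len(outcomes):
        raise ValidationError("calls and outcomes differ in length")
    tp = fp = fn = tn = 0
    for call, sf in zip(calls, outcomes):
        conc = call.concordance if isinstance(call, LocalizationCall) else call
        if conc not in (CC, PC, DC):
            raise ValidationError(f"invalid concordance {conc!r}")
        if sf is None:
            raise ValidationError("missing outcome for a subject")
        inside = conc == CC
        if inside and sf:
            tp += 1
        elif inside and not sf:
            fp += 1
        elif not inside and sf:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp, fp, fn, tn)


def _ratio_ci(k: int, n: int) -> dict:
    if n == 0:
        return {"value": float("nan"), "ci": (float("nan"), float("nan")), "undefined": True}
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")  # Clopper-Pearson
    return {"value": k / n, "ci": (float(lo), float(hi)), "undefined": False}


def diagnostics(table: ConfusionTable) -> dict:
    """Sensitivity, specificity, PPV, NPV with Clopper-Pearson 95% CIs.

    Ratios with a zero denominator come back flagged ``undefined`` (NaN)
    rather than raising.
    """
    tp, fp, fn, tn = table.as_tuple()
    return {
        "sensitivity": _ratio_ci(tp, tp + fn),
        "specificity": _ratio_ci(tn, tn + fp),
        "ppv": _ratio_ci(tp, tp + fp),
        "npv": _ratio_ci(tn, tn + fn),
    }


def cohens_kappa(table: ConfusionTable) -> tuple[float, float]:
    """Cohen's kappa for the 2x2 table and its large-sample z-test p-value.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal fraction and
    p_e from the row/column marginals; the null SE follows the standard
    large-sample formula, p two-sided.
    """
    tp, fp, fn, tn = table.as_tuple()
    n = table.total
    p_o = (tp + tn) / n
    row = np.array([tp + fp, fn + tn]) / n
    col = np.array([tp + fn, fp + tn]) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        raise UndefinedStatisticError("kappa undefined: degenerate marginals (p_e = 1)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    var0_num = p_e + p_e**2 - float(np.sum(row * col * (row + col)))
    se0 = math.sqrt(max(var0_num, 0.0)) / ((1.0 - p_e) * math.sqrt(n))
    if se0 == 0:
        p = float("nan")
    else:
        p = 2.0 * float(stats.norm.sf(abs(kappa / se0)))
    return float(kappa), p


def mcnemar(b: int, c: int) -> float:
    """McNemar's test on discordant-pair counts (b, c).

    Exact two-sided binomial when b + c < 25, otherwise chi-square with
    continuity correction; b = c = 0 returns 1.0 by convention.
    """
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return 1.0
    if m < 25:
        return float(stats.binomtest(min(b, c), m, 0.5).pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / m
    return float(stats.chi2.sf(chi2, df=1))


def mcnemar_from_calls(calls_a, calls_b) -> float:
    """Paired McNemar between two methods on CC-vs-not classifications."""
    if len(calls_a) != len(calls_b):
        raise ValidationError("paired calls differ in length")
    conc = lambda c: (c.concordance if isinstance(c, LocalizationCall) else c) == CC
    b = sum(1 for x, y in zip(calls_a, calls_b) if conc(x) and not conc(y))
    c = sum(1 for x, y in zip(calls_a, calls_b) if not conc(x) and conc(y))
    return mcnemar(b, c)


def recover_confusion_from_rates(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionTable:
    """Integer confusion table matching printed rates by exhaustive search.

    Minimizes |tp/n_pos - sens| + |tn/n_neg - spec| over all integer
    (tp, tn); raises :class:`AmbiguityError` when the minimizer is not
    unique at 3-decimal tolerance.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValidationError("group sizes must be positive")
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValidationError("rates must be in [0, 1]")
    tps, tns = np.meshgrid(np.arange(n_pos + 1), np.arange(n_neg + 1), indexing="ij")
    obj = np.abs(tps / n_pos - sensitivity) + np.abs(tns / n_neg - specificity)
    candidates = np.argwhere(obj <= obj.min() + 1e-3)
    if len(candidates) != 1:
        raise AmbiguityError(
            f"rates are ambiguous; candidate (tp, tn) pairs: {candidates.tolist()}"
        )
    tp, tn = (int(x) for x in candidates[0])
    return ConfusionTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def diagnostic_report(calls, outcomes) -> dict:
    """Full per-method report: rates with CIs, kappa (with p), CC rate."""
    table = build_confusion(calls, outcomes)
    kappa, kappa_p = cohens_kappa(table)
    n_sf = sum(1 for sf in outcomes if sf)
    conc = [c.concordance if isinstance(c, LocalizationCall) else c for c in calls]
    cc_in_sf = sum(1 for c, sf in zip(conc, outcomes) if sf and c == CC)
    return {
        "confusion": table.as_tuple(),
        **diagnostics(table),
        "kappa": kappa,
        "kappa_p": kappa_p,
        "cc_rate": cc_in_sf / n_sf if n_sf else float("nan"),
    }
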