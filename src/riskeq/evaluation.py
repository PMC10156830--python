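"""Model fit and selection-incentive metrics.

Individual-level fit is summarized by the weighted R-squared and
Cumming's Prediction Measure (CPM), its absolute-error analogue.
Selection incentives are read from group-level **mean financial results**
(MFR): the insured-year weighted mean of predicted minus actual spending
over a subgroup, so a negative MFR means the group is undercompensated
and financially unattractive to insurers.  Families of groups (the
dxgroups, multimorbidity strata, chronic conditions) are summarized by
the weighted mean absolute financial result (WMAFR) and by the share of
groups whose MFR falls inside a +/- bracket.

Significance of a nonzero MFR is assessed with a weighted one-sample
z-test using the Kish effective sample size; the same construction,
applied to the paired per-person difference in predictions, tests
whether two models compensate a group differently.  This normal
approximation is a pragmatic choice for heavily skewed spending and is
flagged as such in reports; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .population import PersonRecord, ValidationError

__all__ = [
    "GroupResult",
    "r_squared",
    "cpm",
    "mfr",
    "wmafr",
    "bracket_share",
    "undercompensation_brackets",
    "multimorbidity_partition",
    "compare_models",
    "count_significant_negative",
]


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float((w * x).sum() / w.sum())


def _check_fit_inputs(y, yhat, w):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (y.shape == yhat.shape == w.shape):
        raise ValidationError("y, yhat and w must align")
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    if np.allclose(y, y[0]):
        raise ValidationError("constant outcome: fit measures undefined")
    return y, yhat, w


def r_squared(y, yhat, w) -> float:
    """Weighted R^2: 1 - sum w (y-yhat)^2 / sum w (y-ybar_w)^2."""
    y, yhat, w = _check_fit_inputs(y, yhat, w)
    ybar = _weighted_mean(y, w)
    return 1.0 - float((w * (y - yhat) ** 2).sum()
                       / (w * (y - ybar) ** 2).sum())


def cpm(y, yhat, w) -> float:
    """Cumming's Prediction Measure: like R^2 but with absolute errors."""
    y, yhat, w = _check_fit_inputs(y, yhat, w)
    ybar = _weighted_mean(y, w)
    return 1.0 - float((w * np.abs(y - yhat)).sum()
                       / (w * np.abs(y - ybar)).sum())


@dataclass(frozen=True)
class GroupResult:
    """Under/overcompensation summary for one subgroup.

    ``mfr`` is euros per person-year, predicted minus actual, so
    negative values flag undercompensation.  ``n_weighted`` is the
    group's insured-years.
    """

    group_id: str
    n_weighted: float
    n_members: int
    mfr: float
    se: float
    p_value: float


def _weighted_mean_test(d: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """(mean, SE, two-sided p) for a weighted mean via Kish effective n."""
    mean = _weighted_mean(d, w)
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    var = _weighted_mean((d - mean) ** 2, w)
    if var <= 0.0 or n_eff <= 1.0:
        se = 0.0
        p = 1.0 if mean == 0.0 else 0.0
    else:
        se = float(np.sqrt(var / n_eff))
        p = float(2.0 * sps.norm.sf(abs(mean) / se))
    return mean, se, p


def mfr(
    members: np.ndarray,
    y: np.ndarray,
    yhat: np.ndarray,
    w: np.ndarray,
    group_id: str = "",
) -> GroupResult:
    """Mean financial result of a subgroup given by indices or a mask."""
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.nonzero(members)[0]
    if len(members) == 0:
        raise ValidationError(f"empty group {group_id!r}")
    d = np.asarray(yhat, dtype=float)[members] - np.asarray(y, dtype=float)[members]
    wg = np.asarray(w, dtype=float)[members]
    mean, se, p = _weighted_mean_test(d, wg)
    return GroupResult(
        group_id=group_id,
        n_weighted=float(wg.sum()),
        n_members=int(len(members)),
        mfr=mean,
        se=se,
        p_value=p,
    )


def wmafr(results: Sequence[GroupResult]) -> float:
    """Group-size weighted mean of |MFR| over a family of groups."""
    if not results:
        raise ValidationError("no groups")
    n = np.array([r.n_weighted for r in results])
    if n.sum() <= 0:
        raise ValidationError("all groups carry zero insured-years")
    a = np.array([abs(r.mfr) for r in results])
    return float((n * a).sum() / n.sum())


def bracket_share(results: Sequence[GroupResult], bound: float = 500.0) -> float:
    """Share of groups with |MFR| <= bound (boundary inclusive)."""
    if bound <= 0:
        raise ValidationError("bound must be positive")
    inside = sum(1 for r in results if abs(r.mfr) <= bound)
    return inside / len(results)


def undercompensation_brackets(
    results: Sequence[GroupResult],
    bounds: Sequence[float] = (250.0, 500.0),
) -> dict[str, float]:
    """Among negative-MFR groups, the share within each [-bound, 0) bracket.

    Returns ``{"n_negative": ..., "within_250": share, ...}``; shares are
    relative to the number of undercompensated groups.
    """
    negative = [r for r in results if r.mfr < 0]
    out: dict[str, float] = {"n_negative": float(len(negative))}
    for bound in bounds:
        if negative:
            share = sum(1 for r in negative if r.mfr >= -bound) / len(negative)
        else:
            share = 0.0
        out[f"within_{int(bound)}"] = share
    return out


def multimorbidity_partition(
    records: Sequence[PersonRecord],
    by: str = "dxgroups",
    top_bin: int = 8,
) -> dict[str, np.ndarray]:
    """Partition persons by their dxgroup (or condition) count.

    Strata are labelled ``"0", "1", ..., f"{top_bin}+"``; the top bin is
    open-ended.  Only non-empty strata are returned, in count order, and
    their insured-year weighted frequencies sum to one over the sample.
    """
    if by == "dxgroups":
        counts = np.array([len(r.dxgroups) for r in records])
    elif by == "conditions":
        counts = np.array([len(r.conditions) for r in records])
    else:
        raise ValidationError(f"unknown partition key {by!r}")
    strata: dict[str, np.ndarray] = {}
    for c in range(top_bin):
        idx = np.nonzero(counts == c)[0]
        if len(idx):
            strata[str(c)] = idx
    idx = np.nonzero(counts >= top_bin)[0]
    if len(idx):
        strata[f"{top_bin}+"] = idx
    return strata


def compare_models(
    yhat_a: np.ndarray,
    yhat_b: np.ndarray,
    groups: Mapping[str, np.ndarray],
    w: np.ndarray,
) -> dict[str, GroupResult]:
    """Paired per-group test of the prediction difference a - b.

    Both models must predict the same persons; for each group the
    weighted mean of ``yhat_a - yhat_b`` is tested against zero, which
    equals the difference between the two models' MFRs for that group
    (the actual spending cancels in the pairing).
    """
    yhat_a = np.asarray(yhat_a, dtype=float)
    yhat_b = np.asarray(yhat_b, dtype=float)
    w = np.asarray(w, dtype=float)
    if yhat_a.shape != yhat_b.shape or yhat_a.shape != w.shape:
        raise ValidationError("model predictions are not aligned")
    d = yhat_a - yhat_b
    out: dict[str, GroupResult] = {}
    for gid, idx in groups.items():
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        mean, se, p = _weighted_mean_test(d[idx], w[idx])
        out[gid] = GroupResult(
            group_id=gid,
            n_weighted=float(w[idx].sum()),
            n_members=int(len(idx)),
            mfr=mean,
            se=se,
            p_value=p,
        )
    return out


def count_significant_negative(
    results: Sequence[GroupResult], alpha: float = 0.01
) -> int:
    """Number of groups with a significantly negative MFR at level alpha."""
    return sum(1 for r in results if r.mfr < 0 and r.p_value < alpha)
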