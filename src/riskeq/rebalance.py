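"""Rebalancing a morbidity-enriched subsample to population margins.

GP-style samples over-represent morbidity, so before subgroup results
are computed on them their weights are raked: iterative proportional
fitting (IPF) cyclically rescales per-person weights until the weighted
marginal frequency of every class of every raked classification matches
the population's.  Weights start from the persons' insured fractions,
so the raked weights remain insured-year weights.

A residual difference in mean spending survives raking (the margins
constrain risk classes, not spending); :func:`spending_correction`
removes it, multiplicatively by default so spending stays non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .population import AGE_GENDER, PersonRecord, ValidationError

__all__ = [
    "RakingSpec",
    "RakingWeights",
    "population_margins",
    "ipf_rake",
    "spending_correction",
]


@dataclass(frozen=True)
class RakingSpec:
    """Which classifications to rake on, and when to stop.

    Each dimension must partition the sample (every person in exactly
    one class); convergence is the maximum relative discrepancy between
    weighted marginal shares and their targets after a full cycle.
    """

    dimensions: tuple[str, ...]
    tolerance: float = 1e-8
    max_iterations: int = 1000


@dataclass(frozen=True)
class RakingWeights:
    """Per-person multiplicative weights plus the convergence report."""

    weights: np.ndarray
    iterations: int
    max_discrepancy: float
    converged: bool
    report: dict = field(default_factory=dict)


def _person_class(rec: PersonRecord, dim: str) -> str:
    if dim == AGE_GENDER:
        return rec.age_gender_label
    try:
        return rec.adjuster_flags[dim]
    except KeyError as exc:
        raise ValidationError(
            f"person {rec.person_id} has no class for dimension {dim!r}"
        ) from exc


def population_margins(
    records: Sequence[PersonRecord],
    dimensions: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Insured-year weighted marginal shares per raking dimension."""
    out: dict[str, dict[str, float]] = {}
    w = np.array([r.insured_fraction for r in records])
    total = float(w.sum())
    for dim in dimensions:
        shares: dict[str, float] = {}
        for rec, wi in zip(records, w):
            label = _person_class(rec, dim)
            shares[label] = shares.get(label, 0.0) + float(wi)
        out[dim] = {k: v / total for k, v in sorted(shares.items())}
    return out


def ipf_rake(
    sample: Sequence[PersonRecord],
    targets: Mapping[str, Mapping[str, float]],
    spec: RakingSpec,
) -> RakingWeights:
    """Iterative proportional fitting of sample weights to target margins.

    Weights are initialized at the persons' insured fractions and, for
    each dimension in turn, every class's weights are scaled by
    target-share over current-share.  Because each dimension partitions
    the sample and targets sum to one, the total weight is preserved.
    Stops when the maximum relative discrepancy over all dimensions
    falls within ``spec.tolerance``, or reports non-convergence with the
    best discrepancy reached.
    """
    n = len(sample)
    if n == 0:
        raise ValidationError("empty sample")
    w = np.array([r.insured_fraction for r in sample], dtype=float)

    memberships: dict[str, dict[str, np.ndarray]] = {}
    target_arrays: dict[str, dict[str, float]] = {}
    for dim in spec.dimensions:
        if dim not in targets:
            raise ValidationError(f"no targets for raking dimension {dim!r}")
        tot = sum(targets[dim].values())
        if abs(tot - 1.0) > 1e-6:
            raise ValidationError(
                f"targets for dimension {dim!r} sum to {tot}, expected 1"
            )
        labels = [_person_class(rec, dim) for rec in sample]
        classes: dict[str, list[int]] = {}
        for i, lab in enumerate(labels):
            classes.setdefault(lab, []).append(i)
        for cls, share in targets[dim].items():
            if share > 0 and cls not in classes:
                raise ValidationError(
                    f"target class {dim}:{cls} is empty in the sample"
                )
        extra = set(classes) - set(targets[dim])
        if extra:
            raise ValidationError(
                f"sample classes without targets in dimension {dim!r}: "
                f"{sorted(extra)}"
            )
        memberships[dim] = {
            cls: np.asarray(idx, dtype=int) for cls, idx in classes.items()
        }
        target_arrays[dim] = {
            cls: float(share) for cls, share in targets[dim].items()
        }

    def max_discrepancy() -> float:
        total = w.sum()
        worst = 0.0
        for dim in spec.dimensions:
            for cls, idx in memberships[dim].items():
                share = w[idx].sum() / total
                t = target_arrays[dim][cls]
                if t > 0:
                    worst = max(worst, abs(share - t) / t)
                else:
                    worst = max(worst, share)
        return float(worst)

    disc = max_discrepancy()
    iterations = 0
    while disc > spec.tolerance and iterations < spec.max_iterations:
        for dim in spec.dimensions:
            total = w.sum()
            for cls, idx in memberships[dim].items():
                share = w[idx].sum() / total
                t = target_arrays[dim][cls]
                if share > 0:
                    w[idx] *= t / share
        iterations += 1
        disc = max_discrepancy()

    return RakingWeights(
        weights=w,
        iterations=iterations,
        max_discrepancy=disc,
        converged=disc <= spec.tolerance,
        report={
            "dimensions": list(spec.dimensions),
            "tolerance": spec.tolerance,
            "iteration_order": "cyclic, in the order given",
            "criterion": "max relative marginal discrepancy after a full cycle",
        },
    )


def spending_correction(
    spending: np.ndarray,
    weights: np.ndarray,
    target_mean: float,
    mode: str = "multiplicative",
) -> tuple[np.ndarray, float]:
    """Align the weighted sample mean of spending with ``target_mean``.

    Multiplicative mode (default) scales every spending value by
    target over current weighted mean, preserving non-negativity and
    scale invariance; additive mode shifts by the difference instead.
    Returns the corrected vector and the factor (or shift) applied.
    """
    spending = np.asarray(spending, dtype=float)
    weights = np.asarray(weights, dtype=float)
    current = float((weights * spending).sum() / weights.sum())
    if mode == "multiplicative":
        if current <= 0:
            raise ValidationError("weighted sample mean must be positive")
        factor = target_mean / current
        return spending * factor, factor
    if mode == "additive":
        shift = target_mean - current
        return spending + shift, shift
    raise ValidationError(f"unknown correction mode {mode!r}")
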