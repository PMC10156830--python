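"""Building diagnosis-based cost groups (DCGs) from dxgroups.

Two competing designs are implemented:

* **Traditional two-layer scheme** — dxgroups are ranked by their mean
  residual spending from the partial model and clustered with weighted
  1-D Ward agglomeration into a primary layer (default 15 pDCGs) and a
  secondary layer (default 7 sDCGs).  A person is flagged by at most one
  pDCG (driven by their highest-ranked dxgroup) and one sDCG (their
  second-highest); any further dxgroups are ignored.

* **Interval multi-qualification scheme** — every dxgroup enters the
  full model as its own dummy; the resulting coefficients are sorted and
  greedily swept into clusters whose coefficient range does not exceed a
  configured width (default EUR 500).  The greedy sweep provably
  minimizes the cluster count among contiguous partitions under a range
  constraint on sorted 1-D data.  A person then contributes a *count* to
  every DCG containing any of their dxgroups — including multiple counts
  in one DCG — so multimorbidity is compensated in full.

Candidate diagnoses are screened beforehand on persistence (share of
year-1 patients diagnosed again in year 2, threshold one third),
prevalence and mean spending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .calibration import CalibratedModel
from .population import PersonRecord, ValidationError
from .synthetic import ClaimsHistory

__all__ = [
    "DxgroupStats",
    "DCGScheme",
    "ScreeningReport",
    "screen_dxgroups",
    "dxgroup_stats",
    "ward_cluster_1d",
    "interval_cluster",
    "build_traditional_scheme",
    "assign_traditional",
    "build_multi_scheme",
    "assign_multi",
    "traditional_columns",
    "multi_columns",
]

PERSISTENCE_THRESHOLD = 1.0 / 3.0


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningReport:
    retained: tuple[str, ...]
    excluded: dict[str, tuple[str, ...]]  # diagnosis -> failed criteria
    metrics: dict[str, dict[str, float]]


def screen_dxgroups(
    history: ClaimsHistory,
    persistence_threshold: float = PERSISTENCE_THRESHOLD,
    min_prevalence: float = 0.0005,
    min_mean_spending: float = 500.0,
) -> ScreeningReport:
    """Retain candidate diagnoses meeting all three criteria (inclusive).

    A diagnosis is kept iff its persistence (share of year-1 patients
    also diagnosed in year 2) is at least the threshold AND its
    prevalence and mean related spending are at least their thresholds.
    """
    if not history.diagnoses:
        raise ValidationError("empty candidate diagnosis set")
    retained: list[str] = []
    excluded: dict[str, tuple[str, ...]] = {}
    metrics: dict[str, dict[str, float]] = {}
    for diag in history.diagnoses:
        n1 = len(diag.year1)
        persistence = (len(diag.year1 & diag.year2) / n1) if n1 else 0.0
        prevalence = n1 / history.n_persons
        mean_spending = (
            float(np.mean(list(diag.spending.values()))) if diag.spending else 0.0
        )
        metrics[diag.diagnosis_id] = {
            "persistence": persistence,
            "prevalence": prevalence,
            "mean_spending": mean_spending,
        }
        reasons = []
        if persistence < persistence_threshold:
            reasons.append("persistence")
        if prevalence < min_prevalence:
            reasons.append("prevalence")
        if mean_spending < min_mean_spending:
            reasons.append("mean_spending")
        if reasons:
            excluded[diag.diagnosis_id] = tuple(reasons)
        else:
            retained.append(diag.diagnosis_id)
    return ScreeningReport(tuple(retained), excluded, metrics)


# ---------------------------------------------------------------------------
# Per-dxgroup statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DxgroupStats:
    """Weighted summary of one dxgroup's members.

    ``mean_residual`` (euros/yr from the partial model) is the statistic
    the traditional method clusters on; ``coefficient`` (euros/yr from
    the full-dummy model) is what the interval method clusters on.
    Either may be ``None`` when the corresponding input is not supplied,
    and all fields are ``None`` for a dxgroup with zero flagged
    insured-years.
    """

    dxgroup_id: str
    prevalence: float
    n_weighted: float
    mean_residual: float | None = None
    coefficient: float | None = None

    @property
    def defined(self) -> bool:
        return self.n_weighted > 0


def dxgroup_stats(
    records: Sequence[PersonRecord],
    catalogue: Sequence[str],
    residuals: np.ndarray | None = None,
    model: CalibratedModel | None = None,
) -> list[DxgroupStats]:
    """Weighted prevalence, mean residual and coefficient per dxgroup.

    Mean residual spending for a dxgroup is the insured-year weighted
    mean of the partial-model residuals over its flagged persons;
    prevalence is the flagged share of total insured-years.
    """
    w = np.array([r.insured_fraction for r in records])
    total_w = float(w.sum())
    coef_lookup: dict[str, float] = {}
    if model is not None:
        for label, coef in zip(model.columns, model.coefficients):
            if label.startswith("dx:"):
                coef_lookup[label[3:]] = float(coef)
    members: dict[str, list[int]] = {g: [] for g in catalogue}
    for i, rec in enumerate(records):
        for g in rec.dxgroups:
            if g in members:  # stats only for the requested catalogue
                members[g].append(i)
    out: list[DxgroupStats] = []
    for g in catalogue:
        idx = np.asarray(members[g], dtype=int)
        wg = float(w[idx].sum()) if len(idx) else 0.0
        if wg == 0.0:
            warnings.warn(
                f"dxgroup {g} has zero flagged insured-years; "
                "its statistics are undefined",
                stacklevel=2,
            )
            out.append(DxgroupStats(g, 0.0, 0.0))
            continue
        mean_res = (
            float((w[idx] * residuals[idx]).sum() / wg)
            if residuals is not None else None
        )
        out.append(
            DxgroupStats(
                dxgroup_id=g,
                prevalence=wg / total_w,
                n_weighted=wg,
                mean_residual=mean_res,
                coefficient=coef_lookup.get(g),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Clustering primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Clustering:
    """Partition of ids into clusters, with the recorded merge trace."""

    clusters: tuple[tuple[str, ...], ...]
    merge_trace: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...] = ()

    def mapping(self) -> dict[str, int]:
        return {g: c for c, ids in enumerate(self.clusters) for g in ids}


def ward_cluster_1d(
    values: Sequence[float],
    weights: Sequence[float],
    k: int,
    ids: Sequence[str] | None = None,
) -> Clustering:
    """Weighted 1-D Ward agglomeration down to ``k`` clusters.

    Repeatedly merges the pair of clusters (a, b) minimizing the
    within-variance increase ``W_a W_b / (W_a + W_b) * (m_a - m_b)^2``,
    the merged cluster taking the weighted mean of its members.  Ties
    are broken by the smaller combined weighted mean, then by the
    lexicographically smallest member ids, so the merge trace is fully
    deterministic.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(len(values))]
    if not (len(values) == len(weights) == len(ids)):
        raise ValidationError("values, weights and ids must align")
    if np.any(weights <= 0):
        raise ValidationError("ward weights must be strictly positive")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite ward values")
    if not 1 <= k <= len(values):
        raise ValidationError(f"k={k} outside [1, {len(values)}]")

    clusters = [
        {"ids": (ids[i],), "w": float(weights[i]), "m": float(values[i])}
        for i in range(len(values))
    ]
    trace: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                wa, wb = ca["w"], cb["w"]
                delta = wa * wb / (wa + wb) * (ca["m"] - cb["m"]) ** 2
                merged_mean = (wa * ca["m"] + wb * cb["m"]) / (wa + wb)
                key = (delta, merged_mean, tuple(sorted(ca["ids"] + cb["ids"])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ca, cb = clusters[a], clusters[b]
        trace.append((ca["ids"], cb["ids"], best[0][0]))
        merged = {
            "ids": ca["ids"] + cb["ids"],
            "w": ca["w"] + cb["w"],
            "m": (ca["w"] * ca["m"] + cb["w"] * cb["m"]) / (ca["w"] + cb["w"]),
        }
        clusters = [c for j, c in enumerate(clusters) if j not in (a, b)]
        clusters.append(merged)
    # stable presentation: order clusters by their weighted mean
    clusters.sort(key=lambda c: (c["m"], c["ids"]))
    return Clustering(
        tuple(tuple(sorted(c["ids"])) for c in clusters), tuple(trace)
    )


def interval_cluster(
    values: Mapping[str, float] | Sequence[float],
    max_range: float = 500.0,
    ids: Sequence[str] | None = None,
) -> Clustering:
    """Minimal contiguous partition with cluster range <= ``max_range``.

    Values are sorted ascending and swept left to right; a new cluster
    opens whenever the current value exceeds the open cluster's minimum
    by more than ``max_range``.  For a range constraint on sorted 1-D
    data this greedy sweep yields the minimum possible number of
    clusters.
    """
    if isinstance(values, Mapping):
        ids = list(values.keys())
        vals = np.array([values[g] for g in ids], dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(len(vals))]
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite coefficients in interval clustering")
    if max_range < 0:
        raise ValidationError("max_range must be non-negative")
    order = np.lexsort((np.asarray(ids, dtype=object), vals))
    clusters: list[list[str]] = []
    cluster_min = None
    for j in order:
        v = float(vals[j])
        if cluster_min is None or v - cluster_min > max_range:
            clusters.append([])
            cluster_min = v
        clusters[-1].append(ids[j])
    return Clustering(tuple(tuple(c) for c in clusters))


# ---------------------------------------------------------------------------
# Schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DCGScheme:
    """A dxgroup -> DCG mapping plus per-DCG statistics.

    ``method`` is ``"traditional"`` (two mappings, one per layer, plus
    the severity ranking) or ``"interval"`` (a single multi-qualification
    mapping with the clustered coefficient recorded per DCG).
    """

    method: str
    labels: tuple[str, ...]  # DCG labels, design-column order
    mapping: dict[str, str]  # primary layer for traditional
    secondary_mapping: dict[str, str] = field(default_factory=dict)
    ranking: tuple[str, ...] = ()  # dxgroups, most severe first
    cluster_stats: dict[str, dict] = field(default_factory=dict)
    max_range: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("traditional", "interval"):
            raise ValidationError(f"unknown scheme method {self.method!r}")


def _cluster_stats(clustering: Clustering, values: Mapping[str, float],
                   prefix: str) -> tuple[tuple[str, ...], dict[str, str], dict]:
    labels = tuple(f"{prefix}{c + 1:02d}" for c in range(len(clustering.clusters)))
    mapping: dict[str, str] = {}
    stats: dict[str, dict] = {}
    for label, members in zip(labels, clustering.clusters):
        vals = [values[g] for g in members]
        stats[label] = {
            "members": list(members),
            "min": float(min(vals)),
            "max": float(max(vals)),
        }
        for g in members:
            mapping[g] = label
    return labels, mapping, stats


def build_traditional_scheme(
    stats: Sequence[DxgroupStats],
    n_primary: int = 15,
    n_secondary: int = 7,
) -> DCGScheme:
    """Two-layer scheme: Ward clusters of mean residual spending.

    Dxgroups are ranked by mean residual spending (the severity order
    used to pick a person's primary and secondary dxgroup); the same
    means are clustered once into ``n_primary`` pDCGs and once into
    ``n_secondary`` sDCGs.
    """
    usable = [s for s in stats if s.defined]
    if any(s.mean_residual is None for s in usable):
        raise ValidationError("traditional scheme requires mean residuals")
    if len(usable) < max(n_primary, n_secondary):
        raise ValidationError("fewer dxgroups than requested clusters")
    values = {s.dxgroup_id: float(s.mean_residual) for s in usable}
    weights = {s.dxgroup_id: s.n_weighted for s in usable}
    ids = [s.dxgroup_id for s in usable]
    ranking = tuple(
        sorted(ids, key=lambda g: (-values[g], g))
    )
    primary = ward_cluster_1d(
        [values[g] for g in ids], [weights[g] for g in ids], n_primary, ids
    )
    secondary = ward_cluster_1d(
        [values[g] for g in ids], [weights[g] for g in ids], n_secondary, ids
    )
    # label layers from the most expensive cluster down
    p_labels, p_map, p_stats = _cluster_stats(
        Clustering(tuple(reversed(primary.clusters))), values, "pDCG"
    )
    s_labels, s_map, s_stats = _cluster_stats(
        Clustering(tuple(reversed(secondary.clusters))), values, "sDCG"
    )
    return DCGScheme(
        method="traditional",
        labels=p_labels + s_labels,
        mapping=p_map,
        secondary_mapping=s_map,
        ranking=ranking,
        cluster_stats={**p_stats, **s_stats},
    )


def assign_traditional(
    dxgroups: Iterable[str], scheme: DCGScheme
) -> tuple[str | None, str | None]:
    """(pDCG, sDCG) flags for one person under the two-layer scheme.

    The primary flag comes from the person's highest-ranked dxgroup, the
    secondary flag from the second-highest; persons with fewer dxgroups
    get ``None`` for the missing layer and any further dxgroups are
    ignored.
    """
    if scheme.method != "traditional":
        raise ValidationError("scheme is not a traditional two-layer scheme")
    rank = {g: i for i, g in enumerate(scheme.ranking)}
    try:
        ordered = sorted(dxgroups, key=lambda g: rank[g])
    except KeyError as exc:
        raise ValidationError(f"dxgroup {exc.args[0]!r} not in scheme") from exc
    p = scheme.mapping[ordered[0]] if len(ordered) >= 1 else None
    s = scheme.secondary_mapping[ordered[1]] if len(ordered) >= 2 else None
    return p, s


def build_multi_scheme(
    model: CalibratedModel, max_range: float = 500.0
) -> DCGScheme:
    """Interval multi-qualification scheme from full-dummy coefficients."""
    coefs = {
        label[3:]: float(c)
        for label, c in zip(model.columns, model.coefficients)
        if label.startswith("dx:")
    }
    if not coefs:
        raise ValidationError("model has no per-dxgroup (dx:) columns")
    clustering = interval_cluster(coefs, max_range=max_range)
    labels, mapping, stats = _cluster_stats(clustering, coefs, "DCG")
    return DCGScheme(
        method="interval",
        labels=labels,
        mapping=mapping,
        cluster_stats=stats,
        max_range=max_range,
    )


def assign_multi(dxgroups: Iterable[str], scheme: DCGScheme) -> np.ndarray:
    """Count vector over DCGs: one count per qualifying dxgroup, no cap."""
    if scheme.method != "interval":
        raise ValidationError("scheme is not an interval multi scheme")
    index = {label: j for j, label in enumerate(scheme.labels)}
    counts = np.zeros(len(scheme.labels))
    for g in dxgroups:
        try:
            counts[index[scheme.mapping[g]]] += 1
        except KeyError as exc:
            raise ValidationError(f"dxgroup {g!r} not in scheme") from exc
    return counts


# ---------------------------------------------------------------------------
# Design-matrix columns for calibrating models with DCG adjusters
# ---------------------------------------------------------------------------


def traditional_columns(
    records: Sequence[PersonRecord], scheme: DCGScheme
) -> tuple[list[str], sparse.csr_matrix]:
    """0/1 pDCG and sDCG dummy columns (at most one flag per layer)."""
    index = {label: j for j, label in enumerate(scheme.labels)}
    rows: list[int] = []
    cols: list[int] = []
    for i, rec in enumerate(records):
        p, s = assign_traditional(rec.dxgroups, scheme)
        for flag in (p, s):
            if flag is not None:
                rows.append(i)
                cols.append(index[flag])
    mat = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(records), len(scheme.labels)),
    )
    return [f"dcg:{label}" for label in scheme.labels], mat


def multi_columns(
    records: Sequence[PersonRecord], scheme: DCGScheme
) -> tuple[list[str], sparse.csr_matrix]:
    """Count-valued DCG columns under multi-qualification."""
    index = {label: j for j, label in enumerate(scheme.labels)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for i, rec in enumerate(records):
        seen: dict[int, int] = {}
        for g in rec.dxgroups:
            try:
                j = index[scheme.mapping[g]]
            except KeyError as exc:
                raise ValidationError(f"dxgroup {g!r} not in scheme") from exc
            seen[j] = seen.get(j, 0) + 1
        for j, c in seen.items():
            rows.append(i)
            cols.append(j)
            data.append(float(c))
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(records), len(scheme.labels))
    )
    return [f"dcg:{label}" for label in scheme.labels], mat
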