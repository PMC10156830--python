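"""Weighted least-squares calibration of risk-equalization models.

Payment weights are the coefficients of an individual-level regression
of annualized spending on the risk-class dummies, weighted by each
person's insured fraction.  Two calibrations matter downstream:

* the *partial* model (age-gender and pharmacy cost groups only), whose
  per-dxgroup mean residual spending drives the traditional Ward
  clustering into DCGs; and
* the *full-dummy* model, with one indicator per dxgroup, whose
  coefficients drive the interval clustering of the new method.

The solver uses the normal equations with iterative refinement on the
original least-squares residual, so the weighted orthogonality defect
``max_j |sum_i w_i x_ij r_i|`` is pushed to rounding level.  Rank
deficiency is an error naming the dependent columns, never silent
dropping: dropped columns would silently corrupt the alignment between
scheme classes and payment weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .population import (
    DesignMatrix,
    PersonRecord,
    RiskAdjusterScheme,
    ValidationError,
    build_design,
)

__all__ = [
    "RankDeficiencyError",
    "CalibratedModel",
    "fit_wls",
    "predict",
    "fit_partial",
]

#: Relative tolerance for the weighted residual-orthogonality invariant:
#: max_j |sum_i w_i x_ij r_i| <= ORTHO_TOL * sum(w) * weighted mean |y|.
ORTHO_TOL = 1e-6

PARTIAL_CLASSIFICATIONS = ("age_gender", "pcg")


class RankDeficiencyError(ValidationError):
    """Design matrix is rank deficient; carries the dependent columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = tuple(columns)
        super().__init__(
            "design matrix is rank deficient; merge or drop empty/aliased "
            f"classes: {list(columns)}"
        )


@dataclass(frozen=True)
class CalibratedModel:
    """Fitted WLS model: payment weights plus per-person fit vectors."""

    columns: tuple[str, ...]
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    weights: np.ndarray
    diagnostics: dict

    def coefficient(self, label: str) -> float:
        return float(self.coefficients[self.columns.index(label)])

    def to_json(self, path) -> None:
        payload = {
            "columns": list(self.columns),
            "coefficients": [float(c) for c in self.coefficients],
            "diagnostics": {k: (float(v) if np.isscalar(v) else v)
                            for k, v in self.diagnostics.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def coefficients_from_json(path) -> dict[str, float]:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return dict(zip(payload["columns"],
                        map(float, payload["coefficients"])))


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite values in {name}")


def fit_wls(design: DesignMatrix, y: np.ndarray | None = None,
            w: np.ndarray | None = None) -> CalibratedModel:
    """Minimize sum_i w_i (y_i - x_i beta)^2 over beta.

    ``y`` and ``w`` default to the outcome and weight vectors carried by
    the design matrix.  Deterministic; raises
    :class:`RankDeficiencyError` naming the aliased columns when the
    weighted design loses rank.
    """
    X = design.matrix
    y = design.y if y is None else np.asarray(y, dtype=float)
    w = design.w if w is None else np.asarray(w, dtype=float)
    n, p = X.shape
    if y.shape != (n,) or w.shape != (n,):
        raise ValidationError("y/w not aligned with design rows")
    _check_finite("y", y)
    _check_finite("w", w)
    if w.min() <= 0:
        raise ValidationError("weights must be strictly positive")

    Xw = X.multiply(w[:, None]).tocsr()
    A = (X.T @ Xw).toarray()
    b = X.T @ (w * y)

    # rank-revealing check on the (PSD) normal matrix
    _, R, piv = linalg.qr(A, pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p:
        raise RankDeficiencyError([design.columns[j] for j in piv[rank:]])

    c, low = linalg.cho_factor(A, check_finite=False)
    beta = linalg.cho_solve((c, low), b, check_finite=False)
    # iterative refinement against the original LS problem: drive the
    # weighted orthogonality defect X'W(y - X beta) to rounding level
    for _ in range(3):
        r = y - X @ beta
        g = X.T @ (w * r)
        beta = beta + linalg.cho_solve((c, low), g, check_finite=False)

    fitted = X @ beta
    residuals = y - fitted
    defect = float(np.max(np.abs(X.T @ (w * residuals))))
    scale = float(w.sum() * max(np.abs(y * w).sum() / w.sum(), 1.0))
    diagnostics = {
        "n": n,
        "p": p,
        "rank": rank,
        "max_weighted_orthogonality": defect,
        "orthogonality_relative": defect / scale,
    }
    if defect > ORTHO_TOL * scale:
        raise ValidationError(
            f"orthogonality defect {defect:.3e} exceeds tolerance"
        )
    return CalibratedModel(
        columns=design.columns,
        coefficients=beta,
        fitted=fitted,
        residuals=residuals,
        weights=w,
        diagnostics=diagnostics,
    )


def predict(model: CalibratedModel, design: DesignMatrix) -> np.ndarray:
    """Predicted spending ``X beta`` for a design with matching columns."""
    if design.columns != model.columns:
        raise ValidationError(
            "design columns do not match the calibrated model"
        )
    return design.matrix @ model.coefficients


def fit_partial(
    records: Sequence[PersonRecord],
    scheme: RiskAdjusterScheme,
    classifications: Sequence[str] = PARTIAL_CLASSIFICATIONS,
) -> CalibratedModel:
    """The traditional method's partial model.

    Regresses spending on age-gender and the pharmacy cost groups alone;
    the residuals (with weighted mean zero, by orthogonality to the
    exhaustive age-gender block) are what each dxgroup's mean residual
    spending is computed from.
    """
    sub = scheme.subset(classifications)
    design = build_design(records, sub)
    return fit_wls(design)
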