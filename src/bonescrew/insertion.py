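"""Insertion-torque model and single-parameter strength identification.

Insertion torque is modelled as cutting plus thread friction,

    τ(φ) = σucs·G1 + μT·σucs·(φ − α/2)·G2,

linear in the one unknown, the host material's ultimate compressive strength
σucs (MPa). Identification is therefore a through-origin linear least squares
with regressor x(φ) = G1 + μT·G2·(φ − α/2) and has the closed form
σ̂ = Σ τᵢxᵢ / Σ xᵢ², evaluated without iteration.

The scikit-learn estimator :class:`InsertionStrengthRegressor` is the primary
interface; :func:`predict_insertion_torque` and :func:`identify_strength` are
thin functional wrappers over the same arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import EstimationError
from .geometry import (
    InsertionCoefficients,
    ScrewGeometry,
    derive_insertion_coefficients,
)

__all__ = [
    "StrengthEstimate",
    "predict_insertion_torque",
    "identify_strength",
    "InsertionStrengthRegressor",
]


@dataclass(frozen=True)
class StrengthEstimate:
    """Identified material strength with fit diagnostics.

    ``sse`` is the sum of squared torque residuals (N·mm²); ``fit_range`` the
    (min, max) rotation actually used after excluding the φ < α/2 cutting-only
    regime; ``negative`` flags a (non-physical) negative least-squares
    solution, returned rather than clipped so callers can QC it.
    """

    sigma_ucs: float
    n_samples: int
    sse: float
    fit_range: tuple[float, float]
    negative: bool = False


def _regressor(rotation: np.ndarray, coeffs: InsertionCoefficients,
               mu_thread: float) -> np.ndarray:
    return coeffs.g1 + mu_thread * coeffs.g2 * (rotation - coeffs.alpha / 2.0)


def predict_insertion_torque(
    rotation: np.ndarray,
    sigma_ucs: float,
    coeffs: InsertionCoefficients,
    mu_thread: float,
) -> np.ndarray:
    """Forward insertion-torque model τ(φ), elementwise in rotation (rad).

    For φ < α/2 the friction term would be negative (the tapered tip has not
    yet cut a full thread); it is clamped to zero there while the cutting term
    σ·G1 is retained.
    """
    rotation = np.asarray(rotation, dtype=float)
    if sigma_ucs < 0:
        raise EstimationError("sigma_ucs must be >= 0")
    friction = mu_thread * coeffs.g2 * np.maximum(rotation - coeffs.alpha / 2.0, 0.0)
    return sigma_ucs * (coeffs.g1 + friction)


def identify_strength(
    rotation: np.ndarray,
    torque: np.ndarray,
    coeffs: InsertionCoefficients,
    mu_thread: float,
) -> StrengthEstimate:
    """Closed-form least-squares strength from an insertion segment.

    Minimises Σ (τᵢ − σ·xᵢ)² over σ with xᵢ = G1 + μT·G2·(φᵢ − α/2);
    samples with φ < α/2 are excluded (the clamped model is ill-described
    there). Deterministic, no iteration.
    """
    rotation = np.asarray(rotation, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if rotation.shape != torque.shape:
        raise EstimationError("rotation and torque must have equal length")
    if rotation.size == 0:
        raise EstimationError("empty insertion segment")
    keep = rotation >= coeffs.alpha / 2.0
    rotation, torque = rotation[keep], torque[keep]
    if rotation.size == 0:
        raise EstimationError(
            "no samples at or past the taper offset alpha/2; nothing to fit")
    x = _regressor(rotation, coeffs, mu_thread)
    denom = float(x @ x)
    if denom == 0.0:
        raise EstimationError("degenerate regressor (all x = 0)")
    sigma = float(torque @ x) / denom
    resid = torque - sigma * x
    return StrengthEstimate(
        sigma_ucs=sigma,
        n_samples=int(rotation.size),
        sse=float(resid @ resid),
        fit_range=(float(rotation.min()), float(rotation.max())),
        negative=sigma < 0,
    )


class InsertionStrengthRegressor(RegressorMixin, BaseEstimator):
    """Through-origin regression of insertion torque on rotation.

    A scikit-learn estimator around the physical insertion model: ``fit``
    identifies the single strength parameter σucs from a (rotation, torque)
    segment, ``predict`` evaluates the forward model.

    Parameters
    ----------
    geometry : ScrewGeometry or None
        Screw/hole parameters; ``None`` selects the HB 6.5 reference geometry.
    mu_thread : float or None
        Thread friction coefficient; ``None`` uses the geometry's value.
    taper_offset_policy : {"from-taper-geometry", "explicit-value"}
        Policy for the engagement offset α (see geometry module).
    alpha : float or None
        Explicit α (rad) for the ``"explicit-value"`` policy.

    Attributes
    ----------
    sigma_ucs_ : float
        Identified ultimate compressive strength (MPa).
    sse_ : float
        Sum of squared torque residuals (N·mm²).
    n_samples_ : int
        Samples used after the φ < α/2 exclusion.
    fit_range_ : tuple of float
        (min, max) rotation used (rad).
    coeffs_ : InsertionCoefficients
        Derived model coefficients.

    Examples
    --------
    >>> reg = InsertionStrengthRegressor().fit([10.0, 20.0, 30.0],
    ...                                        [100.0, 180.0, 260.0])
    >>> round(reg.sigma_ucs_, 4)
    2.0287
    """

    def __init__(self, geometry: ScrewGeometry | None = None,
                 mu_thread: float | None = None,
                 taper_offset_policy: str = "from-taper-geometry",
                 alpha: float | None = None):
        self.geometry = geometry
        self.mu_thread = mu_thread
        self.taper_offset_policy = taper_offset_policy
        self.alpha = alpha

    def _resolve(self) -> tuple[InsertionCoefficients, float]:
        geom = self.geometry if self.geometry is not None else ScrewGeometry.hb65()
        coeffs = derive_insertion_coefficients(
            geom, taper_offset_policy=self.taper_offset_policy, alpha=self.alpha)
        mu = geom.mu_thread if self.mu_thread is None else float(self.mu_thread)
        return coeffs, mu

    @staticmethod
    def _as_rotation(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise EstimationError("X must be 1-D rotation or shape (n, 1)")
            arr = arr[:, 0]
        elif arr.ndim != 1:
            raise EstimationError("X must be 1-D rotation or shape (n, 1)")
        return arr

    def fit(self, X, y) -> "InsertionStrengthRegressor":
        """Identify σucs from rotation ``X`` (rad) and torque ``y`` (N·mm)."""
        rotation = self._as_rotation(X)
        coeffs, mu = self._resolve()
        est = identify_strength(rotation, np.asarray(y, dtype=float), coeffs, mu)
        self.coeffs_ = coeffs
        self.mu_thread_ = mu
        self.sigma_ucs_ = est.sigma_ucs
        self.sse_ = est.sse
        self.n_samples_ = est.n_samples
        self.fit_range_ = est.fit_range
        self.estimate_ = est
        return self

    def predict(self, X) -> np.ndarray:
        """Forward-model torque (N·mm) at rotations ``X`` (rad)."""
        if not hasattr(self, "sigma_ucs_"):
            raise EstimationError("estimator is not fitted")
        rotation = self._as_rotation(X)
        return predict_insertion_torque(
            rotation, max(self.sigma_ucs_, 0.0), self.coeffs_, self.mu_thread_)
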