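"""Thread-stripping torque prediction from an identified material strength.

The host material fails by shear of the internal threads over the cylindrical
envelope of the screw (area AC = π·Ds·L) when the screw is tightened against
the plate. With shear direction θτ on that envelope the failure torque is

    τfail = (σucs/√3) · AC · [ (1/3)·(Dhead³ − Dshaft³)/(Dhead² − Dshaft²)·μH·sin θτ
                               − (Ds/2)·cos θτ ],

linear in σucs (θτ is obtuse, so the −cos θτ term is a positive
head-friction-independent contribution). A stress-concentration factor kt ≥ 1
for sharp thread tips is applied, when requested, by dividing τfail by kt —
a brittle-failure bound; ductile materials redistribute local stress and sit
nearer the uncorrected value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import GeometryError
from .geometry import (
    ScrewGeometry,
    StrippingCoefficients,
    derive_stripping_coefficients,
)

__all__ = ["StrippingPrediction", "predict_stripping_torque",
           "stripping_torque_ductility_interpolated"]


@dataclass(frozen=True)
class StrippingPrediction:
    """Predicted stripping torque, with and without stress concentration.

    ``tau_fail`` is the headline value selected by ``kt_mode``;
    ``tau_fail_kt`` is NaN when kt is undefined and no explicit value was
    given.
    """

    sigma_ucs: float
    tau_fail_no_kt: float
    tau_fail_kt: float
    kt_used: float
    kt_mode: str

    @property
    def tau_fail(self) -> float:
        return self.tau_fail_no_kt if self.kt_mode == "none" else self.tau_fail_kt


def _base_torque(sigma_ucs: float, geom: ScrewGeometry,
                 coeffs: StrippingCoefficients) -> float:
    dhead, dshaft = geom.head_diameter, geom.shank_diameter
    head_term = ((dhead ** 3 - dshaft ** 3) / (dhead ** 2 - dshaft ** 2) / 3.0
                 * geom.mu_head * math.sin(coeffs.shear_angle))
    envelope_term = geom.major_diameter / 2.0 * math.cos(coeffs.shear_angle)
    return (sigma_ucs / math.sqrt(3.0) * coeffs.envelope_area
            * (head_term - envelope_term))


def predict_stripping_torque(
    sigma_ucs: float,
    geom: ScrewGeometry,
    coeffs: StrippingCoefficients | None = None,
    kt_mode: str = "none",
    kt_value: float | None = None,
) -> StrippingPrediction:
    """Convert a strength (MPa) into a predicted stripping torque (N·mm).

    Parameters
    ----------
    sigma_ucs : float
        Identified ultimate compressive strength, >= 0.
    geom : ScrewGeometry
    coeffs : StrippingCoefficients, optional
        Derived from ``geom`` when omitted.
    kt_mode : {"none", "full", "value"}
        ``"none"`` reports the uncorrected torque as the headline value
        (ductile limit, the default); ``"full"`` divides by the geometric kt
        (brittle limit; error if kt is undefined for this geometry);
        ``"value"`` divides by the user-supplied ``kt_value``.
    kt_value : float, optional
        Explicit stress-concentration factor for ``kt_mode="value"``.

    Notes
    -----
    Both bounds are always present on the result so cohort reports can show
    the two 1:1 scales; ``tau_fail_kt`` is NaN when no kt is available.
    """
    if sigma_ucs < 0:
        raise GeometryError("sigma_ucs must be >= 0")
    if coeffs is None:
        coeffs = derive_stripping_coefficients(geom)
    tau_no = _base_torque(sigma_ucs, geom, coeffs)

    if kt_mode == "value":
        if kt_value is None:
            raise GeometryError("kt_mode='value' requires kt_value")
        kt = float(kt_value)
    elif kt_mode == "full":
        if not coeffs.kt_defined:
            raise GeometryError(
                "stress concentration factor undefined for this geometry "
                f"(gamma = {coeffs.gamma:.4g} <= 0); use kt_mode='none' or "
                "kt_mode='value' with an explicit kt_value")
        kt = coeffs.kt
    elif kt_mode == "none":
        kt = coeffs.kt if coeffs.kt_defined else math.nan
    else:
        raise GeometryError(f"unknown kt_mode {kt_mode!r}")

    tau_kt = tau_no / kt if math.isfinite(kt) else math.nan
    return StrippingPrediction(
        sigma_ucs=sigma_ucs, tau_fail_no_kt=tau_no, tau_fail_kt=tau_kt,
        kt_used=kt, kt_mode=kt_mode)


def stripping_torque_ductility_interpolated(
    sigma_ucs: float,
    geom: ScrewGeometry,
    ductility_weight: float,
    coeffs: StrippingCoefficients | None = None,
    kt_value: float | None = None,
) -> float:
    """Experimental: interpolate between the ductile and brittle bounds.

    Returns τfail / kt**d for d in [0, 1]: d = 0 is the uncorrected ductile
    limit, d = 1 the fully stress-concentrated brittle limit. A correction
    curve of this form is speculative and excluded from default reports.
    """
    if not 0.0 <= ductility_weight <= 1.0:
        raise GeometryError("ductility_weight must lie in [0, 1]")
    if coeffs is None:
        coeffs = derive_stripping_coefficients(geom)
    pred = predict_stripping_torque(sigma_ucs, geom, coeffs)
    if ductility_weight == 0.0:
        return pred.tau_fail_no_kt
    kt = float(kt_value) if kt_value is not None else coeffs.kt
    if not math.isfinite(kt):
        raise GeometryError(
            "kt undefined for this geometry; supply kt_value explicitly")
    return pred.tau_fail_no_kt / kt ** ductility_weight
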