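"""Screw/hole geometry and the closed-form model coefficients derived from it.

Internal units are mm, MPa, N·mm and radians throughout the package, so that
MPa·mm³ = N·mm and the model equations carry no hidden conversion factors.
Configuration files (YAML/JSON) use degrees and are converted at this boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ConfigError, GeometryError

__all__ = [
    "ScrewGeometry",
    "InsertionCoefficients",
    "StrippingCoefficients",
    "derive_insertion_coefficients",
    "derive_stripping_coefficients",
    "load_geometry",
]

#: Mapping of config-file keys to (field name, conversion to internal units).
_CONFIG_KEYS: dict[str, tuple[str, float]] = {
    "hole_diameter_mm": ("hole_diameter", 1.0),
    "major_diameter_mm": ("major_diameter", 1.0),
    "shank_diameter_mm": ("shank_diameter", 1.0),
    "head_diameter_mm": ("head_diameter", 1.0),
    "minor_diameter_mm": ("minor_diameter", 1.0),
    "half_angle_deg": ("half_angle", math.pi / 180.0),
    "pitch_mm": ("pitch", 1.0),
    "thread_length_mm": ("thread_length", 1.0),
    "mu_thread": ("mu_thread", 1.0),
    "mu_head": ("mu_head", 1.0),
    "end_taper_deg": ("end_taper", math.pi / 180.0),
}


@dataclass(frozen=True)
class ScrewGeometry:
    """Dimensional and friction parameters of a screw/pilot-hole pairing.

    Parameters
    ----------
    hole_diameter : float
        Pilot hole diameter ``Dh`` (mm).
    major_diameter : float
        Screw major (outer thread) diameter ``Ds`` (mm).
    shank_diameter : float
        Shank diameter at the screw head ``Dshaft`` (mm).
    head_diameter : float
        Diameter of the head contact surface ``Dhead`` (mm).
    minor_diameter : float
        Thread minor (core) diameter ``Dminor`` (mm).
    half_angle : float
        Half the included angle of the trapezoidal thread profile ``β`` (rad).
    pitch : float
        Axial advance per revolution ``p`` (mm).
    thread_length : float
        Threaded length ``L`` (mm).
    mu_thread : float
        Thread–host friction coefficient ``μT``.
    mu_head : float
        Head–plate friction coefficient ``μH``.
    end_taper : float
        Taper half-angle of the cutting tip ``θt`` (rad).
    """

    hole_diameter: float
    major_diameter: float
    shank_diameter: float
    head_diameter: float
    minor_diameter: float
    half_angle: float
    pitch: float
    thread_length: float
    mu_thread: float
    mu_head: float
    end_taper: float

    def __post_init__(self) -> None:
        checks = [
            (self.hole_diameter > 0, "hole_diameter must be > 0"),
            (self.major_diameter > self.hole_diameter,
             "major_diameter must exceed hole_diameter"),
            (self.pitch > 0, "pitch must be > 0"),
            (0 < self.half_angle < math.pi / 2,
             "half_angle must lie in (0, pi/2) rad"),
            (self.thread_length > 0, "thread_length must be > 0"),
            (self.mu_thread >= 0, "mu_thread must be >= 0"),
            (self.mu_head >= 0, "mu_head must be >= 0"),
            (self.shank_diameter > 0, "shank_diameter must be > 0"),
            (self.head_diameter > self.shank_diameter,
             "head_diameter must exceed shank_diameter"),
            (self.minor_diameter > 0, "minor_diameter must be > 0"),
            (self.end_taper > 0, "end_taper must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise GeometryError(msg)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "ScrewGeometry":
        """Build a geometry from a config mapping (degree/mm keyed, see docs)."""
        kwargs: dict[str, float] = {}
        for key, (name, scale) in _CONFIG_KEYS.items():
            if key not in cfg:
                raise ConfigError(f"geometry config missing key {key!r}")
            try:
                kwargs[name] = float(cfg[key]) * scale
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"geometry key {key!r} is not numeric") from exc
        extra = set(cfg) - set(_CONFIG_KEYS) - {"alpha_rad"}
        if extra:
            raise ConfigError(f"unknown geometry keys: {sorted(extra)}")
        return cls(**kwargs)

    @classmethod
    def hb65(cls) -> "ScrewGeometry":
        """ISO 5835 HB 6.5 cancellous screw in a 3.2 mm pilot hole.

        The reference configuration used throughout: μT = 0.2 (screw vs. rigid
        PU foam), μH = 0.45 (titanium head on titanium plate).
        """
        return cls(
            hole_diameter=3.2,
            major_diameter=6.5,
            shank_diameter=2.8,
            head_diameter=7.0,
            minor_diameter=3.0,
            half_angle=math.radians(15.0),
            pitch=2.75,
            thread_length=30.0,
            mu_thread=0.2,
            mu_head=0.45,
            end_taper=math.radians(60.0),
        )


@dataclass(frozen=True)
class InsertionCoefficients:
    """Closed-form coefficients of the insertion-torque model.

    ``G1`` (mm³) multiplies strength for the cutting torque, ``G2`` (mm³)
    multiplies strength × rotation for the friction torque; ``alpha`` (rad)
    is the taper engagement offset so the friction term grows with
    ``(φ − α/2)``.
    """

    pitch_angle: float      # θ, rad
    friction_radius: float  # rf, mm
    cutting_radius: float   # rs, mm
    kf0: float              # mm²
    cut_area: float         # Ac, mm²
    g1: float               # mm³
    g2: float               # mm³
    alpha: float            # rad
    alpha_policy: str = field(default="from-taper-geometry")


@dataclass(frozen=True)
class StrippingCoefficients:
    """Closed-form coefficients of the thread-stripping model.

    ``kt`` is NaN when the tip-sharpness ratio γ = (Dshaft − Dminor)/p is not
    positive; consumers must then run without stress concentration or supply a
    value explicitly.
    """

    shear_angle: float    # θτ, rad
    envelope_area: float  # AC = π·Ds·L, mm²
    gamma: float          # dimensionless
    kt: float             # dimensionless; NaN when undefined

    @property
    def kt_defined(self) -> bool:
        return math.isfinite(self.kt)


def derive_insertion_coefficients(
    geom: ScrewGeometry,
    taper_offset_policy: str = "from-taper-geometry",
    alpha: float | None = None,
) -> InsertionCoefficients:
    """Derive the insertion-model coefficients from screw/hole geometry.

    θ = atan(p / (π·Ds)) is the pitch (helix) angle at the major diameter,
    rf = (Dh + Ds)/4 and rs = (2Dh + 2Ds)/6 the effective friction/cutting
    radii, Ac = tanβ · ((Ds − Dh)/2)² the thread cross-section cutting into
    the hole wall, and

        Kf0 = (Ds − Dh)/2 · (1 + tan²β) · sqrt(((Ds + Dh)/4)² + (p/2π)²).

    These combine into G1 = rs·Ac/cosθ (cutting) and G2 = 2·rf·Kf0/cosθ
    (friction).

    Parameters
    ----------
    geom : ScrewGeometry
    taper_offset_policy : {"from-taper-geometry", "explicit-value"}
        How to obtain the engagement offset α. The default derives it from
        the tip taper: α = 2π·Ltaper/p with Ltaper = (Ds − Dh)/(2·tan θt),
        i.e. the rotation needed for the tapered tip to cut to full depth.
        ``"explicit-value"`` takes ``alpha`` verbatim (rad).
    alpha : float, optional
        Required (rad) when ``taper_offset_policy == "explicit-value"``.
    """
    dh, ds, p, beta = (geom.hole_diameter, geom.major_diameter,
                       geom.pitch, geom.half_angle)
    theta = math.atan(p / (math.pi * ds))
    rf = (dh + ds) / 4.0
    rs = (2.0 * dh + 2.0 * ds) / 6.0
    kf0 = (0.5 * (ds - dh) * (1.0 + math.tan(beta) ** 2)
           * math.hypot((ds + dh) / 4.0, p / (2.0 * math.pi)))
    ac = math.tan(beta) * ((ds - dh) / 2.0) ** 2
    g1 = rs * ac / math.cos(theta)
    g2 = 2.0 * rf * kf0 / math.cos(theta)

    if taper_offset_policy == "from-taper-geometry":
        taper_length = (ds - dh) / (2.0 * math.tan(geom.end_taper))
        alpha_val = 2.0 * math.pi * taper_length / p
    elif taper_offset_policy == "explicit-value":
        if alpha is None:
            raise GeometryError(
                "taper_offset_policy='explicit-value' requires alpha (rad)")
        alpha_val = float(alpha)
    else:
        raise GeometryError(
            f"unknown taper_offset_policy {taper_offset_policy!r}")

    return InsertionCoefficients(
        pitch_angle=theta, friction_radius=rf, cutting_radius=rs,
        kf0=kf0, cut_area=ac, g1=g1, g2=g2,
        alpha=alpha_val, alpha_policy=taper_offset_policy,
    )


def derive_stripping_coefficients(geom: ScrewGeometry) -> StrippingCoefficients:
    """Derive the stripping-model coefficients.

    θτ = atan2(p, π·Ds) + atan2(1, −μT) is the direction of the shear
    tractions on the cylindrical failure envelope (obtuse for any μT > 0);
    AC = π·Ds·L is that envelope's area. The stress-concentration factor

        kt = 1 + [1 + 1.5·tanh(0.3·ln γ + 0.7)]·γ,   γ = (Dshaft − Dminor)/p,

    models sharper thread tips raising local stress; with γ ≤ 0 (shank thinner
    than the thread core, as on the reference HB 6.5 screw) it is undefined
    and reported as NaN rather than raising.
    """
    p, ds = geom.pitch, geom.major_diameter
    theta_tau = math.atan2(p, math.pi * ds) + math.atan2(1.0, -geom.mu_thread)
    envelope = math.pi * ds * geom.thread_length
    gamma = (geom.shank_diameter - geom.minor_diameter) / p
    if gamma > 0:
        kt = 1.0 + (1.0 + 1.5 * math.tanh(0.3 * math.log(gamma) + 0.7)) * gamma
    else:
        kt = math.nan
    return StrippingCoefficients(
        shear_angle=theta_tau, envelope_area=envelope, gamma=gamma, kt=kt)


def load_geometry(path: str | Path) -> tuple[ScrewGeometry, float | None]:
    """Read a geometry config (YAML or JSON).

    Returns the geometry plus the optional ``alpha_rad`` override found in the
    file (None when absent).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: geometry config must be a mapping")
    geom = ScrewGeometry.from_dict(cfg)
    alpha = cfg.get("alpha_rad")
    return geom, (float(alpha) if alpha is not None else None)
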