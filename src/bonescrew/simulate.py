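"""Synthetic test-rig simulator: insertion recordings with known ground truth.

Emulates a motorised insertion rig driving a cancellous screw into rigid
polyurethane foam at constant speed until the formed threads strip: a settle
period, thread engagement with partial axial slip, a model-governed insertion
phase, a steep tightening rise once the head seats, a stripping peak and decay
to a residual plateau. Sensor effects are applied last: encoder and draw-wire
quantization and Gaussian torque noise representative of a ±5 N·m transducer.

Every simulated trace carries a :class:`GroundTruth` record (the drawn
strength, realised stripping torque and phase times) so identification,
segmentation and the end-to-end pipeline can be validated without external
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError
from .geometry import ScrewGeometry, derive_insertion_coefficients, \
    derive_stripping_coefficients
from .insertion import predict_insertion_torque
from .stripping import predict_stripping_torque

__all__ = [
    "MaterialSpec",
    "RigSpec",
    "GroundTruth",
    "DEFAULT_MATERIALS",
    "default_materials",
    "simulate_insertion_trace",
    "simulate_cohort",
]

DEG = math.pi / 180.0


@dataclass(frozen=True)
class MaterialSpec:
    """A foam grade: nominal strength plus simulator behaviour knobs.

    ``ductility_weight`` d interpolates the simulated stripping peak between
    the ductile bound (d = 0, τ* = τfail) and the brittle bound
    (d = 1, τ* = τfail/kt). ``strength_cv`` is the lot-to-lot relative spread
    of the drawn strength (lognormal, so strengths stay positive).
    """

    name: str
    sigma_ucs: float
    ductility_weight: float = 0.0
    strength_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_ucs <= 0:
            raise GeometryError("sigma_ucs must be > 0")
        if not 0.0 <= self.ductility_weight <= 1.0:
            raise GeometryError("ductility_weight must lie in [0, 1]")
        if self.strength_cv < 0:
            raise GeometryError("strength_cv must be >= 0")


def default_materials(strength_cv: float = 0.05) -> list[MaterialSpec]:
    """The eight PU-foam grades of the reference cohort.

    Strengths are the data-sheet ultimate compressive strengths (midpoints of
    printed ranges): SikaBlock M80/M150/M330/M450/M600 and SYNBONE
    15/20/30 PCF. Ductility weight is 0 because the reference screw geometry
    has an undefined stress-concentration factor (γ < 0).
    """
    grades = [("M80", 0.8), ("M150", 1.6), ("M330", 4.0), ("M450", 10.0),
              ("M600", 17.0), ("15PCF", 3.0), ("20PCF", 10.0), ("30PCF", 12.5)]
    return [MaterialSpec(name, s, strength_cv=strength_cv)
            for name, s in grades]


DEFAULT_MATERIALS: list[MaterialSpec] = default_materials()


@dataclass(frozen=True)
class RigSpec:
    """Test-rig and protocol parameters.

    Sensor defaults follow the reference rig: 30 RPM insertion, 1 kHz
    sampling, 0.25° encoder steps, 0.025 mm draw-wire steps and a torque
    noise SD of 25 N·mm (0.5 % of the ±5 N·m range). Setting a noise or
    resolution field to 0 disables that sensor effect.

    Phase shape parameters are simulator choices: ``slip_factor`` is the
    fraction of the nominal pitch advanced per revolution during engagement;
    ``bite_angle`` is the rotation before any axial advance begins (kept equal
    to the default crop start threshold so cropping and the generator agree on
    the depth origin); ``tightening_revolutions`` sets the effective
    tightening stiffness as revolutions from head contact to failure.
    """

    rpm: float = 30.0
    sample_rate: float = 1000.0
    torque_noise_sd: float = 25.0              # N·mm
    encoder_resolution: float = 0.25 * DEG     # rad
    drawwire_resolution: float = 0.025         # mm
    engagement_revolutions: float = 1.5
    insertion_revolutions: float = 9.0
    settle_s: float = 1.0
    tightening_revolutions: float = 0.5
    strip_peak_s: float = 0.06
    strip_decay_revolutions: float = 0.75
    strip_plateau_revolutions: float = 0.5
    slip_factor: float = 0.3
    bite_angle: float = 1.0 * DEG
    plateau_fraction: float = 0.3
    sensor_range: float = 5000.0               # N·mm

    def __post_init__(self) -> None:
        positive = ["rpm", "sample_rate", "engagement_revolutions",
                    "insertion_revolutions", "settle_s",
                    "tightening_revolutions", "strip_peak_s",
                    "strip_decay_revolutions", "strip_plateau_revolutions",
                    "slip_factor", "bite_angle", "sensor_range"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise GeometryError(f"RigSpec.{name} must be > 0")
        for name in ["torque_noise_sd", "encoder_resolution",
                     "drawwire_resolution"]:
            if getattr(self, name) < 0:
                raise GeometryError(f"RigSpec.{name} must be >= 0")
        if not 0 < self.plateau_fraction < 1:
            raise GeometryError("plateau_fraction must lie in (0, 1)")

    @property
    def omega(self) -> float:
        """Spindle speed (rad/s)."""
        return 2.0 * math.pi * self.rpm / 60.0


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually realised for one trace."""

    material: str
    sigma_ucs_true: float      # MPa, drawn value the torque was generated from
    tau_strip_true: float      # N·mm, realised stripping peak
    onset_time: float          # s, start of the tightening rise
    strip_time: float          # s, start of the stripping peak
    seed: int
    clipped: bool = field(default=False)  # peak exceeds the sensor range


def _depth_factor(sigma_nominal: float) -> float:
    # Harder foams engage slower and reach head contact after fewer effective
    # model revolutions; spreads the insertion-end/stripping torque ratio
    # across grades (~0.2-0.45) instead of the constant ratio pure geometry
    # would give.
    return float(np.clip(1.4 - 0.04 * sigma_nominal, 0.6, 1.4))


def simulate_insertion_trace(
    material: MaterialSpec,
    geom: ScrewGeometry | None = None,
    rig: RigSpec | None = None,
    seed: int = 0,
    kt: float | None = None,
):
    """Simulate one insertion-to-stripping recording.

    Returns ``(trace, truth)`` where ``trace`` is a
    :class:`~bonescrew.signal.TorqueTrace` and ``truth`` the
    :class:`GroundTruth`. Bit-identical output for identical arguments.

    Parameters
    ----------
    material, geom, rig
        Specs; ``None`` selects the HB 6.5 geometry / default rig.
    seed : int
        Seeds the strength draw, the stripping-peak jitter and the torque
        noise (in that fixed order).
    kt : float, optional
        Stress-concentration factor for the stripping peak when
        ``material.ductility_weight > 0`` and the geometry's own kt is
        undefined.
    """
    from .signal import TorqueTrace  # local import to avoid a cycle

    geom = geom or ScrewGeometry.hb65()
    rig = rig or RigSpec()
    rng = np.random.default_rng(seed)

    ins_coeffs = derive_insertion_coefficients(geom)
    strip_coeffs = derive_stripping_coefficients(geom)

    sigma_true = material.sigma_ucs
    if material.strength_cv > 0:
        sigma_true *= math.exp(rng.normal(0.0, material.strength_cv))

    tau_fail = predict_stripping_torque(sigma_true, geom,
                                        strip_coeffs).tau_fail_no_kt
    d = material.ductility_weight
    if d > 0:
        kt_eff = strip_coeffs.kt if strip_coeffs.kt_defined else kt
        if kt_eff is None or not math.isfinite(kt_eff):
            raise GeometryError(
                "ductility_weight > 0 needs a stress-concentration factor; "
                "geometry kt is undefined, pass kt explicitly")
        tau_fail /= kt_eff ** d
    tau_star = tau_fail
    if material.strength_cv > 0:
        tau_star *= math.exp(rng.normal(0.0, material.strength_cv))

    # Rotation milestones (rad from motor start).
    omega = rig.omega
    two_pi = 2.0 * math.pi
    bite = rig.bite_angle
    eng_end = rig.engagement_revolutions * two_pi
    n_ins = rig.insertion_revolutions * _depth_factor(material.sigma_ucs)
    ins_end = eng_end + n_ins * two_pi
    tight_end = ins_end + rig.tightening_revolutions * two_pi
    peak_end = tight_end + omega * rig.strip_peak_s
    decay_end = peak_end + rig.strip_decay_revolutions * two_pi
    final_rot = decay_end + rig.strip_plateau_revolutions * two_pi

    t_end = rig.settle_s + final_rot / omega
    n = int(math.floor(t_end * rig.sample_rate)) + 1
    time = np.arange(n) / rig.sample_rate
    rot_true = omega * np.maximum(time - rig.settle_s, 0.0)

    # Axial advance begins at the first sample strictly past the bite angle
    # (matching the crop rule's depth origin) with partial slip until the
    # threads fully engage, pitch-true advance during insertion, and none
    # after head contact.
    k0 = int(np.argmax(rot_true > bite))
    rot0 = rot_true[k0]
    pitch_per_rad = geom.pitch / two_pi
    knots_rot = np.array([rot0, eng_end, ins_end])
    knots_pos = np.array([
        0.0,
        rig.slip_factor * pitch_per_rad * (eng_end - rot0),
        rig.slip_factor * pitch_per_rad * (eng_end - rot0)
        + pitch_per_rad * (ins_end - eng_end),
    ])
    position = np.interp(rot_true, knots_rot, knots_pos)
    position[:k0] = 0.0
    phi_equiv = two_pi * position / geom.pitch

    # Noise-free torque, phase by phase.
    torque = np.zeros(n)
    model_tau = predict_insertion_torque(phi_equiv, sigma_true, ins_coeffs,
                                         geom.mu_thread)
    in_eng = (rot_true > bite) & (rot_true < eng_end)
    ramp = (rot_true - bite) / (eng_end - bite)
    torque[in_eng] = (model_tau * ramp)[in_eng]
    in_ins = (rot_true >= eng_end) & (rot_true < ins_end)
    torque[in_ins] = model_tau[in_ins]
    tau_ins_end = float(predict_insertion_torque(
        np.array([two_pi * knots_pos[2] / geom.pitch]), sigma_true,
        ins_coeffs, geom.mu_thread)[0])
    in_tight = (rot_true >= ins_end) & (rot_true < tight_end)
    frac = (rot_true - ins_end) / (tight_end - ins_end)
    torque[in_tight] = (tau_ins_end + frac * (tau_star - tau_ins_end))[in_tight]
    in_peak = (rot_true >= tight_end) & (rot_true < peak_end)
    torque[in_peak] = tau_star
    plateau = rig.plateau_fraction * tau_star
    in_decay = (rot_true >= peak_end) & (rot_true < decay_end)
    u = (rot_true - peak_end) / (decay_end - peak_end)
    torque[in_decay] = (plateau + (tau_star - plateau) * (1.0 - u) ** 2)[in_decay]
    torque[rot_true >= decay_end] = plateau

    # Sensor effects last.
    rotation = rot_true
    if rig.encoder_resolution > 0:
        rotation = np.round(rotation / rig.encoder_resolution) \
            * rig.encoder_resolution
    if rig.drawwire_resolution > 0:
        position = np.round(position / rig.drawwire_resolution) \
            * rig.drawwire_resolution
    if rig.torque_noise_sd > 0:
        torque = torque + rng.normal(0.0, rig.torque_noise_sd, n)

    trace = TorqueTrace(time=time, torque=torque, rotation=rotation,
                        position=position, sample_rate=rig.sample_rate)
    truth = GroundTruth(
        material=material.name,
        sigma_ucs_true=sigma_true,
        tau_strip_true=tau_star,
        onset_time=rig.settle_s + ins_end / omega,
        strip_time=rig.settle_s + tight_end / omega,
        seed=int(seed),
        clipped=tau_star > rig.sensor_range,
    )
    return trace, truth


def simulate_cohort(
    materials: list[MaterialSpec] | None = None,
    n_per_material: int = 10,
    geom: ScrewGeometry | None = None,
    rig: RigSpec | None = None,
    seed: int = 0,
    kt: float | None = None,
):
    """Simulate a full cohort: ``n_per_material`` insertions per material.

    Per-trace seeds are drawn once from the master seed so traces are
    independent yet the whole cohort is reproducible. Returns a list of
    ``(trace, truth)`` pairs ordered material-major.
    """
    if n_per_material < 1:
        raise GeometryError("n_per_material must be >= 1")
    materials = materials if materials is not None else default_materials()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1,
                                  size=len(materials) * n_per_material)
    out = []
    k = 0
    for mat in materials:
        for _ in range(n_per_material):
            out.append(simulate_insertion_trace(
                mat, geom=geom, rig=rig, seed=int(child_seeds[k]), kt=kt))
            k += 1
    return out
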