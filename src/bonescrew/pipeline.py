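"""Batch pipeline: recorded traces in, cohort report out.

Per trace: crop and segment, convert draw-wire position to equivalent
rotation, identify the material strength from the insertion segment, predict
the stripping torque, and measure the empirical stripping torque. Per-trace
failures are collected and reported; they do not abort the batch.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import CohortResult, summarize_cohort
from .exceptions import BoneScrewError, ConfigError
from .geometry import ScrewGeometry, derive_insertion_coefficients, \
    derive_stripping_coefficients
from .insertion import identify_strength
from .io import read_trace_csv
from .signal import SegmentationParams, TorqueTrace, position_to_rotation, \
    segment_trace
from .stripping import predict_stripping_torque

__all__ = ["RunConfig", "process_trace", "run_pipeline"]

log = logging.getLogger("bonescrew")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a pipeline run."""

    geometry: ScrewGeometry = field(default_factory=ScrewGeometry.hb65)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    kt_mode: str = "none"
    kt_value: float | None = None
    taper_offset_policy: str = "from-taper-geometry"
    alpha: float | None = None
    use_encoder_rotation: bool = False  # default: position-derived rotation

    def __post_init__(self) -> None:
        if self.kt_mode not in ("none", "full", "value"):
            raise ConfigError(f"invalid kt_mode {self.kt_mode!r}")
        if self.kt_mode == "value" and self.kt_value is None:
            raise ConfigError("kt_mode='value' requires kt_value")

    def to_dict(self) -> dict[str, Any]:
        """JSON-serialisable provenance record of the resolved config."""
        return {
            "package_version": __version__,
            "geometry": dataclasses.asdict(self.geometry),
            "segmentation": dataclasses.asdict(self.segmentation),
            "kt_mode": self.kt_mode,
            "kt_value": self.kt_value,
            "taper_offset_policy": self.taper_offset_policy,
            "alpha": self.alpha,
            "use_encoder_rotation": self.use_encoder_rotation,
        }


def process_trace(trace: TorqueTrace, config: RunConfig | None = None,
                  material: str = "") -> dict[str, Any]:
    """Run the full estimation chain on one recording.

    Returns a flat record: identified strength, predicted stripping torques
    (both stress-concentration bounds), measured stripping torque and the
    segment indices.
    """
    cfg = config or RunConfig()
    geom = cfg.geometry
    ins_coeffs = derive_insertion_coefficients(
        geom, taper_offset_policy=cfg.taper_offset_policy, alpha=cfg.alpha)
    strip_coeffs = derive_stripping_coefficients(geom)

    cropped, bounds = segment_trace(trace, cfg.segmentation)
    onset_local = bounds.tightening_idx - bounds.start_idx
    if cfg.use_encoder_rotation:
        phi = cropped.rotation - cropped.rotation[0]
    else:
        phi = position_to_rotation(cropped.position, geom.pitch)
    blank = cropped.rotation[0] \
        + cfg.segmentation.blanking_revolutions * 2.0 * math.pi
    in_segment = (np.arange(len(cropped)) < onset_local) \
        & (cropped.rotation > blank)
    est = identify_strength(phi[in_segment], cropped.torque[in_segment],
                            ins_coeffs, geom.mu_thread)
    pred = predict_stripping_torque(
        max(est.sigma_ucs, 0.0), geom, strip_coeffs,
        kt_mode=cfg.kt_mode, kt_value=cfg.kt_value)
    from .signal import measure_true_stripping_torque
    tau_true, _ = measure_true_stripping_torque(
        cropped, cfg.segmentation.median_window_s)
    return {
        "material": material,
        "sigma_hat": est.sigma_ucs,
        "sigma_hat_negative": est.negative,
        "fit_n_samples": est.n_samples,
        "fit_sse": est.sse,
        "tau_pred_no_kt": pred.tau_fail_no_kt,
        "tau_pred_kt": pred.tau_fail_kt,
        "kt_used": pred.kt_used,
        "tau_pred": pred.tau_fail,
        "tau_true": tau_true,
        "start_idx": bounds.start_idx,
        "tightening_idx": bounds.tightening_idx,
        "stripping_idx": bounds.stripping_idx,
        "end_idx": bounds.end_idx,
    }


def run_pipeline(traces: Sequence[str | Path | TorqueTrace],
                 config: RunConfig | None = None,
                 materials: Sequence[str] | None = None) -> CohortResult:
    """Process a batch of traces (paths or in-memory) into a cohort report.

    Per-trace failures are logged once with the trace identifier and listed
    in ``result.failures``; summary statistics are computed over the
    successful records (and require at least four of them).
    """
    cfg = config or RunConfig()
    if len(traces) == 0:
        raise ConfigError("no traces given")
    records: list[dict[str, Any]] = []
    failures: list[dict[str, str]] = []
    for i, item in enumerate(traces):
        name = str(item) if not isinstance(item, TorqueTrace) else f"trace[{i}]"
        material = materials[i] if materials is not None else ""
        try:
            trace = item if isinstance(item, TorqueTrace) \
                else read_trace_csv(item)
            records.append(process_trace(trace, cfg, material=material))
            log.info("processed %s", name)
        except BoneScrewError as exc:
            failures.append({"trace": name, "error": str(exc)})
            log.error("failed %s: %s", name, exc)
    df = pd.DataFrame(
        records,
        columns=["material", "sigma_hat", "sigma_hat_negative",
                 "fit_n_samples", "fit_sse", "tau_pred_no_kt", "tau_pred_kt",
                 "kt_used", "tau_pred", "tau_true", "start_idx",
                 "tightening_idx", "stripping_idx", "end_idx"])
    summary: dict[str, Any] = {"config": cfg.to_dict(),
                               "n_failed": len(failures)}
    if len(df) >= 4:
        summary.update(summarize_cohort(df))
    return CohortResult(records=df, summary=summary, failures=failures)
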