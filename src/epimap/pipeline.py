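"""End-to-end pipeline: simulate -> detect -> conduction/CHI/ARI -> endpoints.

Every machine output carries a provenance record (the full effective
configuration plus the seed), and the whole run is a deterministic
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import conduction, features, io, stats
from .errors import AnalysisError, EpimapError, InvalidParameterError
from .synthetic import (
    WaveformParams,
    default_cohort_params,
    generate_cohort,
    make_geometry,
    simulate_focal_truth,
    simulate_planar_truth,
    synthesize_recording,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run (all units: mm, ms, m/s)."""

    seed: int = 0
    # geometry
    rows: int = 16
    cols: int = 8
    pitch_mm: float = 2.7
    bad_channels: tuple[int, ...] = ()
    # simulated wavefront
    wavefront: str = "planar"  # "planar" | "focal"
    speed_mps: float = 0.9
    direction_deg: float = 0.0
    origin_mm: tuple[float, float] = (0.0, 0.0)
    t0_ms: float = 15.0
    # recording synthesis
    sampling_rate_hz: float = 25_000.0
    duration_s: float = 2.0
    ari_ms: float = 180.0
    noise_sd_mv: float = 0.1
    quantization_bits: int | None = 12
    recording_format: str = "binary"  # "binary" | "csv"
    # detection
    stimulus_index: int = 0
    blanking_ms: float = features.DEFAULT_BLANKING_MS
    min_slope_mv_per_ms: float | None = None
    repol_window_ms: tuple[float, float] = features.DEFAULT_REPOL_WINDOW_MS
    # conduction
    speed_bounds_mps: tuple[float, float] = conduction.DEFAULT_SPEED_BOUNDS
    min_dt_ms: float = conduction.DEFAULT_MIN_DT_MS
    wpv_summary: str = "mean"
    percentile_convention: str = "linear"
    # endpoint statistics
    ttest_variant: str = "student"  # "student" | "welch"
    plateau_fraction: float = 0.95
    # figure export
    figures: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("bad_channels", "origin_mm", "repol_window_ms", "speed_bounds_mps"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidParameterError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.wavefront not in ("planar", "focal"):
            raise InvalidParameterError(f"unknown wavefront kind {self.wavefront!r}")
        if self.recording_format not in ("binary", "csv"):
            raise InvalidParameterError(f"unknown recording format {self.recording_format!r}")
        if self.ttest_variant not in ("student", "welch"):
            raise InvalidParameterError(f"unknown t-test variant {self.ttest_variant!r}")
        if self.percentile_convention != "linear":
            raise InvalidParameterError(
                f"unsupported percentile convention {self.percentile_convention!r}")


def _stage(name: str):
    """Decorator tagging a pipeline stage so failures name their stage."""
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except EpimapError as exc:
                raise AnalysisError(f"stage {name!r} failed: {exc}") from exc
        return run
    return wrap


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the full analysis and write every intermediate artifact.

    Returns a mapping from artifact name to path. Rerunning with the same
    (config, seed) produces byte-identical machine outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config": config.to_dict(), "seed": config.seed}
    paths: dict[str, Path] = {}

    def save_frame(name: str, frame) -> None:
        paths[name] = out / f"{name}.csv"
        io.write_frame_csv(frame, paths[name], provenance=prov)

    log.info("stage simulate: %dx%d grid, %s wavefront at %.2f m/s",
             config.rows, config.cols, config.wavefront, config.speed_mps)
    geometry = _stage("simulate")(make_geometry)(
        config.rows, config.cols, config.pitch_mm,
        bad_channels=config.bad_channels)
    if config.wavefront == "planar":
        truth = simulate_planar_truth(geometry, config.speed_mps,
                                      config.direction_deg, config.t0_ms)
    else:
        truth = simulate_focal_truth(geometry, config.speed_mps,
                                     config.origin_mm, config.t0_ms)
    recording = _stage("simulate")(synthesize_recording)(
        truth, WaveformParams(), ari_ms=config.ari_ms,
        noise_sd_mv=config.noise_sd_mv, seed=config.seed,
        sampling_rate_hz=config.sampling_rate_hz, duration_s=config.duration_s,
        quantization_bits=config.quantization_bits)

    paths["geometry"] = out / "geometry.csv"
    io.write_geometry(geometry, paths["geometry"])
    ext = "egm" if config.recording_format == "binary" else "egm.csv"
    paths["recording"] = out / f"recording.{ext}"
    io.write_recording(recording, paths["recording"], fmt=config.recording_format)

    activation = _stage("detect")(features.detect_activation_times)(
        recording, blanking_ms=config.blanking_ms,
        min_slope_mv_per_ms=config.min_slope_mv_per_ms,
        stimulus_index=config.stimulus_index)
    log.info("stage detect: %d/%d channels valid",
             activation.n_valid, geometry.n_channels)
    save_frame("activation_map", activation.to_frame())

    repol = _stage("detect")(features.detect_repolarization_times)(
        recording, activation, repol_window_ms=config.repol_window_ms)
    save_frame("repolarization_map", repol.to_frame())
    ari = _stage("ari")(features.compute_ari)(activation, repol)
    save_frame("ari_map", ari.to_frame())
    io.write_json({"mean_ms": ari.mean_ms, "sd_ms": ari.sd_ms,
                   "n_valid": ari.n_valid, "provenance": prov},
                  out / "ari_summary.json")
    paths["ari_summary"] = out / "ari_summary.json"

    cond = _stage("conduction")(conduction.wave_propagation_velocity)(
        activation, geometry, speed_bounds=config.speed_bounds_mps,
        min_dt_ms=config.min_dt_ms, summary=config.wpv_summary)
    for reason, count in sorted(cond.rejection_counts().items()):
        log.info("stage conduction: %d triangles rejected (%s)", count, reason)
    log.info("stage conduction: WPV %.3f m/s over %d triangles",
             cond.wpv_mps, cond.n_valid)
    save_frame("conduction_triangles", cond.to_frame())
    io.write_json({**cond.summary_record(), "provenance": prov},
                  out / "conduction_summary.json")
    paths["conduction_summary"] = out / "conduction_summary.json"

    phases = _stage("chi")(conduction.phase_map)(activation, geometry)
    save_frame("phase_map", phases.to_frame())
    io.write_json({**phases.summary_record(), "provenance": prov},
                  out / "phase_summary.json")
    paths["phase_summary"] = out / "phase_summary.json"

    cohort = _stage("cohort")(generate_cohort)(default_cohort_params(), seed=config.seed)
    save_frame("cohort", cohort)
    report = _stage("endpoints")(stats.endpoint_report)(
        cohort, welch=(config.ttest_variant == "welch"))
    frame = stats.report_frame(report)
    paths["endpoints_tsv"] = out / "endpoints.tsv"
    frame.to_csv(paths["endpoints_tsv"], sep="\t", index=False)
    io.write_json({"records": [s.to_record() for s in report], "provenance": prov},
                  out / "endpoints.json")
    paths["endpoints_json"] = out / "endpoints.json"
    trajectory = _stage("endpoints")(stats.map_trajectory_summary)(
        cohort, plateau_fraction=config.plateau_fraction)
    save_frame("map_trajectory", trajectory.weekly)
    io.write_json({"plateau_week": trajectory.plateau_week,
                   "plateau_fraction": trajectory.plateau_fraction,
                   "provenance": prov}, out / "map_plateau.json")
    paths["map_plateau"] = out / "map_plateau.json"

    io.write_json(prov, out / "run_config.json")
    paths["run_config"] = out / "run_config.json"

    if config.figures:
        from .plotting import plot_activation_map, plot_phase_map
        paths["activation_figure"] = out / "activation_map.png"
        plot_activation_map(activation, geometry, paths["activation_figure"])
        paths["phase_figure"] = out / "phase_map.png"
        plot_phase_map(phases, geometry, paths["phase_figure"])

    return paths
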