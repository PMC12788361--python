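"""End-to-end orchestration: input -> Kalman filter -> segmentation ->
metrics/symmetry -> coupling regression -> repeatability -> reports.

A run is fully determined by its configuration and seed: all randomness
derives from the single config seed, per-cycle/per-side streams are
spawned deterministically, and numeric outputs are written with fixed
formatting so identical runs are byte-identical. Every stage writes its
result to disk (CSV/JSON), so any stage can be re-run from the previous
stage's files. Logging goes to stderr; numeric results never to stdout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, DataError
from .filtering import DEFAULT_Q_DIAG, DEFAULT_R_DIAG, build_model, filter_recording
from .metrics import (
    CycleMetrics,
    bilateral_report,
    cycle_metrics,
    metrics_frame,
    symmetry_frame,
)
from .regression import fit_all, fits_frame
from .segmentation import (
    PhaseSegmentation,
    SegmentationParams,
    detect_all_cycles,
    segment_phases,
)
from .synthetic import (
    CHANNELS,
    PRESSURE_CHANNEL,
    MultimodalRecording,
    SyntheticConfig,
    default_config,
    generate_cycle,
    read_recording,
    write_ground_truth,
    write_recording,
)

__all__ = ["PipelineConfig", "RepeatabilityReport", "run", "compare_cycles"]

log = logging.getLogger("slidegait")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Full run description. Exactly one input mode:

    * ``synthetic``: cycles are generated from ``synthetic`` (or the
      calibrated default config) with per-cycle seeds derived from ``seed``;
    * ``files``: ``input_files`` maps side -> recording CSV path.
    """

    mode: str = "synthetic"
    synthetic: SyntheticConfig | None = None
    input_files: dict[str, str] = field(default_factory=dict)
    dt: float | None = None  # defaults to 1/sampling_rate
    q_diag: tuple = tuple(DEFAULT_Q_DIAG)
    r_diag: tuple = tuple(DEFAULT_R_DIAG)
    segmentation: SegmentationParams | None = None
    n_cycles: int = 3  # repeated cycles for the repeatability report
    cycle_index: int | None = None  # burst to analyze in file mode (None = middle)
    output_dir: str = "slidegait_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            missing = [s for s in ("left", "right") if s not in self.input_files]
            if missing:
                raise ConfigurationError(f"file mode needs input_files for {missing}")
            for side, path in self.input_files.items():
                if not Path(path).exists():
                    raise ConfigurationError(f"{side} input file {path} does not exist")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")


@dataclass
class RepeatabilityReport:
    """Across-cycle variability of every metric (coefficient of variation
    and maximum pairwise difference)."""

    table: pd.DataFrame  # columns: side, channel, statistic, mean, sd, cv, max_pairwise_diff, k


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.ndarray, tuple)):
            return list(o)
        return str(o)

    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)  # hash the analysis config, not the run location
    payload.pop("log_level", None)
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _load_inputs(
    config: PipelineConfig, outdir: Path
) -> dict[str, list[MultimodalRecording]]:
    """Per side, the list of repeated-cycle recordings (>= 1)."""
    recordings: dict[str, list[MultimodalRecording]] = {"left": [], "right": []}
    if config.mode == "synthetic":
        base = config.synthetic if config.synthetic is not None else default_config()
        for c in range(config.n_cycles):
            cycle_seed = int(
                np.random.SeedSequence([config.seed & 0x7FFFFFFF, c]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            cfg_c = dataclasses.replace(base, seed=cycle_seed)
            for side in ("left", "right"):
                rec, gt = generate_cycle(cfg_c, side)
                recordings[side].append(rec)
                if c == 0:
                    write_recording(rec, outdir / f"recording_{side}.csv")
                    write_ground_truth(gt, outdir / f"ground_truth_{side}.json")
    else:
        for side in ("left", "right"):
            rec = read_recording(config.input_files[side], side=side)
            recordings[side].append(rec)
    return recordings


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full chain; returns the paths of the written artifacts."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.perf_counter()

    recordings = _load_inputs(config, outdir)
    fs = recordings["left"][0].sampling_rate
    dt = config.dt if config.dt is not None else 1.0 / fs
    model = build_model(dt=dt, q_diag=config.q_diag, r_diag=config.r_diag)
    seg_params = config.segmentation or SegmentationParams(sampling_rate=fs)

    smoothed: dict[str, pd.DataFrame] = {}
    segmentations: dict[str, PhaseSegmentation] = {}
    per_cycle_metrics: dict[str, list[CycleMetrics]] = {"left": [], "right": []}

    for side in ("left", "right"):
        for c, rec in enumerate(recordings[side]):
            log.info("filtering %s cycle %d", side, c)
            filt = filter_recording(rec, model)
            sm_rec = MultimodalRecording(side=side, sampling_rate=fs, data=filt.smoothed)
            cycle = None
            if config.mode == "files":
                bursts = detect_all_cycles(sm_rec.pressure, hold=seg_params.hold, params=seg_params)
                idx = config.cycle_index if config.cycle_index is not None else len(bursts) // 2
                cycle = bursts[idx]
            seg = segment_phases(
                sm_rec.pressure,
                angles={ch: sm_rec.channel(ch) for ch in CHANNELS if ch != PRESSURE_CHANNEL},
                params=seg_params,
                pressure_velocity=filt.velocity(PRESSURE_CHANNEL),
                cycle=cycle,
            )
            per_cycle_metrics[side].append(
                cycle_metrics(sm_rec, cycle=(seg.cycle_start, seg.cycle_end))
            )
            if c == 0:
                smoothed[side] = filt.smoothed
                segmentations[side] = seg
                filt.smoothed.to_csv(
                    outdir / f"smoothed_{side}.csv", index=False, float_format=_FLOAT_FMT
                )
                innov = pd.DataFrame(filt.innovations, columns=[f"innov_{c_}" for c_ in CHANNELS])
                innov.to_csv(outdir / f"innovations_{side}.csv", index=False, float_format=_FLOAT_FMT)
                seg.to_json(outdir / f"segmentation_{side}.json")
                seg.to_bed(outdir / f"phases_{side}.bed")
                artifacts[f"smoothed_{side}"] = outdir / f"smoothed_{side}.csv"
                artifacts[f"segmentation_{side}"] = outdir / f"segmentation_{side}.json"

    # per-side metrics + bilateral symmetry (first cycle)
    mframes = [metrics_frame(per_cycle_metrics[s][0]) for s in ("left", "right")]
    metrics_table = pd.concat(mframes, ignore_index=True)
    metrics_table.to_csv(outdir / "metrics.csv", index=False, float_format=_FLOAT_FMT)
    artifacts["metrics"] = outdir / "metrics.csv"

    sym = bilateral_report(per_cycle_metrics["left"][0], per_cycle_metrics["right"][0])
    sym_df = symmetry_frame(sym)
    sym_df.to_csv(outdir / "symmetry.csv", index=False, float_format=_FLOAT_FMT)
    sym_df.to_json(outdir / "symmetry.json", orient="records", indent=2)
    artifacts["symmetry"] = outdir / "symmetry.csv"

    # coupling regression on the smoothed first cycle
    fits = fit_all(smoothed, segmentations)
    reg_df = fits_frame(fits)
    reg_df.to_csv(outdir / "regression.csv", index=False, float_format=_FLOAT_FMT)
    artifacts["regression"] = outdir / "regression.csv"
    resid = pd.DataFrame(
        {f"{f.side}_{f.joint_name}": pd.Series(f.std_residuals) for f in fits}
    )
    resid.to_csv(outdir / "residuals.csv", index=False, float_format=_FLOAT_FMT)

    # repeatability across cycles
    if config.n_cycles >= 2 and config.mode == "synthetic":
        rep_frames = {
            side: [metrics_frame(m) for m in per_cycle_metrics[side]]
            for side in ("left", "right")
        }
        rep = compare_cycles(rep_frames["left"] )
        rep_r = compare_cycles(rep_frames["right"])
        rep_all = pd.concat([rep.table, rep_r.table], ignore_index=True)
        rep_all.to_csv(outdir / "repeatability.csv", index=False, float_format=_FLOAT_FMT)
        artifacts["repeatability"] = outdir / "repeatability.csv"

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": int(config.seed),
        "mode": config.mode,
        "n_cycles": int(config.n_cycles),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = outdir / "manifest.json"
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return artifacts


def compare_cycles(tables: list[pd.DataFrame]) -> RepeatabilityReport:
    """Across-cycle repeatability of metric tables.

    Each table must be a long-format metrics frame (side, channel,
    statistic, value) with an identical metric set. Reports per metric the
    across-cycle mean, sample SD, CV (SD/|mean|) and maximum pairwise
    difference.
    """
    k = len(tables)
    if k < 2:
        raise DataError("need >= 2 cycles to compare")
    keys = ["side", "channel", "statistic"]
    ref = tables[0][keys]
    for t in tables[1:]:
        if len(t) != len(ref) or not (t[keys].reset_index(drop=True) == ref.reset_index(drop=True)).all().all():
            raise DataError("mismatched metric sets across cycles")
    values = np.column_stack([t["value"].to_numpy(dtype=float) for t in tables])
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    # identical cycles must report exactly zero spread (no epsilon from the
    # mean's rounding)
    identical = values.max(axis=1) == values.min(axis=1)
    sd[identical] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.where(sd == 0, 0.0, np.nan))
    max_diff = values.max(axis=1) - values.min(axis=1)
    table = ref.copy().reset_index(drop=True)
    table["mean"] = mean
    table["sd"] = sd
    table["cv"] = cv
    table["max_pairwise_diff"] = max_diff
    table["k"] = k
    return RepeatabilityReport(table=table)
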