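"""End-to-end orchestration: simulate/load -> preprocess -> deconvolve ->
features -> significance table -> classifier benchmark.

A single :class:`RunConfig` (read from YAML, overridable from the CLI) is
the source of truth; every randomized stage consumes a seed derived from
the master seed by a fixed rule (SeedSequence spawn keys), so a run is
reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    DEFAULT_THRESHOLD,
    build_dataset,
    classifier_catalogue,
    format_benchmark,
    report_benchmark,
    run_benchmark,
)
from .deconv import DEFAULT_REG, extract_scr_driver, make_kernel
from .features import FEATURE_NAMES, extract_features
from .io import (
    GENRES,
    EDASignal,
    SAMResponse,
    StimulusEvent,
    read_e4_eda,
    read_events,
    read_sam,
    write_e4_eda,
    write_events,
    write_feature_sheet,
    write_sam,
)
from .preprocess import preprocess, segment_recording
from .stats import build_significance_table
from .synth import SyntheticConfig, simulate_cohort

logger = logging.getLogger(__name__)

#: stage names -> spawn key offsets for deriving per-stage seeds
STAGE_KEYS = {"simulate": 0, "benchmark": 1}


@dataclass
class RunConfig:
    """Everything a full run needs. See docs/methods.md for the schema."""

    mode: str = "synthetic"  # "synthetic" | "files"
    out_dir: str = "scrkit_run"
    seed: int = 0
    # files mode
    eda_paths: dict[str, str] = field(default_factory=dict)  # participant -> csv
    events_path: str | None = None
    sam_path: str | None = None
    # synthetic mode
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # preprocessing
    lowpass_cutoff: float = 4.0
    smooth_window_s: float = 1.0
    smooth_sigma_s: float = 0.2
    # deconvolution
    tau_rise: float = 0.75
    tau_decay: float = 2.0
    kernel_duration: float = 20.0
    reg: float = DEFAULT_REG
    tonic_window_s: float = 30.0
    tonic_percentile: float = 10.0
    edge_trim_s: float = 5.0  # trimmed from each segment end before features
    # features
    mo_order: int = 3
    # stats
    alpha: float = 0.05
    pairing: str = "paired"
    correction: str | None = None
    # benchmark
    sam_threshold: int = DEFAULT_THRESHOLD
    n_iterations: int = 30
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files":
            missing = [f for f, v in (("eda_paths", self.eda_paths),
                                      ("events_path", self.events_path),
                                      ("sam_path", self.sam_path)) if not v]
            if missing:
                raise ValueError(f"files mode requires field(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(syn, dict):
            cfg.synthetic = SyntheticConfig(**syn)
        if "split" in raw:
            cfg.split = tuple(cfg.split)  # type: ignore[assignment]
        return cfg

    def to_dict(self) -> dict:
        """Config as a plain dict; out_dir and input paths are excluded
        because they do not affect any computed value."""
        d = dataclasses.asdict(self)
        d["synthetic"]["tonic_level_range"] = list(d["synthetic"]["tonic_level_range"])
        d["split"] = list(d["split"])
        for key in ("out_dir", "eda_paths", "events_path", "sam_path"):
            d.pop(key, None)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derivation from the master seed (< 2**31)."""
    ss = np.random.SeedSequence([master, STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _load_sessions(config: RunConfig):
    """Return list of (participant_id, EDASignal, events); plus SAM table."""
    if config.mode == "synthetic":
        syn = dataclasses.replace(
            config.synthetic, seed=derive_seed(config.seed, "simulate")
        )
        sessions = simulate_cohort(syn)
        sam = [r for s in sessions for r in s.sam]
        return [(s.participant_id, s.signal, s.events) for s in sessions], sam
    events = read_events(config.events_path)
    sam = read_sam(config.sam_path)
    out = []
    for pid, path in sorted(config.eda_paths.items()):
        sig, report = read_e4_eda(path, label=pid)
        if report.n_interpolated:
            logger.info("%s: %d interpolated sample(s)", pid, report.n_interpolated)
        out.append((pid, sig, events))
    return out, sam


def compute_feature_sheet(config: RunConfig) -> tuple[pd.DataFrame, list[SAMResponse]]:
    """Run preprocess + deconvolution + feature extraction for every
    participant x segment; return the feature sheet and SAM responses."""
    sessions, sam = _load_sessions(config)
    rows = []
    for pid, sig, events in sessions:
        irf = make_kernel(config.tau_rise, config.tau_decay, sig.fs, config.kernel_duration)
        clean = preprocess(sig, config.lowpass_cutoff, config.smooth_window_s, config.smooth_sigma_s)
        result = extract_scr_driver(
            clean, irf, reg=config.reg,
            window_s=config.tonic_window_s, percentile=config.tonic_percentile,
        )
        scr_sig = EDASignal(np.maximum(result.scr_driver, 0.0) + 0.0, sig.fs, sig.t0, sig.label)
        # segment the phasic driver, not the raw conductance
        for seg in segment_recording(scr_sig, events, pid):
            y = seg.signal.samples
            trim = int(round(config.edge_trim_s * sig.fs))
            if y.size > 2 * trim + 8:
                y = y[trim: y.size - trim]
            fv = extract_features(y, sig.fs, mo_order=config.mo_order)
            row = {"participant_id": pid, "segment_label": seg.event.label}
            row.update(fv.as_dict())
            rows.append(row)
    sheet = pd.DataFrame(rows, columns=["participant_id", "segment_label", *FEATURE_NAMES])
    return sheet, sam


def run_pipeline(config: RunConfig) -> dict:
    """Full run; writes all outputs under ``config.out_dir``.

    Outputs: feature_sheet.csv, significance_table.csv, benchmark.csv,
    benchmark.txt and manifest.yaml.  Returns the manifest dict.
    Deterministic: same (config, seed) -> byte-identical files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "effective_config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = f"error: {exc}"
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        sheet, sam = compute_feature_sheet(config)
    except Exception as exc:  # noqa: BLE001
        fail("features", exc)
    write_feature_sheet(sheet, out / "feature_sheet.csv")
    manifest["stages"]["features"] = f"ok: {len(sheet)} rows"

    try:
        sig_table = build_significance_table(
            sheet, alpha=config.alpha, correction=config.correction, pairing=config.pairing
        )
    except Exception as exc:  # noqa: BLE001
        fail("stats", exc)
    sig_table.to_csv(out / "significance_table.csv")
    manifest["stages"]["stats"] = (
        f"ok: {len(sig_table.table)} rows, {sig_table.count_significant()} significant, "
        f"{sig_table.n_flagged} flagged cells"
    )

    try:
        bench_seed = derive_seed(config.seed, "benchmark")
        catalogue = classifier_catalogue()
        results = {}
        for genre in GENRES:
            X, y = build_dataset(sheet, sam, genre, threshold=config.sam_threshold)
            if len(np.unique(y)) < 2:
                msg = f"benchmark/{genre}: single-class labels, genre skipped"
                logger.warning(msg)
                manifest["warnings"].append(msg)
                continue
            results[genre] = run_benchmark(
                X, y, catalogue, n_iterations=config.n_iterations,
                split=config.split, seed=bench_seed,
            )
        if not results:
            raise ValueError("every genre has single-class labels")
        bench = report_benchmark(results)
    except Exception as exc:  # noqa: BLE001
        fail("benchmark", exc)
    bench.to_csv(out / "benchmark.csv", index=False, float_format="%.17g")
    (out / "benchmark.txt").write_text(format_benchmark(bench) + "\n")
    manifest["stages"]["benchmark"] = f"ok: {len(bench)} rows"

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def export_synthetic_cohort(config: SyntheticConfig, out_dir: str | Path) -> None:
    """Write a simulated cohort to disk in the standard file shapes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = simulate_cohort(config)
    sam_all = []
    for s in sessions:
        write_e4_eda(s.signal, out / f"{s.participant_id}_eda.csv")
        write_events(s.events, out / f"{s.participant_id}_events.csv")
        sam_all.extend(s.sam)
    write_sam(sam_all, out / "sam.csv")
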