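"""End-to-end pipeline: simulate (or load) -> segment -> measure -> classify
-> statistics, with per-stage artifact persistence and structured logging.

All randomness flows from the single ``seed`` in :class:`RunConfig`; a rerun
with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as xio
from .classify import DEFAULT_SAME_END_RATIO, classify_gallery
from .morphometry import measure_all
from .phantom import PhantomConfig, default_fixture_configs, generate_phantom
from .segment import (
    AIR_INTERVAL,
    DEFAULT_MAX_GAP_MM,
    FRASS_BAND_HALFWIDTH,
    FRASS_LEVEL,
    segment_volume,
)
from .stats import summarize_metrics

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("xylotrace")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and volume identifier."""

    def __init__(self, stage: str, ident: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {ident}: {cause}")
        self.stage = stage
        self.ident = ident
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``volumes`` lists input volume files (TIFF + sidecar, or NRRD) or
    ``phantoms`` lists phantom configurations to simulate; leaving both empty
    runs the packaged five-segment fixture.
    """

    outdir: str = "xylotrace_out"
    volumes: list = field(default_factory=list)  # paths of input volumes
    phantoms: list = field(default_factory=list)  # PhantomConfig entries
    seed: int = 0
    threshold_low: float = AIR_INTERVAL[0]
    threshold_high: float = AIR_INTERVAL[1]
    connectivity: int = 26
    max_gap_mm: float = DEFAULT_MAX_GAP_MM
    frass_level: float = FRASS_LEVEL
    band_halfwidth: float = FRASS_BAND_HALFWIDTH
    smooth_radius_mm: float = 0.5
    same_end_ratio: float = DEFAULT_SAME_END_RATIO
    alpha: float = 0.05
    save_volumes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = xio.load_yaml_config(path)
        phantoms = [PhantomConfig(**p) for p in doc.pop("phantoms", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown configuration keys: {sorted(bad)}")
        cfg = cls(**doc)
        cfg.phantoms = phantoms
        return cfg


def _stage(name: str, ident: str, fn, *args, **kwargs):
    t0 = time.time()
    try:
        out = fn(*args, **kwargs)
    except Exception as e:  # noqa: BLE001 - rewrapped with context
        raise PipelineError(name, ident, e) from e
    log.info("stage %-9s %-12s %6.1fs", name, ident, time.time() - t0)
    return out


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Run the full pipeline and return (per-gallery metrics, summary report).

    The metrics CSV, the summary report and (for simulated inputs) the ground
    truth JSON are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run: seed=%d outdir=%s", config.seed, outdir)

    sources: list[tuple[str, object]] = []
    if config.volumes:
        sources = [(Path(p).stem, ("file", p)) for p in config.volumes]
    else:
        phantoms = config.phantoms or default_fixture_configs(seed=config.seed)
        sources = [(f"phantom{i}", ("sim", c)) for i, c in enumerate(phantoms)]

    all_rows = []
    next_label_offset = 0
    for ident, (kind, src) in sources:
        if kind == "file":
            volume = _stage("read", ident, xio.read_volume, src)
        else:
            volume, truths, ring = _stage("simulate", ident, generate_phantom, src)
            xio.write_truths(outdir / f"{ident}_truth.json", truths, ring, seed=src.seed)
            if config.save_volumes:
                xio.write_volume(outdir / f"{ident}.nrrd", volume)
        mask = _stage(
            "segment",
            ident,
            segment_volume,
            volume,
            threshold_low=config.threshold_low,
            threshold_high=config.threshold_high,
            connectivity=config.connectivity,
            max_gap_mm=config.max_gap_mm,
            frass_level=config.frass_level,
            band_halfwidth=config.band_halfwidth,
            smooth_radius_mm=config.smooth_radius_mm,
        )
        if config.save_volumes:
            xio.write_mask(
                outdir / f"{ident}_labels.nrrd", outdir / f"{ident}_blocked.nrrd", mask
            )
        metrics, centerlines, _ = _stage("measure", ident, measure_all, volume, mask)
        for m in metrics:
            call = classify_gallery(
                centerlines[m.label],
                m.vertical_length_mm,
                same_end_ratio=config.same_end_ratio,
                label=m.label,
            )
            m.type_label = call.type_label
            row = m.as_row()
            row["volume"] = ident
            row["label"] = next_label_offset + m.label
            row["separation_ratio"] = call.separation_ratio
            all_rows.append(row)
        next_label_offset += mask.n_labels
        log.info("volume %s: %d galleries measured", ident, len(metrics))

    metrics_df = pd.DataFrame(all_rows)
    metrics_path = outdir / "metrics.csv"
    metrics_df.to_csv(metrics_path, index=False, float_format="%.6g")
    log.info("metrics written: %s (%d galleries)", metrics_path, len(metrics_df))

    report = None
    if len(metrics_df):
        report = _stage(
            "stats", "all", summarize_metrics, metrics_df, alpha=config.alpha
        )
        report.to_csv(outdir / "report.csv", index=False, float_format="%.6g")
        (outdir / "report.md").write_text(_report_markdown(report))
    else:
        log.warning("no galleries recovered; statistics stage skipped")
    return metrics_df, report


def _report_markdown(report: pd.DataFrame) -> str:
    lines = [
        "| parameter | type | n | mean ± SE | letter | F | p |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, r in report.iterrows():
        se = "—" if pd.isna(r["se"]) else f"{r['se']:.2f}"
        F = "—" if pd.isna(r["F"]) else f"{r['F']:.2f}"
        p = "—" if pd.isna(r["p"]) else f"{r['p']:.2f}"
        lines.append(
            f"| {r['parameter']} | {r['type']} | {r['n']} | "
            f"{r['mean']:.2f} ± {se} {r['letter']} | {r['letter']} | {F} | {p} |"
        )
    return "\n".join(lines) + "\n"
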