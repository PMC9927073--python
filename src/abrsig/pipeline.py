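"""End-to-end orchestration: simulate -> extract -> fit -> compare ->
trajectories -> report.

The report's delay summary reads the per-region group difference in mean
latency off the fitted Gamma signatures (Gamma mean = shape * scale):

* per-region delay  = ASD mean latency - nonASD mean latency,
* cumulative delay  = sum of the seven per-region delays,
* net cumulative latency (per group) = mean latency of peak VII, i.e. the
  arrival time of the response at the last brainstem region.

Every stage draws its randomness from a substream derived from the single
global seed by stable hashing of the stage name, so results do not depend
on stage execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as abr_io
from .compare import comparison_matrix
from .datamodel import PEAK_LABELS
from .mms import MMSTransformer, extract_peak_table
from .signatures import MIN_SAMPLES, GammaSignature, gamma_signature
from .synthetic import CohortConfig, generate_cohort
from .trajectories import (
    cohort_curve_lengths,
    fit_exponential_growth,
    interaural_differences,
    weekly_cross_section,
)

logger = logging.getLogger("abrsig")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stable under stage order)."""
    return int(
        np.random.SeedSequence(
            [int(global_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
        % 2**31
    )


@dataclass
class PipelineConfig:
    """Knobs for one pipeline run.

    ``min_n`` enforces the 100-sample signature minimum per context cell;
    cells below it are skipped with a logged warning, never silently
    fitted.
    """

    seed: int = 0
    out_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    min_n: int = 100
    star_levels: tuple = (0.05, 0.01)
    n_boot: int = 100
    min_prominence_uv: float = 0.04
    label_mode: str = "rank"
    peak_windows: dict | None = None
    trajectory_group_keys: tuple = ("nursery", "sex")

    def __post_init__(self):
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2")
        if not self.star_levels[0] > self.star_levels[1]:
            raise ValueError("star levels must be ordered (loose, strict)")


def summarize_delays(signatures: dict) -> dict:
    """Per-region latency delay table from group x peak Gamma signatures.

    ``signatures`` maps (group, peak_label) -> GammaSignature fitted on that
    cell's latency samples.  Peaks missing in either group are omitted from
    the table and flagged.
    """
    rows, flagged = [], []
    for label in PEAK_LABELS:
        sig_a = signatures.get(("ASD", label))
        sig_n = signatures.get(("nonASD", label))
        if sig_a is None or sig_n is None:
            flagged.append(label)
            continue
        rows.append(
            {
                "peak_label": label,
                "mean_latency_asd_ms": sig_a.mean,
                "mean_latency_nonasd_ms": sig_n.mean,
                "delay_ms": sig_a.mean - sig_n.mean,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "peak_label",
            "mean_latency_asd_ms",
            "mean_latency_nonasd_ms",
            "delay_ms",
        ],
    )
    out = {"delays": table, "missing_peaks": flagged}
    if len(table):
        out["cumulative_delay_ms"] = float(table["delay_ms"].sum())
        imax = table["delay_ms"].idxmax()
        imin = table["delay_ms"].idxmin()
        out["largest_delay_region"] = str(table.loc[imax, "peak_label"])
        out["largest_delay_ms"] = float(table.loc[imax, "delay_ms"])
        out["smallest_delay_region"] = str(table.loc[imin, "peak_label"])
        out["smallest_delay_ms"] = float(table.loc[imin, "delay_ms"])
    last = table[table["peak_label"] == "VII"]
    if len(last):
        out["net_cumulative_latency_asd_ms"] = float(
            last["mean_latency_asd_ms"].iloc[0]
        )
        out["net_cumulative_latency_nonasd_ms"] = float(
            last["mean_latency_nonasd_ms"].iloc[0]
        )
    return out


def _fit_signatures(peaks: pd.DataFrame, group_of: dict, min_n: int):
    """Gamma signatures of extracted latencies, pooled per (group, peak)."""
    signatures: dict[tuple, GammaSignature] = {}
    skipped: list[dict] = []
    df = peaks.copy()
    df["group"] = df["subject_id"].map(group_of)
    for (group, label), cell in df.groupby(["group", "peak_label"], sort=True):
        x = cell["latency_ms"].to_numpy()
        if len(x) < min_n:
            skipped.append({"group": group, "peak_label": label, "n": len(x)})
            logger.warning(
                "skipping signature for (%s, %s): n=%d below min_n=%d",
                group, label, len(x), min_n,
            )
            continue
        signatures[(group, label)] = gamma_signature(
            x,
            context={"group": group, "peak_label": label, "feature": "latency"},
            allow_small=min_n < MIN_SAMPLES,
        )
    return signatures, skipped


def signatures_to_frame(signatures: dict) -> pd.DataFrame:
    rows = []
    for (group, label), s in sorted(signatures.items()):
        rows.append(
            {
                "group": group,
                "peak_label": label,
                "shape": s.shape,
                "scale": s.scale,
                "ci95_shape_lo": s.ci95_shape[0],
                "ci95_shape_hi": s.ci95_shape[1],
                "ci95_scale_lo": s.ci95_scale[0],
                "ci95_scale_hi": s.ci95_scale[1],
                "mean_ms": s.mean,
                "variance": s.variance,
                "skewness": s.skewness,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the report bundle.

    The bundle holds all stage outputs (metadata, ledger, extracted peaks,
    MMS table, signatures, comparison tables, trajectories, growth fit,
    delay summary).  With ``out_dir`` set, each table is also written as
    CSV plus a ``report.json`` / ``summary.txt`` pair.  Everything is
    deterministic given ``config.seed``.
    """
    # ---- simulate ----------------------------------------------------
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=stage_seed(config.seed, "simulate")
    )
    metadata, recordings, ledger = generate_cohort(cohort_cfg)
    group_of = {m.subject_id: m.group for m in metadata}
    logger.info("simulated %d subjects, %d recordings", len(metadata), len(recordings))

    # ---- extract -----------------------------------------------------
    peaks = extract_peak_table(
        recordings, windows=config.peak_windows,
        min_prominence=config.min_prominence_uv,
        label_mode=config.label_mode,
    )
    mms_table = MMSTransformer(min_prominence=0.0).fit(recordings).transform(recordings)

    # ---- fit ---------------------------------------------------------
    signatures, skipped = _fit_signatures(peaks, group_of, config.min_n)

    # ---- compare -----------------------------------------------------
    cmp_seed = stage_seed(config.seed, "compare")
    df = peaks.copy()
    df["group"] = df["subject_id"].map(group_of)
    ks_rows = []
    for label, cell in df.groupby("peak_label", sort=True):
        by_group = {
            g: sub["latency_ms"].to_numpy() for g, sub in cell.groupby("group")
        }
        if len(by_group) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = comparison_matrix(
                by_group, metric="ks_median_p",
                seed=stage_seed(cmp_seed, f"ks:{label}"),
                n_boot=config.n_boot, star_levels=config.star_levels,
            )
        ks_rows.append(
            {
                "peak_label": label,
                "median_p": mat.values[1, 0],
                "stars": mat.stars[1, 0],
            }
        )
    ks_table = pd.DataFrame(ks_rows, columns=["peak_label", "median_p", "stars"])

    emd_matrices = {}
    for group, sub in df.groupby("group", sort=True):
        by_peak = {
            label: cell["latency_ms"].to_numpy()
            for label, cell in sub.groupby("peak_label", sort=False)
        }
        by_peak = {k: by_peak[k] for k in PEAK_LABELS if k in by_peak}
        if len(by_peak) >= 2:
            emd_matrices[group] = comparison_matrix(by_peak, metric="emd_normalized")

    # ---- trajectories ------------------------------------------------
    from .datamodel import PeakLatencyRow

    peak_rows = [
        PeakLatencyRow(
            subject_id=str(sid), trial_index=int(trial), ear=str(ear),
            db_level=int(db),
            latency_ms=dict(zip(g["peak_label"], g["latency_ms"])),
        )
        for (sid, trial, ear, db), g in peaks.groupby(
            ["subject_id", "trial_index", "ear", "db_level"], sort=True
        )
    ]
    weekly = weekly_cross_section(
        peak_rows, metadata, group_keys=config.trajectory_group_keys
    )
    lengths = cohort_curve_lengths(recordings, metadata)
    interaural = interaural_differences(peak_rows)
    ega = np.array([m.ega_weeks for m in metadata if m.ega_weeks is not None])
    bw = np.array([m.birth_weight_g for m in metadata if m.birth_weight_g is not None])
    growth = fit_exponential_growth(ega, bw) if len(ega) >= 3 else None

    # ---- report ------------------------------------------------------
    delay_summary = summarize_delays(signatures)
    bundle = {
        "config": config,
        "metadata": metadata,
        "recordings": recordings,
        "ledger": ledger,
        "peaks": peaks,
        "mms": mms_table,
        "signatures": signatures,
        "signatures_frame": signatures_to_frame(signatures),
        "skipped_cells": skipped,
        "ks_table": ks_table,
        "emd_matrices": emd_matrices,
        "weekly": weekly,
        "curve_lengths": lengths,
        "interaural": interaural,
        "growth_fit": growth,
        "delay_summary": delay_summary,
    }
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def render_summary(bundle: dict) -> str:
    """Human-readable run summary (all numbers re-derivable from the CSVs)."""
    d = bundle["delay_summary"]
    lines = ["ABR stochastic-signature pipeline summary", ""]
    if len(d["delays"]):
        lines.append("Per-region mean latencies (ms) and delays (ASD - nonASD):")
        for _, r in d["delays"].iterrows():
            lines.append(
                f"  peak {r['peak_label']:>3}: ASD {r['mean_latency_asd_ms']:.3f}"
                f"  nonASD {r['mean_latency_nonasd_ms']:.3f}"
                f"  delay {r['delay_ms']:+.3f}"
            )
        lines.append(f"Cumulative delay: {d['cumulative_delay_ms']:.3f} ms")
        lines.append(
            f"Largest local delay: {d['largest_delay_ms']:.3f} ms "
            f"(region {d['largest_delay_region']}); smallest: "
            f"{d['smallest_delay_ms']:.3f} ms (region {d['smallest_delay_region']})"
        )
    if "net_cumulative_latency_asd_ms" in d:
        lines.append(
            "Net cumulative latency (mean peak VII arrival): "
            f"ASD {d['net_cumulative_latency_asd_ms']:.2f} ms vs "
            f"nonASD {d['net_cumulative_latency_nonasd_ms']:.2f} ms "
            f"(difference {d['net_cumulative_latency_asd_ms'] - d['net_cumulative_latency_nonasd_ms']:.2f} ms)"
        )
    if d["missing_peaks"]:
        lines.append(f"Peaks missing in a group: {d['missing_peaks']}")
    if len(bundle["ks_table"]):
        lines.append("")
        lines.append("Bootstrap-KS ASD vs nonASD (median p, stars):")
        for _, r in bundle["ks_table"].iterrows():
            lines.append(
                f"  peak {r['peak_label']:>3}: p = {r['median_p']:.3g} {r['stars']}"
            )
    g = bundle.get("growth_fit")
    if g is not None:
        lines.append("")
        lines.append(
            f"BW-EGA exponential fit: BW = {g.alpha:.1f} g * exp({g.beta:.4f} * EGA)"
            f"  (log-residual sd {g.sigma:.3f}, n={g.n})"
        )
    return "\n".join(lines) + "\n"


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    abr_io.write_recordings(bundle["recordings"], out_dir / "recordings.csv")
    abr_io.write_metadata(bundle["metadata"], out_dir / "metadata.csv")
    bundle["ledger"].to_csv(out_dir / "ledger.csv", index=False)
    bundle["peaks"].to_csv(out_dir / "peaks.csv", index=False)
    bundle["mms"].to_csv(out_dir / "mms.csv", index=False)
    bundle["signatures_frame"].to_csv(out_dir / "signatures.csv", index=False)
    bundle["ks_table"].to_csv(out_dir / "ks_comparisons.csv", index=False)
    for group, mat in bundle["emd_matrices"].items():
        pd.DataFrame(mat.values, index=mat.labels, columns=mat.labels).to_csv(
            out_dir / f"emd_matrix_{group}.csv"
        )
    bundle["weekly"].to_csv(out_dir / "weekly_trajectories.csv", index=False)
    bundle["curve_lengths"].to_csv(out_dir / "curve_lengths.csv", index=False)
    bundle["interaural"].to_csv(out_dir / "interaural.csv", index=False)
    d = bundle["delay_summary"]
    report = {
        k: v for k, v in d.items() if k not in ("delays",)
    }
    report["delays"] = d["delays"].to_dict(orient="records")
    g = bundle.get("growth_fit")
    if g is not None:
        report["growth_fit"] = {
            "alpha_g": g.alpha, "beta_per_week": g.beta, "sigma_log": g.sigma,
            "n": g.n,
        }
    report["skipped_cells"] = bundle["skipped_cells"]
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    (out_dir / "summary.txt").write_text(render_summary(bundle))


__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "summarize_delays",
    "render_summary",
    "signatures_to_frame",
    "stage_seed",
]
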