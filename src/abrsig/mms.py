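"""Micro-movement spike (MMS) extraction and peak featurization.

The MMS datatype turns a continuous waveform into a unitless spike train in
[0, 1] while preserving peak timing.  The waveform is first rectified as
absolute deviations from its own empirical mean amplitude; each local peak
of the rectified series, sandwiched between two flanking local minima, is
then normalized as

    MMS = Peak / (Peak + A)

where ``A`` is the average of all rectified samples from the left flanking
minimum to the right flanking minimum inclusive.  Because numerator and
denominator share the waveform's physical scale, multiplying the waveform by
any positive constant leaves the MMS values unchanged — this is what scales
out allometric effects (e.g. head-circumference disparities) across
subjects.  Peak prominence and width follow the standard topographic
definitions (width at half prominence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, peak_prominences, peak_widths
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import ABRRecording, PEAK_LABELS, ValidationError
from .synthetic import ConfigError

#: Default per-label latency windows (ms) for peaks I..VII: midpoints of the
#: canonical neonatal mean latencies, half-open [lo, hi).
DEFAULT_PEAK_WINDOWS_MS = {
    "I": (0.8, 2.15),
    "II": (2.15, 3.25),
    "III": (3.25, 4.35),
    "IV": (4.35, 5.25),
    "V": (5.25, 6.10),
    "VI": (6.10, 7.10),
    "VII": (7.10, 9.50),
}

#: Columns of a peak-feature table (one row per detected peak).
PEAK_FEATURE_COLUMNS = [
    "time_ms",
    "amplitude_uv",
    "prominence_uv",
    "width_ms",
    "left_min_ms",
    "right_min_ms",
]


@dataclass(frozen=True)
class MMSSeries:
    """Unitless [0, 1] spike train with preserved peak timestamps.

    ``source_peak_uv`` keeps the original rectified peak values so MMS can be
    scaled back to physical units; ``empirical_mean_uv`` is the mean
    amplitude the deviations were taken from.
    """

    peak_times_ms: np.ndarray
    mms_values: np.ndarray
    source_peak_uv: np.ndarray
    empirical_mean_uv: float

    def __post_init__(self):
        t = np.asarray(self.peak_times_ms, dtype=float)
        v = np.asarray(self.mms_values, dtype=float)
        s = np.asarray(self.source_peak_uv, dtype=float)
        object.__setattr__(self, "peak_times_ms", t)
        object.__setattr__(self, "mms_values", v)
        object.__setattr__(self, "source_peak_uv", s)
        if len(t) == 0 or len(v) != len(t) or len(s) != len(t):
            raise ValidationError("MMS series must be nonempty, equal-length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("MMS peak times must be strictly increasing")
        if np.any((v < 0) | (v > 1)):
            raise ValidationError("MMS values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.mms_values)


def rectify_deviations(recording_or_values) -> np.ndarray:
    """Absolute deviations of the waveform from its own mean amplitude.

    The empirical mean is the arithmetic mean of the trial's samples; it is
    computed per trial because the fluctuation statistics are nonstationary
    across a session.
    """
    if isinstance(recording_or_values, ABRRecording):
        values = recording_or_values.amplitude_uv
    else:
        values = np.asarray(recording_or_values, dtype=float)
    if len(values) < 2:
        raise ValidationError("need at least 2 samples to rectify")
    return np.abs(values - values.mean())


def _flanking_minima(values: np.ndarray) -> np.ndarray:
    """Indices of local minima, plateau left edges, with endpoint sentinels."""
    n = len(values)
    minima, props = find_peaks(-values, plateau_size=(1, None))
    idx = props["left_edges"] if len(minima) else np.array([], dtype=int)
    return np.unique(np.concatenate(([0], idx, [n - 1])))


def detect_peaks(t_ms, values, min_prominence: float = 0.0) -> pd.DataFrame:
    """Strict local maxima of a series, with flanking minima and topographic
    prominence / width-at-half-prominence.

    Endpoints act as minima sentinels.  Amplitude ties across neighbouring
    samples (plateaus) resolve to the earliest sample.  A flat or monotone
    series yields an empty table, not an error.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValidationError("need at least 3 samples for peak detection")
    peaks, props = find_peaks(v, plateau_size=(1, None))
    if len(peaks) == 0:
        return pd.DataFrame(columns=PEAK_FEATURE_COLUMNS)
    # earliest-sample tie rule for plateau peaks
    idx = props["left_edges"]
    prominences, left_bases, right_bases = peak_prominences(v, peaks)
    widths = peak_widths(
        v, peaks, rel_height=0.5, prominence_data=(prominences, left_bases, right_bases)
    )[0]
    dt = float(np.median(np.diff(t)))
    minima = _flanking_minima(v)
    left_min = minima[np.searchsorted(minima, idx, side="left") - 1]
    right_min = minima[np.searchsorted(minima, idx, side="right")]
    table = pd.DataFrame(
        {
            "time_ms": t[idx],
            "amplitude_uv": v[idx],
            "prominence_uv": prominences,
            "width_ms": widths * dt,
            "left_min_ms": t[left_min],
            "right_min_ms": t[right_min],
            "_index": idx,
            "_left_min_index": left_min,
            "_right_min_index": right_min,
        }
    )
    keep = table["prominence_uv"] >= min_prominence
    return table.loc[keep].reset_index(drop=True)


def compute_mms(t_ms, rectified_values, min_prominence: float = 0.0) -> MMSSeries:
    """MMS normalization of a rectified series: Peak / (Peak + A) per peak.

    ``A`` averages every sample from the left flanking minimum to the right
    flanking minimum inclusive, so the peak's own samples contribute.
    Degenerate flat peaks (Peak + A == 0) are skipped with a warning.
    """
    v = np.asarray(rectified_values, dtype=float)
    table = detect_peaks(t_ms, v, min_prominence=min_prominence)
    if len(table) == 0:
        raise ValidationError("no peaks detected; cannot form an MMS series")
    times, mms, source = [], [], []
    for _, row in table.iterrows():
        lo = int(row["_left_min_index"])
        hi = int(row["_right_min_index"])
        peak = v[int(row["_index"])]
        avg = v[lo : hi + 1].mean()
        denom = peak + avg
        if denom == 0.0:
            warnings.warn("degenerate flat peak skipped (Peak + A == 0)")
            continue
        times.append(row["time_ms"])
        mms.append(peak / denom)
        source.append(peak)
    if not times:
        raise ValidationError("all detected peaks were degenerate")
    return MMSSeries(
        peak_times_ms=np.array(times),
        mms_values=np.array(mms),
        source_peak_uv=np.array(source),
        empirical_mean_uv=float(np.asarray(rectified_values).mean()),
    )


def mms_from_recording(
    recording: ABRRecording,
    rectify: str = "deviations",
    min_prominence: float = 0.0,
) -> MMSSeries:
    """Extract the MMS series of one trial.

    ``rectify='deviations'`` (default) takes absolute deviations from the
    trial's empirical mean amplitude; ``rectify='absolute'`` rectifies the
    raw waveform itself.
    """
    if rectify == "deviations":
        series = rectify_deviations(recording)
        mean = float(recording.amplitude_uv.mean())
    elif rectify == "absolute":
        series = np.abs(recording.amplitude_uv)
        mean = 0.0
    else:
        raise ValueError("rectify must be 'deviations' or 'absolute'")
    out = compute_mms(recording.t_ms, series, min_prominence=min_prominence)
    return MMSSeries(
        peak_times_ms=out.peak_times_ms,
        mms_values=out.mms_values,
        source_peak_uv=out.source_peak_uv,
        empirical_mean_uv=mean,
    )


def assign_peak_labels(table: pd.DataFrame, windows=None) -> pd.DataFrame:
    """Label detected peaks I..VII by latency window.

    Each label receives the most prominent peak whose time falls inside its
    half-open window [lo, hi), or stays missing.  Windows must be
    non-overlapping and increasing.
    """
    if windows is None:
        windows = DEFAULT_PEAK_WINDOWS_MS
    items = [(label, windows[label]) for label in PEAK_LABELS if label in windows]
    for (la, (lo_a, hi_a)), (lb, (lo_b, hi_b)) in zip(items, items[1:]):
        if hi_a > lo_b or lo_a >= hi_a or lo_b >= hi_b:
            raise ConfigError(f"windows for {la} and {lb} overlap or are inverted")
    out = table.copy()
    out["peak_label"] = pd.Series([pd.NA] * len(out), dtype="object")
    for label, (lo, hi) in items:
        inside = out.index[(out["time_ms"] >= lo) & (out["time_ms"] < hi)]
        if len(inside) == 0:
            continue
        best = out.loc[inside, "prominence_uv"].idxmax()
        out.loc[best, "peak_label"] = label
    return out


#: Canonical neonatal mean latencies (ms) used as the label template.
CANONICAL_LATENCIES_MS = (1.6, 2.7, 3.8, 4.9, 5.6, 6.6, 7.6)


def assign_peak_labels_rank(
    table: pd.DataFrame,
    t_range=(0.8, 9.5),
    labels=PEAK_LABELS,
    template_ms=CANONICAL_LATENCIES_MS,
    max_missing: int = 2,
) -> pd.DataFrame:
    """Label peaks sequentially by order of occurrence.

    ABR peaks I..VII appear in a fixed order, so after restricting to the
    post-stimulus latency range the ``len(labels)`` most prominent
    detections, sorted by time, receive the labels in order.  Unlike fixed
    latency windows this tolerates global and per-region latency shifts
    between groups.

    When fewer candidates than labels are present (typically an unresolved
    peak merged into a dominant neighbour's flank), the present peaks are
    still labelled: the missing label(s) are inferred by matching candidate
    times to the canonical latency template, allowing a free common shift.
    Trials missing more than ``max_missing`` peaks are left unlabelled.
    """
    from itertools import combinations

    out = table.copy()
    out["peak_label"] = pd.Series([pd.NA] * len(out), dtype="object")
    inside = out.index[(out["time_ms"] >= t_range[0]) & (out["time_ms"] < t_range[1])]
    k = len(labels)
    if len(inside) > k:
        inside = out.loc[inside].nlargest(k, "prominence_uv").index
    m = len(inside)
    if m < k - max_missing or m == 0:
        return out
    ordered = out.loc[inside].sort_values("time_ms").index
    times = out.loc[ordered, "time_ms"].to_numpy()
    template = np.asarray(template_ms, dtype=float)
    best_cost, best_labels = np.inf, None
    for present in combinations(range(k), m):
        tau = template[list(present)]
        shift = times.mean() - tau.mean()
        cost = float(((times - tau - shift) ** 2).sum())
        if cost < best_cost:
            best_cost = cost
            best_labels = [labels[i] for i in present]
    for label, idx in zip(best_labels, ordered):
        out.loc[idx, "peak_label"] = label
    return out


def labeled_latencies(labeled_table: pd.DataFrame) -> dict:
    """Mapping peak label -> latency (ms) from a labelled feature table."""
    present = labeled_table.dropna(subset=["peak_label"])
    return dict(zip(present["peak_label"], present["time_ms"]))


class MMSTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: ABR recordings -> tidy MMS peak table.

    Parameters
    ----------
    rectify : {"deviations", "absolute"}
        How the waveform is rectified before normalization.
    min_prominence : float
        Minimum topographic prominence (in rectified uV) for a peak to be
        kept; 0 keeps every strict local maximum (noise-free data).
    """

    def __init__(self, rectify: str = "deviations", min_prominence: float = 0.0):
        self.rectify = rectify
        self.min_prominence = min_prominence

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of ABRRecording.  One output row per MMS spike."""
        rows = []
        for rec in X:
            series = mms_from_recording(
                rec, rectify=self.rectify, min_prominence=self.min_prominence
            )
            for t, m, s in zip(
                series.peak_times_ms, series.mms_values, series.source_peak_uv
            ):
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "trial_index": rec.trial_index,
                        "ear": rec.ear,
                        "db_level": rec.db_level,
                        "time_ms": t,
                        "mms": m,
                        "source_peak_uv": s,
                        "empirical_mean_uv": series.empirical_mean_uv,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "trial_index",
                "ear",
                "db_level",
                "time_ms",
                "mms",
                "source_peak_uv",
                "empirical_mean_uv",
            ],
        )


def extract_peak_table(
    recordings,
    windows=None,
    min_prominence: float = 0.0,
    label_mode: str = "rank",
    smooth_sigma_ms: float = 0.08,
):
    """Detect and label peaks I..VII on raw waveforms.

    The waveform is lightly low-pass smoothed (Gaussian kernel,
    ``smooth_sigma_ms``) before peak identification: evoked ABR peaks are a
    few tenths of a millisecond wide while acquisition noise is broadband,
    so smoothing suppresses spurious noise peaks without displacing the
    symmetric evoked peaks.  Set ``smooth_sigma_ms=0`` to detect on the raw
    samples.

    ``label_mode='rank'`` (default) labels the seven most prominent
    post-stimulus peaks in order of occurrence; ``label_mode='windows'``
    assigns by fixed latency windows.  Returns a tidy DataFrame (one row per
    labelled peak) with the trial key, peak label, latency and the
    topographic features.
    """
    if label_mode not in ("rank", "windows"):
        raise ValueError("label_mode must be 'rank' or 'windows'")
    rows = []
    for rec in recordings:
        values = rec.amplitude_uv
        if smooth_sigma_ms > 0:
            sigma_samples = smooth_sigma_ms * rec.sampling_rate_hz / 1000.0
            values = gaussian_filter1d(values, sigma_samples)
        table = detect_peaks(rec.t_ms, values, min_prominence=min_prominence)
        if len(table) == 0:
            continue
        if label_mode == "rank":
            labeled = assign_peak_labels_rank(table)
        else:
            labeled = assign_peak_labels(table, windows=windows)
        present = labeled.dropna(subset=["peak_label"])
        for _, row in present.iterrows():
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "trial_index": rec.trial_index,
                    "ear": rec.ear,
                    "db_level": rec.db_level,
                    "peak_label": row["peak_label"],
                    "latency_ms": row["time_ms"],
                    "amplitude_uv": row["amplitude_uv"],
                    "prominence_uv": row["prominence_uv"],
                    "width_ms": row["width_ms"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "trial_index",
            "ear",
            "db_level",
            "peak_label",
            "latency_ms",
            "amplitude_uv",
            "prominence_uv",
            "width_ms",
        ],
    )


__all__ = [
    "MMSSeries",
    "MMSTransformer",
    "rectify_deviations",
    "detect_peaks",
    "compute_mms",
    "mms_from_recording",
    "assign_peak_labels",
    "assign_peak_labels_rank",
    "labeled_latencies",
    "extract_peak_table",
    "DEFAULT_PEAK_WINDOWS_MS",
    "PEAK_FEATURE_COLUMNS",
]
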