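"""Developmental trajectory statistics.

Four cross-sectional summaries of how ABR responses mature over the first
postnatal weeks:

* the waveform curve length ("Distance"): the cumulative sum of absolute
  first differences of a trial's amplitude series.  Shorter lengths indicate
  lower amplitude variability — the unsigned sum would telescope to
  (end - start) and carry no variability information, so absolute deltas are
  used;
* interaural time differences: |right - left| peak V latency per subject;
* weekly cross sections: per (group, week), the median across subjects of
  each subject's minimum peak V latency over their trials;
* the exponential birth-weight growth law BW = alpha * exp(beta * EGA),
  fitted by least squares of log(BW) on EGA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .datamodel import ABRRecording, ValidationError


@dataclass(frozen=True)
class CurveLengthStat:
    """Curve length of one trial's waveform (cumulative |delta| in uV)."""

    subject_id: str
    ear: str
    length_uv: float
    week: int | None = None

    def __post_init__(self):
        if self.length_uv < 0:
            raise ValidationError("curve length must be non-negative")


def curve_length(recording_or_values) -> float:
    """Sum of absolute first differences of the amplitude series."""
    if isinstance(recording_or_values, ABRRecording):
        v = recording_or_values.amplitude_uv
    else:
        v = np.asarray(recording_or_values, dtype=float)
    if len(v) < 2:
        raise ValidationError("need at least 2 samples for a curve length")
    return float(np.abs(np.diff(v)).sum())


def cohort_curve_lengths(recordings, metadata=None) -> pd.DataFrame:
    """Tidy per-trial curve lengths, joined with subject metadata if given."""
    rows = [
        {
            "subject_id": r.subject_id,
            "trial_index": r.trial_index,
            "ear": r.ear,
            "db_level": r.db_level,
            "length_uv": curve_length(r),
        }
        for r in recordings
    ]
    df = pd.DataFrame(
        rows, columns=["subject_id", "trial_index", "ear", "db_level", "length_uv"]
    )
    if metadata is not None:
        meta = pd.DataFrame(
            [
                {
                    "subject_id": m.subject_id,
                    "sex": m.sex,
                    "group": m.group,
                    "nursery": m.nursery,
                    "postnatal_week": m.postnatal_week,
                }
                for m in metadata
            ]
        )
        df = df.merge(meta, on="subject_id", how="left")
    return df


def interaural_difference(lat_left_ms, lat_right_ms):
    """|right - left| peak V latency (ms); None if either ear is missing."""
    if lat_left_ms is None or lat_right_ms is None:
        return None
    if not (lat_left_ms > 0 and lat_right_ms > 0):
        raise ValidationError("latencies must be positive")
    return abs(float(lat_right_ms) - float(lat_left_ms))


def interaural_differences(peak_rows, peak_label: str = "V") -> pd.DataFrame:
    """Per-subject interaural differences of the minimum peak V latency.

    For each subject and ear, the minimum latency of the given peak across
    that subject's trials is taken first; subjects missing an ear are
    flagged with a missing difference.
    """
    rows = []
    for r in peak_rows:
        lat = r.get(peak_label)
        if lat is not None:
            rows.append({"subject_id": r.subject_id, "ear": r.ear, "latency_ms": lat})
    if not rows:
        return pd.DataFrame(columns=["subject_id", "interaural_ms"])
    df = pd.DataFrame(rows)
    per_ear = df.groupby(["subject_id", "ear"])["latency_ms"].min().unstack()
    out = pd.DataFrame(
        {
            "subject_id": per_ear.index,
            "interaural_ms": [
                interaural_difference(
                    row.get("L") if pd.notna(row.get("L")) else None,
                    row.get("R") if pd.notna(row.get("R")) else None,
                )
                for _, row in per_ear.iterrows()
            ],
        }
    ).reset_index(drop=True)
    return out


def weekly_cross_section(
    peak_rows, metadata, group_keys=("nursery", "sex"), peak_label: str = "V"
) -> pd.DataFrame:
    """Weekly medians of per-subject minimum peak latencies.

    For each (group, postnatal week): the median over subjects of each
    subject's minimum latency of ``peak_label`` across all their trials.
    Weeks with no subjects in a group are simply absent (missing, not zero).
    Duplicating a subject's trials cannot change the result because the
    within-subject minimum is taken first.
    """
    meta = {m.subject_id: m for m in metadata}
    if not meta:
        raise ValidationError("no subjects in metadata")
    rows = []
    for r in peak_rows:
        lat = r.get(peak_label)
        m = meta.get(r.subject_id)
        if lat is None or m is None or m.postnatal_week is None:
            continue
        rec = {"subject_id": r.subject_id, "week": m.postnatal_week, "latency_ms": lat}
        for k in group_keys:
            rec[k] = getattr(m, k)
        rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=[*group_keys, "week", "median_min_latency_ms", "n_subjects"])
    df = pd.DataFrame(rows)
    per_subject = (
        df.groupby([*group_keys, "week", "subject_id"])["latency_ms"].min().reset_index()
    )
    out = (
        per_subject.groupby([*group_keys, "week"])["latency_ms"]
        .agg(median_min_latency_ms="median", n_subjects="size")
        .reset_index()
        .sort_values([*group_keys, "week"])
        .reset_index(drop=True)
    )
    return out


def trajectory_slope(weekly: pd.DataFrame) -> float:
    """Least-squares slope (ms/week) of median minimum latency vs week."""
    if len(weekly) < 2:
        raise ValidationError("need at least 2 weekly medians for a slope")
    return float(
        np.polyfit(weekly["week"], weekly["median_min_latency_ms"], 1)[0]
    )


def sample_cohort_lengths(lengths: pd.DataFrame, n: int, seed=None) -> pd.DataFrame:
    """Seeded uniform subsample (without replacement) of curve-length rows,
    e.g. 100 random subjects per group before signature estimation."""
    if n > len(lengths):
        raise ValidationError(f"cannot sample {n} from {len(lengths)} rows")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lengths), size=n, replace=False)
    return lengths.iloc[np.sort(idx)].reset_index(drop=True)


@dataclass(frozen=True)
class GrowthFit:
    """BW = alpha * exp(beta * EGA); sigma is the residual sd of log(BW)."""

    alpha: float
    beta: float
    sigma: float
    n: int


class ExponentialGrowthModel(RegressorMixin, BaseEstimator):
    """Exponential growth fit, sklearn-style: log-linear least squares.

    ``fit(ega_weeks, bw_g)`` exposes ``alpha_`` (g), ``beta_`` (per week),
    ``sigma_`` (residual sd of log BW); ``predict(ega_weeks)`` returns the
    fitted birth weights.
    """

    def fit(self, X, y):
        ega = np.asarray(X, dtype=float).ravel()
        bw = np.asarray(y, dtype=float).ravel()
        if ega.size != bw.size or ega.size < 3:
            raise ValidationError("need >= 3 (EGA, BW) pairs of equal length")
        if np.any(bw <= 0):
            raise ValidationError("birth weights must be positive")
        if np.ptp(ega) == 0.0:
            raise ValidationError("EGA values are all identical")
        log_bw = np.log(bw)
        beta, intercept = np.polyfit(ega, log_bw, 1)
        resid = log_bw - (beta * ega + intercept)
        self.alpha_ = float(np.exp(intercept))
        self.beta_ = float(beta)
        self.sigma_ = float(resid.std(ddof=2)) if ega.size > 2 else 0.0
        self.n_ = ega.size
        return self

    def predict(self, X) -> np.ndarray:
        ega = np.asarray(X, dtype=float)
        return self.alpha_ * np.exp(self.beta_ * ega)


def fit_exponential_growth(ega_weeks, bw_g) -> GrowthFit:
    """GrowthFit(alpha, beta, sigma) of BW = alpha * exp(beta * EGA)."""
    m = ExponentialGrowthModel().fit(ega_weeks, bw_g)
    return GrowthFit(alpha=m.alpha_, beta=m.beta_, sigma=m.sigma_, n=m.n_)


__all__ = [
    "CurveLengthStat",
    "GrowthFit",
    "ExponentialGrowthModel",
    "curve_length",
    "cohort_curve_lengths",
    "interaural_difference",
    "interaural_differences",
    "weekly_cross_section",
    "trajectory_slope",
    "sample_cohort_lengths",
    "fit_exponential_growth",
]
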