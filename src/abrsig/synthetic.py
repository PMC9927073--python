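"""Synthetic ABR cohort generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without clinical data:

* a Dirac-delta-like evoked waveform with seven Gaussian-shaped peaks
  (peak V dominant), embedded in pre-stimulus and post-refractory baseline
  noise, repeated at 70/75/80 dB with monotone amplitude scaling;
* per-region latency means shifted in the ASD-like group by a configurable
  delay vector whose default sums to 1.74 ms (largest shift region VII,
  smallest region III) with *narrowed* latency dispersion (factor 0.5);
* trial-to-trial latency randomness drawn from Gamma distributions about the
  per-region means — the family the downstream MLE fit is expected to pick;
* per-subject allometric amplitude scaling (a head-circumference proxy) that
  the MMS normalization must scale out;
* an exponential birth-weight vs gestational-age growth law
  BW = alpha * exp(beta * EGA) * lognormal noise over 24-41 weeks.

Every draw is recorded in a "truth ledger" so recovery tests can compare
estimates against the latent values.  The seed fully determines the output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ABRRecording, PeakLatencyRow, SubjectMetadata, PEAK_LABELS


class ConfigError(ValueError):
    """Inconsistent cohort configuration."""


LEDGER_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "nursery",
    "term",
    "postnatal_week",
    "ega_weeks",
    "birth_weight_g",
    "allometric_scale",
    "trial_index",
    "ear",
    "db_level",
    "peak_label",
    "latency_ms",
    "amplitude_uv",
]


@dataclass(frozen=True)
class CohortConfig:
    """Conditions under which a synthetic cohort is generated.

    Defaults emulate a neonatal ASD/nonASD comparison cohort: 20 subjects
    per group, 3 dB levels x 2 ears x 2 trials each, 25 kHz sampling over a
    -2..+12 ms epoch.  Weekly latency drift is off by default; the
    WBN/NICU maturation conditions set ``weekly_drift_ms`` explicitly.
    """

    n_asd: int = 20
    n_nonasd: int = 20
    trials_per_db: int = 2
    db_levels: tuple = (70, 75, 80)
    sampling_rate_hz: float = 25000.0
    epoch_ms: tuple = (-2.0, 12.0)
    #: per-region mean latencies (ms), peaks I..VII, non-ASD-like group
    latency_means_nonasd_ms: tuple = (1.6, 2.7, 3.8, 4.9, 5.6, 6.6, 7.6)
    #: additive per-region delay for the ASD-like group; sums to 1.74 ms
    latency_shift_asd_ms: tuple = (0.20, 0.25, 0.05, 0.30, 0.25, 0.29, 0.40)
    #: trial-to-trial latency sd (ms) in the non-ASD-like group
    latency_sd_ms: float = 0.15
    #: multiplier on latency sd for the ASD-like group (< 1: narrower band)
    dispersion_factor_asd: float = 0.5
    #: base evoked peak amplitudes (uV) at 70 dB, peak V dominant
    peak_amplitudes_uv: tuple = (0.20, 0.25, 0.20, 0.25, 0.50, 0.30, 0.25)
    #: lognormal sigma of per-trial per-peak amplitude jitter
    amplitude_jitter_sd: float = 0.10
    #: Gaussian bump sigma (ms); 0.1274 gives 0.30 ms FWHM
    peak_width_ms: float = 0.1274
    #: baseline (residual, post-averaging-grade) noise sd, uV
    noise_sd_uv: float = 0.02
    #: lognormal sigma of the per-subject allometric amplitude multiplier
    allometric_sd: float = 0.15
    #: probability of NICU assignment (else WBN)
    p_nicu: float = 0.5
    #: per-nursery latency drift (ms per postnatal week), applied to all peaks
    weekly_drift_ms: dict = field(default_factory=lambda: {"WBN": 0.0, "NICU": 0.0})
    postnatal_week_range: tuple = (1, 8)
    ega_range_weeks: tuple = (24.0, 41.0)
    #: BW = bw_alpha_g * exp(bw_beta_per_week * EGA) * exp(N(0, bw_sigma_log))
    bw_alpha_g: float = 52.0
    bw_beta_per_week: float = 0.105
    bw_sigma_log: float = 0.10
    #: copy the left ear's latency draws to the right ear
    pair_ears: bool = False
    #: generate waveforms (set False to emit only metadata + ledger)
    make_waveforms: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_asd < 0 or self.n_nonasd < 0:
            raise ConfigError("subject counts must be non-negative")
        if self.trials_per_db < 1:
            raise ConfigError("trials_per_db must be >= 1")
        means = np.asarray(self.latency_means_nonasd_ms, dtype=float)
        shifts = np.asarray(self.latency_shift_asd_ms, dtype=float)
        if means.shape != (7,) or shifts.shape != (7,):
            raise ConfigError("latency means and shifts must have 7 entries (I..VII)")
        for name, vec in (("non-ASD", means), ("ASD", means + shifts)):
            if np.any(np.diff(vec) <= 0):
                raise ConfigError(f"{name} latency means must be strictly increasing")
            if vec[0] <= 0 or vec[-1] >= self.epoch_ms[1]:
                raise ConfigError(f"{name} latency means must lie inside the epoch")
        if self.latency_sd_ms <= 0 or self.dispersion_factor_asd <= 0:
            raise ConfigError("latency dispersion parameters must be positive")
        if not self.epoch_ms[0] < 0 < self.epoch_ms[1]:
            raise ConfigError("epoch must straddle stimulus onset (t=0)")
        if self.bw_alpha_g <= 0:
            raise ConfigError("bw_alpha_g must be positive")
        if not 0 <= self.p_nicu <= 1:
            raise ConfigError("p_nicu must be a probability")

    def latency_means(self, group: str) -> np.ndarray:
        means = np.asarray(self.latency_means_nonasd_ms, dtype=float)
        if group == "ASD":
            return means + np.asarray(self.latency_shift_asd_ms, dtype=float)
        return means

    def latency_sd(self, group: str) -> float:
        sd = self.latency_sd_ms
        return sd * self.dispersion_factor_asd if group == "ASD" else sd

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("db_levels", "epoch_ms", "latency_means_nonasd_ms",
                  "latency_shift_asd_ms", "peak_amplitudes_uv",
                  "postnatal_week_range", "ega_range_weeks"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


def time_grid(sampling_rate_hz: float, epoch_ms=(-2.0, 12.0)) -> np.ndarray:
    """Uniform sample times (ms) covering the epoch at the given rate."""
    dt = 1000.0 / sampling_rate_hz
    n = int(round((epoch_ms[1] - epoch_ms[0]) / dt)) + 1
    return epoch_ms[0] + np.arange(n) * dt


def db_scale(db_level: float) -> float:
    """Monotone stimulus-level scaling of evoked amplitude; 1.0 at 70 dB."""
    return (db_level - 60.0) / 10.0


def evoked_waveform(t_ms, latencies_ms, amplitudes_uv, db_level, width_ms=0.1274):
    """Noise-free evoked component: Gaussian bumps at the peak latencies."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    scale = db_scale(db_level)
    for lat, amp in zip(latencies_ms, amplitudes_uv):
        out += amp * scale * np.exp(-0.5 * ((t - lat) / width_ms) ** 2)
    return out


def generate_abr_waveform(
    latencies_ms,
    amplitudes_uv,
    db_level,
    noise_sd_uv=0.0,
    sampling_rate_hz=25000.0,
    seed=None,
    epoch_ms=(-2.0, 12.0),
    width_ms=0.1274,
    subject_id="synthetic",
    trial_index=0,
    ear="L",
) -> ABRRecording:
    """One synthetic ABR trial: evoked Gaussian bumps plus baseline noise.

    Latencies must be strictly increasing and lie inside the post-stimulus
    part of the epoch.  The pre-stimulus segment contains noise only.
    """
    latencies = np.asarray(latencies_ms, dtype=float)
    amplitudes = np.asarray(amplitudes_uv, dtype=float)
    if len(latencies) != len(amplitudes):
        raise ConfigError("latencies and amplitudes must have equal length")
    if np.any(np.diff(latencies) <= 0):
        raise ConfigError("latencies must be strictly increasing")
    if len(latencies) and (latencies[0] <= 0 or latencies[-1] >= epoch_ms[1]):
        raise ConfigError("latencies must lie inside (0, epoch end)")
    t = time_grid(sampling_rate_hz, epoch_ms)
    wave = evoked_waveform(t, latencies, amplitudes, db_level, width_ms)
    if noise_sd_uv > 0:
        rng = np.random.default_rng(seed)
        wave = wave + rng.normal(0.0, noise_sd_uv, size=t.shape)
    return ABRRecording(
        subject_id=subject_id,
        trial_index=trial_index,
        ear=ear,
        db_level=int(db_level),
        sampling_rate_hz=float(sampling_rate_hz),
        t_ms=t,
        amplitude_uv=wave,
    )


def _draw_latencies(rng, means, sd, epoch_end):
    """Gamma-distributed latency vector, redrawn until strictly increasing
    and inside the epoch (rare for realistic spacings)."""
    shapes = (means / sd) ** 2
    scales = sd**2 / means
    for _ in range(1000):
        draw = rng.gamma(shapes, scales)
        if np.all(np.diff(draw) > 0) and draw[0] > 0 and draw[-1] < epoch_end:
            return draw
    raise RuntimeError("could not draw an increasing latency vector")


def generate_cohort(config: CohortConfig):
    """Generate (metadata, recordings, truth ledger) for one cohort.

    The ledger is a tidy DataFrame with one row per latent peak draw
    (subject x trial x ear x dB x peak), recording the drawn latency and the
    fully scaled evoked amplitude, alongside the subject's latent covariates.
    """
    rng = np.random.default_rng(config.seed)
    metadata: list[SubjectMetadata] = []
    recordings: list[ABRRecording] = []
    ledger_rows: list[dict] = []

    groups = [("nonASD", "N", config.n_nonasd), ("ASD", "A", config.n_asd)]
    base_amps = np.asarray(config.peak_amplitudes_uv, dtype=float)
    wk_lo, wk_hi = config.postnatal_week_range

    for group, prefix, n in groups:
        for i in range(n):
            sid = f"{prefix}{i:03d}"
            sex = "F" if rng.random() < 0.5 else "M"
            nursery = "NICU" if rng.random() < config.p_nicu else "WBN"
            ega = rng.uniform(*config.ega_range_weeks)
            term = "FT" if ega >= 37.0 else "PT"
            bw = config.bw_alpha_g * np.exp(
                config.bw_beta_per_week * ega + rng.normal(0.0, config.bw_sigma_log)
            )
            week = int(rng.integers(wk_lo, wk_hi + 1))
            allometric = float(np.exp(rng.normal(0.0, config.allometric_sd)))
            metadata.append(
                SubjectMetadata(
                    subject_id=sid,
                    sex=sex,
                    group=group,
                    nursery=nursery,
                    term=term,
                    birth_weight_g=float(bw),
                    ega_weeks=float(ega),
                    postnatal_week=week,
                )
            )
            drift = config.weekly_drift_ms.get(nursery, 0.0) * (week - wk_lo)
            means = config.latency_means(group) + drift
            sd = config.latency_sd(group)
            for db in config.db_levels:
                for trial in range(config.trials_per_db):
                    lat_L = _draw_latencies(rng, means, sd, config.epoch_ms[1])
                    lats = {"L": lat_L}
                    if config.pair_ears:
                        lats["R"] = lat_L.copy()
                    else:
                        lats["R"] = _draw_latencies(
                            rng, means, sd, config.epoch_ms[1]
                        )
                    for ear in ("L", "R"):
                        jitter = np.exp(
                            rng.normal(0.0, config.amplitude_jitter_sd, size=7)
                        )
                        amps = base_amps * jitter * allometric
                        for label, lat, amp in zip(PEAK_LABELS, lats[ear], amps):
                            ledger_rows.append(
                                {
                                    "subject_id": sid,
                                    "group": group,
                                    "sex": sex,
                                    "nursery": nursery,
                                    "term": term,
                                    "postnatal_week": week,
                                    "ega_weeks": ega,
                                    "birth_weight_g": bw,
                                    "allometric_scale": allometric,
                                    "trial_index": trial,
                                    "ear": ear,
                                    "db_level": int(db),
                                    "peak_label": label,
                                    "latency_ms": float(lat),
                                    "amplitude_uv": float(amp * db_scale(db)),
                                }
                            )
                        if config.make_waveforms:
                            recordings.append(
                                generate_abr_waveform(
                                    lats[ear],
                                    amps,
                                    db,
                                    noise_sd_uv=config.noise_sd_uv,
                                    sampling_rate_hz=config.sampling_rate_hz,
                                    seed=rng.integers(2**31),
                                    epoch_ms=config.epoch_ms,
                                    width_ms=config.peak_width_ms,
                                    subject_id=sid,
                                    trial_index=trial,
                                    ear=ear,
                                )
                            )
    ledger = pd.DataFrame(ledger_rows, columns=LEDGER_COLUMNS)
    return metadata, recordings, ledger


def peak_table_from_ledger(ledger: pd.DataFrame) -> list[PeakLatencyRow]:
    """The latent latencies repackaged as a peak-latency table (ground truth)."""
    rows = []
    for (sid, trial, ear, db), g in ledger.groupby(
        ["subject_id", "trial_index", "ear", "db_level"], sort=True
    ):
        rows.append(
            PeakLatencyRow(
                subject_id=str(sid),
                trial_index=int(trial),
                ear=str(ear),
                db_level=int(db),
                latency_ms=dict(zip(g["peak_label"], g["latency_ms"])),
            )
        )
    return rows


__all__ = [
    "CohortConfig",
    "ConfigError",
    "generate_cohort",
    "generate_abr_waveform",
    "evoked_waveform",
    "peak_table_from_ledger",
    "time_grid",
    "db_scale",
    "LEDGER_COLUMNS",
]
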