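"""Domain types for ABR waveform analysis.

An auditory brainstem response (ABR) test delivers a click or burst stimulus
and records the scalp potential for a few milliseconds.  The evoked waveform
carries up to seven canonical peaks (labelled I--VII) whose latencies track
the propagation of the auditory signal from the cochlear nerve through the
brainstem.  These types hold one trial's waveform, the per-peak latency
table, and the subject-level metadata (nursery, term status, birth weight,
gestational age) that the downstream statistics condition on.

All times are in milliseconds relative to stimulus onset (t = 0); amplitudes
are in microvolts.  Missing values are represented as ``None``, never 0 —
zero is a legal amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

PEAK_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")

EARS = ("L", "R")
SEXES = ("F", "M")
GROUPS = ("ASD", "nonASD", "unknown")
NURSERIES = ("WBN", "NICU", "unknown")
TERMS = ("FT", "PT", "unknown")

#: EGA plausibility window (weeks) for validation.
EGA_RANGE_WEEKS = (20.0, 45.0)

#: Peak latencies must fall in this half-open interval (ms).
LATENCY_RANGE_MS = (0.0, 15.0)


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """A file does not have the expected tabular layout."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class ABRRecording:
    """One trial's ABR waveform with its acquisition context.

    Parameters
    ----------
    subject_id : str
    trial_index : int
        Non-negative trial counter within (subject, ear, dB) cell.
    ear : {"L", "R"}
    db_level : int
        Stimulus level in dB (typically 70, 75, or 80).
    sampling_rate_hz : float
        25000 for the neonatal acquisition convention, 40000 for children.
    t_ms : array
        Strictly increasing sample times in ms; t = 0 is stimulus onset,
        pre-stimulus samples are negative.
    amplitude_uv : array
        Same-length scalp potential in microvolts.
    """

    subject_id: str
    trial_index: int
    ear: str
    db_level: int
    sampling_rate_hz: float
    t_ms: np.ndarray
    amplitude_uv: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t_ms", _as_float_array(self.t_ms, "t_ms"))
        object.__setattr__(
            self, "amplitude_uv", _as_float_array(self.amplitude_uv, "amplitude_uv")
        )
        key = f"(subject={self.subject_id!r}, trial={self.trial_index})"
        if self.trial_index < 0:
            raise ValidationError(f"trial_index must be >= 0 in {key}")
        if self.ear not in EARS:
            raise ValidationError(f"ear must be one of {EARS} in {key}")
        if not self.sampling_rate_hz > 0:
            raise ValidationError(f"sampling_rate_hz must be positive in {key}")
        n = len(self.t_ms)
        if n < 2 or len(self.amplitude_uv) != n:
            raise ValidationError(
                f"t_ms and amplitude_uv must be equal length >= 2 in {key}"
            )
        dt = np.diff(self.t_ms)
        if not np.all(dt > 0):
            raise ValidationError(f"t_ms must be strictly increasing in {key}")
        expected_dt = 1000.0 / self.sampling_rate_hz
        if not np.allclose(dt, expected_dt, rtol=1e-9, atol=0.0):
            raise ValidationError(
                f"sampling interval inconsistent with sampling_rate_hz in {key}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ABRRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.trial_index == other.trial_index
            and self.ear == other.ear
            and self.db_level == other.db_level
            and self.sampling_rate_hz == other.sampling_rate_hz
            and np.array_equal(self.t_ms, other.t_ms)
            and np.array_equal(self.amplitude_uv, other.amplitude_uv)
        )

    __hash__ = None


@dataclass(frozen=True)
class SubjectMetadata:
    """Per-subject demographic and clinical context.

    Exactly one of ``postnatal_week`` (neonatal cohorts) or ``age_years``
    (child cohorts) is present, per the cohort's convention.
    """

    subject_id: str
    sex: str = "F"
    group: str = "unknown"
    nursery: str = "unknown"
    term: str = "unknown"
    birth_weight_g: float | None = None
    ega_weeks: float | None = None
    postnatal_week: int | None = None
    age_years: float | None = None

    def __post_init__(self):
        key = f"(subject={self.subject_id!r})"
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES} in {key}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS} in {key}")
        if self.nursery not in NURSERIES:
            raise ValidationError(f"nursery must be one of {NURSERIES} in {key}")
        if self.term not in TERMS:
            raise ValidationError(f"term must be one of {TERMS} in {key}")
        if self.birth_weight_g is not None and not self.birth_weight_g > 0:
            raise ValidationError(f"birth_weight_g must be positive in {key}")
        if self.ega_weeks is not None and not (
            EGA_RANGE_WEEKS[0] <= self.ega_weeks <= EGA_RANGE_WEEKS[1]
        ):
            raise ValidationError(
                f"ega_weeks must lie in {EGA_RANGE_WEEKS} in {key}"
            )
        if self.postnatal_week is not None and not self.postnatal_week >= 1:
            raise ValidationError(f"postnatal_week must be >= 1 in {key}")
        if self.age_years is not None and not self.age_years > 0:
            raise ValidationError(f"age_years must be positive in {key}")
        if (self.postnatal_week is None) == (self.age_years is None):
            raise ValidationError(
                f"exactly one of postnatal_week / age_years must be present in {key}"
            )


@dataclass(frozen=True)
class PeakLatencyRow:
    """Peak I--VII latencies (ms) for one trial of one ear at one dB level.

    Entries may be missing; the present ones must be strictly increasing in
    peak-label order and lie in (0, 15] ms.
    """

    subject_id: str
    trial_index: int
    ear: str
    db_level: int
    latency_ms: dict = field(default_factory=dict)

    def __post_init__(self):
        key = f"(subject={self.subject_id!r}, trial={self.trial_index})"
        if self.ear not in EARS:
            raise ValidationError(f"ear must be one of {EARS} in {key}")
        unknown = set(self.latency_ms) - set(PEAK_LABELS)
        if unknown:
            raise ValidationError(f"unknown peak labels {sorted(unknown)} in {key}")
        present = [
            (label, self.latency_ms[label])
            for label in PEAK_LABELS
            if self.latency_ms.get(label) is not None
        ]
        for label, lat in present:
            if not (LATENCY_RANGE_MS[0] < lat <= LATENCY_RANGE_MS[1]) or math.isnan(lat):
                raise ValidationError(
                    f"latency for peak {label} outside (0, 15] ms in {key}"
                )
        values = [lat for _, lat in present]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValidationError(
                f"latencies must be strictly increasing I..VII in {key}"
            )

    def get(self, label: str):
        return self.latency_ms.get(label)


def check_unique_subjects(metadata) -> None:
    """Raise if two metadata entries share a subject_id."""
    seen = set()
    for m in metadata:
        if m.subject_id in seen:
            raise ValidationError(f"duplicate subject_id {m.subject_id!r} in cohort")
        seen.add(m.subject_id)


def metadata_fields() -> list[str]:
    return [f.name for f in fields(SubjectMetadata)]
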