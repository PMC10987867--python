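"""QRS morphology features and the automatic precordial R/S transition.

Operates on delineated 12-lead ECGs: beats are given by fiducials (QRS
onset / R peak / offset), not detected here.  Two feature families are
produced: per-lead decile voltages (the mean voltage of each 10% section
of the QRS complex) and the precordial R/S transition, i.e. the first
chest lead (V1..V6) in which the R wave dominates the S wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 12 standard leads, in the fixed order used everywhere in this package.
LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Precordial (chest) leads, V1..V6.
PRECORDIAL_LEADS: tuple[str, ...] = LEADS[6:]

#: Sentinel transition index when no precordial lead has a dominant R wave.
NO_TRANSITION: int = 7

#: Epsilon below which an R or S amplitude is treated as absent (mV).
RS_EPSILON: float = 1e-6

#: R/S ratio assigned when R is present but S is (numerically) absent.
RS_RATIO_CAP: float = 1e6

#: Amplitude threshold (mV) for the binarized V3 feature.
V3_AMPLITUDE_THRESHOLD_MV: float = 1.0

SINUS = "sinus"
PVC = "pvc"


def _lead_index(lead: str) -> int:
    try:
        return LEADS.index(lead)
    except ValueError:
        raise KeyError(f"unknown lead {lead!r}; expected one of {LEADS}") from None


@dataclass(frozen=True)
class EcgRecord:
    """A 12-lead ECG: signal matrix (samples x 12, mV) plus sampling rate."""

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = LEADS

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "lead_names", tuple(self.lead_names))
        if sig.ndim != 2 or sig.shape[1] != 12:
            raise ValueError(f"signal must be (samples, 12), got {sig.shape}")
        if sorted(self.lead_names) != sorted(LEADS) or len(self.lead_names) != 12:
            raise ValueError("record must contain each of the 12 standard leads exactly once")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(sig).any():
            raise ValueError("signal contains NaN samples")
        if self.lead_names != LEADS:
            # normalise column order so downstream indexing is fixed
            order = [self.lead_names.index(l) for l in LEADS]
            object.__setattr__(self, "signal", sig[:, order])
            object.__setattr__(self, "lead_names", LEADS)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def lead(self, name: str) -> np.ndarray:
        return self.signal[:, _lead_index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.signal, columns=list(LEADS))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float) -> "EcgRecord":
        missing = [l for l in LEADS if l not in df.columns]
        if missing:
            raise ValueError(f"missing leads in dataframe: {missing}")
        return cls(df[list(LEADS)].to_numpy(dtype=float), fs=fs)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float) -> "EcgRecord":
        return cls.from_dataframe(pd.read_csv(path), fs=fs)


@dataclass(frozen=True)
class BeatAnnotation:
    """Fiducials of one beat: half-open sample window [onset, offset), 0-based."""

    beat_type: str
    onset: int
    peak: int
    offset: int

    def __post_init__(self) -> None:
        bt = self.beat_type.lower()
        if bt not in (SINUS, PVC):
            raise ValueError(f"beat_type must be 'sinus' or 'pvc', got {self.beat_type!r}")
        object.__setattr__(self, "beat_type", bt)
        if not (self.onset < self.peak < self.offset):
            raise ValueError(
                f"fiducials must satisfy onset < peak < offset, got "
                f"({self.onset}, {self.peak}, {self.offset})"
            )


@dataclass(frozen=True)
class QrsSegment:
    """Baseline-corrected per-lead QRS waveform between onset and offset.

    Baseline correction subtracts each lead's value at QRS onset, so every
    lead starts at exactly 0 mV.
    """

    signal: np.ndarray  # (n_samples, 12), mV
    fs: float
    beat_type: str

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        if sig.ndim != 2 or sig.shape[1] != 12:
            raise ValueError(f"segment signal must be (samples, 12), got {sig.shape}")
        if sig.shape[0] < 10:
            raise ValueError(f"QRS segment needs >= 10 samples, got {sig.shape[0]}")
        if not np.allclose(sig[0], 0.0, atol=1e-12):
            raise ValueError("segment is not baseline-corrected (lead values at onset != 0)")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def lead(self, name: str) -> np.ndarray:
        return self.signal[:, _lead_index(name)]

    @classmethod
    def from_record(cls, record: EcgRecord, beat: BeatAnnotation) -> "QrsSegment":
        if beat.offset > record.n_samples:
            raise ValueError("beat offset exceeds record length")
        window = record.signal[beat.onset:beat.offset]
        return cls(window - window[0], fs=record.fs, beat_type=beat.beat_type)


@dataclass(frozen=True)
class RsMeasurement:
    """Per-lead R amplitude, S amplitude (both >= 0, mV) and R/S ratio."""

    lead: str
    r_amplitude: float
    s_amplitude: float
    ratio: float


@dataclass(frozen=True)
class PrecordialTransition:
    """R/S measurements for V1..V6 and the detected transition lead index.

    ``index`` is the smallest k in 1..6 with R/S ratio >= 1 in lead Vk, or
    the sentinel ``NO_TRANSITION`` (7) when no chest lead has a dominant R.
    """

    measurements: tuple[RsMeasurement, ...]
    index: int

    def __post_init__(self) -> None:
        if len(self.measurements) != 6:
            raise ValueError("expected 6 precordial measurements")
        if not (1 <= self.index <= NO_TRANSITION):
            raise ValueError(f"transition index out of range: {self.index}")

    @property
    def ratios(self) -> tuple[float, ...]:
        return tuple(m.ratio for m in self.measurements)


# ---------------------------------------------------------------------------
# beat selection


def extract_pvc_and_preceding_sinus(
    record: EcgRecord, annotations: Sequence[BeatAnnotation]
) -> tuple[QrsSegment, QrsSegment]:
    """Select the first PVC (by onset) and its nearest preceding sinus beat.

    Returns the pair ``(sinus_segment, pvc_segment)``, each baseline
    corrected by subtracting the lead value at QRS onset.
    """
    pvcs = sorted((a for a in annotations if a.beat_type == PVC), key=lambda a: a.onset)
    if not pvcs:
        raise ValueError("no PVC annotated")
    pvc = pvcs[0]
    sinus_before = [a for a in annotations if a.beat_type == SINUS and a.onset < pvc.onset]
    if not sinus_before:
        raise ValueError("PVC has no preceding sinus beat")
    sinus = max(sinus_before, key=lambda a: a.onset)
    return QrsSegment.from_record(record, sinus), QrsSegment.from_record(record, pvc)


# ---------------------------------------------------------------------------
# decile morphology features


def decile_feature_names(leads: Iterable[str] = LEADS) -> list[str]:
    """Feature names ``<lead>_s<i>`` for i = 1..10, concatenated per lead."""
    return [f"{lead}_s{i}" for lead in leads for i in range(1, 11)]


def _section_means(x: np.ndarray) -> np.ndarray:
    """Mean voltage of each 10% section of ``x`` (duration-weighted).

    Section boundaries sit at the fractional sample positions i*n/10, and a
    sample straddling a boundary contributes to both sections in proportion
    to the overlap.  This makes the features exactly invariant to uniform
    integer upsampling of the segment and reduces to plain window means
    whenever the length is a multiple of 10.
    """
    n = x.size
    edges = np.arange(11) * (n / 10.0)
    out = np.empty(10)
    for i in range(10):
        lo, hi = edges[i], edges[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        idx = np.arange(j0, j1)
        w = np.minimum(idx + 1.0, hi) - np.maximum(idx.astype(float), lo)
        out[i] = float(w @ x[j0:j1]) / (hi - lo)
    return out


def decile_features(segment: QrsSegment) -> np.ndarray:
    """120 features: mean voltage of each 10% QRS section, per lead.

    Concatenation order is the fixed lead order I, II, III, aVR, aVL, aVF,
    V1..V6; within a lead, sections run from QRS onset to offset.
    """
    if segment.n_samples < 10:
        raise ValueError("segment too short for decile features")
    return np.concatenate([_section_means(segment.lead(l)) for l in LEADS])


# ---------------------------------------------------------------------------
# R/S measurements and the precordial transition


def rs_measurement(segment: QrsSegment, lead: str) -> RsMeasurement:
    """R amplitude (max positive), S amplitude (|min| negative) and ratio.

    The ratio is R/S; when S is numerically absent (< RS_EPSILON) the ratio
    is 0 if R is also absent, else RS_RATIO_CAP.
    """
    x = segment.lead(lead)
    r = max(0.0, float(np.max(x)))
    s = max(0.0, float(-np.min(x)))
    if s > RS_EPSILON:
        ratio = r / s
    elif r <= RS_EPSILON:
        ratio = 0.0
    else:
        ratio = RS_RATIO_CAP
    return RsMeasurement(lead=lead, r_amplitude=r, s_amplitude=s, ratio=ratio)


def detect_transition(segment: QrsSegment) -> PrecordialTransition:
    """First precordial lead (V1..V6) whose R wave dominates (R/S >= 1).

    A tie (R == S) counts as dominant.  Leads after the transition are not
    required to stay dominant (first-crossing rule).  If no lead qualifies
    the sentinel index 7 is returned.
    """
    measurements = tuple(rs_measurement(segment, lead) for lead in PRECORDIAL_LEADS)
    index = NO_TRANSITION
    for k, m in enumerate(measurements, start=1):
        if m.ratio >= 1.0:
            index = k
            break
    return PrecordialTransition(measurements=measurements, index=index)


def transition_vector(index: int | PrecordialTransition) -> np.ndarray:
    """One-hot length-6 encoding of a transition index; sentinel 7 -> zeros."""
    if isinstance(index, PrecordialTransition):
        index = index.index
    if not (1 <= index <= NO_TRANSITION):
        raise ValueError(f"transition index out of range: {index}")
    v = np.zeros(6)
    if index <= 6:
        v[index - 1] = 1.0
    return v


def combine_pvc_sinus_transition(
    pvc_index: int, sinus_index: int
) -> tuple[int, np.ndarray]:
    """Standardize the PVC transition by the same patient's sinus transition.

    Returns the scalar difference ``pvc - sinus`` and the elementwise
    difference of the two one-hot vectors (the vPTCps encoding).
    """
    scalar = pvc_index - sinus_index
    vector = transition_vector(pvc_index) - transition_vector(sinus_index)
    return scalar, vector


def transition_agreement_stats(
    pairs: Sequence[tuple[int, int]]
) -> dict[str, float]:
    """Agreement between automatic and clinician-reported transition leads.

    The shift is the absolute index difference.  Returns the exact-agreement
    fraction and the mean, median and interquartile range of the shift.
    """
    if len(pairs) == 0:
        raise ValueError("empty list of transition pairs")
    for a, c in pairs:
        if not (1 <= a <= NO_TRANSITION and 1 <= c <= NO_TRANSITION):
            raise ValueError(f"transition indices must be in 1..7, got ({a}, {c})")
    shifts = np.array([abs(a - c) for a, c in pairs], dtype=float)
    q25, q75 = np.percentile(shifts, [25, 75])
    return {
        "exact_agreement": float(np.mean(shifts == 0)),
        "mean_shift": float(np.mean(shifts)),
        "median_shift": float(np.median(shifts)),
        "iqr_shift": float(q75 - q25),
    }


def v3_amplitude(segment: QrsSegment) -> float:
    """Peak R amplitude (max positive deflection, mV) in lead V3."""
    return rs_measurement(segment, "V3").r_amplitude


def binarize_v3_amplitude(amplitude_mv: float) -> int:
    """Binarized V3 amplitude with the classical > 1 mV threshold."""
    return int(amplitude_mv > V3_AMPLITUDE_THRESHOLD_MV)
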