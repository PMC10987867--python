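"""Synthetic cohorts of outflow-tract arrhythmia patients.

Generates desk-scale cohorts of 12-lead ECGs, each with one sinus beat
followed by one premature ventricular contraction (PVC), plus clinical
covariates.  The generator is phenomenological: every QRS is a sum of
three Gaussian bumps (Q, R, S waves) per lead, parameterized by one of
seven site-of-origin templates.  The templates are built so the signal
carries the class structure the downstream analysis relies on:

* LVOT-side origins (including the aortic cusps) have an earlier
  precordial R/S transition (nominal lead <= V3) and higher voltage in
  the V1-V4 R/S segment than RVOT origins (nominal lead >= V4);
* LVOT templates add a small early positive deflection in V2;
* the right coronary cusp (RCC) sits parametrically closer to the RVOT
  septum than the left coronary cusp (LCC) does, mirroring the observed
  clustering tendencies of cusp origins;
* LVOT patients are drawn older, more often male and more often
  hypertensive than RVOT patients.

None of this is electrophysiological modelling; the waveforms are
carriers for a controlled class signal, nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .qrs import LEADS, PVC, SINUS, BeatAnnotation, EcgRecord
from .scenarios import LVOT, RVOT, ClinicalRecord

#: The seven consolidated site-of-origin labels.
ORIGIN_LABELS: tuple[str, ...] = (
    "RCC",
    "LCC",
    "RCC/LCC commissure",
    "LVOT sub valvular",
    "LV summit",
    "RVOT septum",
    "RVOT free wall",
)

_PRECORDIAL_SLICE = slice(6, 12)


@dataclass(frozen=True)
class OriginTemplate:
    """Per-lead QRS shape parameters for one site of origin.

    Amplitudes are in mV (S and Q amplitudes stored as magnitudes of the
    negative deflection; ``q_amp`` may be signed to model an early
    positive deflection), widths and the QRS duration in ms.  The nominal
    transition lead (1..6 for V1..V6) drives the precordial R/S ramp.
    """

    origin_label: str
    binary_class: str
    r_amp: np.ndarray  # (12,) positive deflection, mV
    s_amp: np.ndarray  # (12,) negative deflection magnitude, mV
    q_amp: np.ndarray  # (12,) signed early deflection, mV (positive = upward)
    q_width_ms: float
    r_width_ms: float
    s_width_ms: float
    qrs_duration_ms: float
    transition_lead: int

    def __post_init__(self) -> None:
        for name in ("r_amp", "s_amp", "q_amp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.binary_class not in (LVOT, RVOT):
            raise ValueError(f"binary_class must be LVOT or RVOT, got {self.binary_class!r}")
        if self.qrs_duration_ms <= 0:
            raise ValueError("QRS duration must be positive")
        for name in ("r_amp", "s_amp", "q_amp"):
            a = getattr(self, name)
            if a.shape != (12,) or not np.isfinite(a).all():
                raise ValueError(f"{name} must be 12 finite per-lead values")
        if not (1 <= self.transition_lead <= 6):
            raise ValueError("nominal transition lead must be in 1..6")
        r, s = self.r_amp[_PRECORDIAL_SLICE], self.s_amp[_PRECORDIAL_SLICE]
        t = self.transition_lead
        if not np.all(s[: t - 1] > r[: t - 1]):
            raise ValueError("S must exceed R in precordial leads before the nominal transition")
        if not np.all(r[t - 1 :] >= s[t - 1 :]):
            raise ValueError("R must be >= S at and after the nominal transition lead")

    def amplitude_vector(self) -> np.ndarray:
        """Concatenated (R, S, Q) amplitudes, for template-distance checks."""
        return np.concatenate([self.r_amp, self.s_amp, self.q_amp])


@dataclass(frozen=True)
class CovariateModel:
    """Class-conditional clinical covariate distributions and class prior."""

    lvot_age_mean: float = 62.0
    lvot_age_sd: float = 10.0
    lvot_p_male: float = 0.7
    lvot_p_hta: float = 0.6
    rvot_age_mean: float = 45.0
    rvot_age_sd: float = 12.0
    rvot_p_male: float = 0.4
    rvot_p_hta: float = 0.3
    rvot_prior: float = 0.69

    def __post_init__(self) -> None:
        for p in (self.lvot_p_male, self.lvot_p_hta, self.rvot_p_male,
                  self.rvot_p_hta, self.rvot_prior):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.lvot_age_sd <= 0 or self.rvot_age_sd <= 0:
            raise ValueError("age standard deviations must be positive")


def default_origin_mix(rvot_prior: float = 0.69) -> dict[str, float]:
    """Default 7-way origin mix with the given RVOT share (even RVOT split)."""
    lvot_share = 1.0 - rvot_prior
    lvot_weights = {  # relative prevalence of LVOT-side origins
        "RCC": 0.26, "LCC": 0.22, "RCC/LCC commissure": 0.16,
        "LVOT sub valvular": 0.20, "LV summit": 0.16,
    }
    mix = {k: lvot_share * w for k, w in lvot_weights.items()}
    mix["RVOT septum"] = rvot_prior / 2
    mix["RVOT free wall"] = rvot_prior / 2
    return mix


#: Probabilities of the clinician-reported transition deviating from the
#: nominal lead by -2..+2 (emulating inter-observer variability).
DEFAULT_PTR_SHIFT_PROBS: tuple[float, ...] = (0.10, 0.25, 0.30, 0.25, 0.10)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Everything needed to generate one reproducible cohort."""

    n_patients: int
    covariates: CovariateModel = field(default_factory=CovariateModel)
    origin_mix: Mapping[str, float] | None = None
    fs: float = 500.0
    noise_sd: float = 0.05
    seed: int = 0
    ptr_shift_probs: tuple[float, ...] = DEFAULT_PTR_SHIFT_PROBS

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        mix = self.origin_mix
        if mix is None:
            mix = default_origin_mix(self.covariates.rvot_prior)
        mix = dict(mix)
        if set(mix) - set(ORIGIN_LABELS):
            raise ValueError(f"unknown origin labels: {set(mix) - set(ORIGIN_LABELS)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("origin mix must sum to 1")
        object.__setattr__(self, "origin_mix", mix)
        object.__setattr__(self, "ptr_shift_probs", tuple(self.ptr_shift_probs))
        if abs(sum(self.ptr_shift_probs) - 1.0) > 1e-9:
            raise ValueError("ptr_shift_probs must sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "covariates": vars(self.covariates).copy(),
            "origin_mix": dict(self.origin_mix),
            "fs": self.fs,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "ptr_shift_probs": list(self.ptr_shift_probs),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticCohortConfig":
        d = dict(d)
        if "covariates" in d and isinstance(d["covariates"], Mapping):
            d["covariates"] = CovariateModel(**d["covariates"])
        if "ptr_shift_probs" in d:
            d["ptr_shift_probs"] = tuple(d["ptr_shift_probs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class CohortSample:
    """One synthetic patient: record, beat fiducials, clinical row, truth."""

    patient_id: str
    record: EcgRecord
    annotations: tuple[BeatAnnotation, ...]
    clinical: ClinicalRecord
    origin_label: str
    binary_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "annotations", tuple(self.annotations))
        types = [a.beat_type for a in self.annotations]
        if types.count(SINUS) != 1 or types.count(PVC) != 1:
            raise ValueError("sample must annotate exactly one sinus and one PVC beat")
        sinus = next(a for a in self.annotations if a.beat_type == SINUS)
        pvc = next(a for a in self.annotations if a.beat_type == PVC)
        if sinus.onset >= pvc.onset:
            raise ValueError("sinus beat must precede the PVC")


# ---------------------------------------------------------------------------
# templates


def _precordial_ramp(transition_lead: int, amp: float, steepness: float = 1.5):
    """Logistic R/S share across V1..V6 crossing 0.5 between leads t-1 and t."""
    k = np.arange(1, 7)
    w = 1.0 / (1.0 + np.exp(-steepness * (k - transition_lead + 0.5)))
    return amp * w, amp * (1.0 - w)


def _make_template(
    label: str,
    binary_class: str,
    transition_lead: int,
    precordial_amp: float,
    *,
    limb_r: Sequence[float],
    limb_s: Sequence[float],
    early_v2: float = 0.0,
    qrs_duration_ms: float = 120.0,
    r_width_ms: float = 8.0,
) -> OriginTemplate:
    r_prec, s_prec = _precordial_ramp(transition_lead, precordial_amp)
    r = np.concatenate([limb_r, r_prec])
    s = np.concatenate([limb_s, s_prec])
    q = np.full(12, -0.05)
    q[LEADS.index("V2")] = early_v2 if early_v2 else -0.05
    return OriginTemplate(
        origin_label=label,
        binary_class=binary_class,
        r_amp=r,
        s_amp=s,
        q_amp=q,
        q_width_ms=6.0,
        r_width_ms=r_width_ms,
        s_width_ms=9.0,
        qrs_duration_ms=qrs_duration_ms,
        transition_lead=transition_lead,
    )


# limb-lead blocks (I, II, III, aVR, aVL, aVF); all origins share the typical
# inferior axis of outflow-tract ectopy, with per-origin variations
_LIMB_INFERIOR_R = (0.30, 1.20, 1.00, 0.05, 0.15, 1.10)
_LIMB_INFERIOR_S = (0.10, 0.10, 0.15, 1.00, 0.50, 0.10)
_LIMB_SUMMIT_R = (0.05, 1.40, 1.30, 0.05, 0.05, 1.35)
_LIMB_SUMMIT_S = (0.60, 0.10, 0.10, 1.10, 0.90, 0.10)
_LIMB_FREEWALL_R = (0.40, 0.95, 0.75, 0.05, 0.25, 0.85)
_LIMB_FREEWALL_S = (0.10, 0.10, 0.20, 0.85, 0.45, 0.10)


def default_templates() -> list[OriginTemplate]:
    """The seven shipped origin templates.

    LVOT-side origins (including the aortic cusps) transition by V3 at the
    latest and carry more precordial voltage; RVOT origins transition at
    V4 or later.  The RCC template is deliberately the LVOT-side origin
    closest (in amplitude space) to the RVOT septum.
    """
    return [
        _make_template("RCC", LVOT, 3, 1.30,
                       limb_r=_LIMB_INFERIOR_R, limb_s=_LIMB_INFERIOR_S,
                       early_v2=0.18),
        _make_template("LCC", LVOT, 2, 1.70,
                       limb_r=_LIMB_INFERIOR_R, limb_s=_LIMB_INFERIOR_S,
                       early_v2=0.22),
        _make_template("RCC/LCC commissure", LVOT, 2, 1.50,
                       limb_r=_LIMB_INFERIOR_R, limb_s=_LIMB_INFERIOR_S,
                       early_v2=0.20),
        _make_template("LVOT sub valvular", LVOT, 1, 1.80,
                       limb_r=_LIMB_INFERIOR_R, limb_s=_LIMB_INFERIOR_S,
                       early_v2=0.15),
        _make_template("LV summit", LVOT, 2, 1.90,
                       limb_r=_LIMB_SUMMIT_R, limb_s=_LIMB_SUMMIT_S,
                       early_v2=0.15, qrs_duration_ms=140.0),
        _make_template("RVOT septum", RVOT, 4, 1.10,
                       limb_r=_LIMB_INFERIOR_R, limb_s=_LIMB_INFERIOR_S),
        _make_template("RVOT free wall", RVOT, 5, 0.90,
                       limb_r=_LIMB_FREEWALL_R, limb_s=_LIMB_FREEWALL_S,
                       qrs_duration_ms=150.0, r_width_ms=11.0),
    ]


#: Class-independent sinus-beat template (typical V3/V4 transition).
SINUS_TEMPLATE = _make_template(
    "sinus", RVOT, 4, 1.20,
    limb_r=(0.60, 0.90, 0.40, 0.05, 0.30, 0.60),
    limb_s=(0.10, 0.10, 0.20, 0.90, 0.30, 0.10),
    qrs_duration_ms=90.0,
)


# ---------------------------------------------------------------------------
# waveform synthesis

# wave centers as fractions of the QRS duration
_Q_CENTER, _R_CENTER, _S_CENTER = 0.18, 0.45, 0.75


def synthesize_beat(
    template: OriginTemplate,
    beat_type: str,
    noise_sd: float,
    rng: np.random.Generator,
    fs: float = 500.0,
) -> tuple[np.ndarray, BeatAnnotation]:
    """One QRS complex per lead as a sum of Gaussian Q/R/S bumps plus noise.

    Sinus beats always use the class-independent sinus template; PVC beats
    use the supplied origin template.  Returns the (n_samples, 12) waveform
    and a beat annotation with onset 0, the R-peak sample and the exclusive
    offset.
    """
    bt = beat_type.lower()
    if bt not in (SINUS, PVC):
        raise ValueError(f"beat_type must be 'sinus' or 'pvc', got {beat_type!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tpl = SINUS_TEMPLATE if bt == SINUS else template
    n = int(round(tpl.qrs_duration_ms * fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs
    d = tpl.qrs_duration_ms

    def bump(center_frac: float, width_ms: float) -> np.ndarray:
        return np.exp(-0.5 * ((t_ms - center_frac * d) / width_ms) ** 2)

    wave = (
        np.outer(bump(_Q_CENTER, tpl.q_width_ms), tpl.q_amp)
        + np.outer(bump(_R_CENTER, tpl.r_width_ms), tpl.r_amp)
        - np.outer(bump(_S_CENTER, tpl.s_width_ms), tpl.s_amp)
    )
    if noise_sd > 0:
        wave = wave + rng.normal(0.0, noise_sd, size=wave.shape)
    peak = int(round(_R_CENTER * d * fs / 1000.0))
    return wave, BeatAnnotation(beat_type=bt, onset=0, peak=peak, offset=n)


# record layout (seconds)
_PRE_ROLL_S = 0.10
_INTER_BEAT_GAP_S = 0.30
_TAIL_S = 0.10


def _assemble_record(
    template: OriginTemplate, noise_sd: float, rng: np.random.Generator, fs: float
) -> tuple[EcgRecord, tuple[BeatAnnotation, BeatAnnotation]]:
    sinus_wave, sinus_ann = synthesize_beat(template, SINUS, 0.0, rng, fs)
    pvc_wave, pvc_ann = synthesize_beat(template, PVC, 0.0, rng, fs)
    pre = int(round(_PRE_ROLL_S * fs))
    gap = int(round(_INTER_BEAT_GAP_S * fs))
    tail = int(round(_TAIL_S * fs))
    n_total = pre + len(sinus_wave) + gap + len(pvc_wave) + tail
    signal = np.zeros((n_total, 12))
    s_on = pre
    p_on = pre + len(sinus_wave) + gap
    signal[s_on : s_on + len(sinus_wave)] = sinus_wave
    signal[p_on : p_on + len(pvc_wave)] = pvc_wave
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    ann = (
        BeatAnnotation(SINUS, s_on, s_on + sinus_ann.peak, s_on + sinus_ann.offset),
        BeatAnnotation(PVC, p_on, p_on + pvc_ann.peak, p_on + pvc_ann.offset),
    )
    return EcgRecord(signal, fs=fs), ann


# ---------------------------------------------------------------------------
# population sampling and cohort generation


def sample_population(config: SyntheticCohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw origins, classes and clinical covariates for every patient.

    The clinician-reported transition (ptr) is the template's nominal
    transition lead plus a random -2..+2 shift, clipped to 1..6.
    """
    templates = {t.origin_label: t for t in default_templates()}
    labels = list(config.origin_mix.keys())
    probs = np.array([config.origin_mix[l] for l in labels])
    cov = config.covariates
    n = config.n_patients
    origins = rng.choice(labels, size=n, p=probs)
    rows = []
    shifts = np.arange(-2, 3)
    for i, origin in enumerate(origins):
        tpl = templates[origin]
        is_lvot = tpl.binary_class == LVOT
        age = float(np.clip(rng.normal(
            cov.lvot_age_mean if is_lvot else cov.rvot_age_mean,
            cov.lvot_age_sd if is_lvot else cov.rvot_age_sd), 18.0, 100.0))
        sex = int(rng.random() < (cov.lvot_p_male if is_lvot else cov.rvot_p_male))
        hta = int(rng.random() < (cov.lvot_p_hta if is_lvot else cov.rvot_p_hta))
        shift = int(rng.choice(shifts, p=config.ptr_shift_probs))
        ptr = int(np.clip(tpl.transition_lead + shift, 1, 6))
        rows.append({
            "patient_id": f"p{i:05d}",
            "origin": origin,
            "binary_class": tpl.binary_class,
            "age": age,
            "sex": sex,
            "hta": hta,
            "ptr": ptr,
        })
    return pd.DataFrame(rows)


def generate_cohort(config: SyntheticCohortConfig) -> list[CohortSample]:
    """Generate the full cohort: population draw plus one ECG per patient."""
    rng = np.random.default_rng(config.seed)
    population = sample_population(config, rng)
    templates = {t.origin_label: t for t in default_templates()}
    samples = []
    for row in population.itertuples(index=False):
        tpl = templates[row.origin]
        record, annotations = _assemble_record(tpl, config.noise_sd, rng, config.fs)
        clinical = ClinicalRecord(
            age=row.age, sex=row.sex, hypertension=row.hta,
            soo_binary=tpl.binary_class, ptr=row.ptr, soo_specific=row.origin,
        )
        samples.append(CohortSample(
            patient_id=row.patient_id,
            record=record,
            annotations=annotations,
            clinical=clinical,
            origin_label=row.origin,
            binary_class=tpl.binary_class,
        ))
    return samples


# ---------------------------------------------------------------------------
# on-disk cohort format (signal CSV + fiducial JSON per patient, cohort CSVs)


def write_cohort(samples: Sequence[CohortSample], directory: str | Path) -> None:
    """Write a cohort as per-patient signal CSV + fiducial JSON and two
    cohort-level CSVs (clinical table, ground truth)."""
    directory = Path(directory)
    (directory / "signals").mkdir(parents=True, exist_ok=True)
    (directory / "fiducials").mkdir(parents=True, exist_ok=True)
    clinical_rows, truth_rows = [], []
    for s in samples:
        s.record.to_csv(directory / "signals" / f"{s.patient_id}.csv")
        beats = [
            {"type": a.beat_type, "onset": a.onset, "peak": a.peak, "offset": a.offset}
            for a in s.annotations
        ]
        with open(directory / "fiducials" / f"{s.patient_id}.json", "w") as fh:
            json.dump({"fs": s.record.fs, "beats": beats}, fh, indent=1)
        c = s.clinical
        clinical_rows.append({
            "patient_id": s.patient_id, "age": c.age, "sex": c.sex, "hta": c.hypertension,
            "ptr": f"V{c.ptr}" if c.ptr is not None and c.ptr <= 6 else "NONE",
            "soo_binary": c.soo_binary, "soo_specific": c.soo_specific or "",
        })
        truth_rows.append({
            "patient_id": s.patient_id, "origin": s.origin_label, "binary_class": s.binary_class,
        })
    pd.DataFrame(clinical_rows).to_csv(directory / "clinical.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(directory / "ground_truth.csv", index=False)


def _parse_ptr(value: str) -> int | None:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    value = str(value)
    if value.upper() == "NONE":
        return 7
    if value.upper().startswith("V"):
        return int(value[1:])
    return int(float(value))


def read_cohort(directory: str | Path) -> list[CohortSample]:
    """Read a cohort written by :func:`write_cohort` (or real data in the
    same schema)."""
    directory = Path(directory)
    clinical = pd.read_csv(directory / "clinical.csv")
    samples = []
    for row in clinical.itertuples(index=False):
        pid = row.patient_id
        with open(directory / "fiducials" / f"{pid}.json") as fh:
            fid = json.load(fh)
        record = EcgRecord.from_csv(directory / "signals" / f"{pid}.csv", fs=fid["fs"])
        annotations = tuple(
            BeatAnnotation(b["type"], b["onset"], b["peak"], b["offset"])
            for b in fid["beats"]
        )
        soo_specific = getattr(row, "soo_specific", None)
        if isinstance(soo_specific, float) and np.isnan(soo_specific):
            soo_specific = None
        clin = ClinicalRecord(
            age=row.age, sex=int(row.sex), hypertension=int(row.hta),
            soo_binary=row.soo_binary, ptr=_parse_ptr(row.ptr),
            soo_specific=soo_specific or None,
        )
        samples.append(CohortSample(
            patient_id=pid, record=record, annotations=annotations, clinical=clin,
            origin_label=soo_specific or "", binary_class=row.soo_binary,
        ))
    return samples
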