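"""Synthetic driver-fatigue cohort generator.

Emulates the statistical structure of the study cohort the analysis pipeline
expects: 9 male + 9 female subjects, 60-minute recordings, an alert->fatigued
changepoint per subject, and a 5-rater per-minute mental-state vote process.

RR intervals are generated directly in the interval domain as

    RR_i = mean_rr + amp_lf * sin(2*pi*0.1*t_i) + amp_hf * sin(2*pi*0.25*t_i) + e_i

with Gaussian noise ``e_i`` and a positive floor.  The modulation phase
``t_i`` advances on the nominal beat clock (``i * mean_rr``) rather than the
realised cumulative time: sampling the sinusoids at realised beat times
would oversample the short-interval phases and bias the per-series mean RR
below ``mean_rr`` by ~(amp_lf^2 + amp_hf^2)/(2*mean_rr), a couple of ms at
the default amplitudes.  On the nominal clock the beat-averaged modulation
is unbiased while the realised spectral peaks stay at ~0.1 and ~0.25 Hz.  The ~0.1 Hz and ~0.25 Hz sinusoids realise LF- and
HF-band spectral power of the magnitude reported for the real cohort; a
sinusoid of amplitude ``a`` contributes ~``a^2/2`` ms^2 to its band.  Default
state/sex parameters are calibrated so group means (mean RR, SDNN, LF/HF
band powers) sit at the alert/fatigued levels of the study's descriptive
tables, with the fatigued state shifted in the reported directions
(longer mean RR, larger variability, higher band powers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ingest import EcgRecord, RRSeries

__all__ = [
    "MENTAL_STATES",
    "VOTE_CATEGORIES",
    "StateParams",
    "CohortConfig",
    "SubjectRecording",
    "default_state_params",
    "generate_rr_series",
    "generate_subject_rr",
    "generate_ecg",
    "generate_expert_votes",
    "generate_cohort",
]

MENTAL_STATES = ("alert", "fatigued")
VOTE_CATEGORIES = ("alert", "fatigued", "very_fatigued")

#: hard floor for a generated interval; 300 ms ~ 200 bpm, far above any
#: excursion the default noise levels produce
RR_FLOOR_MS = 300.0

LF_HZ = 0.1
HF_HZ = 0.25


@dataclass(frozen=True)
class StateParams:
    """Interval-domain generator parameters for one mental state (and sex).

    mean_rr_ms   baseline RR interval
    sd_noise_ms  SD of the white interval noise
    amp_lf_ms    amplitude of the ~0.1 Hz modulation (band power ~ amp^2/2)
    amp_hf_ms    amplitude of the ~0.25 Hz modulation
    """

    mean_rr_ms: float
    sd_noise_ms: float
    amp_lf_ms: float
    amp_hf_ms: float

    def __post_init__(self):
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        if min(self.sd_noise_ms, self.amp_lf_ms, self.amp_hf_ms) < 0:
            raise ValueError("noise SD and modulation amplitudes must be >= 0")


# Calibration: mean_rr from the group mean RR; amp_* = sqrt(2 * band power);
# sd_noise chosen so that total interval variance matches the group SDNN^2
# (SDNN^2 ~ amp_lf^2/2 + amp_hf^2/2 + sd_noise^2).
_DEFAULTS: dict[tuple[str, str | None], StateParams] = {
    ("alert", None): StateParams(801.4, 28.3, 38.2, 32.2),
    ("fatigued", None): StateParams(869.9, 44.1, 53.1, 38.7),
    ("alert", "male"): StateParams(815.9, 29.6, 43.6, 34.7),
    ("fatigued", "male"): StateParams(907.0, 52.0, 62.6, 41.3),
    ("alert", "female"): StateParams(788.2, 27.6, 32.4, 29.8),
    ("fatigued", "female"): StateParams(835.3, 37.6, 42.4, 36.2),
}


def default_state_params(state: str, sex: str | None = None) -> StateParams:
    """Calibrated defaults per mental state, optionally sex-specific."""
    if state not in MENTAL_STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {MENTAL_STATES}")
    if sex not in (None, "male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    return _DEFAULTS[(state, sex)]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings.

    ``fatigue_onset_s`` is either a fixed per-subject changepoint or a
    ``(lo, hi)`` range from which each subject's onset is drawn uniformly.
    The default range (minutes 15-30 of a 60-minute drive) guarantees both
    alert and fatigued segments for every subject, with more fatigued than
    alert windows as in the study.
    """

    n_male: int = 9
    n_female: int = 9
    duration_s: float = 3600.0
    fatigue_onset_s: float | tuple[float, float] = (900.0, 1800.0)
    rater_error_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female < 1:
            raise ValueError("need at least one subject; counts must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        lo, hi = self.onset_range
        if not (0 <= lo <= hi <= self.duration_s):
            raise ValueError("fatigue onset must satisfy 0 <= onset <= duration_s")
        if not 0 <= self.rater_error_rate < 0.5:
            raise ValueError("rater_error_rate must lie in [0, 0.5)")

    @property
    def onset_range(self) -> tuple[float, float]:
        if isinstance(self.fatigue_onset_s, (int, float)):
            return float(self.fatigue_onset_s), float(self.fatigue_onset_s)
        lo, hi = self.fatigue_onset_s
        return float(lo), float(hi)


@dataclass(frozen=True)
class SubjectRecording:
    """One simulated subject: RR series, ground truth, and expert votes."""

    subject_id: str
    sex: str
    rr: RRSeries
    fatigue_onset_s: float
    truth_minutes: tuple[str, ...]      # per-minute true mental state
    votes: tuple[tuple[str, ...], ...]  # per-minute 5-rater votes


# ---------------------------------------------------------------------------
# RR generation
# ---------------------------------------------------------------------------

def _rr_value(t: float, params: StateParams, noise: float) -> float:
    rr = (
        params.mean_rr_ms
        + params.amp_lf_ms * np.sin(2 * np.pi * LF_HZ * t)
        + params.amp_hf_ms * np.sin(2 * np.pi * HF_HZ * t)
        + noise
    )
    return max(rr, RR_FLOOR_MS)


def generate_rr_series(
    state: str,
    sex: str | None,
    duration_s: float,
    params: StateParams | None = None,
    seed: int = 0,
) -> RRSeries:
    """Generate an RR series for a single mental state.

    Cumulative timestamps span at least ``duration_s``; every interval is
    positive (floored at ``RR_FLOOR_MS``).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if params is None:
        params = default_state_params(state, sex)
    rng = np.random.default_rng(seed)
    intervals: list[float] = []
    t = 0.0       # realised cumulative time (stopping criterion)
    phase_t = 0.0  # nominal beat clock driving the modulation phase
    while t < duration_s:
        noise = rng.normal(0.0, params.sd_noise_ms) if params.sd_noise_ms > 0 else 0.0
        rr = _rr_value(phase_t, params, noise)
        intervals.append(rr)
        t += rr / 1000.0
        phase_t += params.mean_rr_ms / 1000.0
    return RRSeries.from_intervals(np.asarray(intervals))


def generate_subject_rr(
    duration_s: float,
    fatigue_onset_s: float,
    params_alert: StateParams,
    params_fatigued: StateParams,
    seed: int = 0,
) -> RRSeries:
    """One recording with a single alert->fatigued changepoint.

    Parameters switch at the interval whose onset time reaches the
    changepoint; sinusoid phase is continuous across it (both states are
    evaluated on the same absolute clock).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 0 <= fatigue_onset_s <= duration_s:
        raise ValueError("fatigue_onset_s must lie within the recording")
    rng = np.random.default_rng(seed)
    intervals: list[float] = []
    t = 0.0
    phase_t = 0.0
    while t < duration_s:
        p = params_alert if t < fatigue_onset_s else params_fatigued
        noise = rng.normal(0.0, p.sd_noise_ms) if p.sd_noise_ms > 0 else 0.0
        rr = _rr_value(phase_t, p, noise)
        intervals.append(rr)
        t += rr / 1000.0
        phase_t += p.mean_rr_ms / 1000.0
    return RRSeries.from_intervals(np.asarray(intervals))


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

# beat template: (offset s, amplitude mV, Gaussian width s); R strictly dominant
_BEAT_WAVES = (
    (-0.180, 0.12, 0.025),   # P
    (-0.025, -0.15, 0.006),  # Q
    (0.000, 1.00, 0.008),    # R
    (0.025, -0.20, 0.006),   # S
    (0.250, 0.30, 0.040),    # T
)


def generate_ecg(
    rr: RRSeries,
    fs: float = 1000.0,
    snr_db: float | None = None,
    seed: int = 0,
    subject_id: str = "",
    sex: str = "",
    lead_in_s: float = 0.4,
) -> EcgRecord:
    """Synthesise an ECG waveform with one template QRS per beat timestamp.

    The record starts ``lead_in_s`` before the first beat so no QRS is
    truncated at the edge; the R peak of beat ``i`` therefore sits at
    ``rr.timestamps[i] + lead_in_s`` seconds into the record.  ``snr_db``
    adds white Gaussian noise at the requested signal-to-noise ratio.
    ``fs`` below 100 Hz cannot resolve the QRS template and is rejected.
    """
    if fs < 100:
        raise ValueError(f"fs={fs} Hz too low to resolve the QRS complex (need >= 100)")
    if rr.timestamps.size == 0:
        return EcgRecord(np.empty(0), fs=fs, subject_id=subject_id, sex=sex)
    beat_times = rr.timestamps - rr.timestamps[0] + lead_in_s
    n = int(np.ceil((beat_times[-1] + 0.4) * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    for offset, amp, width in _BEAT_WAVES:
        centers = beat_times + offset
        # each wave only matters within ~5 widths of its center
        for c in centers:
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n, int((c + 5 * width) * fs) + 1)
            if lo < hi:
                sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        p_signal = float(np.var(sig))
        sigma = np.sqrt(p_signal / 10 ** (snr_db / 10.0))
        sig = sig + rng.normal(0.0, sigma, size=n)
    return EcgRecord(sig, fs=fs, subject_id=subject_id, sex=sex)


# ---------------------------------------------------------------------------
# expert votes
# ---------------------------------------------------------------------------

#: probability that a correct rating during fatigued truth is 'very_fatigued'
P_VERY_FATIGUED = 0.3
N_RATERS = 5


def generate_expert_votes(
    true_timeline,
    error_rate: float = 0.1,
    seed: int = 0,
) -> tuple[tuple[str, ...], ...]:
    """Simulate 5 independent per-minute raters.

    Each rater reports the true (pooled) state with probability
    ``1 - error_rate``.  A correct rating during fatigued truth is
    'very_fatigued' with probability ``P_VERY_FATIGUED``, else 'fatigued'.
    An erroneous rating comes from the opposite pooled state ('alert' truth
    -> uniformly 'fatigued' or 'very_fatigued'; 'fatigued' truth -> 'alert').
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out = []
    for state in true_timeline:
        if state not in MENTAL_STATES:
            raise ValueError(f"unknown true state {state!r}")
        minute = []
        for _ in range(N_RATERS):
            err = rng.random() < error_rate
            if state == "alert":
                if err:
                    minute.append("fatigued" if rng.random() < 0.5 else "very_fatigued")
                else:
                    minute.append("alert")
            else:
                if err:
                    minute.append("alert")
                else:
                    minute.append(
                        "very_fatigued" if rng.random() < P_VERY_FATIGUED else "fatigued"
                    )
        out.append(tuple(minute))
    return tuple(out)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def write_votes(votes, path) -> None:
    """Delimited vote table: minute index then the 5 rater categories."""
    with open(path, "w") as fh:
        fh.write("minute\trater1\trater2\trater3\trater4\trater5\n")
        for m, minute in enumerate(votes):
            fh.write(f"{m}\t" + "\t".join(minute) + "\n")


def read_votes(path) -> tuple[tuple[str, ...], ...]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("minute"):
            raise ValueError(f"{path}: missing vote-table header")
        for line in fh:
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}: expected 6 columns, got {len(parts)}")
            out.append(tuple(parts[1:]))
    return tuple(out)


def truth_timeline(duration_s: float, fatigue_onset_s: float) -> tuple[str, ...]:
    """Per-minute true state; a minute is fatigued once its midpoint passes
    the changepoint."""
    n_min = int(duration_s // 60)
    return tuple(
        "fatigued" if (60 * m + 30) >= fatigue_onset_s else "alert"
        for m in range(n_min)
    )


def generate_cohort(
    config: CohortConfig,
    params: dict[tuple[str, str], StateParams] | None = None,
    sex_specific: bool = True,
) -> list[SubjectRecording]:
    """Simulate the full cohort deterministically from ``config.seed``.

    ``params`` may override the generator parameters per ``(state, sex)``;
    with ``sex_specific=False`` the sex-independent defaults are used for
    both sexes (useful for null-calibration experiments).
    """
    root = np.random.SeedSequence(config.seed)
    subjects = [("male", i) for i in range(config.n_male)] + [
        ("female", i) for i in range(config.n_female)
    ]
    recordings = []
    lo, hi = config.onset_range
    for (sex, i), ss in zip(subjects, root.spawn(len(subjects))):
        child = np.random.default_rng(ss)
        onset = lo if lo == hi else float(child.uniform(lo, hi))
        key_sex = sex if sex_specific else None
        if params is not None:
            pa = params[("alert", sex)]
            pf = params[("fatigued", sex)]
        else:
            pa = default_state_params("alert", key_sex)
            pf = default_state_params("fatigued", key_sex)
        rr_seed = int(child.integers(0, 2**31 - 1))
        vote_seed = int(child.integers(0, 2**31 - 1))
        rr = generate_subject_rr(config.duration_s, onset, pa, pf, seed=rr_seed)
        truth = truth_timeline(config.duration_s, onset)
        votes = generate_expert_votes(truth, config.rater_error_rate, seed=vote_seed)
        recordings.append(
            SubjectRecording(
                subject_id=f"{sex[0].upper()}{i + 1:02d}",
                sex=sex,
                rr=rr,
                fatigue_onset_s=onset,
                truth_minutes=truth,
                votes=votes,
            )
        )
    return recordings
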