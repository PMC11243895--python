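"""The 20-feature HRV battery computed from a single 2-minute RR series.

Time domain
    MRR    mean RR interval (ms)
    DRR    sample SD of RR intervals, i.e. SDNN (ms)
    MHR    mean of instantaneous heart rates 60000/RR_i (1/min)
    DRMS   RMS of successive RR differences, i.e. RMSSD (ms)
    NNN15  number of successive pairs differing by more than 15 ms (beats)
    pNN15  NNN15 / total number of RR intervals * 100 (%)

Frequency domain (RR tachogram resampled to 4 Hz, linearly detrended,
Welch-averaged periodogram; VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz,
HF 0.15-0.40 Hz; VLF enters only the total power — 2-minute records are too
short for the VLF band to be interpreted on its own)
    PLF_abs, PHF_abs   absolute band powers (ms^2)
    PLF_nu, PHF_nu     normalised units, band/(LF+HF)*100
    rLF_HF             LF/HF ratio
    Ptot_abs           VLF+LF+HF power (ms^2)

Nonlinear
    LSD1, LSD2, rSD2_SD1   Poincare-plot short/long axis SDs and their ratio
    EAP                    approximate entropy (m=2, r=0.2*SD, Chebyshev,
                           self-matches included)
    ESamp                  sample entropy (self-matches excluded)
    alpha1, alpha2         DFA scaling exponents over 4-16 and 16-64 beats
    D2                     Grassberger-Procaccia correlation dimension
                           (m=10, tau=1, Theiler window tau)

Undefined quantities (e.g. the SD2/SD1 ratio of a constant series, D2 of a
degenerate embedding) are reported as NaN rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from .ingest import RRSeries
from .windows import Segment

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "SpectralConfig",
    "time_domain",
    "frequency_domain",
    "poincare",
    "approximate_entropy",
    "sample_entropy",
    "dfa",
    "dfa_fluctuations",
    "correlation_dimension",
    "correlation_sums",
    "extract_features",
]

#: canonical feature order (used for output tables and classifier tie-breaks)
FEATURE_NAMES = (
    "MRR", "DRR", "MHR", "DRMS", "NNN15", "pNN15",
    "PLF_abs", "PHF_abs", "PLF_nu", "PHF_nu", "rLF_HF", "Ptot_abs",
    "LSD1", "LSD2", "rSD2_SD1", "EAP", "ESamp", "alpha1", "alpha2", "D2",
)

FEATURE_UNITS = {
    "MRR": "ms", "DRR": "ms", "MHR": "1/min", "DRMS": "ms",
    "NNN15": "beats", "pNN15": "%",
    "PLF_abs": "ms^2", "PHF_abs": "ms^2", "PLF_nu": "n.u.", "PHF_nu": "n.u.",
    "rLF_HF": "-", "Ptot_abs": "ms^2",
    "LSD1": "ms", "LSD2": "ms", "rSD2_SD1": "-", "EAP": "-", "ESamp": "-",
    "alpha1": "-", "alpha2": "-", "D2": "-",
}


@dataclass(frozen=True)
class FeatureVector:
    MRR: float
    DRR: float
    MHR: float
    DRMS: float
    NNN15: float
    pNN15: float
    PLF_abs: float
    PHF_abs: float
    PLF_nu: float
    PHF_nu: float
    rLF_HF: float
    Ptot_abs: float
    LSD1: float
    LSD2: float
    rSD2_SD1: float
    EAP: float
    ESamp: float
    alpha1: float
    alpha2: float
    D2: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral-analysis settings for the RR tachogram."""

    resample_hz: float = 4.0
    detrend: str = "linear"
    vlf_band: tuple[float, float] = (0.0033, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    window_s: float = 64.0
    overlap_fraction: float = 0.5

    def __post_init__(self):
        edges = (
            self.vlf_band[0], self.vlf_band[1],
            self.lf_band[0], self.lf_band[1],
            self.hf_band[0], self.hf_band[1],
        )
        if not (
            0 < edges[0] < edges[1] == edges[2] < edges[3] == edges[4] < edges[5]
            <= self.resample_hz / 2
        ):
            raise ValueError(
                "band edges must satisfy 0 < VLF_lo < VLF_hi = LF_lo < LF_hi "
                "= HF_lo < HF_hi <= resample_hz/2"
            )
        if self.detrend not in ("linear", "constant", "none"):
            raise ValueError("detrend must be 'linear', 'constant' or 'none'")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_domain(rr: RRSeries, nn_threshold_ms: float = 15.0):
    """MRR, DRR, MHR, DRMS, NNN15, pNN15.

    pNN15 uses the total number of RR intervals as denominator (not the
    number of successive pairs).
    """
    iv = rr.intervals
    if iv.size < 2:
        raise ValueError(f"need >= 2 intervals, got {iv.size}")
    diffs = np.diff(iv)
    mrr = float(np.mean(iv))
    drr = float(np.std(iv, ddof=1))
    mhr = float(np.mean(60000.0 / iv))
    drms = float(np.sqrt(np.mean(diffs**2)))
    nnn = int(np.sum(np.abs(diffs) > nn_threshold_ms))
    pnn = 100.0 * nnn / iv.size
    return mrr, drr, mhr, drms, nnn, pnn


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def _resample_tachogram(rr: RRSeries, fs: float) -> np.ndarray:
    """Cubic-spline interpolation of RR(t) onto an even grid.

    The RR value is anchored at the time of the beat terminating the
    interval.
    """
    t = rr.timestamps[1:]
    cs = CubicSpline(t, rr.intervals)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    return np.asarray(cs(grid))


def frequency_domain(rr: RRSeries, cfg: SpectralConfig | None = None):
    """PLF_abs, PHF_abs, PLF_nu, PHF_nu, rLF_HF, Ptot_abs via Welch PSD."""
    if cfg is None:
        cfg = SpectralConfig()
    if rr.duration_s < 60.0:
        raise ValueError(
            f"series of {rr.duration_s:.1f} s too short for spectral analysis "
            "(minimum 60 s)"
        )
    if len(rr) < 30:
        raise ValueError(f"need >= 30 beats for spectral analysis, got {len(rr)}")
    fs = cfg.resample_hz
    x = _resample_tachogram(rr, fs)
    if cfg.detrend == "linear":
        x = sps.detrend(x, type="linear")
    elif cfg.detrend == "constant":
        x = x - np.mean(x)
    nperseg = min(x.size, int(round(cfg.window_s * fs)))
    noverlap = int(round(cfg.overlap_fraction * nperseg))
    f, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend=False
    )

    def band_power(lo, hi):
        mask = (f >= lo) & (f < hi)
        if mask.sum() < 2:
            return float(psd[mask].sum() * (f[1] - f[0])) if mask.any() else 0.0
        return float(np.trapezoid(psd[mask], f[mask]))

    p_vlf = band_power(*cfg.vlf_band)
    p_lf = band_power(*cfg.lf_band)
    p_hf = band_power(*cfg.hf_band)
    p_tot = p_vlf + p_lf + p_hf
    if p_lf + p_hf > 0:
        lf_nu = 100.0 * p_lf / (p_lf + p_hf)
        hf_nu = 100.0 * p_hf / (p_lf + p_hf)
    else:
        lf_nu = hf_nu = np.nan
    ratio = p_lf / p_hf if p_hf > 0 else np.nan
    return p_lf, p_hf, lf_nu, hf_nu, ratio, p_tot


# ---------------------------------------------------------------------------
# Poincare plot
# ---------------------------------------------------------------------------

def poincare(rr: RRSeries):
    """SD1/SD2 of the lag-1 Poincare plot (population-variance convention).

    SD1^2 = var(diff)/2; SD2^2 = 2*var(RR) - SD1^2.  The SD2/SD1 ratio of a
    zero-variability series is NaN.
    """
    iv = rr.intervals
    if iv.size < 3:
        raise ValueError(f"need >= 3 intervals, got {iv.size}")
    diffs = np.diff(iv)
    sd1_sq = 0.5 * np.var(diffs)
    sd2_sq = 2.0 * np.var(iv) - sd1_sq
    sd1 = float(np.sqrt(max(sd1_sq, 0.0)))
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    ratio = sd2 / sd1 if sd1 > 0 else np.nan
    return sd1, sd2, ratio


# ---------------------------------------------------------------------------
# entropies (Chebyshev distance, embedding m, tolerance r)
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n <= 0:
        return np.empty((0, m))
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]


def approximate_entropy(rr: RRSeries | np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r) = Phi_m - Phi_{m+1}.

    Template matches use the Chebyshev distance and include self-matches.
    ``r`` defaults to 0.2 times the series SD; a zero-variability series has
    ApEn 0 by definition (every template matches every other).
    """
    x = np.asarray(rr.intervals if isinstance(rr, RRSeries) else rr, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"need >= {m + 2} points, got {x.size}")
    sd = np.std(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        emb = _embed(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = np.mean(d <= r, axis=1)  # includes the self-match
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(rr: RRSeries | np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Richman-Moorman sample entropy -ln(A/B), self-matches excluded.

    A and B count template pairs (i < j, both drawn from the first N - m
    templates) within tolerance at lengths m+1 and m.  Returns NaN with a
    warning when no pairs match at either length.
    """
    x = np.asarray(rr.intervals if isinstance(rr, RRSeries) else rr, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"need >= {m + 2} points, got {x.size}")
    sd = np.std(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    n_templates = x.size - m
    emb_m = _embed(x, m)[:n_templates]
    emb_m1 = _embed(x, m + 1)
    b = int(np.sum(pdist(emb_m, metric="chebyshev") <= r))
    a = int(np.sum(pdist(emb_m1, metric="chebyshev") <= r))
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined: no template matches", stacklevel=2)
        return np.nan
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa_fluctuations(x: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    """F(n) for each box size: RMS of linearly detrended fluctuations of the
    integrated, mean-centered series over non-overlapping boxes."""
    y = np.cumsum(x - np.mean(x))
    out = np.empty(box_sizes.size)
    for k, n in enumerate(box_sizes):
        n_boxes = y.size // n
        if n_boxes < 1:
            out[k] = np.nan
            continue
        seg = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # per-box least-squares line
        coef = np.polynomial.polynomial.polyfit(t, seg.T, 1)
        trend = coef[0][:, None] + coef[1][:, None] * t
        out[k] = np.sqrt(np.mean((seg - trend) ** 2))
    return out


def dfa(
    rr: RRSeries | np.ndarray,
    short_range: tuple[int, int] = (4, 16),
    long_range: tuple[int, int] = (16, 64),
):
    """DFA scaling exponents alpha1 (4-16 beats) and alpha2 (16-64 beats).

    Each exponent is the least-squares slope of log F(n) against log n over
    its box-size range; a range the series is too short to populate (alpha1
    needs ~20 beats, alpha2 ~70) is reported as NaN.
    """
    x = np.asarray(rr.intervals if isinstance(rr, RRSeries) else rr, dtype=float)

    def alpha(lo: int, hi: int, min_len: int) -> float:
        if x.size < min_len:
            return np.nan
        sizes = np.arange(lo, hi + 1)
        sizes = sizes[x.size // sizes >= 2]
        if sizes.size < 2:
            return np.nan
        f = dfa_fluctuations(x, sizes)
        ok = np.isfinite(f) & (f > 0)
        if ok.sum() < 2:
            return np.nan
        slope = np.polyfit(np.log10(sizes[ok]), np.log10(f[ok]), 1)[0]
        return float(slope)

    a1 = alpha(short_range[0], short_range[1], 20)
    a2 = alpha(long_range[0], long_range[1], 70)
    return a1, a2


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def correlation_sums(
    x: np.ndarray, m: int, tau: int, radii: np.ndarray
) -> np.ndarray:
    """C(rho): fraction of delay-embedded point pairs (Euclidean distance,
    Theiler exclusion |i-j| <= tau) closer than each radius."""
    emb = _embed(np.asarray(x, dtype=float), m, tau)
    n = emb.shape[0]
    if n < 2:
        return np.full(len(radii), np.nan)
    d = pdist(emb, metric="euclidean")
    if tau >= 1:
        # drop pairs with |i-j| <= tau (temporal neighbours)
        ii, jj = np.triu_indices(n, k=1)
        d = d[(jj - ii) > tau]
    if d.size == 0:
        return np.full(len(radii), np.nan)
    return np.searchsorted(np.sort(d), radii, side="right") / d.size


def correlation_dimension(
    rr: RRSeries | np.ndarray, m: int = 10, tau: int = 1
) -> float:
    """Grassberger-Procaccia D2 estimate.

    The scaling region is selected automatically as the radii at log-spaced
    quantiles (0.5%-32%) of the pairwise-distance distribution, i.e. the
    small-distance flank of the correlation integral before saturation; D2
    is the least-squares slope of log C against log rho there.  Degenerate
    embeddings (too few points, zero spread) give NaN.
    """
    x = np.asarray(rr.intervals if isinstance(rr, RRSeries) else rr, dtype=float)
    if x.size < m * tau + 10:
        raise ValueError(f"need >= {m * tau + 10} points for m={m}, tau={tau}")
    emb = _embed(x, m, tau)
    n = emb.shape[0]
    d = pdist(emb, metric="euclidean")
    ii, jj = np.triu_indices(n, k=1)
    d = d[(jj - ii) > tau]
    d = d[d > 0]
    if d.size < 50:
        return np.nan
    probs = np.logspace(np.log10(0.005), np.log10(0.32), 12)
    radii = np.quantile(d, probs)
    if radii[0] <= 0 or radii[-1] <= radii[0]:
        return np.nan
    c = np.searchsorted(np.sort(d), radii, side="right") / d.size
    ok = c > 0
    if ok.sum() < 3:
        return np.nan
    slope = np.polyfit(np.log10(radii[ok]), np.log10(c[ok]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_features(
    segment: Segment,
    cfg: SpectralConfig | None = None,
    entropy_m: int = 2,
    entropy_r_factor: float = 0.2,
    d2_m: int = 10,
    d2_tau: int = 1,
) -> FeatureVector:
    """All 20 HRV features for one labeled 2-minute segment.

    Entropy tolerance is ``entropy_r_factor`` times the segment's own RR
    standard deviation.  Sub-operation failures are re-raised with the
    segment identity attached.  A ~150-beat segment is short for a reliable
    m=10 correlation-dimension estimate; D2 is computed regardless and
    should be read as a comparative, not absolute, measure.
    """
    rr = segment.rr
    if len(rr) < 60:
        raise ValueError(
            f"segment {segment.subject_id}#{segment.window_index}: "
            f"{len(rr)} beats < 60 required"
        )
    try:
        mrr, drr, mhr, drms, nnn, pnn = time_domain(rr)
        sd = float(np.std(rr.intervals))
        if sd == 0:
            p_lf = p_hf = p_tot = 0.0
            lf_nu = hf_nu = ratio = np.nan
            eap = esamp = 0.0
            d2 = np.nan
        else:
            p_lf, p_hf, lf_nu, hf_nu, ratio, p_tot = frequency_domain(rr, cfg)
            r = entropy_r_factor * sd
            eap = approximate_entropy(rr, m=entropy_m, r=r)
            esamp = sample_entropy(rr, m=entropy_m, r=r)
            d2 = correlation_dimension(rr, m=d2_m, tau=d2_tau)
        sd1, sd2, sd_ratio = poincare(rr)
        a1, a2 = dfa(rr)
    except ValueError as exc:
        raise ValueError(
            f"segment {segment.subject_id}#{segment.window_index}: {exc}"
        ) from exc
    return FeatureVector(
        MRR=mrr, DRR=drr, MHR=mhr, DRMS=drms, NNN15=float(nnn), pNN15=pnn,
        PLF_abs=p_lf, PHF_abs=p_hf, PLF_nu=lf_nu, PHF_nu=hf_nu,
        rLF_HF=ratio, Ptot_abs=p_tot,
        LSD1=sd1, LSD2=sd2, rSD2_SD1=sd_ratio,
        EAP=eap, ESamp=esamp, alpha1=a1, alpha2=a2, D2=d2,
    )
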