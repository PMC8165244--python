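"""The 20 autonomic (HRV) indices computed per analyzed segment.

Frequency-domain indices use both a Welch (FFT) and a Burg autoregressive
spectrum of the evenly resampled RR tachogram, with the conventional bands
VLF 0-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz and total power capped at
0.4 Hz — so that ``total - VLF = LF + HF`` and the normalized LF/HF powers
sum to one per method.  Time-domain, geometric (triangular index / TINN on
a 1/128 s histogram) and Poincare indices follow the standard Task-Force /
Kubios conventions.  Index 20 is the mean of the hemoglobin series itself.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .chromophore_separation import mean_hemoglobin
from .pulse_extraction import RRSeries, UnusableSegmentError

__all__ = [
    "INDEX_NAMES",
    "SpectrumEstimate",
    "BandPowers",
    "ANSIndexVector",
    "interpolate_tachogram",
    "fft_spectrum",
    "ar_spectrum",
    "burg_coefficients",
    "band_powers",
    "spectral_indices",
    "time_domain_indices",
    "geometric_indices",
    "poincare_indices",
    "compute_index_vector",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 64.0
AR_ORDER = 16
AR_GRID_SIZE = 16384  # rfft grid length for evaluating the AR density
HIST_BIN_MS = 1000.0 / 128.0  # Task-Force geometric-index bin width
MIN_SPECTRUM_SPAN_S = 20.0  # tachogram span floor for spectral estimation
SHORT_SEGMENT_SPAN_S = 60.0  # below this, spectral LF resolution is marginal

#: The 20 index names, in their fixed reporting order.
INDEX_NAMES = (
    "lf_hf_fft",
    "lf_hf_ar",
    "nlf_fft",
    "nhf_fft",
    "nlf_ar",
    "nhf_ar",
    "rel_lf_fft",
    "rel_hf_fft",
    "rel_lf_ar",
    "rel_hf_ar",
    "mean_rri",
    "mean_hr",
    "rmssd",
    "pnn50",
    "tri_index",
    "tinn",
    "sd1",
    "sd2",
    "sd1_sd2",
    "mean_hb",
)


@dataclass
class UniformTachogram:
    """Evenly resampled, mean-detrended RR series."""

    values: np.ndarray  # ms, detrended
    fs: float
    t0: float
    mean: float  # removed mean, ms

    @property
    def span(self) -> float:
        return (self.values.size - 1) / self.fs


@dataclass
class SpectrumEstimate:
    frequencies: np.ndarray  # Hz
    density: np.ndarray  # ms^2/Hz
    method: str  # "FFT" | "AR"

    def __post_init__(self) -> None:
        if np.any(self.density < -1e-12):
            raise ValueError("spectral density must be nonnegative")
        if self.frequencies[-1] < HF_BAND[1]:
            raise ValueError("spectrum grid must span at least [0, 0.4] Hz")


@dataclass
class BandPowers:
    vlf: float
    lf: float
    hf: float

    @property
    def total(self) -> float:
        return self.vlf + self.lf + self.hf


@dataclass
class ANSIndexVector:
    """The 20 named indices for one segment (fixed reporting order)."""

    lf_hf_fft: float
    lf_hf_ar: float
    nlf_fft: float
    nhf_fft: float
    nlf_ar: float
    nhf_ar: float
    rel_lf_fft: float
    rel_hf_fft: float
    rel_lf_ar: float
    rel_hf_ar: float
    mean_rri: float
    mean_hr: float
    rmssd: float
    pnn50: float
    tri_index: float
    tinn: float
    sd1: float
    sd2: float
    sd1_sd2: float
    mean_hb: float
    short_segment: bool = False  # tachogram span < 60 s: marginal LF resolution

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in INDEX_NAMES])

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in INDEX_NAMES}


assert tuple(f.name for f in fields(ANSIndexVector))[:20] == INDEX_NAMES


# ---------------------------------------------------------------------------
# Tachogram and spectra


def interpolate_tachogram(rr: RRSeries) -> UniformTachogram:
    """Cubic-spline interpolate RR(t) at the kept beats, resampled at 4 Hz
    and mean-detrended."""
    if rr.n_kept < 10:
        raise UnusableSegmentError("fewer than 10 kept intervals")
    t, v = rr.kept_times, rr.kept_intervals
    spline = CubicSpline(t, v)
    span = t[-1] - t[0]
    n = int(np.floor(span * RESAMPLE_HZ)) + 1
    grid = t[0] + np.arange(n) / RESAMPLE_HZ
    values = spline(grid)
    mean = float(values.mean())
    return UniformTachogram(values=values - mean, fs=RESAMPLE_HZ, t0=float(t[0]), mean=mean)


def fft_spectrum(tach: UniformTachogram) -> SpectrumEstimate:
    """Welch PSD: Hann window, min(span, 64 s) segments, 50% overlap."""
    if tach.span < MIN_SPECTRUM_SPAN_S:
        raise ValueError(
            f"tachogram span {tach.span:.1f} s is too short for spectral "
            f"estimation (need >= {MIN_SPECTRUM_SPAN_S} s)"
        )
    nperseg = min(tach.values.size, int(WELCH_SEGMENT_S * tach.fs))
    freqs, psd = sps.welch(
        tach.values,
        fs=tach.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return SpectrumEstimate(frequencies=freqs, density=psd, method="FFT")


def burg_coefficients(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg's method AR coefficients ``a`` (for ``1 + a1 z^-1 + ...``) and
    driving-noise variance."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * order:
        raise ValueError("series too short for the requested AR order")
    ef = x[1:].copy()  # forward prediction errors
    eb = x[:-1].copy()  # backward prediction errors
    a = np.zeros(0)
    e = float(np.dot(x, x) / n)
    for _ in range(order):
        denom = np.dot(ef, ef) + np.dot(eb, eb)
        k = 0.0 if denom == 0 else -2.0 * np.dot(ef, eb) / denom
        a = np.concatenate([a, [0.0]])
        a = a + k * np.concatenate([a[-2::-1], [1.0]])
        e *= 1.0 - k * k
        ef, eb = ef[1:] + k * eb[1:], eb[:-1] + k * ef[:-1]
    return a, e


def ar_spectrum(tach: UniformTachogram, order: int = AR_ORDER) -> SpectrumEstimate:
    """Autoregressive (Burg) PSD on the same frequency grid as the Welch
    estimate.  A zero series yields a zero spectrum."""
    if tach.span < MIN_SPECTRUM_SPAN_S:
        raise ValueError(
            f"tachogram span {tach.span:.1f} s is too short for spectral "
            f"estimation (need >= {MIN_SPECTRUM_SPAN_S} s)"
        )
    x = tach.values
    # dense grid: near-deterministic tachograms put the AR poles close to
    # the unit circle, and the resulting narrow peaks need sub-mHz sampling
    # before band integrals are meaningful
    freqs = np.fft.rfftfreq(AR_GRID_SIZE, 1.0 / tach.fs)
    if np.allclose(x, 0.0):
        return SpectrumEstimate(frequencies=freqs, density=np.zeros_like(freqs), method="AR")
    a, sigma2 = burg_coefficients(x, order)
    # one-sided PSD of 1/A(z) driven by white noise of variance sigma2
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, order + 1)) / tach.fs)
    denom = np.abs(1.0 + z @ a) ** 2
    psd = sigma2 / tach.fs / denom
    psd *= 2.0
    psd[0] /= 2.0
    if freqs[-1] == tach.fs / 2:
        psd[-1] /= 2.0
    return SpectrumEstimate(frequencies=freqs, density=psd, method="AR")


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], with interpolated
    band-edge points so adjacent bands tile exactly."""
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate([[lo], freqs[inside], [hi]])
    p = np.concatenate(
        [
            [np.interp(lo, freqs, psd)],
            psd[inside],
            [np.interp(hi, freqs, psd)],
        ]
    )
    return float(np.trapezoid(p, f))


def band_powers(spec: SpectrumEstimate) -> BandPowers:
    """VLF/LF/HF band powers (ms^2); total = VLF + LF + HF by construction."""
    f, p = spec.frequencies, spec.density
    if f[-1] < HF_BAND[1]:
        raise ValueError("spectrum grid does not cover [0, 0.4] Hz")
    return BandPowers(
        vlf=_band_integral(f, p, *VLF_BAND),
        lf=_band_integral(f, p, *LF_BAND),
        hf=_band_integral(f, p, *HF_BAND),
    )


def spectral_indices(bp: BandPowers) -> dict:
    """LF/HF ratio, normalized and relative band powers for one method."""
    if bp.hf <= 0:
        raise ZeroDivisionError("HF band power is zero; LF/HF undefined")
    denom = bp.total - bp.vlf
    if denom <= 0:
        raise ZeroDivisionError("total power equals VLF power; normalization undefined")
    return {
        "lf_hf": bp.lf / bp.hf,
        "nlf": bp.lf / denom,
        "nhf": bp.hf / denom,
        "rel_lf": bp.lf / bp.total,
        "rel_hf": bp.hf / bp.total,
    }


# ---------------------------------------------------------------------------
# Time-domain, geometric and Poincare indices


def time_domain_indices(rr: RRSeries) -> dict:
    """mean RR (ms), mean HR (bpm, mean of per-interval instantaneous HR),
    RMSSD (ms) and pNN50 (fraction), over kept successive pairs only."""
    kept = rr.kept_intervals
    if kept.size < 2:
        raise ValueError("need at least 2 kept intervals")
    # successive pairs: both members kept and adjacent in the original series
    idx = np.nonzero(rr.kept)[0]
    adjacent = np.diff(idx) == 1
    diffs = np.diff(rr.intervals[idx])[adjacent]
    if diffs.size == 0:
        raise ValueError("no adjacent kept interval pairs")
    return {
        "mean_rri": float(kept.mean()),
        "mean_hr": float(np.mean(60000.0 / kept)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "pnn50": float(np.mean(np.abs(diffs) > 50.0)),
    }


def geometric_indices(rr: RRSeries) -> dict:
    """HRV triangular index and TINN from the 1/128 s RR histogram.

    tri_index is the canonical count form: total intervals divided by the
    modal bin count.  TINN is ``M - N`` for the least-squares triangular fit
    with apex fixed at the modal bin, N and M searched on the bin grid.
    """
    kept = rr.kept_intervals
    if kept.size < 2:
        raise ValueError("need at least 2 kept intervals")
    lo_edge = np.floor(kept.min() / HIST_BIN_MS) * HIST_BIN_MS
    hi_edge = (np.floor(kept.max() / HIST_BIN_MS) + 1) * HIST_BIN_MS
    edges = np.arange(lo_edge, hi_edge + HIST_BIN_MS / 2, HIST_BIN_MS)
    counts, _ = np.histogram(kept, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mode = int(np.argmax(counts))
    tri_index = float(kept.size / counts[mode])
    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        return {"tri_index": tri_index, "tinn": float(HIST_BIN_MS)}
    # least-squares triangle: zero at N and M, peak counts[mode] at the mode
    peak = counts[mode]
    best = (np.inf, float(HIST_BIN_MS))
    n_candidates = range(0, mode + 1)
    m_candidates = range(mode, len(centers))
    for ni in n_candidates:
        n_pos = centers[ni] - HIST_BIN_MS  # triangle base just below bin ni
        for mi in m_candidates:
            m_pos = centers[mi] + HIST_BIN_MS
            tri = np.zeros_like(centers, dtype=float)
            up = (centers >= n_pos) & (centers <= centers[mode])
            tri[up] = peak * (centers[up] - n_pos) / (centers[mode] - n_pos)
            down = (centers > centers[mode]) & (centers <= m_pos)
            tri[down] = peak * (m_pos - centers[down]) / (m_pos - centers[mode])
            sse = float(np.sum((counts - tri) ** 2))
            width = m_pos - n_pos
            if sse < best[0] - 1e-12 or (abs(sse - best[0]) <= 1e-12 and width < best[1]):
                best = (sse, width)
    return {"tri_index": tri_index, "tinn": float(best[1])}


def poincare_indices(rr: RRSeries) -> dict:
    """SD1/SD2 of the lag-1 Poincare plot, population-variance convention.

    ``SD1^2 = var(RR_n - RR_{n+1}) / 2``; ``SD2^2 = 2 var(RR) - SD1^2``.
    A constant series has SD1 = SD2 = 0 and an undefined (NaN) ratio.
    """
    kept = rr.kept_intervals
    if kept.size < 3:
        raise ValueError("need at least 3 kept intervals")
    d = np.diff(kept)
    sd1_sq = 0.5 * np.var(d)
    sd2_sq = max(0.0, 2.0 * np.var(kept) - sd1_sq)
    sd1, sd2 = float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    return {"sd1": sd1, "sd2": sd2, "sd1_sd2": ratio}


# ---------------------------------------------------------------------------
# Assembly


def compute_index_vector(rr: RRSeries, hemoglobin: np.ndarray) -> ANSIndexVector:
    """Assemble the full 20-index vector for one segment.

    Raises :class:`UnusableSegmentError` (propagated from the tachogram) or
    ``ValueError`` when a constituent index cannot be computed; callers that
    tolerate missing segments should catch and mask.
    """
    tach = interpolate_tachogram(rr)
    fft_ind = spectral_indices(band_powers(fft_spectrum(tach)))
    ar_ind = spectral_indices(band_powers(ar_spectrum(tach)))
    td = time_domain_indices(rr)
    geom = geometric_indices(rr)
    poi = poincare_indices(rr)
    return ANSIndexVector(
        lf_hf_fft=fft_ind["lf_hf"],
        lf_hf_ar=ar_ind["lf_hf"],
        nlf_fft=fft_ind["nlf"],
        nhf_fft=fft_ind["nhf"],
        nlf_ar=ar_ind["nlf"],
        nhf_ar=ar_ind["nhf"],
        rel_lf_fft=fft_ind["rel_lf"],
        rel_hf_fft=fft_ind["rel_hf"],
        rel_lf_ar=ar_ind["rel_lf"],
        rel_hf_ar=ar_ind["rel_hf"],
        mean_rri=td["mean_rri"],
        mean_hr=td["mean_hr"],
        rmssd=td["rmssd"],
        pnn50=td["pnn50"],
        tri_index=geom["tri_index"],
        tinn=geom["tinn"],
        sd1=poi["sd1"],
        sd2=poi["sd2"],
        sd1_sd2=poi["sd1_sd2"],
        mean_hb=mean_hemoglobin(hemoglobin),
        short_segment=tach.span < SHORT_SEGMENT_SPAN_S,
    )
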