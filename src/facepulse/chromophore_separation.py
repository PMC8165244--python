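"""Skin-chromophore separation of facial RGB traces.

Facial skin color, expressed in log optical density, is modelled as a mixture
of three temporally varying sources: a shading/illumination component that
moves all channels together, a melanin component, and a hemoglobin component
that carries the cardiac pulse.  Shading is removed first by projecting each
frame's density vector onto the achromatic axis ``(1,1,1)/sqrt(3)``; the
two-dimensional residual is then unmixed by FastICA, and the hemoglobin
component is identified as the one dominated by cardiac-band (0.7-3.0 Hz)
power.  Because shading is separated out, the recovered hemoglobin series is
insensitive to uniform changes in illumination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

__all__ = [
    "RGBTrace",
    "ChromophoreTraces",
    "DegenerateInputError",
    "rgb_to_density",
    "remove_shading",
    "unmix_ica",
    "select_hemoglobin",
    "mean_hemoglobin",
    "separate",
]

#: Achromatic (uniform illumination) axis in log-density space.
SHADE_AXIS = np.ones(3) / np.sqrt(3.0)

#: Fixed orthonormal basis of the plane orthogonal to the shade axis.
CHROMA_BASIS = np.stack(
    [
        np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0),
        np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0),
    ],
    axis=1,
)  # shape (3, 2); columns are basis vectors

#: Cardiac frequency band used to identify the hemoglobin component (Hz).
CARDIAC_BAND = (0.7, 3.0)

#: Minimum cardiac-band power fraction before a separation is flagged.
LOW_QUALITY_CARDIAC_FRACTION = 0.05


class DegenerateInputError(ValueError):
    """Raised when the chroma residual has no variance to unmix."""


@dataclass(frozen=True)
class RGBTrace:
    """Per-frame ROI-mean RGB values in (0, 1] at a fixed frame rate."""

    samples: np.ndarray  # (n_frames, 3)
    frame_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("samples must be an (n_frames, 3) array")
        if samples.shape[0] < 2:
            raise ValueError("an RGB trace needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class ChromophoreTraces:
    """Separated hemoglobin / melanin / shade series for one trace."""

    hemoglobin: np.ndarray
    melanin: np.ndarray
    shade: np.ndarray
    frame_rate: float
    #: estimated 3-D mixing directions (unit vectors) for (hemoglobin, melanin)
    mixing_directions: np.ndarray = field(default=None)  # type: ignore[assignment]
    low_quality: bool = False


def rgb_to_density(trace: RGBTrace) -> np.ndarray:
    """Convert an RGB trace to log optical density, ``-log(value)``.

    Raises ``ValueError`` naming the first offending frame if any channel
    value is nonpositive.
    """
    samples = trace.samples
    bad = np.nonzero(~(samples > 0).all(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"nonpositive channel value at frame {int(bad[0])}; density is undefined"
        )
    return -np.log(samples)


def remove_shading(density: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a density trace into a shade series and a 2-D chroma residual.

    The shade series is the scalar projection of each frame onto the
    achromatic axis; the residual is the remainder expressed in the fixed
    orthonormal basis ``CHROMA_BASIS`` of the plane orthogonal to it.
    """
    density = np.asarray(density, dtype=float)
    if density.ndim != 2 or density.shape[1] != 3:
        raise ValueError("density must be (n_frames, 3)")
    if density.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    shade = density @ SHADE_AXIS
    residual = (density - np.outer(shade, SHADE_AXIS)) @ CHROMA_BASIS
    return shade, residual


def unmix_ica(
    residual: np.ndarray, seed: int = 0, tol: float = 1e-6, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix the centered 2-D chroma residual into two independent components.

    Returns ``(components, mixing)`` where ``components`` is (n_frames, 2)
    and ``mixing`` is the estimated (2, 2) mixing matrix such that
    ``residual - mean = components @ mixing.T``.  Deterministic for a fixed
    ``seed`` (deflation-mode FastICA).
    """
    residual = np.asarray(residual, dtype=float)
    if residual.ndim != 2 or residual.shape[1] != 2:
        raise ValueError("residual must be (n_frames, 2)")
    stds = residual.std(axis=0)
    if np.any(stds < 1e-12):
        raise DegenerateInputError(
            "chroma residual is rank deficient (a basis direction is constant)"
        )
    ica = FastICA(
        n_components=2,
        algorithm="deflation",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings handled by tol/max_iter
        components = ica.fit_transform(residual)
    return components, ica.mixing_


def _band_power_fraction(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    freqs, psd = sps.periodogram(x, fs=fs, detrend="constant")
    total = np.trapezoid(psd, freqs)
    if total <= 0:
        return 0.0
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]) / total)


def select_hemoglobin(
    components: np.ndarray, frame_rate: float
) -> tuple[np.ndarray, int, bool]:
    """Pick the hemoglobin component and fix its sign.

    The component with the larger fraction of power in the cardiac band is
    selected.  Its sign is oriented so that pulsatile peaks are positive
    deflections (skewness of the band-passed series >= 0).  Returns
    ``(series, index, low_quality)`` where ``low_quality`` is set when
    neither candidate reaches a 5% cardiac-band fraction.
    """
    components = np.asarray(components, dtype=float)
    if components.ndim != 2 or components.shape[1] != 2:
        raise ValueError("expected exactly two candidate components")
    fractions = [
        _band_power_fraction(components[:, j], frame_rate, CARDIAC_BAND)
        for j in range(2)
    ]
    idx = int(np.argmax(fractions))
    low_quality = max(fractions) < LOW_QUALITY_CARDIAC_FRACTION
    if low_quality:
        warnings.warn(
            "no component is dominated by cardiac-band power; "
            "hemoglobin selection is low quality",
            stacklevel=2,
        )
    series = components[:, idx].copy()
    # orient: positive pulse deflections => nonnegative skew of band-passed series
    from .pulse_extraction import bandpass_pulse

    banded = bandpass_pulse(series, frame_rate)
    sd = banded.std()
    if sd > 0:
        skew = float(np.mean(((banded - banded.mean()) / sd) ** 3))
        if skew < 0:
            series = -series
    return series, idx, low_quality


def mean_hemoglobin(hemoglobin: np.ndarray) -> float:
    """Arithmetic mean of the hemoglobin series (Table-2-style mean index)."""
    hemoglobin = np.asarray(hemoglobin, dtype=float)
    if hemoglobin.size == 0:
        raise ValueError("empty segment")
    return float(hemoglobin.mean())


def separate(trace: RGBTrace, ica_seed: int = 0) -> ChromophoreTraces:
    """Full separation: density -> deshade -> ICA -> labelled components."""
    density = rgb_to_density(trace)
    shade, residual = remove_shading(density)
    components, mixing = unmix_ica(residual, seed=ica_seed)
    hemoglobin, hb_idx, low_quality = select_hemoglobin(components, trace.frame_rate)
    melanin = components[:, 1 - hb_idx].copy()
    directions = np.empty((2, 3))
    for out_row, comp_idx in enumerate((hb_idx, 1 - hb_idx)):
        vec3 = CHROMA_BASIS @ mixing[:, comp_idx]
        norm = np.linalg.norm(vec3)
        directions[out_row] = vec3 / norm if norm > 0 else vec3
    return ChromophoreTraces(
        hemoglobin=hemoglobin,
        melanin=melanin,
        shade=shade,
        frame_rate=trace.frame_rate,
        mixing_directions=directions,
        low_quality=low_quality,
    )
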