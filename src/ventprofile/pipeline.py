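"""From voltage recordings to tidal ventilation images.

Steps: reference the voltage series (time difference TD or normalized time
difference NTD), reconstruct frame-wise, detect breath phases on the mean
in-body signal, average end-inspiration minus end-expiration images over
breaths, then apply either the 10%-of-maximum threshold (no anatomical
post-processing) or the lung-pixel mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .forward import StimulationScheme, VoltageFrame
from .geometry import PixelGrid
from .inverse import ReconstructionMatrix

__all__ = [
    "VoltageSeries",
    "ImageSeries",
    "BreathMarkers",
    "TidalImage",
    "BreathDetectionError",
    "difference_voltages",
    "reconstruct_series",
    "detect_breath_phases",
    "tidal_image",
    "threshold_mask",
    "lung_select",
    "process_recording",
]

Reference = Literal["TD", "NTD"]


class BreathDetectionError(RuntimeError):
    """No usable breath phases could be detected."""


@dataclass
class VoltageSeries:
    """Time-stamped voltage frames; invalid channels are NaN columns."""

    values: np.ndarray  # (T, n_channels)
    timestamps: np.ndarray  # (T,) seconds
    scheme: StimulationScheme
    sampling_rate: float = 48.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.values) != len(self.timestamps):
            raise ValueError("values and timestamps length mismatch")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("sampling must be uniform within 1e-6 s")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def frame(self, i: int) -> VoltageFrame:
        return VoltageFrame(channels=self.values[i], scheme=self.scheme)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[:, self.scheme.valid_flat]


@dataclass
class ImageSeries:
    """Reconstructed impedance-change images Z(t)."""

    frames: np.ndarray  # (T, 32, 32)
    timestamps: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mean_signal(self, body_mask: np.ndarray) -> np.ndarray:
        return self.frames[:, body_mask].mean(axis=1)


@dataclass(frozen=True)
class BreathMarkers:
    """Frame indices of end-inspiration (t_in) and end-expiration (t_ex)."""

    t_in: np.ndarray
    t_ex: np.ndarray

    @property
    def n_breaths(self) -> int:
        return len(self.t_in)

    def pairs(self) -> list[tuple[int, int]]:
        """Each t_in paired with the nearest following t_ex; incomplete
        trailing breaths are dropped."""
        out = []
        for ti in self.t_in:
            after = self.t_ex[self.t_ex > ti]
            if len(after):
                out.append((int(ti), int(after[0])))
        return out


@dataclass
class TidalImage:
    """Breath-averaged end-inspiration minus end-expiration image."""

    pixels: np.ndarray  # (32, 32)
    body_mask: np.ndarray
    masks_applied: Literal["none", "threshold", "lung"] = "none"


def difference_voltages(
    s: VoltageSeries, t_r: int, method: Reference = "TD"
) -> VoltageSeries:
    """Reference the series against frame ``t_r``.

    TD: v - v(t_r); NTD: v / v(t_r) - 1.  Invalid channels stay NaN.
    """
    if not 0 <= t_r < s.n_frames:
        raise IndexError(f"reference frame {t_r} out of range")
    ref = s.values[t_r]
    valid = s.scheme.valid_flat
    if method == "TD":
        out = s.values - ref
    elif method == "NTD":
        zero = valid & (ref == 0.0)
        if np.any(zero):
            raise ZeroDivisionError(
                f"NTD reference frame has zero voltage on channel(s) "
                f"{np.flatnonzero(zero)[:5].tolist()}"
            )
        out = s.values / ref - 1.0
    else:
        raise ValueError(f"unknown reference method {method!r}")
    out = out.copy()
    out[:, ~valid] = np.nan
    return VoltageSeries(
        values=out,
        timestamps=s.timestamps,
        scheme=s.scheme,
        sampling_rate=s.sampling_rate,
    )


def reconstruct_series(R: ReconstructionMatrix, d: VoltageSeries) -> ImageSeries:
    """Frame-wise linear reconstruction of a differenced series."""
    v = d.valid_values
    if v.shape[1] != R.n_valid_channels:
        raise ValueError("series channel basis does not match the matrix")
    return ImageSeries(frames=R.apply(v), timestamps=d.timestamps)


def detect_breath_phases(
    signal: np.ndarray,
    sampling_rate: float,
    nominal_breath_period: float,
    smooth_window: float = 0.5,
    min_separation_fraction: float = 0.6,
) -> BreathMarkers:
    """Locate end-inspiration (maxima) and end-expiration (minima) of the
    mean in-body signal after moving-average smoothing."""
    x = np.asarray(signal, dtype=float)
    if np.ptp(x) < 1e-12:
        raise BreathDetectionError("signal is flat; no breaths detectable")
    win = max(1, int(round(smooth_window * sampling_rate)))
    sm = uniform_filter1d(x, size=win, mode="nearest")
    dist = max(1, int(round(min_separation_fraction * nominal_breath_period * sampling_rate)))
    t_in, _ = find_peaks(sm, distance=dist)
    t_ex, _ = find_peaks(-sm, distance=dist)
    if len(t_in) == 0 or len(t_ex) == 0:
        raise BreathDetectionError("no breath extrema found")
    return BreathMarkers(t_in=t_in, t_ex=t_ex)


def tidal_image(z: ImageSeries, b: BreathMarkers, body_mask: np.ndarray) -> TidalImage:
    """Average Z(t_in) - Z(t_ex) over all complete breaths."""
    pairs = b.pairs()
    if not pairs:
        raise BreathDetectionError("no complete (t_in, t_ex) breath pair")
    dz = np.mean([z.frames[ti] - z.frames[te] for ti, te in pairs], axis=0)
    dz = dz.copy()
    dz[~body_mask] = 0.0
    return TidalImage(pixels=dz, body_mask=body_mask, masks_applied="none")


def threshold_mask(t: TidalImage, frac: float = 0.10) -> TidalImage:
    """Zero pixels below ``frac`` of the image maximum (negatives included)."""
    if not np.any(t.pixels):
        raise ValueError("cannot threshold an all-zero tidal image")
    thr = frac * float(t.pixels.max())
    px = np.where(t.pixels < thr, 0.0, t.pixels)
    return TidalImage(pixels=px, body_mask=t.body_mask, masks_applied="threshold")


def lung_select(t: TidalImage, grid: PixelGrid) -> TidalImage:
    """Keep only pulmonary pixels (anatomical lung mask)."""
    if not np.any(grid.lung_mask):
        raise ValueError("geometry has an empty lung mask")
    px = np.where(grid.lung_mask, t.pixels, 0.0)
    return TidalImage(pixels=px, body_mask=t.body_mask, masks_applied="lung")


def process_recording(
    R: ReconstructionMatrix,
    s: VoltageSeries,
    nominal_breath_period: float,
    reference: Reference | None = None,
) -> tuple[TidalImage, BreathMarkers, ImageSeries]:
    """Full recording pipeline with end-expiration referencing.

    A provisional reference at frame 0 is used to detect breath phases; the
    series is then re-referenced at the first detected end-expiration frame
    (the conventional EIT baseline) and reconstructed again.  Returns the
    unmasked tidal image, the markers, and the re-referenced image series.
    """
    method = reference or (R.config.reference if R.config is not None else "TD")
    body = R.body_mask
    z0 = reconstruct_series(R, difference_voltages(s, 0, method))
    markers = detect_breath_phases(
        z0.mean_signal(body), s.sampling_rate, nominal_breath_period
    )
    t_r = int(markers.t_ex[0])
    z = reconstruct_series(R, difference_voltages(s, t_r, method))
    markers = detect_breath_phases(
        z.mean_signal(body), s.sampling_rate, nominal_breath_period
    )
    return tidal_image(z, markers, body), markers, z
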