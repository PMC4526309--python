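"""Semi-quantitative kinetic analysis of dynamic contrast-enhanced series.

A dynamic acquisition is one pre-contrast frame followed by post-contrast
frames at roughly fixed temporal resolution (about 60 s in the breast
protocol this package models).  Enhancement at a pixel and time t is
frame[t] − frame[0].  Three curve descriptors summarise the signal
intensity vs time curve of an ROI:

* **amplitude** — the maximum enhancement over the post-contrast frames
  (arbitrary units, AU);
* **wash-in** — the up-slope between the enhancement peak and the
  preceding time point (AU/s);
* **wash-out** — the ordinary-least-squares slope fitted to the last
  three (time, signal) points (AU/s), reported signed (positive values
  describe a still-rising delayed phase, negative values true wash-out).

The subtraction convention is post − pre, so that enhancement is
positive; the "residual image" wording sometimes used in the clinical
literature has the opposite sign but the same information.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .masks import as_mask_array

__all__ = [
    "DynamicSeries",
    "SubtractedImage",
    "KineticCurve",
    "KineticParams",
    "subtract",
    "roi_curve",
    "kinetic_params",
    "kinetic_maps",
]

#: an ROI used for kinetic read-out should cover more than this many pixels
MIN_KINETIC_ROI_PIXELS = 9


@dataclass(frozen=True)
class DynamicSeries:
    """Time-indexed stack of 2D frames with acquisition times in seconds."""

    frames: np.ndarray  # (T, H, W) intensities, AU
    times: np.ndarray  # (T,) seconds

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if frames.ndim != 3:
            raise ValueError(f"frames must be a (T, H, W) stack, got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise ValueError("a dynamic series needs at least 2 frames")
        if times.shape != (frames.shape[0],):
            raise ValueError("times must have one entry per frame")
        if not np.all(np.diff(times) > 0):
            raise ValueError("acquisition times must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class SubtractedImage:
    """Post-contrast frame minus the pre-contrast baseline."""

    pixels: np.ndarray
    source_frame_index: int


@dataclass(frozen=True)
class KineticCurve:
    """Mean ROI enhancement per frame; signal[0] is the pre-contrast zero."""

    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and signal must be 1D arrays of equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class KineticParams:
    amplitude: float  # AU
    wash_in: float  # AU/s
    wash_out: float  # AU/s
    peak_index: int


def subtract(series: DynamicSeries, post_index: int = 2) -> SubtractedImage:
    """Subtraction image: frame[post_index] − frame[0].

    The default post_index of 2 is the second post-contrast frame, the
    usual enhancement peak in malignant breast lesions.
    """
    if not 0 <= post_index < series.n_frames:
        raise ValueError(
            f"post_index {post_index} out of range for a {series.n_frames}-frame series"
        )
    return SubtractedImage(series.frames[post_index] - series.frames[0], post_index)


def roi_curve(series: DynamicSeries, mask, strict: bool = False) -> KineticCurve:
    """Signal intensity vs time curve: mean enhancement over the masked pixels.

    A kinetic ROI smaller than ten pixels is flagged (warning by default,
    error when ``strict``); an empty mask is always rejected.
    """
    m = as_mask_array(mask)
    if m.shape != series.frame_shape:
        raise ValueError("mask shape does not match the series frames")
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    if n <= MIN_KINETIC_ROI_PIXELS:
        msg = f"kinetic ROI has only {n} pixels (> {MIN_KINETIC_ROI_PIXELS} recommended)"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    enh = series.frames - series.frames[0]
    signal = enh[:, m].mean(axis=1)
    return KineticCurve(series.times, signal)


def kinetic_params(curve: KineticCurve) -> KineticParams:
    """Amplitude, wash-in and wash-out of an enhancement curve.

    Amplitude is the maximum enhancement over the post-contrast points;
    on ties the earliest frame is taken as the peak.  Wash-in is the
    slope between the peak and the preceding point.  Wash-out is the OLS
    slope over the final three points.
    """
    t, s = curve.times, curve.signal
    if t.size < 4:
        raise ValueError("kinetic parameters need at least 4 time points")
    post = s[1:]
    peak = int(np.argmax(post)) + 1  # earliest maximum wins
    amplitude = float(s[peak])
    wash_in = float((s[peak] - s[peak - 1]) / (t[peak] - t[peak - 1]))
    wash_out = float(np.polyfit(t[-3:], s[-3:], 1)[0])
    return KineticParams(amplitude, wash_in, wash_out, peak)


def kinetic_maps(series: DynamicSeries, rect) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel amplitude and wash-in maps over a rectangular search ROI.

    Each pixel's single-pixel enhancement curve is summarised exactly as
    in :func:`kinetic_params`; pixels outside the ROI are NaN.
    """
    m = as_mask_array(rect)
    if m.shape != series.frame_shape:
        raise ValueError("ROI shape does not match the series frames")
    if not m.any():
        raise ValueError("empty ROI")
    enh = series.frames - series.frames[0]  # (T, H, W)
    post = enh[1:]
    peak = post.argmax(axis=0) + 1  # first max along t, per pixel
    amp = np.take_along_axis(enh, peak[None], axis=0)[0]
    prev = np.take_along_axis(enh, (peak - 1)[None], axis=0)[0]
    dt = series.times[peak] - series.times[peak - 1]
    wash_in = (amp - prev) / dt
    amp = np.where(m, amp, np.nan)
    wash_in = np.where(m, wash_in, np.nan)
    return amp, wash_in
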