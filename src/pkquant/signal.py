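"""Peak integration and signal-to-noise estimation on MRM chromatogram traces.

Supports LLOQ determination from the signal-to-noise ratio of low
calibration standards. S/N is defined as baseline-subtracted peak height
divided by the noise standard deviation (peak-to-RMS convention) with a
default threshold of 10; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientDataError,
    NoLLOQError,
    WindowError,
    ZeroNoiseError,
)

__all__ = [
    "ChromatogramTrace",
    "PeakResult",
    "integrate_peak",
    "estimate_noise",
    "signal_to_noise",
    "determine_lloq",
]

#: default S/N threshold for LOQ determination (bioanalytical convention)
DEFAULT_SNR_THRESHOLD = 10.0

#: noise estimates below this are treated as zero noise
NOISE_FLOOR = 1e-12


@dataclass(frozen=True)
class ChromatogramTrace:
    """Uniformly sampled time-intensity signal on one MRM channel.

    Parameters
    ----------
    times : array-like
        Sample times in minutes, strictly increasing and uniformly spaced.
    intensities : array-like
        Detector intensities, same length as ``times``.
    channel : tuple, optional
        (precursor m/z, product m/z) of the monitored transition.
    """

    times: np.ndarray
    intensities: np.ndarray
    channel: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class PeakResult:
    """Result of integrating one chromatographic peak."""

    area: float  # intensity * min, baseline-subtracted, clipped at 0
    height: float  # baseline-subtracted apex intensity
    apex_time: float  # min; earliest on ties
    baseline_level: float  # intensity units
    snr: float | None = field(default=None)


def _window_mask(trace: ChromatogramTrace, window: Sequence[float]) -> np.ndarray:
    t_start, t_end = float(window[0]), float(window[1])
    if t_end <= t_start:
        raise WindowError(f"empty window [{t_start}, {t_end}]")
    if t_start < trace.times[0] - 1e-12 or t_end > trace.times[-1] + 1e-12:
        raise WindowError(
            f"window [{t_start}, {t_end}] outside trace span "
            f"[{trace.times[0]}, {trace.times[-1]}]"
        )
    return (trace.times >= t_start - 1e-12) & (trace.times <= t_end + 1e-12)


def integrate_peak(
    trace: ChromatogramTrace,
    window: Sequence[float],
    baseline_windows: Sequence[Sequence[float]] | None = None,
) -> PeakResult:
    """Integrate the peak inside ``window = (t_start, t_end)``.

    The baseline is the mean intensity over ``baseline_windows`` when given.
    Otherwise it is the mean over the flanking regions (one window-width on
    each side of the window, clipped to the trace); if no flanking samples
    exist the mean of the two window-endpoint samples is used.

    Returns a :class:`PeakResult` with the trapezoidal area of
    ``max(intensity - baseline, 0)``, the baseline-subtracted height, and the
    apex time (earliest sample on ties).
    """
    mask = _window_mask(trace, window)
    if mask.sum() < 3:
        raise WindowError("window contains fewer than 3 samples")
    t = trace.times[mask]
    y = trace.intensities[mask]

    if baseline_windows is not None:
        bmask = np.zeros_like(mask)
        for bw in baseline_windows:
            bmask |= _window_mask(trace, bw)
        if not bmask.any():
            raise WindowError("baseline windows contain no samples")
        baseline = float(trace.intensities[bmask].mean())
    else:
        width = float(window[1]) - float(window[0])
        lo = max(float(window[0]) - width, float(trace.times[0]))
        hi = min(float(window[1]) + width, float(trace.times[-1]))
        flank = (
            (trace.times >= lo - 1e-12) & (trace.times <= hi + 1e-12) & ~mask
        )
        if flank.any():
            baseline = float(trace.intensities[flank].mean())
        else:
            baseline = float((y[0] + y[-1]) / 2.0)

    sub = y - baseline
    area = float(np.trapezoid(np.clip(sub, 0.0, None), t))
    apex_idx = int(np.argmax(sub))  # argmax returns the first maximum
    return PeakResult(
        area=area,
        height=float(sub[apex_idx]),
        apex_time=float(t[apex_idx]),
        baseline_level=baseline,
    )


def estimate_noise(
    trace: ChromatogramTrace,
    noise_window: Sequence[float],
    ddof: int = 0,
) -> float:
    """Standard deviation of the intensities inside ``noise_window``.

    ``ddof=0`` (population convention, default) or ``ddof=1`` (sample).
    Requires at least 10 samples in the window.
    """
    mask = _window_mask(trace, noise_window)
    if mask.sum() < 10:
        raise InsufficientDataError(
            f"noise window holds {int(mask.sum())} samples; >= 10 required"
        )
    return float(np.std(trace.intensities[mask], ddof=ddof))


def signal_to_noise(peak: PeakResult, noise: float, floor: float = NOISE_FLOOR) -> float:
    """Peak height divided by noise SD; raises rather than returning inf."""
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if noise < floor:
        raise ZeroNoiseError(f"noise {noise!r} below floor {floor!r}")
    return max(peak.height, 0.0) / noise


def determine_lloq(
    standards: Sequence[tuple[float, ChromatogramTrace]],
    threshold: float = DEFAULT_SNR_THRESHOLD,
    *,
    window: Sequence[float],
    noise_window: Sequence[float],
    baseline_windows: Sequence[Sequence[float]] | None = None,
) -> float:
    """Lowest nominal concentration whose S/N reaches ``threshold``.

    ``standards`` is a list of (nominal concentration, trace) pairs; each
    trace is integrated over ``window`` with noise estimated in
    ``noise_window``.
    """
    if not standards:
        raise InsufficientDataError("no standards supplied")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    qualifying: list[float] = []
    for nominal, trace in standards:
        peak = integrate_peak(trace, window, baseline_windows=baseline_windows)
        noise = estimate_noise(trace, noise_window)
        if signal_to_noise(peak, noise) >= threshold:
            qualifying.append(float(nominal))
    if not qualifying:
        raise NoLLOQError(f"no standard reached S/N >= {threshold}")
    return min(qualifying)
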