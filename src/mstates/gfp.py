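"""Global field power and peak-map extraction.

GFP is the spatial standard deviation of the scalp map at each sample —
a reference-free index of global field strength.  Local GFP maxima are
moments of high signal-to-noise and topographic stability, so only the
maps at those peaks enter clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Recording, average_reference_maps, gfp_of_maps


@dataclass
class GfpSeries:
    """Per-sample GFP values plus (optionally) detected peak indices."""

    values: np.ndarray
    excluded: np.ndarray
    sfreq: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)


def compute_gfp(rec: Recording) -> GfpSeries:
    """GFP(t) = sqrt(sum_i (u_i(t) - mean_i u(t))^2 / N) per sample."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    return GfpSeries(
        values=gfp_of_maps(rec.data), excluded=rec.excluded.copy(), sfreq=rec.sfreq
    )


def find_gfp_peaks(series: GfpSeries, min_separation: int = 1) -> np.ndarray:
    """Indices of local GFP maxima eligible for clustering.

    A peak satisfies ``v[t-1] < v[t] >= v[t+1]`` (the first sample of a
    plateau counts); series endpoints are never peaks.  Peaks on
    excluded samples, or immediately adjacent to one, are dropped —
    their maps may straddle artifacts.  If two retained peaks are closer
    than ``min_separation`` samples, the larger survives.
    """
    v = series.values
    if v.size < 3:
        return np.array([], dtype=int)
    t = np.arange(1, v.size - 1)
    is_peak = (v[t] > v[t - 1]) & (v[t] >= v[t + 1])
    peaks = t[is_peak]
    bad = series.excluded
    keep = ~(bad[peaks] | bad[peaks - 1] | bad[peaks + 1])
    peaks = peaks[keep]
    if min_separation > 1 and peaks.size:
        kept: list[int] = []
        for p in peaks:
            if kept and p - kept[-1] < min_separation:
                if v[p] > v[kept[-1]]:
                    kept[-1] = int(p)
            else:
                kept.append(int(p))
        peaks = np.array(kept, dtype=int)
    series.peak_indices = peaks
    return peaks


def peak_maps(rec: Recording, peaks: np.ndarray) -> np.ndarray:
    """Average-referenced maps at the peak samples, in temporal order.

    Returns an ``(n_peaks, N)`` stack; raises on an empty peak list.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("no GFP peaks to extract")
    if peaks.min() < 0 or peaks.max() >= rec.n_samples:
        raise ValueError("peak index out of range")
    return average_reference_maps(rec.data[np.sort(peaks)])
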