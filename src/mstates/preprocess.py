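"""Signal conditioning ahead of microstate analysis.

The standard chain is band-pass filter (1-50 Hz, zero-phase
Butterworth), optional component-based cleaning via an external hook,
decimation to 125 Hz, distance-weighted spatial smoothing, average
re-referencing, and exclusion of +-0.5 s windows around any sample
exceeding 100 uV.  Each stage is usable standalone; :func:`preprocess`
applies them in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal as sps

from .core import Recording, average_reference_maps


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: half-power cutoffs and single-pass order.

    ``zero_phase`` applies the filter forward-backward (non-causal).
    Because the two passes square the magnitude response, the design
    cutoffs are pre-warped so the *combined* response is still -3 dB at
    ``low_hz`` and ``high_hz``.
    """

    low_hz: float = 1.0
    high_hz: float = 50.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, sfreq: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= sfreq / 2:
            raise ValueError("high cutoff must be below Nyquist")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def _halfpower_adjusted_cutoffs(
    spec: FilterSpec, sfreq: float | None = None
) -> tuple[float, float]:
    """Design cutoffs such that two passes give -3 dB at the stated edges.

    For an isolated Butterworth edge of order n, |H|^2 = 1/(1 + (f/fc)^(2n));
    two passes reach half power where (f/fc)^(2n) = sqrt(2) - 1, i.e. the
    design cutoff sits a factor (sqrt(2)-1)^(-1/(2n)) beyond the target.
    In a band-pass the two edges interact slightly, so when the sampling
    rate is known the analytic guess is polished numerically until the
    single-pass response at each stated edge is exactly 2^(-1/4) in
    magnitude (hence 1/2 in power after the second pass).
    """
    shift = (np.sqrt(2.0) - 1.0) ** (-1.0 / (2.0 * spec.order))
    low, high = spec.low_hz / shift, spec.high_hz * shift
    if sfreq is None:
        return low, high
    from scipy.optimize import brentq

    target = 2.0 ** (-0.25)  # single-pass magnitude giving half power twice

    def gain(lo: float, hi: float, f: float) -> float:
        sos = sps.butter(spec.order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
        _, h = sps.sosfreqz(sos, worN=[f], fs=sfreq)
        return float(np.abs(h[0]))

    hi_cap = 0.999 * sfreq / 2
    high = min(high, hi_cap)
    for _ in range(3):  # alternate edges; converges fast
        low = brentq(
            lambda lo: gain(lo, high, spec.low_hz) - target,
            spec.low_hz * 1e-3,
            spec.low_hz,
            xtol=1e-10,
        )
        if spec.high_hz * shift < hi_cap:
            high = brentq(
                lambda hi: gain(low, hi, spec.high_hz) - target,
                spec.high_hz,
                hi_cap,
                xtol=1e-8,
            )
    return low, high


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase Butterworth band-pass; removes DC by construction."""
    spec = spec or FilterSpec()
    spec.validate(rec.sfreq)
    if spec.zero_phase:
        low, high = _halfpower_adjusted_cutoffs(spec, rec.sfreq)
    else:
        low, high = spec.low_hz, spec.high_hz
    sos = sps.butter(spec.order, [low, high], btype="bandpass", fs=rec.sfreq, output="sos")
    if spec.zero_phase:
        data = sps.sosfiltfilt(sos, rec.data, axis=0)
    else:
        data = sps.sosfilt(sos, rec.data, axis=0)
    return rec.copy_with(data=data)


def downsample(rec: Recording, factor: int) -> Recording:
    """Anti-alias low-pass then decimate by an integer factor.

    The excluded mask is decimated conservatively: a new sample is
    excluded if any of its constituent original samples was.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return rec.copy_with(data=rec.data.copy())
    data = sps.decimate(rec.data, factor, axis=0, ftype="fir", zero_phase=True)
    n_new = data.shape[0]
    pad = (-rec.n_samples) % factor
    mask = np.concatenate([rec.excluded, np.zeros(pad, dtype=bool)])
    mask = mask.reshape(n_new, factor).any(axis=1)
    return rec.copy_with(data=data, excluded=mask, sfreq=rec.sfreq / factor)


def _smoothing_weights(
    rec: Recording, n_neighbors: int, strength: float
) -> np.ndarray:
    """Row-stochastic smoothing matrix W: map -> W @ map per sample.

    Each channel mixes with its ``n_neighbors`` nearest neighbors using
    inverse-distance weights (normalized to unit sum), keeping a self
    fraction of ``strength / (strength + 1)``.
    """
    d = rec.montage.distances()
    n = rec.n_channels
    w = np.zeros((n, n))
    k = min(n_neighbors, n - 1)
    for i in range(n):
        order = np.argsort(d[i])
        nbrs = order[1 : k + 1]
        inv = 1.0 / d[i, nbrs]
        inv /= inv.sum()
        w[i, nbrs] = inv / (strength + 1.0)
        w[i, i] = strength / (strength + 1.0)
    return w


def spatial_smooth(
    rec: Recording, strength: float = 1.0, n_neighbors: int = 6
) -> Recording:
    """Instantaneous distance-weighted spatial smoothing of every map.

    Purely spatial (no temporal mixing); ``strength -> inf`` approaches
    the identity.  A declared stand-in for topographic smoothing based
    on the XYZ electrode coordinates.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    w = _smoothing_weights(rec, n_neighbors, strength)
    return rec.copy_with(data=rec.data @ w.T)


def reject_high_amplitude(
    rec: Recording, threshold_uv: float = 100.0, pad_s: float = 0.5
) -> Recording:
    """Exclude windows of +-``pad_s`` around supra-threshold excursions.

    A sample is a trigger when any channel exceeds ``threshold_uv`` in
    absolute value; all samples within ``pad_s`` seconds (inclusive in
    time) of a trigger are marked excluded.  Data values are untouched;
    the operation only grows the mask, so it is idempotent and monotone.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    hot = np.flatnonzero(np.any(np.abs(rec.data) > threshold_uv, axis=1))
    mask = rec.excluded.copy()
    if hot.size:
        pad = int(np.floor(pad_s * rec.sfreq + 1e-9))
        for i in hot:
            mask[max(0, i - pad) : i + pad + 1] = True
    return rec.copy_with(excluded=mask)


def to_average_reference(rec: Recording) -> Recording:
    """Subtract each sample's channel mean (idempotent; GFP-invariant)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.copy_with(data=average_reference_maps(rec.data), reference="average")


def ica_sample_eligibility(n_samples: int, n_channels: int) -> bool:
    """Whether a recording is long enough for a reliable decomposition.

    Component-based cleaning needs more than ``20 * n_channels**2``
    samples; recordings failing this check should be dropped from a
    component-cleaned analysis rather than cleaned on too little data.
    """
    return n_samples > 20 * n_channels**2


def preprocess(
    rec: Recording,
    filter_spec: FilterSpec | None = None,
    downsample_factor: int = 4,
    smooth: bool = True,
    smooth_strength: float = 1.0,
    reject_uv: float = 100.0,
    reject_pad_s: float = 0.5,
    clean_hook: Callable[[Recording], Recording] | None = None,
) -> Recording:
    """Full conditioning chain in canonical order.

    ``clean_hook`` is an optional externally supplied artifact-cleaning
    step (e.g. a component-rejection wrapper) applied after filtering,
    before decimation.
    """
    out = bandpass(rec, filter_spec)
    if clean_hook is not None:
        out = clean_hook(out)
    out = downsample(out, downsample_factor)
    out = to_average_reference(out)
    if smooth:
        out = spatial_smooth(out, strength=smooth_strength)
    out = reject_high_amplitude(out, threshold_uv=reject_uv, pad_s=reject_pad_s)
    return out
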