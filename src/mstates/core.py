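"""Core containers and topographic map algebra.

A *topography* (scalp map) is the vector of potentials across all
electrodes at one sample, considered average-referenced: adding a
constant to every channel does not change it.  Two maps that differ
only by a sign flip are treated as the same topography throughout
(polarity invariance), both in clustering and in back-fitting.

Conventions used package-wide:

* arrays are ``samples x channels`` (maps are rows), float64, microvolts;
* class labels are 0-based integers; :data:`UNASSIGNED` (= -1) marks
  samples carrying no microstate label;
* sample coordinates are 0-based, intervals half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: Label value for samples with no microstate class.
UNASSIGNED = -1


class ZeroVarianceError(ValueError):
    """Raised when a spatial correlation is requested for a flat map."""


# ---------------------------------------------------------------------------
# montage


@dataclass(frozen=True)
class Montage:
    """Electrode array: channel names plus 3-D positions.

    Positions are in arbitrary length units on a head-sized sphere; only
    relative distances are used (spatial smoothing, noise mixing).
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        n = len(self.channel_names)
        if n < 2:
            raise ValueError("a montage needs at least 2 channels")
        if pos.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {pos.shape}")
        if len(set(self.channel_names)) != n:
            raise ValueError("channel names must be unique")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d < 1e-12):
            raise ValueError("two channels share identical coordinates")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean (chord) distances, shape (N, N)."""
        p = self.positions
        return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)


# ---------------------------------------------------------------------------
# recordings


@dataclass
class Recording:
    """A multichannel EEG epoch.

    ``excluded`` flags samples that are dropped from analysis (artifact
    windows); the data values themselves are never modified by the
    rejection stage.
    """

    data: np.ndarray  # (n_samples, n_channels), microvolts
    sfreq: float
    montage: Montage
    excluded: np.ndarray | None = None  # bool (n_samples,)
    reference: str = "vertex"  # "vertex" | "average"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if self.excluded is None:
            self.excluded = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != (self.data.shape[0],):
                raise ValueError("excluded mask length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def analyzed_duration_s(self) -> float:
        """Seconds of non-excluded signal."""
        return float(np.sum(~self.excluded)) / self.sfreq

    def copy_with(self, **kw) -> "Recording":
        out = replace(self, **kw)
        if "excluded" not in kw:
            out.excluded = self.excluded.copy()
        return out


# ---------------------------------------------------------------------------
# template sets and label sequences


@dataclass
class TemplateSet:
    """K cluster template maps, rows zero-mean and unit-GFP.

    ``level`` records whether the set came from a single subject or from
    the pooled group step.  ``names`` are optional cosmetic class labels
    (canonically ``A``..``F``); analysis is label-agnostic.
    """

    maps: np.ndarray  # (K, N)
    level: str = "individual"  # "individual" | "group"
    names: tuple[str, ...] | None = None
    gev_total: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.names is not None:
            self.names = tuple(self.names)
            if len(self.names) != self.maps.shape[0]:
                raise ValueError("one name per template required")

    @property
    def n_templates(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate labels with the winning |correlation|."""

    labels: np.ndarray  # int, UNASSIGNED or 0..K-1
    correlations: np.ndarray  # best |r| per sample, in [0, 1]
    sfreq: float
    excluded: np.ndarray  # bool per sample
    smoothing_converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (self.labels.shape == self.correlations.shape == self.excluded.shape):
            raise ValueError("labels, correlations and mask must align")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def analyzed(self) -> np.ndarray:
        """Boolean mask of samples entering analysis (not excluded)."""
        return ~self.excluded


@dataclass(frozen=True)
class Segment:
    """A maximal run of one microstate class, half-open ``[start, end)``.

    ``truncated`` marks runs abutting an excluded span or the recording
    edge, whose true dwell time is under-observed.
    """

    label: int
    start: int
    end: int
    duration_ms: float
    truncated: bool

    @property
    def n_samples(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# map algebra


def average_reference_maps(maps: np.ndarray) -> np.ndarray:
    """Subtract each map's channel mean (re-reference to the average)."""
    maps = np.asarray(maps, dtype=float)
    return maps - maps.mean(axis=-1, keepdims=True)


def gfp_of_maps(maps: np.ndarray) -> np.ndarray:
    """Global field power of each map: spatial standard deviation.

    ``GFP = sqrt(sum_i (u_i - mean(u))^2 / N)`` — reference-free by
    construction.
    """
    maps = np.asarray(maps, dtype=float)
    centered = maps - maps.mean(axis=-1, keepdims=True)
    return np.sqrt(np.mean(centered**2, axis=-1))


def canonical_sign(maps: np.ndarray) -> np.ndarray:
    """Fix each row's polarity so its largest-|value| channel is positive."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float)).copy()
    idx = np.argmax(np.abs(maps), axis=-1)
    signs = np.sign(maps[np.arange(maps.shape[0]), idx])
    signs[signs == 0] = 1.0
    return maps * signs[:, None]


def normalize_maps(maps: np.ndarray, canonical: bool = True) -> np.ndarray:
    """Average-reference and scale each row to unit GFP.

    Rows with zero variance raise :class:`ZeroVarianceError`.
    """
    maps = average_reference_maps(np.atleast_2d(maps))
    g = gfp_of_maps(maps)
    if np.any(g <= 0):
        raise ZeroVarianceError("cannot normalize a zero-variance map")
    out = maps / g[:, None]
    return canonical_sign(out) if canonical else out


def _unit_rows(maps: np.ndarray) -> np.ndarray:
    centered = average_reference_maps(np.atleast_2d(maps))
    norms = np.linalg.norm(centered, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ZeroVarianceError("zero-variance map in correlation")
    return centered / norms


def spatial_correlation(
    a: np.ndarray, b: np.ndarray, polarity_invariant: bool = True
) -> float:
    """Pearson correlation of two maps across channels.

    With ``polarity_invariant`` the absolute value is returned, treating
    a map and its sign-flip as identical topographies.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have equal channel counts")
    r = float(_unit_rows(a)[0] @ _unit_rows(b)[0])
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r


def correlation_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Signed Pearson correlations between rows of two map stacks.

    Returns shape ``(n_maps, n_templates)``.  Zero-variance map rows get
    correlation 0 against every template (they carry no topography).
    """
    maps = average_reference_maps(np.atleast_2d(maps))
    templates = _unit_rows(templates)
    norms = np.linalg.norm(maps, axis=-1, keepdims=True)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    unit = maps / safe
    c = unit @ templates.T
    c[norms.ravel() == 0, :] = 0.0
    return np.clip(c, -1.0, 1.0)


def run_lengths(labels: Sequence[int]) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values as ``(value, start, end)`` half-open."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]
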