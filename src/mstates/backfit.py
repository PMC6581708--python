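"""Back-fitting: label every sample with its best-matching class.

Each non-excluded sample is assigned, winner-takes-all, to the template
with the highest |spatial correlation| — but only if that correlation
exceeds a floor (default 0.5); otherwise the sample stays unassigned.
An iterative temporal smoothing step (strength ``lambda``, window
half-size ``b``) then rewards labels that agree with their temporal
neighborhood, suppressing spurious single-sample interruptions of a
stable microstate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    UNASSIGNED,
    LabelSequence,
    Recording,
    Segment,
    TemplateSet,
    correlation_matrix,
    gfp_of_maps,
    run_lengths,
)


@dataclass(frozen=True)
class SmoothingSpec:
    """Temporal smoothing parameters.

    ``lam`` (Besag factor) scales the neighborhood-agreement bonus;
    ``window_half_size`` b is the one-sided extent of the neighborhood
    in samples; ``corr_floor`` is the minimum winning |r| for a sample
    to be labeled at all.
    """

    lam: float = 10.0
    window_half_size: int = 3
    corr_floor: float = 0.5
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.window_half_size < 0:
            raise ValueError("window half-size must be >= 0")
        if not (0 <= self.corr_floor < 1):
            raise ValueError("correlation floor must be in [0, 1)")


def label_timepoints(
    rec: Recording, templates: TemplateSet, corr_floor: float = 0.5
) -> LabelSequence:
    """Winner-takes-all labeling by |spatial correlation|.

    Excluded samples, zero-variance samples, and samples whose best |r|
    does not exceed ``corr_floor`` are UNASSIGNED.  Ties break to the
    lowest class index.
    """
    if templates.n_channels != rec.n_channels:
        raise ValueError("templates do not match the recording montage")
    c = np.abs(correlation_matrix(rec.data, templates.maps))
    labels = np.argmax(c, axis=1)
    best = c[np.arange(rec.n_samples), labels]
    labels = labels.astype(int)
    labels[best <= corr_floor] = UNASSIGNED
    labels[rec.excluded] = UNASSIGNED
    best = np.where(labels == UNASSIGNED, np.where(rec.excluded, 0.0, best), best)
    return LabelSequence(
        labels=labels, correlations=best, sfreq=rec.sfreq, excluded=rec.excluded.copy()
    )


def _neighbor_counts(assigned: np.ndarray, labels: np.ndarray, k: int, b: int) -> np.ndarray:
    """n_u(t, b): assigned samples labeled u within t +- b, excluding t."""
    n = labels.shape[0]
    counts = np.zeros((n, k))
    kernel = np.ones(2 * b + 1)
    for u in range(k):
        ind = (assigned & (labels == u)).astype(float)
        win = np.convolve(ind, kernel, mode="same")
        counts[:, u] = win - ind
    return counts


def besag_smooth(
    seq: LabelSequence,
    rec: Recording,
    templates: TemplateSet,
    spec: SmoothingSpec | None = None,
) -> LabelSequence:
    """Iterative temporal relabeling with a neighborhood-agreement bonus.

    Every non-excluded sample is relabeled to the class u maximizing

    ``(GFP(t) * C_u(t))^2 + lam * (2 sigma^2 / (N - 1)) * n_u(t, b)``

    where ``n_u(t, b)`` counts currently-labeled-u samples in the window
    ``t +- b`` (excluding t; unassigned and excluded samples do not
    count as neighbors) and ``sigma^2`` is the mean squared residual of
    the currently assigned fit.  Sweeps use synchronous updates until no
    label changes or ``max_iter`` is reached (then
    ``smoothing_converged`` is False).

    The correlation floor enters as evidence weighting, not as a frozen
    state: a sample whose best |r| is at or below the floor contributes
    no data term, and is captured into a class only when its
    neighborhood supports one (positive score); otherwise it stays
    UNASSIGNED.  Excluded and zero-variance samples are never labeled.
    With ``lam = 0`` the labels are returned unchanged.
    """
    spec = spec or SmoothingSpec()
    k = templates.n_templates
    n_ch = rec.n_channels
    labels = seq.labels.copy()
    c_signed = correlation_matrix(rec.data, templates.maps)
    gfp = gfp_of_maps(rec.data)
    data_term = (gfp[:, None] * c_signed) ** 2  # (GFP * C_u)^2 per class
    best_abs_r = np.max(np.abs(c_signed), axis=1)
    eligible = (~seq.excluded) & (gfp > 0)
    # sub-floor samples carry no usable topographic evidence of their own
    sub_floor = eligible & (best_abs_r <= spec.corr_floor)
    data_term[sub_floor, :] = 0.0
    converged = True

    if spec.lam > 0 and np.any(labels != UNASSIGNED):
        prev = None
        for _ in range(spec.max_iter):
            assigned = labels != UNASSIGNED
            # mean squared residual of the current fit: the GFP-scaled
            # variance left unexplained by each sample's own template
            c2 = np.clip(
                c_signed[np.arange(labels.size), np.maximum(labels, 0)] ** 2, 0.0, 1.0
            )
            # sigma^2 = mean over assigned samples of ||x - proj||^2,
            # the squared residual norm of the winner-takes-all fit
            sigma2 = float(
                np.mean(gfp[assigned] ** 2 * (1.0 - c2[assigned])) * n_ch
            )
            counts = _neighbor_counts(assigned, labels, k, spec.window_half_size)
            score = data_term + spec.lam * (2.0 * sigma2 / (n_ch - 1)) * counts
            arg = np.argmax(score, axis=1)
            top = score[np.arange(labels.size), arg]
            new = np.where(eligible & (top > 0), arg, UNASSIGNED)
            if np.array_equal(new, labels):
                break
            if prev is not None and np.array_equal(new, prev):
                # two-cycle: keep the current state
                break
            prev = labels
            labels = new
        else:
            converged = False
            warnings.warn("temporal smoothing did not converge", stacklevel=2)

    corr = np.where(
        labels == UNASSIGNED,
        0.0,
        np.abs(c_signed[np.arange(labels.size), np.maximum(labels, 0)]),
    )
    return LabelSequence(
        labels=labels,
        correlations=corr,
        sfreq=seq.sfreq,
        excluded=seq.excluded.copy(),
        smoothing_converged=converged,
    )


def extract_segments(seq: LabelSequence) -> list[Segment]:
    """Run-length view of the labeled sequence.

    Maximal runs of one class; UNASSIGNED and excluded spans break runs
    and produce no segment.  A run abutting an excluded span or a
    recording edge is flagged ``truncated`` (its true dwell time is
    under-observed).
    """
    n = seq.n_samples
    out: list[Segment] = []
    for label, start, end in run_lengths(seq.labels):
        if label == UNASSIGNED:
            continue
        left_cut = start == 0 or seq.excluded[start - 1]
        right_cut = end == n or seq.excluded[end]
        out.append(
            Segment(
                label=int(label),
                start=start,
                end=end,
                duration_ms=(end - start) * 1000.0 / seq.sfreq,
                truncated=bool(left_cut or right_cut),
            )
        )
    return out


def backfit(
    rec: Recording,
    templates: TemplateSet,
    spec: SmoothingSpec | None = None,
) -> tuple[LabelSequence, list[Segment]]:
    """Label, smooth, and segment a preprocessed recording."""
    spec = spec or SmoothingSpec()
    seq = label_timepoints(rec, templates, corr_floor=spec.corr_floor)
    seq = besag_smooth(seq, rec, templates, spec)
    return seq, extract_segments(seq)
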