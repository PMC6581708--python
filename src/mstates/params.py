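"""Per-class temporal parameters of a labeled microstate sequence.

Four parameters per class and subject:

* **mean duration** (ms): average dwell time of the class's segments;
* **occurrence** (1/s): segments of the class per analyzed second;
* **coverage** (fraction): share of analyzed time labeled with the class;
* **GEV** (fraction): GFP-weighted variance the class's template explains
  over the samples labeled with it, relative to all analyzed samples.

Analyzed time includes unassigned (but not excluded) samples, so
coverages over classes sum to 1 only when every sample is labeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UNASSIGNED, LabelSequence, Recording, Segment, TemplateSet, correlation_matrix, gfp_of_maps

PARAMETER_NAMES = ("mean_duration_ms", "occurrence_per_s", "coverage", "gev")


def mean_duration(
    segments: list[Segment], label: int, include_truncated: bool = False
) -> float:
    """Mean dwell time (ms) of the class's segments; NaN when absent.

    Truncated segments (cut by an excluded span or the recording edge)
    understate the true dwell time and are excluded by default.
    """
    durations = [
        s.duration_ms
        for s in segments
        if s.label == label and (include_truncated or not s.truncated)
    ]
    return float(np.mean(durations)) if durations else float("nan")


def occurrence(segments: list[Segment], label: int, analyzed_duration_s: float) -> float:
    """Segments of the class per second of analyzed signal."""
    if analyzed_duration_s <= 0:
        raise ValueError("analyzed duration must be positive")
    return sum(1 for s in segments if s.label == label) / analyzed_duration_s


def coverage(seq: LabelSequence, label: int) -> float:
    """Fraction of analyzed (non-excluded) samples labeled with the class.

    Unassigned samples count in the denominator only: the whole analyzed
    time is the reference.
    """
    analyzed = seq.analyzed
    total = int(np.sum(analyzed))
    if total == 0:
        raise ValueError("no analyzed samples")
    return float(np.sum(analyzed & (seq.labels == label))) / total


def gev_per_class(
    seq: LabelSequence, rec: Recording, templates: TemplateSet, label: int
) -> float:
    """Class GEV: sum over the class's samples of (GFP * C)^2, divided by
    the summed GFP^2 over *all* analyzed samples — so class GEVs add up
    to the total GEV of the fitted sequence."""
    analyzed = seq.analyzed
    gfp = gfp_of_maps(rec.data)
    denom = float(np.sum(gfp[analyzed] ** 2))
    if denom == 0:
        raise ValueError("zero GFP over the analyzed samples")
    sel = analyzed & (seq.labels == label)
    if not np.any(sel):
        return 0.0
    c = correlation_matrix(rec.data[sel], templates.maps[label][None, :])[:, 0]
    return float(np.sum((gfp[sel] * c) ** 2) / denom)


@dataclass
class SubjectParameters:
    """All four temporal parameters for one subject, one row per class."""

    subject_id: str
    group: str
    table: pd.DataFrame  # index: class, columns: PARAMETER_NAMES
    unassigned_coverage: float
    gev_total: float

    def value(self, parameter: str, label: int) -> float:
        return float(self.table.loc[label, parameter])


def subject_parameters(
    subject_id: str,
    group: str,
    seq: LabelSequence,
    segments: list[Segment],
    rec: Recording,
    templates: TemplateSet,
    include_truncated_durations: bool = False,
) -> SubjectParameters:
    """Evaluate all parameters for every class of one subject."""
    k = templates.n_templates
    analyzed_s = seq.analyzed.sum() / seq.sfreq
    rows = {}
    for u in range(k):
        rows[u] = {
            "mean_duration_ms": mean_duration(
                segments, u, include_truncated=include_truncated_durations
            ),
            "occurrence_per_s": occurrence(segments, u, analyzed_s),
            "coverage": coverage(seq, u),
            "gev": gev_per_class(seq, rec, templates, u),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[list(PARAMETER_NAMES)]
    return SubjectParameters(
        subject_id=subject_id,
        group=group,
        table=table,
        unassigned_coverage=coverage_unassigned(seq),
        gev_total=float(table["gev"].sum()),
    )


def coverage_unassigned(seq: LabelSequence) -> float:
    """Fraction of analyzed samples left unlabeled."""
    analyzed = seq.analyzed
    total = int(np.sum(analyzed))
    if total == 0:
        raise ValueError("no analyzed samples")
    return float(np.sum(analyzed & (seq.labels == UNASSIGNED))) / total
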