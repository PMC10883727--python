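"""Artefact-based segment exclusion and per-subject global averaging.

Quality control drops artefact-flagged segments; the remaining segments
give each subject's global mapping value (arithmetic mean). Subjects
with every segment excluded are dropped and reported, never raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic_cohort import SEPTAL_LABELS, Subject

__all__ = ["QCReport", "apply_qc", "septal_vs_global"]


@dataclass
class QCReport:
    """Bookkeeping of the exclusion pass over one set of subjects."""

    n_segments_total: int
    n_excluded: int
    per_label_exclusions: dict[str, int] = field(default_factory=dict)
    subjects_dropped: list[str] = field(default_factory=list)

    @property
    def exclusion_rate(self) -> float:
        if self.n_segments_total == 0:
            return 0.0
        return self.n_excluded / self.n_segments_total

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_segments_total": self.n_segments_total,
                "n_excluded": self.n_excluded,
                "exclusion_rate": self.exclusion_rate,
                "per_label_exclusions": self.per_label_exclusions,
                "subjects_dropped": self.subjects_dropped,
            },
            indent=2,
        )


def apply_qc(subjects: Sequence[Subject]) -> tuple[list[Subject], QCReport]:
    """Set ``global_value`` on each subject and report exclusions.

    Returns the kept subjects (those with at least one accepted segment)
    with ``global_value`` = mean of non-artefact segment values, and a
    :class:`QCReport`. Subjects whose segments are all flagged are
    dropped and listed in ``subjects_dropped``.
    """
    kept: list[Subject] = []
    n_total = 0
    n_excl = 0
    per_label: dict[str, int] = {}
    dropped: list[str] = []
    for s in subjects:
        if not s.segments:
            raise ValueError(f"subject {s.id}: no segments")
        good = []
        for seg in s.segments:
            n_total += 1
            if seg.artefact:
                n_excl += 1
                per_label[seg.segment_label] = per_label.get(seg.segment_label, 0) + 1
            else:
                good.append(seg.value)
        if good:
            s.global_value = float(np.mean(good))
            kept.append(s)
        else:
            dropped.append(s.id)
    return kept, QCReport(
        n_segments_total=n_total,
        n_excluded=n_excl,
        per_label_exclusions=per_label,
        subjects_dropped=dropped,
    )


def septal_vs_global(subject: Subject) -> float | None:
    """Signed percent difference of the mid-ventricular septum vs global.

    The mid-ventricular septum is the two septal sectors on the middle
    slice (``floor(n_slices / 2)``, 0-based, with ``n_slices`` inferred
    from the subject's segments). Returns
    ``100 * (septal_mean - global) / global``, negative when the septum
    reads low, or ``None`` when every eligible septal segment is
    artefact-flagged (not computable).
    """
    if subject.global_value is None:
        raise ValueError(f"subject {subject.id}: run apply_qc before septal_vs_global")
    n_slices = max(seg.slice_index for seg in subject.segments) + 1
    mid = n_slices // 2
    septal = [
        seg.value
        for seg in subject.segments
        if seg.slice_index == mid and seg.segment_label in SEPTAL_LABELS and not seg.artefact
    ]
    if not septal:
        return None
    septal_mean = float(np.mean(septal))
    return 100.0 * (septal_mean - subject.global_value) / subject.global_value
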