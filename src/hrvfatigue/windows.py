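"""Overlapping 2-minute windowing and expert-consensus labeling.

A 60-minute recording cut into 120 s windows with a 60 s step yields
floor((3600-120)/60)+1 = 59 segments.  Each window spanning minutes m and
m+1 receives a consensus label from the 5-rater votes of those minutes:
'alert' when >= 3 raters voted alert in BOTH minutes, 'fatigued' when >= 3
raters voted fatigued or very_fatigued (pooled) in BOTH minutes, otherwise
'discordant'.  Discordant segments are dropped before analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from collections import Counter

import numpy as np

from .ingest import RRSeries

__all__ = [
    "Segment",
    "segment_recording",
    "consensus_label",
    "label_segments",
    "filter_discordant",
    "window_count",
]

logger = logging.getLogger("hrvfatigue")

LABELS = ("alert", "fatigued", "discordant")


@dataclass(frozen=True)
class Segment:
    """A labeled 2-minute analysis window of one subject's recording."""

    subject_id: str
    sex: str
    window_index: int
    start_s: float
    end_s: float
    rr: RRSeries
    label: str = "unlabeled"

    @property
    def n_beats(self) -> int:
        return len(self.rr)


def window_count(duration_s: float, window_s: float, step_s: float) -> int:
    """Number of windows: floor((duration - window)/step) + 1."""
    return int(np.floor((duration_s - window_s) / step_s)) + 1


def segment_recording(
    rr: RRSeries,
    duration_s: float,
    window_s: float = 120.0,
    step_s: float = 60.0,
    subject_id: str = "",
    sex: str = "",
) -> list[Segment]:
    """Cut an RR series into overlapping windows.

    Windows start at 0, step_s, 2*step_s, ...; the last window ends at or
    before ``duration_s``.  An interval belongs to the window containing its
    onset timestamp (half-open [start, end)), so no beat is double-counted
    at a boundary.
    """
    if window_s > duration_s:
        raise ValueError(
            f"window ({window_s} s) longer than recording ({duration_s} s)"
        )
    if not 0 < step_s <= window_s:
        raise ValueError("need 0 < step_s <= window_s")
    onsets = rr.onsets_s
    segments = []
    for k in range(window_count(duration_s, window_s, step_s)):
        start = k * step_s
        end = start + window_s
        i0, i1 = np.searchsorted(onsets, [start, end], side="left")
        if i1 > i0:
            sub = RRSeries(rr.intervals[i0:i1], rr.timestamps[i0 : i1 + 1])
        else:
            sub = RRSeries(np.empty(0), np.empty(0))
        segments.append(
            Segment(
                subject_id=subject_id,
                sex=sex,
                window_index=k,
                start_s=float(start),
                end_s=float(end),
                rr=sub,
            )
        )
    return segments


def _minute_consensus(votes) -> str | None:
    """'alert' / 'fatigued' when >= 3 of 5 raters agree (pooled), else None."""
    if len(votes) != 5:
        raise ValueError(f"expected exactly 5 ratings per minute, got {len(votes)}")
    counts = Counter(votes)
    unknown = set(counts) - {"alert", "fatigued", "very_fatigued"}
    if unknown:
        raise ValueError(f"unknown vote categories: {sorted(unknown)}")
    if counts["alert"] >= 3:
        return "alert"
    if counts["fatigued"] + counts["very_fatigued"] >= 3:
        return "fatigued"
    return None


def consensus_label(votes_min1, votes_min2) -> str:
    """Two-minute consensus rule; permutation-invariant in raters."""
    c1, c2 = _minute_consensus(votes_min1), _minute_consensus(votes_min2)
    if c1 == c2 and c1 is not None:
        return c1
    return "discordant"


def label_segments(segments: list[Segment], votes) -> list[Segment]:
    """Assign consensus labels from per-minute votes.

    Each window must cover whole minutes (start and end on 60 s boundaries);
    every covered minute must reach the same >= 3-of-5 consensus for the
    segment to be labeled, mirroring the two-minute rule for the canonical
    120 s window.
    """
    out = []
    for seg in segments:
        if seg.start_s % 60 or seg.end_s % 60:
            raise ValueError(
                f"window [{seg.start_s}, {seg.end_s}) not aligned to whole minutes"
            )
        m0, m1 = int(seg.start_s // 60), int(seg.end_s // 60)
        if m1 > len(votes):
            raise ValueError(
                f"window [{seg.start_s}, {seg.end_s}) extends past the vote table"
            )
        consensus = {_minute_consensus(votes[m]) for m in range(m0, m1)}
        if len(consensus) == 1 and None not in consensus:
            label = consensus.pop()
        else:
            label = "discordant"
        out.append(replace(seg, label=label))
    return out


def filter_discordant(segments: list[Segment]) -> list[Segment]:
    """Drop discordant segments; log per-label, per-sex retention counts."""
    kept = [s for s in segments if s.label in ("alert", "fatigued")]
    counts = Counter((s.label, s.sex) for s in segments)
    for (label, sex), n in sorted(counts.items()):
        logger.info("segments label=%s sex=%s n=%d", label, sex, n)
    if not kept:
        warnings.warn("all segments discordant; nothing retained", stacklevel=2)
    return kept
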