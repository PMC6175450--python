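"""Sliding-window sequence conservation for cis-regulatory comparison.

Two intergenic sequences are globally aligned, percent identity is
computed in a sliding window (default 100 bp, step 1) over alignment
columns, and maximal runs of windows at or above a threshold (default
70%) are reported as conserved regions.  Region coordinates are given in
alignment space and projected to each input sequence's own coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

log = logging.getLogger(__name__)

_VALID = re.compile(r"^[ACGTN]*$")


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of two nucleotide sequences."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def match_columns(self) -> np.ndarray:
        """Boolean per column: identical bases (gap columns are mismatches;
        N matches nothing)."""
        a = np.frombuffer(self.aligned_a.encode(), dtype="S1")
        b = np.frombuffer(self.aligned_b.encode(), dtype="S1")
        return (a == b) & (a != b"-") & (a != b"N")

    def column_to_seq_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per alignment column, the 0-based position in each ungapped
        sequence (position of the residue at or before the column)."""
        a = np.frombuffer(self.aligned_a.encode(), dtype="S1")
        b = np.frombuffer(self.aligned_b.encode(), dtype="S1")
        pos_a = np.cumsum(a != b"-") - 1
        pos_b = np.cumsum(b != b"-") - 1
        return np.maximum(pos_a, 0), np.maximum(pos_b, 0)


@dataclass
class ConservationProfile:
    """Percent identity per sliding window along an alignment."""

    window_starts: np.ndarray   # alignment coordinates, 0-based
    identity: np.ndarray        # percent, same length
    window: int
    alignment_length: int

    @property
    def window_centres(self) -> np.ndarray:
        return self.window_starts + self.window / 2.0


@dataclass
class ConservedRegion:
    start: int        # alignment coordinates, 0-based half-open
    end: int
    mean_identity: float
    max_identity: float


def _validate(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} is empty")
    if not _VALID.match(seq):
        bad = [i for i, ch in enumerate(seq) if ch not in "ACGTN"][:10]
        raise ValueError(f"{name} has non-ACGTN characters at positions {bad}")
    return seq


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 5.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with affine gap penalties.

    Defaults: match +1, mismatch -1, gap open 5, gap extend 1 (penalties
    given as positive costs).  The aligner's first reported optimal
    alignment is taken, which is deterministic for fixed inputs.
    """
    seq_a = _validate(seq_a, "seq_a")
    seq_b = _validate(seq_b, "seq_b")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=-abs(gap_open),
        extend_gap_score=-abs(gap_extend),
    )
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    arr = np.array(best)
    return PairwiseAlignment(
        aligned_a=arr[0].tobytes().decode(),
        aligned_b=arr[1].tobytes().decode(),
        score=float(best.score),
    )


def sliding_identity(
    alignment: PairwiseAlignment, window: int = 100, step: int = 1
) -> ConservationProfile:
    """Percent identity per window of alignment columns.

    Gap columns count as mismatches.  An alignment shorter than the window
    yields a single truncated window (with a warning).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    match = alignment.match_columns().astype(float)
    L = alignment.length
    if L < window:
        log.warning("alignment length %d < window %d; single truncated window", L, window)
        return ConservationProfile(
            window_starts=np.array([0]),
            identity=np.array([100.0 * match.mean()]),
            window=L,
            alignment_length=L,
        )
    csum = np.concatenate([[0.0], np.cumsum(match)])
    starts = np.arange(0, L - window + 1, step)
    ident = 100.0 * (csum[starts + window] - csum[starts]) / window
    return ConservationProfile(starts, ident, window, L)


def call_regions(
    profile: ConservationProfile, threshold: float = 70.0, min_run: int = 1
) -> list[ConservedRegion]:
    """Maximal runs of consecutive windows at/above the threshold, merged
    into regions spanning first window start to last window end.

    Because a region extends a full window past its last qualifying start,
    runs separated by a dip shorter than one window produce overlapping
    spans; such regions are merged, so the output is sorted and
    non-overlapping.
    """
    above = profile.identity >= threshold
    runs: list[tuple[int, int, np.ndarray]] = []  # (span_start, span_end, identities)
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            start = int(profile.window_starts[i])
            end = int(min(profile.window_starts[j] + profile.window, profile.alignment_length))
            runs.append((start, end, profile.identity[i : j + 1]))
        i = j + 1
    merged: list[list] = []  # [span_start, span_end, list of identity arrays]
    for start, end, vals in runs:
        if merged and start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2].append(vals)
        else:
            merged.append([start, end, [vals]])
    return [
        ConservedRegion(
            start, end,
            float(np.concatenate(chunks).mean()),
            float(np.concatenate(chunks).max()),
        )
        for start, end, chunks in merged
    ]


def regions_to_sequence_coords(
    regions: list[ConservedRegion], alignment: PairwiseAlignment
) -> pd.DataFrame:
    """Project alignment-space regions onto each sequence's own 0-based
    half-open coordinates."""
    pos_a, pos_b = alignment.column_to_seq_positions()
    rows = []
    for r in regions:
        rows.append(
            (
                r.start, r.end,
                int(pos_a[r.start]), int(pos_a[r.end - 1]) + 1,
                int(pos_b[r.start]), int(pos_b[r.end - 1]) + 1,
                r.mean_identity, r.max_identity,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "aln_start", "aln_end", "a_start", "a_end", "b_start", "b_end",
            "mean_identity", "max_identity",
        ],
    )


def annotate_overlap(
    regions: list[ConservedRegion],
    features: list[tuple[int, int, str]],
    profile: ConservationProfile | None = None,
) -> pd.DataFrame:
    """Per feature (BED-style 0-based half-open, alignment coordinates):
    fraction of its span covered by called regions and the mean window
    identity within the feature."""
    rows = []
    for start, end, name in features:
        if end <= start:
            raise ValueError(f"feature {name!r} has non-positive span")
        covered = 0
        for r in regions:
            covered += max(0, min(end, r.end) - max(start, r.start))
        frac = covered / (end - start)
        mean_ident = float("nan")
        flagged = False
        if profile is not None:
            in_feat = (profile.window_starts >= start) & (
                profile.window_starts + profile.window <= end
            )
            if in_feat.any():
                mean_ident = float(profile.identity[in_feat].mean())
            if start >= profile.alignment_length:
                flagged = True
                log.warning("feature %r lies outside the alignment span", name)
        rows.append((name, start, end, frac, mean_ident, flagged))
    return pd.DataFrame(
        rows,
        columns=["name", "start", "end", "covered_fraction", "mean_identity", "outside"],
    )
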