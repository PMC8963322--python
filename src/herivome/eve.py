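"""Distinguishing endogenous viral elements (EVEs) from exogenous virus at
the small-RNA read level.

An EVE that diverged ~20-25% from its exogenous counterpart lets most
reads be assigned unambiguously to one reference; reads falling inside
perfectly conserved stretches (identity windows at least one read length
long) cannot be, and are masked out. The module aligns the pair globally,
censuses identity windows, builds the ambiguity mask, and labels reads as
virus / eve / ambiguous / unmapped — with per-label size profiles so that
EVE-derived reads can be shown piRNA-sized while viral reads are
siRNA-sized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .mapper import map_reads
from .profiler import SIZE_MAX, SIZE_MIN, OVERFLOW, SizeProfile

LABELS = ("virus", "eve", "ambiguous", "unmapped")


@dataclass
class IdentityWindow:
    """Maximal run of consecutive identical aligned columns."""
    a_start: int  # first-sequence coordinate (half-open interval start)
    b_start: int  # second-sequence coordinate
    length: int

    @property
    def a_interval(self) -> tuple[int, int]:
        return (self.a_start, self.a_start + self.length)

    @property
    def b_interval(self) -> tuple[int, int]:
        return (self.b_start, self.b_start + self.length)


@dataclass
class PairwiseAlignmentReport:
    aligned_length: int          # aligned (both non-gap) columns
    compared_columns: int        # aligned columns outside excluded intervals
    matches: int
    identity_pct: float | None   # None when degenerate (nothing compared)
    excluded: list[tuple[int, int]]
    windows: list[IdentityWindow]

    @property
    def degenerate(self) -> bool:
        return self.identity_pct is None


@dataclass
class AmbiguityMask:
    """Intervals (0-based half-open, per sequence) within which a read could
    map perfectly to both references."""
    min_read_len: int
    virus_intervals: list[tuple[int, int]] = field(default_factory=list)
    eve_intervals: list[tuple[int, int]] = field(default_factory=list)

    def covers(self, which: str, start: int, end: int) -> bool:
        intervals = self.virus_intervals if which == "virus" else self.eve_intervals
        return any(s <= start and end <= e for s, e in intervals)


def align_pair(virus: str, eve: str,
               exclude: list[tuple[int, int]] | None = None,
               match: float = 1.0, mismatch: float = -1.0,
               gap_open: float = -5.0, gap_extend: float = -1.0,
               ) -> PairwiseAlignmentReport:
    """Global alignment of an exogenous segment against its EVE.

    ``exclude`` intervals are in EVE coordinates (typically the tandem
    duplication copy). Excluded positions are excised from the EVE before
    aligning — a tandem copy makes the gap placement degenerate, so the
    exclusion is applied to the sequence rather than to alignment columns —
    and count toward neither identity nor identity windows. Reported window
    coordinates are in each sequence's own (original) coordinates.
    """
    virus = virus.upper()
    eve = eve.upper()
    if len(virus) < 100 or len(eve) < 100:
        raise ValueError("both sequences must be at least 100 nt")
    exclude = sorted(exclude or [])
    for (s0, e0), (s1, e1) in zip(exclude, exclude[1:]):
        if s1 < e0:
            raise ValueError("excluded intervals overlap")

    # excise excluded EVE positions, remembering the collapsed -> original map
    keep = np.ones(len(eve), dtype=bool)
    for s, e in exclude:
        if not 0 <= s < e <= len(eve):
            raise ValueError(f"excluded interval ({s},{e}) outside EVE bounds")
        keep[s:e] = False
    orig_pos = np.flatnonzero(keep)
    collapsed = "".join(eve[i] for i in orig_pos)
    if len(collapsed) == 0:
        raise ValueError("exclusion removes the entire EVE sequence")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(virus, collapsed)[0]

    aligned_length = 0
    matches = 0
    windows: list[IdentityWindow] = []
    run: IdentityWindow | None = None

    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for k in range(a1 - a0):
            va, vb = a0 + k, b0 + k
            aligned_length += 1
            if virus[va] == collapsed[vb] and virus[va] != "N":
                matches += 1
                if run is not None and run.a_start + run.length == va:
                    run.length += 1
                else:
                    run = IdentityWindow(va, int(orig_pos[vb]), 1)
                    windows.append(run)
            else:
                run = None
        run = None  # gaps between blocks break identity runs

    identity = 100.0 * matches / aligned_length if aligned_length else None
    return PairwiseAlignmentReport(aligned_length, aligned_length, matches,
                                   identity, exclude, windows)


def build_ambiguity_mask(report: PairwiseAlignmentReport,
                         min_read_len: int = 18) -> AmbiguityMask:
    """Union of identity windows long enough to contain a whole read."""
    mask = AmbiguityMask(min_read_len=min_read_len)
    for w in sorted(report.windows, key=lambda w: w.a_start):
        if w.length >= min_read_len:
            mask.virus_intervals.append(w.a_interval)
            mask.eve_intervals.append(w.b_interval)
    return mask


def _size_profile_from_lengths(label: str, lengths: list[int]) -> SizeProfile:
    profile = SizeProfile(label)
    for length in lengths:
        key = length if SIZE_MIN <= length <= SIZE_MAX else OVERFLOW
        profile.counts_sense[key] += 1  # strand-agnostic: store on one track
    return profile


def assign_reads(reads, virus: str, eve: str,
                 mask: AmbiguityMask | None = None,
                 min_match_fraction: float = 0.95,
                 virus_id: str = "virus", eve_id: str = "eve",
                 ) -> tuple[dict[str, str], dict[str, SizeProfile]]:
    """Label each read virus / eve / ambiguous / unmapped.

    A read is ambiguous if it maps at threshold to both references
    (authoritative) or if its placement lies wholly inside a mask
    interval (the precomputed fast path). Returns per-read labels and a
    size profile per label.
    """
    reads = list(reads)
    alignments = map_reads(reads, {virus_id: virus, eve_id: eve},
                           min_match_fraction=min_match_fraction, policy="all")
    by_read: dict[str, list] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)

    labels: dict[str, str] = {}
    lengths: dict[str, list[int]] = {label: [] for label in LABELS}
    for read_id, seq in reads:
        placements = by_read.get(read_id, [])
        targets = {a.contig_id for a in placements}
        if not targets:
            label = "unmapped"
        elif len(targets) == 2:
            label = "ambiguous"
        else:
            target = targets.pop()
            label = "virus" if target == virus_id else "eve"
            if mask is not None and any(
                    mask.covers(label, a.start, a.end) for a in placements):
                label = "ambiguous"
        labels[read_id] = label
        lengths[label].append(len(seq))

    profiles = {label: _size_profile_from_lengths(label, lens)
                for label, lens in lengths.items()}
    return labels, profiles
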