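"""Per-contig small-RNA size profiles and the siRNA-enrichment call.

A sharp peak of 21-nt reads among the 18-31 nt size classes is the
Dicer-2 signature used to call active (and, in germline tissue, inherited)
virus infection. The call criterion — minimum mapped reads, a 21-nt peak
standing above its neighbors, and a minimum normalized 21-nt percentage —
is declared pipeline policy, configurable and recorded in the rationale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

SIZE_MIN = 18
SIZE_MAX = 31
OVERFLOW = "other"


@dataclass
class SizeProfile:
    """Read-length histogram (18-31 nt plus an overflow bin) for one contig."""
    contig_id: str
    counts_sense: dict = field(default_factory=dict)
    counts_antisense: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.counts_sense, self.counts_antisense):
            for k in list(range(SIZE_MIN, SIZE_MAX + 1)) + [OVERFLOW]:
                d.setdefault(k, 0)

    def counts(self, length) -> int:
        return self.counts_sense[length] + self.counts_antisense[length]

    @property
    def total_18_31(self) -> int:
        return sum(self.counts(k) for k in range(SIZE_MIN, SIZE_MAX + 1))

    @property
    def no_data(self) -> bool:
        return self.total_18_31 == 0

    @property
    def norm21(self) -> float | None:
        """21-nt reads as percent of 18-31 nt reads; None when no data."""
        total = self.total_18_31
        if total == 0:
            return None
        return 100.0 * self.counts(21) / total


@dataclass
class SirnaCall:
    contig_id: str
    is_enriched: bool
    checks: dict  # each named comparison with its operands and outcome


def size_profile(alignments) -> dict[str, SizeProfile]:
    """Build per-contig size histograms from read alignments.

    Each alignment contributes its read length to the contig and strand of
    that placement; lengths outside 18-31 land in the overflow bin.
    """
    sense: dict[str, Counter] = {}
    anti: dict[str, Counter] = {}
    for a in alignments:
        length = a.end - a.start
        key = length if SIZE_MIN <= length <= SIZE_MAX else OVERFLOW
        bucket = sense if a.strand == "sense" else anti
        bucket.setdefault(a.contig_id, Counter())[key] += 1
    profiles = {}
    for cid in sorted(set(sense) | set(anti)):
        profiles[cid] = SizeProfile(
            cid,
            counts_sense=dict(sense.get(cid, Counter())),
            counts_antisense=dict(anti.get(cid, Counter())))
    return profiles


def call_sirna_enrichment(profile: SizeProfile, min_reads: int = 50,
                          min_norm21: float = 20.0,
                          peak_ratio: float = 2.0) -> SirnaCall:
    """TRUE iff the profile has enough reads, a dominant 21-nt peak, and a
    high enough normalized 21-nt percentage.

    The min_reads gate keeps sparse profiles (a handful of mapped reads)
    from producing weak positive calls.
    """
    total = profile.total_18_31
    c21 = profile.counts(21)
    neighbor = max(profile.counts(20), profile.counts(22))
    norm21 = profile.norm21
    checks = {
        "min_reads": {"total_18_31": total, "threshold": min_reads,
                      "passed": total >= min_reads},
        "peak_ratio": {"counts_21": c21, "max_neighbor": neighbor,
                       "threshold": peak_ratio,
                       "passed": c21 >= peak_ratio * neighbor},
        "min_norm21": {"norm21": norm21, "threshold": min_norm21,
                       "passed": norm21 is not None and norm21 >= min_norm21},
    }
    return SirnaCall(profile.contig_id,
                     all(c["passed"] for c in checks.values()), checks)


def profiles_to_frame(profiles: dict[str, SizeProfile],
                      calls: dict[str, SirnaCall] | None = None) -> pd.DataFrame:
    """Flatten profiles (and optional calls) into a TSV-ready table."""
    rows = []
    for cid, p in profiles.items():
        row = {"contig_id": cid}
        for k in range(SIZE_MIN, SIZE_MAX + 1):
            row[f"n{k}_sense"] = p.counts_sense[k]
            row[f"n{k}_antisense"] = p.counts_antisense[k]
        row["n_other"] = p.counts(OVERFLOW)
        row["total_18_31"] = p.total_18_31
        row["norm21"] = p.norm21 if p.norm21 is not None else float("nan")
        row["no_data"] = p.no_data
        if calls and cid in calls:
            row["sirna_enriched"] = calls[cid].is_enriched
        rows.append(row)
    return pd.DataFrame(rows)
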