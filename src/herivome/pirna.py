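"""piRNA-pathway detection: the 24-31 nt size filter, positional nucleotide
frequencies, and the U1/A10 ping-pong bias test.

Primary piRNAs carry a 5' uridine bias; secondary (ping-pong) partners on
the opposite strand carry an adenine at position 10. Antisense U1 together
with sense A10 on a viral RNA is therefore the signature of Piwi-mediated
amplification. Each bias is tested with a one-sided exact binomial test
against a background base frequency (0.25 by default — the minimal null;
a contig-composition background can be supplied instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

BASES = "ACGU"  # U displayed for RNA; T is counted as U
MAX_POSITION = 24
DEFAULT_MIN_LEN = 24
DEFAULT_MAX_LEN = 31


@dataclass
class PositionalFrequencyMatrix:
    """Relative A/C/G/U frequencies at read positions 1-24 (5' -> 3').

    Reads shorter than 24 nt contribute only up to their own length, so
    each position is normalized over the reads that cover it.
    """
    strand: str | None
    n_reads: int
    counts: np.ndarray    # (4, 24) base counts per position
    coverage: np.ndarray  # (24,) reads covering each position

    @property
    def no_data(self) -> bool:
        return self.n_reads == 0

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.coverage

    def frequency(self, base: str, position: int) -> float:
        """freq[base][position], position 1-based from the read 5' end."""
        base = base.upper().replace("T", "U")
        return float(self.freq[BASES.index(base), position - 1])

    def base_count(self, base: str, position: int) -> tuple[int, int]:
        base = base.upper().replace("T", "U")
        return (int(self.counts[BASES.index(base), position - 1]),
                int(self.coverage[position - 1]))


@dataclass
class BiasCall:
    u1_freq: float | None
    a10_freq: float | None
    u1_p: float | None
    a10_p: float | None
    verdict: str  # none | u1_only | a10_only | ping_pong
    alpha: float


def filter_pirna_candidates(alignments, min_len: int = DEFAULT_MIN_LEN,
                            max_len: int = DEFAULT_MAX_LEN):
    """Keep alignments whose read length is in [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [a for a in alignments if min_len <= a.end - a.start <= max_len]


def positional_frequencies(seqs, strand: str | None = None,
                           max_position: int = MAX_POSITION) -> PositionalFrequencyMatrix:
    """Positional base composition of a read set (already strand-grouped).

    Zero reads yields an explicit no-data matrix rather than an error.
    """
    counts = np.zeros((4, max_position), dtype=np.int64)
    coverage = np.zeros(max_position, dtype=np.int64)
    lookup = {b: i for i, b in enumerate("ACGT")}
    n = 0
    for seq in seqs:
        n += 1
        s = seq.upper().replace("U", "T")
        for pos, base in enumerate(s[:max_position]):
            coverage[pos] += 1
            if base in lookup:
                counts[lookup[base], pos] += 1
    return PositionalFrequencyMatrix(strand, n, counts, coverage)


def candidate_reads_by_strand(candidates, reads: dict[str, str]) -> dict[str, list[str]]:
    """Group candidate-alignment read sequences by their mapping strand."""
    groups: dict[str, list[str]] = {"sense": [], "antisense": []}
    for a in candidates:
        groups[a.strand].append(reads[a.read_id])
    return groups


def call_bias(antisense: PositionalFrequencyMatrix | None,
              sense: PositionalFrequencyMatrix | None,
              background: float = 0.25, alpha: float = 0.001,
              n_tests: int = 1) -> BiasCall:
    """One-sided exact binomial tests of antisense U1 and sense A10
    enrichment over ``background``; Bonferroni-corrected when several
    contigs are tested (``n_tests``).

    verdict ``ping_pong`` requires both biases significant.
    """
    alpha_eff = alpha / max(n_tests, 1)

    def one_test(matrix, base, position):
        if matrix is None or matrix.no_data:
            return None, None
        k, n = matrix.base_count(base, position)
        if n == 0:
            return None, None
        p = binomtest(k, n, background, alternative="greater").pvalue
        return k / n, float(p)

    u1_freq, u1_p = one_test(antisense, "U", 1)
    a10_freq, a10_p = one_test(sense, "A", 10)
    u1_sig = u1_p is not None and u1_p <= alpha_eff
    a10_sig = a10_p is not None and a10_p <= alpha_eff
    if u1_sig and a10_sig:
        verdict = "ping_pong"
    elif u1_sig:
        verdict = "u1_only"
    elif a10_sig:
        verdict = "a10_only"
    else:
        verdict = "none"
    return BiasCall(u1_freq, a10_freq, u1_p, a10_p, verdict, alpha_eff)
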