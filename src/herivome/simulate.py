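"""Synthetic data generator for the inherited-virome pipeline.

Everything downstream consumes (virus genome segments, EVE copies,
small-RNA libraries with siRNA/piRNA structure, codiverging host/virus
loci) can be produced here from a single seeded :class:`SimulationConfig`.

The generative assumptions mirror the signatures the analysis modules are
built to detect:

* virus-derived siRNAs are exact 21-mers sampled from both strands;
* piRNAs are 24-31 nt with an antisense 5' U bias and a sense position-10
  A bias (the ping-pong signature), modeled as categorical resampling of
  the biased position so the configured probability equals the marginal
  base frequency;
* an EVE is a substitution-diverged copy of a viral segment containing a
  tandem partial gene duplication and short perfectly conserved motifs;
* host COI and virus loci diverge on the same population tree under a
  strict clock, with an optional rate multiplier for the virus locus.

All sequences are DNA-alphabet (U stored as T).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import mutate, random_sequence, revcomp

SIRNA_LENGTH = 21
PIRNA_RANGE = (24, 31)


def _default_pirna_weights() -> dict[int, float]:
    # unimodal over 24-31 nt, peaking near 27 as in EVE-derived piRNA profiles
    return {24: 0.08, 25: 0.14, 26: 0.17, 27: 0.18,
            28: 0.17, 29: 0.12, 30: 0.09, 31: 0.05}


def _default_split_times() -> dict[tuple[str, str], float]:
    """Nested splits (My) for five isolated populations; the deepest split is
    Mid-Pleistocene (0.8 My) and the pop1/pop2 split matches the continental
    COI anchor (2 x 0.407 x 3.54%/My ~= 2.88% divergence)."""
    t = {("pop1", "pop2"): 0.407}
    for p in ("pop1", "pop2"):
        t[(p, "pop3")] = 0.55
    for p in ("pop1", "pop2", "pop3"):
        t[(p, "pop4")] = 0.65
    for p in ("pop1", "pop2", "pop3", "pop4"):
        t[(p, "pop5")] = 0.8
    return t


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the pipeline's
    reference scenario (trisegmented negative-sense virus, siRNA-dominated
    germline library, 22%-diverged EVE, five isolated host populations)."""

    seed: int = 0
    # genome
    genome_length: int = 2000          # nt per segment
    n_segments: int = 3                # trisegmented phasmavirid-like genome
    # small RNA library
    sirna_fraction_21: float = 0.6     # fraction of reads in the 21-nt siRNA class
    pirna_length_weights: dict[int, float] = field(default_factory=_default_pirna_weights)
    u1_prob: float = 0.8               # antisense piRNA 5' U probability
    a10_prob: float = 0.8              # sense piRNA position-10 A probability
    strand_balance: float = 0.5        # probability a read is antisense-derived
    reads_per_contig: int = 10000
    # EVE
    eve_divergence: float = 0.22       # substitutions/site outside conserved motifs
    eve_duplication: tuple[int, int] | None = (1200, 1700)  # tandem-duplicated interval
    conserved_motifs: list[tuple[int, int]] = field(
        default_factory=lambda: [(100, 31), (500, 35), (900, 39)])  # (start, length)
    # codivergence
    n_populations: int = 5
    clock_rate: float = 0.0354         # divergence proportion per My (insect COI clock)
    split_times: dict[tuple[str, str], float] = field(default_factory=_default_split_times)
    n_per_population: int = 1
    host_locus_length: int = 730       # COI barcode amplicon scale
    virus_locus_length: int = 950      # virus segment amplicon scale
    virus_rate_multiplier: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {"sirna_fraction_21": self.sirna_fraction_21, "u1_prob": self.u1_prob,
                 "a10_prob": self.a10_prob, "strand_balance": self.strand_balance}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.pirna_length_weights:
            if not all(PIRNA_RANGE[0] <= k <= PIRNA_RANGE[1]
                       for k in self.pirna_length_weights):
                raise ValueError("pirna_length_weights keys must lie in 24-31")
            total = sum(self.pirna_length_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"pirna_length_weights sum to {total}, not 1")
            if any(w < 0 for w in self.pirna_length_weights.values()):
                raise ValueError("pirna_length_weights must be nonnegative")
        if not 0.0 <= self.eve_divergence <= 0.75:
            raise ValueError(f"eve_divergence={self.eve_divergence} outside [0, 0.75]")
        if self.eve_duplication is not None:
            d0, d1 = self.eve_duplication
            if not 0 <= d0 < d1:
                raise ValueError(f"invalid duplication interval {self.eve_duplication}")
            for start, length in self.conserved_motifs:
                if start < d1 and d0 < start + length:
                    raise ValueError(
                        f"conserved motif ({start},{length}) overlaps the "
                        f"duplication interval {self.eve_duplication}")
        for start, length in self.conserved_motifs:
            if start < 0 or length <= 0:
                raise ValueError(f"invalid motif ({start},{length})")
        if self.n_populations < 2:
            raise ValueError("need at least two populations")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic generator per (seed, stream)."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class EveTruth:
    """Ground truth for a simulated EVE, in both coordinate systems."""
    motifs_virus: list[tuple[int, int]]       # (start, end) half-open, virus coords
    motifs_eve: list[tuple[int, int]]         # same motifs in EVE coords
    duplication_virus: tuple[int, int] | None # source interval, virus coords
    duplication_eve: tuple[int, int] | None   # inserted copy, EVE coords
    substituted_sites: np.ndarray             # virus coords of substituted sites


@dataclass
class CodivergenceTruth:
    populations: list[str]
    tree_newick: str
    host_alignment: dict[str, str]
    virus_alignment: dict[str, str]
    virus_tree_newick: str


def simulate_virus_genome(config: SimulationConfig) -> dict[str, str]:
    """Uniform-random nucleotide contigs, one per genome segment."""
    if config.genome_length < 200:
        raise ValueError(f"genome_length must be >= 200, got {config.genome_length}")
    if config.n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = config.rng(stream=1)
    return {f"virus_seg{i + 1}": random_sequence(config.genome_length, rng)
            for i in range(config.n_segments)}


def simulate_eve(virus_contig: str, config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> tuple[str, EveTruth]:
    """Diverged EVE copy of a viral segment.

    Substitutions fall outside the conserved motifs; the duplication
    interval (if any) is inserted in tandem after its source copy.
    """
    rng = config.rng(stream=2) if rng is None else rng
    L = len(virus_contig)
    motifs = [(s, s + ln) for s, ln in config.conserved_motifs]
    for s, e in motifs:
        if e > L:
            raise ValueError(f"motif ({s},{e}) outside contig of length {L}")
    dup = config.eve_duplication
    if dup is not None and dup[1] > L:
        raise ValueError(f"duplication {dup} outside contig of length {L}")

    mutated = mutate(virus_contig, config.eve_divergence, rng, protected=motifs)
    substituted = np.flatnonzero(
        np.frombuffer(mutated.encode(), np.uint8)
        != np.frombuffer(virus_contig.encode(), np.uint8))

    if dup is None:
        eve = mutated
        dup_eve = None
        motifs_eve = list(motifs)
    else:
        d0, d1 = dup
        eve = mutated[:d1] + mutated[d0:d1] + mutated[d1:]
        shift = d1 - d0
        dup_eve = (d1, d1 + shift)  # the inserted tandem copy
        motifs_eve = [(s, e) if e <= d1 else (s + shift, e + shift) for s, e in motifs]
    return eve, EveTruth(motifs, motifs_eve, dup, dup_eve, substituted)


def eve_identity_truth(virus_contig: str, eve_contig: str,
                       truth: EveTruth) -> tuple[float, list[tuple[int, int, int]]]:
    """Independent position-wise census of the generated pair.

    Removes the inserted duplication copy from the EVE, compares site by
    site, and returns (identity percent, maximal identity runs as
    (virus_start, virus_end, length)). Used as the oracle for align_pair.
    """
    if truth.duplication_eve is not None:
        d0, d1 = truth.duplication_eve
        collapsed = eve_contig[:d0] + eve_contig[d1:]
    else:
        collapsed = eve_contig
    if len(collapsed) != len(virus_contig):
        raise ValueError("collapsed EVE and virus lengths differ")
    same = np.frombuffer(collapsed.encode(), np.uint8) == \
        np.frombuffer(virus_contig.encode(), np.uint8)
    identity = 100.0 * same.mean()
    runs: list[tuple[int, int, int]] = []
    start = None
    for i, ok in enumerate(same):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i, i - start))
            start = None
    if start is not None:
        runs.append((start, len(same), len(same) - start))
    return identity, runs


def simulate_small_rna_library(
        contigs: dict[str, str], config: SimulationConfig,
        rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Seeded small-RNA library plus its truth table.

    Truth table columns: read_id, contig_id, strand, cls (siRNA|piRNA),
    start (0-based on the contig), length. One row per emitted read.
    """
    if not contigs:
        raise ValueError("empty contig set")
    if config.reads_per_contig < 1:
        raise ValueError("reads_per_contig must be >= 1")
    rng = config.rng(stream=3) if rng is None else rng
    if config.sirna_fraction_21 < 1.0 and not config.pirna_length_weights:
        raise ValueError("piRNA reads requested but pirna_length_weights is empty")

    lengths_avail = sorted(config.pirna_length_weights) if config.pirna_length_weights else []
    weights = np.array([config.pirna_length_weights[k] for k in lengths_avail]) \
        if lengths_avail else None

    reads: list[tuple[str, str]] = []
    rows = []
    for contig_id, seq in contigs.items():
        n = config.reads_per_contig
        is_sirna = rng.random(n) < config.sirna_fraction_21
        lens = np.full(n, SIRNA_LENGTH)
        if weights is not None and (~is_sirna).any():
            lens[~is_sirna] = rng.choice(lengths_avail, size=int((~is_sirna).sum()),
                                         p=weights)
        if lens.max() > len(seq):
            raise ValueError("contig shorter than the longest read length")
        starts = (rng.random(n) * (len(seq) - lens + 1)).astype(int)
        antisense = rng.random(n) < config.strand_balance
        u1_hits = rng.random(n) < config.u1_prob
        a10_hits = rng.random(n) < config.a10_prob
        picks = rng.integers(0, 3, size=n)
        for i in range(n):
            s, L = int(starts[i]), int(lens[i])
            window = seq[s:s + L]
            read = revcomp(window) if antisense[i] else window
            if not is_sirna[i]:
                # ping-pong signature: categorical resampling of the biased
                # position so u1_prob/a10_prob are the marginal frequencies
                if antisense[i]:
                    new = "T" if u1_hits[i] else "ACG"[picks[i]]
                    read = new + read[1:]
                else:
                    new = "A" if a10_hits[i] else "CGT"[picks[i]]
                    read = read[:9] + new + read[10:]
            read_id = f"{contig_id}_r{i:06d}"
            reads.append((read_id, read))
            rows.append((read_id, contig_id,
                         "antisense" if antisense[i] else "sense",
                         "siRNA" if is_sirna[i] else "piRNA", s, L))
    truth = pd.DataFrame(rows, columns=["read_id", "contig_id", "strand",
                                        "cls", "start", "length"])
    return reads, truth


# ---------------------------------------------------------------------------
# codiverging host/virus loci


def _build_ultrametric_tree(populations: list[str],
                            split_times: dict[tuple[str, str], float]):
    """Agglomerate populations by increasing split time.

    Returns a nested (children, height_My) tuple tree. Raises ValueError if
    the split times are not ultrametrically consistent.
    """
    def t(a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in split_times:
                return split_times[key]
        raise ValueError(f"missing split time for pair ({a}, {b})")

    clusters: list[tuple[list[str], object]] = [([p], (p, 0.0)) for p in populations]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                times = {t(a, b) for a in clusters[i][0] for b in clusters[j][0]}
                if len(times) > 1:
                    raise ValueError(
                        "inconsistent split_times: members of the same clusters "
                        f"disagree ({sorted(times)})")
                tij = times.pop()
                if best is None or tij < best[0]:
                    best = (tij, i, j)
        tij, i, j = best
        merged = (clusters[i][0] + clusters[j][0],
                  ((clusters[i][1], clusters[j][1]), tij))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return clusters[0][1]


def _tree_to_newick(node) -> str:
    def render(n, parent_height: float) -> str:
        payload, height = n
        bl = parent_height - height
        if isinstance(payload, str):
            return f"{payload}:{bl:.6f}"
        left, right = payload
        return f"({render(left, height)},{render(right, height)}):{bl:.6f}"

    payload, height = node
    if isinstance(payload, str):
        return f"{payload}:0.0;"
    left, right = payload
    return f"({render(left, height)},{render(right, height)});"


def _evolve(node, root_seq: str, rate_per_my: float,
            rng: np.random.Generator) -> dict[str, str]:
    """Independent-sites substitution along the tree; branch lengths in My."""
    out: dict[str, str] = {}

    def walk(n, seq: str, parent_height: float) -> None:
        payload, height = n
        p_sub = rate_per_my * (parent_height - height)
        if p_sub > 0.75:
            raise ValueError("branch substitution probability exceeds 0.75; "
                             "reduce rate or split times")
        child_seq = mutate(seq, p_sub, rng) if p_sub > 0 else seq
        if isinstance(payload, str):
            out[payload] = child_seq
        else:
            for sub in payload:
                walk(sub, child_seq, height)

    payload, height = node
    if isinstance(payload, str):
        out[payload] = root_seq
    else:
        for sub in payload:
            walk(sub, root_seq, height)
    return out


def random_split_times(populations: list[str], depth_my: float,
                       rng: np.random.Generator) -> dict[tuple[str, str], float]:
    """Random ultrametric split times over the given populations (used to
    simulate a virus tree independent of the host tree)."""
    clusters = [[p] for p in populations]
    heights = np.sort(rng.uniform(0.05 * depth_my, depth_my, size=len(populations) - 1))
    times: dict[tuple[str, str], float] = {}
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                times[(a, b)] = float(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return times


def simulate_codiverging_loci(
        config: SimulationConfig, rng: np.random.Generator | None = None,
        virus_split_times: dict[tuple[str, str], float] | None = None,
) -> CodivergenceTruth:
    """Host COI and virus loci evolved on the same population tree.

    Expected pairwise host p-distance between populations split t My ago is
    ~ 2 * clock_rate * t (uncorrected, small-divergence regime). Passing
    ``virus_split_times`` decouples the virus tree (independent-evolution
    null); by default the virus shares the host topology and times, with
    its own clock multiplier.
    """
    rng = config.rng(stream=4) if rng is None else rng
    pops = [f"pop{i + 1}" for i in range(config.n_populations)]
    host_tree = _build_ultrametric_tree(pops, config.split_times)
    vtimes = virus_split_times if virus_split_times is not None else config.split_times
    virus_tree = _build_ultrametric_tree(pops, vtimes)

    host_root = random_sequence(config.host_locus_length, rng)
    virus_root = random_sequence(config.virus_locus_length, rng)
    host_by_pop = _evolve(host_tree, host_root, config.clock_rate, rng)
    virus_by_pop = _evolve(virus_tree, virus_root,
                           config.clock_rate * config.virus_rate_multiplier, rng)

    def expand(by_pop: dict[str, str]) -> dict[str, str]:
        if config.n_per_population == 1:
            return {p: by_pop[p] for p in pops}
        return {f"{p}_i{k + 1}": by_pop[p] for p in pops
                for k in range(config.n_per_population)}

    return CodivergenceTruth(
        populations=pops,
        tree_newick=_tree_to_newick(host_tree),
        host_alignment=expand(host_by_pop),
        virus_alignment=expand(virus_by_pop),
        virus_tree_newick=_tree_to_newick(virus_tree),
    )
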