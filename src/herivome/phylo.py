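"""Distance-based phylogeography: uncorrected p-distances, neighbor-joining
trees, host-virus congruence, molecular-clock dating, and prevalence
arithmetic.

The dating model is deliberately simple: an uncorrected pairwise
divergence d between two isolated populations and a strict clock rate r
(proportion of divergence per million years) give
TMRCA = d / r x 10^6 years, reported rounded to the nearest 100,000 years.
Congruence between host and virus trees is measured two ways: the
Robinson-Foulds distance between the unrooted topologies, and the Pearson
correlation of the two pairwise-distance matrices against a
taxa-permutation null.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import binomtest

GAP_CHARS = set("-.nN")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of uncorrected pairwise p-distances."""
    taxa: list[str]
    values: np.ndarray  # NaN marks pairs with no comparable columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.taxa), dtype=bool)
        return bool(np.isnan(self.values[off]).any())


@dataclass
class ClockEstimate:
    divergence: float
    rate: float           # proportion per million years
    tmrca_years: float
    tmrca_rounded: int    # nearest 100,000 years


@dataclass
class CongruenceResult:
    rf: int
    normalized_rf: float
    correlation: float
    p_value: float
    n_permutations: int


@dataclass
class PrevalenceResult:
    overall_pct: float               # one decimal
    n_screened: int
    n_positive: int
    per_population: pd.DataFrame     # population, n, k, pct, ci_low_pct, ci_high_pct


def p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise proportion of mismatches over mutually non-gap, non-N columns.

    Requires an aligned (equal-length) set of at least two sequences. A
    pair with no comparable columns gets NaN.
    """
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned (lengths {sorted(lengths)})")
    arrs = {t: np.frombuffer(alignment[t].upper().encode(), np.uint8)
            for t in taxa}
    bad = {ord(c) for c in GAP_CHARS}

    def comparable(a: np.ndarray) -> np.ndarray:
        mask = np.ones(a.size, dtype=bool)
        for code in bad:
            mask &= a != code
        return mask

    ok = {t: comparable(arrs[t]) for t in taxa}
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[taxa[i]] & ok[taxa[j]]
            total = int(both.sum())
            if total == 0:
                d = np.nan
            else:
                d = float((arrs[taxa[i]][both] != arrs[taxa[j]][both]).sum()) / total
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa, values)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick) from a complete distance matrix.

    Taxa are sorted lexicographically first so tie-breaking is
    deterministic. Agglomeration is delegated to scikit-bio's ``nj``.
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if dm.has_missing:
        raise ValueError("distance matrix has missing entries")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    order = sorted(range(len(dm.taxa)), key=lambda i: dm.taxa[i])
    taxa = [dm.taxa[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    tree = nj(SkbioDM(values, ids=taxa))
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def _load_tree_pair(host_newick: str, virus_newick: str):
    tns = dendropy.TaxonNamespace()
    host = dendropy.Tree.get(data=host_newick, schema="newick",
                             taxon_namespace=tns)
    virus = dendropy.Tree.get(data=virus_newick, schema="newick",
                              taxon_namespace=tns)
    host_leaves = {leaf.taxon.label for leaf in host.leaf_node_iter()}
    virus_leaves = {leaf.taxon.label for leaf in virus.leaf_node_iter()}
    if host_leaves != virus_leaves:
        raise ValueError(
            f"leaf sets differ: {sorted(host_leaves ^ virus_leaves)}")
    for t in (host, virus):
        t.is_rooted = False
        t.encode_bipartitions()
    return host, virus, sorted(host_leaves)


def _patristic_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tree.taxon_namespace
              if t.label in set(taxa)}
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
            out[i, j] = out[j, i] = d
    return out


def congruence(host_newick: str, virus_newick: str,
               host_dm: DistanceMatrix | None = None,
               virus_dm: DistanceMatrix | None = None,
               n_permutations: int = 9999,
               seed: int = 0) -> CongruenceResult:
    """Topological and distance-based congruence of host and virus trees.

    RF is computed on unrooted topologies and normalized by 2(n-3), the
    maximum for binary trees. The matrix correlation uses the supplied
    sequence distance matrices when given, else patristic distances from
    the trees; its p-value comes from ``n_permutations`` random taxa
    relabelings of the virus matrix (add-one permutation p).
    """
    host, virus, taxa = _load_tree_pair(host_newick, virus_newick)
    rf = int(dendropy.calculate.treecompare.symmetric_difference(host, virus))
    n = len(taxa)
    max_rf = 2 * (n - 3)
    normalized = rf / max_rf if max_rf > 0 else 0.0

    h = host_dm.values[np.ix_([host_dm.taxa.index(t) for t in taxa],
                              [host_dm.taxa.index(t) for t in taxa])] \
        if host_dm is not None else _patristic_matrix(host, taxa)
    v = virus_dm.values[np.ix_([virus_dm.taxa.index(t) for t in taxa],
                               [virus_dm.taxa.index(t) for t in taxa])] \
        if virus_dm is not None else _patristic_matrix(virus, taxa)

    iu = np.triu_indices(n, k=1)
    hvec = h[iu]

    def corr(mat: np.ndarray) -> float:
        vec = mat[iu]
        if hvec.std() == 0 or vec.std() == 0:
            return 0.0
        return float(np.corrcoef(hvec, vec)[0, 1])

    r_obs = corr(v)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(v[np.ix_(perm, perm)]) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return CongruenceResult(rf, normalized, r_obs, p, n_permutations)


def clock_date(divergence: float, rate: float) -> ClockEstimate:
    """Strict-clock TMRCA from uncorrected divergence and a %/My clock rate."""
    if rate <= 0:
        raise ValueError(f"clock rate must be positive, got {rate}")
    if divergence < 0:
        raise ValueError(f"divergence must be nonnegative, got {divergence}")
    tmrca = divergence / rate * 1e6
    rounded = int(round(tmrca / 1e5) * 1e5)
    return ClockEstimate(divergence, rate, tmrca, rounded)


def prevalence(table: pd.DataFrame, confidence: float = 0.95) -> PrevalenceResult:
    """Overall and per-population infection frequency with exact
    (Clopper-Pearson) binomial confidence intervals, in percent."""
    required = {"population", "n_screened", "n_positive"}
    if not required <= set(table.columns):
        raise ValueError(f"screening table must have columns {sorted(required)}")
    if (table.n_screened <= 0).any():
        raise ValueError("every population must have n_screened > 0")
    if ((table.n_positive < 0) | (table.n_positive > table.n_screened)).any():
        raise ValueError("n_positive must satisfy 0 <= n_positive <= n_screened")

    rows = []
    for row in table.itertuples():
        n, k = int(row.n_screened), int(row.n_positive)
        ci = binomtest(k, n).proportion_ci(confidence_level=confidence,
                                           method="exact")
        rows.append({"population": row.population, "n_screened": n,
                     "n_positive": k, "pct": round(100.0 * k / n, 1),
                     "ci_low_pct": round(100.0 * ci.low, 1),
                     "ci_high_pct": round(100.0 * ci.high, 1)})
    total_n = int(table.n_screened.sum())
    total_k = int(table.n_positive.sum())
    return PrevalenceResult(round(100.0 * total_k / total_n, 1),
                            total_n, total_k, pd.DataFrame(rows))
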