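"""Peptide clustering and competitive enrichment.

Enrichment compares a peptide's frequency between the competitor and
non-competitor pannings:

    E = ln(beta / alpha),   alpha = freq(non-competitor), beta = freq(competitor)

so E < 0 means the competitor depleted the peptide — the signature of
binding at the canonical interface.  Because strong binders often have
zero competitor counts, E is estimated per cluster of Hamming-similar
peptides: counts are summed over cluster members (with a small
pseudocount so a zero competitor sum stays finite) and every member
inherits the cluster value.

Clustering is an in-house DBSCAN over the Hamming metric with eps = 1 and
min_pts = 2, which makes the partition exactly the connected components of
the Hamming-1 graph; unclustered peptides become singletons.  Neighbors at
eps = 1 are found by enumerating single-position substitutions against a
hash of the peptide set, so clustering is linear in the number of
peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .reads import AA_ALPHABET, CountTable

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class SamplePair:
    """Matched non-competitor / competitor tables for one protein scope."""

    noncomp: CountTable
    comp: CountTable

    def __post_init__(self):
        if self.noncomp.protein != self.comp.protein:
            raise ValueError(
                f"protein mismatch: {self.noncomp.protein!r} vs {self.comp.protein!r}"
            )

    @property
    def peptides(self) -> list[str]:
        return sorted(set(self.noncomp.counts) | set(self.comp.counts))


@dataclass
class PeptideCluster:
    id: int
    members: frozenset[str]
    e_cluster: float | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if len({len(m) for m in self.members}) != 1:
            raise ValueError("cluster members must share one length")


# ---------------------------------------------------------------------------
# Pooling and distance
# ---------------------------------------------------------------------------

def pool_replicates(tables: list[CountTable]) -> CountTable:
    """Sum counts over biological replicates of one protein/condition.

    Pooling happens at the count level (equivalent to concatenating the
    sequencing runs); frequencies are computed afterwards.
    """
    if not tables:
        raise ValueError("no tables to pool")
    first = tables[0]
    for t in tables[1:]:
        if (t.protein, t.condition) != (first.protein, first.condition):
            raise ValueError(
                f"cannot pool mixed samples: ({t.protein!r}, {t.condition!r}) vs "
                f"({first.protein!r}, {first.condition!r})"
            )
    counts: dict[str, int] = {}
    for t in tables:
        for pep, c in t.counts.items():
            counts[pep] = counts.get(pep, 0) + c
    rejects: dict[str, int] = {}
    for t in tables:
        for reason, k in t.rejects.items():
            rejects[reason] = rejects.get(reason, 0) + k
    return CountTable(
        counts=counts,
        total_reads_in=sum(t.total_reads_in for t in tables),
        total_reads_passed=sum(t.total_reads_passed for t in tables),
        protein=first.protein,
        condition=first.condition,
        replicate="pooled",
        rejects=rejects,
    )


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# DBSCAN over the Hamming metric
# ---------------------------------------------------------------------------

class HammingDBSCAN(ClusterMixin, BaseEstimator):
    """DBSCAN on equal-length sequences under the Hamming metric.

    Parameters follow the usual DBSCAN meaning; ``min_samples`` counts the
    point itself.  With the defaults (eps=1, min_samples=2) the clustering
    equals the connected components of the Hamming-1 graph.  Points are
    processed in lexicographic order so border-point assignment is
    deterministic.  Noise points are returned as singleton clusters rather
    than a noise label, because downstream enrichment treats every peptide
    as belonging to some cluster.

    Attributes after ``fit``: ``labels_`` (cluster id per input sequence)
    and ``clusters_`` (list of member sets indexed by cluster id).
    """

    def __init__(self, eps: int = 1, min_samples: int = 2, alphabet: str = AA_ALPHABET):
        self.eps = eps
        self.min_samples = min_samples
        self.alphabet = alphabet

    def _neighbors_fast(self, ordered: list[str], index: dict[str, int]) -> list[list[int]]:
        neighbors: list[list[int]] = []
        for pep in ordered:
            hits = []
            for pos, current in enumerate(pep):
                prefix, suffix = pep[:pos], pep[pos + 1:]
                for sub in self.alphabet:
                    if sub == current:
                        continue
                    j = index.get(prefix + sub + suffix)
                    if j is not None:
                        hits.append(j)
            neighbors.append(sorted(hits))
        return neighbors

    def _neighbors_generic(self, ordered: list[str]) -> list[list[int]]:
        n = len(ordered)
        neighbors: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if hamming_distance(ordered[i], ordered[j]) <= self.eps:
                    neighbors[i].append(j)
                    neighbors[j].append(i)
        return neighbors

    def fit(self, X, y=None):
        peptides = list(X)
        if len(set(peptides)) != len(peptides):
            raise ValueError("duplicate sequences in clustering input")
        if peptides and len({len(p) for p in peptides}) != 1:
            raise ValueError("all sequences must have equal length")
        if self.eps < 1:
            raise ValueError("eps must be >= 1")
        ordered = sorted(peptides)
        index = {p: i for i, p in enumerate(ordered)}
        if self.eps == 1:
            neighbors = self._neighbors_fast(ordered, index)
        else:
            neighbors = self._neighbors_generic(ordered)
        core = [len(nb) + 1 >= self.min_samples for nb in neighbors]
        labels = np.full(len(ordered), -1, dtype=int)
        next_label = 0
        for i in range(len(ordered)):
            if labels[i] != -1 or not core[i]:
                continue
            labels[i] = next_label
            frontier = [i]
            while frontier:
                p = frontier.pop()
                for q in neighbors[p]:
                    if labels[q] == -1:
                        labels[q] = next_label
                        if core[q]:
                            frontier.append(q)
            next_label += 1
        # noise points become singleton clusters, in lexicographic order
        for i in range(len(ordered)):
            if labels[i] == -1:
                labels[i] = next_label
                next_label += 1
        members: dict[int, set[str]] = {}
        for i, pep in enumerate(ordered):
            members.setdefault(int(labels[i]), set()).add(pep)
        self.clusters_ = [
            PeptideCluster(id=k, members=frozenset(members[k]))
            for k in range(next_label)
        ]
        back = {p: int(labels[i]) for i, p in enumerate(ordered)}
        self.labels_ = np.array([back[p] for p in peptides], dtype=int)
        return self


def cluster_peptides(
    peptides, eps: int = 1, min_pts: int = 2
) -> list[PeptideCluster]:
    """Partition peptides into Hamming-DBSCAN clusters (singletons for noise)."""
    model = HammingDBSCAN(eps=eps, min_samples=min_pts).fit(sorted(set(peptides)))
    return model.clusters_


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def cluster_enrichment(
    cluster: PeptideCluster,
    pair: SamplePair,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Log-ratio enrichment of a cluster's summed frequencies.

    ``E = ln((sum c_comp + q) / N_comp) - ln((sum c_noncomp + q) / N_noncomp)``
    with pseudocount ``q``; a cluster observed in neither sample is an
    error rather than E = 0.
    """
    n_comp = pair.comp.depth
    n_noncomp = pair.noncomp.depth
    if n_comp == 0 or n_noncomp == 0:
        raise ValueError("both samples must contain reads")
    sum_comp = sum(pair.comp.counts.get(p, 0) for p in cluster.members)
    sum_noncomp = sum(pair.noncomp.counts.get(p, 0) for p in cluster.members)
    if sum_comp == 0 and sum_noncomp == 0:
        raise ValueError(f"cluster {cluster.id} not observed in either sample")
    return float(
        np.log((sum_comp + pseudocount) / n_comp)
        - np.log((sum_noncomp + pseudocount) / n_noncomp)
    )


def assign_enrichment(
    clusters: list[PeptideCluster],
    pair: SamplePair,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-peptide enrichment table; members inherit their cluster's E.

    Returns a DataFrame with columns ``peptide``, ``cluster``,
    ``cluster_size`` and ``E`` covering the union peptide set.
    """
    rows = []
    for cl in clusters:
        e = cluster_enrichment(cl, pair, pseudocount)
        for pep in sorted(cl.members):
            rows.append((pep, cl.id, len(cl.members), e))
    table = pd.DataFrame(rows, columns=["peptide", "cluster", "cluster_size", "E"])
    return table.sort_values("peptide", ignore_index=True)


def enrich_pair(
    pair: SamplePair,
    eps: int = 1,
    min_pts: int = 2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Cluster the union peptide set of a sample pair and assign E."""
    clusters = cluster_peptides(pair.peptides, eps=eps, min_pts=min_pts)
    return assign_enrichment(clusters, pair, pseudocount)


def direct_enrichment(
    pair: SamplePair, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-peptide E from each peptide's own counts (no clustering)."""
    rows = []
    n_c, n_nc = pair.comp.depth, pair.noncomp.depth
    for pep in pair.peptides:
        c = pair.comp.counts.get(pep, 0)
        nc = pair.noncomp.counts.get(pep, 0)
        e = np.log((c + pseudocount) / n_c) - np.log((nc + pseudocount) / n_nc)
        rows.append((pep, c, nc, float(e)))
    return pd.DataFrame(rows, columns=["peptide", "count_comp", "count_noncomp", "E_direct"])


def compare_cluster_vs_direct(
    pair: SamplePair,
    table: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict:
    """OLS of per-peptide direct E on cluster-assigned E.

    Restricted to peptides observed in both samples, where the direct
    ratio is well defined.  Returns slope, intercept, r2 and n.
    """
    direct = direct_enrichment(pair, pseudocount)
    both = direct[(direct["count_comp"] > 0) & (direct["count_noncomp"] > 0)]
    merged = both.merge(table[["peptide", "E"]], on="peptide")
    if len(merged) < 3:
        raise ValueError("need at least 3 peptides observed in both samples")
    x = merged["E"].to_numpy()
    y = merged["E_direct"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: enrichment values are constant")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "n": int(len(merged)),
    }


def odr_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal-distance (total least squares) line through a 2-D cloud.

    The slope is the first principal axis of the centered points, so axis
    exchange maps slope -> 1/slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValueError("principal axis is vertical; slope undefined")
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def compare_replicates(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    region_cutoff: float = -1.5,
) -> dict:
    """Replicate agreement inside and outside the responsive region.

    Peptides with E <= cutoff in both replicates form the responsive
    region, fitted with an orthogonal-distance line and summarized by the
    squared Pearson correlation; the complementary common peptides get a
    correlation only.  Mirrors the replicate scatter used to argue that
    only the responsive distribution is reproducible.
    """
    merged = rep1[["peptide", "E"]].merge(
        rep2[["peptide", "E"]], on="peptide", suffixes=("_1", "_2")
    )
    in_region = merged[
        (merged["E_1"] <= region_cutoff) & (merged["E_2"] <= region_cutoff)
    ]
    if len(in_region) < 3:
        raise ValueError("fewer than 3 common peptides in the responsive region")
    x, y = in_region["E_1"].to_numpy(), in_region["E_2"].to_numpy()
    slope, intercept = odr_line(x, y)
    r_region = stats.pearsonr(x, y).statistic
    rest = merged.drop(in_region.index)
    if len(rest) >= 3 and rest["E_1"].std() > 0 and rest["E_2"].std() > 0:
        r_rest = stats.pearsonr(rest["E_1"], rest["E_2"]).statistic
    else:
        r_rest = float("nan")
    return {
        "slope": slope,
        "intercept": intercept,
        "r2_region": float(r_region**2),
        "n_region": int(len(in_region)),
        "r2_complement": float(r_rest**2),
        "n_complement": int(len(rest)),
    }
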