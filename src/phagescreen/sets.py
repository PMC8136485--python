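"""Set-level comparison of binder repertoires across proteins.

Given per-protein enrichment tables restricted to the common universe
(peptides with a measurable E for every protein), the module builds
binder sets at an E cutoff, computes three-way Venn overlaps, classifies
each modern protein's binders as

* ancestral  — shared with the reconstructed ancestor,
* convergent — shared with the other modern paralog but not the ancestor,
* divergent  — unique to that protein,

sweeps these quantities over a cutoff grid, and tests whether the excess
of divergent peptides at stringent cutoffs could arise from sampling
alone: a multinomial resampling envelope for visual comparison and an
exact binomial tail probability for the hypothesis test (the tail is
summed in log space, since the interesting p-values are far below what
Monte Carlo can resolve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

CATEGORIES = ("ancestral", "divergent", "convergent")
#: Window of moderate enrichment used to estimate baseline category proportions.
MODERATE_WINDOW = (-4.0, -1.5)


@dataclass
class BinderSets:
    """Per-protein binder sets at one cutoff over a shared universe."""

    sets: dict[str, set[str]]
    universe: set[str]
    cutoff: float

    def __post_init__(self):
        for name, s in self.sets.items():
            if not s <= self.universe:
                raise ValueError(f"set {name!r} is not within the common universe")

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}


def common_universe(tables: dict[str, pd.DataFrame]) -> set[str]:
    """Peptides with a measurable E for every protein."""
    if not tables:
        raise ValueError("no enrichment tables supplied")
    sets = [set(t["peptide"]) for t in tables.values()]
    universe = set.intersection(*sets)
    return universe


def binder_sets(
    tables: dict[str, pd.DataFrame],
    cutoff: float,
    universe: set[str] | None = None,
) -> BinderSets:
    """Per-protein sets {peptide : E <= cutoff} over the common universe."""
    if universe is None:
        universe = common_universe(tables)
    out = {}
    for protein, table in tables.items():
        mask = table["peptide"].isin(universe) & (table["E"] <= cutoff)
        out[protein] = set(table.loc[mask, "peptide"])
    return BinderSets(sets=out, universe=universe, cutoff=cutoff)


def venn3(a: set, b: set, c: set) -> dict[str, int]:
    """Exclusive 7-region counts for three sets.

    Keys are membership masks in (a, b, c) order, e.g. ``"110"`` counts
    elements in a and b but not c; the values sum to ``len(a | b | c)``.
    """
    regions = {}
    for mask in ("100", "010", "001", "110", "101", "011", "111"):
        ina, inb, inc = (m == "1" for m in mask)
        sel = set.intersection(
            *(s for s, flag in ((a, ina), (b, inb), (c, inc)) if flag)
        )
        for s, flag in ((a, ina), (b, inb), (c, inc)):
            if not flag:
                sel = sel - s
        regions[mask] = len(sel)
    return regions


def categorize(
    peptide: str,
    modern_set: set[str],
    other_modern_set: set[str],
    ancestor_set: set[str],
) -> str:
    """Evolutionary category of one binder of a modern protein."""
    if peptide not in modern_set:
        raise ValueError(f"{peptide!r} is not a binder of the modern protein")
    if peptide in ancestor_set:
        return "ancestral"
    if peptide in other_modern_set:
        return "convergent"
    return "divergent"


def category_counts(
    modern_set: set[str], other_modern_set: set[str], ancestor_set: set[str]
) -> dict[str, int]:
    counts = dict.fromkeys(CATEGORIES, 0)
    for pep in modern_set:
        counts[categorize(pep, modern_set, other_modern_set, ancestor_set)] += 1
    return counts


def cutoff_sweep(
    tables: dict[str, pd.DataFrame],
    grid,
    moderns: tuple[str, str] | None = None,
    ancestor: str | None = None,
) -> pd.DataFrame:
    """Set sizes and category counts at each cutoff of a grid.

    The grid is traversed from most to least stringent (ascending E);
    cumulative counts are non-decreasing because the sets are nested.
    """
    grid = sorted(float(g) for g in grid)
    universe = common_universe(tables)
    rows = []
    for cutoff in grid:
        bs = binder_sets(tables, cutoff, universe=universe)
        row: dict[str, float] = {"cutoff": cutoff}
        for protein, s in bs.sets.items():
            row[f"n_{protein}"] = len(s)
        if moderns and ancestor:
            other = {moderns[0]: moderns[1], moderns[1]: moderns[0]}
            for protein in moderns:
                counts = category_counts(
                    bs.sets[protein], bs.sets[other[protein]], bs.sets[ancestor]
                )
                for cat, k in counts.items():
                    row[f"{protein}_{cat}"] = k
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_proportions(
    table: pd.DataFrame,
    other_table: pd.DataFrame,
    ancestor_table: pd.DataFrame,
    window: tuple[float, float] = MODERATE_WINDOW,
    cutoff: float = -1.5,
) -> dict[str, float]:
    """Category proportions among moderately enriching binders.

    The modern protein's binders with E inside ``window`` are categorized
    against the other modern's and the ancestor's binder sets (both taken
    at ``cutoff``).
    """
    tables = {"m": table, "o": other_table, "a": ancestor_table}
    universe = common_universe(tables)
    bs = binder_sets(tables, cutoff, universe=universe)
    lo, hi = window
    in_window = set(
        table.loc[
            table["peptide"].isin(universe)
            & (table["E"] >= lo)
            & (table["E"] <= hi),
            "peptide",
        ]
    ) & bs.sets["m"]
    if not in_window:
        raise ValueError("no binders in the moderate-enrichment window")
    counts = dict.fromkeys(CATEGORIES, 0)
    for pep in in_window:
        counts[categorize(pep, bs.sets["m"], bs.sets["o"], bs.sets["a"])] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def resampling_envelope(
    proportions,
    totals_per_cutoff,
    n_sims: int = 10000,
    seed: int | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Percentile envelopes for category counts under constant proportions.

    At each cutoff the observed total is resampled as a multinomial over
    the three categories; the envelope is the central ``ci`` interval of
    each category's count.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size != len(CATEGORIES):
        raise ValueError(f"need {len(CATEGORIES)} proportions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    for total in totals_per_cutoff:
        draws = rng.multinomial(int(total), p, size=n_sims)
        row: dict[str, float] = {"total": int(total)}
        for j, cat in enumerate(CATEGORIES):
            row[f"{cat}_lo"] = float(np.percentile(draws[:, j], lo_q))
            row[f"{cat}_hi"] = float(np.percentile(draws[:, j], hi_q))
            row[f"{cat}_mean"] = float(draws[:, j].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def divergence_pvalue(n: int, k: int, p_div: float) -> float:
    """Exact binomial tail P(X >= k | n, p_div), summed in log space.

    The analytic tail is required because the observed excesses of
    divergent peptides correspond to probabilities (~1e-44) far below
    Monte-Carlo resolution.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 <= p_div <= 1:
        raise ValueError("p_div must be a probability")
    if k == 0:
        return 1.0
    if k == n:
        return float(p_div**n)
    ks = np.arange(k, n + 1)
    return float(np.exp(logsumexp(stats.binom.logpmf(ks, n, p_div))))
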