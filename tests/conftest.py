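"""Shared fixtures: small planted experiments with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phagescreen import (
    CountTable,
    SamplePair,
    assign_truth,
    generate_library,
    pool_replicates,
    simulate_counts,
)


def make_table(counts: dict[str, int], protein="p", condition="non-competitor",
               replicate="1") -> CountTable:
    total = sum(counts.values())
    return CountTable(
        counts=dict(counts),
        total_reads_in=total,
        total_reads_passed=total,
        protein=protein,
        condition=condition,
        replicate=replicate,
    )


def make_pair(noncomp: dict[str, int], comp: dict[str, int], protein="p") -> SamplePair:
    return SamplePair(
        noncomp=make_table(noncomp, protein=protein, condition="non-competitor"),
        comp=make_table(comp, protein=protein, condition="competitor"),
    )


@pytest.fixture(scope="session")
def planted_experiment():
    """A mid-sized planted panning experiment: families, truth, counts.

    2,000 Hamming-1 families of three peptides, responsive weight 0.15 at
    N(-2.5, 2.5), two replicates at depth 10^6 (about 170 reads per
    peptide), mirroring a deeply sequenced screen.
    """
    library = generate_library(2000, 2, seed=11)
    truth = assign_truth(library, (0.15, -2.5, 2.5), seed=12)
    tables = simulate_counts(truth, depth=1_000_000, n_replicates=2, seed=13,
                             protein="hA5")
    return {"library": library, "truth": truth, "tables": tables}


@pytest.fixture(scope="session")
def planted_pooled_pair(planted_experiment) -> SamplePair:
    tables = planted_experiment["tables"]
    return SamplePair(
        noncomp=pool_replicates(tables["non-competitor"]),
        comp=pool_replicates(tables["competitor"]),
    )


from phagescreen.simulate import multiprotein_truth  # noqa: F401  (re-export)
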