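# phagescreen

Analysis pipeline for **competitive phage-display** experiments that map the
peptide-binding repertoire of a protein — built around the evolutionary
comparison of the calcium-activated S100 proteins S100A5 and S100A6 with
their reconstructed last common ancestor.

In the underlying assay, a library of randomized 12-mer peptides
(`XXXXXXXXXXXX-GGGSAE`, displayed on M13 phage) is panned against a
biotinylated, Ca²⁺-loaded S100 protein either alone or with a saturating
competitor peptide that occupies the canonical binding cleft. Deep
sequencing of both pools gives per-peptide counts, and the **enrichment**

```
E = ln(f_competitor / f_non-competitor)
```

separates peptides the competitor displaces (*E* < 0, specific binders)
from adventitious ones (*E* ≈ 0). The package implements the full path
from raw reads to evolutionary conclusions:

- **Read QC and counting** (`phagescreen.reads`) — length, invariant-flank
  (≤ 1 mismatch) and mean-phred (≥ 15) filters, standard-code translation,
  and the conservative six-count cutoff.
- **Bayesian count calibration** (`phagescreen.frequency`) — the posterior
  P(f | c, N) ∝ Binomial(c; N, f)·λe^(−λf) over peptide frequency, with a
  closed-form posterior maximum and a diagnostic for where counts map
  linearly onto frequency.
- **Clustered enrichment** (`phagescreen.enrichment`) — an in-house DBSCAN
  over the Hamming metric (ε = 1, min_pts = 2, equal to the Hamming-1 graph
  components) pools counts across single-substitution peptide families so
  that strong binders with zero competitor counts still get finite,
  well-estimated *E*.
- **Mixture classification** (`phagescreen.mixture`) — a two-Gaussian
  responsive/unresponsive model of the *E* distribution; the cutoff *E\**
  solves `pdf_u(E)/(pdf_r(E)+pdf_u(E)) = 0.05`, and the responsive
  component extrapolates the total number of *E* < 0 peptides.
- **Binder-set evolution** (`phagescreen.sets`) — Venn overlaps, the
  ancestral / divergent / convergent categories, cutoff sweeps, multinomial
  resampling envelopes, and an exact log-space binomial tail for testing
  excesses of divergent peptides.
- **Fluorescence-polarization validation** (`phagescreen.fp`) — probe
  titration fits, the mass-action probe/protein complex concentration,
  fractional-saturation conversion with the max(θ) ≥ 0.5 gate, displacement
  fits, and the probe-depletion correction that turns an apparent KD into a
  peptide KD.
- **Synthetic data** (`phagescreen.simulate`) — planted libraries,
  enrichment mixtures, multinomial sequencing, NNK-codon FASTQ emission
  with QC-failing read classes, and noisy FP curves: every analysis stage
  can be tested against known ground truth.

The statistical workhorses follow scikit-learn conventions
(`HammingDBSCAN`, `EnrichmentMixture`, `ProbeBindingModel`,
`CompetitionBindingModel` expose `fit`, fitted `*_` attributes and
`get_params`), with plain functions as thin wrappers.

## Worked example

Simulate a two-replicate competitive screen with planted ground truth
(2,000 Hamming-1 families of three peptides; 15% of families responsive
with true *E* ~ N(−2.5, 2.5²); about 12 reads per peptide), then run the
analysis:

```python
from phagescreen import (
    SamplePair, assign_truth, classify, enrich_pair, estimate_total_negative,
    fit_mixture, generate_library, pool_replicates, simulate_counts,
)
from phagescreen.reads import apply_count_cutoff

library = generate_library(n_families=2000, variants_per_family=2, seed=11)
truth = assign_truth(library, mixture_params=(0.15, -2.5, 2.5), seed=12)
tables = simulate_counts(truth, depth=36_000, n_replicates=2, seed=13)

pair = SamplePair(
    noncomp=apply_count_cutoff(pool_replicates(tables["non-competitor"]), 6),
    comp=apply_count_cutoff(pool_replicates(tables["competitor"]), 6),
)
table = enrich_pair(pair)                      # cluster + assign E
model = fit_mixture(table["E"].to_numpy(), seed=0)
e_star = model.solve_cutoff(p_star=0.05)
binders = classify(table, e_star)
n_total = estimate_total_negative(model, len(binders), e_star)
```

This prints (via the obvious `print` calls):

```
4075 peptides in 2209 clusters
responsive:   mean=-3.73 sd=0.75 w=0.13
unresponsive: mean=-0.04 sd=0.66 w=0.87
E* = -2.17; 538 responsive binders
estimated total peptides with E < 0: 549
```

Reading: of the 4,075 peptides that survived QC and the count cutoff, the
mixture separates a narrow unresponsive peak near *E* = 0 from a broad
responsive component centered well below it; a peptide with *E* ≤ −2.17
has at most a 5% posterior probability of coming from the unresponsive
peak, and 538 peptides clear that bar. Note how censoring shapes the
responsive component at this depth: a strongly depleted cluster has zero
competitor counts, so its *E* piles up near −ln(2·counts) rather than at
its true value — the classifier is designed to be robust to exactly this.

The same pipeline runs from the shell (`phagescreen simulate`, `count`,
`enrich`, `classify`, `sets`, `fp`, or end-to-end with `phagescreen run
--config run.yaml`).

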