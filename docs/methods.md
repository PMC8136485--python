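# Methods

## The measurement model

A competitive phage-display screen compares two pannings of the same
randomized peptide library against one protein: with and without a
saturating competitor peptide that blocks the canonical binding cleft.
For peptide *i* with frequency α\_i in the non-competitor pool and β\_i in
the competitor pool, the enrichment is the signed log-ratio

    E_i = ln(β_i / α_i)

Sign convention: **E < 0 means the competitor depleted the peptide**, the
signature of binding at the blocked interface; E ≈ 0 means the peptide is
indifferent to competitor (unbound or adventitiously bound); E > 0 means
binding is enhanced by the protein–competitor complex. All downstream
rules (the E ≤ −1.5 style cutoff, binder sets) assume this orientation.

Frequencies are counts over the total counted reads of a sample. Both
pools are sequenced, reads are quality-controlled, translated, counted,
and counts below six are discarded as unreliable (see the calibration
section). Biological replicates are pooled by summing counts — the
equivalent of concatenating sequencing runs — before frequencies are
formed.

## Read quality control

A read must contain the variable region (12 codons), the invariant
linker DNA and a stop codon. Three checks run in a fixed order, and the
first failure is the recorded reason, so the rejection accounting is
unambiguous: exact expected length (revertant phage lacking the variable
region fail here), at most one mismatch in the invariant region (one
sequencing error or point mutation is tolerated; wholesale changes are
not), and mean phred ≥ 15 over the whole read. The threshold is
inclusive at exactly 15; the choice of boundary is below the granularity
of real quality strings and is configurable. Reads passing QC are
translated with the standard genetic code; an in-frame stop or non-ACGT
base makes the read untranslatable (a fourth, last-in-precedence
rejection class). Nucleotides are handled case-insensitively and
peptides stored uppercase.

## Why a six-count cutoff: the count→frequency posterior

For a peptide seen *c* times among *N* reads, the posterior over its true
frequency *f* combines a binomial likelihood with an exponential
abundance prior of rate λ (fitted as the inverse mean of the measurable
frequencies, i.e. those of peptides at or above the cutoff):

    P(f | c, N) ∝ Binomial(c; N, f) · λ e^{−λf}

The posterior maximum solves c/f − (N−c)/(1−f) − λ = 0, a quadratic with
the numerically stable root

    f̂ = 2c / ((N+λ) + sqrt((N+λ)² − 4λc))

which tends to c/N as λ→0 (λ = 0 is accepted as the flat-prior limit).
The calibration diagnostic reports the smallest count from which each
step f̂(c+1) − f̂(c) stays within 5% of the ideal slope 1/N. Two
properties are worth stating plainly:

- With a *pure* exponential prior the curvature term 4λc/(N+λ)² is
  negligible for plate-realistic values, so f̂ is essentially linear in c
  from c = 1 — the prior rescales the slope to 1/(N+λ) rather than
  bending the curve at small counts. Sub-linear behavior at one or two
  counts arises with empirical (histogram) priors that flatten at low
  frequency; the exponential idealization does not produce it. The
  diagnostic therefore usually reports onset 1 and errors out when
  λ > tolerance·N (no linear regime at the stated tolerance).
- The production pipeline does not gate on the diagnostic; it uses the
  fixed, conservative cutoff of six counts throughout.

Posterior densities are normalized by trapezoidal integration on a
log-spaced grid spanning [1e−12, 1−1e−12] (frequencies span many orders
of magnitude); mass conservation is checked to 1e−6.

## Clustered enrichment

Strong binders are exactly the peptides most likely to have *zero*
competitor counts, so per-peptide ratios discard the most informative
observations. Instead, peptides are clustered by Hamming distance with
an in-house DBSCAN (ε = 1, min_pts = 2, lexicographic processing order for
determinism). With these defaults the partition equals the connected
components of the Hamming-1 graph — reproducible and checkable against a
graph library. Neighbor search at ε = 1 enumerates the ≤ L×19
single-position substitutions against a hash of the peptide set (linear
total cost); a generic pairwise fallback covers ε > 1. Unclustered
peptides become singleton clusters.

Cluster enrichment sums member counts with a pseudocount q = 0.5:

    E_cluster = ln((Σc_comp + q)/N_comp) − ln((Σc_noncomp + q)/N_noncomp)

and every member inherits E_cluster. The pseudocount keeps E finite when
the competitor sum is zero; it is configurable and reported. A cluster
observed in neither sample is an error, not E = 0. On planted Hamming-1
families at depth 10⁶ the cluster estimate explains > 95% of the variance
of the direct per-peptide ratio (peptides seen in both samples), and the
offset-corrected error spread shrinks monotonically with depth.

Replicate agreement is summarized by a total-least-squares line (first
principal axis of the centered cloud, so axis exchange maps the slope to
its reciprocal) plus squared Pearson correlations, computed separately
for the region with E ≤ cutoff in both replicates and for the
complementary common peptides.

## Two-Gaussian classification

The E distribution is modeled as a narrow "unresponsive" Gaussian near
zero plus a broad "responsive" Gaussian shifted negative. Fitting is EM
on the raw values (scikit-learn mixture, multiple restarts, best
likelihood kept); a histogram least-squares fit is available behind
`method="histogram"` as a fidelity check on binned data. Component
labels are assigned by width (unresponsive = narrower), with sanity
checks — |μ_u| < 0.5 and |μ_u| < |μ_r| — that raise rather than guess,
and near-zero weights or indistinguishable widths are reported as fit
failures (a single-Gaussian input is flagged, not silently returned).

The posterior probability that a value arose from the unresponsive
component is the **unweighted** density ratio

    p_posterior(E) = pdf_u(E) / (pdf_r(E) + pdf_u(E))

(mixture weights deliberately omitted — this matches the convention in
which the rule is usually stated for this assay; the weighted form would
shift the cutoff modestly). It is evaluated from log densities so deep
tails return exact 0/1 limits. The cutoff E\* is the most negative root
of p_posterior(E) = p\*, located by a bracketed scan plus Brent root
finding to 1e−8; peptides with E ≤ E\* (boundary inclusive) are
classified responsive. The expected behavior — E\* becomes more negative
as the unresponsive peak widens — is covered by a monotonicity test.

The number of competitor-depleted peptides that are *not* classifiable
(−cutoff < E < 0, hidden under the central peak) is extrapolated from
the responsive component: with Φ_r its normal CDF,

    n_total(E < 0) = n_below × Φ_r(0) / Φ_r(E*)

This ratio-of-probabilities definition is the implemented contract; it
needs Φ_r(E\*) > 0 and always returns at least n_below.

## Binder sets and evolutionary categories

All set analysis happens on the *common universe* — peptides with a
measurable E for every protein compared (set intersection of the
enrichment tables, before any cutoff). Binder sets are {peptide : E ≤
cutoff}; three-way overlaps are reported as the seven exclusive Venn
regions. Each binder of a modern protein is **ancestral** if the
ancestor also binds it (regardless of the other modern), **convergent**
if only the other modern shares it, **divergent** otherwise — an ordered
definition, tested case by case. Set sizes grow monotonically as the
cutoff relaxes; category counts need not (a divergent peptide can become
ancestral once the ancestor's set grows), which the sweep tests
acknowledge.

The null model for category proportions draws, at each cutoff, a
multinomial over (ancestral, divergent, convergent) with proportions
estimated from the moderate-enrichment window (default −4.0 ≤ E ≤ −1.5)
and reports central 95% envelopes. Hypothesis tests on divergent
excesses use the exact binomial survival probability P(X ≥ k | n, p),
summed in log space — the interesting tails (~1e−40) are far beyond
Monte-Carlo resolution; k = n returns p^n exactly and k = 0 returns 1.

## Fluorescence-polarization validation

Polarization is R = (v_v − G·v_h)/(v_v + 2G·v_h) with G defaulting
to 1. Technical replicate outliers are removed by a 3× scaled-MAD rule
that never drops below two readings (the rule is this package's
construction; it is idempotent and leaves ties untouched). Probe
titrations are fitted to the single-site model P = ΔP_max·[M]/([M]+K_D) +
P₀ by nonlinear least squares with reported standard errors.

For competition experiments the probe/protein complex before competitor
addition is the physical root of the mass-action quadratic,

    [MX] = ((X_T + M_T + K_D) − sqrt((X_T + M_T + K_D)² − 4 X_T M_T)) / 2

(the minus root is the only one with [MX] ≤ min(X_T, M_T)); the expected
signal change is ΔP_pred = ΔP_max·[MX]/X_T with ΔP_max defaulting
to 0.135. Readings convert to fractional saturation θ = (R − P₀)/ΔP_pred;
curves with max(θ) < 0.5 are refused (too little displaceable signal to
fit). The baseline P₀ is estimated by a decreasing single-site pre-fit
whose amplitude is *pinned to ΔP_pred* — the amplitude is known by
construction, and letting it float creates a baseline/amplitude
degeneracy on curves that never reach their plateau. The displacement
isotherm (signal lost = c/(c + K_D,app), i.e. the competition experiment
titrates competitor at fixed protein) yields K_D,apparent, corrected for
probe depletion by

    K_D,peptide = K_D,apparent / (1 + X_T(1 − δ/2)/K_D,probe + δ/(1 − δ)),  δ = [MX]/X_T

valid for δ < 1. The association between enrichment class and detectable
binding is summarized by an uncorrected Pearson χ² (1 df; Yates optional)
and the φ coefficient, which satisfies φ²·N = χ² identically.

**Precision of the full chain.** With the standard design — probe and
protein at ≈3 µM, K_D,probe ≈ 2 µM, so δ ≈ 0.45 and ΔP_pred ≈ 0.06
polarization units — a per-reading noise of 0.005 is ≈8% noise per θ
point. The Fisher information of a 15-well × 3-replicate displacement
curve then bounds the standard error of ln K_D,apparent at roughly 6–9%
even with the baseline known exactly; propagated through the correction,
repeated simulations of the whole chain give a ~13% standard deviation on
the recovered peptide K_D. Recovery to a few percent at this noise level
would need on the order of a hundred wells or several-fold lower noise.
The noiseless round trip recovers the planted K_D to 1e−6 relative, the
quadratic root satisfies mass action to 1e−10, and the δ = 0 limit of the
correction is exact — the chain is correct; its stochastic precision is
set by the experiment design.

## The synthetic-data generator

The generator emulates the screen's study conditions with known truth:

- **Library**: 12-mers over the 20 amino acids with per-position
  frequency vectors (uniform by default) and the fixed GGGSAE linker.
  Peptides come in Hamming-1 families — a seed plus single-substitution
  variants — so clustering has planted structure; truth is assigned at
  the family level, making the cluster estimator exact in truth and
  isolating estimator error from model error.
- **Enrichment truth**: families are responsive with probability w_resp
  (default 0.15) and responsive families draw a shared true E from
  N(−2.5, 2.5²); unresponsive families have true E = 0 exactly, so the
  observed central peak's width is purely counting noise. The defaults
  put roughly a tenth of the library below an E ≤ −1.5 cutoff — the
  binder fraction seen in real screens of this design — and the
  responsive shape matches what mixture fits recover from such screens.
  Renormalizing the competitor frequencies shifts every observed E by one
  global constant (−ln Σ α_i e^{E_i}); analyses that compare E values are
  unaffected, and recovery tests remove the offset before measuring
  noise.
- **Sequencing**: independent multinomial draws per sample and replicate
  at a chosen depth. Counting noise is therefore exactly Poisson-like; a
  depth of ~12 reads per peptide reproduces a central-peak width of ≈0.4.
- **Reads**: NNK degenerate codons (the scheme of commercial randomized
  libraries; an assumption, and configurable), fixed linker DNA, stop
  codon, phred scores from a clipped Gaussian, and three planted
  QC-failing classes (variable-region deletion, two linker mutations,
  low quality) at chosen rates, enabling exact planted-fault recovery
  tests of the QC funnel.
- **FP curves**: noiseless single-site curves (rising probe titrations or
  falling displacement curves) plus Gaussian noise per technical
  replicate.
- **Multi-protein screens**: a four-protein scenario plants a known
  membership mask per peptide over (modern A, modern B, ancestor) with an
  alternate-ancestor subset, shared library frequencies across proteins
  (one input library), and binder strengths N(−4, 0.8) deep enough that
  classification error is negligible against multinomial sampling error
  when recovering Venn regions. Per-sample depth of ~500 reads per
  peptide keeps cutoff-boundary artifacts (see below) out of the binder
  sets.

What the generator does **not** emulate: phage amplification bias between
panning rounds, PCR/sequencing substitution errors inside the variable
region, and overdispersion of counts beyond multinomial. Real central
peaks therefore owe part of their width to noise sources absent here, and
passing recovery tests demonstrate correctness of the estimators under
the stated noise model, not robustness to every noise source of a real
screen.

## Censoring at the count cutoff, and what replicate tests show

Zeroing sub-cutoff counts has a real consequence the simulations expose:
a depleted cluster whose competitor counts straddle the six-count
boundary flips between "counted" and "zeroed" across replicates, jumping
its E by ~ln(6.5/0.5) ≈ 2.6. In the deeply responsive region most E
values are pinned at −ln(counts/pseudocount-scale) and reproduce through
the shared library frequency; the flip noise is what limits
replicate-to-replicate correlation there. At the scale of a real
measurable universe (30,000 peptides, ~12 reads per peptide), simulated
responsive-region replicate R² sits around 0.55–0.65 while the
unresponsive-side correlation stays below 0.01 — the qualitative
structure (reproducible responsive tail, irreproducible central cloud)
is robust; the exact responsive-region value depends on seed and on
noise sources outside the generator's scope.

## Numerical choices and defaults (summary)

| Parameter | Default | Units | Why |
|---|---|---|---|
| mean-phred threshold | 15 (inclusive) | phred | conventional inclusive boundary |
| flank mismatches allowed | 1 | bases | one error tolerated, wholesale change rejected |
| count cutoff | 6 | reads | conservative onset of count–frequency linearity |
| DBSCAN ε / min_pts | 1 / 2 | Hamming / points | equals Hamming-1 graph components; deterministic |
| pseudocount q | 0.5 | counts | finite E at zero competitor counts |
| p\* | 0.05 | probability | posterior cutoff for responsive calls |
| moderate-E window | [−4.0, −1.5] | ln units | baseline category proportions |
| envelope simulations | 10,000 | draws | percentile stability at 95% |
| MAD outlier rule | 3 × scaled MAD, keep ≥ 2 | — | robust, idempotent, never empties a well |
| ΔP_max | 0.135 | polarization | probe-fit amplitude of this assay family |
| G factor | 1.0 | — | instrument convention |
| w_resp / μ_r / σ_r (generator) | 0.15 / −2.5 / 2.5 | — / ln units | ~10% of library below E ≤ −1.5; matches fitted screens |

Degenerate inputs are errors, not silent defaults: empty tables, zero
margins, unobserved clusters, identical mixture components, δ ≥ 1,
posterior without a p\* crossing (the error carries the diagnostic
curve). Ties in clustering are broken lexicographically; all stochastic
stages take explicit seeds fanned out from one run-level seed, and the
pipeline records the config hash and seeds in its provenance file so any
output is reproducible bit-for-bit.
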