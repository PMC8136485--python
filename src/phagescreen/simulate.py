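"""Synthetic phage-display and binding data with known ground truth.

The generator emulates the study conditions of a competitive panning
experiment against a randomized 12-mer library:

* peptides are organized in Hamming-1 families (a seed sequence plus
  single-substitution variants) so that density clustering has planted
  structure to recover;
* each family is responsive (its frequency shifts under competitor, with a
  family-level true enrichment drawn from a Gaussian) or unresponsive
  (true E = 0; any observed spread is pure counting noise);
* library frequencies follow an exponential distribution and sequencing is
  multinomial sampling at a chosen depth;
* reads are reverse-translated with NNK degenerate codons and can be
  corrupted into the QC-failing classes the real pipeline rejects
  (variable-region deletion, flank mutations, low quality);
* fluorescence-polarization titrations are single-site curves with
  Gaussian noise.

Default mixture parameters place the responsive component at
``N(-2.5, 2.5)`` with weight 0.15, which puts roughly ten percent of the
library below the E <= -1.5 cutoff — the binder fraction seen in the
measurable universe of the real screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._util import open_text, spawn_rngs
from .fp import FPTitration
from .reads import (
    AA_ALPHABET,
    FLANK_DNA,
    FLANK_PEPTIDE,
    PHRED_OFFSET,
    STOP_CODON,
    CountTable,
    ReadRecord,
)

# NNK degenerate codons (N = ACGT, K = GT) per amino acid; the TAG stop is
# excluded.  This is the scheme used by commercial randomized libraries.
NNK_CODONS: dict[str, list[str]] = {}
for _c1, _c2, _c3 in product("ACGT", "ACGT", "GT"):
    _codon = _c1 + _c2 + _c3
    _aa = str(Seq(_codon).translate())
    if _aa != "*":
        NNK_CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class LibraryModel:
    """Composition model for the randomized peptide library."""

    peptide_length: int = 12
    alphabet: str = AA_ALPHABET
    position_frequencies: np.ndarray | None = None  # (L, |alphabet|)
    flank: str = FLANK_PEPTIDE

    def __post_init__(self):
        if self.peptide_length <= 0:
            raise ValueError("peptide_length must be positive")
        freqs = self.position_frequencies
        if freqs is None:
            freqs = np.full(
                (self.peptide_length, len(self.alphabet)), 1.0 / len(self.alphabet)
            )
            object.__setattr__(self, "position_frequencies", freqs)
        else:
            freqs = np.asarray(freqs, dtype=float)
            if freqs.shape != (self.peptide_length, len(self.alphabet)):
                raise ValueError("position_frequencies must be (L, |alphabet|)")
            if np.any(freqs < 0):
                raise ValueError("frequencies must be non-negative")
            if np.any(np.abs(freqs.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("each position's frequencies must sum to 1")
            object.__setattr__(self, "position_frequencies", freqs)

    @property
    def sequence_space(self) -> float:
        return float(len(self.alphabet)) ** self.peptide_length


class MixtureParams(NamedTuple):
    """Responsive-component parameters of the planted E mixture."""

    w_resp: float = 0.15
    mu_r: float = -2.5
    sigma_r: float = 2.5


DEFAULT_MIXTURE = MixtureParams()


@dataclass(frozen=True)
class FPGroundTruth:
    """Planted parameters for a simulated FP titration."""

    kd_true: float  # uM
    p0_true: float
    dpmax_true: float
    noise_sd: float
    concentrations: np.ndarray

    def __post_init__(self):
        if self.kd_true <= 0:
            raise ValueError("KD_true must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be non-negative, strictly increasing")
        object.__setattr__(self, "concentrations", conc)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _draw_peptide(rng: np.random.Generator, model: LibraryModel) -> str:
    letters = [
        model.alphabet[rng.choice(len(model.alphabet), p=model.position_frequencies[i])]
        for i in range(model.peptide_length)
    ]
    return "".join(letters)


def generate_library(
    n_families: int,
    variants_per_family: int = 0,
    model: LibraryModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw family seeds and Hamming-1 variants; all peptides unique.

    Returns a DataFrame with columns ``peptide`` and ``family``; the first
    member of each family is its seed sequence.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if variants_per_family < 0:
        raise ValueError("variants_per_family must be >= 0")
    model = model or LibraryModel()
    total = n_families * (1 + variants_per_family)
    if total > model.sequence_space:
        raise ValueError(
            f"requested {total} peptides exceeds sequence space "
            f"{model.sequence_space:.3g}"
        )
    if variants_per_family > model.peptide_length * (len(model.alphabet) - 1):
        raise ValueError("variants_per_family exceeds the Hamming-1 shell size")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows: list[tuple[str, int]] = []
    max_tries = 1000 * total + 1000
    tries = 0
    fam = 0
    while fam < n_families:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place unique peptides; space too dense")
        seed_pep = _draw_peptide(rng, model)
        if seed_pep in seen:
            continue
        variants: list[str] = []
        ok = True
        attempts = 0
        while len(variants) < variants_per_family:
            attempts += 1
            if attempts > 200 * (variants_per_family + 1):
                ok = False
                break
            pos = int(rng.integers(model.peptide_length))
            current = seed_pep[pos]
            others = [a for a in model.alphabet if a != current]
            sub = others[int(rng.integers(len(others)))]
            var = seed_pep[:pos] + sub + seed_pep[pos + 1:]
            if var in seen or var == seed_pep or var in variants:
                continue
            variants.append(var)
        if not ok:
            continue
        seen.add(seed_pep)
        seen.update(variants)
        rows.append((seed_pep, fam))
        rows.extend((v, fam) for v in variants)
        fam += 1
    return pd.DataFrame(rows, columns=["peptide", "family"])


def assign_truth(
    library: pd.DataFrame,
    mixture_params: MixtureParams | tuple = DEFAULT_MIXTURE,
    prior_rate: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach ground-truth enrichment and sample frequencies to a library.

    Families are responsive with probability ``w_resp``; responsive
    families share one ``true_E ~ N(mu_r, sigma_r)`` while unresponsive
    families have ``true_E = 0``.  Non-competitor frequencies are
    exponential draws (rate ``prior_rate``) normalized to 1; competitor
    frequencies are proportional to ``f_noncomp * exp(true_E)``, so a
    negative true E means the competitor depletes the peptide.
    """
    w_resp, mu_r, sigma_r = MixtureParams(*mixture_params)
    if not 0 <= w_resp < 1:
        raise ValueError("w_resp must lie in [0, 1)")
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    if prior_rate <= 0:
        raise ValueError("prior rate must be positive")
    rng_class, rng_e, rng_freq = spawn_rngs(seed, 3)
    truth = library.copy()
    families = truth["family"].unique()
    responsive = pd.Series(
        rng_class.random(families.size) < w_resp, index=families
    )
    family_e = pd.Series(
        np.where(responsive, rng_e.normal(mu_r, sigma_r, families.size), 0.0),
        index=families,
    )
    truth["cls"] = np.where(
        responsive.reindex(truth["family"]).to_numpy(), "responsive", "unresponsive"
    )
    truth["true_E"] = family_e.reindex(truth["family"]).to_numpy()
    f_nc = rng_freq.exponential(1.0 / prior_rate, len(truth))
    f_nc /= f_nc.sum()
    f_c = f_nc * np.exp(truth["true_E"].to_numpy())
    f_c /= f_c.sum()
    truth["f_noncomp"] = f_nc
    truth["f_comp"] = f_c
    return truth


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------

def simulate_counts(
    truth: pd.DataFrame,
    depth: int,
    n_replicates: int = 2,
    seed: int | None = None,
    protein: str = "",
) -> dict[str, list[CountTable]]:
    """Multinomial sequencing of both conditions.

    Returns ``{"non-competitor": [rep tables...], "competitor": [...]}``;
    replicates are independent draws from the same frequency vector,
    mirroring biological replicates panned from one input library.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    peptides = truth["peptide"].to_numpy()
    rngs = spawn_rngs(seed, 2 * n_replicates)
    out: dict[str, list[CountTable]] = {"non-competitor": [], "competitor": []}
    for rep in range(n_replicates):
        for j, (condition, col) in enumerate(
            [("non-competitor", "f_noncomp"), ("competitor", "f_comp")]
        ):
            rng = rngs[2 * rep + j]
            draws = rng.multinomial(depth, truth[col].to_numpy())
            counts = {p: int(c) for p, c in zip(peptides, draws) if c > 0}
            out[condition].append(
                CountTable(
                    counts=counts,
                    total_reads_in=depth,
                    total_reads_passed=depth,
                    protein=protein,
                    condition=condition,
                    replicate=str(rep + 1),
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

DEFAULT_CORRUPTION = {"wrong_length": 0.0, "flank_mismatch": 0.0, "low_quality": 0.0}


def _reverse_translate_nnk(peptide: str, rng: np.random.Generator) -> str:
    return "".join(
        NNK_CODONS[aa][int(rng.integers(len(NNK_CODONS[aa])))] for aa in peptide
    )


def _phred_string(scores: Iterable[int]) -> str:
    return "".join(chr(int(q) + PHRED_OFFSET) for q in scores)


def emit_fastq(
    counts: CountTable,
    model: LibraryModel | None = None,
    corruption_rates: dict[str, float] | None = None,
    seed: int | None = None,
    clean_phred_mean: float = 32.0,
    clean_phred_sd: float = 3.0,
) -> list[ReadRecord]:
    """Emit one read per counted copy of each peptide.

    Clean reads are NNK reverse translations followed by the invariant
    flank DNA and a stop codon, with phred scores from a clipped Gaussian.
    ``corruption_rates`` plants QC-failing classes: ``wrong_length``
    (variable region deleted, the revertant-phage mode), ``flank_mismatch``
    (two bases of the invariant region mutated) and ``low_quality``.
    """
    model = model or LibraryModel()
    rates = dict(DEFAULT_CORRUPTION)
    if corruption_rates:
        unknown = set(corruption_rates) - set(rates)
        if unknown:
            raise ValueError(f"unknown corruption classes: {sorted(unknown)}")
        rates.update(corruption_rates)
    p_corrupt = sum(rates.values())
    if p_corrupt >= 1.0 or any(v < 0 for v in rates.values()):
        raise ValueError("corruption rates must be non-negative and sum to < 1")
    classes = ["clean"] + sorted(rates)
    probs = np.array([1.0 - p_corrupt] + [rates[k] for k in sorted(rates)])
    rng_class, rng_dna, rng_qual = spawn_rngs(seed, 3)
    invariant = FLANK_DNA + STOP_CODON
    records: list[ReadRecord] = []
    idx = 0
    for peptide in sorted(counts.counts):
        for _ in range(counts.counts[peptide]):
            cls = classes[int(rng_class.choice(len(classes), p=probs))]
            dna = _reverse_translate_nnk(peptide, rng_dna) + invariant
            qual = np.clip(
                np.round(rng_qual.normal(clean_phred_mean, clean_phred_sd, len(dna))),
                20,
                40,
            ).astype(int)
            if cls == "wrong_length":
                dna = invariant
                qual = qual[: len(dna)]
            elif cls == "flank_mismatch":
                start = model.peptide_length * 3
                positions = rng_dna.choice(len(invariant), size=2, replace=False)
                dna_list = list(dna)
                for off in positions:
                    pos = start + int(off)
                    dna_list[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[dna_list[pos]]
                dna = "".join(dna_list)
            elif cls == "low_quality":
                qual = np.clip(
                    np.round(rng_qual.normal(8.0, 2.0, len(dna))), 2, 13
                ).astype(int)
            idx += 1
            records.append(
                ReadRecord(id=f"read{idx}:{cls}", dna=dna, quality=tuple(qual))
            )
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write phred+33 FASTQ; gzipped when the path ends in ``.gz``."""
    with open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.dna}\n+\n{_phred_string(rec.quality)}\n")


def multiprotein_truth(
    n_peptides: int = 4000,
    membership_probs: dict[str, float] | None = None,
    binder_mu: float = -4.0,
    binder_sd: float = 0.8,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Planted four-protein screen with a known Venn overlap structure.

    Peptides are singleton families sharing one library frequency vector
    (the four proteins are panned from the same input library).  Each
    peptide carries a membership mask over (hA5, hA6, anc) drawn from
    ``membership_probs`` (mask -> probability, '000' taking the
    remainder); binders of a protein get ``true_E ~ N(binder_mu,
    binder_sd)``, non-binders 0.  A fourth protein, altAll, binds a random
    70% subset of the ancestral binders, mimicking an alternate ancestral
    reconstruction.  Returns (per-protein truth tables, membership table).
    """
    probs = membership_probs or {
        "100": 0.06, "010": 0.05, "001": 0.05,
        "110": 0.02, "101": 0.04, "011": 0.03, "111": 0.03,
    }
    rng = np.random.default_rng(seed)
    library = generate_library(n_peptides, 0, seed=None if seed is None else seed + 1)
    masks = list(probs)
    p = np.array([probs[m] for m in masks])
    p_rest = 1.0 - p.sum()
    if p_rest <= 0:
        raise ValueError("membership probabilities must sum to < 1")
    draw = rng.choice(len(masks) + 1, size=n_peptides, p=np.append(p, p_rest))
    mask_per_pep = np.array(masks + ["000"], dtype=object)[draw]
    f_nc = rng.exponential(1.0, n_peptides)
    f_nc /= f_nc.sum()
    membership = pd.DataFrame({"peptide": library["peptide"], "mask": mask_per_pep})
    anc_binder = np.array([m[2] == "1" for m in mask_per_pep])
    alt_keep = rng.random(n_peptides) < 0.7
    binder_flags = {
        "hA5": np.array([m[0] == "1" for m in mask_per_pep]),
        "hA6": np.array([m[1] == "1" for m in mask_per_pep]),
        "anc": anc_binder,
        "altAll": anc_binder & alt_keep,
    }
    truths = {}
    for name, is_binder in binder_flags.items():
        truth = library.copy()
        truth["cls"] = np.where(is_binder, "responsive", "unresponsive")
        e = np.where(is_binder, rng.normal(binder_mu, binder_sd, n_peptides), 0.0)
        truth["true_E"] = e
        f_c = f_nc * np.exp(e)
        truth["f_noncomp"] = f_nc
        truth["f_comp"] = f_c / f_c.sum()
        truths[name] = truth
        membership[f"binder_{name}"] = is_binder
    return truths, membership


# ---------------------------------------------------------------------------
# Direct mixture sampling and FP curves
# ---------------------------------------------------------------------------

def sample_enrichment_mixture(
    n: int,
    w_resp: float,
    mu_r: float,
    sigma_r: float,
    mu_u: float = 0.0,
    sigma_u: float = 0.4,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw E values from the two-component responsive/unresponsive model.

    Returns ``(E, responsive)`` where ``responsive`` is a boolean label
    array.  Used to test mixture fitting free of counting noise.
    """
    rng_label, rng_draw = spawn_rngs(seed, 2)
    responsive = rng_label.random(n) < w_resp
    e = np.where(
        responsive,
        rng_draw.normal(mu_r, sigma_r, n),
        rng_draw.normal(mu_u, sigma_u, n),
    )
    return e, responsive


def simulate_fp(
    truth: FPGroundTruth,
    mode: str = "probe_titration",
    seed: int | None = None,
    n_replicates: int = 3,
) -> FPTitration:
    """Noisy single-site FP curve.

    ``probe_titration``: polarization rises with protein concentration,
    ``P0 + dPmax * c/(c + KD)``.  ``competition``: polarization falls as
    competitor displaces the probe, ``P0 + dPmax * (1 - c/(c + KD))``;
    here ``kd_true`` plays the role of KD_apparent and ``dpmax_true`` of
    the predicted signal change.
    """
    conc = truth.concentrations
    if mode == "probe_titration":
        clean = truth.p0_true + truth.dpmax_true * conc / (conc + truth.kd_true)
    elif mode == "competition":
        clean = truth.p0_true + truth.dpmax_true * (1.0 - conc / (conc + truth.kd_true))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    readings = clean[:, None] + rng.normal(0.0, truth.noise_sd, (conc.size, n_replicates))
    return FPTitration(concentrations=conc, readings=readings, meta={"mode": mode})
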