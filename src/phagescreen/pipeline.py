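"""End-to-end orchestration: counts -> enrichment -> classification -> sets.

A run is driven by one declarative config (YAML or dict).  Stages
communicate through on-disk TSV/CSV/JSON only, every output directory
carries a provenance record with the config hash and the package version,
and all randomness flows from the single run-level seed, so a rerun with
the same config is bit-identical apart from timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import child_seed
from .enrichment import SamplePair, enrich_pair, pool_replicates
from .mixture import CutoffError, MixtureFitError, fit_mixture
from .reads import CountTable, DEFAULT_TEMPLATE, apply_count_cutoff, count_reads, qc_summary
from .sets import binder_sets, common_universe, cutoff_sweep, venn3

log = logging.getLogger("phagescreen")

CONDITIONS = ("non-competitor", "competitor")


@dataclass
class Sample:
    protein: str
    condition: str
    replicate: str
    path: str
    format: str = "fastq"  # "fastq" | "counts"

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.format not in ("fastq", "counts"):
            raise ValueError(f"unknown sample format {self.format!r}")


@dataclass
class RunConfig:
    samples: list[Sample]
    outdir: str
    seed: int = 0
    min_count: int = 6
    eps: int = 1
    min_pts: int = 2
    pseudocount: float = 0.5
    p_star: float = 0.05
    set_cutoff: float = -1.5
    sweep: list[float] | None = None
    moderns: tuple[str, str] | None = None
    ancestor: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        samples = [Sample(**s) for s in raw["samples"]]
        roles = raw.get("roles", {}) or {}
        params = raw.get("params", {}) or {}
        return cls(
            samples=samples,
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            moderns=tuple(roles["moderns"]) if "moderns" in roles else None,
            ancestor=roles.get("ancestor"),
            sweep=raw.get("sweep"),
            **{k: v for k, v in params.items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "samples": [vars(s) for s in self.samples],
            "outdir": self.outdir,
            "seed": self.seed,
            "params": {
                "min_count": self.min_count,
                "eps": self.eps,
                "min_pts": self.min_pts,
                "pseudocount": self.pseudocount,
                "p_star": self.p_star,
                "set_cutoff": self.set_cutoff,
            },
            "roles": {"moderns": list(self.moderns) if self.moderns else None,
                      "ancestor": self.ancestor},
            "sweep": self.sweep,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        proteins: dict[str, set[str]] = {}
        for s in self.samples:
            proteins.setdefault(s.protein, set()).add(s.condition)
            if not Path(s.path).exists():
                raise FileNotFoundError(
                    f"sample file missing: {s.path} "
                    f"({s.protein}/{s.condition}/rep {s.replicate})"
                )
        for protein, conds in proteins.items():
            missing = set(CONDITIONS) - conds
            if missing:
                raise ValueError(
                    f"protein {protein!r} lacks condition(s): {sorted(missing)}"
                )
        if self.moderns and self.ancestor:
            known = set(proteins)
            for name in (*self.moderns, self.ancestor):
                if name not in known:
                    raise ValueError(f"role refers to unknown protein {name!r}")


def _load_sample(sample: Sample) -> CountTable:
    if sample.format == "counts":
        table = CountTable.read_tsv(sample.path)
        table.protein = sample.protein
        table.condition = sample.condition
        table.replicate = sample.replicate
        return table
    return count_reads(
        sample.path,
        DEFAULT_TEMPLATE,
        protein=sample.protein,
        condition=sample.condition,
        replicate=sample.replicate,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute count -> cutoff -> pool -> cluster -> enrich -> classify -> sets.

    Returns the run directory.  Fails before any computation when the
    config is inconsistent or a sample file is missing.
    """
    config.validate()
    outdir = Path(config.outdir)
    for sub in ("counts", "enrichment", "classify", "sets"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    log.info("run %s starting: %d samples", config.config_hash(), len(config.samples))

    # --- stage 1: per-sample counting + QC, then the count cutoff
    by_protein: dict[str, dict[str, list[CountTable]]] = {}
    qc: list[dict] = []
    for sample in config.samples:
        table = _load_sample(sample)
        qc.append(qc_summary(table))
        table = apply_count_cutoff(table, config.min_count)
        stem = f"{sample.protein}_{sample.condition}_rep{sample.replicate}"
        table.write_tsv(outdir / "counts" / f"{stem}.tsv")
        by_protein.setdefault(sample.protein, {c: [] for c in CONDITIONS})
        by_protein[sample.protein][sample.condition].append(table)
    with open(outdir / "counts" / "qc_summary.json", "w") as fh:
        json.dump(qc, fh, indent=2)

    # --- stage 2: pool replicates, cluster and compute enrichment
    enrichment_tables: dict[str, pd.DataFrame] = {}
    for protein, conds in sorted(by_protein.items()):
        pooled = {c: pool_replicates(tables) for c, tables in conds.items()}
        pair = SamplePair(noncomp=pooled["non-competitor"], comp=pooled["competitor"])
        table = enrich_pair(
            pair, eps=config.eps, min_pts=config.min_pts,
            pseudocount=config.pseudocount,
        )
        table.to_csv(outdir / "enrichment" / f"{protein}.tsv", sep="\t", index=False)
        enrichment_tables[protein] = table
        log.info("%s: %d peptides, %d clusters", protein, len(table),
                 table["cluster"].nunique())

    # --- stage 3: mixture classification per protein
    classification: dict[str, dict] = {}
    for protein, table in enrichment_tables.items():
        entry: dict = {"n_peptides": int(len(table))}
        try:
            model = fit_mixture(
                table["E"].to_numpy(), seed=child_seed(config.seed, 1)
            )
            entry["responsive"] = vars(model.responsive_)
            entry["unresponsive"] = vars(model.unresponsive_)
            entry["log_likelihood"] = model.log_likelihood_
            entry["cutoff"] = model.cutoff_
        except (ValueError, MixtureFitError, CutoffError) as exc:
            entry["error"] = str(exc)
            entry["cutoff"] = None
        cutoff = entry.get("cutoff") or config.set_cutoff
        responsive = table[table["E"] <= cutoff].sort_values("peptide")
        responsive.to_csv(
            outdir / "classify" / f"{protein}_responsive.tsv", sep="\t", index=False
        )
        entry["cutoff_used"] = cutoff
        entry["n_responsive"] = int(len(responsive))
        classification[protein] = entry
    with open(outdir / "classify" / "mixture_models.json", "w") as fh:
        json.dump(classification, fh, indent=2)

    # --- stage 4: cross-protein set analysis
    if config.moderns and config.ancestor:
        trio = {
            name: enrichment_tables[name]
            for name in (*config.moderns, config.ancestor)
        }
        universe = common_universe(trio)
        bs = binder_sets(trio, config.set_cutoff, universe=universe)
        a, b = (bs.sets[m] for m in config.moderns)
        c = bs.sets[config.ancestor]
        regions = venn3(a, b, c)
        venn_df = pd.DataFrame(
            {"region": list(regions), "count": list(regions.values())}
        )
        venn_df.to_csv(outdir / "sets" / "venn_regions.tsv", sep="\t", index=False)
        grid = config.sweep or list(np.round(np.arange(-6.0, config.set_cutoff + 1e-9, 0.25), 4))
        sweep = cutoff_sweep(trio, grid, moderns=config.moderns, ancestor=config.ancestor)
        sweep.to_csv(outdir / "sets" / "cutoff_sweep.csv", index=False)
        with open(outdir / "sets" / "summary.json", "w") as fh:
            json.dump(
                {"universe_size": len(universe), "set_sizes": bs.sizes(),
                 "cutoff": config.set_cutoff},
                fh, indent=2,
            )

    # --- provenance
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": ["count", "cutoff", "pool", "cluster", "enrich", "classify", "sets"],
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    log.info("run %s complete -> %s", config.config_hash(), outdir)
    return outdir
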