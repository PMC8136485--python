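"""FASTQ read quality control and peptide counting.

Each sequencing read covers a displayed peptide: a randomized variable
region (12 codons by default), the invariant linker that tethers the
peptide to the phage coat protein (GGGSAE at the amino-acid level), and a
stop codon.  A read contributes to a peptide's count only if it passes
three checks, applied in a fixed order:

1. the read has exactly the expected length (revertant phage lacking the
   variable region are the dominant failure mode),
2. the invariant region differs from the expected sequence at no more than
   one base,
3. the mean phred quality over the read is at least 15.

Reads passing QC are translated with the standard genetic code; reads whose
variable region contains an in-frame stop or a non-ACGT base are rejected
as untranslatable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import is_handle, open_text

# Amino-acid alphabet in the conventional one-letter ordering.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Invariant C-terminal linker shared by every displayed peptide.
FLANK_PEPTIDE = "GGGSAE"
#: One fixed codon spelling of the linker used by the read template.
FLANK_DNA = "GGTGGAGGTTCTGCTGAA"
STOP_CODON = "TAA"

PHRED_OFFSET = 33
DEFAULT_MIN_MEAN_PHRED = 15.0
DEFAULT_MIN_COUNT = 6


class QCReason(str, enum.Enum):
    OK = "ok"
    WRONG_LENGTH = "wrong_length"
    FLANK_MISMATCH = "flank_mismatch"
    LOW_QUALITY = "low_quality"
    UNTRANSLATABLE = "untranslatable"


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: QCReason

    def __post_init__(self):
        if self.passed != (self.reason is QCReason.OK):
            raise ValueError("reason must be 'ok' iff the read passed")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    dna: str
    quality: tuple[int, ...]

    def __post_init__(self):
        if len(self.dna) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.dna)} != "
                f"quality length {len(self.quality)}"
            )

    @classmethod
    def from_fastq_fields(cls, title: str, seq: str, qual: str) -> "ReadRecord":
        phred = tuple(ord(ch) - PHRED_OFFSET for ch in qual)
        return cls(id=title.split()[0], dna=seq, quality=phred)


@dataclass(frozen=True)
class ReadTemplate:
    """Expected read layout: variable region followed by an invariant tail."""

    variable_length: int = 36
    invariant_dna: str = FLANK_DNA + STOP_CODON
    max_flank_mismatches: int = 1
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED

    def __post_init__(self):
        if self.variable_length % 3 != 0:
            raise ValueError("variable region length must be divisible by 3")

    @property
    def expected_length(self) -> int:
        return self.variable_length + len(self.invariant_dna)


DEFAULT_TEMPLATE = ReadTemplate()


@dataclass
class CountTable:
    """Peptide -> read count for one panning sample.

    ``total_reads_in``/``total_reads_passed`` record the QC funnel;
    ``depth`` (the sum of counts) is the total N used for frequencies.
    """

    counts: dict[str, int]
    total_reads_in: int = 0
    total_reads_passed: int = 0
    protein: str = ""
    condition: str = ""
    replicate: str = ""
    rejects: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def depth(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def pass_fraction(self) -> float:
        if self.total_reads_in == 0:
            return float("nan")
        return self.total_reads_passed / self.total_reads_in

    def frequencies(self) -> pd.Series:
        n = self.depth
        if n == 0:
            return pd.Series(dtype=float)
        ser = pd.Series(self.counts, dtype=float).sort_index()
        return ser / n

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=int).sort_index()

    # ------------------------------------------------------------------ IO
    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open_text(path, "wt") as fh:
            meta = {
                "protein": self.protein,
                "condition": self.condition,
                "replicate": str(self.replicate),
                "total_reads_in": self.total_reads_in,
                "total_reads_passed": self.total_reads_passed,
                "rejects": self.rejects,
            }
            fh.write("# " + json.dumps(meta) + "\n")
            fh.write("peptide\tcount\n")
            for pep in sorted(self.counts):
                fh.write(f"{pep}\t{self.counts[pep]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        path = Path(path)
        meta: dict = {}
        counts: dict[str, int] = {}
        with open_text(path, "rt") as fh:
            first = fh.readline()
            if first.startswith("# "):
                meta = json.loads(first[2:])
                header = fh.readline()
            else:
                header = first
            if not header.startswith("peptide"):
                raise ValueError(f"{path}: expected 'peptide\\tcount' header")
            for line in fh:
                if not line.strip():
                    continue
                pep, cnt = line.rstrip("\n").split("\t")
                counts[pep.upper()] = counts.get(pep.upper(), 0) + int(cnt)
        return cls(
            counts=counts,
            total_reads_in=int(meta.get("total_reads_in", 0)),
            total_reads_passed=int(meta.get("total_reads_passed", 0)),
            protein=meta.get("protein", ""),
            condition=meta.get("condition", ""),
            replicate=meta.get("replicate", ""),
            rejects=meta.get("rejects", {}),
        )


# ---------------------------------------------------------------------------
# QC and translation
# ---------------------------------------------------------------------------

def translate_variable_region(dna: str) -> str | None:
    """Translate a variable region with the standard code.

    Returns ``None`` (untranslatable) on any non-ACGT base or any in-frame
    stop codon inside the region.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError("variable region length must be divisible by 3")
    if any(base not in "ACGT" for base in dna):
        return None
    peptide = str(Seq(dna).translate())
    if "*" in peptide:
        return None
    return peptide


def qc_read(read: ReadRecord, template: ReadTemplate = DEFAULT_TEMPLATE) -> QCResult:
    """Apply the QC checks with fixed precedence: length, flank, quality,
    translatability.  The first failing check is reported."""
    dna = read.dna.upper()
    if len(dna) != template.expected_length:
        return QCResult(False, QCReason.WRONG_LENGTH)
    invariant = dna[template.variable_length:]
    mismatches = sum(a != b for a, b in zip(invariant, template.invariant_dna))
    if mismatches > template.max_flank_mismatches:
        return QCResult(False, QCReason.FLANK_MISMATCH)
    if float(np.mean(read.quality)) < template.min_mean_phred:
        return QCResult(False, QCReason.LOW_QUALITY)
    if translate_variable_region(dna[: template.variable_length]) is None:
        return QCResult(False, QCReason.UNTRANSLATABLE)
    return QCResult(True, QCReason.OK)


def count_reads(
    fastq,
    template: ReadTemplate = DEFAULT_TEMPLATE,
    protein: str = "",
    condition: str = "",
    replicate: str = "",
) -> CountTable:
    """Count peptides over the QC-passing reads of a FASTQ file or handle."""
    if is_handle(fastq):
        handle = fastq
        close = False
    else:
        handle = open_text(fastq, "rt")
        close = True
    counts: dict[str, int] = {}
    rejects = {reason.value: 0 for reason in QCReason if reason is not QCReason.OK}
    n_in = n_pass = 0
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                # FastqGeneralIterator signals malformed/truncated records.
                raise ValueError(
                    f"truncated or malformed FASTQ near line {4 * n_in + 1}: {exc}"
                ) from exc
            n_in += 1
            read = ReadRecord.from_fastq_fields(title, seq, qual)
            result = qc_read(read, template)
            if not result.passed:
                rejects[result.reason.value] += 1
                continue
            peptide = translate_variable_region(
                read.dna.upper()[: template.variable_length]
            )
            assert peptide is not None  # guarded by qc_read
            n_pass += 1
            counts[peptide] = counts.get(peptide, 0) + 1
    finally:
        if close:
            handle.close()
    return CountTable(
        counts=counts,
        total_reads_in=n_in,
        total_reads_passed=n_pass,
        protein=protein,
        condition=condition,
        replicate=replicate,
        rejects=rejects,
    )


def apply_count_cutoff(table: CountTable, min_count: int = DEFAULT_MIN_COUNT) -> CountTable:
    """Discard peptides with fewer than ``min_count`` reads.

    A count of exactly ``min_count`` is retained.  QC totals are carried
    through unchanged so the funnel accounting stays interpretable.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = {p: c for p, c in table.counts.items() if c >= min_count}
    return replace(table, counts=kept)


def library_composition(
    table: CountTable, threshold: float = 0.01
) -> tuple[pd.DataFrame, list[int]]:
    """Count-weighted per-position amino-acid frequencies.

    Returns the L x 20 frequency matrix (rows are 1-based positions) and,
    per position, the number of amino acids above ``threshold``.
    """
    if not table.counts:
        raise ValueError("empty count table")
    lengths = {len(p) for p in table.counts}
    if len(lengths) != 1:
        raise ValueError(f"peptides have mixed lengths: {sorted(lengths)}")
    length = lengths.pop()
    matrix = np.zeros((length, len(AA_ALPHABET)))
    index = {aa: j for j, aa in enumerate(AA_ALPHABET)}
    for peptide, count in table.counts.items():
        for i, aa in enumerate(peptide):
            try:
                matrix[i, index[aa]] += count
            except KeyError:
                raise ValueError(f"non-standard amino acid {aa!r} in {peptide!r}")
    matrix /= matrix.sum(axis=1, keepdims=True)
    freq = pd.DataFrame(
        matrix, index=pd.RangeIndex(1, length + 1, name="position"),
        columns=list(AA_ALPHABET),
    )
    n_above = [int((row > threshold).sum()) for _, row in freq.iterrows()]
    return freq, n_above


def qc_summary(table: CountTable) -> dict:
    """JSON-ready QC funnel summary for one sample."""
    return {
        "protein": table.protein,
        "condition": table.condition,
        "replicate": str(table.replicate),
        "total_reads_in": table.total_reads_in,
        "total_reads_passed": table.total_reads_passed,
        "pass_fraction": table.pass_fraction,
        "rejects": dict(table.rejects),
        "unique_peptides": len(table.counts),
        "counted_reads": table.depth,
    }
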