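"""Readers/writers for the plain-text formats every analysis stage touches.

Formats handled: FASTA sequences, 12-column tabular similarity-search hits
(the de facto BLAST/DIAMOND tabular standard), genes x samples count
matrices with a sample-metadata sheet, differential-expression tables, and
gene -> term annotation maps.  Also the transcript-id to gene-id mapping
used to aggregate assembler isoforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd


class FormatError(ValueError):
    """A file did not conform to its declared plain-text format."""


_NUC_RE = re.compile(r"^[ACGTN]+$")
# amino acids incl. ambiguity X and stop *
_PROT_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO*]+$")


@dataclass
class SequenceRecord:
    """A named sequence with a declared alphabet.

    Residues are stored uppercase; for nucleotide records U is mapped to T
    so a single internal alphabet serves both RNA- and DNA-style input.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        self.residues = self.residues.upper()
        if self.alphabet == "nucleotide":
            self.residues = self.residues.replace("U", "T")
            if not _NUC_RE.match(self.residues):
                raise ValueError(
                    f"record {self.id!r}: residues not nucleotide [ACGTN]"
                )
        elif self.alphabet == "protein":
            if not _PROT_RE.match(self.residues):
                raise ValueError(
                    f"record {self.id!r}: residues not amino-acid"
                )
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HitRecord:
    """One row of a pairwise similarity search (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: "
                "query_start > query_end"
            )
        if self.bit_score <= 0:
            raise ValueError("bit_score must be > 0")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass
class CountMatrix:
    """Gene x sample expected-count matrix plus per-sample metadata.

    ``values`` is a pandas DataFrame (genes as index, samples as columns);
    ``metadata`` is indexed by sample id with columns species / tissue /
    replicate.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.values.values < 0).any():
            raise ValueError("expected counts must be >= 0")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        for col in ("species", "tissue", "replicate"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks column {col!r}")
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class DifferentialResult:
    """One gene's differential-expression call.

    Sign convention: positive log2 fold change = higher in species A.
    ``significant`` is derived from the configured adjusted-p threshold.
    """

    gene_id: str
    log2_fold_change: float
    adjusted_p: float
    significant: bool

    @classmethod
    def from_padj(
        cls, gene_id: str, log2_fold_change: float, adjusted_p: float,
        threshold: float = 0.05,
    ) -> "DifferentialResult":
        return cls(gene_id, log2_fold_change, adjusted_p,
                   adjusted_p < threshold)


@dataclass
class TermAnnotation:
    """Mapping term id -> set of annotated gene ids.

    Terms with no annotated gene are dropped at construction.
    """

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: set(g) for t, g in self.terms.items() if g}

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "nucleotide"
               ) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords, preserving order.

    Residues are uppercased (U -> T for nucleotides).  Duplicate ids and
    structural problems raise FormatError naming the offending line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        parts = header.split(None, 1)
        if not parts:
            raise FormatError(f"line {header_line}: empty FASTA header")
        seq_id = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if seq_id in seen:
            raise FormatError(
                f"line {header_line}: duplicate sequence id {seq_id!r}")
        seq = "".join(chunks)
        if not seq:
            raise FormatError(
                f"line {header_line}: record {seq_id!r} has no residues")
        seen.add(seq_id)
        records.append(SequenceRecord(seq_id, seq, desc, alphabet))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
            else:
                if header is None:
                    raise FormatError(
                        f"line {line_no}: sequence data before first header")
                chunks.append(line.strip())
        flush(line_no + 1 if records or header else 1)
    if not records:
        raise FormatError("line 1: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular hits

_HIT_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def read_hits(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table; order preserved."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for row_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"row {row_no}: expected 12 columns, got {len(fields)}")
            try:
                typed = [t(v) for t, v in zip(_HIT_TYPES, fields)]
            except ValueError as exc:
                raise FormatError(f"row {row_no}: {exc}") from exc
            hits.append(HitRecord(*typed))
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:g}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start),
                        str(h.query_end),
                        str(h.subject_start),
                        str(h.subject_end),
                        f"{h.e_value:g}",
                        f"{h.bit_score:g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# transcript -> gene mapping

_ISOFORM_RE = re.compile(r"_i\d+$")


def transcript_to_gene(transcript_id: str) -> str:
    """Strip the assembler's trailing isoform suffix (``_i<k>``).

    Ids without the suffix pass through unchanged.
    """
    return _ISOFORM_RE.sub("", transcript_id)


# ---------------------------------------------------------------------------
# TSV tables

def read_count_matrix(counts_path: str | Path,
                      metadata_path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV plus a sample-metadata TSV."""
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return CountMatrix(values, meta)


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path,
                       metadata_path: str | Path) -> None:
    matrix.values.to_csv(counts_path, sep="\t")
    matrix.metadata.to_csv(metadata_path, sep="\t")


def read_differential_table(path: str | Path,
                            threshold: float = 0.05
                            ) -> list[DifferentialResult]:
    """Read a DE table (gene_id, log2fc, padj) produced by external fitting."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"DE table lacks columns {sorted(required - set(df.columns))}")
    return [
        DifferentialResult.from_padj(str(r.gene_id), float(r.log2fc),
                                     float(r.padj), threshold)
        for r in df.itertuples()
    ]


def write_differential_table(results: Iterable[DifferentialResult],
                             path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.log2_fold_change, r.adjusted_p) for r in results],
        columns=["gene_id", "log2fc", "padj"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_term_annotation(path: str | Path) -> TermAnnotation:
    """Read gene_id<TAB>term_id lines into a TermAnnotation."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for row_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"row {row_no}: expected gene_id<TAB>term_id")
            gene, term = fields[0], fields[1]
            terms.setdefault(term, set()).add(gene)
    return TermAnnotation(terms)


def write_term_annotation(annotation: TermAnnotation,
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation.terms):
            for gene in sorted(annotation.terms[term]):
                fh.write(f"{gene}\t{term}\n")
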