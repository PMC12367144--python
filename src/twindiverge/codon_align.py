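"""Protein-guided codon alignments and column-level preprocessing.

A pairwise global protein aligner (Needleman-Wunsch via Biopython's
PairwiseAligner) produces the protein alignment; back-translation expands
each amino acid into its source codon to give a codon alignment whose gaps
occur only as whole codons.  Preprocessing operations follow the column
rules used for downstream divergence and tree work: complete deletion of
columns containing gaps or unknown residues, block concatenation, codon
position partitioning, and first-of-window subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

GAP = "-"
_UNKNOWN_PROTEIN = {"X"}
_UNKNOWN_NUCLEOTIDE = {"N"}


@dataclass
class Alignment:
    """A rectangular gapped alignment.

    ``codon=True`` marks a nucleotide alignment whose columns are handled
    as whole codons (width divisible by 3, gaps only as ``---``).
    """

    ids: list[str]
    rows: list[str]
    codon: bool = False
    block_widths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: row widths {sorted(widths)}")
        if self.codon and self.width % 3 != 0:
            raise ValueError("codon alignment width not divisible by 3")
        if not self.block_widths:
            self.block_widths = [self.width]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)].replace(GAP, "")


def _make_aligner(matrix: str | None, match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # affine convention: a gap of length k costs open + k * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    id_a: str,
    protein_a: str,
    id_b: str,
    protein_b: str,
    matrix: str | None = "BLOSUM62",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Optimal global pairwise protein alignment with deterministic traceback.

    Default scoring is BLOSUM62 with affine gaps (open 10, extend 1); pass
    ``matrix=None`` to use simple match/mismatch scores.  An empty sequence
    yields an all-gap row against the other.
    """
    if not protein_a or not protein_b:
        longer = protein_a or protein_b
        gaps = GAP * len(longer)
        row_a = protein_a if protein_a else gaps
        row_b = protein_b if protein_b else gaps
        return Alignment([id_a, id_b], [row_a, row_b])
    aligner = _make_aligner(matrix, match, mismatch, gap_open, gap_extend)
    aln = aligner.align(protein_a, protein_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    return Alignment([id_a, id_b], [row_a, row_b])


def back_translate(protein_alignment: Alignment,
                   cds_by_id: dict[str, str]) -> Alignment:
    """Expand a gapped protein alignment into a codon alignment.

    Each amino acid is replaced by its source codon, each protein gap by
    ``---``.  The degapped protein row must translate its CDS exactly
    (terminal stop codons in the CDS are tolerated and dropped).
    """
    rows = []
    for seq_id, prot_row in zip(protein_alignment.ids,
                                protein_alignment.rows):
        cds = cds_by_id[seq_id]
        if len(cds) % 3 != 0:
            raise ValueError(f"{seq_id}: CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        n_aa = sum(1 for ch in prot_row if ch != GAP)
        if len(codons) == n_aa + 1 and str(Seq(codons[-1]).translate()) == "*":
            codons = codons[:-1]
        if len(codons) != n_aa:
            raise ValueError(
                f"{seq_id}: CDS has {len(codons)} codons but protein row "
                f"has {n_aa} residues")
        out = []
        k = 0
        for pos, ch in enumerate(prot_row, start=1):
            if ch == GAP:
                out.append(GAP * 3)
                continue
            codon = codons[k]
            aa = str(Seq(codon).translate())
            if aa != ch and ch != "X" and aa != "X":
                raise ValueError(
                    f"{seq_id}: codon {codon} translates to {aa!r} but "
                    f"protein alignment has {ch!r} at position {pos}")
            out.append(codon)
            k += 1
        rows.append("".join(out))
    return Alignment(list(protein_alignment.ids), rows, codon=True)


def _column_units(alignment: Alignment) -> int:
    return alignment.width // 3 if alignment.codon else alignment.width


def _unit(row: str, i: int, codon: bool) -> str:
    return row[3 * i : 3 * i + 3] if codon else row[i]


def delete_gap_unknown_columns(alignment: Alignment) -> Alignment:
    """Complete deletion of columns containing a gap or unknown residue.

    Unknown = X for proteins, any N for nucleotides.  For codon alignments
    whole codon columns are removed.
    """
    unknown = _UNKNOWN_NUCLEOTIDE if alignment.codon else _UNKNOWN_PROTEIN
    keep = []
    for i in range(_column_units(alignment)):
        ok = True
        for row in alignment.rows:
            unit = _unit(row, i, alignment.codon)
            if GAP in unit or any(ch in unknown for ch in unit):
                ok = False
                break
        if ok:
            keep.append(i)
    rows = [
        "".join(_unit(row, i, alignment.codon) for i in keep)
        for row in alignment.rows
    ]
    return Alignment(list(alignment.ids), rows, codon=alignment.codon)


def concatenate(alignments: list[Alignment]) -> Alignment:
    """Row-wise concatenation of blocks sharing one id set.

    Rows are matched by id (order taken from the first block); per-block
    widths are retained in ``block_widths`` for provenance.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    first = alignments[0]
    ref_ids = list(first.ids)
    rows = {i: [] for i in ref_ids}
    widths = []
    for block in alignments:
        missing = set(ref_ids) ^ set(block.ids)
        if missing:
            raise ValueError(f"id mismatch across blocks: {sorted(missing)}")
        if block.codon != first.codon:
            raise ValueError("cannot mix codon and residue blocks")
        for seq_id in ref_ids:
            rows[seq_id].append(block.rows[block.ids.index(seq_id)])
        widths.append(block.width)
    return Alignment(ref_ids, ["".join(rows[i]) for i in ref_ids],
                     codon=first.codon, block_widths=widths)


def partition_codon_positions(alignment: Alignment
                              ) -> tuple[Alignment, Alignment, Alignment]:
    """Split a codon alignment into its three codon-position alignments."""
    if alignment.width % 3 != 0:
        raise ValueError("alignment width not divisible by 3")
    parts = []
    for pos in range(3):
        rows = [row[pos::3] for row in alignment.rows]
        parts.append(Alignment(list(alignment.ids), rows, codon=False))
    return tuple(parts)


def subsample_first_of_window(alignment: Alignment, step: int = 4
                              ) -> Alignment:
    """Keep the first column of each ``step``-wide moving window.

    Columns 1, 1+step, 1+2*step, ... (1-based) are retained, so the output
    width is ceil(width / step).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if alignment.codon:
        keep = range(0, _column_units(alignment), step)
        rows = ["".join(row[3 * i : 3 * i + 3] for i in keep)
                for row in alignment.rows]
        return Alignment(list(alignment.ids), rows, codon=True)
    rows = [row[::step] for row in alignment.rows]
    return Alignment(list(alignment.ids), rows, codon=False)


def write_phylip_sequential(alignment: Alignment, path) -> None:
    """PHYLIP sequential writer for downstream tree tools."""
    with open(path, "w") as fh:
        fh.write(f" {len(alignment.ids)} {alignment.width}\n")
        for seq_id, row in zip(alignment.ids, alignment.rows):
            fh.write(f"{seq_id[:10]:<10}{row}\n")
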