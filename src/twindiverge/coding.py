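"""Open-reading-frame extraction from assembled transcripts.

ORFs are maximal stop-to-stop segments in all six frames; an initial ATG is
not required because assembled transcripts are frequently 5'-truncated.
The coding region of a transcript is then chosen by the longest-ORF rule,
a deliberate simplification of likelihood-based coding prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from ._genetic_code import STOP_CODONS
from .io_formats import SequenceRecord

DEFAULT_MIN_AA = 50


@dataclass(frozen=True)
class OrfRecord:
    """One candidate ORF.

    ``start``/``end`` are 1-based inclusive coordinates on the forward
    strand of the source transcript regardless of frame sign.  ``cds``
    retains a terminal stop codon when one bounds the ORF; ``protein`` is
    the translation of the sense codons only.
    """

    transcript_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    start: int
    end: int
    cds: str
    protein: str


def _orfs_in_strand(seq: str, transcript_id: str, sign: int,
                    seq_len: int, min_aa: int) -> list[OrfRecord]:
    out = []
    for offset in range(3):
        frame = sign * (offset + 1)
        codons = [seq[i : i + 3] for i in range(offset, len(seq) - 2, 3)]
        run_start = 0  # codon index where current stop-free run began
        for idx in range(len(codons) + 1):
            at_end = idx == len(codons)
            if at_end or codons[idx] in STOP_CODONS:
                n_sense = idx - run_start
                if n_sense >= min_aa:
                    cds_codons = codons[run_start:idx]
                    if not at_end:
                        cds_codons = cds_codons + [codons[idx]]  # keep stop
                    cds = "".join(cds_codons)
                    protein = str(Seq("".join(codons[run_start:idx])).translate())
                    # coordinates on this strand, 0-based
                    s0 = offset + 3 * run_start
                    e0 = s0 + len(cds)  # exclusive
                    if sign > 0:
                        start, end = s0 + 1, e0
                    else:
                        start, end = seq_len - e0 + 1, seq_len - s0
                    out.append(OrfRecord(transcript_id, frame, start, end,
                                         cds, protein))
                run_start = idx + 1
    return out


def find_orfs(record: SequenceRecord, min_aa: int = DEFAULT_MIN_AA
              ) -> list[OrfRecord]:
    """All maximal stop-to-stop ORFs of >= min_aa amino acids in six frames.

    ``min_aa`` counts sense codons; a bounding stop codon does not count
    toward the threshold but is retained in the reported CDS.
    """
    if record.alphabet != "nucleotide":
        raise ValueError("find_orfs requires a nucleotide record")
    fwd = record.residues
    rev = str(Seq(fwd).reverse_complement())
    orfs = _orfs_in_strand(fwd, record.id, +1, len(fwd), min_aa)
    orfs += _orfs_in_strand(rev, record.id, -1, len(fwd), min_aa)
    return orfs


def select_coding_orf(orfs: list[OrfRecord]) -> OrfRecord | None:
    """The longest ORF; ties go to the 5'-most start on the + strand, then
    to the + strand over the - strand."""
    if not orfs:
        return None
    return min(
        orfs,
        key=lambda o: (-len(o.protein), 0 if o.frame > 0 else 1, o.start),
    )


def strip_stop(cds: str) -> str:
    """Remove a terminal stop codon (TAA/TAG/TGA) if present."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds
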