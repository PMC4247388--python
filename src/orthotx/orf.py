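"""Open-reading-frame extraction and reference-ORF selection.

A *reference ORF* is the representative coding sequence chosen for a gene:
among the gene's transcripts the longest transcript (by nucleotide length)
is kept, and within it the longest complete ORF (ATG through an in-frame
stop, no internal stops) becomes the reference. ORFs are searched on both
strands because de novo assembled transcripts have unknown orientation.

Coordinates are 0-based half-open on the *reported strand*: for a
minus-strand ORF, ``start``/``end`` index into the reverse complement of
the input sequence. Human-facing reports convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
START_CODON = "ATG"
STOP_CODONS = {"TAA", "TAG", "TGA"}


class SequenceError(ValueError):
    """Raised for sequences over an illegal alphabet or malformed CDS."""


@dataclass(frozen=True)
class OrfInterval:
    """A complete ORF located on a transcript.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    reported strand (minus-strand coordinates index the reverse
    complement); ``end - start`` includes the stop codon.
    """

    transcript_id: str
    start: int
    end: int
    frame: int
    strand: str
    has_start: bool = True
    has_stop: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ORF interval must have end > start")
        if self.has_start and self.has_stop and (self.end - self.start) % 3:
            raise ValueError("complete ORF length must be divisible by 3")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferenceORF:
    """The validated coding sequence representing one gene.

    Construction asserts the four codon invariants: length divisible by
    three, leading ATG, terminal stop codon, and no internal stops.
    ``protein_seq`` is the standard-table translation without the stop.
    """

    gene_id: str
    transcript_id: str
    nucleotide_seq: str
    protein_seq: str

    def __post_init__(self) -> None:
        seq = self.nucleotide_seq
        validate_cds(seq)
        expected = str(Seq(seq[:-3]).translate(table=1))
        if expected != self.protein_seq:
            raise SequenceError("protein_seq does not match translation of nucleotide_seq")


@dataclass(frozen=True)
class OrfRejection:
    """Returned instead of a ReferenceORF when a gene has no valid ORF."""

    gene_id: str
    transcript_id: str
    reason: str


def validate_cds(seq: str) -> None:
    """Check the four codon invariants of a complete CDS; raise naming the violation."""
    if len(seq) % 3:
        raise SequenceError("CDS length not divisible by 3")
    if not seq.startswith(START_CODON):
        raise SequenceError("CDS does not begin with ATG")
    if seq[-3:] not in STOP_CODONS:
        raise SequenceError("CDS does not end with a stop codon")
    for i in range(3, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise SequenceError(f"internal stop codon at nucleotide {i}")


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"illegal characters in sequence: {sorted(bad)}")
    return seq


def _codon_ok(codon: str) -> bool:
    return "N" not in codon


def _scan_strand(seq: str, strand: str, transcript_id: str, min_protein_len: int) -> list[OrfInterval]:
    orfs = []
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []  # nested ATGs sharing the next stop
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if not _codon_ok(codon):
                # untranslatable codon: no running ORF can span it
                open_starts.clear()
                continue
            if codon in STOP_CODONS:
                for s in open_starts:
                    if (i - s) // 3 >= min_protein_len:
                        orfs.append(OrfInterval(transcript_id, s, i + 3, frame, strand))
                open_starts.clear()
            elif codon == START_CODON:
                open_starts.append(i)
    return orfs


def find_orfs(seq: str, min_protein_len: int = 1, transcript_id: str = "") -> list[OrfInterval]:
    """All complete ORFs (ATG..stop) in six frames with protein length >= min_protein_len.

    Sorted by descending nucleotide length, then '+' before '-', then
    ascending start. A codon containing N is never a start or stop and
    invalidates any ORF that would span it.
    """
    if min_protein_len < 1:
        raise ValueError("min_protein_len must be >= 1")
    if not seq:
        return []
    seq = _check_alphabet(seq)
    rc = str(Seq(seq).reverse_complement())
    orfs = _scan_strand(seq, "+", transcript_id, min_protein_len)
    orfs += _scan_strand(rc, "-", transcript_id, min_protein_len)
    orfs.sort(key=lambda o: (-o.length, o.strand, o.start))
    return orfs


def translate_orf(seq: str, orf: OrfInterval) -> str:
    """Protein for a complete ORF located by :func:`find_orfs` (stop removed)."""
    seq = _check_alphabet(seq)
    if orf.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    sub = seq[orf.start : orf.end]
    return str(Seq(sub[:-3]).translate(table=1))


def orf_nucleotides(seq: str, orf: OrfInterval) -> str:
    seq = _check_alphabet(seq)
    if orf.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq[orf.start : orf.end]


def select_reference_orf(
    gene_id: str,
    transcripts: Sequence[tuple[str, str]],
    min_protein_len: int = 100,
) -> ReferenceORF | OrfRejection:
    """Pick the gene's representative CDS.

    The longest *transcript* is kept (ties: lexicographically smaller
    transcript id), and its longest complete ORF becomes the reference —
    transcript length, not ORF length, selects the representative. A gene
    whose chosen transcript holds no complete ORF of the minimum length
    yields an :class:`OrfRejection` value, not an exception.
    """
    if not transcripts:
        raise ValueError("at least one transcript required")
    tid, seq = min(transcripts, key=lambda t: (-len(t[1]), t[0]))
    orfs = find_orfs(seq, min_protein_len=min_protein_len, transcript_id=tid)
    if not orfs:
        return OrfRejection(gene_id, tid, "no complete ORF")
    best = orfs[0]
    nt = orf_nucleotides(seq, best)
    return ReferenceORF(gene_id, tid, nt, translate_orf(seq, best))


def select_reference_orfs(
    genes: dict[str, list[tuple[str, str]]], min_protein_len: int = 100
) -> tuple[dict[str, ReferenceORF], list[OrfRejection]]:
    """Vector form of :func:`select_reference_orf` over a gene→transcripts mapping."""
    kept: dict[str, ReferenceORF] = {}
    rejected: list[OrfRejection] = []
    for gene_id in sorted(genes):
        res = select_reference_orf(gene_id, genes[gene_id], min_protein_len)
        if isinstance(res, ReferenceORF):
            kept[gene_id] = res
        else:
            rejected.append(res)
    return kept, rejected
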