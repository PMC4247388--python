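"""Reciprocal-best-hit ortholog pairs and sets, with refinement filters.

An *ortholog pair* links a reference gene's ORF to one species' transcript
when the two are mutual best hits; an *ortholog set* is declared when such
a pair exists in every species of the panel. Declared sets are then
refined: at least 80% of member sequences must carry both a start and a
stop codon, and every member's coding length must lie within +/-50% of the
set's median length (bounds inclusive).

Scoring is a deterministic semi-global (free end gaps) affine alignment —
BLOSUM62 for proteins, +2/-3 match/mismatch for nucleotides — standing in
for an external similarity search at desk scale. Precomputed 12-column
tabular search output can be ingested instead; the decision rules applied
downstream are identical for either source.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .orf import START_CODON, STOP_CODONS, find_orfs, orf_nucleotides

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
NUCLEOTIDE_ALPHABET = set("ACGTN")

BLAST_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class SimilarityHit:
    """One scored query→subject comparison.

    ``identity`` is matches over all alignment columns of the full
    pairwise alignment; ``query_coverage`` is the fraction of query
    residues aligned to subject residues.
    """

    query_id: str
    subject_id: str
    score: float
    identity: float
    query_coverage: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError("query_coverage must be in [0, 1]")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class OrthologPair:
    reference_gene_id: str
    species_id: str
    member_transcript_id: str


@dataclass(frozen=True)
class OrthologMember:
    """One species' coding sequence inside an ortholog set."""

    species_id: str
    transcript_id: str
    cds: str
    has_start: bool
    has_stop: bool

    @property
    def length(self) -> int:
        return len(self.cds)


@dataclass
class OrthologSet:
    reference_gene_id: str
    members: dict[str, OrthologMember] = field(default_factory=dict)
    status: str = "incomplete"  # complete | incomplete | refined-out


@dataclass(frozen=True)
class RefinementReport:
    reference_gene_id: str
    kept: bool
    startstop_fraction: float
    median_length: float
    offending_members: tuple[tuple[str, str], ...]  # (species_id, reason)


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    elif mode == "nucleotide":
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # free end gaps: transcripts carry UTRs around the homologous core
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNERS: dict[str, Align.PairwiseAligner] = {}


def score_pair(
    a: str, b: str, mode: str = "protein",
    query_id: str = "query", subject_id: str = "subject",
) -> SimilarityHit:
    """Deterministic semi-global affine-gap alignment of ``a`` (query) vs ``b``."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alphabet = PROTEIN_ALPHABET if mode == "protein" else NUCLEOTIDE_ALPHABET
    for name, seq in (("query", a), ("subject", b)):
        bad = set(seq.upper()) - alphabet
        if bad:
            raise ValueError(f"{name} has characters outside {mode} alphabet: {sorted(bad)}")
    a, b = a.upper(), b.upper()
    if mode not in _ALIGNERS:
        _ALIGNERS[mode] = _make_aligner(mode)
    aligner = _ALIGNERS[mode]
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    aligned_query = counts.identities + counts.mismatches
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(aln.score),
        identity=counts.identities / columns if columns else 0.0,
        query_coverage=aligned_query / len(a),
    )


Scorer = Callable[[str, str], float]


def make_scorer(mode: str) -> Scorer:
    return lambda q, s: score_pair(q, s, mode=mode).score


def best_hits(
    queries: Mapping[str, str], subjects: Mapping[str, str], scorer: Scorer
) -> dict[str, str]:
    """Each query's single highest-scoring subject; ties go to the
    lexicographically smaller subject id. Mutuality is *not* checked here."""
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    result: dict[str, str] = {}
    subject_ids = sorted(subjects)
    for qid in queries:
        best_sid, best_score = None, -math.inf
        for sid in subject_ids:
            s = scorer(queries[qid], subjects[sid])
            if s > best_score:
                best_sid, best_score = sid, s
        result[qid] = best_sid
    return result


def reciprocal_best_pairs(
    ref_orfs: Mapping[str, str],
    species_transcripts: Mapping[str, str],
    scorer: Scorer,
    species_id: str = "species",
) -> list[OrthologPair]:
    """Ortholog pairs: reference gene and transcript that are mutual best hits."""
    fwd = best_hits(ref_orfs, species_transcripts, scorer)
    rev = best_hits(species_transcripts, ref_orfs, lambda q, s: scorer(s, q))
    pairs = [
        OrthologPair(gid, species_id, tid)
        for gid, tid in fwd.items()
        if rev.get(tid) == gid
    ]
    pairs.sort(key=lambda p: p.reference_gene_id)
    return pairs


def declare_ortholog_sets(
    pairs: Iterable[OrthologPair],
    panel: Sequence[str],
    transcripts: Mapping[str, Mapping[str, str]] | None = None,
) -> list[OrthologSet]:
    """Group pairs by reference gene; a set is complete iff every panel
    species contributed a pair. When ``transcripts`` (species → id → seq)
    is given, members are populated with extracted coding sequences and
    start/stop validity flags; incomplete sets are retained for reporting.
    """
    panel = list(panel)
    by_gene: dict[str, dict[str, OrthologPair]] = {}
    for p in pairs:
        by_gene.setdefault(p.reference_gene_id, {})[p.species_id] = p
    sets = []
    for gid in sorted(by_gene):
        members: dict[str, OrthologMember] = {}
        for sp, pair in by_gene[gid].items():
            if transcripts is not None:
                seq = transcripts[sp][pair.member_transcript_id]
                cds, has_start, has_stop = extract_member_cds(seq)
                members[sp] = OrthologMember(sp, pair.member_transcript_id, cds, has_start, has_stop)
            else:
                members[sp] = OrthologMember(sp, pair.member_transcript_id, "", False, False)
        status = "complete" if set(by_gene[gid]) >= set(panel) else "incomplete"
        sets.append(OrthologSet(gid, members, status))
    return sets


def extract_member_cds(transcript: str) -> tuple[str, bool, bool]:
    """Best coding region of a transcript with start/stop validity flags.

    Candidates are complete ORFs and open-ended readings (ATG to frame end
    without a stop, frame start to first stop without an ATG, or a whole
    stop-free frame); the longest wins, complete ORFs preferred on ties.
    Corrupted transcripts thus still yield a member carrying honest
    has_start/has_stop flags for refinement.
    """
    transcript = transcript.upper()
    candidates: list[tuple[int, int, str, bool, bool]] = []  # (-len, pref, seq, start, stop)
    for orf in find_orfs(transcript, min_protein_len=1):
        candidates.append((-orf.length, 0, orf_nucleotides(transcript, orf), True, True))
    from Bio.Seq import Seq

    for strand, seq in (("+", transcript), ("-", str(Seq(transcript).reverse_complement()))):
        for frame in range(3):
            codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
            stop_idx = [i for i, c in enumerate(codons) if c in STOP_CODONS]
            start_idx = [i for i, c in enumerate(codons) if c == START_CODON]
            # ATG .. frame end, no stop after it
            for si in start_idx:
                if not any(t > si for t in stop_idx):
                    sub = "".join(codons[si:])
                    if sub:
                        candidates.append((-len(sub), 1, sub, True, False))
                    break
            # frame start .. first stop, no ATG before it
            if stop_idx:
                t = stop_idx[0]
                if not any(s < t for s in start_idx):
                    sub = "".join(codons[: t + 1])
                    if sub:
                        candidates.append((-len(sub), 2, sub, False, True))
            elif not start_idx and codons:
                candidates.append((-len(codons) * 3, 3, "".join(codons), False, False))
    if not candidates:
        return transcript, False, False
    candidates.sort()
    _, _, seq, has_start, has_stop = candidates[0]
    return seq, has_start, has_stop


def refine_ortholog_set(
    s: OrthologSet,
    min_startstop_fraction: float = 0.8,
    length_window: float = 0.5,
) -> RefinementReport:
    """Apply the two set-level refinement filters.

    Kept iff the fraction of members with both start and stop codons is at
    least ``min_startstop_fraction`` *and* every member's coding length is
    within ``+/- length_window`` of the set's median length, bounds
    inclusive. Median of an even member count is the mean of the two
    central values; lengths are nucleotides of the coding sequence.
    """
    if s.status != "complete":
        raise ValueError("refinement applies to complete ortholog sets")
    members = [s.members[sp] for sp in sorted(s.members)]
    n = len(members)
    with_both = sum(1 for m in members if m.has_start and m.has_stop)
    frac = with_both / n
    med = float(statistics.median(m.length for m in members))
    lo, hi = (1 - length_window) * med, (1 + length_window) * med
    offending: list[tuple[str, str]] = []
    if frac < min_startstop_fraction:
        offending += [
            (m.species_id, "startstop") for m in members if not (m.has_start and m.has_stop)
        ]
    offending += [
        (m.species_id, "length") for m in members if not (lo <= m.length <= hi)
    ]
    kept = frac >= min_startstop_fraction and not any(r == "length" for _, r in offending)
    if not kept:
        s.status = "refined-out"
    return RefinementReport(s.reference_gene_id, kept, frac, med, tuple(offending))


def assign_reference_protein(
    candidate_peptides: Mapping[str, str],
    reference_proteome: Mapping[str, str],
    hits: Mapping[str, Sequence[SimilarityHit]] | None = None,
    max_evalue: float = 1e-5,
    min_identity: float = 0.5,
    min_query_coverage: float = 0.75,
) -> dict[str, str | None]:
    """Annotate peptides by their best reference-proteome match.

    A hit qualifies only with E-value <= ``max_evalue`` (when an E-value is
    present), identity strictly > ``min_identity`` and query coverage
    strictly > ``min_query_coverage``; the highest-scoring qualifying hit
    wins, otherwise the peptide is unassigned (None). When ``hits`` is not
    supplied, all-vs-all built-in protein scoring is used (no E-values).
    """
    if hits is None:
        hits = {
            pid: [
                score_pair(pseq, rseq, mode="protein", query_id=pid, subject_id=rid)
                for rid, rseq in reference_proteome.items()
            ]
            for pid, pseq in candidate_peptides.items()
        }
    out: dict[str, str | None] = {}
    for pid in candidate_peptides:
        qualifying = [
            h
            for h in hits.get(pid, [])
            if (h.evalue is None or h.evalue <= max_evalue)
            and h.identity > min_identity
            and h.query_coverage > min_query_coverage
        ]
        if qualifying:
            best = max(qualifying, key=lambda h: (h.score, h.subject_id))
            out[pid] = best.subject_id
        else:
            out[pid] = None
    return out


def read_blast_tab(path, query_lengths: Mapping[str, int]) -> dict[str, list[SimilarityHit]]:
    """Ingest standard 12-column tabular search output into SimilarityHits.

    ``score`` is the bit score, ``identity`` = pident/100, and
    ``query_coverage`` = aligned query span / query length.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_TAB_COLUMNS, comment="#")
    hits: dict[str, list[SimilarityHit]] = {}
    for row in df.itertuples(index=False):
        qlen = query_lengths[row.qseqid]
        span = abs(int(row.qend) - int(row.qstart)) + 1
        hits.setdefault(row.qseqid, []).append(
            SimilarityHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                score=float(row.bitscore),
                identity=float(row.pident) / 100.0,
                query_coverage=min(1.0, span / qlen),
                evalue=float(row.evalue),
            )
        )
    return hits


def best_hits_from_table(hits: Mapping[str, Sequence[SimilarityHit]]) -> dict[str, str]:
    """Best subject per query from ingested tabular hits, by descending bit
    score, ties to the lexicographically smaller subject id."""
    return {
        qid: min(hs, key=lambda h: (-h.score, h.subject_id)).subject_id
        for qid, hs in hits.items()
        if hs
    }
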