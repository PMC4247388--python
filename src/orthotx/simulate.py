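"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators, all pure functions of their inputs and a seed:

* coding sequences evolved along a rooted phylogeny by nucleotide-level
  substitution, with an optional frame-preserving constraint (no created
  internal stops, no destroyed start/stop codons);
* transcripts wrapping those CDS in random UTRs, with configurable
  corruptions (lost start codon, lost stop codon, truncation) that
  exercise the downstream ORF and refinement filters;
* negative-binomial count matrices with planted log2 fold-changes for the
  differential-expression stage.

The substitution process makes no evolutionary-realism claim (no rate
heterogeneity, no dN/dS); it exists to verify set logic, so per-branch
random streams are derived by stable hashing of (seed, gene, node) and
adding a gene never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .orf import START_CODON, STOP_CODONS, SequenceError, validate_cds
from .residues import RESIDUE_GROUPS, ResidueClassModel, DEFAULT_MODEL

AMINO_ACIDS = sorted(RESIDUE_GROUPS)
NUCLEOTIDES = "ACGT"
SENSE_CODONS = [
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
]


class PlantingError(ValueError):
    """Raised when a requested lineage-unique substitution cannot exist."""


def stable_hash(*parts) -> int:
    """Deterministic 63-bit stream key from arbitrary labelled parts."""
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:8], "big") >> 1


@dataclass
class PhylogenyModel:
    """A rooted tree with branch lengths in expected substitutions per site."""

    newick_text: str
    focal_species: str
    tree: dendropy.Tree = field(init=False, repr=False)
    species_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tree = dendropy.Tree.get(data=self.newick_text, schema="newick")
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        if self.focal_species not in labels:
            raise ValueError(f"focal species {self.focal_species!r} is not a leaf")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be >= 0")
        self.species_ids = sorted(labels)


def _node_key(node: dendropy.Node) -> str:
    return ",".join(sorted(l.taxon.label for l in node.leaf_iter()))


@dataclass(frozen=True)
class EvolutionConfig:
    per_site_rate: float = 1.0
    preserve_frame: bool = True
    seed: int = 0
    p_drop_start: float = 0.0
    p_drop_stop: float = 0.0
    p_truncate: float = 0.0
    truncate_fraction: float = 0.4
    utr_len_range: tuple[int, int] = (20, 150)

    def __post_init__(self) -> None:
        if self.per_site_rate < 0:
            raise ValueError("per_site_rate must be >= 0")
        for name in ("p_drop_start", "p_drop_stop", "p_truncate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.truncate_fraction < 1.0):
            raise ValueError("truncate_fraction must be in (0, 1)")


def random_cds(n_codons: int, seed: int) -> str:
    """A valid CDS: ATG, ``n_codons - 2`` random sense codons, random stop."""
    if n_codons < 2:
        raise ValueError("need at least start + stop codons")
    rng = np.random.default_rng(stable_hash(seed, "root_cds"))
    body = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons - 2))
    stop = str(rng.choice(sorted(STOP_CODONS)))
    return START_CODON + body + stop


def _frame_ok(seq: list[str], site: int, new_base: str) -> bool:
    ci = site // 3
    codon = seq[3 * ci : 3 * ci + 3]
    codon[site % 3] = new_base
    codon = "".join(codon)
    n_codons = len(seq) // 3
    if ci == 0:
        return codon == START_CODON
    if ci == n_codons - 1:
        return codon in STOP_CODONS
    return codon not in STOP_CODONS


def _mutate_cds(seq: str, n_events: int, rng: np.random.Generator, preserve_frame: bool) -> str:
    chars = list(seq)
    applied = 0
    attempts = 0
    max_attempts = 20 * n_events + 100
    while applied < n_events and attempts < max_attempts:
        attempts += 1
        site = int(rng.integers(len(chars)))
        new_base = NUCLEOTIDES[int(rng.integers(4))]
        if new_base == chars[site]:
            continue
        if preserve_frame and not _frame_ok(chars, site, new_base):
            continue
        chars[site] = new_base
        applied += 1
    return "".join(chars)


def evolve_cds(
    root_cds: str,
    tree: PhylogenyModel,
    cfg: EvolutionConfig,
    gene_id: str = "gene",
) -> tuple[dict[str, str], dict[str, str]]:
    """Evolve a root CDS along the tree; returns (CDS per leaf, protein per leaf).

    Substitutions are proposed uniformly at the nucleotide level and, when
    ``preserve_frame`` is set, rejected if they would create an internal
    stop or destroy the start/stop codon. Per-branch event counts are
    Poisson(branch_length × per_site_rate × length). Identical seeds give
    identical output.
    """
    try:
        validate_cds(root_cds.upper())
    except SequenceError as e:
        raise SequenceError(f"root CDS invalid: {e}") from e
    root_cds = root_cds.upper()
    seqs: dict[dendropy.Node, str] = {tree.tree.seed_node: root_cds}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        blen = node.edge.length or 0.0
        rng = np.random.default_rng(stable_hash(cfg.seed, gene_id, "cds", _node_key(node)))
        n_events = int(rng.poisson(blen * cfg.per_site_rate * len(parent_seq)))
        seqs[node] = _mutate_cds(parent_seq, n_events, rng, cfg.preserve_frame)
    cds_map = {leaf.taxon.label: seqs[leaf] for leaf in tree.tree.leaf_node_iter()}
    proteins = {
        sp: str(Seq(s[:-3]).translate(table=1)) if cfg.preserve_frame
        else str(Seq(s).translate(table=1))
        for sp, s in cds_map.items()
    }
    return cds_map, proteins


def _mutate_protein(
    seq: str,
    n_events: int,
    rng: np.random.Generator,
    within_group_only: bool,
    model: ResidueClassModel,
) -> str:
    chars = list(seq)
    groups: dict[str, list[str]] = {}
    for aa, g in model.groups.items():
        groups.setdefault(g, []).append(aa)
    for g in groups:
        groups[g].sort()
    for _ in range(n_events):
        site = int(rng.integers(len(chars)))
        cur = chars[site]
        if within_group_only:
            pool = [a for a in groups[model.groups[cur]] if a != cur]
            if not pool:
                continue  # singleton group: no within-group move exists
        else:
            pool = [a for a in AMINO_ACIDS if a != cur]
        chars[site] = pool[int(rng.integers(len(pool)))]
    return "".join(chars)


def evolve_protein(
    root_protein: str,
    tree: PhylogenyModel,
    per_site_rate: float,
    seed: int,
    within_group_only: bool = False,
    gene_id: str = "gene",
    model: ResidueClassModel = DEFAULT_MODEL,
) -> dict[str, str]:
    """Evolve a protein along the tree by per-site residue replacement.

    With ``within_group_only`` every replacement stays inside the
    residue's four-class chemical group, so no column can ever acquire a
    lineage-unique class — the scanner's guaranteed-negative condition.
    """
    seqs: dict[dendropy.Node, str] = {tree.tree.seed_node: root_protein.upper()}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        blen = node.edge.length or 0.0
        rng = np.random.default_rng(stable_hash(seed, gene_id, "prot", _node_key(node)))
        n_events = int(rng.poisson(blen * per_site_rate * len(parent_seq)))
        seqs[node] = _mutate_protein(parent_seq, n_events, rng, within_group_only, model)
    return {leaf.taxon.label: seqs[leaf] for leaf in tree.tree.leaf_node_iter()}


def evolve_protein_columns(
    tree: PhylogenyModel, n_columns: int, per_site_rate: float, seed: int
) -> list[dict[str, str]]:
    """Independent neutral columns: a random root residue per column evolved
    along the tree with unrestricted replacement."""
    rng = np.random.default_rng(stable_hash(seed, "root_protein"))
    root = "".join(rng.choice(AMINO_ACIDS) for _ in range(n_columns))
    leaf_seqs = evolve_protein(root, tree, per_site_rate, seed, within_group_only=False)
    return [{sp: leaf_seqs[sp][c] for sp in leaf_seqs} for c in range(n_columns)]


@dataclass(frozen=True)
class PlantedSubstitutionTruth:
    gene_id: str
    species_id: str
    reference_position: int  # 1-based in the reference protein
    background_residues: frozenset[str]
    planted_residue: str
    class_change: tuple[frozenset[str], str]  # others' groups -> focal group
    homogenized: bool

    def __post_init__(self) -> None:
        focal_group = RESIDUE_GROUPS[self.planted_residue]
        bg_groups = {RESIDUE_GROUPS[r] for r in self.background_residues}
        if focal_group in bg_groups:
            raise ValueError("planted residue's group must be absent from the background")


def plant_unique_substitution(
    seqs: Mapping[str, str],
    focal: str,
    position: int,
    target_group: str,
    seed: int = 0,
    gene_id: str = "gene",
    background_group: str | None = None,
    model: ResidueClassModel = DEFAULT_MODEL,
) -> tuple[dict[str, str], PlantedSubstitutionTruth]:
    """Plant a lineage-unique class change at a 1-based column of gapless
    protein sequences.

    The focal sequence receives a residue drawn from ``target_group``. If
    any non-focal residue already belongs to the target group the column
    is first homogenized to a random residue from a single non-target
    group (recorded in the truth). Returns the modified sequences and a
    :class:`PlantedSubstitutionTruth` the scanner must recover.
    """
    groups: dict[str, list[str]] = {}
    for aa, g in model.groups.items():
        groups.setdefault(g, []).append(aa)
    for g in groups:
        groups[g].sort()
    if target_group not in groups:
        raise PlantingError(f"unknown residue group {target_group!r}")
    if background_group is not None:
        if background_group == target_group:
            raise PlantingError(
                "background group cannot equal the target group: the planted "
                "class would not be unique to the focal lineage"
            )
        if background_group not in groups:
            raise PlantingError(f"unknown residue group {background_group!r}")
    if focal not in seqs:
        raise ValueError(f"focal species {focal!r} missing")
    col = position - 1
    for sp, s in seqs.items():
        if not (0 <= col < len(s)):
            raise ValueError(f"position {position} outside sequence of {sp!r}")
    rng = np.random.default_rng(stable_hash(seed, gene_id, "plant", position, target_group))
    out = dict(seqs)
    others = {sp: s[col] for sp, s in seqs.items() if sp != focal}
    needs_homogenize = background_group is not None or any(
        model.groups[r] == target_group for r in others.values()
    )
    if needs_homogenize:
        if background_group is None:
            candidates = sorted(g for g in groups if g != target_group)
            background_group = candidates[int(rng.integers(len(candidates)))]
        bg_residue = groups[background_group][int(rng.integers(len(groups[background_group])))]
        for sp in others:
            out[sp] = out[sp][:col] + bg_residue + out[sp][col + 1 :]
        background = frozenset({bg_residue})
    else:
        background = frozenset(others.values())
    pool = groups[target_group]
    planted = pool[int(rng.integers(len(pool)))]
    out[focal] = out[focal][:col] + planted + out[focal][col + 1 :]
    truth = PlantedSubstitutionTruth(
        gene_id=gene_id,
        species_id=focal,
        reference_position=position,
        background_residues=background,
        planted_residue=planted,
        class_change=(frozenset(model.groups[r] for r in background), target_group),
        homogenized=needs_homogenize,
    )
    return out, truth


@dataclass(frozen=True)
class TranscriptTruth:
    species_id: str
    transcript_id: str
    orf_valid: bool
    corruptions: tuple[str, ...]


def make_transcripts(
    cds_map: Mapping[str, str],
    cfg: EvolutionConfig,
    gene_id: str = "gene",
) -> tuple[dict[str, str], dict[str, TranscriptTruth]]:
    """Wrap each species' CDS in random UTRs and apply configured corruptions.

    Uncorrupted transcripts are guaranteed (by redraw of UTRs) to return
    their embedded CDS under the longest-coding-candidate rule; the truth
    table marks per-transcript ORF validity.
    """
    if not cds_map:
        raise ValueError("cds_map must be non-empty")
    from .orthologs import extract_member_cds

    lo, hi = cfg.utr_len_range
    transcripts: dict[str, str] = {}
    truth: dict[str, TranscriptTruth] = {}
    for sp in sorted(cds_map):
        cds = cds_map[sp].upper()
        rng = np.random.default_rng(stable_hash(cfg.seed, gene_id, "tx", sp))
        corruptions: list[str] = []
        if rng.random() < cfg.p_drop_start:
            corruptions.append("drop_start")
        if rng.random() < cfg.p_drop_stop:
            corruptions.append("drop_stop")
        if rng.random() < cfg.p_truncate:
            corruptions.append("truncate")
        body = cds
        if "truncate" in corruptions:
            n_keep = max(3, 3 * int(len(body) * cfg.truncate_fraction / 3))
            body = body[:n_keep]
        if "drop_start" in corruptions and body.startswith(START_CODON):
            body = "G" + body[1:]
        if "drop_stop" in corruptions and body[-3:] in STOP_CODONS:
            body = body[:-3] + _sense_replacement(body[-3:])
        for _ in range(50):
            utr5 = _random_utr(rng, lo, hi)
            if "truncate" in corruptions:
                utr3 = ""  # a truncated transcript simply ends mid-CDS
            else:
                utr3 = _random_utr(rng, lo, hi, stop_free_frame="drop_stop" in corruptions)
            tx = utr5 + body + utr3
            if corruptions:
                break
            if extract_member_cds(tx)[0] == cds:
                break
        else:
            raise RuntimeError("could not embed CDS recoverably; widen UTR range")
        tid = f"{gene_id}.{sp}.t1"
        transcripts[sp] = tx
        truth[sp] = TranscriptTruth(sp, tid, orf_valid=not corruptions, corruptions=tuple(corruptions))
    return transcripts, truth


def _sense_replacement(stop: str) -> str:
    return {"TAA": "TAC", "TAG": "TAC", "TGA": "TGC"}[stop]


def _random_utr(rng: np.random.Generator, lo: int, hi: int, stop_free_frame: bool = False) -> str:
    n = int(rng.integers(lo, hi + 1))
    if not stop_free_frame:
        return "".join(NUCLEOTIDES[int(b)] for b in rng.integers(0, 4, size=n))
    # continue the upstream reading frame without a stop codon
    n_codons = (n + 2) // 3
    return "".join(
        SENSE_CODONS[int(i)] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)
    )[:n]


@dataclass(frozen=True)
class CountSimConfig:
    n_genes: int
    samples: tuple[tuple[str, str, str], ...]  # (sample_id, species_id, group)
    library_sizes: tuple[int, ...]
    nb_dispersion: float = 0.05
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.samples) != len(self.library_sizes):
            raise ValueError("one library size per sample required")
        if any(s <= 0 for s in self.library_sizes):
            raise ValueError("library sizes must be positive")
        groups = [g for _, _, g in self.samples]
        for g in ("focal", "other"):
            if groups.count(g) < 2:
                raise ValueError(f"need >= 2 samples in group {g!r}")
        if set(g for _, _, g in self.samples) - {"focal", "other"}:
            raise ValueError("groups must be 'focal' or 'other'")
        bad = set(self.planted_effects) - set(gene_ids(self.n_genes))
        if bad:
            raise ValueError(f"planted effects for unknown genes: {sorted(bad)}")

    @property
    def nb_dispersion_valid(self) -> float:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        return self.nb_dispersion


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


def simulate_counts(cfg: CountSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with planted focal-vs-other fold-changes.

    Baseline relative abundances are drawn once (log-normal, renormalized
    per sample so the expected column sum equals the library size); focal
    samples multiply planted genes' abundance by 2^effect. Returns
    ``(counts, labels, truth)``: counts genes × samples, labels with
    sample/species/group, truth with the planted log2 effects.
    """
    disp = cfg.nb_dispersion_valid
    genes = gene_ids(cfg.n_genes)
    rng = np.random.default_rng(stable_hash(cfg.seed, "counts", cfg.n_genes))
    base = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_genes)
    base /= base.sum()
    effects = np.array([cfg.planted_effects.get(g, 0.0) for g in genes])
    cols = {}
    for (sid, _, group), lib in zip(cfg.samples, cfg.library_sizes):
        w = base * np.exp2(effects) if group == "focal" else base
        w = w / w.sum()
        mu = lib * w
        srng = np.random.default_rng(stable_hash(cfg.seed, "counts", "sample", sid))
        if disp < 1e-8:
            cols[sid] = srng.poisson(mu)
        else:
            r = 1.0 / disp
            p = r / (r + mu)
            cols[sid] = srng.negative_binomial(r, p)
    counts = pd.DataFrame(cols, index=genes)
    labels = pd.DataFrame(
        [(sid, sp, g) for sid, sp, g in cfg.samples],
        columns=["sample_id", "species_id", "group"],
    ).set_index("sample_id")
    truth = pd.DataFrame({"log2_effect": effects}, index=genes)
    return counts, labels, truth
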