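"""Lineage-unique amino-acid detection over a four-class residue grouping.

Residues are partitioned into acidic (E, D), basic (K, H, R), cysteine (C)
and "other" (the remaining 14). A column of a cross-species protein
alignment is called when the focal species carries a residue whose class
is absent from every informative residue of the other species — e.g. the
focal lineage holds an arginine where all other species hold S/T/Q. Calls
are reported with 1-based coordinates in the designated reference species'
ungapped sequence and a compact change string such as ``STQ174R``.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import beta

RESIDUE_GROUPS: dict[str, str] = {}
for _grp, _res in (
    ("acidic", "ED"),
    ("basic", "KHR"),
    ("cysteine", "C"),
    ("other", "STYNQGAVLIFPMW"),
):
    for _aa in _res:
        RESIDUE_GROUPS[_aa] = _grp

STANDARD_AMINO_ACIDS = frozenset(RESIDUE_GROUPS)
assert len(STANDARD_AMINO_ACIDS) == 20

GAP = "-"
UNKNOWN = "X"


@dataclass(frozen=True)
class ResidueClassModel:
    """The four-class partition of the 20 standard amino acids."""

    groups: Mapping[str, str] = field(default_factory=lambda: dict(RESIDUE_GROUPS))

    def __post_init__(self) -> None:
        if set(self.groups) != STANDARD_AMINO_ACIDS:
            raise ValueError("residue class model must cover exactly the 20 standard residues")


DEFAULT_MODEL = ResidueClassModel()


def classify_residue(aa: str, model: ResidueClassModel = DEFAULT_MODEL) -> str:
    """Group of a standard residue; gaps/X/non-standard raise (pre-filter per ScanConfig)."""
    aa = aa.upper()
    if aa not in model.groups:
        raise ValueError(f"cannot classify non-standard residue {aa!r}")
    return model.groups[aa]


@dataclass
class AlignmentMatrix:
    """Species × aligned-residue matrix with designated focal and reference rows."""

    species_ids: list[str]
    rows: dict[str, str]
    focal_species: str
    reference_species: str

    def __post_init__(self) -> None:
        lengths = {len(self.rows[s]) for s in self.species_ids}
        if len(lengths) != 1:
            raise ValueError("all alignment rows must have equal length")
        for s in (self.focal_species, self.reference_species):
            if s not in self.rows:
                raise ValueError(f"species {s!r} missing from alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, i: int) -> dict[str, str]:
        return {s: self.rows[s][i] for s in self.species_ids}


@dataclass(frozen=True)
class ScanConfig:
    """Gap/unknown policy for the scan.

    ``min_informative_others``: informative (non-gap, non-X) residues
    required among the non-focal species for a column to be eligible.
    ``treat_x``: 'ignore' skips X residues among others; 'disqualify-column'
    drops any column containing X in a non-focal row.
    """

    min_informative_others: int = 30
    treat_x: str = "ignore"

    def __post_init__(self) -> None:
        if self.min_informative_others < 1:
            raise ValueError("min_informative_others must be >= 1")
        if self.treat_x not in ("ignore", "disqualify-column"):
            raise ValueError("treat_x must be 'ignore' or 'disqualify-column'")


@dataclass(frozen=True)
class UniqueSiteCall:
    column: int
    reference_position: int
    focal_residue: str
    others_residues: tuple[str, ...]
    focal_group: str
    others_groups: frozenset[str]
    change_string: str

    def __post_init__(self) -> None:
        if self.focal_group in self.others_groups:
            raise ValueError("focal group must be absent from other species' groups")


def map_to_reference_position(aln: AlignmentMatrix, column: int) -> int:
    """1-based residue index in the reference species' ungapped sequence:
    the count of non-gap reference residues in columns 0..column inclusive."""
    ref = aln.rows[aln.reference_species]
    if ref[column] == GAP:
        raise ValueError(f"reference species is gapped at column {column}")
    return sum(1 for c in ref[: column + 1] if c != GAP)


def format_change_string(
    others_residues: Iterable[str], position: int, focal_residue: str
) -> str:
    """Compact change notation: distinct other-species residues (descending
    frequency, ties alphabetical), the 1-based reference position, then the
    focal residue — e.g. ``STQ174R``."""
    counts = Counter(others_residues)
    if not counts:
        raise ValueError("others_residues must be non-empty")
    ordered = sorted(counts, key=lambda r: (-counts[r], r))
    return f"{''.join(ordered)}{position}{focal_residue}"


_CHANGE_RE = re.compile(r"^([A-Z]+)(\d+)([A-Z])$")


def parse_change_string(s: str) -> tuple[frozenset[str], int, str]:
    """Inverse of :func:`format_change_string` up to residue ordering."""
    m = _CHANGE_RE.match(s)
    if not m:
        raise ValueError(f"malformed change string {s!r}")
    return frozenset(m.group(1)), int(m.group(2)), m.group(3)


def scan_alignment(
    aln: AlignmentMatrix,
    cfg: ScanConfig = ScanConfig(),
    model: ResidueClassModel = DEFAULT_MODEL,
) -> list[UniqueSiteCall]:
    """All columns where the focal residue's class is absent from every
    informative non-focal residue.

    A column yields a call iff (a) the focal residue is a standard amino
    acid, (b) at least ``min_informative_others`` informative non-focal
    residues exist, (c) no informative non-focal residue shares the focal
    residue's group, and (d) the reference species is ungapped there.
    Calls are sorted by column.
    """
    calls: list[UniqueSiteCall] = []
    focal_row = aln.rows[aln.focal_species]
    ref_row = aln.rows[aln.reference_species]
    other_species = [s for s in aln.species_ids if s != aln.focal_species]
    for col in range(aln.n_columns):
        focal = focal_row[col].upper()
        if focal not in model.groups:
            continue  # gap/X/non-standard focal residue: column skipped
        if ref_row[col] == GAP:
            continue
        others = [aln.rows[s][col].upper() for s in other_species]
        if cfg.treat_x == "disqualify-column" and UNKNOWN in others:
            continue
        informative = [r for r in others if r in model.groups]
        if len(informative) < cfg.min_informative_others:
            continue
        focal_group = model.groups[focal]
        others_groups = {model.groups[r] for r in informative}
        if focal_group in others_groups:
            continue
        pos = map_to_reference_position(aln, col)
        calls.append(
            UniqueSiteCall(
                column=col,
                reference_position=pos,
                focal_residue=focal,
                others_residues=tuple(informative),
                focal_group=focal_group,
                others_groups=frozenset(others_groups),
                change_string=format_change_string(informative, pos, focal),
            )
        )
    return calls


def neutral_fp_simulation(
    tree_newick: str,
    focal_species: str,
    n_columns: int,
    seed: int,
    per_site_rate: float = 1.0,
    cfg: ScanConfig | None = None,
    reference_species: str | None = None,
):
    """False-call rate of the scanner under neutral (unplanted) evolution.

    Columns are evolved independently along the tree with unrestricted
    residue replacement; any call the scanner makes is by construction a
    chance event. Returns ``(count, rate, (ci_low, ci_high))`` with a
    95% Jeffreys binomial interval over columns; seed-deterministic.
    """
    from .simulate import PhylogenyModel, evolve_protein_columns

    phylo = PhylogenyModel(tree_newick, focal_species=focal_species)
    if reference_species is None:
        reference_species = next(s for s in phylo.species_ids if s != focal_species)
    if cfg is None:
        cfg = ScanConfig(min_informative_others=min(30, len(phylo.species_ids) - 1))
    columns = evolve_protein_columns(phylo, n_columns, per_site_rate, seed)
    rows = {
        s: "".join(columns[c][s] for c in range(n_columns)) for s in phylo.species_ids
    }
    aln = AlignmentMatrix(list(phylo.species_ids), rows, focal_species, reference_species)
    calls = scan_alignment(aln, cfg)
    k, n = len(calls), n_columns
    lo = beta.ppf(0.025, k + 0.5, n - k + 0.5) if k > 0 else 0.0
    hi = beta.ppf(0.975, k + 0.5, n - k + 0.5) if k < n else 1.0
    return k, k / n, (float(lo), float(hi))
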