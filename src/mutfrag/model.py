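"""Core data model: settings, sequence containers, mutation specifications.

All base-pair coordinates are 0-based half-open; protein residues are
1-based in user-facing labels. Circular plasmids use modular arithmetic
throughout (see :func:`circular_slice`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterator, Optional, Union

import yaml

DNA_ALPHABET = set("ACGT")
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class DesignError(Exception):
    """Base class for all design-stage failures."""


class MutationParseError(DesignError):
    pass


class GeneLocationError(DesignError):
    pass


class MutationValidationError(DesignError):
    pass


class ClusteringError(DesignError):
    pass


class FragmentDesignError(DesignError):
    pass


class PrimerDesignError(DesignError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice a circular sequence; ``start``/``end`` may be any integers with
    0 <= end - start <= len(seq)."""
    n = len(seq)
    length = end - start
    if not 0 <= length <= n:
        raise ValueError(f"slice length {length} outside [0, {n}]")
    s = start % n
    if s + length <= n:
        return seq[s : s + length]
    return seq[s:] + seq[: length - (n - s)]


# ---------------------------------------------------------------------------
# Settings
# ---------------------------------------------------------------------------


@dataclass
class DesignSettings:
    """Tunable parameters of the whole design pipeline.

    Fragment-size defaults follow common synthesis-provider limits for
    dsDNA gene fragments (300-1500 bp); homology flanks for IVA cloning are
    at least 15 bp with a melting temperature inside ``flank_tm_window``.
    """

    min_fragment_bp: int = 300
    max_fragment_bp: int = 1500
    min_flank_bp: int = 15
    max_flank_bp: int = 60
    flank_tm_window: tuple[float, float] = (47.0, 52.0)
    optimization_mode: str = "quantity"  # or "length"
    cost_per_bp: float = 0.05
    silent_markers_per_end: int = 2
    random_seed: int = 42
    # primer parameter block
    primer_min_len: int = 18
    primer_max_len: int = 30
    primer_tm_window: tuple[float, float] = (57.0, 63.0)
    primer_gc_window: tuple[float, float] = (0.40, 0.60)
    pair_tm_diff_max: float = 3.0
    sequencing_read_bp: int = 800
    sequencing_spacing_bp: int = 500
    sequencing_upstream_bp: int = 150

    def __post_init__(self) -> None:
        if not 0 < self.min_fragment_bp <= self.max_fragment_bp:
            raise ValueError("require 0 < min_fragment_bp <= max_fragment_bp")
        if self.min_flank_bp < 1:
            raise ValueError("min_flank_bp must be >= 1")
        for lo, hi in (self.flank_tm_window, self.primer_tm_window,
                       self.primer_gc_window):
            if lo > hi:
                raise ValueError("window low bound exceeds high bound")
        if self.optimization_mode not in ("quantity", "length"):
            raise ValueError("optimization_mode must be 'quantity' or 'length'")

    @property
    def min_region_core_bp(self) -> int:
        """Minimum wild-type region length implied by the fragment minimum
        once both minimal flanks are subtracted."""
        return self.min_fragment_bp - 2 * self.min_flank_bp

    @classmethod
    def from_yaml(cls, path: str) -> "DesignSettings":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown settings keys: {sorted(unknown)}")
        for key in ("flank_tm_window", "primer_tm_window", "primer_gc_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Sequence containers
# ---------------------------------------------------------------------------


@dataclass
class Plasmid:
    name: str
    sequence: str
    circular: bool = True
    # (label, start, end, strand) with 0-based half-open intervals
    features: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("plasmid sequence is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"plasmid contains non-ACGT symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneContext:
    """A coding sequence located on a plasmid.

    ``plasmid_offset`` is the 0-based start of the gene's occurrence
    interval on the plasmid regardless of strand; on the '-' strand the
    coding sequence is the reverse complement of that interval.
    """

    gene_id: str
    cds: str
    plasmid_offset: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if len(self.cds) % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def n_residues(self) -> int:
        return len(self.cds) // 3

    def codon(self, residue: int) -> str:
        if not 1 <= residue <= self.n_residues:
            raise IndexError(f"residue {residue} outside [1, {self.n_residues}]")
        return self.cds[3 * (residue - 1) : 3 * residue]


# ---------------------------------------------------------------------------
# Mutation specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointSub:
    wt_aa: str
    residue: int
    mut_aa: str

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.residue}{self.mut_aa}"


@dataclass(frozen=True)
class PointMutation:
    wt_aa: str
    residue: int
    mut_aa: str

    kind = "point"

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.residue}{self.mut_aa}"

    @property
    def subs(self) -> tuple[PointSub, ...]:
        return (PointSub(self.wt_aa, self.residue, self.mut_aa),)

    @property
    def net_indel_bp(self) -> int:
        return 0

    def extents(self) -> list[tuple[int, int]]:
        return [(3 * (self.residue - 1), 3 * self.residue)]

    def residues(self) -> list[int]:
        return [self.residue]


@dataclass(frozen=True)
class CombinedMutation:
    """Two or more point mutations required to co-occur in one mutant."""

    members: tuple[PointSub, ...]

    kind = "combined"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("combined mutation needs >= 2 members")

    @property
    def label(self) -> str:
        return "+".join(m.label for m in self.members)

    @property
    def subs(self) -> tuple[PointSub, ...]:
        return self.members

    @property
    def net_indel_bp(self) -> int:
        return 0

    def extents(self) -> list[tuple[int, int]]:
        return [(3 * (m.residue - 1), 3 * m.residue) for m in self.members]

    def residues(self) -> list[int]:
        return [m.residue for m in self.members]


@dataclass(frozen=True)
class Insertion:
    """Insert ``peptide`` immediately after residue ``anchor``."""

    anchor: int
    peptide: str

    kind = "insertion"

    @property
    def label(self) -> str:
        return f"ins{self.anchor}-{self.peptide}"

    @property
    def net_indel_bp(self) -> int:
        return 3 * len(self.peptide)

    def extents(self) -> list[tuple[int, int]]:
        p = 3 * self.anchor
        return [(p, p)]

    def residues(self) -> list[int]:
        return [self.anchor]


@dataclass(frozen=True)
class Deletion:
    """Delete residues ``first``..``last`` inclusive."""

    first: int
    last: int

    kind = "deletion"

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("deletion first > last")

    @property
    def label(self) -> str:
        return f"del{self.first}-{self.last}"

    @property
    def net_indel_bp(self) -> int:
        return -3 * (self.last - self.first + 1)

    def extents(self) -> list[tuple[int, int]]:
        return [(3 * (self.first - 1), 3 * self.last)]

    def residues(self) -> list[int]:
        return list(range(self.first, self.last + 1))


MutationSpec = Union[PointMutation, CombinedMutation, Insertion, Deletion]


def spec_hull(spec: MutationSpec) -> tuple[int, int]:
    """Smallest bp interval on the CDS touched by a spec."""
    ext = spec.extents()
    return min(s for s, _ in ext), max(e for _, e in ext)


# ---------------------------------------------------------------------------
# Clustering / fragment containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationPoint:
    """One clusterable data point: a representative bp coordinate of (part
    of) a mutation on the CDS."""

    mutation_ref: str
    member_index: int
    position_bp: int
    extent_bp: tuple[int, int]


@dataclass
class Clustering:
    k: int
    assignment: dict[str, int]  # mutation label -> cluster index
    valid: bool
    total_fragment_bp: int
    n_fragments: int
    source: str = "pam"


@dataclass
class FragmentRegion:
    """Codon-aligned interval on the CDS (possibly extending into backbone,
    i.e. start < 0 or end > len(cds)) plus the mutations it hosts."""

    start: int
    end: int
    mutations: tuple[str, ...]
    cluster_index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Fragment:
    """One synthesizable mutant dsDNA molecule: homology flank, mutated
    region (with silent markers), homology flank."""

    name: str
    region: FragmentRegion
    mutation_label: str
    mutant_region_seq: str
    flank5: str
    flank3: str
    # (residue, wild-type codon, marker codon)
    silent_markers: tuple[tuple[int, str, str], ...]
    cost: float
    # label -> (start, end) offsets within mutant_region_seq
    feature_offsets: dict[str, tuple[int, int]] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    @property
    def full_seq(self) -> str:
        return self.flank5 + self.mutant_region_seq + self.flank3

    def __len__(self) -> int:
        return len(self.full_seq)


@dataclass
class Primer:
    name: str
    sequence: str
    plasmid_position: int
    strand: int  # +1 / -1
    tm: float
    gc_fraction: float
    flags: frozenset[str] = frozenset()
    warnings: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_length_bp: int
    purpose: str  # "linearization" or "sequencing"


@dataclass
class DesignBundle:
    fragments: list[Fragment]
    linearization_pairs: list[PrimerPair]
    sequencing_primers: list[Primer]
    regions: list[FragmentRegion]
    clustering: Clustering
    genbank_paths: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Coding-strand view of a plasmid
# ---------------------------------------------------------------------------


@dataclass
class DesignView:
    """The plasmid oriented so the gene reads 5'->3' on the top strand.

    All region/flank/primer design happens in view coordinates; output
    writers map back to the original plasmid orientation.
    """

    plasmid: Plasmid
    gene: GeneContext
    seq: str
    gene_offset: int

    @classmethod
    def build(cls, plasmid: Plasmid, gene: GeneContext) -> "DesignView":
        n = len(plasmid)
        if gene.strand == "+":
            seq = plasmid.sequence
            off = gene.plasmid_offset
        else:
            seq = reverse_complement(plasmid.sequence)
            off = (n - (gene.plasmid_offset + len(gene.cds))) % n
        if circular_slice(seq, off, off + len(gene.cds)) != gene.cds:
            raise GeneLocationError("gene context inconsistent with plasmid")
        return cls(plasmid, gene, seq, off)

    def cds_to_view(self, start: int, end: int) -> tuple[int, int]:
        """Map a CDS bp interval (which may extend beyond the CDS) to
        un-reduced view coordinates."""
        return self.gene_offset + start, self.gene_offset + end

    def slice(self, start: int, end: int) -> str:
        return circular_slice(self.seq, start, end)
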