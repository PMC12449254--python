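"""Synthetic eligibility study: how long can an insertion or deletion be,
and how far apart can a paired mutation sit, before a single dsDNA fragment
can no longer be designed under the provider's size limits?

Each test case is a random gene on a toy circular plasmid carrying five
random point mutations plus one controlled-length variant (insertion,
deletion, or paired mutation). The sweep runs the full design pipeline
(clustering, region definition, fragment assembly) on a grid of variant
lengths and reports per-length success rates.
"""
from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

from .clustering import find_valid_clusterings, select_clustering
from .codons import SENSE_CODONS, translate_codon, uniform_usage_table
from .fragments import define_region, design_fragment, region_flanks
from .model import (
    AA_LETTERS,
    CombinedMutation,
    Deletion,
    DesignError,
    DesignSettings,
    DesignView,
    GeneContext,
    Insertion,
    MutationSpec,
    Plasmid,
    PointMutation,
    PointSub,
)

VARIANT_TYPES = ("insertion", "deletion", "paired")

#: point mutations per test case, as in the synthetic validation design
POINTS_PER_CASE = 5

#: default gene length (codons incl. start/stop) for the sweep
DEFAULT_GENE_CODONS = 800

BACKBONE_BP = 2000


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary labels (independent across parts,
    reproducible across runs; always < 2**31)."""
    digest = hashlib.blake2s(":".join(map(str, parts)).encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ---------------------------------------------------------------------------
# Random genes and panels
# ---------------------------------------------------------------------------


def random_gene(n_codons: int, seed: int) -> tuple[Plasmid, GeneContext]:
    """ATG + uniform non-stop codons + TAA, embedded mid-backbone in a
    random 2 kb circular plasmid."""
    if n_codons < 50:
        raise DesignError("random gene needs >= 50 codons")
    rng = random.Random(seed)
    cds = "ATG" + "".join(rng.choice(SENSE_CODONS)
                          for _ in range(n_codons - 2)) + "TAA"
    backbone = "".join(rng.choice("ACGT") for _ in range(BACKBONE_BP))
    half = BACKBONE_BP // 2
    plasmid = Plasmid(f"synplasmid{seed}", backbone[:half] + cds + backbone[half:])
    gene = GeneContext(f"syngene{seed}", cds, half, "+")
    return plasmid, gene


@dataclass
class TestCase:
    plasmid: Plasmid
    gene: GeneContext
    panel: list[MutationSpec]
    variant_type: str
    variant_length: int
    seed: int


def _random_point(rng: random.Random, gene: GeneContext, residue: int
                  ) -> PointMutation:
    wt = translate_codon(gene.codon(residue))
    mut = rng.choice([aa for aa in AA_LETTERS if aa != wt])
    return PointMutation(wt, residue, mut)


def make_test_case(plasmid: Plasmid, gene: GeneContext, variant_type: str,
                   variant_length: int, seed: int) -> TestCase:
    """Five random distinct point mutations plus one controlled-length
    variant; point residues never fall inside the deleted range or on the
    paired sites."""
    if variant_type not in VARIANT_TYPES:
        raise ValueError(f"unknown variant type {variant_type!r}")
    rng = random.Random(seed)
    last = gene.n_residues - 1  # keep the stop codon untouched
    L = variant_length
    blocked: set[int] = set()
    if variant_type == "deletion":
        hi = last - L + 1
        if hi < 2:
            raise DesignError(f"gene too short for a {L}-residue deletion")
        start = rng.randint(2, hi)
        variant: MutationSpec = Deletion(start, start + L - 1)
        blocked = set(range(start, start + L))
    elif variant_type == "insertion":
        anchor = rng.randint(1, last)
        peptide = "".join(rng.choice(AA_LETTERS) for _ in range(L))
        variant = Insertion(anchor, peptide)
    else:  # paired
        hi = last - L
        if hi < 2:
            raise DesignError(f"gene too short for a {L}-residue pair distance")
        r = rng.randint(2, hi)
        subs = []
        for residue in (r, r + L):
            wt = translate_codon(gene.codon(residue))
            subs.append(PointSub(wt, residue,
                                 rng.choice([aa for aa in AA_LETTERS if aa != wt])))
        variant = CombinedMutation(tuple(subs))
        blocked = {r, r + L}
    available = [r for r in range(2, last + 1) if r not in blocked]
    residues = rng.sample(available, POINTS_PER_CASE)
    panel = [_random_point(rng, gene, r) for r in sorted(residues)]
    panel.append(variant)
    return TestCase(plasmid, gene, panel, variant_type, variant_length, seed)


# ---------------------------------------------------------------------------
# Designability
# ---------------------------------------------------------------------------


def is_designable(case: TestCase, settings: DesignSettings | None = None) -> bool:
    """True iff the full pipeline (clustering -> region definition ->
    fragment assembly) completes for every mutation of the panel."""
    settings = settings or DesignSettings()
    table = uniform_usage_table()
    try:
        candidates = find_valid_clusterings(case.panel, case.gene, settings)
        selected = select_clustering(candidates, settings.optimization_mode)
        view = DesignView.build(case.plasmid, case.gene)
        by_label = {m.label: m for m in case.panel}
        clusters: dict[int, list[MutationSpec]] = {}
        for label, c in selected.assignment.items():
            clusters.setdefault(c, []).append(by_label[label])
        for idx in sorted(clusters):
            region = define_region(clusters[idx], view, settings, idx)
            flanks = region_flanks(view, region, settings, clusters[idx])
            for spec in clusters[idx]:
                design_fragment(region, spec, view, table, settings,
                                flanks=flanks)
    except DesignError:
        return False
    return True


def geometric_designable(variant_type: str, length: int,
                         settings: DesignSettings | None = None,
                         gene_codons: int = DEFAULT_GENE_CODONS) -> bool:
    """Closed-form size predicate, independent of the pipeline.

    With min_core = min_fragment - 2*min_flank and F = 2*min_flank:
    a paired mutation L residues apart spans 3*(L+1) wild-type bp, so it
    fits iff 3*(L+1) + F <= max_fragment; an insertion of L residues fits
    iff max(min_core - 3L, 0) + 3L + F <= max_fragment; a deletion is
    compensated by region expansion (region = min_core + 3L wild-type bp)
    and is limited only by the gene/plasmid capacity.
    """
    settings = settings or DesignSettings()
    flanks = 2 * settings.min_flank_bp
    core = settings.min_region_core_bp
    if variant_type == "paired":
        fits = 3 * (length + 1) + flanks <= settings.max_fragment_bp
        return fits and length <= gene_codons - 3
    if variant_type == "insertion":
        w = max(core - 3 * length, 0)
        return w + 3 * length + flanks <= settings.max_fragment_bp
    if variant_type == "deletion":
        capacity = 3 * gene_codons + BACKBONE_BP - flanks
        return (length <= gene_codons - 3
                and core + 3 * length <= capacity)
    raise ValueError(f"unknown variant type {variant_type!r}")


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepRow:
    variant_type: str
    variant_length: int
    n_total: int
    n_designable: int

    @property
    def success_rate(self) -> float:
        return self.n_designable / self.n_total


@dataclass
class SweepResult:
    base_seed: int
    gene_codons: int
    n_genes: int
    replicates: int
    rows: list[SweepRow] = field(default_factory=list)

    def rate(self, variant_type: str, length: int) -> float:
        for row in self.rows:
            if row.variant_type == variant_type and row.variant_length == length:
                return row.success_rate
        raise KeyError((variant_type, length))


def run_sweep(lengths: list[int],
              types: tuple[str, ...] = VARIANT_TYPES,
              n_genes: int = 3,
              replicates: int = 10,
              base_seed: int = 0,
              gene_codons: int = DEFAULT_GENE_CODONS,
              settings: DesignSettings | None = None) -> SweepResult:
    """For every (type, length): n_genes x replicates seeded cases through
    the full pipeline; success = fraction with a complete design."""
    settings = settings or DesignSettings()
    genes = [random_gene(gene_codons, derive_seed(base_seed, "gene", i))
             for i in range(n_genes)]
    result = SweepResult(base_seed, gene_codons, n_genes, replicates)
    for vtype in types:
        for length in lengths:
            ok = total = 0
            for gi, (plasmid, gene) in enumerate(genes):
                for rep in range(replicates):
                    case_seed = derive_seed(base_seed, gi, vtype, length, rep)
                    case = make_test_case(plasmid, gene, vtype, length, case_seed)
                    total += 1
                    ok += is_designable(case, settings)
            result.rows.append(SweepRow(vtype, length, total, ok))
    return result


def write_sweep_tsv(result: SweepResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# base_seed={result.base_seed} gene_codons={result.gene_codons} "
                 f"n_genes={result.n_genes} replicates={result.replicates}\n")
        fh.write("variant_type\tvariant_length\tn_total\tn_designable\t"
                 "success_rate\n")
        for row in result.rows:
            fh.write(f"{row.variant_type}\t{row.variant_length}\t{row.n_total}\t"
                     f"{row.n_designable}\t{row.success_rate:.4f}\n")
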