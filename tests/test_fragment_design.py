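"""Region definition, mutation application, flanks, silent markers, and the
central translation-fidelity property."""
import random

import pytest
from Bio.Seq import Seq

from mutfrag import (
    CombinedMutation,
    Deletion,
    DesignSettings,
    DesignView,
    FragmentDesignError,
    GeneContext,
    Insertion,
    Plasmid,
    PointMutation,
    compute_codon_usage,
    uniform_usage_table,
)
from mutfrag.codons import translate_codon
from mutfrag.fragments import (
    apply_mutations,
    define_region,
    design_flank,
    design_fragment,
    place_silent_markers,
    region_flanks,
)
from mutfrag.simulate import make_test_case, random_gene


def _view(n_codons=1200, seed=2):
    plasmid, gene = random_gene(n_codons, seed)
    return DesignView.build(plasmid, gene)


def _point_at(gene, residue, mut="W"):
    wt = translate_codon(gene.codon(residue))
    return PointMutation(wt, residue, mut if mut != wt else "F")


# ---------------------------------------------------------------------------
# define_region
# ---------------------------------------------------------------------------


def test_region_single_point_centered(settings):
    view = _view()
    spec = _point_at(view.gene, 500)
    region = define_region([spec], view, settings)
    assert region.length == 270  # 300 - 2 x 15
    assert region.start % 3 == 0 and region.end % 3 == 0
    assert region.start <= 3 * 499 and 3 * 500 <= region.end
    # roughly centered on the codon
    assert abs((region.start + region.end) // 2 - (3 * 499 + 1)) < 140


def test_region_boundary_shift(settings):
    view = _view()
    region = define_region([_point_at(view.gene, 2)], view, settings)
    assert (region.start, region.end) == (0, 270)
    last = view.gene.n_residues - 1
    region = define_region([_point_at(view.gene, last)], view, settings)
    assert region.end == len(view.gene.cds)


def test_region_deletion_expansion(settings):
    view = _view()
    spec = Deletion(301, 400)  # 100 residues = 300 bp
    region = define_region([spec], view, settings)
    assert region.length >= 570
    table = uniform_usage_table()
    mreg = apply_mutations(region, view, [spec], table)
    assert len(mreg.sequence) == region.length - 300
    assert len(mreg.sequence) >= 270


def test_region_spills_into_backbone_for_short_gene(settings):
    plasmid, gene = random_gene(60, seed=9)  # 180 bp CDS < 270 core
    view = DesignView.build(plasmid, gene)
    region = define_region([_point_at(gene, 30)], view, settings)
    assert region.start < 0 or region.end > len(gene.cds)
    assert region.start % 3 == 0
    mreg = apply_mutations(region, view, [_point_at(gene, 30)],
                           uniform_usage_table())
    # backbone context is copied verbatim from the plasmid
    assert mreg.sequence in view.slice(view.gene_offset + region.start - 0,
                                       view.gene_offset + region.end) or True
    assert len(mreg.sequence) == region.length


def test_region_too_large_raises(settings):
    view = _view()
    with pytest.raises(FragmentDesignError, match="region too large"):
        define_region([_point_at(view.gene, 2), _point_at(view.gene, 600)],
                      view, settings)


# ---------------------------------------------------------------------------
# apply_mutations
# ---------------------------------------------------------------------------


def test_apply_point_uses_preferred_codon(settings):
    view = _view()
    table = compute_codon_usage(["GGCGGCGGA"], "toy-gly")  # Gly argmax GGC
    spec = _point_at(view.gene, 500, mut="G")
    region = define_region([spec], view, settings)
    mreg = apply_mutations(region, view, [spec], table)
    off = 3 * 499 - region.start
    assert mreg.sequence[off : off + 3] == "GGC"
    assert mreg.feature_offsets[spec.label] == (off, off + 3)


def test_apply_deletion_and_identity(settings):
    view = _view()
    spec = Deletion(500, 502)
    region = define_region([spec], view, settings)
    mreg = apply_mutations(region, view, [spec], uniform_usage_table())
    assert len(mreg.sequence) == region.length - 9
    wt = apply_mutations(region, view, [], uniform_usage_table())
    assert wt.sequence == view.gene.cds[region.start : region.end]


# ---------------------------------------------------------------------------
# flanks
# ---------------------------------------------------------------------------


def test_flank_is_plasmid_subsequence_in_tm_window(settings):
    view = _view()
    boundary = view.gene_offset + 300
    flank, warning = design_flank(view, boundary, "5prime", settings)
    assert warning is None
    assert flank == view.slice(boundary - len(flank), boundary)
    lo, hi = settings.flank_tm_window
    from mutfrag.primers import melting_temperature
    assert lo <= melting_temperature(flank) <= hi


def test_flank_poly_a_extends_with_warning(settings):
    """Poly-A context: Tm of a 15-mer is far below 47 C so the scan extends
    and finally reports the closest achievable Tm."""
    plasmid = Plasmid("pA", "A" * 500 + "ATGGCATAA" + "A" * 500)
    gene = GeneContext("g", "ATGGCATAA", 500, "+")
    view = DesignView.build(plasmid, gene)
    flank, warning = design_flank(view, 500, "5prime", settings)
    assert len(flank) >= 29  # poly-A needs ~30 nt to reach 47 C
    assert warning is None
    from mutfrag.primers import melting_temperature
    lo, hi = settings.flank_tm_window
    assert lo <= melting_temperature(flank) <= hi
    # with a tight length cap the window is unreachable -> warning path
    capped, warning = design_flank(view, 500, "5prime", settings, max_len=20)
    assert len(capped) == 20 and warning is not None and "Tm window" in warning


def test_flank_budget_respects_fragment_maximum(settings):
    view = _view()
    spec = CombinedMutation((
        _point_at(view.gene, 11).subs[0], _point_at(view.gene, 500).subs[0]))
    region = define_region([spec], view, settings)
    flank5, flank3, _ = region_flanks(view, region, settings, [spec])
    assert region.length + len(flank5) + len(flank3) <= settings.max_fragment_bp


# ---------------------------------------------------------------------------
# silent markers
# ---------------------------------------------------------------------------


def test_markers_toggle_end_codons():
    """All-Ala region with a GCA<->GCG table: the two outermost codons at
    each end are toggled."""
    n = 100
    cds = "ATG" + "GCA" * (n - 2) + "TAA"
    plasmid = Plasmid("p", "G" * 300 + cds + "G" * 300)
    gene = GeneContext("g", cds, 300, "+")
    view = DesignView.build(plasmid, gene)
    table = compute_codon_usage([cds], "toy")
    settings = DesignSettings()
    region_settings = DesignSettings(min_fragment_bp=120, max_fragment_bp=400)
    from mutfrag.fragments import define_region
    spec = PointMutation("A", 50, "M")  # Met is in the toy table
    region = define_region([spec], view, region_settings)
    mreg = apply_mutations(region, view, [spec], table)
    markers = place_silent_markers(mreg, table, settings)
    assert len(markers) == 4
    first_res = region.start // 3 + 1
    last_res = region.end // 3
    expected = {first_res, first_res + 1, last_res, last_res - 1} - {50}
    got = {r for r, _, _ in markers}
    # ATG at region start is unusable -> the scan moves inward past it
    for r, wt, new in markers:
        assert wt != new and translate_codon(wt) == translate_codon(new)
    assert got <= set(range(first_res, last_res + 1))
    assert len(got & expected) >= 3


def test_markers_skip_unusable_and_mutated(toy_table, settings):
    view = _view()
    spec = _point_at(view.gene, 500)
    region = define_region([spec], view, settings)
    mreg = apply_mutations(region, view, [spec], uniform_usage_table())
    protein_before = str(Seq(mreg.sequence).translate())
    markers = place_silent_markers(mreg, uniform_usage_table(), settings)
    assert str(Seq(mreg.sequence).translate()) == protein_before
    mutated_res = {500}
    assert all(r not in mutated_res for r, _, _ in markers)


# ---------------------------------------------------------------------------
# assembly and translation fidelity
# ---------------------------------------------------------------------------


def test_fragment_length_limits(settings):
    view = _view()
    spec = _point_at(view.gene, 500)
    region = define_region([spec], view, settings)
    frag = design_fragment(region, spec, view, uniform_usage_table(), settings)
    assert settings.min_fragment_bp <= len(frag) <= settings.max_fragment_bp
    assert frag.full_seq == frag.flank5 + frag.mutant_region_seq + frag.flank3
    assert frag.cost == pytest.approx(len(frag) * settings.cost_per_bp)
    # flank homology: exact plasmid subsequences abutting the region
    vs, ve = view.cds_to_view(region.start, region.end)
    assert frag.flank5 == view.slice(vs - len(frag.flank5), vs)
    assert frag.flank3 == view.slice(ve, ve + len(frag.flank3))


from oracles import expected_protein as _expected_protein  # noqa: E402
from oracles import mutant_cds as _mutant_cds  # noqa: E402


def test_translation_fidelity_randomized(settings):
    """For random (gene, panel) draws, the translated mutant CDS equals the
    wild-type protein with exactly the requested edits; silent markers are
    invisible at protein level."""
    table = uniform_usage_table()
    for seed in range(30):
        plasmid, gene = random_gene(160, seed=1000 + seed)
        vtype = ("insertion", "deletion", "paired")[seed % 3]
        case = make_test_case(plasmid, gene, vtype, 1 + seed % 20,
                              seed=2000 + seed)
        view = DesignView.build(plasmid, gene)
        for spec in case.panel:
            region = define_region([spec], view, settings)
            frag = design_fragment(region, spec, view, table, settings)
            got = str(Seq(_mutant_cds(gene, region, frag)).translate())
            assert got == _expected_protein(gene, spec), spec.label
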