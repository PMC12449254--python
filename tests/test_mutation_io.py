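"""Mutation-list grammar, gene location, validation and output writers."""
import random

import pytest
from Bio import SeqIO
from Bio.Seq import Seq

from mutfrag import (
    CombinedMutation,
    Deletion,
    DesignError,
    DesignSettings,
    Fragment,
    FragmentRegion,
    GeneLocationError,
    Insertion,
    MutationParseError,
    MutationValidationError,
    Plasmid,
    PointMutation,
    locate_gene,
    parse_mutation_file,
    parse_mutation_line,
    validate_mutations,
)
from mutfrag.model import GeneContext, reverse_complement
from mutfrag.seqio import (
    build_mutant_record,
    read_plasmid_genbank,
    well_position,
    write_order_sheet,
)


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("line,expected", [
    ("L123A", PointMutation("L", 123, "A")),
    ("G45D+S210R", None),  # combined, checked below
    ("del70-75", Deletion(70, 75)),
    ("ins5-GGS", Insertion(5, "GGS")),
])
def test_grammar_forms(line, expected):
    spec = parse_mutation_line(line)
    if expected is not None:
        assert spec == expected
    assert spec.label == line


def test_combined_members():
    spec = parse_mutation_line("G45D+S210R")
    assert isinstance(spec, CombinedMutation)
    assert [(s.wt_aa, s.residue, s.mut_aa) for s in spec.members] == [
        ("G", 45, "D"), ("S", 210, "R")]


@pytest.mark.parametrize("bad", ["L123", "123A", "B5A", "del9-3", "ins3-GJX",
                                 "L123A+G", "delx-3"])
def test_malformed_lines_rejected(bad, tmp_path):
    path = tmp_path / "muts.txt"
    path.write_text("L1A\n" + bad + "\n")
    with pytest.raises(MutationParseError) as err:
        parse_mutation_file(str(path))
    assert "line 2" in str(err.value)


def test_comments_blanks_and_duplicates(tmp_path):
    path = tmp_path / "muts.txt"
    path.write_text("# header\n\nL123A\nG45D+S210R\n")
    specs = parse_mutation_file(str(path))
    assert [s.label for s in specs] == ["L123A", "G45D+S210R"]
    path.write_text("L123A\nG2V\nL123A\n")
    with pytest.raises(MutationParseError, match="duplicate"):
        parse_mutation_file(str(path))


# ---------------------------------------------------------------------------
# Gene location
# ---------------------------------------------------------------------------


def test_locate_gene_plus_strand_with_wraparound():
    plasmid = Plasmid("p", "AAATGGCATAACC")
    gene = locate_gene(plasmid, "ATGGCATAA")
    assert (gene.plasmid_offset, gene.strand) == (2, "+")
    # same gene crossing the origin
    rotated = Plasmid("p", "CATAACCAAATGG")
    gene = locate_gene(rotated, "ATGGCATAA")
    assert (gene.plasmid_offset, gene.strand) == (9, "+")


def test_locate_gene_minus_strand():
    cds = "ATGGCATTAGGCTAA"
    plasmid = Plasmid("p", "CCCC" + reverse_complement(cds) + "GGGGTT")
    gene = locate_gene(plasmid, cds)
    assert (gene.plasmid_offset, gene.strand) == (4, "-")


def test_locate_gene_errors():
    with pytest.raises(GeneLocationError, match="not found"):
        locate_gene(Plasmid("p", "ACGT" * 10), "ATGGCATAA")
    double = Plasmid("p", "ATGGCATAA" + "CCCC" + "ATGGCATAA" + "GG")
    with pytest.raises(GeneLocationError, match="2 times"):
        locate_gene(double, "ATGGCATAA")


def test_locate_gene_recovers_construction_offset():
    """Property: random backbone + gene + random backbone always recovers
    the construction offset."""
    rng = random.Random(42)
    for _ in range(20):
        gene_seq = "ATG" + "".join(
            rng.choice(["GCA", "TGC", "GAT", "CTG", "AAA"]) for _ in range(60)
        ) + "TAA"
        left = "".join(rng.choice("ACGT") for _ in range(rng.randint(50, 400)))
        right = "".join(rng.choice("ACGT") for _ in range(rng.randint(50, 400)))
        plasmid = Plasmid("p", left + gene_seq + right)
        found = locate_gene(plasmid, gene_seq)
        assert (found.plasmid_offset, found.strand) == (len(left), "+")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def test_validate_against_translation_oracle(small_gene):
    _, gene = small_gene
    protein = str(Seq(gene.cds).translate())
    ok = PointMutation(protein[49], 50, "A" if protein[49] != "A" else "G")
    assert validate_mutations([ok], gene) == [ok]
    wrong_aa = next(a for a in "ACDEFGHIK" if a != protein[119])
    bad = PointMutation(wrong_aa, 120, "W")
    with pytest.raises(MutationValidationError) as err:
        validate_mutations([bad], gene)
    assert protein[119] in str(err.value)
    with pytest.raises(MutationValidationError, match="outside gene"):
        validate_mutations([Deletion(1, 9999)], gene)


# ---------------------------------------------------------------------------
# Order sheet
# ---------------------------------------------------------------------------


def _dummy_fragment(name, seq):
    region = FragmentRegion(0, len(seq), (name,), 0)
    return Fragment(name=name, region=region, mutation_label=name,
                    mutant_region_seq=seq, flank5="", flank3="",
                    silent_markers=(), cost=0.0)


def test_well_layout_and_cost(tmp_path):
    assert [well_position(i)[1] for i in range(3)] == ["A1", "A2", "A3"]
    assert well_position(12) == (1, "B1")
    assert well_position(96) == (2, "A1")  # 97th fragment starts plate 2
    frags = [_dummy_fragment("f1", "A" * 300)]
    out = tmp_path / "sheet.csv"
    write_order_sheet(frags, [], DesignSettings(cost_per_bp=0.05), str(out))
    rows = out.read_text().strip().splitlines()
    assert rows[1].split(",")[:4] == ["f1", "dsDNA_fragment", "1", "A1"]
    assert rows[1].split(",")[-1] == "15.00"  # 300 bp x 0.05/bp


# ---------------------------------------------------------------------------
# Mutant GenBank output
# ---------------------------------------------------------------------------


def _design_one(plasmid, gene, spec, settings):
    from mutfrag import DesignView, uniform_usage_table
    from mutfrag.fragments import define_region, design_fragment
    view = DesignView.build(plasmid, gene)
    region = define_region([spec], view, settings, 0)
    return design_fragment(region, spec, view, uniform_usage_table(), settings)


def test_genbank_roundtrip_and_point_diff(small_gene, settings, tmp_path):
    """The point-mutant plasmid differs from wild type at exactly the
    mutated codon plus the silent-marker codons (brute-force diff)."""
    plasmid, gene = small_gene
    protein = str(Seq(gene.cds).translate())
    spec = PointMutation(protein[99], 100, "W" if protein[99] != "W" else "F")
    frag = _design_one(plasmid, gene, spec, settings)
    record = build_mutant_record(plasmid, gene, frag)
    assert len(record.seq) == len(plasmid)  # no net indel
    path = tmp_path / "mut.gb"
    SeqIO.write(record, str(path), "genbank")
    back = SeqIO.read(str(path), "genbank")
    assert str(back.seq) == str(record.seq)
    assert back.annotations["topology"] == "circular"
    diffs = {i for i, (a, b) in
             enumerate(zip(plasmid.sequence, str(record.seq))) if a != b}
    allowed_codons = {100} | {r for r, _, _ in frag.silent_markers}
    allowed = set()
    for r in allowed_codons:
        start = gene.plasmid_offset + 3 * (r - 1)
        allowed |= {start, start + 1, start + 2}
    assert diffs and diffs <= allowed
    assert len(frag.silent_markers) == 2 * settings.silent_markers_per_end


def test_genbank_indel_length_bookkeeping(small_gene, settings):
    plasmid, gene = small_gene
    frag_del = _design_one(plasmid, gene, Deletion(80, 89), settings)
    rec = build_mutant_record(plasmid, gene, frag_del)
    assert len(rec.seq) == len(plasmid) - 30
    frag_ins = _design_one(plasmid, gene, Insertion(80, "GGSGG"), settings)
    rec = build_mutant_record(plasmid, gene, frag_ins)
    assert len(rec.seq) == len(plasmid) + 15


def test_minus_strand_gene_design_maps_back(settings):
    """Designing on a minus-strand gene yields the same protein edit after
    mapping back to the original plasmid orientation."""
    from mutfrag.simulate import random_gene
    p, g = random_gene(150, seed=3)
    flipped = Plasmid(p.name, reverse_complement(p.sequence))
    gene = locate_gene(flipped, g.cds)
    assert gene.strand == "-"
    protein = str(Seq(g.cds).translate())
    spec = PointMutation(protein[59], 60, "A" if protein[59] != "A" else "V")
    frag = _design_one(flipped, gene, spec, settings)
    record = build_mutant_record(flipped, gene, frag)
    mut_cds = reverse_complement(str(record.seq))  # recover coding strand
    # the mutant CDS is still embedded at the same coding-strand offset
    view_off = (len(flipped) - (gene.plasmid_offset + len(g.cds))) % len(flipped)
    codon = mut_cds[view_off + 177 : view_off + 180]
    assert str(Seq(codon).translate()) == spec.mut_aa


def test_snapgene_refused(tmp_path):
    path = tmp_path / "plasmid.dna"
    path.write_bytes(b"\x00binary")
    with pytest.raises(DesignError, match="GenBank"):
        read_plasmid_genbank(str(path))
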