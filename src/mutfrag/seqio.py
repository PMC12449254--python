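"""Input parsing (plasmid GenBank, gene FASTA, mutation list) and output
writers (per-mutant GenBank files, order sheet CSV).

Mutation-list grammar, one spec per non-empty non-comment line:

* ``L123A``            point mutation (wild-type aa, 1-based residue, new aa)
* ``G45D+S210R``       combined mutation (members must co-occur, hence
  land in one fragment)
* ``del70-75``         deletion of residues 70..75 inclusive
* ``ins5-GGS``         insertion of peptide GGS after residue 5

Lines starting with ``#`` are comments. Duplicate labels are an error.
"""
from __future__ import annotations

import csv
import re

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codons import translate_codon
from .model import (
    AA_LETTERS,
    CombinedMutation,
    Deletion,
    DesignError,
    DesignSettings,
    DesignView,
    Fragment,
    GeneContext,
    GeneLocationError,
    Insertion,
    MutationParseError,
    MutationSpec,
    MutationValidationError,
    Plasmid,
    PointMutation,
    PointSub,
    Primer,
    PrimerPair,
    circular_slice,
    reverse_complement,
)

_POINT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DEL_RE = re.compile(r"^del(\d+)-(\d+)$")
_INS_RE = re.compile(r"^ins(\d+)-([A-Z]+)$")

#: fixed LOCUS date so identical designs give byte-identical files
_GENBANK_DATE = "01-JAN-1980"


# ---------------------------------------------------------------------------
# Mutation list
# ---------------------------------------------------------------------------


def _parse_point(tok: str, lineno: int) -> PointSub:
    m = _POINT_RE.match(tok)
    if not m:
        raise MutationParseError(f"line {lineno}: cannot parse point spec {tok!r}")
    wt, res, mut = m.group(1), int(m.group(2)), m.group(3)
    for aa in (wt, mut):
        if aa not in AA_LETTERS:
            raise MutationParseError(
                f"line {lineno}: {aa!r} is not a standard amino acid in {tok!r}")
    return PointSub(wt, res, mut)


def parse_mutation_line(line: str, lineno: int = 0) -> MutationSpec:
    line = line.strip()
    m = _DEL_RE.match(line)
    if m:
        first, last = int(m.group(1)), int(m.group(2))
        if first > last:
            raise MutationParseError(f"line {lineno}: deletion {line!r} has first > last")
        return Deletion(first, last)
    m = _INS_RE.match(line)
    if m:
        anchor, peptide = int(m.group(1)), m.group(2)
        bad = set(peptide) - set(AA_LETTERS)
        if bad:
            raise MutationParseError(
                f"line {lineno}: insertion peptide contains non-amino-acid "
                f"letters {sorted(bad)}")
        return Insertion(anchor, peptide)
    if "+" in line:
        subs = tuple(_parse_point(tok.strip(), lineno) for tok in line.split("+"))
        return CombinedMutation(subs)
    sub = _parse_point(line, lineno)
    return PointMutation(sub.wt_aa, sub.residue, sub.mut_aa)


def parse_mutation_file(path: str) -> list[MutationSpec]:
    specs: list[MutationSpec] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            spec = parse_mutation_line(line, lineno)
            if spec.label in seen:
                raise MutationParseError(
                    f"line {lineno}: duplicate mutation {spec.label!r} "
                    f"(first seen on line {seen[spec.label]})")
            seen[spec.label] = lineno
            specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# Plasmid / gene input
# ---------------------------------------------------------------------------


def read_plasmid_genbank(path: str) -> Plasmid:
    if path.lower().endswith(".dna"):
        raise DesignError(
            "SnapGene .dna files are a proprietary binary format; please "
            "export the plasmid as GenBank (.gb) and retry")
    record = SeqIO.read(path, "genbank")
    features = []
    for feat in record.features:
        label = (feat.qualifiers.get("label") or feat.qualifiers.get("gene")
                 or feat.qualifiers.get("product") or [feat.type])[0]
        features.append((label, int(feat.location.start), int(feat.location.end),
                         feat.location.strand or 1))
    return Plasmid(record.name or record.id, str(record.seq), circular=True,
                   features=features)


def read_gene_fasta(path: str) -> tuple[str, str]:
    record = SeqIO.read(path, "fasta")
    return record.id, str(record.seq).upper()


def locate_gene(plasmid: Plasmid, gene_seq: str, gene_id: str = "gene") -> GeneContext:
    """Find the unique occurrence of the gene on either strand of the
    circular plasmid."""
    gene_seq = gene_seq.upper()
    if len(gene_seq) % 3 != 0:
        raise GeneLocationError(
            f"gene length {len(gene_seq)} is not a multiple of 3")
    n = len(plasmid)
    if len(gene_seq) > n:
        raise GeneLocationError("gene longer than plasmid")

    def occurrences(target: str) -> list[int]:
        hay = plasmid.sequence + plasmid.sequence[: len(target) - 1]
        out, start = [], 0
        while True:
            i = hay.find(target, start)
            if i == -1:
                break
            out.append(i)
            start = i + 1
        return out

    fwd = occurrences(gene_seq)
    rev = occurrences(reverse_complement(gene_seq))
    hits = [(p, "+") for p in fwd] + [(p, "-") for p in rev]
    if not hits:
        raise GeneLocationError("gene not found in plasmid (either strand)")
    if len(hits) > 1:
        raise GeneLocationError(
            f"gene occurs {len(hits)} times in the plasmid; cannot decide "
            "which copy to mutate")
    offset, strand = hits[0]
    return GeneContext(gene_id, gene_seq, offset, strand)


def validate_mutations(muts: list[MutationSpec], gene: GeneContext
                       ) -> list[MutationSpec]:
    """Check every spec against the gene: residue bounds and wild-type
    amino-acid identity (via codon-by-codon translation)."""
    n = gene.n_residues
    for spec in muts:
        for r in spec.residues():
            if not 1 <= r <= n:
                raise MutationValidationError(
                    f"{spec.label}: residue {r} outside gene (1..{n})")
        if spec.kind in ("point", "combined"):
            for sub in spec.subs:
                found = translate_codon(gene.codon(sub.residue))
                if found != sub.wt_aa:
                    raise MutationValidationError(
                        f"{spec.label}: residue {sub.residue} is {found}, "
                        f"not {sub.wt_aa}")
        elif spec.kind == "insertion" and not 1 <= spec.anchor <= n:
            raise MutationValidationError(
                f"{spec.label}: anchor {spec.anchor} outside gene (1..{n})")
    return muts


# ---------------------------------------------------------------------------
# Mutant plasmid GenBank output
# ---------------------------------------------------------------------------


def _sanitize_locus(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", name)[:20] or "mutant"


def build_mutant_record(plasmid: Plasmid, gene: GeneContext, fragment: Fragment,
                        primers: list[Primer] | None = None) -> SeqRecord:
    """The full mutant plasmid: wild-type plasmid with the fragment's
    mutated region substituted, annotated with the region, every mutation,
    every silent marker and every primer site."""
    view = DesignView.build(plasmid, gene)
    n = len(plasmid)
    vs, ve = view.cds_to_view(fragment.region.start, fragment.region.end)
    region_len = fragment.region.length
    mut_region = fragment.mutant_region_seq
    shift = len(mut_region) - region_len
    ns = vs % n

    if ns + region_len <= n:  # no origin wrap
        mutant_view = view.seq[:ns] + mut_region + view.seq[ns + region_len:]

        def map_pos(p: int) -> int:
            p %= n
            return p if p < ns else p + shift

        region_at = ns
    else:  # region spans the origin: emit with the origin at the region start
        mutant_view = mut_region + circular_slice(view.seq, ve, vs + n)

        def map_pos(p: int) -> int:
            return (p - (ve % n)) % n + len(mut_region)

        region_at = 0

    m = len(mutant_view)
    feats: list[tuple[str, int, int, int, str]] = [
        (fragment.name, region_at, region_at + len(mut_region), 1, "misc_feature")
    ]
    for label, (s, e) in sorted(fragment.feature_offsets.items()):
        a, b = region_at + s, region_at + e
        if a == b:  # deletion junction: mark one flanking base
            a, b = max(a - 1, region_at), min(a + 1, region_at + len(mut_region))
        ftype = "misc_feature"
        feats.append((label, a, b, 1, ftype))
    for primer in primers or []:
        ps = primer.plasmid_position
        # in region-relative coordinates the replaced interval is [0, region_len)
        rel = (ps - ns) % n
        overlaps = rel < region_len or rel + len(primer) > n
        if overlaps:
            # its wild-type binding site no longer exists in this mutant
            continue
        feats.append((primer.name, map_pos(ps), map_pos(ps) + len(primer),
                      primer.strand, "primer_bind"))

    if gene.strand == "-":
        mutant_seq = reverse_complement(mutant_view)
        feats = [(lab, m - e, m - s, -st, ft) for lab, s, e, st, ft in feats]
    else:
        mutant_seq = mutant_view

    record = SeqRecord(
        Seq(mutant_seq),
        id=_sanitize_locus(fragment.name),
        name=_sanitize_locus(fragment.name),
        description=f"mutant plasmid {plasmid.name} {fragment.mutation_label}",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "data_file_division": "SYN",
            "date": _GENBANK_DATE,
        },
    )
    for lab, s, e, st, ft in feats:
        if not 0 <= s < e <= m:
            continue
        record.features.append(
            SeqFeature(SimpleLocation(s, e, strand=st), type=ft,
                       qualifiers={"label": [lab]}))
    return record


def write_mutant_genbank(plasmid: Plasmid, gene: GeneContext, fragment: Fragment,
                         primers: list[Primer], out_path: str) -> None:
    record = build_mutant_record(plasmid, gene, fragment, primers)
    with open(out_path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


# ---------------------------------------------------------------------------
# Order sheet
# ---------------------------------------------------------------------------


def well_position(index: int) -> tuple[int, str]:
    """Row-major 96-well layout: index 0 -> plate 1 well A1; index 96 ->
    plate 2 well A1."""
    plate, within = divmod(index, 96)
    row, col = divmod(within, 12)
    return plate + 1, f"{'ABCDEFGH'[row]}{col + 1}"


def write_order_sheet(fragments: list[Fragment],
                      primers: list[Primer],
                      settings: DesignSettings,
                      out_path: str) -> None:
    """CSV with one row per fragment (plate/well filled row-major, cost =
    length x cost_per_bp) and one row per primer."""
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "type", "plate", "well", "sequence",
                         "length_bp", "cost"])
        for i, frag in enumerate(fragments):
            plate, well = well_position(i)
            seq = frag.full_seq
            writer.writerow([frag.name, "dsDNA_fragment", plate, well, seq,
                             len(seq), f"{len(seq) * settings.cost_per_bp:.2f}"])
        for primer in primers:
            writer.writerow([primer.name, "primer", "", "", primer.sequence,
                             len(primer), ""])


def flatten_primers(pairs: list[PrimerPair], sequencing: list[Primer]
                    ) -> list[Primer]:
    out: list[Primer] = []
    for pair in pairs:
        out.extend([pair.forward, pair.reverse])
    out.extend(sequencing)
    return out
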