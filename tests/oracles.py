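"""Independent oracles shared by the test suite.

Everything here is re-derived from first principles (residue arithmetic,
exhaustive enumeration, direct string editing) and never calls into the
search/design code paths it is used to check.
"""
import itertools

from Bio.Seq import Seq

from mutfrag import CombinedMutation, Deletion, Insertion, PointMutation, PointSub
from mutfrag.codons import translate_codon


# ---------------------------------------------------------------------------
# Partition enumeration (clustering oracle)
# ---------------------------------------------------------------------------


def oracle_hull_net(spec):
    """A spec's wild-type bp hull and net indel length, from residue
    semantics."""
    if spec.kind == "point":
        r = spec.residue
        return 3 * (r - 1), 3 * r, 0
    if spec.kind == "combined":
        rs = [s.residue for s in spec.members]
        return 3 * (min(rs) - 1), 3 * max(rs), 0
    if spec.kind == "deletion":
        return (3 * (spec.first - 1), 3 * spec.last,
                -3 * (spec.last - spec.first + 1))
    return 3 * spec.anchor, 3 * spec.anchor, 3 * len(spec.peptide)


def oracle_block(block, settings):
    """(valid, implied fragment length) of one candidate cluster: a
    wild-type window length W must exist so that every member's mutant
    fragment W + net + 2*min_flank fits [min_fragment, max_fragment]."""
    hulls = [oracle_hull_net(s) for s in block]
    s0 = min(h[0] for h in hulls)
    e0 = max(h[1] for h in hulls)
    span = (e0 + (-e0) % 3) - (s0 - s0 % 3)
    nets = [h[2] for h in hulls]
    core = settings.min_fragment_bp - 2 * settings.min_flank_bp
    w_low = max(span, core - min(nets), 0)
    w_low += (-w_low) % 3
    w_high = settings.max_fragment_bp - 2 * settings.min_flank_bp - max(nets)
    return w_low <= w_high, w_low + 2 * settings.min_flank_bp + sum(nets)


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def oracle_minima(specs, settings):
    """Brute force: (minimum valid block count over ALL set partitions,
    minimum total bp over position-contiguous partitions). Either may be
    None when no valid partition of that family exists."""
    best_k = None
    for part in set_partitions(list(specs)):
        if all(oracle_block(b, settings)[0] for b in part):
            best_k = len(part) if best_k is None else min(best_k, len(part))
    atoms = sorted(specs, key=lambda s: oracle_hull_net(s)[:2])
    best_contig = None
    n = len(atoms)
    for cuts in itertools.product([0, 1], repeat=n - 1):
        blocks, cur = [], [atoms[0]]
        for i, cut in enumerate(cuts):
            if cut:
                blocks.append(cur)
                cur = []
            cur.append(atoms[i + 1])
        blocks.append(cur)
        checks = [oracle_block(b, settings) for b in blocks]
        if all(v for v, _ in checks):
            total = sum(t for _, t in checks)
            best_contig = total if best_contig is None else min(best_contig,
                                                                total)
    return best_k, best_contig


def random_panel(rng, gene):
    """2-8 mutation atoms: mostly points, some combined pairs, at most one
    indel — the composition of a realistic mutant-library request."""
    last = gene.n_residues - 1
    n_atoms = rng.randint(2, 8)
    specs, used, indel_used = [], set(), False

    def point(r):
        wt = translate_codon(gene.codon(r))
        return PointMutation(wt, r, "G" if wt != "G" else "A")

    while len(specs) < n_atoms:
        roll = rng.random()
        if roll < 0.15 and not indel_used:
            if rng.random() < 0.5:
                length = rng.randint(1, 120)
                start = rng.randint(2, last - length)
                if used & set(range(start, start + length)):
                    continue
                specs.append(Deletion(start, start + length - 1))
                used |= set(range(start, start + length))
            else:
                specs.append(Insertion(rng.randint(1, last),
                                       "G" * rng.randint(1, 150)))
            indel_used = True
        elif roll < 0.35:
            r1 = rng.randint(2, last - 500)
            r2 = r1 + rng.randint(5, 480)
            if {r1, r2} & used:
                continue
            p1, p2 = point(r1), point(r2)
            specs.append(CombinedMutation((
                PointSub(p1.wt_aa, r1, p1.mut_aa),
                PointSub(p2.wt_aa, r2, p2.mut_aa))))
            used |= {r1, r2}
        else:
            r = rng.randint(2, last)
            if r in used:
                continue
            specs.append(point(r))
            used.add(r)
    return specs


# ---------------------------------------------------------------------------
# Protein editing (translation-fidelity oracle)
# ---------------------------------------------------------------------------


def expected_protein(gene, spec):
    """Edit the wild-type protein string directly."""
    prot = str(Seq(gene.cds).translate())
    if spec.kind in ("point", "combined"):
        chars = list(prot)
        for sub in spec.subs:
            chars[sub.residue - 1] = sub.mut_aa
        return "".join(chars)
    if spec.kind == "deletion":
        return prot[: spec.first - 1] + prot[spec.last :]
    return prot[: spec.anchor] + spec.peptide + prot[spec.anchor :]


def mutant_cds(gene, region, fragment):
    """Splice the fragment's mutated region back into the wild-type CDS
    (dropping any backbone overhang the region carries)."""
    cds_len = len(gene.cds)
    up = max(0, -region.start)
    down = max(0, region.end - cds_len)
    core = fragment.mutant_region_seq[up : len(fragment.mutant_region_seq)
                                      - down or None]
    return (gene.cds[: max(region.start, 0)] + core
            + gene.cds[min(region.end, cds_len) :])
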