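"""Turn a mutation cluster into a synthesizable mutant dsDNA fragment.

Pipeline per cluster: define a codon-aligned region around the member
mutations, apply the mutations with the expression organism's preferred
codons, add Tm-constrained homology flanks taken verbatim from the plasmid,
and toggle silent marker codons near both region ends so a short sequencing
read over either fragment junction identifies the insert.

Each member mutation of a region yields its own Fragment (one mutant
molecule); the region — and therefore the plasmid-linearization PCR — is
shared by all fragments of the cluster.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import cluster_stats
from .codons import CodonUsageTable, most_frequent_codon, silent_alternative
from .model import (
    DesignSettings,
    DesignView,
    Fragment,
    FragmentDesignError,
    FragmentRegion,
    MutationSpec,
    spec_hull,
)
from .primers import melting_temperature


def _align_down(x: int) -> int:
    return x - x % 3


def _align_up(x: int) -> int:
    return x + (-x) % 3


# ---------------------------------------------------------------------------
# Region definition
# ---------------------------------------------------------------------------


def define_region(specs: list[MutationSpec], view: DesignView,
                  settings: DesignSettings, cluster_index: int = 0
                  ) -> FragmentRegion:
    """Smallest codon-aligned interval containing all member extents,
    expanded symmetrically until every member's mutant fragment reaches the
    minimum size; expansion that hits a CDS boundary is shifted to the
    other side, and spills into the plasmid backbone only when the CDS
    itself is too short (keeping codon phase inside the CDS)."""
    st = cluster_stats(specs, settings)
    if not st.valid:
        labels = ", ".join(s.label for s in specs)
        raise FragmentDesignError(
            f"region too large for [{labels}]: wild-type region needs "
            f">= {st.w_low} bp but at most {st.w_high} bp fits the "
            f"{settings.max_fragment_bp} bp fragment maximum")
    hulls = [spec_hull(s) for s in specs]
    s0 = _align_down(min(h[0] for h in hulls))
    e0 = _align_up(max(h[1] for h in hulls))
    w = st.w_low
    extra_codons = (w - (e0 - s0)) // 3
    left = extra_codons // 2
    s = s0 - 3 * left
    e = s + w
    cds_len = len(view.gene.cds)
    if s < 0:  # shift the remainder to the 3' side
        s, e = 0, w
    if e > cds_len:
        s, e = cds_len - w, cds_len
    if s < 0:  # CDS shorter than the region: extend into backbone evenly
        over = -s
        s = -_align_up(over // 2)
        e = s + w
    return FragmentRegion(s, e, tuple(x.label for x in specs), cluster_index)


# ---------------------------------------------------------------------------
# Applying mutations
# ---------------------------------------------------------------------------


@dataclass
class _Codon:
    seq: str
    residue: int | None  # original residue number; None for inserted codons
    mutated: bool = False
    marker: bool = False


@dataclass
class MutantRegion:
    """Working representation of a region being mutated codon-by-codon."""

    upstream: str               # backbone bases 5' of the CDS, if any
    codons: list[_Codon]
    downstream: str             # backbone bases 3' of the CDS, if any
    feature_offsets: dict[str, tuple[int, int]] = field(default_factory=dict)
    junctions: list[tuple[str, _Codon | None]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return self.upstream + "".join(c.seq for c in self.codons) + self.downstream

    def span_of(self, codons: list["_Codon"]) -> tuple[int, int]:
        idx = [i for i, c in enumerate(self.codons) if any(c is x for x in codons)]
        s = len(self.upstream) + 3 * min(idx)
        return s, len(self.upstream) + 3 * (max(idx) + 1)


def apply_mutations(region: FragmentRegion, view: DesignView,
                    specs: list[MutationSpec], table: CodonUsageTable
                    ) -> MutantRegion:
    """Rewrite the wild-type region with the given mutations.

    Substituted residues and inserted peptides get the table's most
    frequent codon; deleted codons are excised. Length bookkeeping:
    output = region length + 3*(inserted - deleted residues).
    """
    gene = view.gene
    cds_len = len(gene.cds)
    cs, ce = max(region.start, 0), min(region.end, cds_len)
    upstream = (view.slice(view.gene_offset + region.start, view.gene_offset)
                if region.start < 0 else "")
    downstream = (view.slice(view.gene_offset + cds_len,
                             view.gene_offset + region.end)
                  if region.end > cds_len else "")
    codons = [_Codon(gene.cds[i : i + 3], i // 3 + 1) for i in range(cs, ce, 3)]
    mreg = MutantRegion(upstream, codons, downstream)
    by_residue = {c.residue: c for c in codons}

    applied: dict[str, list[_Codon]] = {}
    for spec in specs:
        if spec.kind in ("point", "combined"):
            for sub in spec.subs:
                codon = by_residue.get(sub.residue)
                if codon is None:
                    raise FragmentDesignError(
                        f"{sub.label}: residue outside region "
                        f"[{region.start}, {region.end})")
                codon.seq = most_frequent_codon(table, sub.mut_aa)
                codon.mutated = True
                applied[sub.label] = [codon]
        elif spec.kind == "deletion":
            victims = []
            for r in range(spec.first, spec.last + 1):
                codon = by_residue.get(r)
                if codon is None:
                    raise FragmentDesignError(
                        f"{spec.label}: residue {r} outside region")
                victims.append(codon)
            first_idx = mreg.codons.index(victims[0])
            for v in victims:
                mreg.codons.remove(v)
                del by_residue[v.residue]
            after = (mreg.codons[first_idx]
                     if first_idx < len(mreg.codons) else None)
            mreg.junctions.append((spec.label, after))
        else:  # insertion
            boundary = 3 * spec.anchor
            ins_idx = (boundary - cs) // 3
            if not 0 <= ins_idx <= len(mreg.codons):
                raise FragmentDesignError(
                    f"{spec.label}: insertion point outside region")
            # locate insertion index in the (possibly edited) codon list
            new = [_Codon(most_frequent_codon(table, aa), None, mutated=True)
                   for aa in spec.peptide]
            mreg.codons[ins_idx:ins_idx] = new
            applied[spec.label] = new
    # resolve feature offsets after all edits
    for label, members in applied.items():
        mreg.feature_offsets[label] = mreg.span_of(members)
    for label, after in mreg.junctions:
        if after is not None:
            s, _ = mreg.span_of([after])
        else:
            s = len(mreg.upstream) + 3 * len(mreg.codons)
        mreg.feature_offsets[label] = (s, s)
    return mreg


def place_silent_markers(mreg: MutantRegion, table: CodonUsageTable,
                         settings: DesignSettings
                         ) -> list[tuple[int, str, str]]:
    """Toggle the ``silent_markers_per_end`` usable codons nearest each end
    of the mutant region to their preferred synonymous alternative.

    Usable: inside the CDS, not part of an intended mutation, and the amino
    acid has more than one codon. Translation is unchanged by construction.
    """
    per_end = settings.silent_markers_per_end
    eligible = [i for i, c in enumerate(mreg.codons)
                if c.residue is not None and not c.mutated
                and silent_alternative(table, c.seq) is not None]
    chosen = eligible[:per_end]
    right = [i for i in eligible[::-1] if i not in chosen][:per_end]
    chosen = chosen + right[::-1]
    if len(chosen) < 2 * per_end:
        mreg.warnings.append(
            f"only {len(chosen)} of {2 * per_end} silent marker codons "
            "could be placed")
    markers: list[tuple[int, str, str]] = []
    for i in sorted(chosen):
        codon = mreg.codons[i]
        alt = silent_alternative(table, codon.seq)
        assert alt is not None and codon.residue is not None
        markers.append((codon.residue, codon.seq, alt))
        codon.seq = alt
        codon.marker = True
        s, e = mreg.span_of([codon])
        mreg.feature_offsets[f"silent_{codon.residue}"] = (s, e)
    return markers


# ---------------------------------------------------------------------------
# Flanks and assembly
# ---------------------------------------------------------------------------


def design_flank(view: DesignView, boundary: int, side: str,
                 settings: DesignSettings,
                 max_len: int | None = None) -> tuple[str, str | None]:
    """Wild-type plasmid subsequence abutting ``boundary`` whose melting
    temperature lands inside the flank Tm window, preferring the length
    closest to the window midpoint. Falls back to the closest-Tm length
    (with a warning) when no admissible length reaches the window —
    pathological base composition, or a ``max_len`` budget imposed by the
    provider's fragment-size maximum."""
    lo, hi = settings.flank_tm_window
    mid = (lo + hi) / 2.0
    cap = settings.max_flank_bp if max_len is None else min(
        settings.max_flank_bp, max_len)
    if cap < settings.min_flank_bp:
        raise FragmentDesignError(
            f"{side} flank: length budget {cap} bp below the "
            f"{settings.min_flank_bp} bp minimum")
    best_in: tuple[float, str] | None = None
    best_any: tuple[float, str] | None = None
    for length in range(settings.min_flank_bp, cap + 1):
        if side == "5prime":
            seq = view.slice(boundary - length, boundary)
        else:
            seq = view.slice(boundary, boundary + length)
        tm = melting_temperature(seq)
        dev = abs(tm - mid)
        if lo <= tm <= hi and (best_in is None or dev < best_in[0]):
            best_in = (dev, seq)
        if best_any is None or dev < best_any[0]:
            best_any = (dev, seq)
    if best_in is not None:
        return best_in[1], None
    assert best_any is not None
    return best_any[1], (f"{side} flank: no length in "
                         f"[{settings.min_flank_bp}, {cap}] bp "
                         f"reaches Tm window [{lo}, {hi}] C; closest used")


def region_flanks(view: DesignView, region: FragmentRegion,
                  settings: DesignSettings,
                  specs: list[MutationSpec] | None = None
                  ) -> tuple[str, str, tuple[str, ...]]:
    """Flanks shared by all fragments of a region. The flank length budget
    is set by the longest member fragment so that no mutant molecule can
    exceed the provider maximum."""
    worst_net = max((s.net_indel_bp for s in specs), default=0) if specs else 0
    budget = settings.max_fragment_bp - (region.length + worst_net)
    cap5 = budget // 2
    cap3 = budget - cap5
    vs, ve = view.cds_to_view(region.start, region.end)
    flank5, w5 = design_flank(view, vs, "5prime", settings, max_len=cap5)
    flank3, w3 = design_flank(view, ve, "3prime", settings, max_len=cap3)
    warnings = tuple(w for w in (w5, w3) if w)
    return flank5, flank3, warnings


def design_fragment(region: FragmentRegion, spec: MutationSpec,
                    view: DesignView, table: CodonUsageTable,
                    settings: DesignSettings,
                    flanks: tuple[str, str, tuple[str, ...]] | None = None,
                    name: str | None = None) -> Fragment:
    """Build the complete mutant fragment for one mutation on its region."""
    mreg = apply_mutations(region, view, [spec], table)
    markers = place_silent_markers(mreg, table, settings)
    if flanks is None:
        flanks = region_flanks(view, region, settings, [spec])
    flank5, flank3, flank_warnings = flanks
    if name is None:
        name = (f"{view.plasmid.name}_{view.gene.gene_id}_"
                f"r{region.cluster_index + 1}_{spec.label}")
    seq = flank5 + mreg.sequence + flank3
    if not settings.min_fragment_bp <= len(seq) <= settings.max_fragment_bp:
        raise FragmentDesignError(
            f"fragment {name}: length {len(seq)} bp outside "
            f"[{settings.min_fragment_bp}, {settings.max_fragment_bp}]")
    return Fragment(
        name=name,
        region=region,
        mutation_label=spec.label,
        mutant_region_seq=mreg.sequence,
        flank5=flank5,
        flank3=flank3,
        silent_markers=tuple(markers),
        cost=len(seq) * settings.cost_per_bp,
        feature_offsets=dict(mreg.feature_offsets),
        warnings=tuple(mreg.warnings) + flank_warnings,
    )
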