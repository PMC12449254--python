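"""Linearization and sequencing primer design with Tm/GC, secondary
structure and off-target diagnostics.

Selection is a deterministic window scan: primer lengths are swept and the
candidate whose nearest-neighbor Tm lies inside the configured window and
closest to its midpoint wins. Tm model: unified dinucleotide
nearest-neighbor parameters at 50 mM monovalent salt and 500 nM oligo.
"""
from __future__ import annotations

import math

from Bio.SeqUtils import MeltingTemp as _mt
from Bio.SeqUtils import gc_fraction as _gc

from .model import (
    DesignSettings,
    DesignView,
    DNA_ALPHABET,
    Primer,
    PrimerDesignError,
    PrimerPair,
    reverse_complement,
)

#: off-target probe: the primer's 3'-terminal k-mer
OFF_TARGET_KMER = 12
HAIRPIN_MIN_STEM = 4
HAIRPIN_MIN_LOOP = 3
SELF_DIMER_MIN_RUN = 8


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor duplex Tm in degrees C (unified parameter set,
    50 mM Na+, 500 nM oligo). Identical for a sequence and its reverse
    complement (duplex symmetry)."""
    seq = seq.upper()
    if len(seq) < 8:
        raise PrimerDesignError(f"sequence too short for Tm ({len(seq)} < 8 nt)")
    if set(seq) - DNA_ALPHABET:
        raise PrimerDesignError("Tm input must be plain ACGT")
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=50, dnac1=500, dnac2=0))


# ---------------------------------------------------------------------------
# Structure / uniqueness checks
# ---------------------------------------------------------------------------


def check_secondary_structure(seq: str) -> frozenset[str]:
    """Flags: ``hairpin`` for an internal inverted repeat (stem >= 4 bp,
    loop >= 3 nt); ``self_dimer`` for a self-complementary run >= 8 bp."""
    seq = seq.upper()
    flags = set()
    n = len(seq)
    stem = HAIRPIN_MIN_STEM
    for i in range(n - stem + 1):
        probe = reverse_complement(seq[i : i + stem])
        if probe in seq[i + stem + HAIRPIN_MIN_LOOP:]:
            flags.add("hairpin")
            break
    rc = reverse_complement(seq)
    run = SELF_DIMER_MIN_RUN
    for i in range(n - run + 1):
        if seq[i : i + run] in rc:
            flags.add("self_dimer")
            break
    return frozenset(flags)


def _binding_positions(kmer: str, template: str, circular: bool = True) -> set[int]:
    """Positions where ``kmer`` (or its reverse complement) matches the
    plus strand; a palindromic site yields one position, not two."""
    rc = reverse_complement(kmer)
    hay = template + (template[: len(kmer) - 1] if circular else "")
    out = set()
    for probe in {kmer, rc}:
        start = 0
        while True:
            i = hay.find(probe, start)
            if i == -1:
                break
            out.add(i % len(template))
            start = i + 1
    return out


def check_off_target(primer_seq: str, plasmid_seq: str,
                     circular: bool = True) -> frozenset[str]:
    """``off_target`` when the primer's 3'-terminal 12-mer binds more than
    one site across both strands of the (circular) plasmid."""
    end = primer_seq.upper()[-OFF_TARGET_KMER:]
    sites = _binding_positions(end, plasmid_seq.upper(), circular)
    return frozenset({"off_target"} if len(sites) > 1 else ())


# ---------------------------------------------------------------------------
# Candidate scanning
# ---------------------------------------------------------------------------


def _candidates(view: DesignView, anchor: int, direction: str,
                settings: DesignSettings) -> list[Primer]:
    """All primer lengths whose Tm is inside the window at a fixed
    annealing anchor. ``fwd``: 5' end at ``anchor`` extending 3'-ward on the
    plus strand; ``rev``: 3' end at ``anchor`` on the minus strand."""
    lo, hi = settings.primer_tm_window
    glo, ghi = settings.primer_gc_window
    n = len(view.seq)
    out = []
    for length in range(settings.primer_min_len, settings.primer_max_len + 1):
        if direction == "fwd":
            site = anchor % n
            seq = view.slice(anchor, anchor + length)
            strand = 1
        else:
            site = (anchor - length) % n
            seq = reverse_complement(view.slice(anchor - length, anchor))
            strand = -1
        tm = melting_temperature(seq)
        if not lo <= tm <= hi:
            continue
        gc = _gc(seq)
        warnings = ()
        if not glo <= gc <= ghi:
            warnings = (f"GC fraction {gc:.2f} outside [{glo}, {ghi}]",)
        out.append(Primer(name="", sequence=seq, plasmid_position=site,
                          strand=strand, tm=tm, gc_fraction=gc,
                          warnings=warnings))
    return out


def design_linearization_pair(view: DesignView, region_interval: tuple[int, int],
                              settings: DesignSettings,
                              name_prefix: str = "lin") -> PrimerPair:
    """The outward-facing pair that amplifies the whole plasmid minus the
    fragment region: forward anneals from the region's 3' boundary, reverse
    ends exactly at the 5' boundary on the opposite strand, so the
    linearized ends are perfectly homologous to the fragment flanks."""
    vs, ve = region_interval
    n = len(view.seq)
    region_len = ve - vs
    fwd = _candidates(view, ve, "fwd", settings)
    if not fwd:
        raise PrimerDesignError(
            "forward linearization primer: no length reaches the Tm window")
    rev = _candidates(view, vs, "rev", settings)
    if not rev:
        raise PrimerDesignError(
            "reverse linearization primer: no length reaches the Tm window")
    mid = sum(settings.primer_tm_window) / 2.0
    for cands in (fwd, rev):
        for c in cands:
            c.flags = (check_secondary_structure(c.sequence)
                       | check_off_target(c.sequence, view.seq))
    pairs = [(f, r) for f in fwd for r in rev
             if abs(f.tm - r.tm) <= settings.pair_tm_diff_max]
    if not pairs:
        raise PrimerDesignError(
            f"no linearization pair with Tm difference <= "
            f"{settings.pair_tm_diff_max} C")
    # prefer check-clean candidates; a length scan can often dodge a
    # hairpin/self-dimer or an off-target 3' end at the fixed boundary
    f, r = min(pairs, key=lambda p: (len((p[0].flags | p[1].flags)
                                         & {"off_target"}),
                                     len(p[0].flags) + len(p[1].flags),
                                     abs(p[0].tm - mid) + abs(p[1].tm - mid),
                                     len(p[0]), len(p[1])))
    f.name = f"{name_prefix}_fwd"
    r.name = f"{name_prefix}_rev"
    for primer in (f, r):
        if "off_target" in primer.flags:
            raise PrimerDesignError(
                f"linearization primer {primer.name} fails checks: "
                f"{', '.join(sorted(primer.flags))}")
        if primer.flags:
            primer.warnings = primer.warnings + tuple(
                f"secondary structure: {fl}" for fl in sorted(primer.flags))
    return PrimerPair(forward=f, reverse=r,
                      product_length_bp=n - region_len,
                      purpose="linearization")


def design_sequencing_primers(view: DesignView, region_interval: tuple[int, int],
                              settings: DesignSettings,
                              name_prefix: str = "seq") -> list[Primer]:
    """Plus-strand primers walking the region: the first 100-200 bp
    upstream of the region start, then one every <= 500 bp until the region
    end is covered by the assumed read length."""
    vs, ve = region_interval
    region_len = ve - vs
    spacing = settings.sequencing_spacing_bp
    count = max(1, math.ceil((region_len + 200) / spacing))
    mid = sum(settings.primer_tm_window) / 2.0
    glo, ghi = settings.primer_gc_window
    primers: list[Primer] = []
    for i in range(count):
        target = vs - settings.sequencing_upstream_bp + i * spacing
        found = None
        for off in (0, 10, -10, 20, -20, 30, -30, 40, -40, 50, -50):
            cands = [c for c in _candidates(view, target + off, "fwd", settings)
                     if glo <= c.gc_fraction <= ghi
                     and not check_off_target(c.sequence, view.seq)]
            if cands:
                found = min(cands, key=lambda c: (abs(c.tm - mid), len(c)))
                break
        if found is None:
            raise PrimerDesignError(
                f"sequencing primer {i + 1}/{count}: no Tm/GC-window primer "
                f"within +-50 bp of position {target % len(view.seq)}")
        found.name = f"{name_prefix}_{i + 1}"
        found.flags = check_secondary_structure(found.sequence)
        primers.append(found)
    return primers


def locate_primer(primer: Primer, template: str, circular: bool = True) -> set[int]:
    """All plus/minus-strand binding positions of the full primer sequence
    on the template (self-consistency diagnostic)."""
    return _binding_positions(primer.sequence, template, circular)
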