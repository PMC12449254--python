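# Methods

This note documents the models, parameters and numerical choices behind
`mutfrag`, and what the synthetic validation does and does not show.

## Problem setting

A mutant library request is a set of protein-level edits on one gene of
interest carried by a circular expression plasmid: point substitutions
(`L123A`), combined substitutions that must co-occur in one mutant
(`G45D+S210R`), insertions (`ins5-GGS`, peptide inserted after residue 5)
and deletions (`del70-75`, inclusive). Each mutant is realized by
synthesizing a dsDNA fragment — mutated gene segment plus terminal homology
flanks — and inserting it by IVA cloning into the plasmid opened by a single
outward-facing PCR. Mutations that share a *fragment region* share that PCR,
so the design problem is: partition the mutations into as few (or as cheap)
regions as possible subject to the synthesis provider's fragment-size
limits.

Coordinates: user-facing residues are 1-based; all internal bp coordinates
are 0-based half-open; circular sequences use modular arithmetic. Genes on
the minus strand are designed on the coding strand and mapped back when
writing output.

## Cluster size feasibility

Each mutation occupies a wild-type bp hull on the CDS (codon(s) touched; an
insertion is a zero-width boundary) and has a net indel length
(±3·residues). For a candidate cluster with hull span `span` and member net
indels `net_m`, a wild-type region window of length `W` yields, for member
`m`, a mutant fragment of `W + net_m + 2·f` bp, where `f` = 15 bp is the
minimal flank. The cluster is feasible iff a `W` exists with

```
W_low = max(span, (min_frag − 2f) − min_m net_m)  ≤  W  ≤
W_high = (max_frag − 2f) − max_m net_m
```

with `min_frag = 300`, `max_frag = 1500` (typical gBlocks-style limits; both
settable, as is the per-bp cost used on the order sheet). The per-member
form matters for mixed clusters: a deletion member needs extra wild-type
window to compensate the excised bases, while an insertion member tightens
the upper bound. Consequences worth knowing:

* paired mutations L residues apart span 3·(L+1) bp, so a single region can
  host them iff 3·(L+1) + 30 ≤ 1500 (L ≤ 489 at defaults);
* insertions fit iff 3·L + 30 ≤ 1500 once the insert itself exceeds the
  270 bp core (L ≤ 490);
* deletions are always compensated by widening the region
  (`W = 270 + 3·L`), limited only by gene/plasmid capacity.

These closed forms are exported as
`mutfrag.simulate.geometric_designable` and tested against the pipeline.

## Clustering search

The search couples two candidate generators, and a selection step picks by
objective (`quantity`: fewest regions, tie-broken by total bp; `length`:
fewest total bp, tie-broken by region count; remaining ties by smaller k and
a canonical partition order).

1. **PAM over k.** Partitioning-around-medoids (deterministic greedy BUILD,
   best-improvement SWAP; a seed, default 42, shuffles exact ties only) on
   the |Δposition| matrix, with distances between members of a combined
   mutation multiplied by 0.01 so they co-cluster; a hard post-check rejects
   any clustering that still separates a combined group. k runs from 1
   upward and stops once every cluster's wild-type span is already below
   the 270 bp minimum core (further splitting cannot help), or at k = n.
2. **Exact dynamic programs.** PAM minimizes distance-to-medoid, which is
   not guaranteed to find a feasible partition at the smallest feasible k.
   For panels of ≤ 12 mutation atoms an O(3ⁿ) subset DP computes, for every
   k, the minimum-total-bp partition over *all* set partitions; beyond 12
   atoms an O(n²·k) DP over position-sorted atoms finds the optimal
   contiguous partition (plus an interval enumeration around a single indel
   atom, which must sometimes be excluded from blocks it would oversize).
   Small-panel optimality is verified in the test suite against an
   independent exhaustive enumeration of set partitions.

## Fragment construction

The region is the smallest codon-aligned interval containing the cluster's
hulls, expanded symmetrically to `W_low`; expansion that hits a CDS boundary
shifts to the other side and spills into plasmid backbone only when the CDS
itself is too short (codon phase inside the CDS is preserved). One fragment
is then built per member mutation: substituted or inserted residues receive
the most frequent codon of the target amino acid in the usage table (ties
alphabetical), deletions are excised, and the `silent_markers_per_end = 2`
eligible codons nearest each end (inside the CDS, not part of an intended
mutation, amino acid with >1 codon) are toggled to their preferred
synonymous alternative. Markers sit in the insert-only part of the fragment,
never in the flanks, so flank homology stays perfect.

Flanks are wild-type plasmid sequence abutting the region boundaries. The
length scan (15–60 bp) picks the length whose nearest-neighbor Tm lies in
the 47–52 °C window closest to the 49.5 °C midpoint; a per-region length
budget (`max_frag` minus the longest member fragment) caps the scan so the
provider maximum is never exceeded — when the window is unreachable within
the budget the closest Tm is used and a warning attached.

## Codon usage

Relative synonymous-codon frequencies are genome-wide codon counts over a
user-supplied CDS FASTA (or a precomputed `aa<TAB>codon<TAB>freq` TSV),
normalized per amino acid; stop codons are tallied under `*` but never used
for design. When no source is given a uniform table over the 61 sense
codons is used (preferred codon = alphabetically first); the simulation
module always uses the uniform table so that sweep outcomes reflect
geometry, not organism-specific codon bias.

## Primers

Tm model: unified dinucleotide nearest-neighbor thermodynamics at 50 mM
monovalent salt and 500 nM oligo (biopython `Tm_NN` with the unified table);
flank and primer lengths are therefore reproducible across machines. The
linearization pair anneals flush at the region boundaries facing outward, so
`product length = plasmid − region` and the linearized ends equal the
fragment flanks. Lengths 18–30 nt are scanned for Tm 57–63 °C and GC
0.40–0.60 (settable); pair ΔTm ≤ 3 °C is enforced jointly. Diagnostics:
hairpin = inverted repeat with stem ≥ 4 bp and loop ≥ 3 nt; self-dimer =
self-complementary run ≥ 8 bp; off-target = the 3′-terminal 12-mer binding
more than one site across both strands (position-deduplicated so a
palindromic site counts once). Because the linearization primers cannot
move, and a 4-bp inverted repeat occurs in most random 20-mers, structure
flags are reported as warnings on the chosen primer (the length scan prefers
clean candidates) while an off-target hit — a genuine mispriming risk —
aborts with an error. Sequencing primers are plus-strand, the first 150 bp
upstream of the region, then every 500 bp (assuming ~800 bp reads), each
allowed to slide ±50 bp to satisfy its windows and uniqueness.

## Synthetic validation

`mutfrag validate` / `run_sweep` generates random genes (ATG + uniform
sense codons + TAA, default 800 codons, embedded mid-backbone in a random
2 kb circular plasmid) and panels of five random point mutations plus one
controlled variant — an insertion or deletion of L residues, or a combined
pair exactly L residues apart. Point residues avoid the deleted range and
the paired sites. Per (variant type, L) the default grid runs 3 genes × 10
replicates through the full pipeline and reports the designable fraction;
all seeds derive from one base seed via a stable hash, so results are
bit-for-bit reproducible. `scripts/acceptance.py` reports the rates at
L = 185 (deletion), 115 (insertion) and 230 (paired), the scale the sweep
design targets; the acceptance and CI grids use the same generator at
reduced length grids to stay fast.

What the sweep does and does not show: the genes are uniform-random with no
repeats, extreme GC, or codon bias, and the toy plasmid backbone is random —
so success rates measure the *geometric* limits of single-fragment design
under provider size limits, not synthesis-vendor sequence-complexity
screens (homopolymers, GC windows) or biological viability of the mutants.
Under the per-member mutant-length feasibility rule, success is a sharp
step: ~100% up to the closed-form bound (489/490 residues for paired/
insertion variants) and 0% beyond; deletions, being compensated by region
widening, succeed across the entire 1–600 sweep range. Reported ≥90% rates
at 185/115/230 are therefore saturated at 100%.

## Known limitations

* Multi-fragment assembly (splitting one mutant across several fragments)
  is out of scope; requests exceeding the single-fragment bounds fail with
  an explanatory clustering error.
* Exact partition optimality is guaranteed up to 12 mutation atoms; larger
  panels fall back to the contiguous DP + PAM search, which is optimal for
  panels whose combined pairs do not interleave with indels.
* Only GenBank is read/written for plasmids; SnapGene `.dna` (a proprietary
  binary format) is refused with an explanatory error.
* Vendor-specific synthesis-complexity screens and cross-dimer checks
  between different primer pairs are not implemented.
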