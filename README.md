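# mutfrag

One-step design of large mutant plasmid libraries from synthesized dsDNA
gene fragments.

Generating many variants of a protein — point mutants, multi-site mutants,
insertions, deletions — by classic per-mutant PCR mutagenesis is slow: every
mutation needs its own primer pair, and mutations far apart in the gene need
sequential rounds. A faster route is to order short synthetic double-stranded
DNA (dsDNA) fragments, each carrying one mutant version of a gene segment,
and insert them into a single PCR-linearized expression plasmid by in vivo
assembly (IVA) cloning, which needs only ~15 bp of terminal homology and no
ligase. `mutfrag` automates the design side of that workflow for molecular
biologists and protein engineers:

1. **Cluster** the requested mutations along the gene so that mutations close
   in sequence share one *fragment region* (one linearization PCR serves all
   mutants of that region). Clustering is partitioning-around-medoids (PAM)
   over base-pair positions, iterated over the cluster count k; distances
   inside a combined (must-co-occur) mutation are shrunk ×0.01 to steer
   co-clustering, and an exact dynamic program guarantees the selected
   partition is optimal. Two objectives are available: `quantity` (fewest
   regions, i.e. fewest PCRs) and `length` (fewest total base pairs, i.e.
   cheapest synthesis).
2. **Build one mutant fragment per mutation**: the region sequence with the
   mutation applied using the expression organism's most frequent codon
   (from a codon-usage table computed over a CDS FASTA), homology flanks of
   ≥15 bp with melting temperature in 47–52 °C taken verbatim from the
   plasmid, and two silent (synonymous) marker codons near each fragment end
   so a short sequencing read over a junction identifies the insert.
   Fragment sizes respect provider limits (default 300–1500 bp).
3. **Design primers**: the outward-facing linearization pair that opens the
   plasmid flush at the region boundaries (so the linearized ends are exactly
   homologous to the fragment flanks), plus sequencing primers walking the
   region every ≤500 bp. Primer selection is a deterministic length scan
   against Tm/GC windows with nearest-neighbor thermodynamics (unified
   dinucleotide parameters, 50 mM Na⁺, 500 nM oligo), hairpin/self-dimer
   screening and an off-target check on the 3′-terminal 12-mer.

Outputs are order-ready: a complete annotated GenBank file per mutant
plasmid, a CSV order sheet (96-well layout, per-fragment cost), and a
plain-text map of fragment regions on the gene.

## Worked example

Inputs: a circular plasmid in GenBank format, the gene of interest as FASTA,
and a plain-text mutation list (one spec per line; `L123A` point,
`G45D+S210R` combined, `del70-75` deletion, `ins350-GGSGG` insertion after
residue 350; `#` comments):

```bash
mutfrag design --plasmid plasmid.gb --gene gene.fasta \
               --mutations muts.txt --seed 1 --out outdemo
```

For a 400-codon gene with five requested mutations this prints

```
5 mutations -> 1 fragment region(s), 5 mutant fragments (5602 bp, cost 280.10)
outputs written to outdemo
```

meaning: all five mutations fit one 1083 bp fragment region (one
linearization PCR), five mutant fragments totalling 5602 bp were designed at
the default 0.05/bp synthesis price, and `outdemo/` now holds five annotated
mutant GenBank files, `order_sheet.csv` (fragments in wells A1–A5 plus all
primers) and `region_map.txt`:

```
gene goi: 1200 bp (400 codons), strand +
5' ---------------------------------------------------------------------- 3'
      r1=============================================================
      *                *          *                             *    *
r1: bp 57..1140 (codons 20..380): G20A, G380K, P25G+L210S, del180-185, ins350-GGSGG
```

The built-in synthetic validation sweep measures, for each variant class,
how long an insertion/deletion (or how distant a paired mutation) can be
before no single fragment satisfies the provider limits:

```bash
mutfrag validate --lengths 1:601:5 --out sweep/
```

Under the default 300–1500 bp limits, paired mutations design up to 489
residues apart and insertions up to 490 residues (both set by the hard bound
3·L + 2 flanks ≤ 1500 bp), while deletions are compensated by widening the
wild-type region and succeed throughout the sweep range.

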