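"""Codon-usage tables: relative synonymous-codon frequencies computed from a
CDS collection, plus preferred-codon and silent-alternative lookup.

Frequencies are genome-wide codon counts over all provided CDS records,
normalized per amino acid. Stop codons are tallied under ``'*'`` but never
used for design. Ties are always broken alphabetically so outputs are
deterministic.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .model import DesignError, DNA_ALPHABET

logger = logging.getLogger(__name__)

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> amino acid (stops mapped to '*'), standard genetic code
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
GENETIC_CODE.update({c: "*" for c in _STANDARD.stop_codons})

#: amino acid -> alphabetically sorted synonymous codons
SYNONYMS: dict[str, list[str]] = defaultdict(list)
for _codon in sorted(GENETIC_CODE):
    SYNONYMS[GENETIC_CODE[_codon]].append(_codon)
SYNONYMS = dict(SYNONYMS)

STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))
SENSE_CODONS = tuple(c for c in sorted(GENETIC_CODE) if GENETIC_CODE[c] != "*")


def translate_codon(codon: str) -> str:
    try:
        return GENETIC_CODE[codon.upper()]
    except KeyError:
        raise DesignError(f"not a standard codon: {codon!r}") from None


@dataclass
class CodonUsageTable:
    """Per-amino-acid relative codon frequencies.

    ``freq[aa][codon]`` sums to 1 over the observed synonymous codons of
    each amino acid.
    """

    organism_label: str
    freq: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa, codons in self.freq.items():
            for codon in codons:
                if translate_codon(codon) != aa:
                    raise ValueError(f"codon {codon} does not encode {aa}")


def compute_codon_usage(cds_records: list[str], organism_label: str) -> CodonUsageTable:
    """Tally codons over a CDS collection and normalize per amino acid.

    Records whose length is not a multiple of 3 are skipped with a warning;
    individual codons containing non-ACGT symbols are skipped silently.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    n_used = 0
    for i, rec in enumerate(cds_records):
        rec = rec.upper()
        if len(rec) % 3 != 0:
            logger.warning("CDS record %d length %d not a multiple of 3; skipped",
                           i, len(rec))
            continue
        for j in range(0, len(rec), 3):
            codon = rec[j : j + 3]
            if set(codon) - DNA_ALPHABET:
                continue
            counts[GENETIC_CODE[codon]][codon] += 1
            n_used += 1
    if n_used == 0:
        raise DesignError("no usable codons in the provided CDS records")
    freq = {
        aa: {codon: c / sum(codons.values()) for codon, c in sorted(codons.items())}
        for aa, codons in sorted(counts.items())
    }
    return CodonUsageTable(organism_label, freq)


def uniform_usage_table(organism_label: str = "uniform") -> CodonUsageTable:
    """A neutral table in which every synonymous codon of an amino acid has
    equal frequency (preferred codon = alphabetically first)."""
    freq = {
        aa: {codon: 1.0 / len(codons) for codon in codons}
        for aa, codons in SYNONYMS.items()
    }
    return CodonUsageTable(organism_label, freq)


def most_frequent_codon(table: CodonUsageTable, aa: str) -> str:
    """The highest-frequency codon for ``aa``; ties broken alphabetically."""
    codons = table.freq.get(aa)
    if not codons:
        raise DesignError(
            f"amino acid {aa!r} has no observed codons in usage table "
            f"{table.organism_label!r}"
        )
    return min(codons, key=lambda c: (-codons[c], c))


def silent_alternative(table: CodonUsageTable, codon: str) -> str | None:
    """A synonymous codon different from ``codon``: the highest-frequency
    observed alternative, falling back to the alphabetically first
    standard-code synonym. Returns None for single-codon amino acids
    (Met, Trp) — the 'unusable' signal."""
    codon = codon.upper()
    aa = translate_codon(codon)
    alternatives = [c for c in SYNONYMS[aa] if c != codon]
    if not alternatives:
        return None
    observed = table.freq.get(aa, {})
    scored = [c for c in alternatives if c in observed]
    if scored:
        return min(scored, key=lambda c: (-observed[c], c))
    return alternatives[0]


def write_usage_table(table: CodonUsageTable, path: str) -> None:
    """TSV with columns: amino acid, codon, relative frequency."""
    with open(path, "w") as fh:
        fh.write(f"# codon usage: {table.organism_label}\n")
        fh.write("aa\tcodon\tfrequency\n")
        for aa in sorted(table.freq):
            for codon in sorted(table.freq[aa]):
                fh.write(f"{aa}\t{codon}\t{table.freq[aa][codon]:.10g}\n")


def read_usage_table(path: str, organism_label: str | None = None) -> CodonUsageTable:
    freq: dict[str, dict[str, float]] = defaultdict(dict)
    label = organism_label
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if label is None and ":" in line:
                    label = line.split(":", 1)[1].strip()
                continue
            parts = line.split("\t")
            if parts[0] == "aa":
                continue
            aa, codon, f = parts[0], parts[1].upper(), float(parts[2])
            freq[aa][codon] = f
    if not freq:
        raise DesignError(f"no codon usage rows in {path}")
    return CodonUsageTable(label or "table", dict(freq))
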