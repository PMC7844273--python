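"""Codon counting, amino-acid frequencies and RSCU for mitochondrial PCGs.

The genetic code is the vertebrate mitochondrial table (NCBI table 2):
AGA/AGG are stops, ATA codes Met, TGA codes Trp. Serine and leucine each
form a single six-fold synonymous family; every other amino acid is two- or
four-fold. Relative synonymous codon usage is

    RSCU(c) = count(c) * d_a / sum over the family of count,

the observed count of a codon divided by its expected count under uniform
use within its synonymous family (d_a = family degeneracy).

Protein-coding genes are extracted on their coding strand (L-strand genes
reverse-complemented), trailing incomplete-stop nucleotides (T-, TA-) are
dropped, and codons are read in frame from the annotated start. Start
codons (including the non-ATG GTG start of COI) are tallied as Met when
computing amino-acid frequencies, the usual convention of codon-usage
software.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .composition import _slice, reverse_complement
from .errors import ValidationError
from .features import MitogenomeAnnotation, classify_stop_codon

GENETIC_CODE_ID = 2  # vertebrate mitochondrial
_TABLE = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]

ALL_CODONS = tuple("".join(p) for p in itertools.product("TCAG", repeat=3))
STOP_CODONS = tuple(_TABLE.stop_codons)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: codon -> one-letter amino acid; stops map to "*".
CODON_TO_AA: dict[str, str] = {
    **{c: _TABLE.forward_table[c] for c in SENSE_CODONS},
    **{c: "*" for c in STOP_CODONS},
}

#: amino acid (one-letter, "*" for stop) -> tuple of synonymous codons.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in ALL_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_c], tuple())
FAMILIES = {
    aa: tuple(c for c in ALL_CODONS if CODON_TO_AA[c] == aa) for aa in FAMILIES
}

AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Stop",
}


@dataclass
class CodonUsage:
    """Codon counts over the 64 codons for a set of coding genes.

    ``start_counts`` records the first codon of each counted gene so that
    non-ATG starts can be re-assigned to Met in amino-acid tallies;
    ``skipped_genes`` lists (gene, reason) for genes excluded with a frame
    warning.
    """

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    genetic_code: str = "vertebrate_mitochondrial"
    start_counts: dict[str, int] = field(default_factory=dict)
    skipped_genes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def add(self, codon: str, is_start: bool = False) -> None:
        self.counts[codon] = self.counts.get(codon, 0) + 1
        if is_start:
            self.start_counts[codon] = self.start_counts.get(codon, 0) + 1


def extract_coding_sequence(
    a: MitogenomeAnnotation, seq: str, gene: str
) -> tuple[str, int]:
    """(coding-strand sequence with incomplete-stop nt trimmed, trimmed nt).

    The slice is taken wrap-aware from the H strand and reverse-complemented
    for L-strand genes, so position 0 is the annotated start codon.
    """
    f = a.feature(gene)
    s = _slice(seq, f.start, f.end, a.genome_length).upper()
    if f.strand == "L":
        s = reverse_complement(s)
    trim = 0
    if f.stop_codon and classify_stop_codon(f.stop_codon) == "incomplete":
        trim = len(f.stop_codon.rstrip("-"))
        s = s[:-trim]
    return s, trim


def count_codons(
    a: MitogenomeAnnotation, seq: str, genes: list[str] | None = None
) -> CodonUsage:
    """Count in-frame codons (start and complete stop included) over PCGs.

    Genes whose trimmed length is not a multiple of 3 are skipped and
    recorded in ``skipped_genes`` rather than silently truncated.
    """
    if len(seq) != a.genome_length:
        raise ValidationError(
            f"sequence length {len(seq)} != genome_length {a.genome_length}"
        )
    usage = CodonUsage()
    targets = genes if genes is not None else [f.name for f in a.features_of_class("PCG")]
    for gene in targets:
        coding, _ = extract_coding_sequence(a, seq, gene)
        if len(coding) % 3 != 0:
            usage.skipped_genes.append(
                (gene, f"trimmed length {len(coding)} not divisible by 3")
            )
            continue
        for i in range(0, len(coding), 3):
            codon = coding[i : i + 3]
            if any(ch not in "ACGT" for ch in codon):
                continue
            usage.add(codon, is_start=(i == 0))
    return usage


def rscu(u: CodonUsage, include_stops: bool = False) -> dict[str, float]:
    """RSCU per codon; families with zero total get 0.0 for all members."""
    if u.n_codons == 0:
        raise ValidationError("empty codon usage")
    out: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if aa == "*" and not include_stops:
            continue
        total = sum(u.counts.get(c, 0) for c in codons)
        d = len(codons)
        for c in codons:
            out[c] = (u.counts.get(c, 0) * d / total) if total else 0.0
    return out


def aa_frequencies(u: CodonUsage, three_letter: bool = True) -> dict[str, float]:
    """Percent usage of each amino acid among non-stop codons.

    Start codons are counted as Met regardless of their own translation;
    stop codons are excluded from the denominator. Returns an empty dict
    (with no error) for an all-zero usage.
    """
    aa_counts: dict[str, float] = {}
    for codon, n in u.counts.items():
        aa = CODON_TO_AA[codon]
        if aa == "*":
            continue
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    # re-assign non-Met start codons to Met
    for codon, n in u.start_counts.items():
        aa = CODON_TO_AA[codon]
        if aa in ("M", "*"):
            continue
        aa_counts[aa] = aa_counts.get(aa, 0) - n
        aa_counts["M"] = aa_counts.get("M", 0) + n
    total = sum(aa_counts.values())
    if total == 0:
        return {}
    key = (lambda aa: AA_THREE_LETTER[aa]) if three_letter else (lambda aa: aa)
    return {key(aa): 100.0 * n / total for aa, n in sorted(aa_counts.items()) if n}
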