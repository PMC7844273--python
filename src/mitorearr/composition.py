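"""Base composition, A+T content, and strand-asymmetry (skew) statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) measure the
asymmetry of base usage between the two strands of mtDNA; both are
dimensionless values in [-1, 1] and can be computed identically from raw
counts or from percentages. Composition is reported on the H strand for
every region regardless of coding strand (the convention under which the
published ND6 row of a rearranged eel mitogenome is reproducible); a
``strand_mode`` switch also supports coding-strand slices.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RegionLookupError, UndefinedSkewError, ValidationError
from .features import MitogenomeAnnotation

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BaseComposition:
    """A/C/G/T content of a region, as counts or percentages.

    ``n_a`` .. ``n_t`` may be integer counts or percentage values — the skew
    formulas are scale-free. ``n_other`` counts ambiguity codes (N etc.),
    which are excluded from the four base totals.
    """

    n_a: float
    n_c: float
    n_g: float
    n_t: float
    n_other: float = 0.0
    region_label: str = ""

    @classmethod
    def from_sequence(cls, seq: str, region_label: str = "") -> "BaseComposition":
        s = seq.upper()
        a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
        return cls(a, c, g, t, n_other=len(s) - a - c - g - t, region_label=region_label)

    @classmethod
    def from_percentages(
        cls, pct_a: float, pct_c: float, pct_g: float, pct_t: float, region_label: str = ""
    ) -> "BaseComposition":
        for p in (pct_a, pct_c, pct_g, pct_t):
            if not 0 <= p <= 100:
                raise ValidationError(f"percentage {p} outside [0, 100]")
        return cls(pct_a, pct_c, pct_g, pct_t, region_label=region_label)

    @property
    def total(self) -> float:
        return self.n_a + self.n_c + self.n_g + self.n_t

    @property
    def pct_a(self) -> float:
        return 100.0 * self.n_a / self.total

    @property
    def pct_c(self) -> float:
        return 100.0 * self.n_c / self.total

    @property
    def pct_g(self) -> float:
        return 100.0 * self.n_g / self.total

    @property
    def pct_t(self) -> float:
        return 100.0 * self.n_t / self.total

    @property
    def at_percent(self) -> float:
        return self.pct_a + self.pct_t


def at_skew(c: BaseComposition) -> float:
    """(A - T)/(A + T); raises if A + T is zero."""
    denom = c.n_a + c.n_t
    if denom == 0:
        raise UndefinedSkewError(f"A+T is zero for region {c.region_label!r}")
    return (c.n_a - c.n_t) / denom


def gc_skew(c: BaseComposition) -> float:
    """(G - C)/(G + C); raises if G + C is zero."""
    denom = c.n_g + c.n_c
    if denom == 0:
        raise UndefinedSkewError(f"G+C is zero for region {c.region_label!r}")
    return (c.n_g - c.n_c) / denom


def _slice(seq: str, start: int, end: int, genome_length: int) -> str:
    """1-based inclusive H-strand slice, wrapping across the origin when end < start."""
    if end >= start:
        return seq[start - 1 : end]
    return seq[start - 1 : genome_length] + seq[:end]


def region_composition(
    seq: str,
    a: MitogenomeAnnotation,
    region: str,
    strand_mode: str = "H",
) -> BaseComposition:
    """Composition of a named feature, a feature class, or the whole genome.

    ``region`` may be a feature name (``"ND6"``), a class (``"tRNA"`` —
    slices of all members are concatenated), or ``"genome"``. With the
    default ``strand_mode="H"`` slices are taken verbatim from the H
    strand; ``strand_mode="coding"`` reverse-complements L-strand features
    first.
    """
    if len(seq) != a.genome_length:
        raise ValidationError(
            f"sequence length {len(seq)} != genome_length {a.genome_length}"
        )
    if strand_mode not in ("H", "coding"):
        raise ValidationError(f"unknown strand_mode {strand_mode!r}")
    if region == "genome":
        return BaseComposition.from_sequence(seq, region_label="genome")
    try:
        feats = [a.feature(region)]
    except KeyError:
        feats = list(a.features_of_class(region))
        if not feats:
            raise RegionLookupError(
                f"no feature or class named {region!r} in annotation"
            ) from None
    parts = []
    for f in feats:
        s = _slice(seq, f.start, f.end, a.genome_length)
        if strand_mode == "coding" and f.strand == "L":
            s = reverse_complement(s)
        parts.append(s)
    return BaseComposition.from_sequence("".join(parts), region_label=region)


def motif_scan(seq: str, motifs: list[str]) -> list[tuple[str, int, str]]:
    """All (possibly overlapping) motif occurrences, 1-based, on the given strand.

    Note that the control-region palindrome pair TACAT / ATGTA are reverse
    complements of one another, so scanning the H strand for both covers
    hits on either strand of the duplex.
    """
    if not motifs:
        raise ValidationError("motif list is empty")
    for m in motifs:
        if not m or any(ch not in "ACGT" for ch in m.upper()):
            raise ValidationError(f"motif {m!r} contains non-ACGT characters")
    s = seq.upper()
    hits = []
    for m in motifs:
        mu = m.upper()
        start = s.find(mu)
        while start != -1:
            hits.append((m, start + 1, "H"))
            start = s.find(mu, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits
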