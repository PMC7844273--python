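"""Synthetic annotated mitogenomes with recorded ground truth.

The generator lays a gene order out on a circle with configurable lengths
and junction gaps (negative = overlap), fills protein-coding genes with an
annotated start codon, in-frame sense codons drawn from a codon-bias
distribution and a (possibly incomplete) stop codon, fills everything else
i.i.d. from a base-composition distribution, and plants the TACAT/ATGTA
palindrome pair in control regions. Every emission is driven by a single
seeded generator, so the same seed reproduces the genome byte for byte.

The default parameterization is a structural twin of the published
17,673 bp rearranged eel mitogenome: published gene lengths, the
coordinate-derived junction gaps, whole-genome base composition
(A 32.1 / C 23.8 / G 16.6 / T 27.6 %), and the single six-gene TDRL event
that produces the observed order. What the twin does not emulate: real
tRNA/rRNA secondary structure, codon bias estimated from the real genome,
and the published COI length (kept as printed, which leaves one
out-of-frame nucleotide — the validator flags it, exactly as it flags the
published table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import SENSE_CODONS, CodonUsage
from .composition import reverse_complement
from .errors import ConfigError, RegionLookupError, ValidationError
from .features import GeneFeature, MitogenomeAnnotation
from .order import (
    CANONICAL_TOKENS,
    GeneOrder,
    base_label,
    canonical_vertebrate_order,
    token_label,
    token_sign,
)
from .tdrl import TDRLEvent, apply_tdrl

PCG_LABELS = frozenset(
    ("ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
     "COI", "COII", "COIII", "ATP6", "ATP8", "Cytb")
)
RRNA_LABELS = frozenset(("12S", "16S"))

#: Published per-gene lengths (bp) of the eel mitogenome, keyed by order label.
REFERENCE_GENE_LENGTHS: dict[str, int] = {
    "F": 72, "12S": 962, "V": 70, "16S": 1706, "L1": 76, "ND1": 969,
    "I": 72, "Q": 71, "M": 70, "ND2": 1044, "W": 70, "A": 69, "N": 73,
    "OL": 39, "C": 66, "Y": 71, "COI": 1603, "S1": 71, "D": 68,
    "COII": 691, "K": 75, "ATP8": 168, "ATP6": 684, "COIII": 786,
    "G": 70, "ND3": 351, "R": 70, "ND4L": 297, "ND4": 1381, "H": 69,
    "S2": 71, "L2": 72, "ND5": 1857, "ND6": 516, "E": 69, "Cytb": 1140,
    "T": 72, "P": 77, "CR": 944, "CR1": 902, "CR2": 944,
}

#: Published start/stop codons; every unlisted PCG starts ATG, stops TAA.
REFERENCE_START_CODONS: dict[str, str] = {"COI": "GTG"}
REFERENCE_STOP_CODONS: dict[str, str] = {
    "ND1": "TAA", "ND2": "TAG", "COI": "TAA", "COII": "T-", "ATP8": "TAA",
    "ATP6": "TAA", "COIII": "TAA", "ND3": "TAG", "ND4L": "TAA",
    "ND4": "T-", "ND5": "TAA", "Cytb": "AGA", "ND6": "AGG",
}

#: Whole-genome base composition of the published eel mitogenome (A, C, G, T).
REFERENCE_BASE_PROBS: tuple[float, float, float, float] = (0.321, 0.238, 0.166, 0.275)


def eel_tdrl_event() -> TDRLEvent:
    """The single event producing the eel arrangement from the canonical order.

    The six-gene window (-ND6, -E, Cytb, T, -P, CR) is tandemly duplicated;
    copy 1 keeps {Cytb, T, CR} and copy 2 keeps {ND6, E, P, CR}, so the
    control region survives twice and ND6+trnE land between trnT and trnP.
    """
    return TDRLEvent(
        window_start=CANONICAL_TOKENS.index("-ND6"),
        window_length=6,
        kept_in_copy1=frozenset({"Cytb", "T", "CR"}),
        kept_in_copy2=frozenset({"ND6", "E", "P", "CR"}),
    )


def reference_spacer_plan() -> dict[tuple[str, str], int]:
    """Coordinate-derived junction gaps of the published eel annotation."""
    from .data import load_reference_annotation
    from .features import intergenic_spacers

    a = load_reference_annotation()

    def tok(name: str) -> str:
        return name[3:] if name.startswith("trn") else name

    plan = {}
    for u, d, g in intergenic_spacers(a).pairs:
        plan[(tok(u), tok(d))] = g
    plan.pop(("CR2", "F"), None)  # wrap junction handled by wrap_gap
    return plan


@dataclass
class SynthesisConfig:
    """Everything needed to emit one synthetic annotated mitogenome.

    ``gene_lengths`` is keyed by order label, with instance labels (CR1)
    taking precedence over base labels (CR); ``spacer_plan`` maps
    ``(upstream label, downstream label)`` to a gap in nt (negative =
    overlap, unlisted = abutting). ``pcg_codon_counts`` optionally forces a
    gene's in-frame codon count (start and complete stop included),
    overriding its length.
    """

    gene_template: GeneOrder = field(default_factory=canonical_vertebrate_order)
    tdrl_events: tuple[TDRLEvent, ...] = ()
    base_probs: tuple[float, float, float, float] = REFERENCE_BASE_PROBS
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(REFERENCE_GENE_LENGTHS)
    )
    pcg_codon_counts: dict[str, int] | None = None
    spacer_plan: dict[tuple[str, str], int] = field(default_factory=dict)
    wrap_gap: int = 0
    genome_length: int | None = None
    codon_bias: dict[str, float] | None = None
    start_codons: dict[str, str] = field(
        default_factory=lambda: dict(REFERENCE_START_CODONS)
    )
    stop_codons: dict[str, str] = field(
        default_factory=lambda: dict(REFERENCE_STOP_CODONS)
    )
    plant_motifs: bool = True
    organism: str = "synthetic mitogenome"
    accession: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ConfigError(f"base_probs sum to {sum(self.base_probs)}, not 1")
        for lbl, ln in self.gene_lengths.items():
            if ln <= 0:
                raise ConfigError(f"non-positive length for {lbl}: {ln}")


def muraenesox_like_config(seed: int = 0) -> SynthesisConfig:
    """Structural twin of the published rearranged eel mitogenome (17,673 bp)."""
    return SynthesisConfig(
        tdrl_events=(eel_tdrl_event(),),
        spacer_plan=reference_spacer_plan(),
        genome_length=17673,
        organism="synthetic eel-like mitogenome",
        seed=seed,
    )


def frame_clean_config(seed: int = 0) -> SynthesisConfig:
    """Canonical-order genome whose 13 PCGs are all in frame with complete stops.

    Per-gene codon counts follow the published amino-acid column, scaled so
    the 13 genes total exactly 3,818 codons (11,454 coding nt).
    """
    counts = {
        "ND1": 323, "ND2": 348, "COI": 534, "COII": 230, "ATP8": 56,
        "ATP6": 228, "COIII": 262, "ND3": 117, "ND4L": 99, "ND4": 460,
        "ND5": 609, "Cytb": 380, "ND6": 172,
    }
    return SynthesisConfig(
        pcg_codon_counts=counts,
        stop_codons={g: "TAA" for g in counts},
        start_codons={},
        organism="synthetic canonical mitogenome",
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator planted, recorded before emission."""

    true_order: GeneOrder
    true_events: tuple[TDRLEvent, ...]
    base_probs: tuple[float, float, float, float]
    true_codon_counts: CodonUsage
    frame_skipped: tuple[str, ...]      # PCGs emitted with a trailing pad nt
    overlapped: tuple[str, ...]          # features partially overwritten later
    motif_positions: tuple[tuple[str, int], ...]
    realized_spacers: dict[tuple[str, str], int]

    def to_dict(self) -> dict:
        return {
            "true_order": str(self.true_order),
            "n_events": len(self.true_events),
            "base_probs": list(self.base_probs),
            "n_true_codons": self.true_codon_counts.n_codons,
            "frame_skipped": list(self.frame_skipped),
            "overlapped": list(self.overlapped),
            "motif_positions": [list(m) for m in self.motif_positions],
        }


def _gene_class(label: str) -> str:
    b = base_label(label)
    if b in PCG_LABELS:
        return "PCG"
    if b in RRNA_LABELS:
        return "rRNA"
    if b == "CR":
        return "CR"
    if b == "OL":
        return "OL"
    return "tRNA"


def _feature_name(label: str) -> str:
    return label if _gene_class(label) != "tRNA" else f"trn{label}"


def synthesize(cfg: SynthesisConfig) -> tuple[str, MitogenomeAnnotation, GroundTruth]:
    """Emit (sequence, annotation, ground truth) for a synthesis configuration.

    Deterministic given ``cfg.seed``; raises ConfigError when the laid-out
    coordinates contradict an explicitly requested genome length.
    """
    rng = np.random.default_rng(cfg.seed)
    order = cfg.gene_template
    for e in cfg.tdrl_events:
        order = apply_tdrl(order, e)

    # ---- layout ----------------------------------------------------------
    lengths: dict[str, int] = {}
    for t in order.tokens:
        lbl = token_label(t)
        b = base_label(lbl)
        if cfg.pcg_codon_counts and b in cfg.pcg_codon_counts:
            stop = cfg.stop_codons.get(b, "TAA")
            trim = 0 if not stop.endswith("-") else len(stop.rstrip("-"))
            lengths[lbl] = 3 * cfg.pcg_codon_counts[b] + trim
        elif lbl in cfg.gene_lengths:
            lengths[lbl] = cfg.gene_lengths[lbl]
        elif b in cfg.gene_lengths:
            lengths[lbl] = cfg.gene_lengths[b]
        else:
            raise ConfigError(f"no length for order label {lbl!r}")

    coords: dict[str, tuple[int, int]] = {}
    pos = 1
    realized: dict[tuple[str, str], int] = {}
    toks = order.tokens
    for i, t in enumerate(toks):
        lbl = token_label(t)
        if i > 0:
            prev = token_label(toks[i - 1])
            gap = cfg.spacer_plan.get(
                (prev, lbl),
                cfg.spacer_plan.get((base_label(prev), base_label(lbl)), 0),
            )
            pos += gap
            realized[(prev, lbl)] = gap
        start = pos
        end = start + lengths[lbl] - 1
        coords[lbl] = (start, end)
        pos = end + 1
    total = coords[token_label(toks[-1])][1] + cfg.wrap_gap
    if cfg.genome_length is not None and cfg.genome_length != total:
        raise ConfigError(
            f"layout spans {total} nt but genome_length={cfg.genome_length}"
        )
    genome_length = total

    # ---- background sequence --------------------------------------------
    pa, pc, pg, pt = cfg.base_probs
    seq = rng.choice(np.array(list("ACGT")), size=genome_length, p=[pa, pc, pg, pt])

    # overlap bookkeeping: which features get (partially) overwritten later
    spans = [(token_label(t), coords[token_label(t)]) for t in toks]
    overlapped = []
    for i, (lbl, (s1, e1)) in enumerate(spans):
        for lbl2, (s2, e2) in spans[i + 1 :]:
            if s2 <= e1 and e2 >= s1:
                overlapped.append(lbl)
                break

    # ---- fill features ---------------------------------------------------
    usage = CodonUsage()
    frame_skipped: list[str] = []
    motif_positions: list[tuple[str, int]] = []
    sense = np.array(SENSE_CODONS)
    if cfg.codon_bias:
        weights = np.array([cfg.codon_bias.get(c, 0.0) for c in SENSE_CODONS], float)
        if weights.sum() <= 0:
            raise ConfigError("codon_bias has no weight on sense codons")
        weights /= weights.sum()
    else:
        weights = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))

    def place(lbl: str, content: str, strand: int) -> None:
        if strand < 0:
            content = reverse_complement(content)
        s, e = coords[lbl]
        seq[s - 1 : e] = list(content)

    features: list[GeneFeature] = []
    for t in toks:
        lbl = token_label(t)
        b = base_label(lbl)
        cls = _gene_class(lbl)
        strand = token_sign(t)
        s, e = coords[lbl]
        start_codon = stop_codon = None
        if cls == "PCG":
            L = lengths[lbl]
            start_codon = cfg.start_codons.get(b, "ATG")
            stop_codon = cfg.stop_codons.get(b, "TAA")
            trim = 0 if not stop_codon.endswith("-") else len(stop_codon.rstrip("-"))
            usable = L - (len(stop_codon) if trim == 0 else 0)
            # usable nt hold start + body (+ the incomplete-stop prefix later)
            body_nt = usable - 3 - trim
            n_body = body_nt // 3
            pad = body_nt % 3
            body = [str(c) for c in rng.choice(sense, size=n_body, p=weights)]
            parts = [start_codon] + body
            if trim == 0:
                parts.append(stop_codon)
            else:
                parts.append(stop_codon.rstrip("-"))
            if pad:
                parts.append("".join(rng.choice(np.array(list("ACGT")), size=pad,
                                                p=[pa, pc, pg, pt])))
                frame_skipped.append(lbl)
            else:
                usage.add(start_codon, is_start=True)
                for c in body:
                    usage.add(c)
                if trim == 0:
                    usage.add(stop_codon)
            content = "".join(parts)
            assert len(content) == L
            place(lbl, content, strand)
        elif cls == "CR" and cfg.plant_motifs and lengths[lbl] >= 50:
            L = lengths[lbl]
            cr = [str(c) for c in rng.choice(np.array(list("ACGT")), size=L,
                                             p=[pa, pc, pg, pt])]
            cr[10:15] = list("TACAT")
            cr[40:45] = list("ATGTA")
            motif_positions.append(("TACAT", s + 10))
            motif_positions.append(("ATGTA", s + 40))
            place(lbl, "".join(cr), strand)
        # tRNA/rRNA/OL keep the background i.i.d. fill
        features.append(
            GeneFeature(
                name=_feature_name(lbl),
                gene_class=cls,
                start=s,
                end=e,
                strand="H" if strand > 0 else "L",
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )

    # planted codon counts are only trustworthy for clean, non-overwritten genes
    overlapped_pcgs = [l for l in overlapped if _gene_class(l) == "PCG"]

    annotation = MitogenomeAnnotation(
        genome_length=genome_length,
        features=tuple(features),
        circular=True,
        organism=cfg.organism,
        accession=cfg.accession,
    )
    truth = GroundTruth(
        true_order=order,
        true_events=cfg.tdrl_events,
        base_probs=cfg.base_probs,
        true_codon_counts=usage,
        frame_skipped=tuple(frame_skipped),
        overlapped=tuple(overlapped),
        motif_positions=tuple(motif_positions),
        realized_spacers=realized,
    )
    if overlapped_pcgs:
        truth.true_codon_counts.skipped_genes.extend(
            (l, "overlapped by a later feature") for l in overlapped_pcgs
        )
    return "".join(seq), annotation, truth


def perturb_order(
    order: GeneOrder,
    op: str,
    params: dict | None = None,
    seed: int | None = None,
) -> tuple[GeneOrder, dict]:
    """Apply one labelled perturbation (translocate / invert / duplicate).

    ``params`` for translocate: ``block`` (tuple of signed tokens, must be
    contiguous) and ``after`` (label); for invert: ``block``; for
    duplicate: ``label`` and ``after``. Missing params are drawn with the
    seeded generator. Returns the new order plus a record of what was done.
    """
    rng = np.random.default_rng(seed)
    toks = list(order.tokens)
    n = len(toks)
    params = dict(params or {})

    def find_block(block: tuple[str, ...]) -> int:
        for i in range(n):
            if tuple(toks[(i + j) % n] for j in range(len(block))) == tuple(block):
                return i
        raise RegionLookupError(f"block {block} not found in order")

    if op == "translocate":
        block = tuple(params.get("block") or ())
        if not block:
            i = int(rng.integers(n))
            block = tuple(toks[i : i + 1])
        i = find_block(block)
        remaining = [t for j, t in enumerate(toks)
                     if not (i <= j < i + len(block)
                             or j < i + len(block) - n)]
        after = params.get("after")
        if after is None:
            after = token_label(remaining[int(rng.integers(len(remaining)))])
        after = token_label(after)
        try:
            k = next(j for j, t in enumerate(remaining) if token_label(t) == after)
        except StopIteration:
            raise RegionLookupError(f"insertion point {after!r} not found") from None
        new = remaining[: k + 1] + list(block) + remaining[k + 1 :]
        return GeneOrder(tuple(new), order.circular), {
            "op": "translocate", "block": block, "after": after,
        }

    if op == "invert":
        block = tuple(params.get("block") or ())
        if not block:
            i = int(rng.integers(n))
            block = tuple(toks[i : i + 1])
        i = find_block(block)
        flipped = [
            (t[1:] if t.startswith("-") else f"-{t}") for t in reversed(block)
        ]
        for j in range(len(block)):
            toks[(i + j) % n] = flipped[j]
        return GeneOrder(tuple(toks), order.circular), {
            "op": "invert", "block": block,
        }

    if op == "duplicate":
        label = params.get("label")
        if label is None:
            label = token_label(toks[int(rng.integers(n))])
        label = token_label(label)
        i = next(
            (j for j, t in enumerate(toks) if token_label(t) == label), None
        )
        if i is None:
            raise RegionLookupError(f"label {label!r} not found")
        after = token_label(params.get("after", toks[-1]))
        k = next(
            (j for j, t in enumerate(toks) if token_label(t) == after), None
        )
        if k is None:
            raise RegionLookupError(f"insertion point {after!r} not found")
        sign = "-" if token_sign(toks[i]) < 0 else ""
        toks[i] = f"{sign}{label}1"
        copy = f"{sign}{label}2"
        out = toks[: k + 1] + [copy] + toks[k + 1 :]
        return GeneOrder(tuple(out), order.circular), {
            "op": "duplicate", "label": label, "after": after,
        }

    raise ValidationError(f"unknown perturbation op {op!r}")


def random_tdrl_event(
    order: GeneOrder,
    rng: np.random.Generator,
    window_cap: int = 8,
    dup_bases: tuple[str, ...] = ("CR",),
) -> TDRLEvent:
    """Draw a random valid, non-trivial TDRL event on ``order``."""
    n = len(order)
    for _ in range(1000):
        wl = int(rng.integers(2, min(window_cap, n - 1) + 1))
        ws = int(rng.integers(n))
        window = [order.tokens[(ws + i) % n] for i in range(wl)]
        bases = [base_label(token_label(t)) for t in window]
        if len(set(bases)) != len(bases):
            continue
        choices = []
        for b in bases:
            opts = [1, 2, 3] if b in dup_bases else [1, 2]
            choices.append(int(rng.choice(opts)))
        if all(c in (1, 2) for c in choices) and all(
            a <= b for a, b in zip(choices, choices[1:])
        ):
            continue  # trivial split, try again
        kept1 = frozenset(b for b, c in zip(bases, choices) if c in (1, 3))
        kept2 = frozenset(b for b, c in zip(bases, choices) if c in (2, 3))
        return TDRLEvent(ws, wl, kept1, kept2)
    raise ValidationError("could not draw a non-trivial event")
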