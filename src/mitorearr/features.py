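"""Annotated circular mitogenome feature tables and their geometry.

A vertebrate mitogenome is a circular molecule of ~16-20 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs, the light-strand replication
origin (OL) and one or — in rearranged genomes — two control regions (CR).
This module models such an annotation as a list of 1-based, inclusive
features on the heavy (H) strand and derives all geometric quantities from
it: feature lengths (wrap-around aware), intergenic spacers and overlaps,
and stop-codon completeness.

Coordinates follow the GenBank convention: 1-based, inclusive on both ends,
always expressed on the H strand. A feature whose ``end`` is smaller than
its ``start`` wraps around the circular origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .errors import FormatError, ValidationError

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "CR", "OL")
STRANDS = ("H", "L")

COMPLETE_STOPS = ("TAA", "TAG", "AGA", "AGG")
INCOMPLETE_STOPS = ("TA-", "T-")

#: Columns of the feature-table TSV dialect, in order. Extra columns are
#: tolerated and ignored by the parser; '.' marks an absent value.
TSV_COLUMNS = (
    "name",
    "class",
    "start",
    "end",
    "strand",
    "start_codon",
    "stop_codon",
    "anticodon",
)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated element of a mitogenome.

    ``start``/``end`` are 1-based inclusive H-strand coordinates; ``strand``
    is ``"H"`` or ``"L"``; codon fields are optional annotations (stop codon
    may be an incomplete ``"T-"`` or ``"TA-"``, completed in vivo by
    polyadenylation).
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: str
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def length(self, genome_length: int) -> int:
        return feature_length(self, genome_length)

    @property
    def wraps(self) -> bool:
        return self.end < self.start


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in nt of a feature, counting across the circular origin if needed."""
    if f.end >= f.start:
        return f.end - f.start + 1
    return genome_length - f.start + 1 + f.end


def classify_stop_codon(stop: str) -> str:
    """Classify an annotated stop codon as ``"complete"`` or ``"incomplete"``.

    Complete stops under the vertebrate mitochondrial code are TAA, TAG,
    AGA and AGG; ``T-`` and ``TA-`` denote stops truncated at the mRNA
    boundary.
    """
    if stop in COMPLETE_STOPS:
        return "complete"
    if stop in INCOMPLETE_STOPS:
        return "incomplete"
    raise ValidationError(f"unknown stop codon token: {stop!r}")


@dataclass
class MitogenomeAnnotation:
    """A circular genome length plus its ordered features.

    Features are kept sorted by start coordinate; duplicate elements (two
    control regions) must arrive pre-disambiguated (CR1, CR2). ``warnings``
    collects non-fatal oddities found during validation, e.g. a PCG whose
    length is not compatible with its annotated stop codon.
    """

    genome_length: int
    features: tuple[GeneFeature, ...]
    circular: bool = True
    organism: str = ""
    accession: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = tuple(sorted(self.features, key=lambda f: f.start))
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        self.warnings = []
        for f in self.features:
            if f.gene_class not in GENE_CLASSES:
                raise ValidationError(f"{f.name}: unknown class {f.gene_class!r}")
            if f.strand not in STRANDS:
                raise ValidationError(f"{f.name}: unknown strand {f.strand!r}")
            if not (1 <= f.start <= self.genome_length):
                raise ValidationError(
                    f"{f.name}: start {f.start} outside [1, {self.genome_length}]"
                )
            if not (1 <= f.end <= self.genome_length):
                raise ValidationError(
                    f"{f.name}: end {f.end} outside [1, {self.genome_length}]"
                )
            if f.wraps and not self.circular:
                raise ValidationError(
                    f"{f.name}: wrap-around feature on a linear genome"
                )
            if f.name in seen:
                raise ValidationError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)
            length = f.length(self.genome_length)
            if f.gene_class == "tRNA" and not (60 <= length <= 100):
                self.warnings.append(
                    f"{f.name}: tRNA length {length} outside the typical 60-100 nt"
                )
            if f.gene_class == "PCG" and f.stop_codon:
                kind = classify_stop_codon(f.stop_codon)
                # incomplete stops contribute 1 (T-) or 2 (TA-) annotated nt
                trim = 0 if kind == "complete" else len(f.stop_codon.rstrip("-"))
                if (length - trim) % 3 != 0:
                    self.warnings.append(
                        f"{f.name}: length {length} with stop {f.stop_codon} "
                        "leaves an out-of-frame remainder"
                    )

    # -- lookups ---------------------------------------------------------
    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_class(self, gene_class: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.gene_class == gene_class)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.gene_class] = counts.get(f.gene_class, 0) + 1
        return counts


@dataclass(frozen=True)
class SpacerReport:
    """Gaps between consecutive features around the circle.

    Each pair is ``(upstream name, downstream name, gap nt)``; positive gaps
    are spacers, negative gaps overlaps, zero abutting. ``total_spacer_nt``
    sums positive gaps only.
    """

    pairs: tuple[tuple[str, str, int], ...]

    @property
    def total_spacer_nt(self) -> int:
        return sum(g for _, _, g in self.pairs if g > 0)

    @property
    def n_spacers(self) -> int:
        return sum(1 for _, _, g in self.pairs if g > 0)

    @property
    def n_overlaps(self) -> int:
        return sum(1 for _, _, g in self.pairs if g < 0)

    def gap(self, upstream: str, downstream: str) -> int:
        for u, d, g in self.pairs:
            if u == upstream and d == downstream:
                return g
        raise KeyError((upstream, downstream))


def intergenic_spacers(
    a: MitogenomeAnnotation, include_wrap: bool | None = None
) -> SpacerReport:
    """Compute the gap at every junction between consecutive features.

    The gap between features *i* and *i+1* (sorted by start) is
    ``start[i+1] - end[i] - 1``. When the annotation is circular (or
    ``include_wrap`` forces it) the junction from the last feature back to
    the first is included, measured across the origin.
    """
    feats = a.features
    if len(feats) < 2:
        raise ValidationError("need at least two features to compute spacers")
    if include_wrap is None:
        include_wrap = a.circular
    pairs = []
    for prev, nxt in zip(feats, feats[1:]):
        pairs.append((prev.name, nxt.name, nxt.start - prev.end - 1))
    if include_wrap:
        last, first = feats[-1], feats[0]
        wrap_gap = (a.genome_length - last.end) + (first.start - 1)
        pairs.append((last.name, first.name, wrap_gap))
    return SpacerReport(pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _parse_meta(lines: Iterable[str]) -> dict[str, str]:
    meta = {}
    for ln in lines:
        m = re.match(r"#\s*(\w+)\s*=\s*(.*)\s*$", ln)
        if m:
            meta[m.group(1)] = m.group(2)
    return meta


def parse_feature_table(path: str | Path, format: str | None = None) -> MitogenomeAnnotation:
    """Read an annotation from a feature-table TSV or a GenBank flat file.

    ``format`` is ``"tsv"`` or ``"genbank"``; when omitted it is guessed
    from the file suffix (``.gb``/``.gbk``/``.genbank`` -> GenBank).
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "tsv"
    if format == "genbank":
        ann, _ = parse_genbank(path)
        return ann
    if format != "tsv":
        raise FormatError(f"unknown feature-table format {format!r}")

    text = path.read_text().splitlines()
    comments = [ln for ln in text if ln.startswith("#")]
    body = [ln for ln in text if ln.strip() and not ln.startswith("#")]
    if not body:
        raise FormatError(f"{path}: empty feature table")
    meta = _parse_meta(comments)
    if "genome_length" not in meta:
        raise FormatError(f"{path}: missing '# genome_length=' header")
    genome_length = int(meta["genome_length"])
    circular = meta.get("circular", "true").lower() != "false"

    header = body[0].rstrip("\n").split("\t")
    for col in TSV_COLUMNS:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    idx = {col: header.index(col) for col in header}

    def get(row: list[str], col: str) -> str | None:
        v = row[idx[col]].strip()
        return None if v in (".", "") else v

    feats = []
    for line_no, ln in enumerate(body[1:], start=2):
        row = ln.rstrip("\n").split("\t")
        if len(row) < len(TSV_COLUMNS):
            raise FormatError(f"{path}:{line_no}: expected >= {len(TSV_COLUMNS)} fields")
        try:
            feats.append(
                GeneFeature(
                    name=get(row, "name") or "",
                    gene_class=get(row, "class") or "",
                    start=int(get(row, "start") or "0"),
                    end=int(get(row, "end") or "0"),
                    strand=get(row, "strand") or "",
                    start_codon=get(row, "start_codon"),
                    stop_codon=get(row, "stop_codon"),
                    anticodon=get(row, "anticodon"),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: {exc}") from exc

    return MitogenomeAnnotation(
        genome_length=genome_length,
        features=tuple(feats),
        circular=circular,
        organism=meta.get("organism", ""),
        accession=meta.get("accession", ""),
    )


def write_feature_table(a: MitogenomeAnnotation, path: str | Path) -> None:
    """Serialize an annotation in the TSV dialect (round-trips with the parser)."""
    path = Path(path)
    lines = []
    if a.organism:
        lines.append(f"# organism={a.organism}")
    if a.accession:
        lines.append(f"# accession={a.accession}")
    lines.append(f"# genome_length={a.genome_length}")
    lines.append(f"# circular={'true' if a.circular else 'false'}")
    lines.append("\t".join(TSV_COLUMNS))
    for f in a.features:
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.gene_class,
                    str(f.start),
                    str(f.end),
                    f.strand,
                    f.start_codon or ".",
                    f.stop_codon or ".",
                    f.anticodon or ".",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_GB_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR", "rep_origin": "OL"}


def parse_genbank(path: str | Path) -> tuple[MitogenomeAnnotation, str | None]:
    """Read (annotation, sequence) from a GenBank flat file via Biopython.

    CDS/tRNA/rRNA/D-loop/rep_origin features are mapped to the toolkit's
    classes; duplicated names are disambiguated with numeric suffixes in
    file order (CR, CR -> CR1, CR2). The sequence is returned when present.
    """
    from Bio import SeqIO

    record = SeqIO.read(str(path), "genbank")
    genome_length = len(record.seq) if record.seq is not None else None
    feats: list[GeneFeature] = []
    for ft in record.features:
        if ft.type not in _GB_CLASS:
            continue
        quals = ft.qualifiers
        name = (quals.get("gene") or quals.get("product") or [ft.type])[0]
        name = name.replace(" ", "_")
        start = int(ft.location.start) + 1
        end = int(ft.location.end)
        strand = "L" if ft.location.strand == -1 else "H"
        feats.append(
            GeneFeature(
                name=name,
                gene_class=_GB_CLASS[ft.type],
                start=start,
                end=end,
                strand=strand,
                start_codon=None,
                stop_codon=None,
                anticodon=(quals.get("anticodon") or [None])[0],
            )
        )
    # disambiguate duplicate names in file order
    counts: dict[str, int] = {}
    for f in feats:
        counts[f.name] = counts.get(f.name, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for f in feats:
        if counts[f.name] > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            out.append(replace(f, name=f"{f.name}{seen[f.name]}"))
        else:
            out.append(f)
    if genome_length is None:
        raise FormatError(f"{path}: GenBank record has no length")
    topology = (record.annotations or {}).get("topology", "circular")
    ann = MitogenomeAnnotation(
        genome_length=genome_length,
        features=tuple(out),
        circular=topology != "linear",
        organism=(record.annotations or {}).get("organism", ""),
        accession=record.id or "",
    )
    seq = str(record.seq) if record.seq is not None and len(record.seq) else None
    return ann, seq


def table2_style_rows(a: MitogenomeAnnotation) -> list[dict]:
    """Rows mirroring a published feature table: coordinates, length, codons, gaps."""
    spacers = intergenic_spacers(a)
    gap_before = {d: g for _, d, g in spacers.pairs}
    rows = []
    for f in a.features:
        rows.append(
            {
                "name": f.name,
                "class": f.gene_class,
                "from": f.start,
                "to": f.end,
                "length": f.length(a.genome_length),
                "start_codon": f.start_codon,
                "stop_codon": f.stop_codon,
                "anticodon": f.anticodon,
                "strand": f.strand,
                "intergenic": gap_before.get(f.name),
            }
        )
    return rows
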