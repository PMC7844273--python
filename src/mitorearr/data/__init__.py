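"""Packaged reference tables for the dagger-tooth pike conger mitogenome.

The feature table transcribes the published annotation of the rearranged
*Muraenesox cinereus* mitochondrial genome (GenBank MT571331, 17,673 bp):
40 features — 13 PCGs, 22 tRNAs, 2 rRNAs, OL and two control regions. The
composition table holds the published per-region base percentages and
skews. Both are data inputs; geometry is always recomputed from the
coordinates, and ``cross_check_intergenic`` reports junctions where the
published intergenic column disagrees with the coordinates.
"""

from __future__ import annotations

from importlib.resources import as_file, files

from ..features import MitogenomeAnnotation, intergenic_spacers, parse_feature_table

_FEATURES = "mcinereus_features.tsv"
_COMPOSITION = "mcinereus_composition.tsv"


def load_reference_annotation() -> MitogenomeAnnotation:
    """The published eel annotation as a validated MitogenomeAnnotation."""
    with as_file(files(__package__).joinpath(_FEATURES)) as p:
        return parse_feature_table(p, format="tsv")


def load_printed_intergenic() -> dict[str, int]:
    """Published intergenic column: feature name -> gap upstream of it (bp)."""
    text = files(__package__).joinpath(_FEATURES).read_text()
    out: dict[str, int] = {}
    header: list[str] | None = None
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        row = ln.split("\t")
        if header is None:
            header = row
            continue
        rec = dict(zip(header, row))
        out[rec["name"]] = int(rec["intergenic"])
    return out


def load_reference_composition() -> dict[str, dict[str, float]]:
    """Published per-region composition rows keyed by region label."""
    text = files(__package__).joinpath(_COMPOSITION).read_text()
    out: dict[str, dict[str, float]] = {}
    header: list[str] | None = None
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        row = ln.split("\t")
        if header is None:
            header = row
            continue
        rec = dict(zip(header, row))
        out[rec["region"]] = {k: float(v) for k, v in rec.items() if k != "region"}
    return out


def cross_check_intergenic(
    a: MitogenomeAnnotation | None = None,
) -> list[tuple[str, str, int, int]]:
    """Junctions where the coordinate-derived gap differs from the published one.

    Returns (upstream, downstream, computed, published) tuples. For the
    published eel table exactly the two junctions flanking OL disagree:
    trnN -> OL (computed 0, published -7) and OL -> trnC (computed 11,
    published 7); the published positive gaps total 89 bp over 12 spacers,
    the coordinate-derived ones 93 bp over the same 12 junctions.
    """
    if a is None:
        a = load_reference_annotation()
    printed = load_printed_intergenic()
    mismatches = []
    for u, d, g in intergenic_spacers(a).pairs:
        if d in printed and printed[d] != g:
            mismatches.append((u, d, g, printed[d]))
    return mismatches
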