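"""End-to-end mitogenome reports tying the analysis modules together.

``run_describe`` produces the descriptive half (feature geometry, spacers,
composition/skews, codon usage/RSCU, control-region motifs); sections that
need a sequence are explicitly marked skipped when only an annotation is
supplied. ``run_rearrange`` produces the comparative half (gene order vs a
reference, TDRL scenarios, model adjudication).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import codons as _codons
from . import composition as _comp
from .features import (
    MitogenomeAnnotation,
    classify_stop_codon,
    intergenic_spacers,
    parse_feature_table,
    table2_style_rows,
)
from .order import GeneOrder, canonical_vertebrate_order, compare_orders, extract_order
from .tdrl import adjudicate_models, infer_tdrl

PALINDROME_MOTIFS = ["TACAT", "ATGTA"]


@dataclass
class ReportBundle:
    """Named report sections; every expected section is present or marked skipped."""

    sections: dict = field(default_factory=dict)
    status: int = 0  # 0 ok, 1 analysis infeasibility

    def skipped(self, name: str) -> bool:
        sec = self.sections.get(name)
        return isinstance(sec, dict) and "skipped" in sec

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.sections, indent=indent, default=str)

    def to_text(self) -> str:
        import pandas as pd

        out = []
        for name, sec in self.sections.items():
            out.append(f"== {name} ==")
            if isinstance(sec, list) and sec and isinstance(sec[0], dict):
                out.append(pd.DataFrame(sec).to_string(index=False))
            elif isinstance(sec, dict):
                for k, v in sec.items():
                    out.append(f"{k}: {v}")
            else:
                out.append(str(sec))
            out.append("")
        return "\n".join(out)


def read_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def _load_annotation(source) -> MitogenomeAnnotation:
    if isinstance(source, MitogenomeAnnotation):
        return source
    return parse_feature_table(source)


def run_describe(
    annotation,
    fasta_path: str | Path | None = None,
    sequence: str | None = None,
    circular: bool | None = None,
) -> ReportBundle:
    """Geometry + composition + codon report for one annotated mitogenome."""
    a = _load_annotation(annotation)
    if circular is not None:
        a = MitogenomeAnnotation(
            genome_length=a.genome_length, features=a.features, circular=circular,
            organism=a.organism, accession=a.accession,
        )
    seq = sequence
    if seq is None and fasta_path is not None:
        seq = read_fasta(fasta_path)

    bundle = ReportBundle()
    bundle.sections["summary"] = {
        "organism": a.organism,
        "accession": a.accession,
        "genome_length": a.genome_length,
        "circular": a.circular,
        "feature_counts": a.class_counts(),
        "validation_warnings": list(a.warnings),
    }
    bundle.sections["features"] = table2_style_rows(a)
    sp = intergenic_spacers(a)
    bundle.sections["spacers"] = {
        "pairs": [list(p) for p in sp.pairs],
        "total_spacer_nt": sp.total_spacer_nt,
        "n_spacers": sp.n_spacers,
        "n_overlaps": sp.n_overlaps,
    }
    bundle.sections["stop_codons"] = {
        f.name: classify_stop_codon(f.stop_codon)
        for f in a.features_of_class("PCG")
        if f.stop_codon
    }

    if seq is None:
        reason = {"skipped": "no sequence provided"}
        for name in ("composition", "codon_usage", "rscu", "aa_frequencies", "motifs"):
            bundle.sections[name] = dict(reason)
        return bundle

    regions = ["genome"] + [f.name for f in a.features_of_class("PCG")] + [
        "tRNA", "rRNA", "CR",
    ]
    comp_rows = []
    for region in regions:
        c = _comp.region_composition(seq, a, region)
        comp_rows.append(
            {
                "region": region,
                "pct_a": round(c.pct_a, 1),
                "pct_t": round(c.pct_t, 1),
                "pct_c": round(c.pct_c, 1),
                "pct_g": round(c.pct_g, 1),
                "at_percent": round(c.at_percent, 1),
                "at_skew": round(_comp.at_skew(c), 3),
                "gc_skew": round(_comp.gc_skew(c), 3),
                "length": int(c.total + c.n_other),
            }
        )
    bundle.sections["composition"] = comp_rows

    usage = _codons.count_codons(a, seq)
    rscu_map = _codons.rscu(usage)
    bundle.sections["codon_usage"] = {
        "n_codons": usage.n_codons,
        "skipped_genes": list(usage.skipped_genes),
        "counts": usage.counts,
    }
    bundle.sections["rscu"] = {c: round(v, 3) for c, v in rscu_map.items()}
    bundle.sections["aa_frequencies"] = {
        aa: round(p, 2) for aa, p in _codons.aa_frequencies(usage).items()
    }

    motif_hits = []
    for cr in a.features_of_class("CR"):
        sub = _comp._slice(seq, cr.start, cr.end, a.genome_length)
        for m, pos, strand in _comp.motif_scan(sub, PALINDROME_MOTIFS):
            motif_hits.append(
                {"region": cr.name, "motif": m, "position_in_region": pos,
                 "genome_position": (cr.start + pos - 2) % a.genome_length + 1,
                 "strand": strand}
            )
    bundle.sections["motifs"] = motif_hits
    return bundle


def run_rearrange(
    annotation,
    reference: GeneOrder | None = None,
    max_events: int = 2,
) -> ReportBundle:
    """Gene-order comparison, TDRL inference and model adjudication."""
    a = _load_annotation(annotation) if not isinstance(annotation, GeneOrder) else None
    obs = annotation if isinstance(annotation, GeneOrder) else extract_order(a)
    ref = reference or canonical_vertebrate_order()

    bundle = ReportBundle()
    bundle.sections["observed_order"] = str(obs)
    bundle.sections["reference_order"] = str(ref)

    call = compare_orders(obs, ref)
    bundle.sections["comparison"] = {
        "kinds": list(call.kinds),
        "identical": call.identical,
        "moved_blocks": [
            {"labels": list(mb.labels), "old_context": list(mb.old_context),
             "new_context": list(mb.new_context)}
            for mb in call.moved_blocks
        ],
        "inverted_blocks": [list(b) for b in call.inverted_blocks],
        "duplicated": list(call.duplicated),
        "lost": list(call.lost),
    }

    search = infer_tdrl(obs, ref, max_events=max_events)
    bundle.sections["tdrl"] = {
        "feasible": search.feasible,
        "reason": search.reason,
        "n_minimal_scenarios": len(search.scenarios),
        "scenarios": [
            s.to_dict(search.reference) for s in search.scenarios[:10]
        ],
    }

    spacers = intergenic_spacers(a) if a is not None else None
    verdict = adjudicate_models(obs, ref, spacers, max_events=max_events)
    bundle.sections["adjudication"] = {
        "recombination_plausible": verdict.recombination_plausible,
        "tdrl_plausible": verdict.tdrl_plausible,
        "tdnl_plausible": verdict.tdnl_plausible,
        "drrl_plausible": verdict.drrl_plausible,
        "reasons": verdict.reasons,
        "note": verdict.note,
    }
    if not call.identical and not search.feasible and not verdict.any_plausible:
        bundle.status = 1
    return bundle
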