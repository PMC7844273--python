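# mitorearr

Vertebrate mitochondrial genomes are compact circles of ~16–20 kb carrying a
nearly fixed inventory — 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs,
the light-strand replication origin (O<sub>L</sub>) and a control region (CR)
— in a gene order so conserved that departures from it are phylogenetically
informative. `mitorearr` is a toolkit for characterizing annotated
mitogenomes and analysing such departures. It was built around the
rearranged mitogenome of the dagger-tooth pike conger *Muraenesox cinereus*
(Anguilliformes), in which *ND6* and its bound *trnE* are translocated to
between *trnT* and *trnP* and the control region is duplicated, and it ships
that genome's published coordinate and composition tables as packaged
reference data.

It is aimed at researchers in mitogenomics and molecular evolution who want
to go from a feature table (TSV or GenBank flat file) to:

- **annotation geometry** — wrap-around-aware feature lengths, intergenic
  spacers and overlaps around the circle, start/stop-codon classification
  (including the incomplete `T-`/`TA-` stops completed by polyadenylation);
- **composition statistics** — per-region base content and the strand
  asymmetry skews AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C);
- **codon usage** — counts, amino-acid frequencies and relative synonymous
  codon usage, RSCU(c) = count(c) · d<sub>a</sub> / Σ<sub>c′∈a</sub> count(c′),
  under the vertebrate mitochondrial code (AGA/AGG stops, ATA = Met,
  TGA = Trp; Ser and Leu as six-fold families);
- **rearrangement analysis** — comparison of circular signed gene orders
  against the canonical vertebrate arrangement (translocation, inversion,
  shuffling, duplication calls), exhaustive inference of parsimonious
  tandem-duplication–random-loss (TDRL) scenarios (a window of genes is
  duplicated in tandem, then one copy of each duplicate is lost, reordering
  the survivors without ever flipping a strand), and rule-based adjudication
  among four mechanisms: recombination, TDRL, tandem-duplication–non-random
  loss (TDNL) and double-replication–random loss (DRRL);
- **tree character mapping** — monophyly of a binary rearranged/canonical
  character on a newick phylogeny;
- **synthetic mitogenomes** — a seeded generator emitting sequence, feature
  table and ground truth (planted codon counts, composition, TDRL events,
  control-region palindromes), including a structural twin of the 17,673 bp
  eel genome, so every analysis is testable without downloads.

## Worked example

```python
from mitorearr import (adjudicate_models, canonical_vertebrate_order,
                       compare_orders, extract_order, infer_tdrl,
                       intergenic_spacers)
from mitorearr.data import load_reference_annotation

ann = load_reference_annotation()
obs, ref = extract_order(ann), canonical_vertebrate_order()
call = compare_orders(obs, ref)
print("+".join(call.kinds), call.moved_blocks[0].labels)

best = infer_tdrl(obs, ref, max_events=1).scenarios[0]
ev = best.events[0]
print(ev.window_length, sorted(ev.kept_in_copy1), sorted(ev.kept_in_copy2))

verdict = adjudicate_models(obs, ref, intergenic_spacers(ann))
print(verdict.tdrl_plausible, verdict.tdnl_plausible)
```

prints

```
duplication+translocation ('-ND6', '-E')
6 ['CR', 'Cytb', 'T'] ['CR', 'E', 'ND6', 'P']
True False
```

meaning: relative to the canonical order, the (−ND6, −E) block now sits
between trnT and trnP with the control region duplicated; the most
parsimonious explanation is a single TDRL event duplicating the six-gene
window (−ND6, −E, Cytb, T, −P, CR) with copy 1 keeping {Cytb, T, CR} and
copy 2 keeping {ND6, E, P, CR} (the CR surviving twice); and of the four
mechanisms only TDRL is adjudicated plausible — supported by four positive
intergenic spacers flanking the rearranged region, the expected remnants of
incompletely deleted duplicates.

The `examples/` directory holds one narrative script per capability
(`describe_mitogenome.py`, `rearrangement_scenario.py`,
`synthesize_genome.py`, `tree_character.py`); each prints the numbers it
computes with a line on what they mean. A thin CLI wraps the same pipeline:
`mitorearr describe`, `rearrange`, `synthesize`, `tree-map`.

## Scope notes

The toolkit analyses *annotated* genomes: it does not call genes, fold
tRNAs, align sequences or infer trees. Where the published eel tables are
internally inconsistent (the intergenic column around O<sub>L</sub>, the COI
length/stop combination), the toolkit recomputes from coordinates and
reports the discrepancy rather than silently correcting either side; see
`docs/methods.md`.
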