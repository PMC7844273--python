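"""Mapping the rearrangement character onto a family-level phylogeny.

Scores each of 15 eel family tips as 'rearranged' (ND6+trnE translocated,
control region duplicated) or 'canonical', and asks whether each state
forms a single clade — the pattern that makes gene order a usable
phylogenetic marker.
"""

from mitorearr import map_character_on_tree

NEWICK = (
    "(Outgroup,(Nemichthyidae,(Serrivomeridae,(Anguillidae,(Moringuidae,"
    "(Chlopsidae,(Muraenidae,(Myrocongridae,(Heterenchelyidae,"
    "(Synaphobranchidae,((Derichthyidae,Nettastomatidae),"
    "(Congridae,(Muraenesocidae,Ophichthidae)))))))))))));"
)

states = {t: "canonical" for t in (
    "Outgroup", "Nemichthyidae", "Serrivomeridae", "Anguillidae", "Moringuidae",
    "Chlopsidae", "Muraenidae", "Myrocongridae", "Heterenchelyidae",
    "Synaphobranchidae",
)}
for t in ("Derichthyidae", "Nettastomatidae", "Congridae",
          "Muraenesocidae", "Ophichthidae"):
    states[t] = "rearranged"

report = map_character_on_tree(NEWICK, states)
for state, mono in report.state_monophyletic.items():
    print(f"{state:10s} tips form a clade: {mono}")
print("smallest clade holding all rearranged tips:",
      ", ".join(report.smallest_clade_with_rearranged))
# a monophyletic 'rearranged' state is consistent with a single origin of
# the translocation + CR duplication in the ancestor of these families
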