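"""Gene-order comparison, TDRL inference and mechanism adjudication.

Extracts the observed gene order from the packaged eel annotation, compares
it to the canonical vertebrate arrangement, searches for the most
parsimonious tandem-duplication-random-loss scenario, and asks which of the
four rearrangement mechanisms the evidence supports.
"""

from mitorearr import (
    adjudicate_models,
    canonical_vertebrate_order,
    compare_orders,
    extract_order,
    infer_tdrl,
    intergenic_spacers,
)
from mitorearr.data import load_reference_annotation

ann = load_reference_annotation()
obs = extract_order(ann)
ref = canonical_vertebrate_order()
print("observed suffix :", ",".join(obs.tokens[-8:]))
print("canonical suffix:", ",".join(ref.tokens[-7:]))

call = compare_orders(obs, ref)
print(f"\ncall: {'+'.join(call.kinds)}; duplicated {list(call.duplicated)}")
for mb in call.moved_blocks:
    print(f"  block {list(mb.labels)} moved from between {mb.old_context} "
          f"to between {mb.new_context}")

search = infer_tdrl(obs, ref, max_events=1)
best = search.scenarios[0]
ev = best.events[0]
print(f"\nminimal TDRL scenario: {best.n_events} event, "
      f"window {list(ev.window_tokens(search.reference))}")
print(f"  copy 1 keeps {sorted(ev.kept_in_copy1)}, "
      f"copy 2 keeps {sorted(ev.kept_in_copy2)}")
print("  (the control region survives in both copies; "
      "ND6+trnE land between trnT and trnP)")

verdict = adjudicate_models(obs, ref, intergenic_spacers(ann))
for model in ("recombination", "tdrl", "tdnl", "drrl"):
    flag = getattr(verdict, f"{model}_plausible")
    print(f"{model:14s} {'plausible' if flag else 'implausible'}: "
          f"{verdict.reasons[model]}")
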