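"""Independent brute-force oracles for the rearrangement search.

These deliberately re-derive results by naive enumeration (apply every
candidate event and compare) so the toolkit's optimized search can be
checked against them; they share no code path with the implementation
beyond ``apply_tdrl`` itself, whose output is the definition of an event.
"""

from __future__ import annotations

import itertools

from mitorearr import GeneOrder, TDRLEvent, ValidationError, apply_tdrl
from mitorearr.order import base_label, token_label


def brute_single_event_scenarios(
    obs: GeneOrder,
    ref: GeneOrder,
    window_cap: int,
    dup_bases: tuple[str, ...] = ("CR",),
) -> set[tuple[int, int, frozenset, frozenset]]:
    """Every single event whose application to ref reproduces obs.

    Naive enumeration: all windows x all per-label assignments to copy 1,
    copy 2 or (for duplicable labels) both, each applied and compared.
    """
    n = len(ref)
    found = set()
    for ws in range(n):
        for wl in range(1, min(window_cap, n) + 1):
            window = [ref.tokens[(ws + i) % n] for i in range(wl)]
            bases = [base_label(token_label(t)) for t in window]
            if len(set(bases)) != len(bases):
                continue
            opts = [
                ((1,), (2,), (1, 2)) if b in dup_bases else ((1,), (2,))
                for b in bases
            ]
            for choice in itertools.product(*opts):
                k1 = frozenset(b for b, c in zip(bases, choice) if 1 in c)
                k2 = frozenset(b for b, c in zip(bases, choice) if 2 in c)
                ev = TDRLEvent(ws, wl, k1, k2)
                try:
                    res = apply_tdrl(ref, ev)
                except ValidationError:
                    continue
                if res.equals(obs, base=True):
                    found.add((ws, wl, k1, k2))
    return found


def brute_segment_feasible(window: list[str], segment: list[str]) -> bool:
    """Is the observed segment producible by some loss bipartition of the window?

    Enumerates every kept-set pair (no both-copy retention: callers use
    duplicate-free segments) and compares the survivor concatenation with
    the segment directly.
    """
    wl = len(window)
    for mask in range(2 ** wl):
        copy1 = [window[i] for i in range(wl) if mask >> i & 1]
        copy2 = [window[i] for i in range(wl) if not mask >> i & 1]
        if copy1 + copy2 == segment:
            return True
    return False
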