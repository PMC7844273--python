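"""Tandem-duplication-random-loss (TDRL) scenario inference and model adjudication.

Under the TDRL mechanism a contiguous window of genes is duplicated in
tandem and one copy of each duplicated gene is subsequently lost; the
surviving copies reorder the genome without ever flipping a gene's strand.
An event is described by the duplicated window plus the per-copy loss
pattern: every window gene is kept in copy 1, copy 2, or (for retainable
elements such as the control region) both.

``infer_tdrl`` searches for parsimonious event sequences transforming a
reference order into an observed one; ``adjudicate_models`` applies the
verbal criteria distinguishing four rearrangement mechanisms —
recombination (inverted fragments), TDRL, tandem-duplication-non-random-
loss (TDNL: polarity-clustered, order-preserved losses) and double-
replication-random-loss (DRRL: rearrangement confined between two control
regions) — to an observed/reference pair plus intergenic-spacer evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .features import SpacerReport
from .order import (
    GeneOrder,
    base_label,
    base_token,
    compare_orders,
    token_label,
    token_sign,
)

DEFAULT_WINDOW_CAP = 12
DEFAULT_DUP_BASES = ("CR",)


@dataclass(frozen=True)
class TDRLEvent:
    """One tandem duplication of a reference window with per-copy losses.

    ``window_start`` indexes the order the event is applied to (0-based,
    circular); kept sets hold unsigned base labels. A label kept in both
    copies survives twice (suffixes 1/2); a label kept in neither would be
    a deletion, which is disallowed.
    """

    window_start: int
    window_length: int
    kept_in_copy1: frozenset[str]
    kept_in_copy2: frozenset[str]

    def window_tokens(self, ref: GeneOrder) -> tuple[str, ...]:
        n = len(ref)
        return tuple(ref.tokens[(self.window_start + i) % n] for i in range(self.window_length))


def apply_tdrl(ref: GeneOrder, e: TDRLEvent) -> GeneOrder:
    """Deterministically apply a TDRL event to a gene order.

    Result = prefix + copy-1 survivors (in window order) + copy-2 survivors
    (in window order) + suffix. Labels kept in both copies get numeric
    suffixes (CR -> CR1, CR2). Strand signs are never changed.
    """
    n = len(ref)
    if not (1 <= e.window_length <= n):
        raise ValidationError(f"window length {e.window_length} outside [1, {n}]")
    if e.window_start + e.window_length > n and not ref.circular:
        raise ValidationError("window wraps around a linear order")
    window = e.window_tokens(ref)
    wbases = [base_label(token_label(t)) for t in window]
    if len(set(wbases)) != len(wbases):
        raise ValidationError("window contains duplicate base labels")
    wset = set(wbases)
    for kept in (e.kept_in_copy1, e.kept_in_copy2):
        if not kept <= wset:
            raise ValidationError(f"kept set {sorted(kept - wset)} outside window")
    neither = wset - (e.kept_in_copy1 | e.kept_in_copy2)
    if neither:
        raise ValidationError(
            f"labels kept in neither copy (deletion not allowed): {sorted(neither)}"
        )
    both = e.kept_in_copy1 & e.kept_in_copy2

    def survivors(kept: frozenset[str], suffix: str) -> list[str]:
        out = []
        for t, b in zip(window, wbases):
            if b in kept:
                lbl = token_label(t)
                if b in both:
                    lbl = f"{base_label(lbl)}{suffix}"
                out.append(lbl if token_sign(t) > 0 else f"-{lbl}")
        return out

    rest = [ref.tokens[(e.window_start + e.window_length + i) % n]
            for i in range(n - e.window_length)]
    tokens = tuple(survivors(e.kept_in_copy1, "1") + survivors(e.kept_in_copy2, "2") + rest)
    # restore the original rotation for non-wrapping windows, purely cosmetic
    if ref.circular and e.window_start + e.window_length <= n:
        shift = len(tokens) - e.window_start
        tokens = tokens[shift:] + tokens[:shift]
    return GeneOrder(tokens, ref.circular)


@dataclass(frozen=True)
class TDRLScenario:
    """An ordered list of events transforming the reference into the target."""

    events: tuple[TDRLEvent, ...]
    result: GeneOrder

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def total_window_length(self) -> int:
        return sum(e.window_length for e in self.events)

    def to_dict(self, ref: GeneOrder) -> dict:
        cur = ref
        events = []
        for e in self.events:
            events.append(
                {
                    "window": list(e.window_tokens(cur)),
                    "kept_in_copy1": sorted(e.kept_in_copy1),
                    "kept_in_copy2": sorted(e.kept_in_copy2),
                }
            )
            cur = apply_tdrl(cur, e)
        return {"n_events": self.n_events, "events": events, "result": str(self.result)}


@dataclass
class TDRLSearchResult:
    """All minimal scenarios found, or an explicit infeasibility verdict."""

    scenarios: list[TDRLScenario]
    feasible: bool
    reason: str = ""
    reference: GeneOrder | None = None  # rotation the window indices refer to

    def __iter__(self):
        return iter(self.scenarios)

    def __len__(self):
        return len(self.scenarios)


def _signed_base_counts(o: GeneOrder) -> dict[str, int]:
    out: dict[str, int] = {}
    for t in o.tokens:
        bt = base_token(t)
        out[bt] = out.get(bt, 0) + 1
    return out


def segment_splits(window_indices: list[int]) -> list[int]:
    """Split points turning an index sequence into two increasing runs.

    A single TDRL event leaves the observed window segment as the copy-1
    survivors (in window order) followed by the copy-2 survivors (in window
    order): a concatenation of two strictly increasing runs of window
    indices. Returns every cut position ``p`` such that ``indices[:p]`` and
    ``indices[p:]`` are both strictly increasing — empty when the segment
    is not reachable by one event with this window.
    """
    L = len(window_indices)
    inc_prefix = [True] * (L + 1)
    for p in range(2, L + 1):
        inc_prefix[p] = inc_prefix[p - 1] and (
            window_indices[p - 2] < window_indices[p - 1]
        )
    inc_suffix = [True] * (L + 1)
    for p in range(L - 2, -1, -1):
        inc_suffix[p] = inc_suffix[p + 1] and (
            window_indices[p] < window_indices[p + 1]
        )
    return [p for p in range(L + 1) if inc_prefix[p] and inc_suffix[p]]


def interleaving_feasible(window_indices: list[int]) -> bool:
    """Single-event feasibility of an observed window segment.

    Equivalent to the segment having at most one descent, i.e. admitting a
    cut into two strictly increasing runs; agrees with brute-force loss-
    bipartition enumeration (a property exercised in the test suite).
    """
    return bool(segment_splits(window_indices))


def _single_event_scenarios(
    cur: GeneOrder,
    obs: GeneOrder,
    window_cap: int,
    dup_bases: tuple[str, ...],
) -> list[TDRLEvent]:
    """Exhaustively find every single TDRL event mapping ``cur`` onto ``obs``.

    For each candidate window the rest of ``cur`` must appear intact in
    ``obs`` (up to rotation); the remaining observed segment must then be an
    interleaving of two subsequences of the window, enumerated exactly.
    """
    n = len(cur)
    m = len(obs)
    obs_b = [base_token(t) for t in obs.tokens]
    cur_b = [base_token(t) for t in cur.tokens]
    obs_pos: dict[str, list[int]] = {}
    for i, t in enumerate(obs_b):
        obs_pos.setdefault(t, []).append(i)
    events: list[TDRLEvent] = []
    max_wl = min(window_cap, n)
    for ws in range(n):
        for wl in range(1, max_wl + 1):
            if not cur.circular and ws + wl > n:
                break
            window = [cur_b[(ws + i) % n] for i in range(wl)]
            wbases = [token_label(t) for t in window]
            if len(set(wbases)) != len(wbases):
                continue
            rest = [cur_b[(ws + wl + i) % n] for i in range(n - wl)]
            seg_len = m - len(rest)
            if seg_len < wl:  # cannot cover every window label
                continue
            if seg_len > 2 * wl:
                continue
            # candidate rotations: the tail must start with rest[0] (or any
            # rotation when the window covers the whole order)
            if rest:
                starts = [
                    (p - seg_len) % m for p in obs_pos.get(rest[0], [])
                ]
            else:
                starts = list(range(m))
            if not obs.circular:
                starts = [k for k in starts if k == 0]
            for k in starts:
                rot = obs_b[k:] + obs_b[:k]
                if rot[seg_len:] != rest:
                    continue
                seg = rot[:seg_len]
                idx_of = {b: i for i, b in enumerate(window)}
                if any(t not in idx_of for t in seg):
                    continue
                seg_counts: dict[str, int] = {}
                for t in seg:
                    seg_counts[t] = seg_counts.get(t, 0) + 1
                ok = True
                for t, c in seg_counts.items():
                    b = base_label(token_label(t))
                    if c > 2 or (c == 2 and b not in dup_bases):
                        ok = False
                        break
                if not ok or len(set(seg)) != wl:
                    continue
                indices = [idx_of[t] for t in seg]
                seen_split: set[tuple[frozenset, frozenset]] = set()
                for p in segment_splits(indices):
                    kept1 = frozenset(wbases[idx_of[t]] for t in seg[:p])
                    kept2 = frozenset(wbases[idx_of[t]] for t in seg[p:])
                    if (kept1, kept2) in seen_split:
                        continue
                    seen_split.add((kept1, kept2))
                    events.append(TDRLEvent(ws, wl, kept1, kept2))
                break  # one matching rotation is enough per window
    # dedupe
    seen = set()
    uniq = []
    for e in events:
        key = (e.window_start, e.window_length, e.kept_in_copy1, e.kept_in_copy2)
        if key not in seen:
            seen.add(key)
            uniq.append(e)
    return uniq


def _displaced_positions(cur: GeneOrder, obs: GeneOrder) -> set[int]:
    """Positions in ``cur`` whose neighbourhood differs from its context in obs."""
    obs_ctx: dict[str, set[tuple[str, str]]] = {}
    m = len(obs)
    for i, t in enumerate(obs.tokens):
        bt = base_token(t)
        ctx = (base_token(obs.tokens[(i - 1) % m]), base_token(obs.tokens[(i + 1) % m]))
        obs_ctx.setdefault(bt, set()).add(ctx)
    out = set()
    n = len(cur)
    for i, t in enumerate(cur.tokens):
        bt = base_token(t)
        ctx = (base_token(cur.tokens[(i - 1) % n]), base_token(cur.tokens[(i + 1) % n]))
        if ctx not in obs_ctx.get(bt, set()):
            out.add(i)
    return out


def _all_nontrivial_events(
    cur: GeneOrder,
    window_cap: int,
    dup_bases: tuple[str, ...],
    restrict_to: set[int] | None,
) -> list[TDRLEvent]:
    """Enumerate candidate intermediate events (those that change the order)."""
    n = len(cur)
    cur_b = [token_label(base_token(t)) for t in cur.tokens]
    events = []
    for ws in range(n):
        for wl in range(1, min(window_cap, n) + 1):
            if not cur.circular and ws + wl > n:
                break
            span = [(ws + i) % n for i in range(wl)]
            if restrict_to is not None and not (set(span) & restrict_to):
                continue
            wbases = [cur_b[p] for p in span]
            if len(set(wbases)) != len(wbases):
                continue
            choice_sets = [
                ((1,), (2,), (1, 2)) if base_label(b) in dup_bases else ((1,), (2,))
                for b in wbases
            ]
            import itertools as _it

            for choices in _it.product(*choice_sets):
                kept1 = frozenset(wbases[i] for i, c in enumerate(choices) if 1 in c)
                kept2 = frozenset(wbases[i] for i, c in enumerate(choices) if 2 in c)
                # skip order-preserving splits with no retained duplicate:
                # those reproduce the window unchanged
                flat = [c[0] for c in choices]
                if all(len(c) == 1 for c in choices) and all(
                    a <= b for a, b in zip(flat, flat[1:])
                ):
                    continue
                events.append(TDRLEvent(ws, wl, kept1, kept2))
    return events


def infer_tdrl(
    obs: GeneOrder,
    ref: GeneOrder,
    max_events: int = 1,
    window_cap: int = DEFAULT_WINDOW_CAP,
    dup_bases: tuple[str, ...] = DEFAULT_DUP_BASES,
) -> TDRLSearchResult:
    """Search for minimal TDRL scenarios transforming ``ref`` into ``obs``.

    The search is exhaustive for single events (all windows up to
    ``window_cap`` x all loss bipartitions; both-copy retention restricted
    to ``dup_bases``, by default the control region). For deeper searches
    on large orders, candidate intermediate windows are restricted to the
    region where the two orders disagree. Scenarios are returned sorted by
    (event count, total window length, window start); an empty scenario is
    returned when the orders already agree, and an infeasibility result —
    not an exception — when nothing is found within ``max_events``.
    """
    if max_events > 3:
        raise ValidationError("max_events is capped at 3")
    ref_a = ref.anchored("F") if _has_unique(ref, "F") else ref
    # feasibility pre-checks: TDRL preserves signs, never deletes, and only
    # duplicates; surplus copies are allowed only for dup_bases.
    rc, oc = _signed_base_counts(ref_a), _signed_base_counts(obs)
    missing = [t for t in rc if t not in oc]
    if missing:
        return TDRLSearchResult(
            [], False,
            f"labels absent from observed order (TDRL cannot delete or flip strand): {sorted(missing)}",
            ref_a,
        )
    novel = [t for t in oc if t not in rc]
    if novel:
        return TDRLSearchResult(
            [], False,
            f"observed labels not in reference (sign flips or foreign genes): {sorted(novel)}",
            ref_a,
        )
    bad_dup = [
        t for t, c in oc.items()
        if c > rc[t] and base_label(token_label(t)) not in dup_bases
    ]
    if bad_dup:
        return TDRLSearchResult(
            [], False,
            f"retained duplicates outside the allowed classes: {sorted(bad_dup)}",
            ref_a,
        )

    if ref_a.equals(obs, base=True):
        return TDRLSearchResult([TDRLScenario((), ref_a)], True, "orders identical", ref_a)

    def search(cur: GeneOrder, depth: int) -> list[tuple[TDRLEvent, ...]]:
        if cur.equals(obs, base=True):
            return [()]
        single = _single_event_scenarios(cur, obs, window_cap, dup_bases)
        if single:
            return [(e,) for e in single]
        if depth <= 1:
            return []
        restrict = _displaced_positions(cur, obs) if len(cur) > 15 else None
        found: list[tuple[TDRLEvent, ...]] = []
        seen_mid: set[tuple[str, ...]] = set()
        for ev in _all_nontrivial_events(cur, window_cap, dup_bases, restrict):
            try:
                mid = apply_tdrl(cur, ev)
            except ValidationError:
                continue
            key = mid.canonical_form(base=True)
            if key in seen_mid:
                continue
            seen_mid.add(key)
            for tail in search(mid, depth - 1):
                found.append((ev,) + tail)
        if found:
            best = min(len(s) for s in found)
            found = [s for s in found if len(s) == best]
        return found

    event_lists = search(ref_a, max_events)
    if not event_lists:
        return TDRLSearchResult(
            [], False, f"no scenario within {max_events} event(s)", ref_a
        )
    scenarios = []
    for evs in event_lists:
        cur = ref_a
        for e in evs:
            cur = apply_tdrl(cur, e)
        scenarios.append(TDRLScenario(tuple(evs), cur))
    scenarios.sort(
        key=lambda s: (
            s.n_events,
            s.total_window_length,
            tuple((e.window_start, tuple(sorted(e.kept_in_copy1))) for e in s.events),
        )
    )
    return TDRLSearchResult(scenarios, True, "", ref_a)


def _has_unique(o: GeneOrder, label: str) -> bool:
    return sum(1 for t in o.tokens if token_label(t) == label) == 1


# ---------------------------------------------------------------------------
# Model adjudication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelAdjudication:
    """Plausibility verdicts for the four rearrangement mechanisms."""

    recombination_plausible: bool
    tdrl_plausible: bool
    tdnl_plausible: bool
    drrl_plausible: bool
    reasons: dict = field(default_factory=dict)
    note: str = ""

    @property
    def any_plausible(self) -> bool:
        return any(
            (self.recombination_plausible, self.tdrl_plausible,
             self.tdnl_plausible, self.drrl_plausible)
        )


def _context_sides(obs: GeneOrder, ref: GeneOrder) -> list[tuple[bool, bool]]:
    """Per obs position: does (previous, next) neighbour match the reference?

    A side matches when the neighbouring signed label is one this token
    abuts on that side somewhere in the reference; a token whose signed
    label is absent from the reference (sign flip) matches on neither side.
    """
    m, n = len(obs), len(ref)
    ref_prev: dict[str, set[str]] = {}
    ref_next: dict[str, set[str]] = {}
    for i, t in enumerate(ref.tokens):
        bt = base_token(t)
        ref_prev.setdefault(bt, set()).add(base_token(ref.tokens[(i - 1) % n]))
        ref_next.setdefault(bt, set()).add(base_token(ref.tokens[(i + 1) % n]))
    sides = []
    for i, t in enumerate(obs.tokens):
        bt = base_token(t)
        p = base_token(obs.tokens[(i - 1) % m])
        q = base_token(obs.tokens[(i + 1) % m])
        sides.append((p in ref_prev.get(bt, set()), q in ref_next.get(bt, set())))
    return sides


def _rearranged_region(obs: GeneOrder, ref: GeneOrder) -> tuple[int, int] | None:
    """Minimal circular span of obs covering every context-changed token.

    Returns (start, length) over obs positions, or None when nothing
    changed.
    """
    sides = _context_sides(obs, ref)
    marked = {i for i, (p, q) in enumerate(sides) if not (p and q)}
    if not marked:
        return None
    m = len(obs)
    pos = sorted(marked)
    if not obs.circular:
        return (pos[0], pos[-1] - pos[0] + 1)
    # smallest circular window covering all marked positions = complement of
    # the largest unmarked gap
    gaps = []
    for a, b in zip(pos, pos[1:] + [pos[0] + m]):
        gaps.append((b - a - 1, a))
    gap_len, gap_start = max(gaps)
    start = (gap_start + gap_len + 1) % m
    length = m - gap_len
    return (start, length)


def _polarity_clustered_order_preserved(
    region_tokens: list[str], ref: GeneOrder
) -> tuple[bool, str]:
    """TDNL/DRRL signature: each strand forms one run, internal order as in ref."""
    signs = [token_sign(t) for t in region_tokens]
    runs = 1 + sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    n_strands = len(set(signs))
    if runs > n_strands:
        return False, "mixed strands: polarity classes are not contiguous"
    ref_pos = {token_label(base_token(t)): i for i, t in enumerate(ref.tokens)}
    for s in set(signs):
        sub = [ref_pos.get(token_label(base_token(t)))
               for t in region_tokens if token_sign(t) == s]
        sub = [p for p in sub if p is not None]
        if any(a > b for a, b in zip(sub, sub[1:])):
            return False, "relative order within a polarity class changed"
    return True, "polarity-clustered with order preserved"


def adjudicate_models(
    obs: GeneOrder,
    ref: GeneOrder,
    spacers: SpacerReport | None = None,
    max_events: int = 2,
    min_supporting_spacers: int = 2,
) -> ModelAdjudication:
    """Decide which rearrangement mechanisms can explain obs given ref.

    Rules: recombination needs an inverted fragment. TDNL needs the
    rearranged region polarity-clustered with per-strand order preserved,
    no sign flips, and no retained duplicate inside the region (polarity-
    determined loss is complete — a surviving duplicate control region is
    evidence of random loss). DRRL needs two control regions with every
    changed gene strictly between them and the between-segment polarity-
    clustered. TDRL needs a scenario from ``infer_tdrl`` plus (when a
    spacer report is supplied) at least ``min_supporting_spacers`` positive
    intergenic spacers in or adjacent to the rearranged region — the
    duplication-remnant evidence.
    """
    call = compare_orders(obs, ref)
    reasons: dict[str, str] = {}
    if call.identical:
        return ModelAdjudication(
            False, False, False, False,
            reasons={k: "orders identical" for k in ("recombination", "tdrl", "tdnl", "drrl")},
            note="no rearrangement",
        )

    recomb = bool(call.inverted_blocks)
    reasons["recombination"] = (
        f"inverted fragment(s) present: {call.inverted_blocks}" if recomb
        else "no inverted fragment; recombination explains only exchange/reversal of small fragments"
    )

    region = _rearranged_region(obs, ref)
    m = len(obs)
    if region is None:
        region_tokens: list[str] = []
        region_idx: set[int] = set()
    else:
        start, length = region
        region_idx = {(start + i) % m for i in range(length)}
        region_tokens = [obs.tokens[(start + i) % m] for i in range(length)]

    dup_in_region = sorted(
        {base_label(token_label(t)) for t in region_tokens}
        & set(call.duplicated)
    )
    clustered, why = _polarity_clustered_order_preserved(region_tokens, ref)
    if not region_tokens:
        tdnl = False
        reasons["tdnl"] = "no rearranged region"
    elif recomb:
        tdnl = False
        reasons["tdnl"] = "sign-flipped genes present; duplication-loss cannot invert"
    elif dup_in_region:
        tdnl = False
        reasons["tdnl"] = (
            f"retained duplicate ({', '.join(dup_in_region)}) in the rearranged "
            "region; polarity-determined loss leaves no duplicates"
        )
    else:
        tdnl = clustered
        reasons["tdnl"] = why

    cr_pos = [i for i, t in enumerate(obs.tokens)
              if base_label(token_label(t)) == "CR"]
    if len(cr_pos) < 2:
        drrl = False
        reasons["drrl"] = "fewer than two control regions"
    elif recomb:
        drrl = False
        reasons["drrl"] = "sign-flipped genes present; duplication-loss cannot invert"
    else:
        lo, hi = min(cr_pos), max(cr_pos)
        between = set(range(lo, hi + 1))
        sides = _context_sides(obs, ref)
        cr_set = set(cr_pos)

        def _boundary_artifact(i: int) -> bool:
            # a token flanking an inserted CR copy, intact on its other
            # side, is the expected junction scar of the CR insertion
            # itself, not an independently rearranged gene
            prev_cr = ((i - 1) % m) in cr_set
            next_cr = ((i + 1) % m) in cr_set
            p_ok, q_ok = sides[i]
            return (prev_cr and q_ok) or (next_cr and p_ok)

        outside = {
            i for i in region_idx - between
            if base_label(token_label(obs.tokens[i])) != "CR"
            and not _boundary_artifact(i)
        }
        if outside:
            drrl = False
            reasons["drrl"] = (
                "rearranged genes extend outside the segment between the two "
                f"control regions: {sorted(obs.tokens[i] for i in outside)}"
            )
        else:
            strictly_between = [
                obs.tokens[i] for i in range(lo + 1, hi)
            ]
            drrl, why_b = _polarity_clustered_order_preserved(strictly_between, ref)
            reasons["drrl"] = why_b
    drrl = bool(region_tokens) and drrl

    search = infer_tdrl(obs, ref, max_events=max_events)
    if not search.feasible:
        tdrl_ok = False
        reasons["tdrl"] = search.reason
    else:
        if spacers is None:
            tdrl_ok = True
            reasons["tdrl"] = "scenario found (no spacer report supplied)"
        else:
            adjacent = set()
            if region is not None:
                start, length = region
                adjacent = {(start - 1) % m, (start + length) % m}
            near_labels = {
                token_label(obs.tokens[i]) for i in (region_idx | adjacent)
            }
            def _tok(name: str) -> str:
                return name[3:] if name.startswith("trn") else name
            supporting = [
                (u, d, g) for u, d, g in spacers.pairs
                if g >= 1 and (_tok(u) in near_labels or _tok(d) in near_labels)
            ]
            tdrl_ok = len(supporting) >= min_supporting_spacers
            reasons["tdrl"] = (
                f"scenario found; {len(supporting)} positive spacer(s) in/adjacent to the "
                f"rearranged region: {[(u, d) for u, d, _ in supporting]}"
            )
    return ModelAdjudication(
        recombination_plausible=recomb,
        tdrl_plausible=tdrl_ok,
        tdnl_plausible=tdnl,
        drrl_plausible=drrl,
        reasons=reasons,
        note="" if (recomb or tdrl_ok or tdnl or drrl) else "none of the four models fits",
    )
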