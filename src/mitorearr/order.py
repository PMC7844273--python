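"""Circular signed gene orders and their comparison.

A gene order is the sequence of gene labels around the (circular) genome,
each signed by coding strand: positive = heavy (H) strand, negative = light
(L) strand, written ``-ND6``. Orders compare equal up to rotation. The
canonical vertebrate arrangement (trnF first, single control region last)
is the fixed reference against which rearrangements are called:
translocated blocks, inverted (sign-flipped, reversed) blocks, duplicated
labels (e.g. a second control region), and losses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ComparisonError, RegionLookupError, ValidationError
from .features import MitogenomeAnnotation

#: The typical vertebrate mitochondrial gene order, 39 tokens, anchored at
#: trnF; signs mark L-strand elements. ND6 with its bound trnE sits between
#: ND5 and Cytb, and the single control region closes the circle.
CANONICAL_TOKENS: tuple[str, ...] = (
    "F", "12S", "V", "16S", "L1", "ND1", "I", "-Q", "M", "ND2", "W", "-A",
    "-N", "OL", "-C", "-Y", "COI", "-S1", "D", "COII", "K", "ATP8", "ATP6",
    "COIII", "G", "ND3", "R", "ND4L", "ND4", "H", "S2", "L2", "ND5", "-ND6",
    "-E", "Cytb", "T", "-P", "CR",
)

KNOWN_LABELS = frozenset(t.lstrip("-") for t in CANONICAL_TOKENS)


def token_sign(token: str) -> int:
    return -1 if token.startswith("-") else 1

def token_label(token: str) -> str:
    return token[1:] if token.startswith("-") else token


def base_label(label: str) -> str:
    """Strip the numeric disambiguation suffix of duplicated labels.

    ``CR1`` and ``CR2`` share base ``CR``. Labels that are themselves
    canonical gene names (ND6, ATP8, ...) are never stripped, and a suffix
    is only stripped when the remaining stem is a canonical label — user-
    defined labels such as ``X12`` stay intact.
    """
    if label in KNOWN_LABELS:
        return label
    m = re.match(r"^(.*?)(\d+)$", label)
    if m and m.group(1) in KNOWN_LABELS:
        return m.group(1)
    return label


def base_token(token: str) -> str:
    lbl = base_label(token_label(token))
    return lbl if token_sign(token) > 0 else f"-{lbl}"


@dataclass(frozen=True)
class GeneOrder:
    """An ordered tuple of signed gene tokens, circular by default."""

    tokens: tuple[str, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValidationError("empty gene order")

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return ",".join(self.tokens)

    @classmethod
    def from_string(cls, text: str, circular: bool = True) -> "GeneOrder":
        return cls(tuple(t.strip() for t in text.split(",") if t.strip()), circular)

    # -- rotation algebra ------------------------------------------------
    def rotate(self, k: int) -> "GeneOrder":
        if not self.circular:
            raise ValidationError("cannot rotate a linear order")
        n = len(self.tokens)
        k %= n
        return GeneOrder(self.tokens[k:] + self.tokens[:k], self.circular)

    def anchored(self, anchor: str = "F") -> "GeneOrder":
        """Rotate so the (unique) token with label ``anchor`` comes first."""
        if not self.circular:
            return self
        hits = [i for i, t in enumerate(self.tokens) if token_label(t) == anchor]
        if len(hits) != 1:
            raise RegionLookupError(f"anchor {anchor!r} not unique in order")
        return self.rotate(hits[0])

    def base_tokens(self) -> tuple[str, ...]:
        return tuple(base_token(t) for t in self.tokens)

    def canonical_form(self, base: bool = False) -> tuple[str, ...]:
        toks = self.base_tokens() if base else self.tokens
        if not self.circular:
            return toks
        n = len(toks)
        return min(tuple(toks[k:] + toks[:k]) for k in range(n))

    def equals(self, other: "GeneOrder", base: bool = True) -> bool:
        """Rotation-invariant equality; ``base=True`` ignores duplicate suffixes."""
        if len(self) != len(other):
            return False
        if self.circular and other.circular:
            return self.canonical_form(base) == other.canonical_form(base)
        a = self.base_tokens() if base else self.tokens
        b = other.base_tokens() if base else other.tokens
        return a == b


def canonical_vertebrate_order() -> GeneOrder:
    """The fixed 39-token typical vertebrate mitochondrial gene order."""
    return GeneOrder(CANONICAL_TOKENS)


def extract_order(a: MitogenomeAnnotation) -> GeneOrder:
    """Signed gene order of an annotation, features taken in ascending start order.

    Feature names map to order tokens by dropping a ``trn`` prefix
    (``trnF`` -> ``F``); other names are used verbatim (``ND6``, ``CR1``).
    """
    tokens = []
    for f in a.features:
        label = f.name[3:] if f.name.startswith("trn") else f.name
        tokens.append(label if f.strand == "H" else f"-{label}")
    return GeneOrder(tuple(tokens), circular=a.circular)


#: Observed M. cinereus-style rearranged order: ND6+trnE moved between trnT
#: and trnP with the duplicated control region upstream of ND6.
REARRANGED_EEL_TOKENS: tuple[str, ...] = CANONICAL_TOKENS[:33] + (
    "Cytb", "T", "CR1", "-ND6", "-E", "-P", "CR2",
)


@dataclass(frozen=True)
class MovedBlock:
    labels: tuple[str, ...]          # signed tokens, in observed order
    old_context: tuple[str | None, str | None]
    new_context: tuple[str | None, str | None]


@dataclass(frozen=True)
class RearrangementCall:
    """Outcome of comparing an observed order against a reference."""

    kinds: tuple[str, ...]
    moved_blocks: tuple[MovedBlock, ...] = ()
    inverted_blocks: tuple[tuple[str, ...], ...] = ()
    duplicated: tuple[str, ...] = ()
    lost: tuple[str, ...] = ()
    extra_copies: tuple[str, ...] = ()   # obs token names treated as the new copies
    ambiguous_duplicates: tuple[str, ...] = ()

    @property
    def identical(self) -> bool:
        return self.kinds == ("identical",)


def _counts(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return out


def _neighbors(tokens: tuple[str, ...], i: int, circular: bool = True):
    n = len(tokens)
    prev = tokens[(i - 1) % n] if (circular or i > 0) else None
    nxt = tokens[(i + 1) % n] if (circular or i < n - 1) else None
    return prev, nxt


def _best_alignment_rotation(obs: tuple[str, ...], ref: tuple[str, ...]) -> int:
    """Rotation offset of obs maximizing the common prefix with ref.

    Ties broken by the smallest offset, which keeps the choice independent
    of label spelling.
    """
    best_k, best_len = 0, -1
    n = len(obs)
    for k in range(n):
        rot = obs[k:] + obs[:k]
        m = 0
        while m < min(len(rot), len(ref)) and rot[m] == ref[m]:
            m += 1
        if m > best_len:
            best_k, best_len = k, m
    return best_k


def compare_orders(obs: GeneOrder, ref: GeneOrder) -> RearrangementCall:
    """Classify how ``obs`` differs from ``ref`` on the circle.

    Duplicated labels in ``obs`` are matched to their reference copy by
    neighbourhood similarity and the surplus copies set aside; the
    remaining sequences are aligned under the rotation anchored at trnF
    (falling back to the best common-prefix rotation) and a
    duplication-guided longest-common-subsequence picks the minimal set of
    moved tokens. Sign-flipped reversed runs are reported as inversions.
    """
    obs_base = [base_token(t) for t in obs.tokens]
    ref_base = [base_token(t) for t in ref.tokens]
    obs_lbl = [token_label(t) for t in obs_base]
    ref_lbl = [token_label(t) for t in ref_base]
    if not set(obs_lbl) & set(ref_lbl):
        raise ComparisonError("orders share no gene labels")

    if obs.equals(ref, base=True):
        return RearrangementCall(kinds=("identical",))

    oc, rc = _counts(obs_lbl), _counts(ref_lbl)
    duplicated = tuple(sorted(l for l in oc if oc[l] > rc.get(l, 0)))
    lost = tuple(sorted(l for l in rc if rc[l] > oc.get(l, 0)))

    # --- set aside surplus duplicate copies, matching by context ---------
    extra_idx: set[int] = set()
    ambiguous: list[str] = []
    for lbl in duplicated:
        obs_pos = [i for i, l in enumerate(obs_lbl) if l == lbl]
        ref_pos = [i for i, l in enumerate(ref_lbl) if l == lbl]
        n_keep = len(ref_pos)
        if n_keep == 0:
            extra_idx.update(obs_pos)
            continue
        ref_ctx = {
            (token_label(p) if p else None, token_label(q) if q else None)
            for rp in ref_pos
            for p, q in [_neighbors(tuple(ref_base), rp, ref.circular)]
        }
        scored = []
        for op in obs_pos:
            p, q = _neighbors(tuple(obs_base), op, obs.circular)
            ctx = (token_label(p) if p else None, token_label(q) if q else None)
            score = max(
                (ctx[0] == rctx[0]) + (ctx[1] == rctx[1]) for rctx in ref_ctx
            )
            scored.append((score, op))
        scored.sort(key=lambda s: (-s[0], s[1]))
        if len(scored) > n_keep and scored[n_keep - 1][0] == scored[n_keep][0]:
            ambiguous.append(lbl)
        extra_idx.update(op for _, op in scored[n_keep:])

    obs_core = [t for i, t in enumerate(obs_base) if i not in extra_idx]
    extra_names = tuple(obs.tokens[i] for i in sorted(extra_idx))
    ref_core = [t for i, t in enumerate(ref_base) if ref_lbl[i] not in lost]

    core_counts = _counts(token_label(t) for t in obs_core)
    if any(v > 1 for v in core_counts.values()):
        return RearrangementCall(
            kinds=("complex",), duplicated=duplicated, lost=lost,
            extra_copies=extra_names, ambiguous_duplicates=tuple(ambiguous),
        )

    # --- fix rotations ---------------------------------------------------
    def _rotated(tokens: list[str], circular: bool, other: list[str]) -> list[str]:
        if not circular:
            return tokens
        anchors = [i for i, t in enumerate(tokens) if token_label(t) == "F"]
        if len(anchors) == 1 and any(token_label(t) == "F" for t in other):
            k = anchors[0]
        else:
            k = _best_alignment_rotation(tuple(tokens), tuple(other))
        return tokens[k:] + tokens[:k]

    ref_al = _rotated(ref_core, ref.circular, obs_core)
    obs_al = _rotated(obs_core, obs.circular, ref_al)

    ref_index = {token_label(t): i for i, t in enumerate(ref_al)}
    ref_sign = {token_label(t): token_sign(t) for t in ref_al}

    # --- inversions: maximal sign-flipped runs that are reversed in ref --
    flipped = [
        token_sign(t) != ref_sign.get(token_label(t), token_sign(t))
        for t in obs_al
    ]
    inverted_blocks: list[tuple[str, ...]] = []
    obs_fixed = list(obs_al)
    i = 0
    while i < len(obs_al):
        if not flipped[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(obs_al) and flipped[j + 1]:
            j += 1
        run = obs_al[i : j + 1]
        pos = [ref_index[token_label(t)] for t in run]
        # a reversed block reads as consecutive descending reference positions
        if pos == list(range(pos[0], pos[0] - len(pos), -1)):
            inverted_blocks.append(tuple(run))
            restored = [
                ref_al[ref_index[token_label(t)]] for t in reversed(run)
            ]
            obs_fixed[i : j + 1] = restored
        i = j + 1

    # --- weighted LCS for moved tokens -----------------------------------
    # Maximizing the plain LCS minimizes the number of moved tokens. When
    # two interpretations are equally parsimonious (moving block X == moving
    # the complementary block Y), a tiny weight increasing with reference
    # index makes the LCS keep downstream tokens, i.e. report the upstream
    # reference block as the moved one. The weight is a power of two so the
    # DP sums stay exact and the backtrack is deterministic.
    A, B = ref_al, obs_fixed
    la, lb = len(A), len(B)
    DELTA = 2.0 ** -20
    dp = [[0.0] * (lb + 1) for _ in range(la + 1)]
    for ia in range(1, la + 1):
        for jb in range(1, lb + 1):
            best = max(dp[ia - 1][jb], dp[ia][jb - 1])
            if A[ia - 1] == B[jb - 1]:
                best = max(best, dp[ia - 1][jb - 1] + 1.0 + DELTA * (ia - 1))
            dp[ia][jb] = best
    matched_b: set[int] = set()
    ia, jb = la, lb
    while ia > 0 and jb > 0:
        if (
            A[ia - 1] == B[jb - 1]
            and dp[ia][jb] == dp[ia - 1][jb - 1] + 1.0 + DELTA * (ia - 1)
        ):
            matched_b.add(jb - 1)
            ia -= 1
            jb -= 1
        elif dp[ia - 1][jb] >= dp[ia][jb - 1]:
            ia -= 1
        else:
            jb -= 1

    moved_blocks: list[MovedBlock] = []
    j = 0
    while j < lb:
        if j in matched_b:
            j += 1
            continue
        k = j
        while k + 1 < lb and (k + 1) not in matched_b:
            k += 1
        block = tuple(obs_al[j : k + 1])  # report with observed signs
        pos = sorted(ref_index[token_label(t)] for t in block)
        old_prev = A[pos[0] - 1] if pos[0] > 0 else (A[-1] if ref.circular else None)
        old_next = A[(pos[-1] + 1) % la] if (pos[-1] + 1 < la or ref.circular) else None
        new_prev = B[j - 1] if j > 0 else (B[-1] if obs.circular else None)
        new_next = B[(k + 1) % lb] if (k + 1 < lb or obs.circular) else None
        moved_blocks.append(
            MovedBlock(
                labels=block,
                old_context=(old_prev, old_next),
                new_context=(new_prev, new_next),
            )
        )
        j = k + 1

    # --- classification ---------------------------------------------------
    kinds: set[str] = set()
    if duplicated:
        kinds.add("duplication")
    if inverted_blocks:
        kinds.add("inversion")
    for mb in moved_blocks:
        pos = sorted(ref_index[token_label(t)] for t in mb.labels)
        new_start = next(
            j for j in range(lb) if obs_al[j : j + len(mb.labels)] == list(mb.labels)
        )
        displacement = abs(new_start - pos[0])
        kinds.add("shuffling" if displacement <= 1 else "translocation")
    if lost or len(moved_blocks) > 1 or (inverted_blocks and moved_blocks):
        kinds.add("complex")
    if not kinds:
        kinds.add("complex")  # differs but nothing classified cleanly

    return RearrangementCall(
        kinds=tuple(sorted(kinds)),
        moved_blocks=tuple(moved_blocks),
        inverted_blocks=tuple(inverted_blocks),
        duplicated=duplicated,
        lost=lost,
        extra_copies=extra_names,
        ambiguous_duplicates=tuple(ambiguous),
    )


# ---------------------------------------------------------------------------
# Character mapping on trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyReport:
    """Whether each character state forms a clade on a rooted tree."""

    state_monophyletic: dict[str, bool]
    state_tips: dict[str, tuple[str, ...]]
    smallest_clade_with_rearranged: tuple[str, ...]


def map_character_on_tree(
    tree_newick: str,
    states: dict[str, str],
    rearranged_state: str = "rearranged",
) -> MonophylyReport:
    """Map a binary rearrangement character onto a rooted newick tree.

    ``states`` assigns every tip a state label (e.g. ``"rearranged"`` /
    ``"canonical"``). For each state the report says whether its tips form
    a clade, and gives the leaf set of the smallest clade containing all
    tips in ``rearranged_state``.
    """
    import dendropy

    tree = dendropy.Tree.get(
        data=tree_newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    unknown = set(states) - set(tips)
    if unknown:
        raise RegionLookupError(f"tips not in tree: {sorted(unknown)}")
    missing = set(tips) - set(states)
    if missing:
        raise RegionLookupError(f"tips without a state: {sorted(missing)}")

    def clade_leaves(labels: list[str]) -> tuple[str, ...]:
        taxa = [tips[l].taxon for l in labels]
        if len(taxa) == 1:
            return (labels[0],)
        mrca = tree.mrca(taxa=taxa)
        return tuple(leaf.taxon.label for leaf in mrca.leaf_iter())

    state_mono: dict[str, bool] = {}
    state_tips: dict[str, tuple[str, ...]] = {}
    for state in sorted(set(states.values())):
        labels = sorted(l for l, s in states.items() if s == state)
        state_tips[state] = tuple(labels)
        state_mono[state] = set(clade_leaves(labels)) == set(labels)

    rearranged_tips = [l for l, s in states.items() if s == rearranged_state]
    smallest = clade_leaves(sorted(rearranged_tips)) if rearranged_tips else ()
    return MonophylyReport(
        state_monophyletic=state_mono,
        state_tips=state_tips,
        smallest_clade_with_rearranged=tuple(sorted(smallest)),
    )
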