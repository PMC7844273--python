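"""TDRL event application, scenario inference and model adjudication."""

import numpy as np
import pytest

from mitorearr import (
    GeneOrder,
    TDRLEvent,
    ValidationError,
    adjudicate_models,
    apply_tdrl,
    infer_tdrl,
    intergenic_spacers,
    interleaving_feasible,
)
from mitorearr.order import REARRANGED_EEL_TOKENS, base_label, token_label
from mitorearr.synth import eel_tdrl_event, perturb_order, random_tdrl_event
from mitorearr.tdrl import _single_event_scenarios, segment_splits

from _oracles import brute_segment_feasible, brute_single_event_scenarios


class TestApply:
    def test_eel_event_reproduces_observed_order(self, canonical):
        out = apply_tdrl(canonical, eel_tdrl_event())
        assert out.equals(GeneOrder(REARRANGED_EEL_TOKENS))
        assert out.tokens[-7:] == ("Cytb", "T", "CR1", "-ND6", "-E", "-P", "CR2")

    def test_window_kept_whole_in_one_copy_is_identity(self, canonical):
        e = TDRLEvent(5, 1, frozenset({"ND1"}), frozenset())
        assert apply_tdrl(canonical, e).equals(canonical)

    def test_both_copies_keep_all_gives_full_tandem_duplication(self):
        o = GeneOrder(("a", "CR", "b"))
        e = TDRLEvent(1, 1, frozenset({"CR"}), frozenset({"CR"}))
        assert apply_tdrl(o, e).tokens == ("a", "CR1", "CR2", "b")

    def test_label_kept_nowhere_is_rejected(self, canonical):
        e = TDRLEvent(0, 2, frozenset({"F"}), frozenset())
        with pytest.raises(ValidationError, match="neither"):
            apply_tdrl(canonical, e)

    def test_signs_are_never_flipped(self, canonical):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ev = random_tdrl_event(canonical, rng)
            out = apply_tdrl(canonical, ev)
            signs = {
                base_label(token_label(t)): t.startswith("-") for t in canonical.tokens
            }
            for t in out.tokens:
                assert t.startswith("-") == signs[base_label(token_label(t))]


class TestInfer:
    def test_eel_minimal_scenario_is_the_published_one(self, eel_order, canonical):
        res = infer_tdrl(eel_order, canonical, max_events=1)
        assert res.feasible
        best = res.scenarios[0]
        assert best.n_events == 1
        e = best.events[0]
        assert e.window_length == 6
        assert set(e.window_tokens(res.reference)) == {
            "-ND6", "-E", "Cytb", "T", "-P", "CR",
        }
        assert e.kept_in_copy1 == frozenset({"Cytb", "T", "CR"})
        assert e.kept_in_copy2 == frozenset({"ND6", "E", "P", "CR"})
        assert best.result.equals(eel_order)

    def test_eel_no_shorter_window_works(self, eel_order, canonical):
        # brute force confirms 6 is the minimal single-event window length
        brute = brute_single_event_scenarios(eel_order, canonical, window_cap=8)
        assert brute
        assert min(wl for _, wl, _, _ in brute) == 6

    def test_identical_orders_give_empty_scenario(self, canonical):
        res = infer_tdrl(canonical, canonical.rotate(11))
        assert res.feasible
        assert res.scenarios[0].events == ()

    def test_inversion_is_infeasible(self, canonical):
        inv, _ = perturb_order(canonical, "invert", {"block": ("COI",)})
        res = infer_tdrl(inv, canonical, max_events=2)
        assert not res.feasible
        assert not res.scenarios
        assert "flip" in res.reason or "absent" in res.reason

    def test_rotation_invariance(self, eel_order, canonical):
        base = infer_tdrl(eel_order, canonical)
        rot = infer_tdrl(eel_order.rotate(17), canonical.rotate(5))
        assert len(base) == len(rot)
        e1, e2 = base.scenarios[0].events[0], rot.scenarios[0].events[0]
        assert (e1.kept_in_copy1, e1.kept_in_copy2) == (e2.kept_in_copy1, e2.kept_in_copy2)

    @pytest.mark.parametrize("seed", range(40))
    def test_apply_then_infer_roundtrip(self, canonical, seed):
        rng = np.random.default_rng(seed)
        ev = random_tdrl_event(canonical, rng)
        obs = apply_tdrl(canonical, ev)
        res = infer_tdrl(obs, canonical, max_events=1)
        assert res.feasible
        assert res.scenarios[0].result.equals(obs)

    def test_two_event_recovery_on_small_order(self):
        small = GeneOrder(("a", "b", "c", "d", "e", "f"))
        e1 = TDRLEvent(1, 3, frozenset({"c"}), frozenset({"b", "d"}))
        mid = apply_tdrl(small, e1)
        e2 = TDRLEvent(3, 3, frozenset({"e"}), frozenset({"d", "f"}))
        obs = apply_tdrl(mid, e2)
        assert not infer_tdrl(obs, small, max_events=1, window_cap=4).feasible
        res = infer_tdrl(obs, small, max_events=2, window_cap=4)
        assert res.feasible
        assert res.scenarios[0].n_events == 2
        assert res.scenarios[0].result.equals(obs)

    def test_max_events_is_capped(self, canonical):
        with pytest.raises(ValidationError):
            infer_tdrl(canonical, canonical, max_events=4)


class TestOracleAgreement:
    SMALL = GeneOrder(("a", "-b", "c", "d", "CR", "e", "-f", "g"))

    @pytest.mark.parametrize("seed", range(25))
    def test_single_event_search_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ev = random_tdrl_event(self.SMALL, rng, window_cap=5)
        obs = apply_tdrl(self.SMALL, ev)
        mine = {
            (e.window_start, e.window_length, e.kept_in_copy1, e.kept_in_copy2)
            for e in _single_event_scenarios(self.SMALL, obs, 5, ("CR",))
        }
        brute = brute_single_event_scenarios(obs, self.SMALL, window_cap=5)
        assert mine == brute

    @pytest.mark.parametrize("seed", range(30))
    def test_interleaving_criterion_matches_bipartition_enumeration(self, seed):
        # a window segment is single-event reachable iff some loss
        # bipartition's survivor concatenation equals it; the fast check
        # says: at most one descent of window indices
        rng = np.random.default_rng(1000 + seed)
        wl = int(rng.integers(2, 9))
        window = [f"w{i}" for i in range(wl)]
        # losses never delete: the segment is a permutation of the window
        seg_idx = [int(i) for i in rng.permutation(wl)]
        segment = [window[i] for i in seg_idx]
        assert interleaving_feasible(seg_idx) == brute_segment_feasible(
            window, segment
        )
        # and every reported split really is two increasing runs
        for p in segment_splits(seg_idx):
            assert all(a < b for a, b in zip(seg_idx[:p], seg_idx[1:p]))
            assert all(a < b for a, b in zip(seg_idx[p:], seg_idx[p + 1 :]))


class TestAdjudication:
    def test_eel_inputs_support_tdrl_only(self, eel_order, canonical, eel_annotation):
        sp = intergenic_spacers(eel_annotation)
        v = adjudicate_models(eel_order, canonical, sp)
        assert v.tdrl_plausible
        assert not v.recombination_plausible
        assert not v.tdnl_plausible
        assert not v.drrl_plausible
        # the duplication-remnant evidence: four positive spacers around the
        # rearranged region
        assert "4 positive spacer" in v.reasons["tdrl"]

    def test_identical_orders_no_rearrangement(self, canonical):
        v = adjudicate_models(canonical, canonical, None)
        assert not v.any_plausible
        assert v.note == "no rearrangement"

    def test_inversion_only_recombination(self, canonical):
        inv, _ = perturb_order(canonical, "invert", {"block": ("COI",)})
        v = adjudicate_models(inv, canonical, None)
        assert v.recombination_plausible
        assert not v.tdrl_plausible and not v.tdnl_plausible and not v.drrl_plausible

    def test_translocation_without_duplication_admits_tdnl(self, canonical):
        # the sister species' arrangement: ND6+trnE between trnT and trnP,
        # single control region — polarity-clustered, order preserved
        bagio, _ = perturb_order(
            canonical, "translocate", {"block": ("-ND6", "-E"), "after": "T"}
        )
        v = adjudicate_models(bagio, canonical, None)
        assert v.tdnl_plausible
        assert v.tdrl_plausible  # order-compatible; no spacer report given
        assert not v.drrl_plausible  # only one control region

    def test_drrl_positive_control(self):
        ref = GeneOrder(("F", "A", "-B", "C", "-D", "CR"))
        obs = GeneOrder(("F", "CR1", "A", "C", "-B", "-D", "CR2"))
        v = adjudicate_models(obs, ref, None, max_events=2)
        assert v.drrl_plausible
        assert not v.tdnl_plausible  # the retained CR duplicate rules TDNL out
        assert not v.recombination_plausible
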