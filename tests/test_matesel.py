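"""Mate selection: feasibility, evaluation arithmetic, frontier, EA optimality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lofmate.matesel import (
    MateSelContext,
    ObjectiveConfig,
    evaluate,
    frontier_endpoints,
    solve_at_degrees,
    validate_matings,
)

from conftest import point_probs


def make_context(
    n_sires=4,
    n_dams=6,
    m_sire=None,
    m_dam=None,
    carriers=(),
    q=(0.1,),
    kinship=None,
):
    sires = [f"S{i}" for i in range(n_sires)]
    dams = [f"D{i}" for i in range(n_dams)]
    ids = sires + dams
    m = pd.Series(0.0, index=ids)
    if m_sire is not None:
        m[sires] = np.asarray(m_sire, dtype=float)
    if m_dam is not None:
        m[dams] = np.asarray(m_dam, dtype=float)
    if kinship is None:
        kinship = pd.DataFrame(np.eye(len(ids)) * 0.5, index=ids, columns=ids)
    L = len(q)
    probs = {
        a: point_probs([1] * L if a in carriers else [0] * L) for a in ids
    }
    return MateSelContext(sires, dams, m, kinship, probs, np.array(q))


class TestValidateMatings:
    def setup_method(self):
        self.ctx = make_context()
        self.cfg = ObjectiveConfig(n_matings=3, max_per_sire=2)

    def test_valid_list_passes(self):
        validate_matings(
            self.ctx, [("S0", "D0"), ("S0", "D1"), ("S1", "D2")], self.cfg
        )

    @pytest.mark.parametrize(
        "matings,msg",
        [
            ([("S0", "D0"), ("S0", "D1")], "expected 3"),
            ([("S0", "D0"), ("S0", "D0"), ("S1", "D1")], "more than once"),
            ([("S0", "D0"), ("S0", "D1"), ("S0", "D2")], "per-sire limit"),
            ([("D0", "D1"), ("S0", "D2"), ("S1", "D3")], "not a candidate sire"),
            ([("S0", "S1"), ("S0", "D2"), ("S1", "D3")], "not a candidate dam"),
        ],
        ids=["wrong-count", "dam-reuse", "sire-cap", "bad-sire", "bad-dam"],
    )
    def test_invalid_lists_raise(self, matings, msg):
        with pytest.raises(ValueError, match=msg):
            validate_matings(self.ctx, matings, self.cfg)


class TestEvaluate:
    def test_mean_index_is_mid_parent_average(self):
        ctx = make_context(m_sire=[100, 60, 0, 0], m_dam=[40, 20, 0, 0, 0, 0])
        cfg = ObjectiveConfig(n_matings=2, max_per_sire=2)
        ev = evaluate(ctx, [("S0", "D0"), ("S1", "D1")], cfg)
        # progeny indexes: (100+40)/2 = 70 and (60+20)/2 = 40 -> mean 55
        assert ev.mean_index == pytest.approx(55.0)

    def test_coancestry_single_unrelated_pair(self):
        ctx = make_context()
        cfg = ObjectiveConfig(n_matings=1, max_per_sire=1)
        ev = evaluate(ctx, [("S0", "D0")], cfg)
        assert ev.coancestry == pytest.approx(0.25)

    def test_penalty_arithmetic(self):
        # one carrier x carrier mating among 100: LethalG = 0.25/100 not
        # possible here, so use 1 mating: LethalG = 0.25 and with w_g = 1 the
        # penalized objective is mean_index - 200 * 0.25
        ctx = make_context(carriers={"S0", "D0"}, m_sire=[100, 0, 0, 0],
                           m_dam=[100, 0, 0, 0, 0, 0])
        cfg = ObjectiveConfig(n_matings=1, max_per_sire=1, w_g=1.0)
        ev = evaluate(ctx, [("S0", "D0")], cfg)
        assert ev.lethal_g == pytest.approx(0.25)
        assert ev.penalized == pytest.approx(100.0 - 200.0 * 0.25)

    def test_penalty_includes_lethal_a(self):
        ctx = make_context(carriers={"S0"}, q=(0.1,))
        cfg = ObjectiveConfig(n_matings=1, max_per_sire=1, w_a=1.0)
        ev = evaluate(ctx, [("S0", "D0")], cfg)
        # carrier x clear progeny transmits w.p. 1/4; LethalA = 0.25 * 0.1
        assert ev.lethal_a == pytest.approx(0.025)
        assert ev.penalized == pytest.approx(0.0 - 200.0 * 0.025)


class TestFrontier:
    def test_truncation_endpoint_uses_best_parents(self):
        ctx = make_context(m_sire=[10, 50, 20, 0], m_dam=[1, 9, 5, 3, 7, 0])
        cfg = ObjectiveConfig(n_matings=2, max_per_sire=2)
        fr = frontier_endpoints(ctx, cfg)
        # best: sire S1 for both matings, dams D1 and D4
        assert fr.index_max == pytest.approx(0.5 * (50 + (9 + 7) / 2))
        assert fr.index_min <= fr.index_max
        assert fr.coancestry_min <= fr.coancestry_max

    def test_min_coancestry_spreads_usage(self):
        # one popular inbred-favoring setup: with equal kinship, spreading
        # sires evenly minimizes x'Kx
        ctx = make_context(n_sires=2, n_dams=4)
        cfg = ObjectiveConfig(n_matings=4, max_per_sire=4)
        fr = frontier_endpoints(ctx, cfg)
        # x'Kx with equal use of 2 sires and 4 dams, unrelated, diag 0.5:
        # sires: 2 * (1/4)^2 * 0.5; dams: 4 * (1/8)^2 * 0.5
        assert fr.coancestry_min == pytest.approx(2 * 0.0625 * 0.5 + 4 * 0.5 / 64)

    def test_zero_and_ninety_degree_targets(self):
        ctx = make_context(m_sire=[10, 50, 20, 0], m_dam=[1, 9, 5, 3, 7, 0])
        cfg0 = ObjectiveConfig(n_matings=2, max_per_sire=2, target_degrees=0.0,
                               pop_size=16, max_generations=200, seed=1)
        matings0, fr0, ev0 = solve_at_degrees(ctx, cfg0)
        assert ev0.mean_index == pytest.approx(fr0.index_max)
        cfg90 = ObjectiveConfig(n_matings=2, max_per_sire=2, target_degrees=90.0)
        matings90, fr90, ev90 = solve_at_degrees(ctx, cfg90)
        assert ev90.coancestry == pytest.approx(fr90.coancestry_min, abs=1e-9)
        assert ev90.mean_index <= ev0.mean_index + 1e-9


class TestEvolutionaryAlgorithm:
    def _exhaustive_best(self, ctx, cfg):
        best = -np.inf
        n_d = len(ctx.dams)
        for dam_pair in itertools.permutations(range(n_d), cfg.n_matings):
            for sire_combo in itertools.product(
                range(len(ctx.sires)), repeat=cfg.n_matings
            ):
                counts = np.bincount(sire_combo, minlength=len(ctx.sires))
                if counts.max() > cfg.max_per_sire:
                    continue
                matings = [
                    (ctx.sires[s], ctx.dams[d])
                    for s, d in zip(sire_combo, dam_pair)
                ]
                ev = evaluate(ctx, matings, cfg)
                best = max(best, ev.penalized)
        return best

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_optimum_on_tiny_instances(self, seed):
        rng = np.random.default_rng(200 + seed)
        ctx = make_context(
            n_sires=2,
            n_dams=4,
            m_sire=rng.uniform(0, 100, 2),
            m_dam=rng.uniform(0, 100, 4),
            carriers={"S0", "D1"},
        )
        cfg = ObjectiveConfig(
            n_matings=3, max_per_sire=2, target_degrees=0.0, w_g=0.05,
            pop_size=24, max_generations=300, seed=seed,
        )
        matings, fr, ev = solve_at_degrees(ctx, cfg)
        validate_matings(ctx, matings, cfg)
        best = self._exhaustive_best(ctx, cfg)
        assert ev.penalized == pytest.approx(best, abs=1e-9)

    def test_deterministic_given_seed(self):
        ctx = make_context(m_sire=[10, 50, 20, 0], m_dam=[1, 9, 5, 3, 7, 0],
                           carriers={"S1", "D1"})
        cfg = ObjectiveConfig(n_matings=4, max_per_sire=2, target_degrees=25.0,
                              w_g=0.1, pop_size=16, max_generations=150, seed=7)
        a = solve_at_degrees(ctx, cfg)
        b = solve_at_degrees(ctx, cfg)
        assert a[0] == b[0]
        assert a[2] == b[2]

    def test_heavier_carrier_penalty_weakly_lowers_lethal_g(self):
        rng = np.random.default_rng(3)
        ctx = make_context(
            n_sires=4, n_dams=8,
            m_sire=rng.uniform(0, 100, 4), m_dam=rng.uniform(0, 100, 8),
            carriers={"S0", "S1", "D0", "D1", "D2"},
        )
        lgs = []
        for w_g in (0.0, 0.1, 100.0):
            cfg = ObjectiveConfig(n_matings=6, max_per_sire=3,
                                  target_degrees=0.0, w_g=w_g,
                                  pop_size=32, max_generations=400, seed=11)
            _, _, ev = solve_at_degrees(ctx, cfg)
            lgs.append(ev.lethal_g)
        assert lgs[1] <= lgs[0] + 1e-9
        assert lgs[2] <= lgs[1] + 1e-9

    def test_avoids_carrier_by_carrier_when_possible(self):
        # with w_g large and enough clear mates, no carrier x carrier matings
        ctx = make_context(
            n_sires=2, n_dams=4, m_sire=[100, 0], m_dam=[100, 0, 0, 0],
            carriers={"S0", "D0"},
        )
        cfg = ObjectiveConfig(n_matings=2, max_per_sire=2, target_degrees=0.0,
                              w_g=100.0, pop_size=24, max_generations=300, seed=2)
        matings, _, ev = solve_at_degrees(ctx, cfg)
        assert ev.lethal_g == 0.0
        assert ("S0", "D0") not in matings
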