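"""Mk likelihood engine: transition probabilities, discrete gamma, pruning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats
from scipy.linalg import expm

from archroot.matrix import BinaryCharacterMatrix
from archroot.mk import (
    MkModel,
    discrete_gamma_rates,
    effective_branch_lengths,
    log_likelihood,
    transition_probs,
)
from archroot.trees import parse_newick
from conftest import random_matrix


def brute_force_log_likelihood(tree, matrix, model):
    """Exhaustive sum over all interior-state assignments (independent oracle)."""
    tree.reindex()
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    rates = discrete_gamma_rates(model.alpha, model.K)
    rho = model.root_freq
    order = {t: i for i, t in enumerate(matrix.taxa)}

    def pattern_likelihood(get_state):
        total = 0.0
        for r in rates:
            for assign in itertools.product([0, 1], repeat=len(internals)):
                amap = dict(zip(internals, assign))
                p = (1 - rho, rho)[amap[tree.root]]
                for nd in nodes:
                    if nd.parent is None:
                        continue
                    P = transition_probs(model.pi1, nd.length, r)
                    ps = amap[nd.parent]
                    if nd.is_leaf:
                        s = get_state(nd.label)
                        p *= 1.0 if s == 2 else P[ps, s]
                    else:
                        p *= P[ps, amap[nd]]
                total += p
        return total / len(rates)

    p_cond = 0.0
    if model.ascertainment != "none":
        p_cond = pattern_likelihood(lambda lb: 0)
        if model.ascertainment == "variable-only":
            p_cond += pattern_likelihood(lambda lb: 1)
    out = 0.0
    for j in range(len(matrix.characters)):
        L = pattern_likelihood(lambda lb: matrix.states[order[lb], j])
        if model.ascertainment != "none":
            L /= 1.0 - p_cond
        out += np.log(L)
    return out


class TestTransitionProbs:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_probs(0.3, 0.0), np.eye(2))

    def test_long_time_reaches_stationarity(self):
        P = transition_probs(0.3, 1e6)
        assert np.allclose(P, [[0.7, 0.3], [0.7, 0.3]], atol=1e-12)

    def test_symmetric_half_substitution(self):
        # pi1=0.5, t=0.5: off-diagonals 0.5(1−e⁻¹)
        P = transition_probs(0.5, 0.5)
        assert P[0, 1] == pytest.approx(0.5 * (1 - np.exp(-1)), abs=1e-12)

    @pytest.mark.parametrize("pi1,t,rate", [(0.3, 0.5, 1.0), (0.8, 2.0, 0.3), (0.5, 0.1, 4.0)])
    def test_matches_matrix_exponential(self, pi1, t, rate):
        pi0 = 1 - pi1
        mu = 1 / (2 * pi0 * pi1)
        Q = mu * np.array([[-pi1, pi1], [pi0, -pi0]])
        assert np.allclose(transition_probs(pi1, t, rate), expm(Q * rate * t), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        pi1=st.floats(0.05, 0.95),
        t1=st.floats(0.0, 3.0),
        t2=st.floats(0.0, 3.0),
    )
    def test_chapman_kolmogorov(self, pi1, t1, t2):
        lhs = transition_probs(pi1, t1) @ transition_probs(pi1, t2)
        assert np.allclose(lhs, transition_probs(pi1, t1 + t2), atol=1e-12)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            transition_probs(1.0, 0.5)


class TestDiscreteGamma:
    def test_single_category_is_unit(self):
        assert discrete_gamma_rates(2.0, 1).tolist() == [1.0]

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0])
    @pytest.mark.parametrize("K", [4, 8, 12])
    def test_mean_one_and_quadrature(self, alpha, K):
        r = discrete_gamma_rates(alpha, K)
        assert abs(r.mean() - 1.0) < 1e-10
        edges = stats.gamma.ppf(np.arange(0, K + 1) / K, a=alpha, scale=1 / alpha)
        for k in range(K):
            val, _ = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1 / alpha),
                edges[k],
                edges[k + 1],
                limit=400,
            )
            assert r[k] == pytest.approx(val * K, abs=1e-8)


class TestLogLikelihood:
    def test_all_unknown_character_contributes_zero(self, quartet_tree):
        m = BinaryCharacterMatrix(list("ABCD"), ["c1"], np.full((4, 1), 2))
        model = MkModel(pi1=0.4, ascertainment="none")
        assert log_likelihood(quartet_tree, m, model) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("asc", ["none", "no-all-absent", "variable-only"])
    def test_matches_exhaustive_enumeration(self, rng, quartet_tree, asc):
        for _ in range(5):
            model = MkModel(
                pi1=rng.uniform(0.1, 0.9),
                rho1=rng.uniform(0.1, 0.9),
                alpha=rng.uniform(0.2, 3.0),
                K=int(rng.choice([1, 4])),
                ascertainment=asc,
            )
            m = random_matrix(rng, list("ABCD"), 6, p_unknown=0.2)
            assert log_likelihood(quartet_tree, m, model) == pytest.approx(
                brute_force_log_likelihood(quartet_tree, m, model), abs=1e-10
            )

    def test_reversible_likelihood_is_rooting_invariant(self, rng):
        t = parse_newick("((A:0.3,B:0.7):0.2,((C:0.5,D:0.9):0.1,E:0.4):0.4);")
        m = random_matrix(rng, list("ABCDE"), 30)
        model = MkModel(pi1=0.3, alpha=0.7, K=4, ascertainment="no-all-absent")
        base = log_likelihood(t, m, model)
        for edge in t.edges():
            assert log_likelihood(t.rerooted(edge, 0.3), m, model) == pytest.approx(base, abs=1e-8)

    def test_directional_likelihood_depends_on_root(self, rng):
        t = parse_newick("((A:0.3,B:0.7):0.2,((C:0.5,D:0.9):0.1,E:0.4):0.4);")
        m = random_matrix(rng, list("ABCDE"), 30)
        model = MkModel(pi1=0.3, rho1=0.9, alpha=0.7, K=4, ascertainment="no-all-absent")
        base = log_likelihood(t, m, model)
        diffs = [abs(log_likelihood(t.rerooted(e, 0.3), m, model) - base) for e in t.edges()]
        assert max(diffs) > 1e-3

    def test_negative_branch_length_rejected(self, rng, quartet_tree):
        m = random_matrix(rng, list("ABCD"), 3)
        bad = quartet_tree.copy()
        bad.root.children[0].length = -0.1
        with pytest.raises(ValueError, match="negative"):
            log_likelihood(bad, m, MkModel())

    def test_taxon_mismatch_rejected(self, rng, quartet_tree):
        m = random_matrix(rng, list("ABCE"), 3)
        with pytest.raises(ValueError, match="match"):
            log_likelihood(quartet_tree, m, MkModel())

    def test_ascertainment_correction_removes_bias(self, rng):
        """MLE of pi1 from data without all-absent characters: corrected
        likelihood recovers the truth, uncorrected is downward-biased."""
        from scipy.optimize import minimize_scalar

        from archroot.simulate import simulate_matrix, simulate_tree

        truth_pi = 0.35
        tree = simulate_tree([("X", 4), ("Y", 4)], seed=11, height=1.5)
        gen = MkModel(pi1=truth_pi, alpha=1.0, K=1, ascertainment="no-all-absent")
        m, _ = simulate_matrix(tree, gen, 4000, seed=12)

        def mle(asc):
            def nll(p):
                return -log_likelihood(tree, m, MkModel(pi1=p, K=1, ascertainment=asc))

            return minimize_scalar(nll, bounds=(0.01, 0.99), method="bounded").x

        corrected, uncorrected = mle("no-all-absent"), mle("none")
        assert abs(corrected - truth_pi) < 0.05
        assert uncorrected > corrected + 0.02  # conditioning inflates apparent presence


class TestEffectiveBranchLengths:
    def test_none_is_identity(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        lens = effective_branch_lengths(t, "none")
        assert sorted(lens.values()) == sorted(nd.length for nd in t.edges())

    def test_zero_variance_igr_equals_strict(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        a = effective_branch_lengths(t, "strict", rate=0.5)
        b = effective_branch_lengths(t, "igr", rate=0.5, igr_variance=0.0)
        assert a == b

    def test_igr_multipliers_have_unit_mean(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        rng = np.random.default_rng(5)
        v = 0.4
        draws = []
        for _ in range(20000):
            lens = effective_branch_lengths(t, "igr", igr_variance=v, rng=rng)
            draws.extend(m / nd.length for nd, m in zip(t.edges(), [lens[n.index] for n in t.edges()]))
        draws = np.asarray(draws)
        se = np.sqrt(v / draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_clock_on_non_ultrametric_tree_rejected(self):
        t = parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            effective_branch_lengths(t, "strict")
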