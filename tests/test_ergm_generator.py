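"""Fixed-coefficient ERGM sampler: models, acceptance, tuning, conservation."""

import numpy as np
import pytest

from triadnet import (
    ErgmModel,
    Network,
    SamplerConfig,
    acceptance_probability,
    build_ideal,
    default_spec,
    hierarchical_fix_model,
    sample,
    triad_model,
    tune_edges,
)
from triadnet.ergm_generator import EDGES
from triadnet.triad_profiles import THREE_PATHS


class TestModels:
    def test_triad_model_signs(self):
        spec = default_spec("cohesive")
        model = triad_model(spec, "all")
        theta = dict(zip(model.statistics, model.theta))
        assert theta["300"] == 2.0 and theta["102"] == 2.0 and theta["003"] == 2.0
        assert theta["012"] == -2.0 and theta["210"] == -2.0
        assert len(model.statistics) == 16

    def test_with_stat_replaces_and_appends(self):
        m = ErgmModel(("003",), np.array([2.0]))
        m2 = m.with_stat(EDGES, 1.5).with_stat("003", -1.0)
        assert m2.statistics == ("003", EDGES)
        assert m2.theta.tolist() == [-1.0, 1.5]

    def test_hierarchical_fix_model_contents(self):
        model = hierarchical_fix_model()
        theta = dict(zip(model.statistics, model.theta))
        assert theta[THREE_PATHS] == -2.0
        assert theta["021C"] == 4.0
        assert theta["021U"] == 2.0 and theta["021D"] == 2.0 and theta["003"] == 2.0
        # boost=2 reduces the chain coefficient to the common allowed value
        m2 = hierarchical_fix_model(boost=2.0)
        assert dict(zip(m2.statistics, m2.theta))["021C"] == 2.0
        # the alternative orientation flag changes only that coefficient
        m3 = hierarchical_fix_model(boost_label="021D")
        t3 = dict(zip(m3.statistics, m3.theta))
        assert t3["021D"] == 4.0 and t3[THREE_PATHS] == -2.0


class TestAcceptanceProbability:
    def test_no_change_is_certain(self):
        model = ErgmModel(("003",), np.array([2.0]))
        net = Network(4, [(0, 1)])
        assert acceptance_probability(model, net, net) == 1.0

    def test_unit_forbidden_increase_is_exp_minus_two(self):
        """One extra forbidden triad at theta=-2 -> exp(-2) = 0.1353."""
        model = ErgmModel(("012",), np.array([-2.0]))
        current = Network(3)
        proposal = Network(3, [(0, 1)])
        p = acceptance_probability(model, current, proposal)
        assert p == pytest.approx(np.exp(-2), abs=1e-12)

    def test_antisymmetry_of_log_ratio(self):
        """Swapping current and proposal inverts the exponent's sign."""
        model = ErgmModel(("012", "003"), np.array([-2.0, 1.0]))
        a, b = Network(4, [(0, 1)]), Network(4, [(0, 1), (2, 3)])
        r = float(np.exp(model.theta @ (model.g(b) - model.g(a))))
        assert acceptance_probability(model, a, b) == pytest.approx(min(1.0, r))
        assert acceptance_probability(model, b, a) == pytest.approx(min(1.0, 1 / r))


class TestSample:
    def test_fixed_density_conserves_arcs(self):
        spec = default_spec("cohesive")
        model = triad_model(spec, "all")
        for seed in (0, 1, 2):
            net = sample(model, SamplerConfig("fixed_density", 2000, seed=seed),
                         spec=spec)
            assert net.m == 168

    def test_seeded_reproducibility(self):
        spec = default_spec("cohesive")
        model = triad_model(spec, "allowed")
        cfg = SamplerConfig("fixed_density", 1000, seed=11)
        assert sample(model, cfg, spec=spec) == sample(model, cfg, spec=spec)

    def test_zero_theta_edges_free_mode_means_half_density(self):
        """With only an edges term at theta=0 the stationary law is uniform
        over all digraphs, i.e. Bernoulli(1/2) arcs."""
        model = ErgmModel((EDGES,), np.array([0.0]))
        rng = np.random.default_rng(0)
        n = 12
        dens = []
        for _ in range(40):
            init = Network.from_adjacency(
                (rng.random((n, n)) < 0.5).astype(np.uint8) * ~np.eye(n, dtype=bool))
            net = sample(model, SamplerConfig("free_density", 2000,
                                              seed=int(rng.integers(2**31))),
                         initial=init)
            dens.append(net.density)
        se = np.std(dens) / np.sqrt(len(dens))
        assert abs(np.mean(dens) - 0.5) < 3 * se + 0.02

    def test_zero_theta_fixed_mode_matches_uniform_census(self, rng):
        """All-zero coefficients in fixed mode sample uniformly over m-arc
        digraphs; the mean census must match direct uniform draws."""
        from triadnet import randomize, triad_census

        spec = default_spec("cohesive")
        model = ErgmModel(tuple("003 102 300".split()), np.zeros(3))
        ideal = build_ideal(spec)
        reps = 60
        chain_counts = np.array([
            triad_census(sample(model, SamplerConfig(
                "fixed_density", 2000, seed=int(rng.integers(2**31))),
                spec=spec)).as_array()
            for _ in range(reps)])
        unif_counts = np.array([
            triad_census(randomize(ideal, rng)).as_array() for _ in range(reps)])
        for idx in (0, 2, 15):  # 003, 102, 300
            diff = chain_counts[:, idx].mean() - unif_counts[:, idx].mean()
            se = np.sqrt(chain_counts[:, idx].var() / reps
                         + unif_counts[:, idx].var() / reps)
            assert abs(diff) < 4 * se + 1e-9

    def test_degenerate_fixed_start_rejected(self):
        model = ErgmModel((EDGES,), np.array([0.0]))
        with pytest.raises(ValueError):
            sample(model, SamplerConfig("fixed_density", 10, seed=0),
                   initial=Network(5))


class TestTuneEdges:
    def test_null_model_targets_half_density_at_theta_zero(self):
        """For a pure edges model the stationary density is the logistic of
        theta, so matching a 0.5-density ideal needs theta near 0."""
        spec = default_spec("cohesive", (4, 4, 4))
        # ideal cohesive on 12 units has density 36/132; use a model with no
        # other statistics so the logistic closed form applies
        model = ErgmModel(("003",), np.array([0.0]))
        theta, dens = tune_edges(model, spec, window=0.05, reps=8,
                                 iterations=3000, seed=0)
        ideal_density = build_ideal(spec).density
        assert abs(dens - ideal_density) <= 0.05
        expect = np.log(ideal_density / (1 - ideal_density))
        assert abs(theta - expect) < 0.75

    def test_postcondition_on_fresh_networks(self):
        spec = default_spec("hierarchical_null_diag")
        model = triad_model(spec, "selected")
        theta, _ = tune_edges(model, spec, reps=6, iterations=4000, seed=3)
        m = model.with_stat(EDGES, theta)
        rng = np.random.default_rng(4)
        dens = [sample(m, SamplerConfig("free_density", 4000,
                                        seed=int(rng.integers(2**31))),
                       spec=spec).density for _ in range(6)]
        assert abs(np.mean(dens) - build_ideal(spec).density) <= 0.12

    def test_unreachable_window_raises(self):
        spec = default_spec("cohesive")
        model = ErgmModel(("003",), np.array([0.0]))
        with pytest.raises(RuntimeError):
            tune_edges(model, spec, window=1e-6, reps=2, iterations=200,
                       seed=0, max_steps=4)


def test_hierarchical_fix_suppresses_mutuals_and_three_paths():
    """The augmented model keeps reciprocity out and drives the three-arc
    trail count to a small fraction of the unfixed model's."""
    from triadnet import count_three_paths

    spec = default_spec("hierarchical_null_diag")
    rng = np.random.default_rng(5)
    fix = hierarchical_fix_model(edges_theta=35.0)
    base = triad_model(spec, "selected", edges_theta=5.0)
    tp_fix, tp_base, mutuals = [], [], []
    for _ in range(6):
        net_f = sample(fix, SamplerConfig("free_density", 10_000,
                                          seed=int(rng.integers(2**31))), spec=spec)
        net_b = sample(base, SamplerConfig("free_density", 10_000,
                                           seed=int(rng.integers(2**31))), spec=spec)
        tp_fix.append(count_three_paths(net_f))
        tp_base.append(count_three_paths(net_b))
        mutuals.append(int((net_f.A * net_f.A.T).sum()) // 2)
    assert sum(mutuals) == 0
    assert np.median(tp_fix) <= 0.05 * max(np.median(tp_base), 1)
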