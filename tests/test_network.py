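import numpy as np
import pytest

from pfcsim.config import default_config
from pfcsim.network import (
    ConnectivitySpec,
    _adjust_reciprocity,
    _common_neighbor_pass,
    build_network,
    build_population,
    conductance_calibration,
    lsps_rescale,
    sample_synapse,
)


class TestPopulation:
    def test_resolved_counts_at_1000(self, cfg):
        layout = build_population(1000, cfg)
        assert layout.counts[("L23", "PC")] == 470
        assert layout.counts[("L5", "PC")] == 380
        assert layout.counts[("L23", "IN-F")] == 21

    @pytest.mark.parametrize("n", [100, 517, 1000, 2431])
    def test_counts_conserve_total(self, cfg, n):
        layout = build_population(n, cfg)
        assert sum(layout.counts.values()) == n

    def test_cross_column_basket_cells_use_pyramidal_parameters(self, cfg):
        layout = build_population(1000, cfg)
        assert layout.model[("L23", "IN-CC")] == "PC-L23"
        assert layout.model[("L5", "IN-CC")] == "PC-L5"
        assert not layout.excitatory[layout.ids("L23", "IN-CC")].any()

    def test_minimum_size_enforced(self, cfg):
        with pytest.raises(ValueError):
            build_population(50, cfg)


class TestWiring:
    def test_realized_connection_probability(self, cfg):
        g = build_network(1000, seed=2, cfg=cfg)
        layout = g.layout
        pre = layout.ids("L23", "PC")
        post = layout.ids("L23", "PC")
        sel = np.isin(g.pre, pre) & np.isin(g.post, post) & (g.g_ampa > 0)
        n = sel.sum()
        n_possible = len(pre) * (len(post) - 1)
        p = 0.139
        sigma = np.sqrt(n_possible * p * (1 - p))
        assert abs(n - n_possible * p) < 3 * sigma

    def test_reciprocity_of_pc_pairs(self, cfg):
        g = build_network(1000, seed=2, cfg=cfg)
        ids = g.layout.ids("L23", "PC")
        sel = np.isin(g.pre, ids) & np.isin(g.post, ids)
        pairs = set(zip(g.pre[sel], g.post[sel]))
        seen, bi, uni = set(), 0, 0
        for i, j in pairs:
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            if (j, i) in pairs:
                bi += 1
            else:
                uni += 1
        frac = bi / (bi + uni)
        assert abs(frac - 0.47) < 0.03

    def test_reciprocity_adjustment_conserves_edges(self, rng):
        adj = rng.random((200, 200)) < 0.12
        np.fill_diagonal(adj, False)
        out = _adjust_reciprocity(adj, 0.47, np.random.default_rng(0))
        assert out.sum() == adj.sum()
        np.fill_diagonal(out, False)

    def test_common_neighbor_rule_boosts_degree_variance(self):
        rng = np.random.default_rng(5)
        p = 0.12
        base = rng.random((400, 400)) < p
        np.fill_diagonal(base, False)
        var_cn, var_ctrl, mean_cn, mean_ctrl = [], [], [], []
        for k in range(5):
            r = np.random.default_rng(100 + k)
            boosted = _common_neighbor_pass(base, p, beta=1.0, rng=r)
            ctrl = r.random((400, 400)) < p
            np.fill_diagonal(ctrl, False)
            var_cn.append(boosted.sum(1).var())
            var_ctrl.append(ctrl.sum(1).var())
            mean_cn.append(boosted.sum(1).mean())
            mean_ctrl.append(ctrl.sum(1).mean())
        # equal mean degree, strictly larger variance: the rule's signature
        assert np.mean(mean_cn) == pytest.approx(np.mean(mean_ctrl), rel=0.05)
        assert np.mean(var_cn) > 1.1 * np.mean(var_ctrl)

    def test_zero_probability_pair_has_no_edges(self, cfg):
        # no IN L2/3 -> IN L5 row exists: cross-layer IN-IN must be absent
        g = build_network(1000, seed=2, cfg=cfg)
        pre = g.layout.ids("L23", "IN-L")
        post = g.layout.ids("L5", "IN-L")
        assert not (np.isin(g.pre, pre) & np.isin(g.post, post)).any()

    def test_interneuron_wiring_uses_lumped_rows(self, cfg):
        spec = ConnectivitySpec.from_config(cfg)
        row = spec.lookup(("L23", "IN-F"), ("L23", "IN-CL"))
        assert row["p_con"] == 0.25
        row5 = spec.lookup(("L5", "IN-CC"), ("L5", "IN-F"))
        assert row5["p_con"] == 0.60

    def test_in_cc_inherits_basket_rows(self, cfg):
        spec = ConnectivitySpec.from_config(cfg)
        assert spec.lookup(("L23", "IN-CC"), ("L23", "PC"))["p_con"] == 0.466
        assert spec.lookup(("L23", "PC"), ("L23", "IN-CC"))["p_con"] == 0.325


class TestSynapseSampling:
    def test_lognormal_moments_in_table_units(self):
        cfg = default_config()
        cfg["synapses"]["g_unit"] = "nS"  # read the table values verbatim
        spec = ConnectivitySpec.from_config(cfg)
        rng = np.random.default_rng(9)
        draws = np.array([
            sample_synapse(("L23", "PC"), ("L23", "PC"), 0, spec, cfg,
                           rng).spec.g_max
            for _ in range(10_000)])
        sem = 0.49 / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.84) < 3 * sem
        assert abs(draws.std() - 0.49) / 0.49 < 0.10
        assert (draws > 0).all()

    def test_cross_column_attenuation_and_delay_scaling(self, cfg, rng):
        spec = ConnectivitySpec.from_config(cfg)
        g0 = [sample_synapse(("L23", "PC"), ("L23", "PC"), 0, spec, cfg,
                             np.random.default_rng(k)) for k in range(300)]
        g1 = [sample_synapse(("L23", "PC"), ("L23", "PC"), 1, spec, cfg,
                             np.random.default_rng(k)) for k in range(300)]
        m0 = np.mean([s.spec.g_max for s in g0])
        m1 = np.mean([s.spec.g_max for s in g1])
        assert m1 / m0 == pytest.approx(np.exp(-300.0 / 114.0), rel=1e-6)
        d0 = np.mean([s.spec.tau_D for s in g0])
        d1 = np.mean([s.spec.tau_D for s in g1])
        assert d1 / d0 == pytest.approx(2.0, rel=1e-6)

    def test_nmda_companion_tracks_ampa(self, cfg, rng):
        spec = ConnectivitySpec.from_config(cfg)
        s = sample_synapse(("L23", "PC"), ("L5", "PC"), 0, spec, cfg, rng)
        assert s.nmda is not None
        assert s.nmda.g_max == pytest.approx(1.09 * s.spec.g_max)
        assert s.nmda.tau_D == s.spec.tau_D
        i = sample_synapse(("L23", "IN-L"), ("L23", "PC"), 0, spec, cfg, rng)
        assert i.nmda is None and i.spec.receptor == "GABA_A"

    def test_missing_pair_raises(self, cfg, rng):
        spec = ConnectivitySpec.from_config(cfg)
        with pytest.raises(KeyError):
            sample_synapse(("L23", "IN-L"), ("L5", "IN-L"), 0, spec, cfg, rng)

    def test_psp_calibration_positive_and_ordered(self, cfg):
        calib = conductance_calibration(cfg)
        for key, val in calib.items():
            assert val > 0
        # a large slow cell integrates more charge per nS than a small fast one
        assert calib[("AMPA", "PC-L5")] < calib[("AMPA", "FS")]


class TestGraph:
    def test_no_self_connections(self, small_graph):
        assert (small_graph.pre != small_graph.post).all()

    def test_gaussian_weight_control_matches_moments(self, cfg):
        g_ln = build_network(600, seed=3, cfg=cfg, weight_dist="lognormal")
        g_n = build_network(600, seed=3, cfg=cfg, weight_dist="normal")
        # compare moments where truncation at zero is a small correction
        # (excitatory rows have CV < 1; high-CV inhibitory rows are
        # necessarily distorted by any non-negativity rule)
        a, b = g_ln.g_ampa[g_ln.g_ampa > 0], g_n.g_ampa[g_n.g_ampa > 0]
        assert a.mean() == pytest.approx(b.mean(), rel=0.1)
        assert (g_n.g_gaba >= 0).all() and (b >= 0).all()

    def test_inhibition_scaling(self, small_graph):
        g2 = small_graph.scale_inhibition(0.3)
        assert np.allclose(g2.g_gaba, 0.3 * small_graph.g_gaba)
        assert np.shares_memory(g2.g_ampa, small_graph.g_ampa)

    def test_edge_frame_export(self, small_graph):
        df = small_graph.to_edge_frame()
        assert len(df) == small_graph.n_synapses
        assert set(df.columns) >= {"pre_id", "post_id", "receptor", "tau_D"}


class TestLSPS:
    def test_consistent_map_yields_unit_factors(self):
        p = np.array([[0.1, 0.2], [0.3, 0.4]])
        g = np.array([[1.0, 2.0], [0.5, 1.5]])
        I = 3.7 * p * g
        assert np.allclose(lsps_rescale(p, g, I), 1.0)

    def test_linearity_in_target_map(self):
        p = np.full((2, 2), 0.25)
        g = np.ones((2, 2))
        I = np.array([[1.0, 1.0], [1.0, 1.0]])
        base = lsps_rescale(p, g, I)
        I2 = I.copy()
        I2[0, 0] *= 2.0
        out = lsps_rescale(p, g, I2)
        # doubling one entry doubles its factor up to the global renormalization
        assert out[0, 0] / base[0, 0] == pytest.approx(2.0 * I.sum() / I2.sum())

    def test_two_by_two_hand_computation(self):
        p = np.array([[0.1, 0.2], [0.3, 0.4]])
        g = np.array([[2.0, 1.0], [1.0, 2.0]])
        I = np.array([[4.0, 1.0], [2.0, 3.0]])
        pg = p * g
        expected = (I / I.sum()) / (pg / pg.sum())
        assert np.allclose(lsps_rescale(p, g, I), expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            lsps_rescale(np.ones((2, 2)), np.ones((2, 2)), np.ones(3))
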