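import json

import numpy as np
import pytest

from sdtrace import (
    PMMParams,
    SDParams,
    SimConfig,
    build_covariance,
    build_mean,
    displacement_covariance,
    is_ultrametric,
    make_fixture,
    parse_newick,
    read_character_matrix,
    read_locations,
    simulate_frames,
    simulate_locations,
    simulate_sequences,
    simulate_topology,
    validate_inputs,
    write_newick,
)
from sdtrace.trees import MISSING


class TestTopology:
    def test_two_leaves_minimal_shape(self):
        t = simulate_topology(2, 5.0, seed=0)
        assert t.n_leaves == 2
        assert len(t.children[t.root]) == 1
        ok, dev = is_ultrametric(t, 5.0, tol=0.0)
        assert ok and dev < 1e-9

    def test_valid_and_ultrametric(self):
        for seed in range(5):
            t = simulate_topology(17, 216.0, seed=seed)
            t.validate()
            ok, _ = is_ultrametric(t, 216.0, tol=1e-12)
            assert ok

    def test_deterministic_per_seed(self):
        a = simulate_topology(9, 10.0, seed=4)
        b = simulate_topology(9, 10.0, seed=4)
        c = simulate_topology(9, 10.0, seed=5)
        assert write_newick(a) == write_newick(b)
        assert write_newick(a) != write_newick(c)

    def test_rejects_single_leaf(self):
        with pytest.raises(ValueError):
            simulate_topology(1, 5.0)


class TestLocations:
    def test_noise_free_displacement_geometry(self, cherry):
        u = cherry.children[cherry.root][0]
        params = SDParams(sigma=1e-12, r=2.0, theta={u: 0.0})
        loc = simulate_locations(cherry, params, seed=0)
        i = loc.names.index("A")
        j = loc.names.index("B")
        assert loc.x[i] == pytest.approx(2.0, abs=1e-6)
        assert loc.x[j] == pytest.approx(-2.0, abs=1e-6)
        assert loc.y[i] == pytest.approx(0.0, abs=1e-6)

    def test_empirical_moments_match_model(self):
        # mean and covariance of simulated leaf locations vs the MVN forms
        tree = simulate_topology(5, 4.0, seed=3)
        rng = np.random.default_rng(8)
        theta = {u: float(rng.uniform(0, 2 * np.pi))
                 for u in tree.bifurcations()}
        params = SDParams(sigma=1.2, r=1.5, theta=theta, x0=1.0, y0=-2.0)
        R = 4000
        xs = np.empty((R, 5))
        ys = np.empty((R, 5))
        for i in range(R):
            loc = simulate_locations(tree, params, seed=rng)
            xs[i], ys[i] = loc.x, loc.y
        mx = build_mean(tree, params, "x")
        my = build_mean(tree, params, "y")
        cov = build_covariance(tree, params.sigma)
        se_mean = np.sqrt(np.diag(cov) / R)
        assert np.all(np.abs(xs.mean(0) - mx) < 4 * se_mean)
        assert np.all(np.abs(ys.mean(0) - my) < 4 * se_mean)
        emp = np.cov(xs.T)
        se_cov = np.sqrt((np.outer(np.diag(cov), np.diag(cov))
                          + cov ** 2) / R)
        assert np.all(np.abs(emp - cov) < 4 * se_cov)

    def test_missing_angles_drawn_and_reported(self):
        tree = simulate_topology(6, 3.0, seed=1)
        loc, pos, used = simulate_locations(
            tree, SDParams(sigma=1.0, r=1.0), seed=2, return_internal=True)
        assert set(used.theta) == set(tree.bifurcations())
        assert len(pos) == tree.n_nodes


class TestSequences:
    def test_no_rates_gives_all_zero(self, five_leaf):
        sim = SimConfig(n_leaves=5)
        mat = simulate_sequences(
            five_leaf, PMMParams(lam=0.0, nu=0.0, phi=0.0),
            sim.alphabets(), seed=0)
        assert (mat.data == 0).all()

    def test_full_dropout_gives_all_missing(self, five_leaf):
        sim = SimConfig(n_leaves=5)
        mat = simulate_sequences(
            five_leaf, PMMParams(lam=0.2, nu=0.0, phi=1.0),
            sim.alphabets(), seed=0)
        assert (mat.data == MISSING).all()

    def test_leaf_state_frequencies_match_chain(self):
        # single-leaf tree: observed frequencies vs the transition row
        # from state 0 composed with dropout
        from sdtrace import transition_matrix
        from sdtrace.sequence_pmm import SiteAlphabet
        t = parse_newick("(A:2.0)r;")
        params = PMMParams(lam=0.3, nu=0.1, phi=0.1)
        site = SiteAlphabet(n_states=2)
        K = 4000
        mat = simulate_sequences(t, params,
                                 [site] * K, seed=5)
        row = transition_matrix(site, params, 2.0)[0]
        p_obs0 = row[0] * 0.9
        p_obs1 = row[1] * 0.9
        p_missing = row[3] + (row[0] + row[1] + row[2]) * 0.1
        freq0 = (mat.data == 0).mean()
        freq1 = (mat.data == 1).mean()
        freqm = (mat.data == MISSING).mean()
        for freq, p in [(freq0, p_obs0), (freq1, p_obs1),
                        (freqm, p_missing)]:
            assert abs(freq - p) < 4 * np.sqrt(p * (1 - p) / K)

    def test_deterministic_per_seed(self, five_leaf):
        sim = SimConfig(n_leaves=5)
        a = simulate_sequences(five_leaf, sim.pmm_params(),
                               sim.alphabets(), seed=3)
        b = simulate_sequences(five_leaf, sim.pmm_params(),
                               sim.alphabets(), seed=3)
        np.testing.assert_array_equal(a.data, b.data)


class TestFrames:
    def test_symmetric_displacement_at_fine_interval(self):
        # with negligible diffusion the daughters sit exactly opposite
        tree = simulate_topology(4, 8.0, seed=2)
        params = SDParams(sigma=1e-9, r=3.0)
        frames = simulate_frames(tree, params, frame_interval=0.05, seed=0)
        from sdtrace import angles_at_lag
        angles = angles_at_lag(frames, lag=1)
        assert len(angles) > 0
        assert np.all(angles > 179.0)

    def test_final_positions_match_location_simulator_distribution(self):
        # the frame walk sampled at tau_end and the one-shot location
        # simulator draw from the same law
        from scipy.stats import ks_2samp
        tree = simulate_topology(6, 6.0, seed=7)
        params = SDParams(sigma=1.0, r=2.0,
                          theta={u: 0.3 for u in tree.bifurcations()})
        xs_frames, xs_direct = [], []
        for rep in range(300):
            fr = simulate_frames(tree, params, frame_interval=1.5,
                                 seed=rep)
            last = fr[fr.frame == fr.frame.max()]
            xs_frames.extend(last.x.tolist())
            loc = simulate_locations(tree, params, seed=rep + 10_000)
            xs_direct.extend(loc.x.tolist())
        assert ks_2samp(xs_frames, xs_direct).pvalue > 0.01

    def test_lineage_links_present(self):
        tree = simulate_topology(5, 10.0, seed=1)
        frames = simulate_frames(tree, SDParams(sigma=1.0, r=1.0),
                                 frame_interval=1.0, seed=1)
        assert set(frames.columns) == {"frame", "cell", "parent", "x", "y"}
        kids = frames[frames.parent != ""]["parent"].unique()
        assert len(kids) >= 1


class TestMakeFixture:
    def test_default_preset_truth_values(self, tmp_path):
        paths = make_fixture("default", seed=1, out_dir=tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        cfg = truth["config"]
        assert cfg["sigma"] == 1.5 and cfg["r"] == 6.68
        assert cfg["n_sites"] == 10 and cfg["lam"] == 0.006

    def test_sigma_variant_presets(self, tmp_path):
        low = make_fixture("sigma-low", seed=1, out_dir=tmp_path / "lo")
        high = make_fixture("sigma-high", seed=1, out_dir=tmp_path / "hi")
        lo = json.loads(open(low["truth"]).read())
        hi = json.loads(open(high["truth"]).read())
        assert lo["config"]["sigma"] == 0.5
        assert hi["config"]["sigma"] == 3.0

    def test_unknown_preset_lists_options(self, tmp_path):
        with pytest.raises(KeyError, match="sigma-low"):
            make_fixture("nope", seed=0, out_dir=tmp_path)

    def test_fixture_round_trips_clean(self, tmp_path):
        paths = make_fixture("default", seed=2, out_dir=tmp_path,
                             overrides={"n_leaves": 8})
        tree = parse_newick(open(paths["tree"]).read())
        mat = read_character_matrix(paths["matrix"])
        loc = read_locations(paths["locations"])
        _, diag = validate_inputs(tree, mat, loc)
        assert diag.ok()
        ok, _ = is_ultrametric(tree, 216.0, tol=1e-9)
        assert ok

    def test_byte_identical_per_seed(self, tmp_path):
        p1 = make_fixture("default", seed=3, out_dir=tmp_path / "a",
                          overrides={"n_leaves": 6})
        p2 = make_fixture("default", seed=3, out_dir=tmp_path / "b",
                          overrides={"n_leaves": 6})
        for k in ("tree", "matrix", "locations"):
            assert open(p1[k]).read() == open(p2[k]).read()
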