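"""Synthetic cohort / connectome generator: configured moments are
recovered, planted signal is local, determinism holds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcintel import synth
from fcintel.connectome import NodeAtlas
from fcintel.synth import (GeneratorConfig, LoadingSpec, exclude_by_motion,
                           generate_cohort, generate_cognitive_measures,
                           generate_connectomes, MEASURE_NAMES)


class TestGenerateCohort:
    def test_component_correlations_hit_targets(self):
        # independent subjects so the iid Monte-Carlo tolerance applies
        cfg = GeneratorConfig(n_subjects=5000, family_icc=0.0)
        _, truth = generate_cohort(cfg, seed=11)
        lat = np.c_[truth.true_g, truth.true_gc, truth.true_gf]
        got = np.corrcoef(lat.T)
        want = cfg.corr_matrix()
        assert np.all(np.abs(got - want) < 0.03)

    def test_family_clustering_preserves_correlations(self, big_cohort):
        # the family random effect must not shift the marginal correlation
        # structure; clustered sampling error is wider than the iid case
        _, truth = big_cohort
        lat = np.c_[truth.true_g, truth.true_gc, truth.true_gf]
        got = np.corrcoef(lat.T)
        want = truth.generator_config.corr_matrix()
        assert np.all(np.abs(got - want) < 0.06)

    def test_independent_components_config(self):
        cfg = GeneratorConfig(n_subjects=5000, component_corr=(0, 0, 0))
        _, truth = generate_cohort(cfg, seed=2)
        lat = np.c_[truth.true_g, truth.true_gc, truth.true_gf]
        off = np.corrcoef(lat.T) - np.eye(3)
        assert np.all(np.abs(off) < 0.05)

    def test_same_seed_byte_identical(self):
        cfg = GeneratorConfig(n_subjects=200)
        a, _ = generate_cohort(cfg, seed=5)
        b, _ = generate_cohort(cfg, seed=5)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_confound_target_correlations(self, big_cohort):
        cohort, truth = big_cohort
        targets = truth.generator_config.confound_target_corr
        for name, want in targets.items():
            got = np.corrcoef(cohort[name], truth.true_g)[0, 1]
            assert got == pytest.approx(want, abs=0.04), name

    def test_family_structure(self, big_cohort):
        cohort, truth = big_cohort
        sizes = cohort.groupby("family_id").size()
        assert sizes.max() <= truth.generator_config.max_family_size
        assert sizes.min() >= 1
        # family clustering: within-family g correlation is positive
        fam = cohort["family_id"].to_numpy()
        g = truth.true_g
        multi = [np.flatnonzero(fam == f) for f in pd.unique(fam)]
        pairs = [(g[i[0]], g[i[1]]) for i in multi if len(i) >= 2]
        a, b = np.array(pairs).T
        assert np.corrcoef(a, b)[0, 1] > 0.15

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(GeneratorConfig(n_subjects=0), seed=0)
        bad = GeneratorConfig(component_corr=(0.9, 0.9, -0.9))
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_cohort(bad, seed=0)


class TestCognitiveMeasures:
    def _truth(self, n=5000, seed=3):
        cfg = GeneratorConfig(n_subjects=n)
        _, truth = generate_cohort(cfg, seed=seed)
        return truth

    def test_zero_noise_pure_g(self):
        truth = self._truth(n=500)
        spec = LoadingSpec(general={m: 1.0 for m in MEASURE_NAMES},
                           noise_sd={m: 0.0 for m in MEASURE_NAMES})
        meas = generate_cognitive_measures(truth, spec, seed=1)
        for m in MEASURE_NAMES:
            assert np.corrcoef(meas[m], truth.true_g)[0, 1] == pytest.approx(1.0)

    def test_loading_gives_expected_correlation(self):
        # loading 0.7, total variance 1 -> corr(measure, g) = 0.7
        truth = self._truth()
        spec = LoadingSpec(general={m: 0.7 for m in MEASURE_NAMES})
        meas = generate_cognitive_measures(truth, spec, seed=2)
        got = np.mean([np.corrcoef(meas[m], truth.true_g)[0, 1]
                       for m in MEASURE_NAMES])
        assert got == pytest.approx(0.7, abs=0.03)

    def test_intercorrelations_match_factor_model(self):
        # cov(m1, m2) = a1*a2 for measures loading only on g
        truth = self._truth(seed=4)
        load = dict(zip(MEASURE_NAMES, np.linspace(0.5, 0.9, 12)))
        spec = LoadingSpec(general=load)
        meas = generate_cognitive_measures(truth, spec, seed=5)
        got = np.corrcoef(meas.to_numpy().T)
        a = np.array(list(load.values()))
        want = np.outer(a, a)
        np.fill_diagonal(want, 1.0)
        assert np.all(np.abs(got - want) < 0.05)


class TestGenerateConnectomes:
    def test_symmetric_zero_diagonal(self, small_atlas):
        cfg = GeneratorConfig(n_subjects=20, n_nodes=30, n_relevant=50)
        cohort, truth = generate_cohort(cfg, seed=6)
        conn = generate_connectomes(truth, small_atlas, states=("rest", "wm"),
                                    cohort=cohort)
        m = conn.matrix(0, "rest")
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_zero_signal_state_is_null(self):
        cfg = GeneratorConfig(n_subjects=1000, n_nodes=15, n_relevant=20,
                              state_signal={"rest": 0.0},
                              confound_leakage={})
        cohort, truth = generate_cohort(cfg, seed=7)
        conn = generate_connectomes(truth, NodeAtlas.default(15),
                                    states=("rest",), cohort=cohort)
        x = conn.state("rest")
        g = (truth.true_g - truth.true_g.mean()) / truth.true_g.std()
        r = (x - x.mean(0)).T @ g / len(g)
        r /= x.std(0)
        # Bonferroni-corrected null bound for 105 correlations at n=1000
        bound = stats.norm.ppf(1 - 0.025 / x.shape[1]) / np.sqrt(len(g))
        assert np.max(np.abs(r)) < bound

    def test_planted_edge_correlation_closed_form(self):
        # coherent single block, beta/sigma fixed: corr = b/sqrt(b^2+s^2)
        beta, sigma = 0.15, 0.2
        cfg = GeneratorConfig(n_subjects=5000, n_nodes=10, n_relevant=5,
                              n_blocks=1, block_coherence=1.0, beta=beta,
                              edge_noise_sd=(sigma, sigma), node_noise_sd=0.0,
                              state_signal={"wm": 1.0}, confound_leakage={},
                              retest_reliability=(1.0, 1.0))
            # fully stable noise so run-averaging does not shrink sigma
        cohort, truth = generate_cohort(cfg, seed=8)
        conn = generate_connectomes(truth, NodeAtlas.default(10),
                                    states=("wm",), cohort=cohort)
        planted = truth.relevant_edges["wm"]
        g = truth.true_g
        want = beta / np.hypot(beta, sigma)
        got = np.mean([abs(np.corrcoef(conn.state("wm")[:, e], g)[0, 1])
                       for e in planted])
        assert got == pytest.approx(want, abs=0.03)

    def test_determinism_and_truth_bookkeeping(self, small_atlas):
        cfg = GeneratorConfig(n_subjects=30, n_nodes=30, n_relevant=40)
        cohort, truth = generate_cohort(cfg, seed=9)
        c1 = generate_connectomes(truth, small_atlas, states=("rest",),
                                  cohort=cohort, seed=77)
        c2 = generate_connectomes(truth, small_atlas, states=("rest",),
                                  cohort=cohort, seed=77)
        assert np.array_equal(c1.values, c2.values)
        assert len(truth.relevant_edges["rest"]) == 40
        assert truth.effect_sizes.shape == (40,)

    def test_errors(self, small_atlas):
        cfg = GeneratorConfig(n_subjects=10, n_nodes=20)
        cohort, truth = generate_cohort(cfg, seed=1)
        with pytest.raises(ValueError, match="node count"):
            generate_connectomes(truth, small_atlas, states=("rest",))
        cfg30 = GeneratorConfig(n_subjects=10, n_nodes=30)
        _, truth30 = generate_cohort(cfg30, seed=1)
        with pytest.raises(KeyError, match="not in configured state set"):
            generate_connectomes(truth30, small_atlas, states=("nosuch",))


class TestMotionExclusion:
    @pytest.mark.parametrize("fd,spike,mx,kept", [
        (0.25, 0.05, 1.0, False),   # mean FD at/over 0.2 mm
        (0.10, 0.10, 2.0, True),
        (0.10, 0.25, 1.0, False),   # spike proportion over 20%
        (0.10, 0.05, 6.0, False),   # a spike above 5 mm
        (0.19, 0.19, 5.0, True),    # all three just inside
    ])
    def test_rules(self, fd, spike, mx, kept):
        df = pd.DataFrame({"subject_id": ["a"], "mean_fd": [fd],
                           "spike_proportion": [spike], "max_spike": [mx]})
        out = exclude_by_motion(df)
        assert (len(out) == 1) == kept

    def test_order_preserved_and_empty_allowed(self):
        df = pd.DataFrame({"subject_id": list("abc"),
                           "mean_fd": [0.1, 0.3, 0.15],
                           "spike_proportion": [0.1, 0.1, 0.1],
                           "max_spike": [1, 1, 1]})
        out = exclude_by_motion(df)
        assert list(out["subject_id"]) == ["a", "c"]
        none = exclude_by_motion(df, mean_fd_max=0.01)
        assert len(none) == 0
        with pytest.raises(ValueError):
            exclude_by_motion(df, mean_fd_max=-1)


def test_planted_features_expected_correlation():
    x, y, planted = synth.planted_features(5000, 50, 10, beta=0.5,
                                           noise_sd=1.0, seed=0)
    want = 0.5 / np.hypot(0.5, 1.0)
    got = np.mean([np.corrcoef(x[:, j], y)[0, 1] for j in planted])
    assert got == pytest.approx(want, abs=0.03)
    others = np.setdiff1d(np.arange(50), planted)
    null = np.max(np.abs([np.corrcoef(x[:, j], y)[0, 1] for j in others]))
    assert null < 0.06
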