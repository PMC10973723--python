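"""Correlation clustering, PCA, Pareto fronts, directional anisotropy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from mediaopt.design import MediaComposition
from mediaopt.downstream_analysis import (
    AnisotropyConfig,
    anisotropy_profile,
    asymmetry_index,
    filter_asymmetric,
    find_titre_center,
    hierarchical_cluster,
    pareto_front,
    pca,
    sample_tradeoff,
    spearman_matrix,
)
from mediaopt.synthetic_data import PanelSpec, SurfaceFunction, make_metabolite_panel


class TestSpearman:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"a": rng.normal(size=10)})
        t["b"] = t["a"]
        assert spearman_matrix(t).matrix.loc["a", "b"] == pytest.approx(1.0)

    def test_monotone_invariance(self):
        x = np.linspace(-2, 2, 15)
        t = pd.DataFrame({"x": x, "expx": np.exp(x)})
        assert spearman_matrix(t).matrix.loc["x", "expx"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        got = spearman_matrix(t).matrix.to_numpy()
        ranks = np.column_stack([rankdata(t[c]) for c in t])
        expected = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(got, expected, atol=1e-12)

    def test_constant_column_warns_and_is_nan(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_matrix(t)
        assert np.isnan(res.matrix.loc["a", "c"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestHierarchicalCluster:
    def test_two_perfect_blocks_recovered(self):
        rng = np.random.default_rng(2)
        base1, base2 = rng.normal(size=20), rng.normal(size=20)
        t = pd.DataFrame({"a1": base1, "a2": 2 * base1 + 1, "b1": base2, "b2": -(-base2)})
        res = hierarchical_cluster(spearman_matrix(t), k=2)
        labels = res.labels
        assert labels["a1"] == labels["a2"] != labels["b1"] == labels["b2"]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.normal(size=(30, 8)), columns=list("abcdefgh"))
        Z = hierarchical_cluster(spearman_matrix(t), k=3).linkage
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_planted_panel_recovery_single_seed(self, space):
        panel = make_metabolite_panel(seed=0, space=space)
        X = space.from_unit(np.random.default_rng(10).random((200, 2)))
        t = pd.DataFrame({n: s.on_points(X) for n, s in zip(panel.names, panel.surfaces)})
        res = hierarchical_cluster(spearman_matrix(t), k=4)
        assert adjusted_rand_score(panel.group_labels, res.labels.to_numpy()) >= 0.9

    def test_recovery_degrades_with_weaker_within_weight(self, space):
        X = space.from_unit(np.random.default_rng(11).random((200, 2)))
        aris = []
        for w in (0.95, 0.6, 0.2):
            panel = make_metabolite_panel(PanelSpec(within_group_weight=w, n_asymmetric=0), seed=4, space=space)
            t = pd.DataFrame({n: s.on_points(X) for n, s in zip(panel.names, panel.surfaces)})
            res = hierarchical_cluster(spearman_matrix(t), k=4)
            aris.append(adjusted_rand_score(panel.group_labels, res.labels.to_numpy()))
        assert aris[0] > aris[-1]

    def test_missing_correlations_rejected(self):
        m = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        m.loc["a", "b"] = m.loc["b", "a"] = np.nan
        with pytest.raises(ValueError, match="a.*b"):
            hierarchical_cluster(m, k=2)


class TestPCA:
    def test_collinear_columns_single_component(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        t = pd.DataFrame({"a": x, "b": 3 * x + 2})
        res = pca(t, standardise=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.normal(size=(10, 6)))
        res = pca(t, standardise=False)
        C = np.cov(t.to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        expected = evals / evals.sum()
        assert np.allclose(res.explained_variance_ratio, expected, atol=1e-10)
        # scores match up to sign
        X = t.to_numpy() - t.to_numpy().mean(0)
        _, vecs = np.linalg.eigh(C)
        lead = vecs[:, -1]
        s_o = X @ lead
        s_g = res.scores["PC1"].to_numpy()
        assert np.allclose(np.abs(s_g), np.abs(s_o), atol=1e-10)

    def test_fractions_sum_to_one_and_orthogonal_components(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(rng.normal(size=(15, 5)))
        res = pca(t)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        V = res.loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(5), atol=1e-9)

    def test_sample_permutation_permutes_scores(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.normal(size=(9, 4)))
        perm = rng.permutation(9)
        r1 = pca(t)
        r2 = pca(t.iloc[perm])
        assert np.allclose(r2.scores.to_numpy(), r1.scores.to_numpy()[perm], atol=1e-10)
        assert np.allclose(r1.explained_variance_ratio, r2.explained_variance_ratio)

    def test_zero_variance_column_rejected_when_standardising(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="c"):
            pca(t, standardise=True)


def brute_force_front(T, O):
    keep = []
    for i in range(len(T)):
        dominated = False
        for j in range(len(T)):
            if i == j:
                continue
            if T[j] >= T[i] and O[j] >= O[i] and (T[j] > T[i] or O[j] > O[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return set(keep)


class TestPareto:
    def test_single_point_is_the_front(self):
        pts = pd.DataFrame({"titre": [1.0], "max_od": [0.5]})
        assert pareto_front(pts).front_indices.tolist() == [0]

    def test_strictly_decreasing_curve_all_on_front(self):
        t = np.linspace(0, 1, 10)
        pts = pd.DataFrame({"titre": t, "max_od": 1 - t})
        assert len(pareto_front(pts).front_indices) == 10

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 120))
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = pd.DataFrame({"titre": rng.random(n).round(2), "max_od": rng.random(n).round(2)})
        got = set(pareto_front(pts).front_indices.tolist())
        assert got == brute_force_front(pts["titre"].to_numpy(), pts["max_od"].to_numpy())

    def test_sample_tradeoff_uses_model_surfaces(self, landscape, space):
        od = SurfaceFunction(lambda g, n: np.asarray(g, float) * 0 + 1.0)
        pairs = sample_tradeoff(landscape, od, 50, space, seed=0)
        assert len(pairs) == 50
        assert np.allclose(pairs["max_od"], 1.0)
        assert space.contains([pairs["glucose_pct"].min(), pairs["nh4cl_mM"].min()])


class TestAnisotropy:
    CENTER = MediaComposition(0.8, 50.0)

    def test_constant_surface_zero_gradients(self, space):
        const = SurfaceFunction(lambda g, n: np.ones(np.broadcast(g, n).shape))
        prof = anisotropy_profile(const, None, AnisotropyConfig(center=self.CENTER), space)
        assert np.all(np.abs(prof.gradients) < 1e-10)
        assert asymmetry_index(prof) == 0.0

    def test_radially_symmetric_surface_uniform_gradient_magnitude(self, space):
        cfg = AnisotropyConfig(center=self.CENTER)
        rad = SurfaceFunction(
            lambda g, n: np.exp(
                -np.hypot((np.asarray(g, float) - 0.8) / 0.6, (np.asarray(n, float) - 50.0) / 24.0) ** 2
            )
        )
        prof = anisotropy_profile(rad, None, cfg, space)
        mags = np.abs(prof.gradients)
        assert mags.max() - mags.min() < 1e-6

    def test_linear_surface_cosine_law(self, space):
        a = 1.7
        lin = SurfaceFunction(lambda g, n: a * (np.asarray(g, float) - 0.8) / 0.6)
        cfg = AnisotropyConfig(center=self.CENTER, n_path=100)
        prof = anisotropy_profile(lin, None, cfg, space)
        expected = a * np.cos(np.deg2rad(prof.angles_deg))
        assert np.allclose(prof.gradients, expected, atol=1e-3)

    def test_linear_surface_antisymmetric_under_180_degrees(self, space):
        lin = SurfaceFunction(lambda g, n: 0.5 * (np.asarray(n, float) - 50.0) / 24.0)
        cfg = AnisotropyConfig(center=self.CENTER, n_angles=36)
        g = anisotropy_profile(lin, None, cfg, space).gradients
        assert np.allclose(g + np.roll(g, 18), 0.0, atol=1e-9)

    def test_constructed_asymmetric_profile_detected_with_direction(self):
        angles = np.arange(0, 360, 10.0)
        grads = np.ones(36)
        grads[angles == 130.0] = 3.0
        from mediaopt.downstream_analysis import AnisotropyProfile

        prof = AnisotropyProfile("x", angles, grads, self.CENTER)
        sym = AnisotropyProfile("y", angles, np.ones(36), self.CENTER)
        flagged = filter_asymmetric([prof, sym], threshold=0.5)
        assert [f.name for f in flagged] == ["x"]
        assert flagged[0].dominant_angle_deg == 130.0

    def test_center_defaults_to_titre_argmax(self, landscape, space):
        c = find_titre_center(landscape, space)
        assert abs(c.glucose_pct - 0.8) < 0.02 and abs(c.nh4cl_mM - 50.0) < 1.0

    def test_panel_filter_recovers_planted_asymmetric_members(self, space):
        panel = make_metabolite_panel(seed=3, space=space)
        cfg = AnisotropyConfig(center=self.CENTER)
        profs = [
            anisotropy_profile(s, None, cfg, space, name=n)
            for n, s in zip(panel.names, panel.surfaces)
        ]
        flagged = {f.name for f in filter_asymmetric(profs)}
        assert flagged == {panel.names[i] for i in panel.asymmetric_indices}
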