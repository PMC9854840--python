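"""Superimposition, symmetry, shape PCA and the permutation ANOVA."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kstest

from morphherit import simulate as sim
from morphherit.morphometry import (
    GPAConvergenceError,
    centroid_size,
    gpa,
    procrustes_anova,
    shape_pca,
    symmetric_component,
)
from morphherit.scheme import viper_head_scheme

from _oracles import grid_gpa

SCHEME = viper_head_scheme()


def _random_configs(n, seed=0, asym=0.002):
    truth = sim.viper_truth(t=3)
    truth.asym_noise_sd = asym
    ped = sim.simulate_pedigree(4, 3, 6, [max(1, (n - 7) // 6)] * 6, seed=seed)
    configs, _ = sim.simulate_dataset(truth, ped, phenotype_parents=True, seed=seed)
    return configs[:n]


class TestCentroidSize:
    def test_unit_square(self):
        cs = centroid_size(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert cs == pytest.approx(np.sqrt(2.0), abs=1e-12)

    @given(
        scale=st.floats(0.01, 100.0),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_similarity_behavior(self, scale, tx, ty):
        rng = np.random.default_rng(7)
        coords = rng.random((6, 2))
        base = centroid_size(coords)
        assert centroid_size(coords * scale) == pytest.approx(scale * base, rel=1e-9)
        assert centroid_size(coords + [tx, ty]) == pytest.approx(base, rel=1e-9)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid_size(np.ones((5, 2)))


class TestGPA:
    def test_similarity_transform_removed(self):
        tri = np.array([[0.0, 0.0], [2.0, 0.0], [0.5, 1.5]])
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        other = tri @ R * 3.0 + [5.0, -2.0]
        aligned = gpa([tri, other], project=False)
        d = np.linalg.norm(aligned.shapes[0] - aligned.shapes[1])
        assert d < 1e-10

    def test_output_invariant_to_input_similarity_transforms(self):
        configs = _random_configs(12, seed=4)
        ref = gpa(configs, scheme=SCHEME).shapes
        rng = np.random.default_rng(0)
        jittered = []
        for cfg in configs:
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            s = rng.uniform(0.3, 4.0)
            t = rng.uniform(-10, 10, 2)
            jittered.append(cfg.coords @ R * s + t)
        again = gpa(jittered, scheme=SCHEME).shapes
        assert np.max(np.abs(ref - again)) < 1e-8

    def test_residual_sum_nonincreasing_over_iterations(self):
        configs = _random_configs(25, seed=9)
        aligned = gpa(configs, scheme=SCHEME, slide=False)
        ss = np.array(aligned.ss_history)
        assert np.all(np.diff(ss) <= 1e-10)

    def test_unit_size_and_centering_without_projection(self):
        configs = _random_configs(10, seed=2)
        aligned = gpa(configs, scheme=SCHEME, project=False)
        X = aligned.as_landmarks()
        assert np.max(np.abs(X.mean(axis=1))) < 1e-10
        cs = np.sqrt((X**2).sum(axis=(1, 2)))
        assert np.max(np.abs(cs - 1.0)) < 1e-10
        assert np.max(np.abs(
            aligned.consensus - aligned.shapes.mean(axis=0)
        )) < 1e-10

    def test_matches_rotation_grid_oracle(self):
        tris = [
            np.array([[0.0, 0.0], [2.0, 0.1], [0.6, 1.4]]),
            np.array([[0.1, -0.2], [1.7, 0.3], [0.2, 1.8]]),
            np.array([[-0.3, 0.0], [2.2, -0.1], [1.0, 1.2]]),
        ]
        oracle_shapes, oracle_mean, oracle_val = grid_gpa(tris)
        aligned = gpa(tris, project=False)
        got = aligned.as_landmarks()
        ss = float(((got - got.mean(axis=0)) ** 2).sum())
        assert ss == pytest.approx(oracle_val, abs=1e-6)
        # align the oracle frame onto the package frame (rotation gauge)
        H = sum(o.T @ g for o, g in zip(oracle_shapes, got))
        a, b = H[0, 0] + H[1, 1], H[1, 0] - H[0, 1]
        r = np.hypot(a, b)
        R = np.array([[a / r, -b / r], [b / r, a / r]])
        for o, g in zip(oracle_shapes, got):
            assert np.max(np.abs(o @ R - g)) < 1e-6
        assert np.max(np.abs(oracle_mean @ R - got.mean(axis=0))) < 1e-6

    def test_sliding_is_a_fixed_point_when_not_needed(self):
        # copies of the template under rigid motions only: semilandmarks
        # already minimize bending energy against the consensus
        tpl = sim.viper_template()
        rng = np.random.default_rng(1)
        configs = []
        for _ in range(6):
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            configs.append(tpl @ R * rng.uniform(0.5, 2.0) + rng.uniform(-3, 3, 2))
        no_slide = gpa(configs, scheme=SCHEME, slide=False)
        slid = gpa(configs, scheme=SCHEME, slide=True)
        assert np.max(np.abs(no_slide.shapes - slid.shapes)) < 1e-8

    def test_degenerate_configuration_rejected(self):
        good = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="zero centroid size"):
            gpa([good, np.zeros((3, 2))])

    def test_nonconvergence_raises_with_delta(self):
        configs = _random_configs(15, seed=5)
        with pytest.raises(GPAConvergenceError, match="change"):
            gpa(configs, scheme=SCHEME, max_iter=1, tol=1e-16)


class TestSymmetricComponent:
    def test_already_symmetric_input_unchanged(self):
        tpl = sim.viper_template()
        basis = sim.symmetric_basis(tpl, SCHEME)
        rng = np.random.default_rng(6)
        configs = [
            tpl + (basis @ (0.01 * rng.standard_normal(38))).reshape(40, 2)
            for _ in range(8)
        ]
        aligned = gpa(configs, scheme=SCHEME, project=False)
        symm = symmetric_component(aligned, SCHEME, project=False)
        # compare up to alignment: superimpose each pair
        for a, b in zip(aligned.as_landmarks(), symm.as_landmarks()):
            H = a.T @ b
            ang = np.arctan2(H[1, 0] - H[0, 1], H[0, 0] + H[1, 1])
            R = np.array([[np.cos(ang), -np.sin(ang)],
                          [np.sin(ang), np.cos(ang)]])
            assert np.linalg.norm(a @ R - b) < 1e-8

    def test_output_exactly_mirror_symmetric(self):
        configs = _random_configs(20, seed=3, asym=0.01)
        aligned = gpa(configs, scheme=SCHEME)
        symm = symmetric_component(aligned, SCHEME)
        perm = SCHEME.reflection_permutation()
        X = symm.as_landmarks()
        XR = X[:, perm, :].copy()
        XR[:, :, 0] *= -1.0
        assert np.max(np.abs(X - XR)) < 1e-8

    def test_symmetric_space_has_38_positive_eigenvalues(self):
        configs = _random_configs(45, seed=8)
        aligned = gpa(configs, scheme=SCHEME, slide=True)
        symm = symmetric_component(aligned, SCHEME)
        space = shape_pca(symm)
        n_pos = int(np.sum(space.eigenvalues > 1e-10 * space.eigenvalues[0]))
        assert n_pos == 38

    def test_scheme_without_pairs_rejected(self):
        from morphherit.scheme import LandmarkScheme

        flat = LandmarkScheme(n_landmarks=3, pairs=(), midline=(1, 2, 3))
        configs = [np.random.default_rng(i).random((3, 2)) for i in range(3)]
        aligned = gpa(configs)
        with pytest.raises(ValueError, match="pairs"):
            symmetric_component(aligned, flat)


class TestShapePCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(8)
        direction /= np.linalg.norm(direction)
        shapes = np.outer(rng.standard_normal(30), direction)
        from morphherit.morphometry import AlignedShapes

        aligned = AlignedShapes(
            shapes=shapes, centroid_sizes=np.ones(30),
            consensus=shapes.mean(axis=0), specimen_ids=[str(i) for i in range(30)],
        )
        space = shape_pca(aligned, n_retained=1)
        frac = space.eigenvalues[0] / space.eigenvalues.sum()
        assert frac == pytest.approx(1.0, abs=1e-12)
        assert np.all(space.eigenvalues[1:] < 1e-12 * space.eigenvalues[0])

    def test_matches_explicit_covariance_eigendecomposition(self):
        configs = _random_configs(30, seed=12)
        aligned = gpa(configs, scheme=SCHEME)
        space = shape_pca(aligned)
        Xc = aligned.shapes - aligned.shapes.mean(axis=0)
        cov = Xc.T @ Xc / (len(configs) - 1)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        got = space.eigenvalues[: len(expected)]
        assert np.allclose(got, np.clip(expected, 0, None),
                           rtol=1e-8, atol=1e-12 * expected[0])
        # invariants
        assert np.allclose(space.loadings.T @ space.loadings,
                           np.eye(space.n_retained), atol=1e-10)
        assert np.max(np.abs(space.scores.mean(axis=0))) < 1e-10
        assert space.eigenvalues.sum() == pytest.approx(
            float((Xc**2).sum()) / (len(configs) - 1), rel=1e-8
        )
        cum = space.cumulative_variance
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[space.rank - 1] == pytest.approx(1.0, abs=1e-8)

    def test_back_projection_round_trip(self):
        configs = _random_configs(25, seed=13)
        aligned = gpa(configs, scheme=SCHEME)
        space = shape_pca(aligned)  # full rank retained
        centered = aligned.shapes[3] - space.consensus
        rebuilt = space.back_project(space.project(aligned.shapes[3])[0])
        assert np.max(np.abs(rebuilt - centered)) < 1e-10

    def test_retaining_beyond_rank_reports_rank(self):
        configs = _random_configs(20, seed=14)
        aligned = gpa(configs, scheme=SCHEME)
        with pytest.raises(ValueError, match=r"rank"):
            shape_pca(aligned, n_retained=75)


class TestProcrustesAnova:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((30, 4))
        g = np.repeat(["x", "y", "z"], 10)
        r1 = procrustes_anova(Y, g, n_perm=300, seed=42)
        r2 = procrustes_anova(Y, g, n_perm=300, seed=42)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    def test_extreme_separation_gives_minimum_p(self):
        Y = np.concatenate([np.zeros(10), np.full(10, 50.0)])
        Y = Y[:, None] + np.linspace(0, 0.1, 20)[:, None] * 0.01
        g = np.repeat(["a", "b"], 10)
        res = procrustes_anova(Y, g, n_perm=1000, seed=1)
        assert res.p_value == pytest.approx(1.0 / 1001.0, abs=1e-12)

    def test_pvalue_lower_bound(self):
        rng = np.random.default_rng(5)
        res = procrustes_anova(
            rng.standard_normal(24), np.repeat(["a", "b"], 12), n_perm=99, seed=2
        )
        assert res.p_value >= 1.0 / 100.0
        assert res.p_value <= 1.0

    @pytest.mark.parametrize(
        "response,groups,err",
        [
            (np.ones(10), ["a"] * 5 + ["b"] * 5, "constant"),
            (np.arange(10.0), ["a"] * 9 + ["b"], "fewer than 2"),
            (np.arange(10.0), ["a"] * 10, "2 groups"),
        ],
    )
    def test_invalid_inputs_rejected(self, response, groups, err):
        with pytest.raises(ValueError, match=err):
            procrustes_anova(response, groups, n_perm=10, seed=0)

    def test_null_pvalues_uniform(self, null_anova_pvalues):
        stat = kstest(null_anova_pvalues, "uniform").statistic
        assert stat < 0.12
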