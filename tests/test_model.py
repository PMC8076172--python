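"""Cholesky component covariances and the FIML likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import twinchol as tc
from twinchol.model import MeansModel

path_coeff = st.floats(-1.5, 1.5, allow_nan=False)
diag_coeff = st.floats(0.3, 1.5, allow_nan=False)

valid_params = st.builds(
    tc.CholeskyParams,
    a11=path_coeff, a21=path_coeff, a22=path_coeff,
    c11=path_coeff, c21=path_coeff, c22=path_coeff,
    e11=diag_coeff, e21=path_coeff, e22=diag_coeff,
)


class TestComponentCovariance:
    def test_single_path(self):
        p = tc.CholeskyParams(a11=1.0)
        assert np.allclose(tc.component_covariance(p, "A"), [[1, 0], [0, 0]])

    def test_identity_factor(self):
        p = tc.CholeskyParams(e11=1.0, e21=0.0, e22=1.0)
        assert np.allclose(tc.component_covariance(p, "E"), np.eye(2))

    def test_published_fit_genetic_covariance(self):
        p = tc.CholeskyParams(
            a11=math.sqrt(0.62), a21=math.sqrt(0.16), a22=math.sqrt(0.19)
        )
        # direct L @ L.T arithmetic
        L = np.array([[math.sqrt(0.62), 0], [math.sqrt(0.16), math.sqrt(0.19)]])
        assert np.allclose(tc.component_covariance(p, "A"), L @ L.T)
        assert np.round(tc.component_covariance(p, "A"), 3).tolist() == [
            [0.620, 0.315],
            [0.315, 0.350],
        ]


class TestExpectedPairCovariance:
    def test_pure_shared_genetic_mz(self):
        p = tc.CholeskyParams(a11=1.0, e11=1e-6, e22=1e-6)
        sigma = tc.expected_pair_covariance(p, "MZ")
        expect = np.zeros((4, 4))
        for i in (0, 2):
            for j in (0, 2):
                expect[i, j] = 1.0
        assert np.allclose(sigma, expect, atol=1e-10)

    def test_dz_halves_cross_twin_genetics(self):
        p = tc.CholeskyParams(a11=1.0, e11=1e-6, e22=1e-6)
        sigma = tc.expected_pair_covariance(p, "DZ")
        assert sigma[0, 0] == pytest.approx(1.0)
        assert sigma[0, 2] == pytest.approx(0.5)

    def test_published_fit_mz_blocks(self, published_params):
        sigma = tc.expected_pair_covariance(published_params, "MZ")
        assert np.allclose(np.diag(sigma), 1.0)
        assert sigma[0, 1] == pytest.approx(0.315, abs=5e-4)  # within-twin v1,v2
        assert sigma[0, 2] == pytest.approx(0.620, abs=5e-4)  # cross-twin v1,v1
        assert sigma[1, 3] == pytest.approx(0.350, abs=5e-4)  # cross-twin v2,v2
        assert sigma[0, 3] == pytest.approx(0.315, abs=5e-4)  # cross-twin v1,v2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(params=valid_params, zyg=st.sampled_from(["MZ", "DZ"]))
    def test_symmetric_positive_definite(self, params, zyg):
        sigma = tc.expected_pair_covariance(params, zyg)
        assert np.allclose(sigma, sigma.T)
        np.linalg.cholesky(sigma)  # raises if not positive definite

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(params=valid_params)
    def test_mz_minus_dz_cross_block_is_half_genetic(self, params):
        mz = tc.expected_pair_covariance(params, "MZ")
        dz = tc.expected_pair_covariance(params, "DZ")
        diff = mz[:2, 2:] - dz[:2, 2:]
        assert np.allclose(diff, 0.5 * tc.component_covariance(params, "A"), atol=1e-12)

    def test_unknown_zygosity(self, published_params):
        with pytest.raises(ValueError):
            tc.expected_pair_covariance(published_params, "XZ")


class TestPairLoglik:
    def mvn_oracle(self, y, mu, sigma):
        return stats.multivariate_normal(mean=mu, cov=sigma).logpdf(y)

    def test_complete_pair_matches_generic_density(self, published_params, pair_factory):
        pair = pair_factory(phenotype=((0.3, -0.2), (0.1, 0.4)))
        means = MeansModel(mu=(0.05, -0.1))
        sigma = tc.expected_pair_covariance(published_params, "MZ")
        y = np.array([0.3, -0.2, 0.1, 0.4])
        mu = np.array([0.05, -0.1, 0.05, -0.1])
        expected = self.mvn_oracle(y, mu, sigma)
        assert tc.pair_loglik(published_params, means, pair) == pytest.approx(
            expected, abs=1e-10
        )

    def test_singleton_uses_within_twin_marginal(self, published_params, pair_factory):
        nan = float("nan")
        pair = pair_factory(
            phenotype=((0.3, -0.2), (nan, nan)), singleton=True
        )
        means = MeansModel(mu=(0.0, 0.0))
        sigma = tc.expected_pair_covariance(published_params, "MZ")[:2, :2]
        expected = self.mvn_oracle([0.3, -0.2], [0.0, 0.0], sigma)
        assert tc.pair_loglik(published_params, means, pair) == pytest.approx(
            expected, abs=1e-10
        )

    def test_partial_pattern_matches_submatrix_density(self, published_params, pair_factory):
        nan = float("nan")
        pair = pair_factory(zygosity="DZ", phenotype=((0.3, nan), (nan, 0.4)))
        means = MeansModel(mu=(0.1, 0.2))
        sigma = tc.expected_pair_covariance(published_params, "DZ")
        idx = [0, 3]
        expected = self.mvn_oracle(
            [0.3, 0.4], [0.1, 0.2], sigma[np.ix_(idx, idx)]
        )
        assert tc.pair_loglik(published_params, means, pair) == pytest.approx(
            expected, abs=1e-10
        )

    def test_all_missing_contributes_zero(self, published_params, pair_factory):
        nan = float("nan")
        pair = pair_factory(phenotype=((nan, nan), (nan, nan)))
        assert tc.pair_loglik(published_params, MeansModel(), pair) == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(params=valid_params, data=st.data())
    def test_twin_relabel_invariance(self, params, data):
        vals = [
            data.draw(st.floats(-2, 2) | st.none(), label=f"slot{i}") for i in range(4)
        ]
        nan = float("nan")
        grid = [[v if v is not None else nan for v in vals[:2]],
                [v if v is not None else nan for v in vals[2:]]]
        pair = tc.TwinPair(
            family_id="f", zygosity="DZ", ethnicity="EA", sex1="F", sex2="F",
            phenotype=np.asarray(grid, dtype=float),
            map_bp=np.full((2, 2), nan), age=np.full((2, 2), nan),
        )
        means = MeansModel(mu=(0.1, -0.3))
        a = tc.pair_loglik(params, means, pair)
        b = tc.pair_loglik(params, means, pair.swap_twins())
        assert a == pytest.approx(b, abs=1e-10)


class TestDatasetDeviance:
    def test_single_pair_additivity(self, published_params, pair_factory):
        pair = pair_factory(phenotype=((0.3, -0.2), (0.1, 0.4)))
        means = MeansModel(mu=(0.0, 0.0))
        ds = tc.TwinDataset([pair])
        assert tc.dataset_m2ll(published_params, means, ds) == pytest.approx(
            -2.0 * tc.pair_loglik(published_params, means, pair), abs=1e-10
        )

    def test_swap_all_twins_invariance(self, published_params, small_cohort):
        means = MeansModel(mu=(0.0, 0.0))
        swapped = tc.TwinDataset(
            [p.swap_twins() for p in small_cohort], transform="log"
        )
        a = tc.dataset_m2ll(published_params, means, small_cohort)
        b = tc.dataset_m2ll(published_params, means, swapped)
        assert a == pytest.approx(b, abs=1e-8)

    def test_matches_per_pair_density_accumulation(self, published_params):
        cfg = tc.simple_cohort_config(
            n_mz=25, n_dz=25, n_singletons=10, params=published_params,
            missingness=(0.15, 0.15),
        )
        ds = tc.log_transform(tc.simulate_cohort(cfg, seed=13))
        means = MeansModel(mu=(0.05, -0.05))
        brute = 0.0
        for pair in ds:
            y, mask = pair.observed_vector()
            if not mask.any():
                continue
            sigma = tc.expected_pair_covariance(published_params, pair.zygosity)
            mu = np.array([0.05, -0.05, 0.05, -0.05])
            brute += stats.multivariate_normal(
                mean=mu[mask], cov=sigma[np.ix_(mask, mask)]
            ).logpdf(y[mask])
        assert tc.dataset_m2ll(published_params, means, ds) == pytest.approx(
            -2.0 * brute, abs=1e-8
        )

    def test_factorizes_without_cross_visit_paths(self, published_params):
        # with a21 = c21 = e21 = 0 the two visits are independent, so the
        # joint deviance equals the sum of the per-visit marginal deviances
        params = tc.CholeskyParams(a11=0.7, a22=0.5, e11=0.6, e22=0.8)
        cfg = tc.simple_cohort_config(n_mz=20, n_dz=20, params=published_params)
        ds = tc.log_transform(tc.simulate_cohort(cfg, seed=21))
        means = MeansModel(mu=(0.0, 0.0))
        joint = tc.dataset_m2ll(params, means, ds)
        marginal = 0.0
        for visit_slots in ([0, 2], [1, 3]):
            for pair in ds:
                y, mask = pair.observed_vector()
                keep = np.zeros(4, bool)
                keep[visit_slots] = True
                keep &= mask
                if not keep.any():
                    continue
                sigma = tc.expected_pair_covariance(params, pair.zygosity)
                marginal += stats.multivariate_normal(
                    mean=np.zeros(int(keep.sum())), cov=sigma[np.ix_(keep, keep)]
                ).logpdf(y[keep])
        assert joint == pytest.approx(-2.0 * marginal, abs=1e-8)


class TestModelSpec:
    def test_free_path_counting(self):
        ace = tc.ModelSpec(components=("A", "C", "E"))
        ae = tc.ModelSpec(components=("A", "E"))
        assert len(ace.free_paths) == 9
        assert len(ae.free_paths) == 6
        dropped = tc.ModelSpec(components=("A", "E"), drop_paths={"e21"})
        assert "e21" not in dropped.free_paths
        assert len(dropped.free_paths) == 5

    def test_e_component_mandatory(self):
        with pytest.raises(ValueError):
            tc.ModelSpec(components=("A", "C"))

    def test_serialization_roundtrip(self):
        spec = tc.ModelSpec(
            components=("A", "E"), drop_paths={"e21"}, grouping="ethnicity",
            equate_paths=False, covariates=("map",),
        )
        assert tc.ModelSpec.from_dict(spec.to_dict()) == spec

    def test_sign_reflection_preserves_covariance(self):
        p = tc.CholeskyParams(a11=-0.7, a21=0.4, a22=-0.5, e11=0.6, e22=0.8)
        r = p.reflect_signs()
        assert r.a11 >= 0 and r.a22 >= 0
        assert np.allclose(
            tc.component_covariance(p, "A"), tc.component_covariance(r, "A")
        )
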