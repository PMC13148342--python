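"""SVD basis derivation, the -pi/4 rotation, and framework statistics."""

import numpy as np
import pytest

from ousiometrics.errors import ContractError
from ousiometrics.frameworks import (
    DEFAULT_CONE_HALF_ANGLE,
    FrameworkBasis,
    ScoreMatrix,
    apply_basis,
    derive_gas_basis,
    explained_variances,
    gpads_scores,
    pairwise_correlations,
    plane_svd_ellipse,
    rank_terms_in_cone,
    rotate_gas_to_pds,
    rotate_primary_plane,
)

# Published two-decimal VAD->GAS and VAD->PDS weight matrices.
GAS_PRINTED = np.array(
    [[+0.86, -0.15, +0.48], [-0.16, +0.83, +0.54], [+0.48, +0.55, -0.69]]
)
PDS_PRINTED = np.array(
    [[+0.50, +0.48, +0.72], [-0.72, +0.69, +0.04], [+0.48, +0.55, -0.69]]
)
SIGMA_PRINTED = (34.1, 27.2, 13.8)


def exact_gas_scores(n, variances, seed):
    """Scores whose columns are exactly orthogonal with exact variances
    (sum of squares n*var_i), via the left singular vectors of a random
    matrix -- an oracle construction independent of the basis code."""
    rng = np.random.default_rng(seed)
    u, _, _ = np.linalg.svd(rng.standard_normal((n, len(variances))), full_matrices=False)
    values = u * np.sqrt(np.asarray(variances) * n)
    return ScoreMatrix(
        terms=[f"t{i}" for i in range(n)],
        values=values,
        dims=("Gd", "Ag", "St")[: len(variances)],
        framework="GAS",
    )


class TestRotation:
    def test_printed_gas_matrix_rotates_to_printed_pds(self):
        """Rotating the published GAS weights reproduces the published
        PDS weights entry-by-entry within print rounding."""
        rotated = rotate_primary_plane(GAS_PRINTED)
        assert np.abs(rotated - PDS_PRINTED).max() <= 0.01

    def test_rotation_is_invertible(self, vad_scores):
        gas = derive_gas_basis(vad_scores)
        pds = rotate_gas_to_pds(gas)
        inv_sqrt2 = 1.0 / np.sqrt(2.0)
        back = np.vstack(
            [
                (pds.matrix[0] - pds.matrix[1]) * inv_sqrt2,
                (pds.matrix[0] + pds.matrix[1]) * inv_sqrt2,
                pds.matrix[2],
            ]
        )
        assert np.abs(back - gas.matrix).max() < 1e-12

    def test_closed_form_variance_and_correlation(self):
        """Rotating uncorrelated axes with variance shares 55.6/35.3
        splits the plane evenly (45.45 each) with correlation
        (v2 - v1)/(v1 + v2) ~ -0.223."""
        scores = exact_gas_scores(20_000, (55.6, 35.3, 9.1), seed=13)
        pw = (scores.column("Gd") + scores.column("Ag")) / np.sqrt(2)
        dg = (-scores.column("Gd") + scores.column("Ag")) / np.sqrt(2)
        st = scores.column("St")
        variances = np.array([v.var() for v in (pw, dg, st)])
        shares = 100 * variances / variances.sum()
        assert shares[0] == pytest.approx(45.45, abs=0.1)
        assert shares[1] == pytest.approx(45.45, abs=0.1)
        r = np.corrcoef(pw, dg)[0, 1]
        assert r == pytest.approx((35.3 - 55.6) / 90.9, abs=0.01)
        assert r == pytest.approx(-0.22, abs=0.01)

    def test_basis_rotation_matches_score_rotation(self, vad_scores):
        """Rotating the basis then applying equals applying then rotating."""
        gas = derive_gas_basis(vad_scores)
        pds = rotate_gas_to_pds(gas)
        via_basis = apply_basis(vad_scores, pds).values
        g = apply_basis(vad_scores, gas).values
        direct = np.column_stack(
            [
                (g[:, 0] + g[:, 1]) / np.sqrt(2),
                (-g[:, 0] + g[:, 1]) / np.sqrt(2),
                g[:, 2],
            ]
        )
        assert np.abs(via_basis - direct).max() < 1e-12

    def test_pds_explained_variance_splits_primary_plane(self, vad_scores):
        gas = derive_gas_basis(vad_scores)
        pds = rotate_gas_to_pds(gas)
        e1, e2, e3 = gas.explained_variance
        assert pds.explained_variance[:2] == pytest.approx([(e1 + e2) / 2] * 2)
        assert pds.explained_variance[2] == pytest.approx(e3)

    def test_wrong_dims_rejected(self, vad_scores):
        gas = derive_gas_basis(vad_scores)
        pds = rotate_gas_to_pds(gas)
        with pytest.raises(ContractError):
            rotate_gas_to_pds(pds)


class TestDeriveGasBasis:
    def test_axis_aligned_data_gives_signed_permutation_identity(self):
        scores = exact_gas_scores(1000, (3.0, 2.0, 1.0), seed=2)
        vad_like = ScoreMatrix(
            terms=scores.terms, values=scores.values, dims=("Va", "Ar", "Dm"),
            framework="VAD",
        )
        basis = derive_gas_basis(vad_like)
        expected = np.diag([1.0, 1.0, -1.0])  # St anchored negative on Dm
        assert np.abs(basis.matrix - expected).max() < 1e-9

    def test_recovers_known_mixing_matrix(self):
        """Parameter recovery: a lexicon generated through a known
        orthonormal mixing with >=20% singular-value gaps is recovered
        to within 0.02 absolute entry error at n = 20,000."""
        n, seed = 20_000, 17
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        sd = np.array([0.20, 0.15, 0.08])  # gaps >= 20%
        latent = rng.standard_normal((n, 3)) * sd
        scores = ScoreMatrix(
            terms=[f"t{i}" for i in range(n)], values=latent @ q.T,
            dims=("Va", "Ar", "Dm"), framework="VAD",
        )
        basis = derive_gas_basis(scores)
        recovered = basis.matrix
        target = q.T.copy()
        for i in range(3):  # compare up to sign
            if np.dot(recovered[i], target[i]) < 0:
                target[i] *= -1.0
        assert np.abs(recovered - target).max() <= 0.02

    def test_sign_convention_and_idempotence(self, vad_scores):
        a = derive_gas_basis(vad_scores)
        b = derive_gas_basis(vad_scores)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.matrix[0, 0] > 0  # Gd weight on Va
        assert a.matrix[1, 1] > 0  # Ag weight on Ar
        assert a.matrix[2, 2] < 0  # St weight on Dm

    def test_rows_orthonormal_and_variances_sum_to_one(self, vad_scores):
        basis = derive_gas_basis(vad_scores)
        assert np.abs(basis.matrix @ basis.matrix.T - np.eye(3)).max() < 1e-9
        assert basis.explained_variance.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(basis.singular_values) <= 0).all()

    def test_singular_values_carry_total_sum_of_squares(self, vad_scores):
        basis = derive_gas_basis(vad_scores)
        total = (vad_scores.values**2).sum()
        assert (basis.singular_values**2).sum() == pytest.approx(total, rel=1e-6)

    def test_rank_deficient_input_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        xy = rng.standard_normal((100, 2))
        values = np.column_stack([xy[:, 0], xy[:, 1], xy[:, 0] + xy[:, 1]])
        scores = ScoreMatrix(
            terms=[f"t{i}" for i in range(100)], values=values,
            dims=("Va", "Ar", "Dm"), framework="VAD",
        )
        basis = derive_gas_basis(scores)
        assert basis.degenerate

    def test_svd_decorrelates_gas_scores(self, demeaned_scores):
        """On exactly mean-free data the GAS coordinates are pairwise
        uncorrelated to machine precision."""
        gas = derive_gas_basis(demeaned_scores)
        corr = pairwise_correlations(apply_basis(demeaned_scores, gas)).to_numpy()
        assert np.abs(corr - np.eye(3)).max() < 1e-9

    def test_basis_json_round_trip(self, vad_scores, tmp_path):
        basis = derive_gas_basis(vad_scores)
        path = tmp_path / "basis.json"
        basis.to_json(path)
        back = FrameworkBasis.from_json(path)
        assert np.array_equal(back.matrix, basis.matrix)
        assert back.target_dims == basis.target_dims
        assert np.array_equal(back.singular_values, basis.singular_values)


class TestExplainedVariances:
    def test_printed_singular_values(self):
        ev = explained_variances(SIGMA_PRINTED)
        assert np.round(ev, 3).tolist() == [0.556, 0.353, 0.091]
        assert (ev[0] + ev[1]) * 100 == pytest.approx(90.9, abs=0.05)

    def test_equal_values_split_evenly(self):
        assert explained_variances((2.0, 2.0, 2.0)) == pytest.approx([1 / 3] * 3)

    def test_rank_one(self):
        assert explained_variances((5.0, 0.0, 0.0)).tolist() == [1.0, 0.0, 0.0]

    def test_all_zero_is_fatal(self):
        with pytest.raises(ContractError):
            explained_variances((0.0, 0.0, 0.0))


class TestApplyBasis:
    def test_zero_vector_maps_to_zero(self, vad_scores):
        gas = derive_gas_basis(vad_scores)
        zero = ScoreMatrix(terms=["z"], values=np.zeros((1, 3)),
                           dims=("Va", "Ar", "Dm"), framework="VAD")
        assert np.array_equal(apply_basis(zero, gas).values, np.zeros((1, 3)))

    def test_dimension_mismatch_is_fatal(self, vad_scores):
        gas = derive_gas_basis(vad_scores)
        already = apply_basis(vad_scores, gas)
        with pytest.raises(ContractError):
            apply_basis(already, gas)

    def test_gpads_composite_columns(self, vad_scores):
        gas = derive_gas_basis(vad_scores)
        pds = rotate_gas_to_pds(gas)
        comp = gpads_scores(vad_scores, gas, pds)
        assert comp.dims == ("Gd", "Pw", "Ag", "Dg", "St")
        assert np.array_equal(comp.column("Pw"), apply_basis(vad_scores, pds).column("Pw"))


class TestPairwiseCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        scores = ScoreMatrix(terms=[f"t{i}" for i in range(10)],
                             values=np.column_stack([x, 2 * x]),
                             dims=("a", "b"), framework="X")
        assert pairwise_correlations(scores).loc["a", "b"] == pytest.approx(1.0)

    def test_single_term_weight_is_flagged_undefined(self, vad_scores):
        weights = {vad_scores.terms[0]: 5.0}
        corr = pairwise_correlations(vad_scores, weights)
        assert np.isnan(corr.loc["Va", "Dm"])
        assert corr.loc["Va", "Va"] == 1.0

    def test_weighted_correlation_shifts_with_mass(self, vad_scores):
        """Concentrating weight on high-Va/high-Dm terms changes the
        weighted correlation away from the unweighted one."""
        unweighted = pairwise_correlations(vad_scores).loc["Va", "Dm"]
        idx = np.argsort(vad_scores.column("Va"))[-1000:]
        weights = {vad_scores.terms[i]: 1.0 for i in idx}
        weighted = pairwise_correlations(vad_scores, weights).loc["Va", "Dm"]
        assert weighted != pytest.approx(unweighted, abs=1e-3)


class TestPlaneEllipse:
    def test_collinear_points(self):
        x = np.linspace(-1, 1, 50)
        scores = ScoreMatrix(terms=[f"t{i}" for i in range(50)],
                             values=np.column_stack([x, x]),
                             dims=("a", "b"), framework="X")
        ell = plane_svd_ellipse(scores, ("a", "b"))
        assert np.abs(ell.axes[0] - np.array([1, 1]) / np.sqrt(2)).max() < 1e-9
        assert ell.radii[1] == pytest.approx(0.0, abs=1e-9)
        assert ell.degenerate is False  # major axis has variance

    def test_isotropic_cloud_radii_near_equal(self):
        rng = np.random.default_rng(23)
        xy = rng.standard_normal((10_000, 2)) * 0.1
        scores = ScoreMatrix(terms=[f"t{i}" for i in range(10_000)], values=xy,
                             dims=("a", "b"), framework="X")
        ell = plane_svd_ellipse(scores, ("a", "b"))
        assert ell.radii[1] / ell.radii[0] > 0.95
        # eigen-decomposition oracle on the sample covariance
        evals = np.linalg.eigvalsh(np.cov(xy.T, bias=True))
        assert ell.radii[0] ** 2 == pytest.approx(evals[1], rel=1e-9)
        assert ell.radii[1] ** 2 == pytest.approx(evals[0], rel=1e-9)

    def test_gas_frame_ellipse_axis_aligned(self, demeaned_scores):
        gas = derive_gas_basis(demeaned_scores)
        g = apply_basis(demeaned_scores, gas)
        ell = plane_svd_ellipse(g, ("Gd", "Ag"))
        angle = np.arctan2(ell.axes[0, 1], ell.axes[0, 0])
        assert min(abs(angle), abs(abs(angle) - np.pi)) < 1e-6

    def test_weighted_center_is_weighted_mean(self, vad_scores):
        weights = {t: 1.0 for t in vad_scores.terms[:100]}
        ell = plane_svd_ellipse(vad_scores, ("Va", "Dm"), weights)
        assert ell.center[0] == pytest.approx(vad_scores.values[:100, 0].mean())


class TestConeRanking:
    def test_default_half_angle_in_degrees(self):
        assert np.degrees(DEFAULT_CONE_HALF_ANGLE) == pytest.approx(17.63, abs=0.01)

    def test_term_on_axis_included_with_magnitude_projection(self):
        scores = ScoreMatrix(terms=["on", "off"],
                             values=np.array([[0.4, 0.0, 0.0], [0.0, 0.4, 0.0]]),
                             dims=("Pw", "Dg", "St"), framework="PDS")
        ranking = rank_terms_in_cone(scores, (1, 0, 0))
        assert ranking.ranked == [("on", pytest.approx(0.4))]

    def test_term_at_30_degrees_excluded_by_default(self):
        theta = np.radians(30.0)
        scores = ScoreMatrix(terms=["t"],
                             values=np.array([[np.cos(theta), np.sin(theta), 0.0]]),
                             dims=("Pw", "Dg", "St"), framework="PDS")
        assert rank_terms_in_cone(scores, (1, 0, 0)).ranked == []
        wide = rank_terms_in_cone(scores, (1, 0, 0), half_angle=np.radians(31))
        assert len(wide.ranked) == 1

    def test_ranked_descending_and_truncated(self, vad_scores):
        gas = derive_gas_basis(vad_scores)
        pds = rotate_gas_to_pds(gas)
        p = apply_basis(vad_scores, pds)
        ranking = rank_terms_in_cone(p, (1, 0, 0), top_n=20)
        comps = [c for _, c in ranking.ranked]
        assert len(comps) == 20
        assert comps == sorted(comps, reverse=True)
        # brute-force membership oracle
        unit = np.array([1.0, 0.0, 0.0])
        for term, comp in ranking.ranked:
            v = p.values[p.terms.index(term)]
            angle = np.arccos(np.clip(v @ unit / np.linalg.norm(v), -1, 1))
            assert angle <= DEFAULT_CONE_HALF_ANGLE + 1e-9

    def test_zero_axis_is_fatal(self, vad_scores):
        with pytest.raises(ContractError):
            rank_terms_in_cone(vad_scores, (0, 0, 0))
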