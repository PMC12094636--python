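import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msgradient import plsgenes, synthetic
from msgradient.synthetic import (
    generate_clinical,
    generate_cohort,
    generate_expression,
    generate_sphere_parcellation,
    hierarchy_axis,
)


class TestParcellation:
    def test_default_split_unit_norms(self):
        p = generate_sphere_parcellation(152, 156, seed=1)
        assert p.n_regions == 308
        assert len(p.ids("left")) == 152 and len(p.ids("right")) == 156
        norms = np.linalg.norm(p.centroids, axis=1)
        assert np.abs(norms - 1).max() < 1e-9

    def test_hemisphere_sign_convention(self):
        p = generate_sphere_parcellation(4, 4, seed=7)
        assert p.n_regions == 8
        assert (p.centroids_of("left")[:, 0] < 0).all()
        assert (p.centroids_of("right")[:, 0] > 0).all()

    def test_seeded_determinism_byte_identical(self, tmp_path):
        a = generate_sphere_parcellation(152, 156, seed=1)
        b = generate_sphere_parcellation(152, 156, seed=1)
        assert a.table.to_csv() == b.table.to_csv()
        c = generate_sphere_parcellation(152, 156, seed=2)
        assert not a.table.equals(c.table)

    def test_too_small_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            generate_sphere_parcellation(3, 10, seed=0)

    def test_labels_spatially_coherent(self, parc):
        # azimuthal sectors: each Yeo label occupies a contiguous angle range
        left = parc.table[parc.table["hemisphere"] == "left"]
        phi = np.mod(np.arctan2(left["z"], left["y"]), 2 * np.pi)
        for lab in left["yeo_label"].unique():
            vals = np.sort(phi[left["yeo_label"] == lab])
            assert vals.max() - vals.min() < 2 * np.pi / 7 + 1e-9


class TestCohort:
    def test_null_effect_cell_level_calibration(self):
        """With effect_size=0 the groups are exchangeable: two-sample t at
        every region x feature cell rejects at the nominal rate."""
        rejections, total = 0, 0
        for seed in range(5):
            p = generate_sphere_parcellation(30, 32, seed=seed)
            ft, _ = generate_cohort(p, n_per_group=20, effect_size=0.0, seed=seed)
            a = ft.values[:20].reshape(20, -1)
            b = ft.values[20:].reshape(20, -1)
            pv = stats.ttest_ind(a, b, axis=0).pvalue
            rejections += (pv < 0.05).sum()
            total += pv.size
        rate = rejections / total
        assert 0.035 < rate < 0.065

    def test_zero_noise_degeneracy(self, parc):
        ft, _ = generate_cohort(parc, n_per_group=3, noise_sd=0.0, seed=0)
        assert np.allclose(ft.values[0], ft.values[1])
        assert np.allclose(ft.values[3], ft.values[4])

    def test_seeded_determinism(self, parc):
        a, _ = generate_cohort(parc, n_per_group=5, seed=9)
        b, _ = generate_cohort(parc, n_per_group=5, seed=9)
        assert np.array_equal(a.values, b.values)
        assert a.subjects.equals(b.subjects)

    def test_saturated_effect_warns(self, parc):
        with pytest.warns(UserWarning, match="saturated"):
            generate_cohort(
                parc,
                n_per_group=3,
                effect_regions=(parc.region_ids[0],),
                effect_size=11.0,
                seed=0,
            )

    def test_effect_region_validation(self, parc):
        with pytest.raises(ValueError, match="effect_regions"):
            generate_cohort(parc, n_per_group=3, effect_regions=("nope",), seed=0)

    def test_planted_shift_magnitude(self, parc):
        """RMS per-feature mean shift in effect regions ~ effect_size * noise_sd."""
        region = parc.region_ids[5]
        base, _ = generate_cohort(parc, n_per_group=200, noise_sd=0.3, seed=4)
        shifted, _ = generate_cohort(
            parc, n_per_group=200, effect_regions=(region,), effect_size=0.8,
            noise_sd=0.3, seed=4,
        )
        i = parc.region_ids.index(region)
        delta = shifted.values[200:, i, :].mean(0) - base.values[200:, i, :].mean(0)
        rms = np.sqrt((delta**2).mean())
        assert rms == pytest.approx(0.8 * 0.3, rel=0.15)


class TestExpression:
    def test_validation_errors(self, parc):
        t = pd.Series(np.arange(30, dtype=float), index=parc.ids("left"))
        with pytest.raises(ValueError, match="smoothness"):
            generate_expression(parc, t, smoothness=0.0)
        with pytest.raises(ValueError, match="n_coupled"):
            generate_expression(parc, t, n_genes=10, n_coupled=11)
        with pytest.raises(ValueError, match="left-hemisphere"):
            generate_expression(parc, t.iloc[:10])

    def test_seeded_determinism(self, parc):
        t = pd.Series(np.random.default_rng(0).standard_normal(30),
                      index=parc.ids("left"))
        a, _ = generate_expression(parc, t, n_genes=50, n_coupled=10, seed=3)
        b, _ = generate_expression(parc, t, n_genes=50, n_coupled=10, seed=3)
        assert a.equals(b)

    def test_all_coupled_strong_coupling_saturates_pls1(self, parc):
        t = pd.Series(np.random.default_rng(1).standard_normal(30),
                      index=parc.ids("left"))
        expr, _ = generate_expression(
            parc, t, n_genes=40, n_coupled=40, coupling=50.0, seed=2
        )
        fit = plsgenes.pls_fit(expr, t, n_components=1)
        assert fit.explained_variance_y[0] > 0.99

    def test_null_mean_abs_correlation(self, parc):
        """coupling=0: mean |r(gene, tmap)| matches the white-map expectation
        sqrt(2/(pi (n-1))) because the target map is independent noise."""
        n = 30
        t = pd.Series(np.random.default_rng(5).standard_normal(n),
                      index=parc.ids("left"))
        expr, _ = generate_expression(parc, t, n_genes=400, coupling=0.0, seed=6)
        r = np.array([np.corrcoef(expr[g], t)[0, 1] for g in expr.columns])
        expected = np.sqrt(2 / (np.pi * (n - 1)))
        assert np.mean(np.abs(r)) == pytest.approx(expected, rel=0.15)


class TestClinical:
    def test_noiseless_one_hot_rank_correlation(self, parc, rng):
        grads = pd.DataFrame(
            rng.standard_normal((40, parc.n_regions)),
            index=[f"s{i}" for i in range(40)],
            columns=parc.region_ids,
        )
        region = parc.region_ids[3]
        loadings = pd.DataFrame(
            [[1.0]], index=["positive"], columns=[region]
        )
        scores, _ = generate_clinical(grads, loadings, noise_sd=0.0, seed=0)
        rho = stats.spearmanr(scores["positive"], grads[region]).statistic
        assert rho > 0.99

    def test_zero_loading_factor_rejected(self, parc, rng):
        grads = pd.DataFrame(
            rng.standard_normal((10, parc.n_regions)), columns=parc.region_ids
        )
        loadings = pd.DataFrame(
            np.zeros((1, parc.n_regions)), index=["negative"],
            columns=parc.region_ids,
        )
        with pytest.raises(ValueError, match="nonzero loading"):
            generate_clinical(grads, loadings, seed=0)

    def test_seeded_determinism_and_range(self, parc, rng):
        grads = pd.DataFrame(
            rng.standard_normal((25, parc.n_regions)), columns=parc.region_ids
        )
        loadings = pd.DataFrame(
            rng.standard_normal((5, parc.n_regions)),
            index=list(synthetic.FACTOR_NAMES),
            columns=parc.region_ids,
        )
        a, _ = generate_clinical(grads, loadings, seed=1)
        b, _ = generate_clinical(grads, loadings, seed=1)
        assert a.equals(b)
        assert a.to_numpy().min() >= 7 and a.to_numpy().max() <= 49


def test_hierarchy_axis_is_standardized_geometry(parc):
    g = hierarchy_axis(parc)
    assert abs(g.mean()) < 1e-10
    assert g.std(ddof=1) == pytest.approx(1.0)
    # monotone in the superior-inferior coordinate
    z = parc.table["z"]
    assert np.corrcoef(g, z)[0, 1] > 0.999999
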