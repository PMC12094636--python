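import numpy as np
import pandas as pd
import pytest

from msgradient._pls import PLSResult
from msgradient.plsclinical import (
    fit_clinical_pls,
    load_default_factor_mapping,
    panss_five_factors,
    top_regions_per_factor,
    vip_scores,
)

from ._oracles import pls2_power_oracle, vip_by_hand


def _xy(rng, n=40, p=12, q=5, noise=0.3):
    x = pd.DataFrame(
        rng.standard_normal((n, p)),
        index=[f"scz{i:04d}" for i in range(n)],
        columns=[f"lh_{j:04d}" for j in range(p)],
    )
    b = rng.standard_normal((p, q))
    y = pd.DataFrame(
        x.to_numpy() @ b + noise * rng.standard_normal((n, q)),
        index=x.index,
        columns=["positive", "negative", "disorganized", "excited", "depressed"],
    )
    return x, y


class TestPANSSFactors:
    def test_floor_of_scale(self):
        mapping = load_default_factor_mapping()
        items = pd.DataFrame(
            1, index=["a", "b"], columns=sorted(mapping["item"].unique())
        )
        out = panss_five_factors(items, mapping)
        counts = mapping.groupby("factor")["item"].count()
        for factor, count in counts.items():
            assert (out[factor] == count).all()

    def test_hand_summed_fixture(self):
        """Wallwork mapping on explicit item scores, checked against sums
        computed by hand."""
        items = pd.DataFrame(
            {
                # positive items: P1, P3, P5, G9
                "P1": [4, 1], "P3": [2, 7], "P5": [1, 2], "G9": [3, 1],
                # negative: N1, N2, N3, N4, N6, G7
                "N1": [5, 1], "N2": [2, 2], "N3": [1, 3], "N4": [2, 1],
                "N6": [3, 1], "G7": [1, 2],
                # disorganized: P2, N5, G11
                "P2": [6, 1], "N5": [2, 2], "G11": [1, 1],
                # excited: P4, P7, G8, G14
                "P4": [1, 4], "P7": [2, 1], "G8": [1, 1], "G14": [3, 2],
                # depressed: G2, G3, G6
                "G2": [4, 2], "G3": [1, 1], "G6": [2, 5],
            },
            index=["s1", "s2"],
        )
        out = panss_five_factors(items)
        assert out.loc["s1", "positive"] == 4 + 2 + 1 + 3
        assert out.loc["s2", "positive"] == 1 + 7 + 2 + 1
        assert out.loc["s1", "negative"] == 5 + 2 + 1 + 2 + 3 + 1
        assert out.loc["s1", "disorganized"] == 6 + 2 + 1
        assert out.loc["s2", "excited"] == 4 + 1 + 1 + 2
        assert out.loc["s1", "depressed"] == 4 + 1 + 2
        assert out.loc["s1", "total"] == items.loc["s1"].sum()

    def test_out_of_range_item_rejected(self):
        mapping = load_default_factor_mapping()
        items = pd.DataFrame(
            8, index=["a"], columns=sorted(mapping["item"].unique())
        )
        with pytest.raises(ValueError, match="1-7"):
            panss_five_factors(items, mapping)

    def test_single_item_factors_identity(self):
        mapping = pd.DataFrame({"item": ["P1", "N1"], "factor": ["pos", "neg"]})
        items = pd.DataFrame({"P1": [3, 5], "N1": [2, 6]}, index=["a", "b"])
        out = panss_five_factors(items, mapping)
        assert (out["pos"] == items["P1"]).all()
        assert (out["neg"] == items["N1"]).all()


class TestClinicalPLS:
    def test_exact_fit_limit(self, rng):
        x, _ = _xy(rng, n=30, p=6)
        b = rng.standard_normal((6, 2))
        y = pd.DataFrame(x.to_numpy() @ b, index=x.index, columns=["f1", "f2"])
        fit = fit_clinical_pls(x, y, n_components=6)
        assert fit.cumulative_r2[-1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_two_block_power_oracle(self, rng):
        x = pd.DataFrame(
            np.random.default_rng(12).standard_normal((12, 6)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"r{j}" for j in range(6)],
        )
        y = pd.DataFrame(
            np.random.default_rng(13).standard_normal((12, 2)),
            index=x.index,
            columns=["f1", "f2"],
        )
        fit = fit_clinical_pls(x, y, n_components=2)
        xz = (x - x.mean()) / x.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        t_o, w_o, ev_o = pls2_power_oracle(xz.to_numpy(), yz.to_numpy(), 2)
        for a in range(2):
            sign = np.sign(fit.x_weights[:, a] @ w_o[:, a])
            assert np.abs(fit.x_weights[:, a] - sign * w_o[:, a]).max() < 1e-8
            assert np.abs(fit.x_scores[:, a] - sign * t_o[:, a]).max() < 1e-8
        assert np.abs(fit.explained_variance_y - ev_o).max() < 1e-8

    def test_independent_response_at_permutation_null_level(self, rng):
        x, _ = _xy(rng, n=40, p=8)
        y = pd.DataFrame(
            rng.standard_normal((40, 3)), index=x.index, columns=list("abc")
        )
        fit = fit_clinical_pls(x, y, n_components=1)
        null_ev = []
        for _ in range(99):
            y_perm = y.sample(frac=1, random_state=rng.integers(2**31)).set_axis(
                y.index
            )
            null_ev.append(
                fit_clinical_pls(x, y_perm, n_components=1).explained_variance_y[0]
            )
        lo, hi = np.quantile(null_ev, [0.0, 1.0])
        assert lo * 0.5 <= fit.explained_variance_y[0] <= hi * 1.5

    def test_rank_bound_enforced(self, rng):
        x, y = _xy(rng, n=8, p=4)
        with pytest.raises(ValueError, match="rank"):
            fit_clinical_pls(x, y, n_components=6)

    def test_cv_component_choice_deterministic(self, rng):
        x, y = _xy(rng, n=30, p=10)
        a = fit_clinical_pls(x, y, n_components=None, seed=4)
        b = fit_clinical_pls(x, y, n_components=None, seed=4)
        assert a.n_components == b.n_components <= 5


class TestVIP:
    def _dummy_fit(self, weights, ss):
        weights = np.asarray(weights, float)
        p, a = weights.shape
        return PLSResult(
            n_components=a,
            x_scores=np.zeros((3, a)),
            x_weights=weights,
            x_loadings=weights,
            y_loadings=np.ones((1, a)),
            explained_variance_y=np.asarray(ss, float),
            predictor_names=tuple(f"r{i}" for i in range(p)),
            response_names=("f",),
            sample_names=("a", "b", "c"),
            x_mean=np.zeros(p),
            x_sd=np.ones(p),
            y_mean=np.zeros(1),
            y_sd=np.ones(1),
        )

    def test_one_hot_weight_closed_form(self):
        p = 6
        w = np.zeros((p, 1))
        w[2, 0] = 1.0
        vip = vip_scores(self._dummy_fit(w, [0.4]))
        assert vip.loc[2, "vip"] == pytest.approx(np.sqrt(p))
        assert vip.drop(index=2)["vip"].max() == 0

    def test_equal_weights_give_unit_vip(self):
        w = np.full((8, 1), -0.35)
        vip = vip_scores(self._dummy_fit(w, [0.2]))
        assert np.allclose(vip["vip"], 1.0)
        assert not vip["contributing"].any()

    def test_matches_formula_oracle(self, rng):
        x, y = _xy(rng, n=30, p=6)
        fit = fit_clinical_pls(x, y, n_components=3)
        vip = vip_scores(fit)
        hand = vip_by_hand(fit.x_weights, fit.explained_variance_y)
        assert np.abs(vip["vip"].to_numpy() - hand).max() < 1e-10

    def test_sum_of_squares_identity(self, rng):
        for n_comp in (1, 2, 4):
            x, y = _xy(rng, n=35, p=9)
            fit = fit_clinical_pls(x, y, n_components=n_comp)
            vip = vip_scores(fit)
            assert (vip["vip"] ** 2).sum() == pytest.approx(9, abs=1e-6)

    def test_factor_reordering_invariance(self, rng):
        x, y = _xy(rng, n=30, p=7)
        a = vip_scores(fit_clinical_pls(x, y, n_components=2))
        b = vip_scores(fit_clinical_pls(x, y[list(y.columns[::-1])], n_components=2))
        assert np.abs(a["vip"] - b["vip"]).max() < 1e-9

    def test_region_permutation_permutes_vip(self, rng):
        x, y = _xy(rng, n=30, p=7)
        perm = rng.permutation(7)
        a = vip_scores(fit_clinical_pls(x, y, n_components=2)).set_index("region_id")
        b = vip_scores(
            fit_clinical_pls(x.iloc[:, perm], y, n_components=2)
        ).set_index("region_id")
        assert np.abs(a["vip"] - b["vip"].loc[a.index]).max() < 1e-9

    def test_zero_explained_variance_rejected(self):
        fit = self._dummy_fit(np.ones((4, 1)), [0.0])
        with pytest.raises(ValueError, match="no explained"):
            vip_scores(fit)


class TestTopRegions:
    def test_planted_one_hot_region_ranks_first(self, rng):
        x, _ = _xy(rng, n=40, p=10)
        y = pd.DataFrame({"positive": x.iloc[:, 4]}, index=x.index)
        out = top_regions_per_factor(x, y, k=3, n_components=1)
        assert out["positive"].loc[0, "region_id"] == x.columns[4]

    def test_full_ranking_and_k_bound(self, rng):
        x, y = _xy(rng, n=30, p=6)
        out = top_regions_per_factor(x, y, k=6, n_components=2)
        assert len(out["total"]) == 6
        with pytest.raises(ValueError, match="exceeds"):
            top_regions_per_factor(x, y, k=7)

    def test_loaded_regions_recovered_in_top5(self, rng):
        """Three planted regions per factor surface in the top-5 VIP list."""
        hits = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            x = pd.DataFrame(
                r.standard_normal((60, 15)),
                index=[f"s{i}" for i in range(60)],
                columns=[f"lh_{j:04d}" for j in range(15)],
            )
            loaded = [1, 6, 11]
            signal = x.iloc[:, loaded].mean(axis=1)
            y = pd.DataFrame(
                {"positive": signal + 0.3 * r.standard_normal(60)}, index=x.index
            )
            out = top_regions_per_factor(x, y, k=5, n_components=1)
            top = set(out["positive"]["region_id"])
            hits += set(x.columns[loaded]) <= top
        assert hits >= 0.9 * reps
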