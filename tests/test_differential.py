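"""NB differential testing, BH correction, and divergence classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboscape.differential import (
    bh_adjust,
    classify_divergence,
    direction_summary,
    direction_totals,
    divergence_summary,
    dteg_test,
    fit_nb_glm,
    format_divergence_summary,
    nb_two_group_test,
    size_factors,
)

COLS = [f"s{i}" for i in range(6)]
GROUPS = pd.Series(["g1"] * 3 + ["g2"] * 3, index=COLS)


def _nb(rng, mean, phi):
    return rng.poisson(rng.gamma(1.0 / phi, np.asarray(mean) * phi))


def _bh_bruteforce(p):
    """Textbook step-up BH, computed the slow explicit way."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        out[i] = running
    return out


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_is_excluded(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], _bh_bruteforce([0.01, 0.02]))

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), _bh_bruteforce(p))

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_adjusted_values_dominate_raw_and_stay_rank_monotone(self, p):
        p = np.asarray(p)
        out = bh_adjust(p)
        assert ((out >= p - 1e-12) & (out <= 1.0)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(out[order]) >= -1e-12).all()


class TestNbGlmFit:
    def test_matches_statsmodels_at_fixed_dispersion(self, rng):
        """Dual route: vectorised IRLS vs statsmodels NB GLM, same alpha."""
        import statsmodels.api as sm

        Y = _nb(rng, np.full((15, 6), 150.0), 0.1).astype(float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        off = np.log(np.linspace(0.8, 1.2, 6))
        alpha = np.full(15, 0.1)
        beta, se, conv = fit_nb_glm(Y, X, np.broadcast_to(off, Y.shape), alpha)
        assert conv.all()
        for g in range(15):
            ref = sm.GLM(
                Y[g], X, family=sm.families.NegativeBinomial(alpha=0.1), offset=off
            ).fit()
            assert np.allclose(beta[g], ref.params, atol=1e-5)
            assert np.allclose(se[g], ref.bse, rtol=1e-4)


class TestNbTwoGroupTest:
    def test_identical_groups_give_null_result(self):
        Y = pd.DataFrame(
            np.tile([[100, 120, 80]], (5, 2)), index=[f"g{i}" for i in range(5)],
            columns=COLS,
        )
        res = nb_two_group_test(Y, GROUPS)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["p_value"] > 0.99).all()

    def test_all_zero_gene_flagged(self, rng):
        Y = pd.DataFrame(_nb(rng, np.full((10, 6), 50.0), 0.1), columns=COLS)
        Y.iloc[0] = 0
        res = nb_two_group_test(Y, GROUPS)
        assert res.iloc[0]["status"] == "all_zero"
        assert res.iloc[0]["p_value"] == 1.0 and res.iloc[0]["log2fc"] == 0.0

    def test_size_factors_median_of_ratios(self, rng):
        Y = pd.DataFrame(_nb(rng, np.full((500, 3), 200.0), 0.05), columns=list("abc"))
        Y["b"] *= 2
        sf = size_factors(Y)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=0.05)

    def test_sign_and_recovery_of_strong_effects(self, rng):
        sign = rng.choice([-1.0, 1.0], 200)
        mean = np.full((1000, 6), 500.0)
        mean[:200, 3:] *= 2.0 ** (2 * sign[:, None])
        Y = pd.DataFrame(_nb(rng, mean, 0.1), columns=COLS)
        res = nb_two_group_test(Y, GROUPS)
        assert (np.sign(res["log2fc"][:200]) == sign).mean() >= 0.99
        sig = (res["fdr"] < 0.05) & (res["log2fc"].abs() >= 1)
        assert sig[:200].mean() >= 0.9

    def test_agrees_with_pydeseq2_on_strong_effects(self, rng):
        """Independent oracle: DESeq2 (pydeseq2) on the same counts."""
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
        from scipy.stats import spearmanr

        sign = rng.choice([-1.0, 1.0], 60)
        mean = np.full((200, 6), 300.0)
        mean[:60, 3:] *= 4.0**sign[:, None]
        Y = pd.DataFrame(
            _nb(rng, mean, 0.1), columns=COLS, index=[f"g{i}" for i in range(200)]
        )
        meta = pd.DataFrame({"condition": GROUPS.to_numpy()}, index=COLS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=Y.T, metadata=meta, design="~condition", quiet=True)
            dds.deseq2()
            st = DeseqStats(dds, contrast=["condition", "g2", "g1"], quiet=True)
            st.summary()
        ref = st.results_df
        mine = nb_two_group_test(Y, GROUPS)
        rho = spearmanr(ref["log2FoldChange"], mine["log2fc"]).statistic
        assert rho > 0.99
        assert (
            np.sign(ref["log2FoldChange"][:60].to_numpy())
            == np.sign(mine["log2fc"][:60].to_numpy())
        ).all()


class TestDtegTest:
    def test_identical_shift_in_both_layers_cancels(self, rng):
        mean = np.full((300, 6), 300.0)
        mean[:, 3:] *= 4.0   # both layers shifted the same way
        rna = pd.DataFrame(_nb(rng, mean, 0.1), columns=COLS)
        ribo = pd.DataFrame(_nb(rng, mean, 0.1), columns=COLS)
        res = dteg_test(rna, ribo, GROUPS)
        # interaction is centred on zero (mean SE ~0.5 log2 units here)
        assert abs(res["log2fc"].mean()) < 0.1
        assert (res["p_value"] < 0.05).mean() < 0.08
        assert ((res["fdr"] < 0.05) & (res["log2fc"].abs() >= 1)).mean() < 0.02

    def test_ribo_only_shift_recovered(self, rng):
        aff = 300
        mean_r = np.full((600, 6), 500.0)
        sign = rng.choice([-1.0, 1.0], aff)
        mean_b = mean_r.copy()
        mean_b[:aff, 3:] *= 2.0 ** (2 * sign[:, None])
        rna = pd.DataFrame(_nb(rng, mean_r, 0.1), columns=COLS)
        ribo = pd.DataFrame(_nb(rng, mean_b, 0.1), columns=COLS)
        res = dteg_test(rna, ribo, GROUPS)
        sig = (res["fdr"] < 0.05) & (res["log2fc"].abs() >= 1)
        assert sig[:aff].mean() >= 0.85
        assert (np.sign(res["log2fc"][:aff]) == sign).mean() >= 0.99

    def test_zero_in_either_layer_flagged(self, rng):
        rna = pd.DataFrame(_nb(rng, np.full((5, 6), 50.0), 0.1), columns=COLS)
        ribo = rna.copy()
        ribo.iloc[2] = 0
        res = dteg_test(rna, ribo, GROUPS)
        assert res.iloc[2]["status"] == "all_zero"


class TestClassifyDivergence:
    def _diff(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "fdr"]).assign(
            p_value=lambda d: d["fdr"]
        )

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((2.0, 0.01), (1.5, 0.01), "Homodirection"),
            ((-1.2, 0.01), (1.3, 0.02), "Opposite"),
            ((2.0, 0.01), (0.2, 0.6), "Transcription"),
            ((0.2, 0.6), (2.0, 0.01), "Translation"),
            ((0.0, 1.0), (0.0, 1.0), "Unchanged"),
            ((1.0, 0.05), (0.0, 1.0), "Unchanged"),   # FDR not < threshold
            ((0.99, 0.01), (0.0, 1.0), "Unchanged"),  # |lfc| below threshold
        ],
    )
    def test_rule_table(self, a, b, expected):
        cat = classify_divergence(self._diff([a]), self._diff([b]))
        assert cat.iloc[0] == expected

    def test_partition_and_exclusion(self):
        a = self._diff([(2.0, 0.01), (0.0, 1.0)])
        b = self._diff([(2.0, 0.01)])
        cat = classify_divergence(a, b)
        assert len(cat) == 1   # gene present in one contrast only is excluded


class TestSummaries:
    def test_percentages_round_to_two_decimals(self):
        counts = {"Transcription": 1, "Unchanged": 2}
        s = divergence_summary(counts)
        assert s.loc["Transcription", "percent"] == 33.33
        assert s["count"].sum() == 3

    def test_formatted_output_shape(self):
        txt = format_divergence_summary({"Transcription": 5, "Unchanged": 5})
        assert txt.startswith("Transcription (50.00%, 5)")

    def test_direction_summary_counts(self):
        diff = pd.DataFrame(
            {"log2fc": [2.0, -3.0, 0.5, 1.5], "fdr": [0.01, 0.01, 0.01, 0.5]}
        )
        s = direction_summary(diff)
        assert s == {"up": 1, "down": 1, "total": 2}
        assert direction_totals(3, 4)["total"] == 7
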