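"""Control-gene size factors, dispersion estimation, the NB Wald engine, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bromoscreen import (
    Contrast,
    DeConfig,
    RnaSimConfig,
    bh_adjust,
    control_gene_size_factors,
    estimate_dispersions,
    high_confidence_sets,
    median_of_ratios_size_factors,
    run_de,
    simulate_counts,
    wald_test,
)
from bromoscreen.simulate import spikein_ids


def spike_rows(counts):
    return [r for r in counts.index if str(r).startswith("ERCC-")]


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self, tiny_counts):
        counts = pd.concat([tiny_counts[["s0"]]] * 3, axis=1)
        counts.columns = ["a", "b", "c"]
        factors = control_gene_size_factors(counts, spike_rows(counts))
        np.testing.assert_allclose(factors, 1.0)

    def test_doubled_sample_hand_example(self, tiny_counts):
        counts = tiny_counts[["s0"]].copy()
        counts["s1"] = counts["s0"] * 2
        factors = control_gene_size_factors(counts, spike_rows(counts))
        np.testing.assert_allclose(factors, [1 / np.sqrt(2), np.sqrt(2)])

    def test_zero_bearing_controls_excluded_from_reference(self, tiny_counts):
        counts = tiny_counts.copy()
        counts.loc["ERCC-00001", "s0"] = 0  # cannot contribute a geometric mean
        with_zero = control_gene_size_factors(counts, spike_rows(counts))
        without = control_gene_size_factors(
            counts.drop(index="ERCC-00001"), spike_rows(counts.drop(index="ERCC-00001"))
        )
        np.testing.assert_allclose(with_zero, without)

    def test_too_few_controls_rejected(self, tiny_counts):
        with pytest.raises(ValueError, match="control rows"):
            control_gene_size_factors(tiny_counts, ["ERCC-00001", "ERCC-00002"])

    @given(st.floats(min_value=0.25, max_value=4.0))
    def test_scale_equivariance(self, c):
        """Scaling one sample's counts by c scales its factor by c relative to the others."""
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(10, 500, (30, 3)).astype(float),
            index=[f"ERCC-{i:05d}" for i in range(30)],
            columns=["a", "b", "c"],
        )
        base = median_of_ratios_size_factors(counts)
        scaled_counts = counts.copy()
        scaled_counts["a"] = counts["a"] * c
        scaled = median_of_ratios_size_factors(scaled_counts)
        assert (scaled["a"] / scaled["b"]) / (base["a"] / base["b"]) == pytest.approx(c, rel=1e-9)


class TestDispersions:
    def _conditions(self, columns, n_a):
        return pd.Series(["a"] * n_a + ["b"] * (len(columns) - n_a), index=columns)

    def test_poisson_counts_yield_near_zero_dispersion(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (500, 20)), columns=[f"s{i}" for i in range(20)])
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf, self._conditions(counts.columns, 10))
        assert disp["final"].median() < 0.05

    def test_nb_dispersion_recovered_by_moments(self):
        rng = np.random.default_rng(1)
        mu, alpha = 100.0, 0.2
        lam = rng.gamma(1 / alpha, mu * alpha, size=(500, 20))
        counts = pd.DataFrame(rng.poisson(lam), columns=[f"s{i}" for i in range(20)])
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf, self._conditions(counts.columns, 10))
        assert 0.1 <= disp["mom"].median() <= 0.3

    def test_constant_counts_fall_to_floor(self):
        counts = pd.DataFrame(50, index=[f"g{i}" for i in range(20)], columns=list("abcd"))
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf, self._conditions(counts.columns, 2))
        np.testing.assert_allclose(disp["final"], DeConfig().dispersion_floor)

    def test_single_sample_condition_rejected(self):
        counts = pd.DataFrame(50, index=["g"], columns=list("abc"))
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            estimate_dispersions(counts, sf, pd.Series(["a", "a", "b"], index=counts.columns))


class TestWaldTest:
    def test_sign_convention_and_statsmodels_agreement(self):
        """Treated mean above control gives log2fc > 0; coefficients and SEs
        match an independent per-gene statsmodels NB GLM fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        control = rng.poisson(100, (5, 3))
        treated = rng.poisson(400, (5, 3))
        counts = pd.DataFrame(
            np.hstack([control, treated]),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(3)] + [f"t{i}" for i in range(3)],
        )
        sf = pd.Series(1.0, index=counts.columns)
        alpha = pd.Series(0.05, index=counts.index)
        contrast = Contrast(treated=("t0", "t1", "t2"), control=("c0", "c1", "c2"))
        result = wald_test(counts, sf, alpha, contrast)
        assert (result["log2fc"] > 0).all()

        design = sm.add_constant(np.array([0, 0, 0, 1, 1, 1], dtype=float))
        for gene in counts.index:
            fit = sm.GLM(
                counts.loc[gene].to_numpy(),
                design,
                family=sm.families.NegativeBinomial(alpha=0.05),
            ).fit()
            assert result.loc[gene, "log2fc"] == pytest.approx(fit.params[1] / np.log(2), abs=1e-4)
            assert result.loc[gene, "se"] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-3)

    def test_all_zero_genes_excluded_from_m(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(50, (10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        counts.iloc[0] = 0
        sf = pd.Series(1.0, index=counts.columns)
        alpha = pd.Series(0.1, index=counts.index)
        contrast = Contrast(treated=tuple(counts.columns[3:]), control=tuple(counts.columns[:3]))
        result = wald_test(counts, sf, alpha, contrast)
        assert np.isnan(result.iloc[0]["p"]) and np.isnan(result.iloc[0]["padj"])
        assert result.iloc[0]["direction"] == "ns"
        assert result["p"].notna().sum() == 9

    def test_agrees_with_pydeseq2_on_planted_effects(self):
        """External cross-check: planted log2FCs from an independent DE tool."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, truth, sheet = simulate_counts(
            RnaSimConfig(n_genes=300, seed=17, planted_de_fraction=0.2, depth_sd=0.0)
        )
        contrast = Contrast(
            treated=tuple(sheet.loc[sheet.condition == "treated", "sample_id"]),
            control=tuple(sheet.loc[sheet.condition == "DMSO", "sample_id"]),
        )
        mine = run_de(counts, contrast, DeConfig(control_ids=tuple(spikein_ids())))

        meta = sheet.set_index("sample_id")[["condition"]]
        dds = DeseqDataSet(
            counts=counts.T.astype(int), metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "treated", "DMSO"], quiet=True)
        stats.summary()
        theirs = stats.results_df

        planted = truth.index[truth["is_planted_de"] & (truth["baseline_mean"] >= 50)]
        diff = (mine.loc[planted, "log2fc"] - theirs.loc[planted, "log2FoldChange"]).abs()
        assert diff.median() < 0.25


class TestBhAdjust:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_nas_excluded_from_m(self):
        adjusted = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adjusted[1])
        np.testing.assert_allclose(adjusted[[0, 2]], bh_adjust([0.01, 0.02]))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
    def test_stepup_preserves_order_statistics(self, ps):
        adjusted = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
        assert np.all(adjusted >= np.asarray(ps) - 1e-12)


class TestHighConfidenceSets:
    @staticmethod
    def _table(genes, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2fc": lfc}, index=genes)

    def test_concordant_significant_genes_enter_sets(self):
        genes = ["g1", "g2", "g3", "g4"]
        a = self._table(genes, [0.01, 0.01, 0.5, 0.01], [-1, 2, -1, -1])
        b = self._table(genes, [0.02, 0.02, 0.01, 0.01], [-2, 1, -1, 1.5])
        up, down = high_confidence_sets({"lineA": a, "lineB": b})
        assert down == {"g1"}  # significant and down in both
        assert up == {"g2"}
        # g3: significant in one line only; g4: discordant directions
        assert "g3" not in down and "g4" not in down and "g4" not in up

    def test_mismatched_universes_intersected_with_warning(self, caplog):
        a = self._table(["g1", "g2"], [0.01, 0.01], [-1, -1])
        b = self._table(["g1", "g3"], [0.01, 0.01], [-1, -1])
        with caplog.at_level("WARNING"):
            _, down = high_confidence_sets({"a": a, "b": b})
        assert down == {"g1"}
        assert "universes differ" in caplog.text

    def test_requires_two_lines(self):
        with pytest.raises(ValueError, match=">= 2"):
            high_confidence_sets({"only": self._table(["g"], [0.01], [1])})
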