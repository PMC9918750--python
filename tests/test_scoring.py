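import logging

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

import siascore as s
from siascore.io import ExpressionMatrix
from siascore.scoring import (compute_is, compute_sia, rna_is_like, rna_sia,
                              sc_qc_filter, sc_sia)


class TestSIA:
    @pytest.mark.parametrize("cd8, m2, expected", [
        (100.0, 100.0, 0.5),
        (0.0, 50.0, 0.0),
        (50.0, 0.0, 1.0),
    ])
    def test_closed_form(self, cd8, m2, expected):
        assert compute_sia(cd8, m2) == expected

    def test_zero_zero_undefined(self):
        assert np.isnan(compute_sia(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_sia(-1.0, 2.0)

    def test_monotonicity(self):
        cd8 = np.linspace(1, 100, 50)
        sia = compute_sia(cd8, np.full(50, 20.0))
        assert (np.diff(sia) > 0).all()
        m2 = np.linspace(1, 100, 50)
        sia2 = compute_sia(np.full(50, 20.0), m2)
        assert (np.diff(sia2) < 0).all()


class TestIS:
    def _oracle(self, channels):
        """Independent rank-then-average implementation."""
        out = {}
        pct = {}
        for col in channels:
            v = channels[col].dropna()
            pct[col] = dict(zip(v.index, 100 * rankdata(v) / len(v)))
        for pid in channels.index:
            vals = [pct[c][pid] for c in channels if pid in pct[c]]
            out[pid] = np.mean(vals) if vals else np.nan
        return pd.Series(out)

    def test_five_patient_hand_cohort_matches_oracle(self):
        channels = pd.DataFrame({
            "cd3_centre": [120.0, 40.0, 300.0, np.nan, 80.0],
            "cd8_centre": [60.0, 10.0, 150.0, 90.0, 20.0],
            "cd3_margin": [200.0, 55.0, np.nan, 130.0, 95.0],
            "cd8_margin": [75.0, 5.0, 220.0, 140.0, np.nan],
        }, index=list("ABCDE"))
        result = compute_is(channels)
        expected = self._oracle(channels)
        pd.testing.assert_series_equal(result["IS"], expected,
                                       check_names=False)

    def test_top_patient_scores_100_high(self):
        channels = pd.DataFrame({
            "cd3": [1.0, 2.0, 10.0], "cd8": [3.0, 1.0, 9.0],
        }, index=list("abc"))
        res = compute_is(channels)
        assert res.loc["c", "IS"] == 100.0
        assert res.loc["c", "IS_category"] == "High"

    def test_boundary_25_is_low(self):
        res = compute_is(pd.DataFrame({"cd8": [1.0, 2.0, 3.0, 4.0]},
                                      index=list("abcd")))
        assert res.loc["a", "IS"] == 25.0
        assert res.loc["a", "IS_category"] == "Low"

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        channels = pd.DataFrame({
            "cd3": rng.gamma(2, 50, 20), "cd8": rng.gamma(2, 40, 20),
        })
        base = compute_is(channels)["IS"]
        warped = compute_is(channels.apply(lambda c: np.log1p(c) ** 3))["IS"]
        pd.testing.assert_series_equal(base, warped)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            compute_is(pd.DataFrame({"cd8": [1.0, 2.0]}))


def _bulk_matrix(data, obs=None):
    return ExpressionMatrix(pd.DataFrame(data).astype(float),
                            obs if obs is not None else pd.DataFrame())


class TestRnaSIA:
    def test_simple_ratio(self):
        mat = _bulk_matrix({"s1": {"CD8A": 10.0, "C1QA": 5.0}})
        assert rna_sia(mat).loc["s1"] == 2.0

    def test_duplicate_samples_averaged(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [10.0, 5.0], "s2": [20.0, 5.0]},
                         index=["CD8A", "C1QA"]),
            pd.DataFrame({"patient": ["p", "p"],
                          "timepoint": ["pre", "pre"]}, index=["s1", "s2"]),
        )
        assert rna_sia(mat).loc["p"] == 3.0

    def test_pre_therapy_filter(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [10.0, 5.0], "s2": [99.0, 1.0]},
                         index=["CD8A", "C1QA"]),
            pd.DataFrame({"patient": ["p", "p"],
                          "timepoint": ["pre-treatment", "on-treatment"]},
                         index=["s1", "s2"]),
        )
        assert rna_sia(mat).loc["p"] == 2.0

    def test_zero_denominator_sentinels(self):
        mat = _bulk_matrix({"s1": {"CD8A": 3.0, "C1QA": 0.0},
                            "s2": {"CD8A": 0.0, "C1QA": 0.0}})
        score = rna_sia(mat)
        assert np.isinf(score.loc["s1"])
        assert np.isnan(score.loc["s2"])

    def test_missing_gene_errors(self):
        mat = _bulk_matrix({"s1": {"CD8A": 1.0}})
        with pytest.raises(KeyError, match="C1QA"):
            rna_sia(mat)

    def test_scale_invariance_under_library_rescaling(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.gamma(2, 10, size=(2, 8)),
                            index=["CD8A", "C1QB"])
        base = rna_sia(ExpressionMatrix(vals.copy()), denominator="C1QB")
        scaled = rna_sia(ExpressionMatrix(vals * rng.uniform(0.1, 10, 8)),
                         denominator="C1QB")
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy())

    def test_noiseless_simulation_perfect_rank_agreement(self):
        spec = s.SimulationSpec(n_patients=40, expression_noise_sigma=0.0,
                                seed=9)
        gt = pd.DataFrame({
            "cd8_density": np.random.default_rng(9).gamma(2, 60, 40),
            "m2_density": np.random.default_rng(10).gamma(2, 30, 40),
        }, index=[f"P{i}" for i in range(40)])
        gt["sia_true"] = gt["cd8_density"] / (gt["cd8_density"] + gt["m2_density"])
        mat = s.simulate_bulk_expression(gt, spec)
        score = rna_sia(mat)
        rho, _ = spearmanr(score.loc[gt.index], gt["sia_true"])
        assert rho == pytest.approx(1.0)


class TestRnaISLike:
    def test_mean_of_two_genes(self):
        mat = _bulk_matrix({"s1": {"CD8A": 4.0, "CD3E": 6.0}})
        assert rna_is_like(mat).loc["s1"] == 5.0

    def test_identity_when_equal(self):
        mat = _bulk_matrix({"s1": {"CD8A": 7.0, "CD3E": 7.0}})
        assert rna_is_like(mat).loc["s1"] == 7.0

    def test_strictly_monotone_in_cd8a(self):
        cd8a = np.linspace(0, 10, 11)
        mat = ExpressionMatrix(pd.DataFrame(
            [cd8a, np.full(11, 3.0)], index=["CD8A", "CD3E"],
            columns=[f"s{i}" for i in range(11)]))
        assert (np.diff(rna_is_like(mat).to_numpy()) > 0).all()


@pytest.fixture(scope="module")
def sc_matrix():
    spec = s.SimulationSpec(cells_per_patient=300, seed=21)
    return spec, s.simulate_single_cell(spec, n_patients=8)


class TestSingleCell:
    def test_qc_boundary_conventions(self):
        counts = pd.DataFrame(
            np.zeros((300, 3)), index=[f"G{i}" for i in range(300)],
            columns=["a", "b", "c"],
        )
        counts.iloc[:249, 0] = 1.0   # 249 detected genes -> removed at 250
        counts.iloc[:250, 1] = 1.0   # exactly 250 -> kept
        counts.iloc[:100, 2] = 1.0   # 100 -> kept at threshold 100
        mat = ExpressionMatrix(counts)
        filtered, report = sc_qc_filter(mat, min_genes=250)
        assert list(filtered.values.columns) == ["b"]
        assert report["n_removed_min_genes"] == 2
        filtered, _ = sc_qc_filter(mat, min_genes=100)
        assert set(filtered.values.columns) == {"a", "b", "c"}

    def test_qc_removes_exactly_constructed_outliers(self, sc_matrix):
        spec, mat = sc_matrix
        filtered, report = sc_qc_filter(mat, min_genes=100, mito_ceiling=0.05)
        kept = set(filtered.values.columns)
        flagged = mat.obs.index[mat.obs["low_quality"] | mat.obs["high_mito"]]
        assert kept.isdisjoint(flagged)
        clean = mat.obs.index[~(mat.obs["low_quality"] | mat.obs["high_mito"])]
        assert len(kept) >= 0.99 * len(clean)

    def test_no_mito_genes_skips_filter(self, caplog):
        counts = pd.DataFrame(np.ones((5, 2)),
                              index=[f"G{i}" for i in range(5)],
                              columns=["a", "b"])
        with caplog.at_level(logging.WARNING, logger="siascore"):
            filtered, report = sc_qc_filter(ExpressionMatrix(counts),
                                            min_genes=1)
        assert report["n_removed_mito"] == 0
        assert any("skipped" in r.message for r in caplog.records)

    def test_sc_sia_arithmetic(self):
        counts = pd.DataFrame(
            0.0, index=["CD8A", "CD68", "CD163"],
            columns=[f"c{i}" for i in range(40)],
        )
        counts.loc["CD8A", counts.columns[:30]] = 2.0
        counts.loc[["CD68", "CD163"], counts.columns[30:]] = 1.0
        obs = pd.DataFrame({"patient": ["p"] * 40}, index=counts.columns)
        sia = sc_sia(ExpressionMatrix(counts, obs))
        assert sia.loc["p"] == 0.75

    def test_sc_sia_boundary_no_m2(self):
        counts = pd.DataFrame(
            {"c0": [1.0, 0.0, 0.0]}, index=["CD8A", "CD68", "CD163"])
        obs = pd.DataFrame({"patient": ["p"]}, index=["c0"])
        assert sc_sia(ExpressionMatrix(counts, obs)).loc["p"] == 1.0

    def test_sc_sia_matches_class_count_truth(self, sc_matrix):
        spec, mat = sc_matrix
        filtered, _ = sc_qc_filter(mat, min_genes=100)
        sia = sc_sia(filtered, m2_definition="CD68&CD163")
        obs = filtered.obs
        for pid, grp in obs.groupby("patient"):
            n_cd8 = (grp["true_class"] == "CD8 T cell").sum()
            n_m2 = (grp["true_class"] == "M2 macrophage").sum()
            truth = n_cd8 / (n_cd8 + n_m2)
            assert sia.loc[pid] == pytest.approx(truth, abs=0.05)

    def test_unknown_m2_definition_rejected(self, sc_matrix):
        _, mat = sc_matrix
        with pytest.raises(ValueError, match="M2 definition"):
            sc_sia(mat, m2_definition="CD68&ACTB")
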