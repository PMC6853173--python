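import numpy as np
import pandas as pd
import pytest

from xsub import scoring, signatures, synthetic
from xsub.errors import XsubError
from xsub.scoring import (
    NOTCH_PANEL,
    center_by_batch,
    classify_by_correlation,
    correlation_score_samples,
    infiltration_scores,
    median_stratify,
    model_subtype_correlation,
    panel_sum_score,
    zscore_by_gene,
)
from xsub.signatures import GeneSignature


def random_expr(rng, n_genes=30, n_samples=12, prefix="g"):
    return pd.DataFrame(
        rng.normal(5, 2, size=(n_genes, n_samples)),
        index=pd.Index([f"{prefix}{i:03d}" for i in range(n_genes)], name="gene"),
        columns=[f"s{i:02d}" for i in range(n_samples)],
    )


class TestZscoreByGene:
    def test_three_point_row(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        z = zscore_by_gene(expr)
        np.testing.assert_allclose(z.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_row_becomes_zero(self, caplog):
        expr = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=["a", "b", "c"])
        with caplog.at_level("WARNING", logger="xsub.scoring"):
            z = zscore_by_gene(expr)
        assert (z.loc["g"] == 0).all()
        assert "zero-variance" in caplog.text

    def test_rows_standardized(self, rng):
        z = zscore_by_gene(random_expr(rng))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(XsubError):
            zscore_by_gene(pd.DataFrame([[1.0]], index=["g"], columns=["s"]))


class TestPanelSumScore:
    def test_equals_zsum_oracle(self, rng):
        expr = random_expr(rng, n_genes=3, n_samples=4)
        scores = panel_sum_score(expr, list(expr.index))
        # direct computation: column sums of the row-z matrix
        z = (expr.sub(expr.mean(axis=1), axis=0)).div(expr.std(axis=1, ddof=1), axis=0)
        np.testing.assert_allclose(scores, z.sum(axis=0), atol=1e-12)

    def test_cohort_mean_zero(self, rng):
        expr = random_expr(rng, n_genes=20)
        scores = panel_sum_score(expr, list(expr.index[:10]))
        assert abs(scores.mean()) < 1e-10

    def test_missing_panel_gene_dropped_with_warning(self, rng, caplog):
        expr = random_expr(rng, n_genes=13, prefix="NG")
        expr.index = list(NOTCH_PANEL[:13])  # HES2 absent when panel has 14 genes
        with caplog.at_level("WARNING", logger="xsub.scoring"):
            scores = panel_sum_score(expr, NOTCH_PANEL, name="notch")
        assert "1 panel gene(s) absent" in caplog.text
        assert len(scores) == expr.shape[1]

    def test_no_gene_present_is_error(self, rng):
        expr = random_expr(rng)
        with pytest.raises(XsubError, match="no panel gene"):
            panel_sum_score(expr, ["ABSENT1", "ABSENT2"])

    def test_signed_panel(self, rng):
        expr = random_expr(rng, n_genes=2)
        genes = list(expr.index)
        plus = panel_sum_score(expr, genes)
        mixed = panel_sum_score(expr, genes, signs={genes[1]: -1.0})
        z = zscore_by_gene(expr)
        np.testing.assert_allclose(mixed, z.iloc[0] - z.iloc[1], atol=1e-12)
        assert not np.allclose(plus, mixed)


class TestMedianStratify:
    def test_strictly_above_median_is_high(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = median_stratify(scores)
        assert list(groups) == ["low", "low", "high", "high"]

    def test_all_equal_scores_all_low(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        assert (median_stratify(scores) == "low").all()

    def test_within_stratum_medians_match_brute_force(self, rng):
        scores = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        strata = pd.Series(
            ["mut" if i % 2 else "wt" for i in range(40)], index=scores.index
        )
        groups = median_stratify(scores, strata=strata)
        for label in ("mut", "wt"):
            idx = strata.index[strata == label]
            med = np.median(scores.loc[idx])
            expected = np.where(scores.loc[idx] > med, "high", "low")
            np.testing.assert_array_equal(groups.loc[idx].to_numpy(), expected)


class TestCorrelationScoreSamples:
    def _signature(self, genes, weights):
        return GeneSignature(name="sig", genes=list(genes), weights=np.asarray(weights))

    def test_sample_proportional_to_weights_scores_one(self, rng):
        weights = rng.normal(size=10)
        genes = [f"g{i}" for i in range(10)]
        base = rng.normal(5, 1, size=(10, 3))
        expr = pd.DataFrame(base, index=genes, columns=["s1", "s2", "s3"])
        # make s1's centred profile an affine image of the weights
        expr["s1"] = expr[["s2", "s3"]].mean(axis=1) + 3.0 * weights
        scores = correlation_score_samples(expr, self._signature(genes, weights))
        assert scores["s1"] > 0.9

    def test_exact_pearson_oracle(self, rng):
        genes = [f"g{i}" for i in range(200)]
        expr = pd.DataFrame(
            rng.normal(size=(200, 8)), index=genes, columns=[f"s{i}" for i in range(8)]
        )
        weights = rng.normal(size=200)
        scores = correlation_score_samples(expr, self._signature(genes, weights))
        centred = expr.sub(expr.mean(axis=1), axis=0)
        for s in expr.columns:
            r = np.corrcoef(centred[s], weights)[0, 1]
            assert scores[s] == pytest.approx(r, abs=1e-12)

    def test_negated_profile_negates_score(self, rng):
        genes = [f"g{i}" for i in range(50)]
        expr = pd.DataFrame(
            rng.normal(size=(50, 4)), index=genes, columns=list("abcd")
        )
        weights = rng.normal(size=50)
        sig_pos = self._signature(genes, weights)
        sig_neg = self._signature(genes, -weights)
        np.testing.assert_allclose(
            correlation_score_samples(expr, sig_pos),
            -correlation_score_samples(expr, sig_neg),
            atol=1e-12,
        )

    def test_affine_weight_rescaling_invariance(self, rng):
        genes = [f"g{i}" for i in range(60)]
        expr = pd.DataFrame(
            rng.normal(size=(60, 5)), index=genes, columns=[f"s{i}" for i in range(5)]
        )
        weights = rng.normal(size=60)
        a = correlation_score_samples(expr, self._signature(genes, weights))
        b = correlation_score_samples(expr, self._signature(genes, 2.5 * weights + 1.0))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_too_few_overlapping_genes(self, rng):
        expr = random_expr(rng)
        sig = self._signature(["x1", "x2", expr.index[0]], [1.0, 2.0, 3.0])
        with pytest.raises(XsubError, match=">=3"):
            correlation_score_samples(expr, sig)


class TestClassifyByCorrelation:
    @pytest.mark.parametrize(
        "score, mode, expected",
        [
            (0.15, "two_group", "high"),
            (0.10, "two_group", "low"),
            (0.15, "three_group", "positive"),
            (0.05, "three_group", "unassigned"),
            (-0.2, "three_group", "negative"),
        ],
    )
    def test_threshold_rules(self, score, mode, expected):
        labels = classify_by_correlation(pd.Series([score], index=["s"]), mode=mode)
        assert labels["s"] == expected

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(XsubError):
            classify_by_correlation(
                pd.Series([0.0], index=["s"]), pos_threshold=-0.1, neg_threshold=0.1
            )


class TestModelSubtypeCorrelation:
    def test_model_equal_to_column_scores_one(self, subtype_de):
        template = signatures.build_subtype_templates(subtype_de, 75, 0.75)
        de = pd.DataFrame(
            {
                "log_fc": template.weights["CMS2"],
                "p_value": 0.001,
                "p_adj": 0.01,
            }
        )
        de.index.name = "gene"
        r, n = model_subtype_correlation({"clone": de}, template)
        assert r.loc["clone", "CMS2"] == pytest.approx(1.0)
        assert r.loc["clone"].idxmax() == "CMS2"
        assert (n.loc["clone"] == len(template.genes)).all()

    def test_planted_model_argmax_is_target(self, small_cohort, subtype_de):
        cfg, _, _ = small_cohort
        template = signatures.build_subtype_templates(subtype_de, 75, 0.75)
        mouse = synthetic.simulate_mouse_profiles(
            synthetic.MouseSimConfig(target_subtype="CMS4", overlap_fraction=1.0, seed=0),
            cfg.blocks(),
            gene_universe=cfg.genes,
        )
        r, _ = model_subtype_correlation({"KPN": mouse}, template)
        assert r.loc["KPN"].idxmax() == "CMS4"

    def test_cells_match_pearson_oracle_on_shared_genes(self, rng, subtype_de):
        template = signatures.build_subtype_templates(subtype_de, 75, 0.75)
        # model covers a random subset of the template genes
        subset = list(rng.choice(template.genes, size=120, replace=False))
        de = pd.DataFrame(
            {"log_fc": rng.normal(size=120), "p_value": 0.5, "p_adj": 0.5},
            index=pd.Index(subset, name="gene"),
        )
        r, n = model_subtype_correlation({"m": de}, template)
        shared = [g for g in template.genes if g in de.index]
        for subtype in template.subtypes:
            expected = np.corrcoef(
                de.loc[shared, "log_fc"], template.weights.loc[shared, subtype]
            )[0, 1]
            assert r.loc["m", subtype] == pytest.approx(expected, abs=1e-12)
            assert n.loc["m", subtype] == len(shared)

    def test_insufficient_overlap_names_model(self, subtype_de):
        template = signatures.build_subtype_templates(subtype_de, 75, 0.75)
        de = pd.DataFrame(
            {"log_fc": [1.0, 2.0], "p_value": [0.1, 0.1], "p_adj": [0.1, 0.1]},
            index=pd.Index(["zzz1", "zzz2"], name="gene"),
        )
        with pytest.raises(XsubError, match="tiny"):
            model_subtype_correlation({"tiny": de}, template)


class TestInfiltrationScores:
    def test_mean_then_z_oracle(self, rng):
        expr = random_expr(rng, n_genes=30, n_samples=10)
        sets = {
            "Tcell": list(expr.index[:5]),
            "Bcell": list(expr.index[5:12]),
            "Neutrophil": list(expr.index[12:20]),
        }
        scores = infiltration_scores(expr, sets)
        for celltype, markers in sets.items():
            raw = expr.loc[markers].mean(axis=0)
            z = (raw - raw.mean()) / raw.std(ddof=1)
            np.testing.assert_allclose(scores.loc[celltype], z, atol=1e-12)

    def test_single_marker_set_reduces_to_gene_z_row(self, rng):
        expr = random_expr(rng, n_genes=5, n_samples=8)
        g = expr.index[2]
        scores = infiltration_scores(expr, {"only": [g]})
        np.testing.assert_allclose(scores.loc["only"], zscore_by_gene(expr).loc[g], atol=1e-12)

    def test_empty_overlap_names_set(self, rng):
        expr = random_expr(rng)
        with pytest.raises(XsubError, match="ghost"):
            infiltration_scores(expr, {"ghost": ["ABSENT"]})

    def test_constant_matrix_all_zero(self):
        expr = pd.DataFrame(
            np.full((4, 6), 3.0),
            index=[f"g{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        scores = infiltration_scores(expr, {"ct": ["g0", "g1"]})
        assert (scores.to_numpy() == 0).all()


class TestCenterByBatch:
    def test_single_batch_identity(self, rng):
        expr = random_expr(rng)
        batches = pd.Series("b1", index=expr.columns)
        out = center_by_batch(expr, batches)
        np.testing.assert_allclose(out, expr, atol=1e-12)

    def test_additive_offset_removed_and_means_preserved(self, rng):
        expr = random_expr(rng, n_samples=10)
        batches = pd.Series(["b1"] * 5 + ["b2"] * 5, index=expr.columns)
        shifted = expr.copy()
        shifted.iloc[:, 5:] += 4.0
        out = center_by_batch(shifted, batches)
        gap = out.iloc[:, :5].mean(axis=1) - out.iloc[:, 5:].mean(axis=1)
        np.testing.assert_allclose(gap, 0.0, atol=1e-10)
        np.testing.assert_allclose(out.mean(axis=1), shifted.mean(axis=1), atol=1e-10)

    def test_singleton_batch_rejected(self, rng):
        expr = random_expr(rng, n_samples=3)
        batches = pd.Series(["b1", "b1", "b2"], index=expr.columns)
        with pytest.raises(XsubError, match="singleton"):
            center_by_batch(expr, batches)
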