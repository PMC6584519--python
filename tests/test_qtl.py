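"""Scan engine checks against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import methmed as mm
from methmed.qtl import ScanConfig, bh_fdr, cis_pairs, fit_pair, run_scan, significant_pairs


def _point_ann(ids, chroms, positions):
    return pd.DataFrame(
        {
            "feature_id": ids,
            "feature_class": "snp",
            "chrom": chroms,
            "pos": positions,
            "tss": np.nan,
            "tes": np.nan,
        }
    )


def _interval_ann(ids, chroms, tss, tes):
    return pd.DataFrame(
        {
            "feature_id": ids,
            "feature_class": "transcript",
            "chrom": chroms,
            "pos": np.nan,
            "tss": tss,
            "tes": tes,
        }
    )


def brute_force_pairs(pred, resp, cfg):
    """Exhaustive double loop over all predictor x response combinations."""
    w = cfg.cis_window_bp
    out = set()
    for _, a in pred.iterrows():
        for _, b in resp.iterrows():
            if a["chrom"] != b["chrom"]:
                continue
            if cfg.pair_type == "meqtl":
                if abs(a["pos"] - b["pos"]) <= w:
                    out.add((a["feature_id"], b["feature_id"]))
            else:
                if b["tss"] - w <= a["pos"] <= b["tes"] + w:
                    out.add((a["feature_id"], b["feature_id"]))
    return out


class TestCisPairs:
    def test_boundary_inclusive_point_point(self):
        pred = _point_ann(
            ["s1", "s2", "s3"], ["chr1"] * 3, [1_500_000, 3_400_001, 3_400_000]
        )
        resp = _point_ann(["c1"], ["chr1"], [2_400_000]).assign(feature_class="cpg")
        pairs = cis_pairs(pred, resp, ScanConfig("meqtl"))
        # 900 kb and exactly 1 Mb pair; 1 Mb + 1 bp does not
        assert set(pairs.a_id) == {"s1", "s3"}
        d = dict(zip(pairs.a_id, pairs.distance_bp))
        assert d["s1"] == -900_000 and d["s3"] == 1_000_000

    def test_different_chromosomes_not_paired(self):
        pred = _point_ann(["s1"], ["chr1"], [100])
        resp = _point_ann(["c1", "c2"], ["chr2", "chr1"], [200, 300]).assign(
            feature_class="cpg"
        )
        pairs = cis_pairs(pred, resp, ScanConfig("meqtl"))
        assert list(pairs.b_id) == ["c2"]

    def test_interval_distance_zero_when_overlapping(self):
        pred = _point_ann(["s1", "s2", "s3"], ["chr1"] * 3, [5_000, 2_000, 9_000])
        resp = _interval_ann(["t1"], ["chr1"], [4_000], [6_000])
        pairs = cis_pairs(pred, resp, ScanConfig("eqtl", cis_window_bp=10_000))
        d = dict(zip(pairs.a_id, pairs.distance_bp))
        assert d == {"s1": 0, "s2": -2_000, "s3": 3_000}

    def test_chrom_mismatch_error(self):
        pred = _point_ann(["s1"], ["1"], [100])
        resp = _point_ann(["c1"], ["chr1"], [200]).assign(feature_class="cpg")
        with pytest.raises(ValueError, match="chr"):
            cis_pairs(pred, resp, ScanConfig("meqtl"))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("pair_type", ["meqtl", "eqtl"])
    def test_matches_brute_force_on_random_layouts(self, seed, pair_type):
        rng = np.random.default_rng(seed)
        chroms = [f"chr{c}" for c in rng.integers(1, 4, 200)]
        pred = _point_ann(
            [f"s{i}" for i in range(200)], chroms, rng.integers(1, 30_000_000, 200)
        )
        rchroms = [f"chr{c}" for c in rng.integers(1, 4, 100)]
        if pair_type == "meqtl":
            resp = _point_ann(
                [f"c{i}" for i in range(100)], rchroms, rng.integers(1, 30_000_000, 100)
            ).assign(feature_class="cpg")
        else:
            tss = rng.integers(1, 30_000_000, 100)
            resp = _interval_ann(
                [f"t{i}" for i in range(100)], rchroms, tss, tss + rng.integers(1_000, 200_000, 100)
            )
        cfg = ScanConfig(pair_type)
        got = cis_pairs(pred, resp, cfg)
        assert set(zip(got.a_id, got.b_id)) == brute_force_pairs(pred, resp, cfg)

    def test_sorted_by_response_then_predictor(self):
        rng = np.random.default_rng(1)
        pred = _point_ann([f"s{i}" for i in range(50)], ["chr1"] * 50, rng.integers(1, 3_000_000, 50))
        resp = _point_ann([f"c{i}" for i in range(20)], ["chr1"] * 20, rng.integers(1, 3_000_000, 20)).assign(feature_class="cpg")
        pairs = cis_pairs(pred, resp, ScanConfig("meqtl"))
        pos_b = resp.set_index("feature_id")["pos"]
        pos_a = pred.set_index("feature_id")["pos"]
        keys = [(pos_b[b], pos_a[a]) for a, b in zip(pairs.a_id, pairs.b_id)]
        assert keys == sorted(keys)


class TestFitPair:
    def test_perfect_linear_fit(self, covariates_30):
        cov = covariates_30.iloc[:10]
        x = np.arange(10, dtype=float)
        y = 2 * x + 1
        res = fit_pair(x, y, cov)
        assert res["beta_hat"] == pytest.approx(2.0, abs=1e-10)
        assert res["p_value"] < 1e-12

    def test_constant_predictor_convention(self, covariates_30):
        res = fit_pair(np.ones(30), np.random.default_rng(0).normal(size=30), covariates_30)
        assert res["degenerate"] and res["p_value"] == 1.0

    def test_too_few_observations(self, covariates_30):
        x = np.full(30, np.nan)
        x[:4] = [0, 1, 2, 1]
        with pytest.raises(ValueError):
            fit_pair(x, np.zeros(30), covariates_30)

    def test_pairwise_deletion_of_missing_genotypes(self, covariates_30):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 30).astype(float)
        y = 0.5 * x + rng.normal(size=30)
        x_miss = x.copy()
        x_miss[[2, 11, 17]] = np.nan
        res = fit_pair(x_miss, y, covariates_30)
        assert res["n_used"] == 27
        keep = ~np.isnan(x_miss)
        X = sm.add_constant(
            np.column_stack(
                [x[keep], covariates_30.age[keep], covariates_30.disease_status[keep]]
            )
        )
        ref = sm.OLS(y[keep], X).fit()
        assert res["beta_hat"] == pytest.approx(ref.params[1], rel=1e-10)
        assert res["p_value"] == pytest.approx(ref.pvalues[1], rel=1e-8)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_statsmodels_oracle(self, seed, covariates_30):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 30).astype(float)
        y = rng.normal(size=30) + 0.3 * x
        res = fit_pair(x, y, covariates_30)
        X = sm.add_constant(
            np.column_stack([x, covariates_30.age, covariates_30.disease_status])
        )
        ref = sm.OLS(y, X).fit()
        assert res["beta_hat"] == pytest.approx(ref.params[1], rel=1e-8)
        assert res["se"] == pytest.approx(ref.bse[1], rel=1e-8)
        assert res["t_stat"] == pytest.approx(ref.tvalues[1], rel=1e-8)
        assert res["p_value"] == pytest.approx(ref.pvalues[1], rel=1e-8)


def stepup_oracle(p):
    """Literal BH step-up definition: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.9]), [0.04, 0.04, 0.04, 0.9]
        )

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 400))
        np.testing.assert_allclose(bh_fdr(p), stepup_oracle(p), rtol=1e-12)


class TestRunScan:
    def _scan(self, data, pair_type="meqtl", **kwargs):
        ann = data.annotation
        cls = {
            "meqtl": ("snp", "cpg", data.genotypes, data.methylation),
            "eqtm": ("cpg", "transcript", data.methylation, data.expression),
            "eqtl": ("snp", "transcript", data.genotypes, data.expression),
        }
        pc, rc, pred, resp = cls[pair_type]
        return run_scan(
            pred,
            resp,
            ann[ann.feature_class == pc],
            ann[ann.feature_class == rc],
            data.covariates,
            ScanConfig(pair_type, **kwargs),
        )

    def test_planted_meqtls_recovered(self, mixed_dataset):
        results, summary = self._scan(mixed_dataset)
        sig = significant_pairs(results)
        truth = mixed_dataset.truth
        planted = truth[truth.beta_lg != 0]
        hits = set(zip(sig.a_id, sig.b_id)) & set(zip(planted.snp_id, planted.cpg_id))
        assert len(hits) >= 0.9 * len(planted)

    def test_summary_unique_counts_consistent(self, mixed_dataset):
        results, summary = self._scan(mixed_dataset)
        sig = significant_pairs(results)
        assert summary["n_unique_predictors"] == sig.a_id.nunique()
        assert summary["n_unique_responses"] == sig.b_id.nunique()
        assert summary["n_significant"] == len(sig)
        assert summary["max_p_significant"] == pytest.approx(sig.p_value.max())

    def test_order_invariance(self, small_dataset):
        d = small_dataset
        results, _ = self._scan(d)
        ann = d.annotation
        rng = np.random.default_rng(0)
        shuffled_geno = mm.OmicsMatrix(
            d.genotypes.data.sample(frac=1, axis=1, random_state=1), d.genotypes.role
        )
        ann_shuffled = ann.sample(frac=1, random_state=2)
        results2, _ = run_scan(
            shuffled_geno,
            d.methylation,
            ann_shuffled[ann_shuffled.feature_class == "snp"],
            ann_shuffled[ann_shuffled.feature_class == "cpg"],
            d.covariates,
            ScanConfig("meqtl"),
        )
        key = ["a_id", "b_id"]
        a = results.sort_values(key).reset_index(drop=True)
        b = results2.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=1e-12)

    def test_fast_path_matches_per_pair_fits(self, small_dataset):
        """The vectorized no-missing path agrees with fit_pair exactly."""
        d = small_dataset
        results, _ = self._scan(d)
        rng = np.random.default_rng(5)
        for _, row in results.sample(25, random_state=1).iterrows():
            ref = fit_pair(
                d.genotypes.data[row.a_id].to_numpy(float),
                d.methylation.data[row.b_id].to_numpy(float),
                d.covariates,
            )
            assert row.beta_hat == pytest.approx(ref["beta_hat"], rel=1e-9)
            assert row.p_value == pytest.approx(ref["p_value"], rel=1e-8)

    def test_missing_genotypes_fall_back_pairwise(self, small_dataset):
        d = small_dataset
        geno = d.genotypes.data.copy()
        geno.iloc[0, 0] = np.nan
        gm = mm.OmicsMatrix(geno, d.genotypes.role)
        ann = d.annotation
        results, _ = run_scan(
            gm,
            d.methylation,
            ann[ann.feature_class == "snp"],
            ann[ann.feature_class == "cpg"],
            d.covariates,
            ScanConfig("meqtl"),
        )
        affected = results[results.a_id == geno.columns[0]]
        if len(affected):
            assert (affected.n_used == d.config.n_samples - 1).all()

    def test_logit_transform_changes_scale_not_hits(self, mixed_dataset):
        raw, s_raw = self._scan(mixed_dataset)
        lg, s_lg = self._scan(mixed_dataset, transform="logit")
        planted = mixed_dataset.truth.query("beta_lg != 0")
        sig = significant_pairs(lg)
        hits = set(zip(sig.a_id, sig.b_id)) & set(zip(planted.snp_id, planted.cpg_id))
        assert len(hits) >= 0.9 * len(planted)
        assert not np.allclose(
            raw.sort_values(["a_id", "b_id"]).beta_hat.to_numpy(),
            lg.sort_values(["a_id", "b_id"]).beta_hat.to_numpy(),
        )
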