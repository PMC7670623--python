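"""Combined Pearson/Spearman association, trait tests, gene annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methresp.containers import ConsistencyError, MethylationMatrix
from methresp.ewas import (
    EWAS,
    annotate_features_to_genes,
    combined_correlation,
    ewas_scan,
    paired_change_tests,
    phenotype_correlations,
    relative_weight_change,
)


def pheno_from_weights(weights):
    rows = []
    for i, (w0, w18) in enumerate(weights):
        for tp, w in (("T0", w0), ("T18", w18)):
            rows.append(
                {
                    "sample_id": f"S{i}_{tp}", "subject_id": f"S{i}", "timepoint": tp,
                    "sex": "male", "age": 50, "arm": "low_fat", "weight": w, "bmi": 30,
                    "weight_T0": w0, "weight_T6": w, "weight_T18": w18,
                }
            )
    return pd.DataFrame(rows)


class TestRelativeWeightChange:
    @pytest.mark.parametrize(
        "w0,w18,expected",
        [(100.0, 84.0, -16.0), (90.0, 90.0, 0.0), (87.6, 83.6, -4.57)],
    )
    def test_arithmetic(self, w0, w18, expected):
        wc = relative_weight_change(pheno_from_weights([(w0, w18)]))
        assert wc.iloc[0] == pytest.approx(expected, abs=0.005)

    def test_missing_weight_errors_list_subjects(self):
        pheno = pheno_from_weights([(100, 90), (80, np.nan)])
        with pytest.raises(ValueError, match="S1"):
            relative_weight_change(pheno)


class TestCombinedCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        cc = combined_correlation(x, 2 * x + 1)
        assert cc.pearson_r == pytest.approx(1.0)
        assert cc.spearman_rho == pytest.approx(1.0)
        assert cc.combined_r == pytest.approx(1.0)
        assert not cc.sign_discordant

    def test_geometric_mean_identities(self):
        # sqrt(0.04 * 0.09) = 0.06; sqrt(p*p) = p
        from methresp.ewas import _geometric_mean_p

        assert _geometric_mean_p(0.04, 0.09) == pytest.approx(0.06)
        assert _geometric_mean_p(0.37, 0.37) == pytest.approx(0.37)

    def test_combined_p_between_component_ps(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.normal(size=(2, 12))
            cc = combined_correlation(x, y)
            assert min(cc.pearson_p, cc.spearman_p) <= cc.combined_p <= max(
                cc.pearson_p, cc.spearman_p
            )

    def test_exact_spearman_for_tiny_n(self):
        # perfectly monotone n=6 without ties: only the identity and the
        # reversal of ranks reach |rho| = 1, so the exact two-sided p = 2/6!
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([10.0, 20.0, 25.0, 40.0, 55.0, 70.0])
        cc = combined_correlation(x, y)
        assert cc.spearman_p == pytest.approx(2 / 720)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            combined_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            combined_correlation([1, 2, 3], [3, 2, 1])


def baseline_matrix(betas, subjects):
    beta = pd.DataFrame(
        betas,
        index=[f"cg{i}" for i in range(len(betas))],
        columns=[f"{s}_T0" for s in subjects],
    )
    return MethylationMatrix(beta)


class TestEwasScan:
    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(1)
        subjects = [f"S{i}" for i in range(20)]
        m = baseline_matrix(rng.uniform(0.2, 0.8, (50, 20)), subjects)
        wc = pd.Series(rng.normal(size=20), index=subjects)
        a = ewas_scan(m, wc)
        b = ewas_scan(m, -wc)
        np.testing.assert_allclose(a["combined_p"], b.loc[a.index, "combined_p"])
        np.testing.assert_allclose(a["combined_r"], -b.loc[a.index, "combined_r"])

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(2)
        subjects = [f"S{i}" for i in range(15)]
        m = baseline_matrix(rng.uniform(0.2, 0.8, (30, 15)), subjects)
        wc = pd.Series(rng.normal(size=15), index=subjects)
        a = ewas_scan(m, wc)
        perm = rng.permutation(15)
        m2 = MethylationMatrix(m.beta.iloc[:, perm])
        b = ewas_scan(m2, wc)
        np.testing.assert_allclose(a["combined_p"], b.loc[a.index, "combined_p"], rtol=1e-10)

    def test_planted_correlation_ranks_first(self):
        rng = np.random.default_rng(3)
        n = 60
        subjects = [f"S{i}" for i in range(n)]
        wc = pd.Series(rng.normal(size=n), index=subjects)
        betas = rng.uniform(0.3, 0.7, (200, n))
        z = (wc - wc.mean()) / wc.std()
        betas[0] = np.clip(0.5 + 0.08 * z.to_numpy() + rng.normal(0, 0.03, n), 0, 1)
        m = baseline_matrix(betas, subjects)
        table = ewas_scan(m, wc)
        assert table.index[0] == "cg0"
        assert table["combined_p"].iloc[0] < 1e-6

    def test_threshold_tier_memberships_are_nested(self):
        rng = np.random.default_rng(4)
        subjects = [f"S{i}" for i in range(20)]
        m = baseline_matrix(rng.uniform(0.2, 0.8, (100, 20)), subjects)
        wc = pd.Series(rng.normal(size=20), index=subjects)
        t = ewas_scan(m, wc, thresholds=(1e-2, 1e-3))
        assert (t["below_0.001"] <= t["below_0.01"]).all()

    def test_unmatchable_outcome_index_raises(self):
        rng = np.random.default_rng(5)
        m = baseline_matrix(rng.uniform(0.2, 0.8, (10, 6)), [f"S{i}" for i in range(6)])
        wc = pd.Series(rng.normal(size=6), index=[f"X{i}" for i in range(6)])
        with pytest.raises(ConsistencyError):
            ewas_scan(m, wc)


class TestPhenotypeCorrelations:
    def test_planted_linear_trait_is_significant(self):
        rng = np.random.default_rng(6)
        n = 30
        pheno = pheno_from_weights([(100, 95)] * n)
        pheno["subject_id"] = [f"S{i}" for i in range(n)] * 2
        pheno["sample_id"] = [f"S{i}_T0" for i in range(n)] + [f"S{i}_T18" for i in range(n)]
        betas = rng.uniform(0.3, 0.7, (5, 2 * n))
        m = MethylationMatrix(
            pd.DataFrame(betas, index=[f"cg{i}" for i in range(5)], columns=pheno["sample_id"])
        )
        pheno["insulin"] = np.concatenate([10 + 20 * betas[0, :n], 10 + 20 * betas[0, n:]])
        table = phenotype_correlations(m, pheno, ["insulin"], ["cg0", "cg1"])
        hit = table[(table["probe_id"] == "cg0") & (table["contrast"] == "level_T0")]
        assert hit["combined_p"].iloc[0] < 1e-6

    def test_empty_probe_set_gives_empty_table(self):
        pheno = pheno_from_weights([(100, 95)] * 5)
        m = MethylationMatrix(
            pd.DataFrame(
                np.full((2, 10), 0.5), index=["cg0", "cg1"], columns=pheno["sample_id"]
            )
        )
        assert phenotype_correlations(m, pheno, ["weight"], []).empty


class TestPairedChangeTests:
    def test_no_change_gives_t_zero_p_one(self):
        pheno = pheno_from_weights([(w, w) for w in (80, 90, 100, 110)])
        table = paired_change_tests(pheno, ["weight"])
        assert table.loc["weight", "t"] == 0.0 and table.loc["weight", "p"] == 1.0

    def test_constant_shift_degenerate_flagged(self):
        pheno = pheno_from_weights([(80, 79), (90, 89), (100, 99)])
        table = paired_change_tests(pheno, ["weight"])
        assert table.loc["weight", "p"] == 0.0 and table.loc["weight", "degenerate"]

    def test_cohort_scale_change_is_overwhelming(self):
        rng = np.random.default_rng(7)
        w0 = rng.normal(90, 11, 120)
        d = rng.normal(-3.65, 5.2, 120)
        pheno = pheno_from_weights(list(zip(w0, w0 + d)))
        table = paired_change_tests(pheno, ["weight"])
        assert table.loc["weight", "p"] < 1e-10
        assert table.loc["weight", "mean_change"] == pytest.approx(d.mean(), abs=1e-9)


def brute_gene_overlap(features, genes, upstream=1500):
    """All-pairs oracle for upstream-extended gene annotation."""
    out = []
    for _, f in features.iterrows():
        names = []
        for _, g in genes.iterrows():
            start, end = g["start"], g["end"]
            if g.get("strand", "+") == "-":
                end = end + upstream
            else:
                start = max(1, start - upstream)
            if g["chrom"] == f["chrom"] and start <= f["end"] and f["start"] <= end:
                if g["name"] not in names:
                    names.append(g["name"])
        out.append(",".join(names))
    return out


class TestGeneAnnotation:
    def genes(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [1500, 5000],
                "end": [3000, 6000],
                "strand": ["+", "-"],
                "name": ["GENE_A", "GENE_B"],
            }
        )

    def test_upstream_extension_reaches_cpg(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1000]})
        assert annotate_features_to_genes(feats, self.genes()) == ["GENE_A"]

    def test_point_past_extended_boundary_not_annotated(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [3011], "end": [3011]})
        # GENE_A ends at 3000 ('+': no downstream extension); GENE_B ('-')
        # extends to 7500 upstream but starts at 5000
        assert annotate_features_to_genes(feats, self.genes()) == [""]

    def test_minus_strand_extends_rightward(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [7000], "end": [7000]})
        assert annotate_features_to_genes(feats, self.genes()) == ["GENE_B"]

    def test_feature_overlapping_two_genes_reports_both_in_order(self):
        genes = self.genes()
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [5500]})
        assert annotate_features_to_genes(feats, genes) == ["GENE_A,GENE_B"]

    def test_matches_all_pairs_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n_g, n_f = rng.integers(1, 15, size=2)
            genes = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], n_g),
                    "start": rng.integers(1, 5000, n_g),
                    "strand": rng.choice(["+", "-"], n_g),
                    "name": [f"G{i}" for i in range(n_g)],
                }
            )
            genes["end"] = genes["start"] + rng.integers(0, 2000, n_g)
            starts = rng.integers(1, 8000, n_f)
            feats = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], n_f),
                    "start": starts,
                    "end": starts + rng.integers(0, 500, n_f),
                }
            )
            assert annotate_features_to_genes(feats, genes) == brute_gene_overlap(feats, genes)


class TestEWASModel:
    def test_model_selects_baseline_and_reports_hits(self, small_dataset):
        manifest, cohort, m, truth = small_dataset
        res = EWAS(m, cohort, manifest).fit()
        assert res.model.baseline.n_samples == cohort["subject_id"].nunique()
        planted = truth.planted_ewas_cpgs.set_index("probe_id")
        sub = res.table.loc[planted.index]
        # planted correlations carry the planted sign
        assert (np.sign(sub["combined_r"]) == planted["sign"]).all()
        assert "combined_p" in res.summary() or "CpGs" in res.summary()
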