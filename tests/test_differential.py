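"""Responder selection, probe clustering, 2D-KS, segmentation, DMR calls, BH."""

import numpy as np
import pandas as pd
import pytest

from methresp.containers import MethylationMatrix
from methresp.differential import (
    DMRParams,
    GroupDesign,
    ProbeCluster,
    SelectionError,
    bh_adjust,
    call_dmrs,
    cluster_probes,
    dmp_single_cpg,
    ks2d_pvalue,
    ks2d_statistic,
    segment_cluster,
    select_responders,
)


def ks2d_brute(a, b):
    """Independent oracle: enumerate all anchors x 4 closed quadrants."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pts = np.vstack([a, b])
    best = 0.0
    for x0, y0 in pts:
        for fx in (np.less_equal, np.greater_equal):
            for fy in (np.less_equal, np.greater_equal):
                fa = np.mean(fx(a[:, 0], x0) & fy(a[:, 1], y0))
                fb = np.mean(fx(b[:, 0], x0) & fy(b[:, 1], y0))
                best = max(best, abs(fa - fb))
    return best


def make_pheno(changes, sexes=None, subject_ids=None):
    n = len(changes)
    subject_ids = subject_ids or [f"S{i:03d}" for i in range(n)]
    sexes = sexes or ["male"] * n
    rows = []
    for sid, sex, pct in zip(subject_ids, sexes, changes):
        w0 = 100.0
        w18 = w0 * (1 + pct / 100)
        for tp, w in (("T0", w0), ("T18", w18)):
            rows.append(
                {
                    "sample_id": f"{sid}_{tp}", "subject_id": sid, "timepoint": tp,
                    "sex": sex, "age": 50.0, "arm": "low_fat", "weight": w,
                    "bmi": 30.0, "weight_T0": w0, "weight_T6": w, "weight_T18": w18,
                }
            )
    return pd.DataFrame(rows)


class TestSelectResponders:
    def test_extreme_deciles_selected_and_disjoint(self):
        changes = list(range(-10, 10))  # -10 .. +9, distinct
        design = select_responders(make_pheno(changes), n_per_group=2)
        assert set(design.group_a_subjects) == {"S000", "S001"}
        assert set(design.group_b_subjects) == {"S018", "S019"}
        assert not set(design.group_a_sample_ids) & set(design.group_b_sample_ids)

    def test_boundary_tie_broken_by_ascending_subject_id(self):
        changes = [-5, -5, -5, 1, 2, 3]
        design = select_responders(make_pheno(changes), n_per_group=2)
        assert design.group_a_subjects == ["S000", "S001"]

    def test_combined_timepoints_doubles_sample_count(self):
        changes = list(range(-10, 10))
        combined = select_responders(make_pheno(changes), n_per_group=3, timepoints="combined")
        single = select_responders(make_pheno(changes), n_per_group=3, timepoints="T0")
        assert len(combined.group_a_sample_ids) == 2 * len(single.group_a_sample_ids)
        assert combined.combined_timepoints and not single.combined_timepoints

    def test_planted_cohort_matches_truth_labels(self, small_dataset):
        _, cohort, _, truth = small_dataset
        design = select_responders(cohort, n_per_group=10)
        labels = truth.responder_labels
        assert set(design.group_a_subjects) == set(labels[labels == "responder"].index)
        assert set(design.group_b_subjects) == set(labels[labels == "non_responder"].index)

    def test_too_few_subjects_raises(self):
        with pytest.raises(SelectionError):
            select_responders(make_pheno([1, 2, 3]), n_per_group=2)


class TestClusterProbes:
    def manifest(self, positions, chroms=None):
        chroms = chroms or ["chr1"] * len(positions)
        return pd.DataFrame(
            {"chrom": chroms, "pos": positions, "cross_reactive": 0, "snp": 0, "genes": ""},
            index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id"),
        )

    def test_gap_scan_drops_far_probe(self):
        clusters = cluster_probes(self.manifest([1, 500, 1400, 2600]))
        assert len(clusters) == 1
        assert clusters[0].probe_ids == ["cg0", "cg1", "cg2"]
        assert (clusters[0].start, clusters[0].end) == (1, 1400)

    def test_exact_1000nt_gap_is_inclusive(self):
        clusters = cluster_probes(self.manifest([1, 1001, 2001]))
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_chromosomes_never_co_clustered(self):
        clusters = cluster_probes(
            self.manifest([1, 100, 200, 250, 300, 400], ["chr1"] * 3 + ["chr2"] * 3)
        )
        assert len(clusters) == 2
        assert {c.chrom for c in clusters} == {"chr1", "chr2"}


class TestKS2DStatistic:
    def test_identical_point_sets_give_zero(self):
        pts = np.array([[0.0, 0.1], [1.0, 0.5], [2.0, 0.9]])
        assert ks2d_statistic(pts, pts.copy()) == 0.0

    def test_full_separation_gives_one(self):
        a = np.array([[0.0, 0.1], [1.0, 0.2], [2.0, 0.15]])
        b = np.array([[0.0, 0.8], [1.0, 0.9], [2.0, 0.85]])
        assert ks2d_statistic(a, b) == 1.0

    def test_checkerboard_example(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert ks2d_statistic(a, b) == pytest.approx(0.5)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            na, nb = rng.integers(1, 9, size=2)
            # mix continuous and lattice coordinates to exercise ties
            if rng.random() < 0.5:
                a, b = rng.random((na, 2)), rng.random((nb, 2))
            else:
                a = rng.integers(0, 3, (na, 2)).astype(float)
                b = rng.integers(0, 3, (nb, 2)).astype(float)
            d = ks2d_statistic(a, b)
            assert d == pytest.approx(ks2d_brute(a, b), abs=1e-12)
            assert d == pytest.approx(ks2d_statistic(b, a), abs=1e-12)
            assert 0.0 <= d <= 1.0


class TestKS2DPvalue:
    def test_identical_groups_give_p_near_one(self):
        pts = np.random.default_rng(0).random((10, 2))
        _, p = ks2d_pvalue(pts, pts.copy(), n_perm=200, seed=1)
        assert p > 0.9

    def test_n_perm_below_100_rejected(self):
        pts = np.random.default_rng(0).random((5, 2))
        with pytest.raises(ValueError):
            ks2d_pvalue(pts, pts, n_perm=50)

    def test_power_on_separated_groups(self):
        # planted beta shift of 0.13 over 5 probes, 10 vs 10 samples
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pos = np.linspace(0, 1, 5)
            a = [np.column_stack([pos, 0.50 + rng.normal(0, 0.03, 5)]) for _ in range(10)]
            b = [np.column_stack([pos, 0.37 + rng.normal(0, 0.03, 5)]) for _ in range(10)]
            _, p = ks2d_pvalue(a, b, n_perm=300, seed=seed)
            hits += p < 0.01
        assert hits >= 0.9 * n_seeds

    def test_asymptotic_agrees_with_permutation_in_order_of_magnitude(self):
        rng = np.random.default_rng(3)
        a = rng.random((40, 2))
        b = rng.random((40, 2))
        _, p_perm = ks2d_pvalue(a, b, n_perm=500, seed=0)
        _, p_asym = ks2d_pvalue(a, b, method="asymptotic")
        assert 0.01 < p_asym <= 1.0 and abs(np.log10(p_asym) - np.log10(p_perm)) < 1.0


def two_group_matrix(diff_profile, n_per=8, noise=0.0, seed=0, base=0.4):
    """Probes x (2*n_per) matrix with group A shifted by diff_profile."""
    rng = np.random.default_rng(seed)
    n_probes = len(diff_profile)
    a = base + np.tile(np.asarray(diff_profile)[:, None], (1, n_per))
    b = np.full((n_probes, n_per), base)
    x = np.hstack([a, b]) + rng.normal(0, noise, (n_probes, 2 * n_per))
    beta = pd.DataFrame(
        np.clip(x, 0, 1),
        index=[f"cg{i}" for i in range(n_probes)],
        columns=[f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)],
    )
    m = MethylationMatrix(beta)
    design = GroupDesign(
        [f"a{i}" for i in range(n_per)], [f"b{i}" for i in range(n_per)]
    )
    return m, design


class TestSegmentCluster:
    def cluster(self, n):
        return ProbeCluster("chr1", [f"cg{i}" for i in range(n)], list(range(0, 100 * n, 100)))

    def test_uniform_signal_stays_whole(self):
        m, design = two_group_matrix([0.1] * 8)
        segs = segment_cluster(self.cluster(8), m, design)
        assert len(segs) == 1 and len(segs[0]) == 8

    def test_step_signal_splits_at_the_step(self):
        m, design = two_group_matrix([0.0] * 5 + [0.12] * 5)
        segs = segment_cluster(self.cluster(10), m, design)
        assert len(segs) == 2
        assert segs[0].probe_ids == [f"cg{i}" for i in range(5)]
        assert segs[1].probe_ids == [f"cg{i}" for i in range(5, 10)]

    def test_minimum_width_cluster_returned_unsplit(self):
        m, design = two_group_matrix([0.0, 0.2, 0.0])
        segs = segment_cluster(self.cluster(3), m, design, min_probes=3)
        assert len(segs) == 1 and len(segs[0]) == 3


class TestCallDMRs:
    def test_planted_regions_called_and_bounds_on_probes(self, small_dataset):
        manifest, cohort, m, truth = small_dataset
        design = select_responders(cohort, n_per_group=10)
        table = call_dmrs(m, manifest, design, DMRParams(n_perm=200, seed=5))
        # region bounds coincide with member probe positions, never cross chrom
        for _, row in table.iterrows():
            probes = row["probe_ids"].split(";")
            sub = manifest.loc[probes]
            assert sub["chrom"].nunique() == 1
            assert row["start"] == sub["pos"].min() and row["end"] == sub["pos"].max()
        # every planted region is recovered at the permutation floor
        floor = 1 / 201
        for _, region in truth.planted_dmrs.iterrows():
            probes = set(region["probe_ids"].split(";"))
            hits = table[table["probe_ids"].map(lambda s: len(probes & set(s.split(";"))) >= 3)]
            assert (hits["ks2d_p"] <= floor + 1e-12).any()
            best = hits.loc[hits["ks2d_p"].idxmin()]
            assert best["deltaM"] == pytest.approx(region["deltaM"], abs=0.02)

    def test_missing_design_samples_raise(self, small_dataset):
        manifest, cohort, m, _ = small_dataset
        design = GroupDesign(["nope_T0"], ["also_nope_T0"])
        with pytest.raises(Exception, match="absent"):
            call_dmrs(m, manifest, design)


class TestDMPSingleCpG:
    def test_planted_shift_is_highly_significant(self):
        m, design = two_group_matrix([0.10] * 1, n_per=10, noise=0.02, seed=1)
        outcome = [1] * 10 + [0] * 10
        table = dmp_single_cpg(m, outcome=outcome)
        assert table["p"].iloc[0] < 1e-4
        assert table["effect"].iloc[0] == pytest.approx(0.10, abs=0.03)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(9)
        beta = pd.DataFrame(
            rng.uniform(0.3, 0.7, (2000, 30)),
            index=[f"cg{i}" for i in range(2000)],
            columns=[f"s{i}" for i in range(30)],
        )
        outcome = rng.normal(size=30)
        table = dmp_single_cpg(MethylationMatrix(beta), outcome=outcome)
        from scipy.stats import kstest

        assert kstest(table["p"], "uniform").pvalue > 0.01

    def test_constant_probe_flagged_with_p_one(self):
        beta = pd.DataFrame(
            {"s1": [0.5, 0.2], "s2": [0.5, 0.8], "s3": [0.5, 0.4], "s4": [0.5, 0.6],
             "s5": [0.5, 0.3], "s6": [0.5, 0.7]},
            index=["flat", "vary"],
        )
        table = dmp_single_cpg(MethylationMatrix(beta), outcome=[1, 1, 1, 0, 0, 0])
        assert table.loc["flat", "p"] == 1.0 and table.loc["flat", "zero_variance"]

    def test_paired_mode_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(2)
        n = 12
        t0 = rng.uniform(0.3, 0.6, (5, n))
        t18 = t0 + 0.05 + rng.normal(0, 0.02, (5, n))
        beta = pd.DataFrame(
            np.clip(np.hstack([t0, t18]), 0, 1),
            index=[f"cg{i}" for i in range(5)],
            columns=[f"S{i}_T0" for i in range(n)] + [f"S{i}_T18" for i in range(n)],
        )
        pairs = [(f"S{i}_T0", f"S{i}_T18") for i in range(n)]
        table = dmp_single_cpg(MethylationMatrix(beta), paired=True, pairs=pairs)
        from scipy.stats import ttest_1samp

        d = (t18 - t0)[0]
        expected = ttest_1samp(d, 0)
        row = table.loc["cg0"]
        assert row["statistic"] == pytest.approx(expected.statistic)
        assert row["p"] == pytest.approx(expected.pvalue)


def bh_brute(p):
    """Step-up definition with monotonicity, as an independent oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random(rng.integers(1, 50))
            np.testing.assert_allclose(bh_adjust(p), bh_brute(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone_in_sorted_order(self):
        rng = np.random.default_rng(8)
        p = rng.random(100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
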