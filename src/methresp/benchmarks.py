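"""End-to-end benchmark studies on synthetic cohorts with planted truth.

Each function simulates the study conditions it needs, runs the relevant
pipeline stages, and returns the measured quantities (calibration of null
p-values, sensitivity and effect-size recovery for planted regions,
deconvolution error, predictive AUCs). They are consumed by the validation
suite and by the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .celltype import CellReference, adjust_for_composition, estimate_cell_proportions
from .containers import MethylationMatrix
from .differential import (
    DMRParams,
    call_dmrs,
    cluster_probes,
    dmp_single_cpg,
    ks2d_pvalue,
    select_responders,
)
from .ewas import ewas_scan, relative_weight_change
from .predict import evaluate_predictors, fit_age_bmi_predictor
from .simulate import SimulationConfig, simulate_beta, simulate_cohort, simulate_manifest


def _null_config(seed: int, n_probes: int) -> SimulationConfig:
    return dataclasses.replace(
        SimulationConfig(),
        n_subjects=120,
        n_probes=n_probes,
        n_planted_dmrs=0,
        n_planted_ewas_cpgs=0,
        markers_per_cell_type=0,
        detection_bad_probe_fraction=0.0,
        noise_sd=0.10,
        seed=seed,
    )


def null_calibration(
    seed: int = 0,
    n_probes: int = 10_000,
    n_perm_clusters: int = 250,
    n_perm: int = 200,
    n_null_runs: int = 20,
    null_run_probes: int = 2000,
) -> dict:
    """Calibration of the pipeline's tests on methylation-null cohorts.

    Returns KS-uniformity p-values for single-CpG and 2D-KS permutation
    p-values on one 120-subject cohort, plus the fraction of independent
    null cohorts yielding zero DMRs at BH-adjusted p < 0.05.
    """
    cfg = _null_config(seed, n_probes)
    manifest = simulate_manifest(cfg)
    cohort = simulate_cohort(cfg)
    m, _, _ = simulate_beta(manifest, cohort, cfg)

    # single-CpG p-values: baseline betas vs relative weight change
    t0 = cohort[cohort["timepoint"] == "T0"]
    baseline = m.subset_samples(list(t0["sample_id"]))
    wc = relative_weight_change(cohort)
    outcome = wc.loc[[s.rsplit("_", 1)[0] for s in baseline.sample_ids]].to_numpy()
    dmp = dmp_single_cpg(baseline, outcome=outcome)
    dmp_ks_p = float(stats.kstest(dmp["p"], "uniform").pvalue)

    # 2D-KS permutation p-values on fixed null regions
    design = select_responders(cohort, n_per_group=10)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    clusters = cluster_probes(manifest)[:n_perm_clusters]
    from .differential import _region_points

    ks_ps = []
    for c in clusters:
        pa = _region_points(m.beta, c.probe_ids, c.positions, design.group_a_sample_ids, True)
        pb = _region_points(m.beta, c.probe_ids, c.positions, design.group_b_sample_ids, True)
        _, p = ks2d_pvalue(pa, pb, n_perm=n_perm, seed=rng)
        ks_ps.append(p)
    ks_ps = np.asarray(ks_ps)
    ks2d_ks_p = float(stats.kstest(ks_ps, "uniform").pvalue)
    ks2d_reject_at_05 = float((ks_ps <= 0.05).mean())

    # zero significant DMRs across independent null cohorts
    zero_runs = 0
    for k in range(n_null_runs):
        c2 = dataclasses.replace(_null_config(0, null_run_probes), seed=int(seed) + 1000 + k)
        man2 = simulate_manifest(c2)
        coh2 = simulate_cohort(c2)
        m2, _, _ = simulate_beta(man2, coh2, c2)
        des2 = select_responders(coh2, n_per_group=10)
        table = call_dmrs(m2, man2, des2, DMRParams(n_perm=100, seed=int(seed) + k))
        if len(table) == 0 or (table["adj_p"] >= 0.05).all():
            zero_runs += 1
    return {
        "dmp_ks_uniformity_p": dmp_ks_p,
        "ks2d_ks_uniformity_p": ks2d_ks_p,
        "ks2d_type1_error_at_05": ks2d_reject_at_05,
        "null_runs_zero_dmrs_fraction": zero_runs / n_null_runs,
        "n_probes": n_probes,
        "n_null_runs": n_null_runs,
    }


def dmr_signal_recovery(seed: int = 0, n_regions: int = 50, n_perm: int = 200) -> dict:
    """Sensitivity and deltaM accuracy for planted regions.

    Conditions: 50 regions of 5 CpGs with |deltaM| = 0.10, 10 vs 10 male
    samples, logit noise 0.03.
    """
    cfg = dataclasses.replace(
        SimulationConfig(),
        n_subjects=20,
        male_fraction=1.0,
        n_probes=2500,
        n_planted_dmrs=n_regions,
        planted_deltaM=0.10,
        dmr_width_probes=5,
        n_planted_ewas_cpgs=0,
        markers_per_cell_type=0,
        detection_bad_probe_fraction=0.0,
        noise_sd=0.03,
        seed=seed,
    )
    manifest = simulate_manifest(cfg)
    cohort = simulate_cohort(cfg)
    m, _, truth = simulate_beta(manifest, cohort, cfg)
    design = select_responders(cohort, n_per_group=10, timepoints="T0")
    table = call_dmrs(m, manifest, design, DMRParams(n_perm=n_perm, seed=seed))
    sig = table[table["adj_p"] < 0.05]

    recovered = 0
    delta_errors = []
    for _, region in truth.planted_dmrs.iterrows():
        probes = set(region["probe_ids"].split(";"))
        hits = sig[sig["probe_ids"].map(lambda s: len(probes & set(s.split(";"))) >= 3)]
        if len(hits):
            recovered += 1
            best = hits.loc[
                hits["probe_ids"].map(lambda s: len(probes & set(s.split(";")))).idxmax()
            ]
            delta_errors.append(abs(best["deltaM"] - region["deltaM"]))
    return {
        "sensitivity": recovered / len(truth.planted_dmrs),
        "delta_m_mean_abs_error": float(np.mean(delta_errors)) if delta_errors else float("nan"),
        "delta_m_max_abs_error": float(np.max(delta_errors)) if delta_errors else float("nan"),
        "n_planted": len(truth.planted_dmrs),
        "n_candidates": len(table),
    }


def ewas_signal_recovery(seed: int = 0, n_seeds: int = 20, n_probes: int = 5000) -> dict:
    """Rank of a planted r = 0.42 CpG among nulls, over independent cohorts."""
    top10 = 0
    ranks = []
    for k in range(n_seeds):
        cfg = dataclasses.replace(
            SimulationConfig(),
            n_subjects=120,
            n_probes=n_probes,
            n_planted_dmrs=0,
            n_planted_ewas_cpgs=1,
            planted_r=0.42,
            markers_per_cell_type=0,
            detection_bad_probe_fraction=0.0,
            noise_sd=0.10,
            # continuous weight-change outcome without the extreme responder
            # tails: this study measures rank recovery of a planted
            # correlation, not tail-group contrasts
            n_responders=0,
            n_nonresponders=0,
            seed=int(seed) + 2000 + k,
        )
        manifest = simulate_manifest(cfg)
        cohort = simulate_cohort(cfg)
        m, _, truth = simulate_beta(manifest, cohort, cfg)
        t0 = cohort[cohort["timepoint"] == "T0"]
        baseline = m.subset_samples(list(t0["sample_id"]))
        wc = relative_weight_change(cohort)
        table = ewas_scan(baseline, wc)
        probe = truth.planted_ewas_cpgs["probe_id"].iloc[0]
        rank = int(table.index.get_loc(probe)) + 1
        ranks.append(rank)
        top10 += rank <= 10
    return {
        "top10_fraction": top10 / n_seeds,
        "median_rank": float(np.median(ranks)),
        "n_seeds": n_seeds,
        "n_probes": n_probes,
    }


def deconvolution_recovery(seed: int = 0) -> dict:
    """Proportion recovery without and with noise, plus confounder adjustment."""

    def run(noise_sd: float) -> float:
        cfg = dataclasses.replace(
            SimulationConfig(),
            n_subjects=30,
            n_probes=1500,
            n_planted_dmrs=0,
            n_planted_ewas_cpgs=0,
            markers_per_cell_type=100,
            detection_bad_probe_fraction=0.0,
            noise_sd=noise_sd,
            seed=seed,
        )
        manifest = simulate_manifest(cfg)
        cohort = simulate_cohort(cfg)
        m, _, truth = simulate_beta(manifest, cohort, cfg)
        ref = CellReference(truth.cell_reference)
        props = estimate_cell_proportions(m, ref)
        return float(
            np.abs(props - truth.true_cell_proportions.loc[props.index]).mean().mean()
        )

    mae_noiseless = run(0.0)
    mae_noisy = run(0.02)

    # composition confounder: group effect + composition effect on the same
    # probes; residualization must restore the planted group difference
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    n_per, planted = 20, 0.08
    group = np.array([1] * n_per + [0] * n_per)
    w = np.vstack([rng.dirichlet([5, 4], n_per), rng.dirichlet([4, 5], n_per)])
    beta = np.clip(
        0.2 + 0.6 * w[:, 0] + planted * group + rng.normal(0, 0.01, (30, 2 * n_per)),
        0.01,
        0.99,
    )
    samples = [f"s{i}" for i in range(2 * n_per)]
    m = MethylationMatrix(
        pd.DataFrame(beta, index=[f"cg{i}" for i in range(30)], columns=samples)
    )
    props = pd.DataFrame(w, index=samples, columns=["A", "B"])
    adj = adjust_for_composition(m, props).beta.to_numpy()
    raw_delta = float(beta[:, group == 1].mean() - beta[:, group == 0].mean())
    adj_delta = float(adj[:, group == 1].mean() - adj[:, group == 0].mean())
    return {
        "mae_noiseless": mae_noiseless,
        "mae_noisy": mae_noisy,
        "confounded_raw_delta_error": abs(raw_delta - planted),
        "adjusted_delta_error": abs(adj_delta - planted),
    }


def prediction_benchmark(seed: int = 0, n_seeds: int = 20, n_shuffles: int = 20) -> dict:
    """Methylation score vs grid-maximized age/BMI baseline, plus the
    label-permutation ceiling of the maximized age/BMI AUC at n = 20."""
    meth_wins = 0
    meth_aucs, clin_aucs = [], []
    shuffle_aucs = []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9]))
    for k in range(n_seeds):
        cfg = dataclasses.replace(
            SimulationConfig(),
            n_subjects=120,
            n_probes=2000,
            n_planted_dmrs=0,
            n_planted_ewas_cpgs=10,
            planted_r=0.42,
            markers_per_cell_type=0,
            detection_bad_probe_fraction=0.0,
            noise_sd=0.10,
            seed=int(seed) + 3000 + k,
        )
        manifest = simulate_manifest(cfg)
        cohort = simulate_cohort(cfg)
        m, _, _ = simulate_beta(manifest, cohort, cfg)
        t0 = cohort[cohort["timepoint"] == "T0"]
        baseline = m.subset_samples(list(t0["sample_id"]))
        wc = relative_weight_change(cohort)
        assoc = ewas_scan(baseline, wc)
        design = select_responders(cohort, n_per_group=10, timepoints="T0")
        table = evaluate_predictors(baseline, assoc, cohort, design)
        meth = table[table["kind"] == "methylation"]["auc"]
        clin = float(table[table["kind"] == "clinical"]["auc"].iloc[0])
        if len(meth):
            meth_aucs.append(float(meth.max()))
            clin_aucs.append(clin)
            meth_wins += meth.max() > clin
        if k == 0:
            # label-permutation ceiling of the maximized clinical score
            subjects = design.group_a_subjects + design.group_b_subjects
            sub = cohort[(cohort["timepoint"] == "T0") & cohort["subject_id"].isin(subjects)]
            sub = sub.set_index("subject_id").loc[subjects]
            age = sub["age"].to_numpy()
            bmi = sub["bmi"].to_numpy()
            base_labels = np.array([1] * 10 + [0] * 10)
            for _ in range(n_shuffles):
                labels = rng.permutation(base_labels)
                _, _, res = fit_age_bmi_predictor(age, bmi, labels)
                shuffle_aucs.append(res.auc)
    return {
        "methylation_wins_fraction": meth_wins / n_seeds,
        "mean_methylation_auc": float(np.mean(meth_aucs)),
        "mean_age_bmi_auc": float(np.mean(clin_aucs)),
        "shuffled_age_bmi_auc_mean": float(np.mean(shuffle_aucs)),
        "n_seeds": n_seeds,
    }
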