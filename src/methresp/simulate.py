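"""Synthetic cohort generator with known planted truth.

Emulates a two-timepoint (T0/T18) lifestyle-intervention cohort profiled on a
beta-value methylation array: a gap-clustered probe manifest, a phenotype
table with a weight trajectory carrying extreme responder / non-responder
tails, and beta matrices built as cell-type reference mixtures with planted
differentially methylated regions and planted baseline CpGs correlated with
relative weight change. Every planted effect is returned as an explicit
truth object so downstream callers can be scored against it.

Betas are generated on the logit scale (Gaussian noise, inverse-logit
back-transform) so values stay strictly inside (0, 1) without rejection
sampling.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import ConsistencyError, MethylationMatrix, validate_manifest

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_manifest",
    "simulate_cohort",
    "simulate_beta",
    "simulate_dataset",
]

#: Leukocyte subtypes of the classic six-cell blood reference.
BLOOD_CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Neu")

#: Dirichlet concentration giving realistic blood fractions (granulocyte
#: dominated) with subject-to-subject variation.
BLOOD_DIRICHLET = (4.0, 2.5, 1.5, 1.5, 2.0, 13.0)


class InvalidConfigError(ValueError):
    """Raised for out-of-range simulation parameters."""


@dataclasses.dataclass
class ClusterGapModel:
    """Genomic spacing model: tight CpG clusters separated by long gaps."""

    intra_cluster_spacing: int = 200  # mean nt between probes inside a cluster
    inter_cluster_spacing: int = 20000  # mean nt between clusters / singletons


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study conditions: 120 subjects at two timepoints,
    110/120 male, mean relative weight change about -4% (SD 5.8%, i.e.
    -3.65 +/- 5.2 kg on a 90.3 kg baseline), ten extreme responders near
    -16% and ten non-responders near +2.4%, planted regional effects of
    |deltaM| ~ 0.10 on the beta scale and planted baseline CpGs with
    |r| ~ 0.40 against relative weight change, mixed over six blood cell
    types.
    """

    n_subjects: int = 120
    male_fraction: float = 110 / 120
    n_probes: int = 6000
    n_chromosomes: int = 4
    cluster_gap_model: ClusterGapModel = dataclasses.field(default_factory=ClusterGapModel)
    cluster_fraction: float = 0.7  # fraction of probes placed in >=3-probe clusters
    n_planted_dmrs: int = 8
    planted_deltaM: float = 0.10
    dmr_width_probes: int = 5
    n_planted_ewas_cpgs: int = 15
    planted_r: float = 0.40
    weight_change_mean_pct: float = -4.0
    weight_change_sd_pct: float = 5.8
    n_responders: int = 10
    n_nonresponders: int = 10
    responder_mean_pct: float = -16.0
    nonresponder_mean_pct: float = 2.4
    tail_sd_pct: float = 1.2
    cell_types: Sequence[str] = BLOOD_CELL_TYPES
    dirichlet_concentration: Sequence[float] = BLOOD_DIRICHLET
    markers_per_cell_type: int = 100
    noise_sd: float = 0.10  # logit-scale Gaussian noise SD
    detection_bad_probe_fraction: float = 0.005
    detection_fail_rate: float = 0.5  # per-sample failure rate on bad probes
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 0 or self.n_subjects < 0 or self.n_planted_dmrs < 0:
            raise InvalidConfigError("counts must be non-negative")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise InvalidConfigError("male_fraction must lie in [0, 1]")
        if not -1.0 < self.planted_deltaM < 1.0:
            raise InvalidConfigError("planted_deltaM must lie in (-1, 1)")
        if not abs(self.planted_r) < 1.0:
            raise InvalidConfigError("|planted_r| must be < 1")
        if self.dmr_width_probes < 3:
            raise InvalidConfigError("dmr_width_probes must be >= 3")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise InvalidConfigError("cluster_fraction must lie in [0, 1]")
        if not 0.0 <= self.detection_bad_probe_fraction <= 1.0:
            raise InvalidConfigError("detection_bad_probe_fraction must lie in [0, 1]")
        if len(self.cell_types) != len(self.dirichlet_concentration):
            raise InvalidConfigError("cell_types and dirichlet_concentration lengths differ")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of every planted effect.

    planted_dmrs: one row per region (chrom, start, end, probe_ids
    semicolon-joined, deltaM signed on the beta scale).
    planted_ewas_cpgs: one row per probe (probe_id, true_r, sign).
    true_cell_proportions: sample x cell-type matrix, rows summing to 1.
    responder_labels: subject -> {responder, non_responder, neither}.
    """

    planted_dmrs: pd.DataFrame
    planted_ewas_cpgs: pd.DataFrame
    true_cell_proportions: pd.DataFrame
    responder_labels: pd.Series
    cell_reference: pd.DataFrame  # marker-probe x cell-type mean betas
    bad_detection_probes: list[str]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per stage, all keyed off config.seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# manifest


def simulate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate a gap-clustered probe manifest sorted by (chrom, pos).

    Roughly ``cluster_fraction`` of probes fall in clusters of 3+ probes with
    consecutive gaps well under 1000 nt; the remainder are isolated probes
    separated by the inter-cluster spacing. Cross-reactive and SNP flags are
    set on small random subsets; clusters are annotated with synthetic gene
    symbols.
    """
    config.validate()
    rng = _rng(config, 1)
    cols = ["chrom", "pos", "cross_reactive", "snp", "genes"]
    if config.n_probes == 0:
        return pd.DataFrame(columns=cols).rename_axis("probe_id")

    gap = config.cluster_gap_model
    per_chrom = np.full(config.n_chromosomes, config.n_probes // config.n_chromosomes)
    per_chrom[: config.n_probes % config.n_chromosomes] += 1

    rows: list[tuple[str, int]] = []
    genes: list[str] = []
    gene_counter = 0
    for ci, n_c in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 0
        placed = 0
        while placed < n_c:
            pos += int(rng.integers(gap.inter_cluster_spacing // 2, gap.inter_cluster_spacing * 2))
            in_cluster = rng.random() < config.cluster_fraction
            if in_cluster and n_c - placed >= 3:
                size = int(rng.integers(3, max(4, config.dmr_width_probes + 4)))
                size = min(size, n_c - placed)
                gene_counter += 1
                gene = f"GENE{gene_counter}" if rng.random() < 0.7 else ""
                for _ in range(size):
                    rows.append((chrom, pos))
                    genes.append(gene)
                    # intra-cluster gap kept strictly below the 1000 nt rule
                    pos += int(rng.integers(10, min(2 * gap.intra_cluster_spacing, 900)))
                placed += size
            else:
                rows.append((chrom, pos))
                genes.append("")
                placed += 1

    n = len(rows)
    manifest = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": [r[1] + 1 for r in rows],  # 1-based coordinates
            "cross_reactive": (rng.random(n) < 0.02).astype(int),
            "snp": (rng.random(n) < 0.03).astype(int),
            "genes": genes,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id"),
    )
    return validate_manifest(manifest)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the per-sample phenotype table (two rows per subject).

    Relative weight change is drawn from the configured normal, with
    ``n_responders`` male subjects re-drawn from the responder tail and
    ``n_nonresponders`` males from the regain tail. BMI tracks weight; ages
    and baseline weights follow the cohort's descriptive statistics.
    """
    config.validate()
    if config.n_subjects < 2:
        raise InvalidConfigError("need at least 2 subjects")
    rng = _rng(config, 2)
    n = config.n_subjects
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    n_male = int(round(config.male_fraction * n))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sex)

    age = np.clip(rng.normal(49.0, 9.3, n), 25, 75).round(1)
    weight_t0 = np.clip(rng.normal(90.32, 11.5, n), 55, 150).round(2)
    bmi_t0 = np.clip(rng.normal(30.17, 3.3, n), 22, 45).round(2)
    arms = np.array(["low_carb", "low_carb_pa", "low_fat", "low_fat_pa"])[np.arange(n) % 4]

    pct = rng.normal(config.weight_change_mean_pct, config.weight_change_sd_pct, n)
    male_idx = np.flatnonzero(sex == "male")
    n_tail = config.n_responders + config.n_nonresponders
    if n_tail > 0:
        if len(male_idx) < n_tail:
            raise InvalidConfigError("not enough male subjects for the configured tails")
        tail = rng.choice(male_idx, size=n_tail, replace=False)
        resp, nonresp = tail[: config.n_responders], tail[config.n_responders:]
        pct[resp] = rng.normal(config.responder_mean_pct, config.tail_sd_pct, len(resp))
        pct[nonresp] = rng.normal(config.nonresponder_mean_pct, config.tail_sd_pct, len(nonresp))

    weight_t18 = (weight_t0 * (1 + pct / 100)).round(2)
    # truth labels are the *realized* extremes among males (same ranking and
    # tie rule as the downstream responder selection), so planted regional
    # effects always coincide with the groups a caller will select
    labels = np.array(["neither"] * n, dtype=object)
    if n_tail > 0:
        rel = (weight_t18 - weight_t0) / weight_t0 * 100.0
        male_order = sorted(male_idx, key=lambda i: (rel[i], subjects[i]))
        labels[male_order[: config.n_responders]] = "responder"
        if config.n_nonresponders:
            labels[male_order[-config.n_nonresponders:]] = "non_responder"
    # weight at 6 months: roughly the nadir of the trajectory, not profiled
    weight_t6 = (weight_t0 * (1 + 0.9 * pct / 100)).round(2)
    bmi_t18 = (bmi_t0 * weight_t18 / weight_t0).round(2)

    rows = []
    for tp, w, b in (("T0", weight_t0, bmi_t0), ("T18", weight_t18, bmi_t18)):
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{s}_{tp}" for s in subjects],
                    "subject_id": subjects,
                    "timepoint": tp,
                    "sex": sex,
                    "age": age,
                    "arm": arms,
                    "weight": w,
                    "bmi": b,
                    "weight_T0": weight_t0,
                    "weight_T6": weight_t6,
                    "weight_T18": weight_t18,
                }
            )
        )
    pheno = pd.concat(rows, ignore_index=True)
    pheno.attrs["responder_labels"] = pd.Series(labels, index=subjects, name="label")
    return pheno


# ---------------------------------------------------------------------------
# beta matrix


def _pick_dmr_clusters(manifest: pd.DataFrame, width: int, n_regions: int, rng) -> list[pd.DataFrame]:
    """Pick disjoint runs of `width` consecutive probes that satisfy the
    (>=3 probes, <=1000 nt gaps) region geometry."""
    from .differential import cluster_probes  # local import to avoid a cycle

    clusters = [c for c in cluster_probes(manifest, max_gap=1000, min_probes=width)]
    rng.shuffle(clusters)
    picked = []
    for c in clusters[:n_regions]:
        sub = manifest.loc[c.probe_ids[:width]]
        picked.append(sub)
    if len(picked) < n_regions:
        raise InvalidConfigError(
            f"manifest geometry yields only {len(picked)} clusters of width {width}; "
            f"asked for {n_regions} planted regions"
        )
    return picked


def simulate_beta(
    manifest: pd.DataFrame,
    cohort: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate beta and detection-p matrices with planted truth.

    Per-sample betas are cell-type reference mixtures (marker probes) or a
    shared baseline profile (elsewhere), perturbed on the logit scale by
    planted regional group effects, planted weight-change correlations, and
    Gaussian noise, then inverse-logit transformed.
    """
    config.validate()
    if manifest.empty or cohort.empty:
        raise ConsistencyError("manifest and cohort must be non-empty")
    rng = _rng(config, 3)
    probe_ids = manifest.index.to_numpy()
    n_probes = len(probe_ids)
    sample_ids = cohort["sample_id"].to_numpy()
    n_samples = len(sample_ids)
    subjects = cohort.drop_duplicates("subject_id")
    subj_ids = subjects["subject_id"].to_numpy()

    labels: pd.Series = cohort.attrs.get(
        "responder_labels", pd.Series("neither", index=subj_ids)
    )

    # baseline probe means: bimodal like a real methylation array
    comp = rng.random(n_probes)
    mu = np.where(
        comp < 0.35,
        rng.beta(2, 12, n_probes),
        np.where(comp < 0.70, rng.beta(12, 2, n_probes), rng.beta(6, 6, n_probes)),
    )
    mu = np.clip(mu, 0.03, 0.97)

    # --- cell reference: block-structured, strongly separated marker profiles
    cell_types = list(config.cell_types)
    k = len(cell_types)
    n_markers = config.markers_per_cell_type * k
    if n_markers > n_probes:
        raise InvalidConfigError("not enough probes for the requested marker panel")
    marker_ids = probe_ids[rng.choice(n_probes, size=n_markers, replace=False)]
    profile = np.full((n_markers, k), 0.0)
    base_marker = rng.uniform(0.08, 0.25, n_markers)
    profile += base_marker[:, None]
    for t in range(k):
        block = slice(t * config.markers_per_cell_type, (t + 1) * config.markers_per_cell_type)
        profile[block, t] = rng.uniform(0.75, 0.92, config.markers_per_cell_type)
    reference = pd.DataFrame(profile, index=marker_ids, columns=cell_types)

    alpha = np.asarray(config.dirichlet_concentration, dtype=float)
    props = rng.dirichlet(alpha, size=n_samples)
    true_props = pd.DataFrame(props, index=sample_ids, columns=cell_types)

    # per-sample expected beta
    expected = np.tile(mu[:, None], (1, n_samples))
    marker_pos = manifest.index.get_indexer(marker_ids)
    expected[marker_pos, :] = profile @ props.T

    x = logit(np.clip(expected, 1e-4, 1 - 1e-4))

    # --- planted DMRs: shift responder vs non-responder group means so the
    # beta-scale difference equals planted_deltaM in expectation
    dmr_rows = []
    dmr_probe_shift = {}  # probe id -> (sign, per-sample shift applicability)
    if config.n_planted_dmrs > 0:
        regions = _pick_dmr_clusters(manifest, config.dmr_width_probes, config.n_planted_dmrs, rng)
        subj_label = cohort["subject_id"].map(labels).to_numpy()
        is_resp = subj_label == "responder"
        is_nonresp = subj_label == "non_responder"
        for ri, region in enumerate(regions):
            sign = 1.0 if ri % 2 == 0 else -1.0
            d = sign * config.planted_deltaM
            ridx = manifest.index.get_indexer(region.index)
            for i in ridx:
                # re-anchor the probe to mid-range so +/- deltaM/2 stays in (0,1)
                center = float(np.clip(mu[i], 0.2, 0.8))
                hi = logit(np.clip(center + d / 2, 1e-4, 1 - 1e-4))
                lo = logit(np.clip(center - d / 2, 1e-4, 1 - 1e-4))
                x[i, :] = logit(center)
                x[i, is_resp] = hi
                x[i, is_nonresp] = lo
            dmr_rows.append(
                {
                    "chrom": region["chrom"].iloc[0],
                    "start": int(region["pos"].min()),
                    "end": int(region["pos"].max()),
                    "probe_ids": ";".join(region.index),
                    "deltaM": d,
                }
            )
    planted_dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "probe_ids", "deltaM"])

    # --- planted EWAS CpGs: baseline betas correlated with relative weight change
    used = set(planted_dmrs["probe_ids"].str.split(";").explode()) if len(planted_dmrs) else set()
    used |= set(marker_ids)
    free = np.array([p for p in probe_ids if p not in used])
    ewas_rows = []
    if config.n_planted_ewas_cpgs > 0:
        if len(free) < config.n_planted_ewas_cpgs:
            raise InvalidConfigError("not enough free probes for planted EWAS CpGs")
        chosen = rng.choice(free, size=config.n_planted_ewas_cpgs, replace=False)
        rel = (subjects["weight_T18"].to_numpy() - subjects["weight_T0"].to_numpy()) / subjects[
            "weight_T0"
        ].to_numpy() * 100.0
        z = (rel - rel.mean()) / (rel.std() if rel.std() > 0 else 1.0)
        z_per_sample = cohort["subject_id"].map(dict(zip(subj_ids, z))).to_numpy()
        sigma = max(config.noise_sd, 1e-6)
        c = sigma * config.planted_r / np.sqrt(1 - config.planted_r**2)
        for pi, p in enumerate(chosen):
            sign = 1.0 if pi % 2 == 0 else -1.0
            i = manifest.index.get_loc(p)
            # pin the probe to mid-range so the logit slope is informative
            x[i, :] = logit(np.clip(rng.uniform(0.35, 0.65), 1e-4, 1 - 1e-4))
            x[i, :] += sign * c * z_per_sample
            ewas_rows.append({"probe_id": p, "true_r": sign * config.planted_r, "sign": int(sign)})
    planted_ewas = pd.DataFrame(ewas_rows, columns=["probe_id", "true_r", "sign"])

    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
    beta = expit(x)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)

    # --- detection p: clean probes near zero, designated bad probes fail often
    det = rng.uniform(0.0, 0.005, size=(n_probes, n_samples))
    n_bad = int(round(config.detection_bad_probe_fraction * n_probes))
    bad_idx = rng.choice(n_probes, size=n_bad, replace=False) if n_bad else np.array([], dtype=int)
    for i in bad_idx:
        fails = rng.random(n_samples) < config.detection_fail_rate
        det[i, fails] = rng.uniform(0.02, 1.0, fails.sum())
    det_df = pd.DataFrame(det, index=probe_ids, columns=sample_ids)

    truth = SyntheticTruth(
        planted_dmrs=planted_dmrs,
        planted_ewas_cpgs=planted_ewas,
        true_cell_proportions=true_props,
        responder_labels=labels,
        cell_reference=reference,
        bad_detection_probes=[probe_ids[i] for i in bad_idx],
    )
    return MethylationMatrix(beta_df, det_df), det_df, truth


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: manifest + cohort + beta/detection + truth."""
    manifest = simulate_manifest(config)
    cohort = simulate_cohort(config)
    matrix, detection, truth = simulate_beta(manifest, cohort, config)
    return manifest, cohort, matrix, truth
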