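"""Responder/non-responder DMR discovery via the two-dimensional KS test.

Subjects are ranked by relative weight change; the extreme tails form the
responder and non-responder groups (optionally pooling both timepoints as
replicates). Probes are clustered into candidate regions (>= 3 CpGs, gaps
<= 1000 nt), refined by metilene-style recursive binary segmentation of the
group-difference signal, and each candidate region is tested by comparing
the two groups' (position, beta) point clouds with the Fasano-Franceschini
two-dimensional Kolmogorov-Smirnov statistic. P-values come from a
sample-level permutation test by default (points of one sample move
together) with a large-sample approximation as an alternative. Region
effect size deltaM is the difference between groups of the mean average
methylation rate across the region's probes, on the beta scale.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConsistencyError, MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "ProbeCluster",
    "DMRParams",
    "select_responders",
    "cluster_probes",
    "ks2d_statistic",
    "ks2d_pvalue",
    "segment_cluster",
    "call_dmrs",
    "dmp_single_cpg",
    "bh_adjust",
    "DMRAnalysis",
    "DMRResults",
]


@dataclasses.dataclass
class GroupDesign:
    """Two disjoint sample groups entering a differential contrast."""

    group_a_sample_ids: list[str]
    group_b_sample_ids: list[str]
    label_a: str = "A"
    label_b: str = "B"
    combined_timepoints: bool = False
    group_a_subjects: list[str] | None = None
    group_b_subjects: list[str] | None = None
    mean_age_a: float | None = None
    mean_age_b: float | None = None
    age_balance_flag: bool = False

    def __post_init__(self) -> None:
        if not self.group_a_sample_ids or not self.group_b_sample_ids:
            raise ValueError("both groups must be non-empty")
        if set(self.group_a_sample_ids) & set(self.group_b_sample_ids):
            raise ValueError("groups must be disjoint")


@dataclasses.dataclass
class ProbeCluster:
    """A position-ordered run of nearby probes on one chromosome."""

    chrom: str
    probe_ids: list[str]
    positions: list[int]

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]

    def __len__(self) -> int:
        return len(self.probe_ids)


class SelectionError(ValueError):
    pass


def select_responders(
    pheno: pd.DataFrame,
    n_per_group: int = 10,
    sex_filter: str | None = "male",
    timepoints: str = "combined",
    age_tolerance: float = 5.0,
) -> GroupDesign:
    """Pick the top responders and bottom non-responders by weight change.

    Subjects are ranked by relative weight change ((wT18-wT0)/wT0*100); the
    ``n_per_group`` most negative are responders, the most positive
    non-responders. Ties at a boundary break by ascending subject id. The
    groups' mean ages are reported and flagged when they differ by more than
    ``age_tolerance`` years (post-hoc balance check, not pair matching).

    ``timepoints`` is "T0", "T18" or "combined" (both samples per subject
    enter the group, treated as replicates — no dependence correction is
    applied; a caveat is logged).
    """
    subj = pheno.drop_duplicates("subject_id").set_index("subject_id")
    if sex_filter is not None:
        subj = subj[subj["sex"] == sex_filter]
    if len(subj) < 2 * n_per_group:
        raise SelectionError(
            f"only {len(subj)} subjects after sex filter; need {2 * n_per_group}"
        )
    rel = (subj["weight_T18"] - subj["weight_T0"]) / subj["weight_T0"] * 100.0
    order = pd.DataFrame({"rel": rel}).sort_values(["rel"], kind="stable")
    order = order.loc[order.index.sort_values()].sort_values("rel", kind="stable")
    responders = list(order.index[:n_per_group])
    non_responders = list(order.index[-n_per_group:])

    tps = ["T0", "T18"] if timepoints == "combined" else [timepoints]
    by_subj = pheno[pheno["timepoint"].isin(tps)]

    def samples(subjects):
        rows = by_subj[by_subj["subject_id"].isin(subjects)]
        return sorted(rows["sample_id"].tolist())

    mean_age_a = float(subj.loc[responders, "age"].mean())
    mean_age_b = float(subj.loc[non_responders, "age"].mean())
    flag = abs(mean_age_a - mean_age_b) > age_tolerance
    if flag:
        logger.warning(
            "responder/non-responder mean ages differ by %.1f years (> %.1f)",
            abs(mean_age_a - mean_age_b),
            age_tolerance,
        )
    if timepoints == "combined":
        logger.info(
            "combined-timepoint design: both samples per subject enter as replicates "
            "without dependence correction"
        )
    return GroupDesign(
        group_a_sample_ids=samples(responders),
        group_b_sample_ids=samples(non_responders),
        label_a="responder",
        label_b="non_responder",
        combined_timepoints=(timepoints == "combined"),
        group_a_subjects=responders,
        group_b_subjects=non_responders,
        mean_age_a=mean_age_a,
        mean_age_b=mean_age_b,
        age_balance_flag=flag,
    )


def cluster_probes(
    manifest: pd.DataFrame, max_gap: int = 1000, min_probes: int = 3
) -> list[ProbeCluster]:
    """Maximal runs of same-chromosome probes with consecutive gaps <= max_gap.

    The gap boundary is inclusive (a gap of exactly ``max_gap`` nt stays in
    the run). Runs with fewer than ``min_probes`` members are discarded.
    """
    mf = manifest.sort_values(["chrom", "pos"], kind="stable")
    clusters: list[ProbeCluster] = []
    for chrom, sub in mf.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for run_ids, run_pos in zip(np.split(ids, breaks), np.split(pos, breaks)):
            if len(run_ids) >= min_probes:
                clusters.append(ProbeCluster(chrom, list(run_ids), [int(p) for p in run_pos]))
    return clusters


# ---------------------------------------------------------------------------
# two-dimensional KS


def _as_points(points) -> np.ndarray:
    a = np.asarray(points, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    return a


def _quadrant_matrices(pts: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Anchor x point membership matrices for the 4 closed quadrants."""
    x, y = pts[:, 0], pts[:, 1]
    le_x = x[None, :] <= x[:, None]
    le_y = y[None, :] <= y[:, None]
    ge_x = ~le_x | (x[None, :] == x[:, None])
    ge_y = ~le_y | (y[None, :] == y[:, None])
    mats = [
        (qx & qy).astype(float) for qx in (le_x, ge_x) for qy in (le_y, ge_y)
    ]
    totals = [q.sum(axis=1) for q in mats]
    return mats, totals


def _quadrant_fraction_diff_max(pts: np.ndarray, in_a: np.ndarray) -> float:
    """Max over pooled anchors and 4 closed quadrants of |F_A - F_B|."""
    mats, totals = _quadrant_matrices(pts)
    wa = in_a.astype(float)
    na = wa.sum()
    nb = len(wa) - na
    best = 0.0
    for q, tot in zip(mats, totals):
        ca = q @ wa
        best = max(best, float(np.abs(ca / na - (tot - ca) / nb).max()))
    return best


def ks2d_statistic(points_a, points_b) -> float:
    """Fasano-Franceschini 2D KS statistic D in [0, 1].

    D is the maximum over all data points of both sets, and over the four
    axis-aligned quadrant orientations anchored at that point (boundaries
    inclusive), of the absolute difference between the two samples'
    empirical quadrant fractions. Symmetric in A and B; 0 for identical
    point multisets, 1 under complete quadrant separation.
    """
    a = _as_points(points_a)
    b = _as_points(points_b)
    pts = np.vstack([a, b])
    in_a = np.zeros(len(pts), dtype=bool)
    in_a[: len(a)] = True
    return _quadrant_fraction_diff_max(pts, in_a)


def _units(points) -> list[np.ndarray]:
    """Normalize input into a list of per-sample point blocks."""
    if isinstance(points, np.ndarray):
        return [row.reshape(1, 2) for row in _as_points(points)]
    if isinstance(points, (list, tuple)) and points and np.ndim(points[0]) == 2:
        return [_as_points(p) for p in points]
    return [row.reshape(1, 2) for row in _as_points(points)]


def ks2d_pvalue(
    points_a,
    points_b,
    method: str = "permutation",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """P-value for the 2D KS statistic; returns (D, p).

    ``points_a``/``points_b`` may be flat (n, 2) arrays or lists of per-sample
    (n_i, 2) blocks. The permutation test permutes sample-group labels, so
    all points of one sample move together (flat arrays degrade to
    point-level permutation). p = (1 + #{D_perm >= D_obs}) / (n_perm + 1).

    The asymptotic method uses the Fasano-Franceschini large-n approximation
    of the D null distribution, with a correction for the within-sample
    correlation of the two coordinates.
    """
    units_a = _units(points_a)
    units_b = _units(points_b)
    a = np.vstack(units_a)
    b = np.vstack(units_b)
    pts = np.vstack([a, b])
    in_a = np.zeros(len(pts), dtype=bool)
    in_a[: len(a)] = True
    d_obs = _quadrant_fraction_diff_max(pts, in_a)

    if method == "asymptotic":
        n1, n2 = len(a), len(b)
        n_eff = n1 * n2 / (n1 + n2)

        def _r2(p):
            if len(p) < 2 or p[:, 0].std() == 0 or p[:, 1].std() == 0:
                return 0.0
            return float(np.corrcoef(p[:, 0], p[:, 1])[0, 1]) ** 2

        r2 = 0.5 * (_r2(a) + _r2(b))
        sq = np.sqrt(n_eff) * d_obs / (1.0 + np.sqrt(1.0 - r2) * (0.25 - 0.75 / np.sqrt(n_eff)))
        p = float(stats.kstwobign.sf(sq))
        return d_obs, min(1.0, max(p, 0.0))

    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 100:
        raise ValueError("permutation test requires n_perm >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    units = units_a + units_b
    sizes = [len(u) for u in units]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_units_a = len(units_a)
    n_pts = len(pts)
    na = float(len(a))
    nb = float(len(b))
    # one 0/1 column per permutation: all points of a sample move together
    W = np.zeros((n_pts, n_perm))
    for j in range(n_perm):
        perm = rng.permutation(len(units))
        for ui in perm[:n_units_a]:
            W[offsets[ui] : offsets[ui + 1], j] = 1.0
    mats, totals = _quadrant_matrices(pts)
    d_perm = np.zeros(n_perm)
    for q, tot in zip(mats, totals):
        ca = q @ W  # anchors x permutations
        np.maximum(d_perm, np.abs(ca / na - (tot[:, None] - ca) / nb).max(axis=0), out=d_perm)
    count = int((d_perm >= d_obs - 1e-12).sum())
    return d_obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# segmentation and DMR calling


def segment_cluster(
    cluster: ProbeCluster,
    m: MethylationMatrix,
    design: GroupDesign,
    min_probes: int = 3,
) -> list[ProbeCluster]:
    """Recursive binary segmentation of a cluster's group-difference signal.

    Splits at the probe boundary maximizing the difference between the two
    sub-segments' mean group differences, accepting a split only when it
    increases |deltaM| over the parent segment; segments shorter than
    2 * min_probes are left intact. Emitted candidates have >= min_probes
    probes.
    """
    beta = m.beta.loc[cluster.probe_ids]
    d = (
        beta[design.group_a_sample_ids].mean(axis=1)
        - beta[design.group_b_sample_ids].mean(axis=1)
    ).to_numpy()
    out: list[ProbeCluster] = []

    def emit(lo: int, hi: int) -> None:
        out.append(
            ProbeCluster(
                cluster.chrom, cluster.probe_ids[lo:hi], cluster.positions[lo:hi]
            )
        )

    def rec(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_probes:
            emit(lo, hi)
            return
        seg_mean = abs(d[lo:hi].mean())
        best_s, best_gain = None, -np.inf
        for s in range(lo + min_probes, hi - min_probes + 1):
            gain = abs(d[lo:s].mean() - d[s:hi].mean())
            if gain > best_gain:
                best_gain, best_s = gain, s
        left = abs(d[lo:best_s].mean())
        right = abs(d[best_s:hi].mean())
        if max(left, right) > seg_mean + 1e-12:
            rec(lo, best_s)
            rec(best_s, hi)
        else:
            emit(lo, hi)

    rec(0, len(cluster))
    return [c for c in out if len(c) >= min_probes]


@dataclasses.dataclass
class DMRParams:
    max_gap: int = 1000
    min_probes: int = 3
    p_method: str = "permutation"  # or "asymptotic"
    n_perm: int = 1000
    seed: int = 0
    scale_positions: bool = True  # min-max scale positions within each region
    segment: bool = True


def _region_points(
    beta: pd.DataFrame,
    probes: Sequence[str],
    positions: Sequence[int],
    sample_ids: Sequence[str],
    scale: bool,
) -> list[np.ndarray]:
    pos = np.asarray(positions, dtype=float)
    if scale:
        span = pos.max() - pos.min()
        pos = (pos - pos.min()) / span if span > 0 else np.zeros_like(pos)
    sub = beta.loc[list(probes), list(sample_ids)].to_numpy()
    return [np.column_stack([pos, sub[:, j]]) for j in range(sub.shape[1])]


def call_dmrs(
    m: MethylationMatrix,
    manifest: pd.DataFrame,
    design: GroupDesign,
    params: DMRParams | None = None,
) -> pd.DataFrame:
    """Full DMR pipeline: cluster, segment, 2D-KS test, deltaM, BH adjust.

    Returns a table sorted by adjusted p with columns chrom, start, end,
    n_probes, deltaM (group A - group B), ks2d_p, adj_p, snp_probes,
    cross_reactive, genes, probe_ids. Coordinates are 1-based inclusive.
    """
    params = params or DMRParams()
    missing = [
        s
        for s in design.group_a_sample_ids + design.group_b_sample_ids
        if s not in m.beta.columns
    ]
    if missing:
        raise ConsistencyError(f"design samples absent from matrix: {missing}")
    mf = manifest.loc[manifest.index.intersection(m.probe_ids)]
    rng = np.random.default_rng(params.seed)

    records = []
    for cluster in cluster_probes(mf, params.max_gap, params.min_probes):
        candidates = (
            segment_cluster(cluster, m, design, params.min_probes)
            if params.segment
            else [cluster]
        )
        for cand in candidates:
            pa = _region_points(
                m.beta, cand.probe_ids, cand.positions, design.group_a_sample_ids, params.scale_positions
            )
            pb = _region_points(
                m.beta, cand.probe_ids, cand.positions, design.group_b_sample_ids, params.scale_positions
            )
            d_stat, p = ks2d_pvalue(
                pa, pb, method=params.p_method, n_perm=params.n_perm, seed=rng
            )
            sub = m.beta.loc[cand.probe_ids]
            delta = float(
                (
                    sub[design.group_a_sample_ids].mean(axis=1)
                    - sub[design.group_b_sample_ids].mean(axis=1)
                ).mean()
            )
            ann = mf.loc[cand.probe_ids]
            genes = []
            for g in ann["genes"]:
                for name in str(g).split(";"):
                    if name and name not in genes:
                        genes.append(name)
            records.append(
                {
                    "chrom": cand.chrom,
                    "start": cand.start,
                    "end": cand.end,
                    "n_probes": len(cand),
                    "deltaM": delta,
                    "ks2d_D": d_stat,
                    "ks2d_p": p,
                    "snp_probes": int(ann["snp"].sum()),
                    "cross_reactive": int(ann["cross_reactive"].sum()),
                    "genes": ",".join(genes),
                    "probe_ids": ";".join(cand.probe_ids),
                }
            )
    table = pd.DataFrame(
        records,
        columns=[
            "chrom",
            "start",
            "end",
            "n_probes",
            "deltaM",
            "ks2d_D",
            "ks2d_p",
            "adj_p",
            "snp_probes",
            "cross_reactive",
            "genes",
            "probe_ids",
        ],
    )
    if len(table):
        table["adj_p"] = bh_adjust(table["ks2d_p"].to_numpy())
        table = table.sort_values(["adj_p", "ks2d_p", "chrom", "start"], kind="stable")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# single-CpG analysis and BH


def dmp_single_cpg(
    m: MethylationMatrix,
    outcome=None,
    paired: bool = False,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-probe differential methylation by OLS / paired t.

    Unpaired: regress each probe's betas on ``outcome`` (binary group coding
    or continuous); the slope t-test equals the two-sample t for a binary
    outcome. Paired: one-sample t on within-subject (second - first)
    differences over ``pairs`` of sample ids. Zero-variance probes get p = 1
    and a flag. q is BH across probes.
    """
    B = m.beta.to_numpy()
    if paired:
        if not pairs:
            raise ValueError("paired mode requires pairs of sample ids")
        ia = [m.beta.columns.get_loc(a) for a, _ in pairs]
        ib = [m.beta.columns.get_loc(b) for _, b in pairs]
        D = B[:, ib] - B[:, ia]
        n = D.shape[1]
        mean_d = D.mean(axis=1)
        sd_d = D.std(axis=1, ddof=1)
        flag = sd_d == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_d / (sd_d / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
        p = np.where(flag & (mean_d == 0), 1.0, p)
        p = np.where(flag & (mean_d != 0), 0.0, p)
        t = np.where(flag, 0.0, t)
        effect = mean_d
    else:
        y = np.asarray(outcome, dtype=float)
        if len(y) != m.n_samples:
            raise ValueError("outcome length must equal the number of samples")
        n = len(y)
        yc = y - y.mean()
        sy = np.sqrt((yc**2).sum())
        if sy == 0:
            raise ValueError("constant outcome")
        Bc = B - B.mean(axis=1, keepdims=True)
        sb = np.sqrt((Bc**2).sum(axis=1))
        flag = sb == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Bc @ yc) / (sb * sy)
        r = np.clip(np.nan_to_num(r), -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(flag, 1.0, p)
        t = np.where(flag, 0.0, t)
        with np.errstate(divide="ignore", invalid="ignore"):
            effect = np.where(flag, 0.0, (Bc @ yc) / (yc**2).sum())
    out = pd.DataFrame(
        {
            "effect": effect,
            "statistic": t,
            "p": p,
            "q": bh_adjust(p),
            "zero_variance": flag,
        },
        index=m.probe_ids,
    )
    return out.sort_values("p", kind="stable")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model-style wrapper


class DMRAnalysis:
    """DMR discovery model between two sample groups.

    Either pass an explicit ``design`` or a phenotype table, in which case
    the responder/non-responder design is derived (top/bottom
    ``n_per_group`` male subjects by relative weight change, both
    timepoints pooled).
    """

    def __init__(
        self,
        m: MethylationMatrix,
        manifest: pd.DataFrame,
        design: GroupDesign | None = None,
        pheno: pd.DataFrame | None = None,
        params: DMRParams | None = None,
        n_per_group: int = 10,
    ):
        if design is None:
            if pheno is None:
                raise ValueError("need either a design or a phenotype table")
            design = select_responders(pheno, n_per_group=n_per_group)
        self.m = m
        self.manifest = manifest
        self.design = design
        self.params = params or DMRParams()

    def fit(self) -> "DMRResults":
        table = call_dmrs(self.m, self.manifest, self.design, self.params)
        return DMRResults(self, table)


class DMRResults:
    def __init__(self, model: DMRAnalysis, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["adj_p"] < 0.05]

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "DMR analysis (2D-KS)",
            "=" * 20,
            f"groups: {d.label_a} (n={len(d.group_a_sample_ids)}) vs "
            f"{d.label_b} (n={len(d.group_b_sample_ids)})"
            + (" [combined timepoints]" if d.combined_timepoints else ""),
            f"candidate regions tested: {len(self.table)}",
            f"significant at adj_p < 0.05: {len(self.significant)}",
        ]
        if d.mean_age_a is not None:
            lines.append(
                f"mean age {d.label_a}: {d.mean_age_a:.1f}  {d.label_b}: {d.mean_age_b:.1f}"
                + ("  [age imbalance flagged]" if d.age_balance_flag else "")
            )
        if len(self.significant):
            cols = ["chrom", "start", "end", "n_probes", "deltaM", "ks2d_p", "adj_p", "genes"]
            lines.append(self.significant[cols].round(4).to_string(index=False))
        return "\n".join(lines)
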