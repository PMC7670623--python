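"""Combined Pearson/Spearman EWAS against relative weight change.

Each baseline CpG is correlated with the subject's relative weight change
(percent of initial body weight) using both Pearson (linearity) and
Spearman (monotonicity) statistics; the two two-sided p-values are combined
by their geometric mean, and the combined correlation is reported as the
arithmetic mean of r and rho (with a flag when the two disagree in sign).
The same machinery serves correlations of candidate probes with clinical
phenotypes, and paired t-tests of trait changes between timepoints.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConsistencyError, MethylationMatrix
from .differential import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CombinedCorrelation",
    "relative_weight_change",
    "combined_correlation",
    "ewas_scan",
    "phenotype_correlations",
    "paired_change_tests",
    "annotate_features_to_genes",
    "EWAS",
    "EWASResults",
]


def relative_weight_change(pheno: pd.DataFrame) -> pd.Series:
    """Per-subject relative weight change, (wT18 - wT0)/wT0 * 100 (negative = loss)."""
    subj = pheno.drop_duplicates("subject_id").set_index("subject_id")
    problems = []
    for sid, row in subj.iterrows():
        if not np.isfinite(row.get("weight_T0", np.nan)) or row.get("weight_T0", 0) <= 0:
            problems.append(f"{sid}: invalid T0 weight")
        elif not np.isfinite(row.get("weight_T18", np.nan)):
            problems.append(f"{sid}: missing T18 weight")
    if problems:
        raise ValueError("weight-change errors: " + "; ".join(problems))
    return ((subj["weight_T18"] - subj["weight_T0"]) / subj["weight_T0"] * 100.0).rename(
        "relative_change_pct"
    )


@dataclasses.dataclass
class CombinedCorrelation:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    combined_p: float
    combined_r: float
    sign_discordant: bool


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float | None:
    """Exact two-sided Spearman p for n <= 9 without ties, by enumeration."""
    n = len(x)
    if n > 9:
        return None
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if len(set(rx)) < n or len(set(ry)) < n:
        return None  # ties: fall back to the t approximation
    d2_obs = ((rx - ry) ** 2).sum()
    ranks = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))))
    d2 = ((ranks[perms] - ry[None, :]) ** 2).sum(axis=1)
    denom = n * (n**2 - 1) / 6.0
    rho = np.abs(1 - d2 / denom)
    rho_obs = abs(1 - d2_obs / denom)
    return float((rho >= rho_obs - 1e-12).mean())


def combined_correlation(x, y) -> CombinedCorrelation:
    """Pearson + Spearman correlation with geometric-mean combined p.

    combined_p = sqrt(pearson_p * spearman_p), computed in log space to
    survive extreme significance; combined_r = (r + rho)/2 with a
    discordant-sign flag. Spearman p is exact (enumeration) for n <= 9
    without ties, the t approximation otherwise. Requires n >= 4 and two
    non-constant finite vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    exact = _exact_spearman_p(x, y)
    if exact is not None:
        sp = exact
    combined_p = _geometric_mean_p(pp, sp)
    discord = bool(np.sign(pr) * np.sign(sr) < 0)
    return CombinedCorrelation(
        pearson_r=float(pr),
        pearson_p=float(pp),
        spearman_rho=float(sr),
        spearman_p=float(sp),
        combined_p=combined_p,
        combined_r=float((pr + sr) / 2),
        sign_discordant=discord,
    )


def _geometric_mean_p(*ps: float) -> float:
    ps_arr = np.asarray(ps, dtype=float)
    if (ps_arr == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(ps_arr))))


def _corr_t_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def _vector_corr(B: np.ndarray, y: np.ndarray) -> np.ndarray:
    Bc = B - B.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Bc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Bc @ yc) / denom
    return np.nan_to_num(r)


def ewas_scan(
    m_baseline: MethylationMatrix,
    wc: pd.Series,
    manifest: pd.DataFrame | None = None,
    thresholds: tuple[float, ...] = (1e-3, 1e-4, 1e-2),
) -> pd.DataFrame:
    """Epigenome-wide combined Pearson/Spearman scan against weight change.

    ``m_baseline`` must hold one baseline sample per subject; ``wc`` maps
    subject id (or sample id) to relative weight change. Vectorized across
    probes with t-approximation p-values. Returns a table sorted by
    combined_p with threshold-tier memberships and manifest annotations.
    """
    y = _align_outcome(wc, m_baseline)
    B = m_baseline.beta.to_numpy()
    n = len(y)
    if n < 4:
        raise ConsistencyError("need at least 4 samples")
    r = _vector_corr(B, y)
    pearson_p = _corr_t_p(r, n)
    ranks = stats.rankdata(B, axis=1)
    ry = stats.rankdata(y)
    rho = _vector_corr(ranks, ry)
    spearman_p = _corr_t_p(rho, n)
    with np.errstate(divide="ignore"):
        combined_p = np.exp(0.5 * (np.log(pearson_p) + np.log(spearman_p)))
    out = pd.DataFrame(
        {
            "pearson_r": r,
            "pearson_p": pearson_p,
            "spearman_rho": rho,
            "spearman_p": spearman_p,
            "combined_p": combined_p,
            "combined_r": (r + rho) / 2,
            "sign_discordant": np.sign(r) * np.sign(rho) < 0,
        },
        index=m_baseline.probe_ids,
    )
    for thr in thresholds:
        out[f"below_{thr:g}"] = out["combined_p"] < thr
    if manifest is not None:
        ann = manifest.reindex(out.index)
        out["chrom"] = ann["chrom"]
        out["pos"] = ann["pos"]
        out["snp_flag"] = ann["snp"].fillna(0).astype(int)
        out["cross_reactive_flag"] = ann["cross_reactive"].fillna(0).astype(int)
        out["genes"] = ann["genes"].fillna("")
    return out.sort_values("combined_p", kind="stable")


def _align_outcome(wc: pd.Series, m: MethylationMatrix) -> np.ndarray:
    """Map a subject- or sample-indexed outcome onto the matrix columns."""
    cols = m.sample_ids
    if set(cols).issubset(set(wc.index)):
        return wc.loc[cols].to_numpy(dtype=float)
    # samples named <subject>_<timepoint>
    subjects = [c.rsplit("_", 1)[0] for c in cols]
    if set(subjects).issubset(set(wc.index)):
        return wc.loc[subjects].to_numpy(dtype=float)
    raise ConsistencyError("outcome index matches neither sample nor subject ids")


def phenotype_correlations(
    m: MethylationMatrix,
    pheno: pd.DataFrame,
    traits: list[str],
    probe_set: list[str],
) -> pd.DataFrame:
    """Combined correlations of candidate probes with clinical traits.

    For each probe and trait: the trait level at T0 and at T18 (against the
    methylation of the matching timepoint samples) and the T18-T0 trait
    change (against baseline methylation). BH adjustment across the whole
    table. Traits with < 4 non-missing values are skipped with a warning.
    """
    missing = [p for p in probe_set if p not in m.beta.index]
    if missing:
        raise ConsistencyError(f"probes absent from matrix: {missing}")
    if len(probe_set) == 0:
        return pd.DataFrame(
            columns=["probe_id", "trait", "contrast", "pearson_r", "spearman_rho", "combined_p", "q"]
        )
    ph = pheno.set_index("sample_id")
    rows = []
    for trait in traits:
        contrasts = {}
        for tp in ("T0", "T18"):
            sub = ph[(ph["timepoint"] == tp)]
            sub = sub[sub.index.isin(m.sample_ids)]
            vals = sub[trait]
            ok = vals.notna()
            if ok.sum() < 4:
                logger.warning("trait %s at %s: <4 non-missing values, skipped", trait, tp)
                continue
            contrasts[f"level_{tp}"] = (list(sub.index[ok]), vals[ok].to_numpy(dtype=float))
        piv = pheno.pivot_table(index="subject_id", columns="timepoint", values=trait, aggfunc="first")
        if {"T0", "T18"}.issubset(piv.columns):
            delta = (piv["T18"] - piv["T0"]).dropna()
            t0_samples = ph[(ph["timepoint"] == "T0") & ph["subject_id"].isin(delta.index)]
            t0_samples = t0_samples[t0_samples.index.isin(m.sample_ids)]
            order = t0_samples["subject_id"]
            if len(order) >= 4:
                contrasts["delta_T18_T0"] = (list(t0_samples.index), delta.loc[order].to_numpy(dtype=float))
        for probe in probe_set:
            for contrast, (samples, vals) in contrasts.items():
                betas = m.beta.loc[probe, samples].to_numpy(dtype=float)
                if betas.std() == 0 or np.std(vals) == 0:
                    continue
                cc = combined_correlation(betas, vals)
                rows.append(
                    {
                        "probe_id": probe,
                        "trait": trait,
                        "contrast": contrast,
                        "pearson_r": cc.pearson_r,
                        "spearman_rho": cc.spearman_rho,
                        "combined_p": cc.combined_p,
                    }
                )
    out = pd.DataFrame(rows, columns=["probe_id", "trait", "contrast", "pearson_r", "spearman_rho", "combined_p"])
    if len(out):
        out["q"] = bh_adjust(out["combined_p"].to_numpy())
    else:
        out["q"] = []
    return out


def paired_change_tests(pheno: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Paired t-tests of trait changes between T0 and T18.

    Reports mean +/- SD at each timepoint, the mean change, the paired t
    statistic and two-sided p. Subjects lacking either timepoint are
    excluded (count reported). A constant non-zero shift with zero
    difference variance is degenerate and reported as p = 0 with a flag.
    """
    rows = []
    for trait in traits:
        piv = pheno.pivot_table(index="subject_id", columns="timepoint", values=trait, aggfunc="first")
        if "T0" not in piv.columns or "T18" not in piv.columns:
            continue
        ok = piv[["T0", "T18"]].notna().all(axis=1)
        excluded = int((~ok).sum())
        a = piv.loc[ok, "T0"].to_numpy(dtype=float)
        b = piv.loc[ok, "T18"].to_numpy(dtype=float)
        d = b - a
        degenerate = False
        if len(d) >= 2 and d.std(ddof=1) == 0:
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p, degenerate = np.inf * np.sign(d.mean()), 0.0, True
        else:
            t, p = stats.ttest_rel(b, a)
        rows.append(
            {
                "trait": trait,
                "n": len(d),
                "n_excluded": excluded,
                "mean_T0": a.mean(),
                "sd_T0": a.std(ddof=1),
                "mean_T18": b.mean(),
                "sd_T18": b.std(ddof=1),
                "mean_change": d.mean(),
                "sd_change": d.std(ddof=1) if len(d) > 1 else 0.0,
                "t": float(t),
                "p": float(p),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def annotate_features_to_genes(
    features: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 1500,
) -> list[str]:
    """Annotate features with genes extended upstream on their strand.

    ``features``: columns chrom, start, end (1-based inclusive; a CpG has
    start == end). ``genes``: columns chrom, start, end, strand, name
    (1-based inclusive). Each gene is extended ``upstream`` nt upstream of
    its TSS ('+': lower coordinate; '-': higher), clipped at 1; a feature is
    annotated with every extended gene interval it overlaps. Returns one
    comma-joined gene string per feature row, genes in input order.
    """
    from intervaltree import IntervalTree

    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene intervals must satisfy start <= end")
    trees: dict[str, IntervalTree] = {}
    for i, g in genes.reset_index(drop=True).iterrows():
        strand = g.get("strand", "+")
        if strand not in ("+", "-"):
            logger.warning("unknown strand %r for gene %s; treating as '+'", strand, g["name"])
            strand = "+"
        start, end = int(g["start"]), int(g["end"])
        if strand == "+":
            start = max(1, start - upstream)
        else:
            end = end + upstream
        # interval tree uses half-open [begin, end); inclusive end -> end + 1
        trees.setdefault(g["chrom"], IntervalTree()).addi(start, end + 1, (i, g["name"]))
    out = []
    for _, f in features.iterrows():
        if f["start"] > f["end"]:
            raise ValueError("feature start > end")
        tree = trees.get(f["chrom"])
        hits = sorted(tree.overlap(int(f["start"]), int(f["end"]) + 1)) if tree else []
        names = []
        for iv in sorted(hits, key=lambda iv: iv.data[0]):
            if iv.data[1] not in names:
                names.append(iv.data[1])
        out.append(",".join(names))
    return out


# ---------------------------------------------------------------------------
# model-style wrapper


class EWAS:
    """EWAS model: baseline methylation vs relative weight change.

    Pass the full matrix and phenotype table; the baseline (T0) samples are
    selected automatically and the per-subject relative weight change is
    computed from the weight trajectory.
    """

    def __init__(
        self,
        m: MethylationMatrix,
        pheno: pd.DataFrame,
        manifest: pd.DataFrame | None = None,
        thresholds: tuple[float, ...] = (1e-3, 1e-4, 1e-2),
    ):
        self.pheno = pheno
        self.manifest = manifest
        self.thresholds = thresholds
        t0 = pheno[pheno["timepoint"] == "T0"]
        self.baseline = m.subset_samples([s for s in m.sample_ids if s in set(t0["sample_id"])])
        self.weight_change = relative_weight_change(pheno)

    def fit(self) -> "EWASResults":
        table = ewas_scan(self.baseline, self.weight_change, self.manifest, self.thresholds)
        return EWASResults(self, table)


class EWASResults:
    def __init__(self, model: EWAS, table: pd.DataFrame):
        self.model = model
        self.table = table

    def hits(self, threshold: float = 1e-4) -> pd.DataFrame:
        return self.table[self.table["combined_p"] < threshold]

    def summary(self) -> str:
        lines = [
            "EWAS: baseline methylation vs relative weight change",
            "=" * 52,
            f"probes: {len(self.table)}  samples: {self.model.baseline.n_samples}",
        ]
        for thr in self.model.thresholds:
            lines.append(f"combined_p < {thr:g}: {int((self.table['combined_p'] < thr).sum())} CpGs")
        top = self.table.head(10)
        cols = [c for c in ("chrom", "pos", "combined_p", "combined_r", "genes") if c in top.columns]
        if not cols:
            cols = ["combined_p", "combined_r"]
        lines.append("top CpGs:")
        lines.append(top[cols].to_string())
        return "\n".join(lines)
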