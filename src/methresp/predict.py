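"""Baseline methylation scores and ROC prediction of weight-loss success.

Four predictor CpG sets are selected from the EWAS table by correlation
sign x combined-p threshold (p < 1e-3 and p < 1e-4, each sign); a sample's
methylation score is the unweighted mean of its betas over the set. Scores
are benchmarked by ROC/AUC against a linear age/BMI baseline whose
coefficients are chosen by an exhaustive direction (angle-grid) search that
maximizes in-sample AUC. Because CpG selection and evaluation share the
same samples, these AUCs quantify in-sample separation, not generalization
— the selection bias is itself measurable by label permutation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .differential import GroupDesign

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSpec",
    "ROCResult",
    "build_predictor_sets",
    "methylation_score",
    "roc_auc",
    "fit_age_bmi_predictor",
    "evaluate_predictors",
    "WeightLossPrediction",
    "WeightLossPredictionResults",
]


@dataclasses.dataclass
class PredictorSpec:
    """A threshold/sign-selected CpG set scoring predictor."""

    name: str
    cpg_ids: list[str]
    selection_sign: str  # "negative" | "positive"
    selection_threshold: float
    orientation: int  # +1: higher score predicts success (greater loss)

    def __post_init__(self) -> None:
        if not self.cpg_ids:
            raise ValueError("cpg_ids must be non-empty")
        if not 0 < self.selection_threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclasses.dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def build_predictor_sets(
    assoc: pd.DataFrame, thresholds: tuple[float, float] = (1e-3, 1e-4)
) -> list[PredictorSpec]:
    """Four CpG sets by (combined_r sign) x (combined_p threshold).

    CpGs correlating negatively with weight change are hypomethylated-at-
    baseline markers of success: for those sets a higher mean beta predicts
    greater weight loss (orientation +1); positive sets are oriented the
    other way. Empty sets are omitted with a warning.
    """
    specs = []
    for sign_label, mask, orientation in (
        ("negative", assoc["combined_r"] < 0, +1),
        ("positive", assoc["combined_r"] > 0, -1),
    ):
        for thr in thresholds:
            ids = list(assoc.index[mask & (assoc["combined_p"] < thr)])
            name = f"{sign_label}_p{thr:g}"
            if not ids:
                logger.warning("predictor %s: no CpGs below threshold; omitted", name)
                continue
            specs.append(
                PredictorSpec(
                    name=name,
                    cpg_ids=ids,
                    selection_sign=sign_label,
                    selection_threshold=thr,
                    orientation=orientation,
                )
            )
    return specs


def methylation_score(m_baseline, spec: PredictorSpec) -> pd.Series:
    """Per-sample mean beta over the predictor's CpG set."""
    missing = [c for c in spec.cpg_ids if c not in m_baseline.beta.index]
    if missing:
        raise ValueError(f"CpGs absent from matrix: {missing}")
    return m_baseline.beta.loc[spec.cpg_ids].mean(axis=0).rename(spec.name)


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC over all cut-points; trapezoidal AUC (ties count 1/2).

    Equivalent to the Mann-Whitney concordance probability
    U / (n_pos * n_neg).
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, thresholds = roc_curve(y, s)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(roc_auc_score(y, s)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC via average ranks (ties count one half)."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def fit_age_bmi_predictor(
    age, bmi, labels, grid: int = 721
) -> tuple[float, float, ROCResult]:
    """AUC-maximizing linear combination x*age + y*BMI by angle-grid search.

    The ROC of a linear score depends only on its direction, so scanning
    (x, y) = (cos t, sin t) over a grid on [0, 2pi) is exhaustive up to
    resolution. Returns the best (x, y) rescaled so x = -1 when x != 0
    (raw unit-vector coefficients in ``result`` attrs are recoverable by
    renormalization), together with its ROC.
    """
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    y = np.asarray(labels).astype(int)
    if grid < 180:
        raise ValueError("grid must provide at least 180 angles")
    if age.std() == 0 and bmi.std() == 0:
        raise ValueError("degenerate covariates: age and BMI both constant")
    best = (-np.inf, 0.0, 0.0)
    for theta in np.linspace(0.0, 2 * np.pi, grid, endpoint=False):
        cx, cy = np.cos(theta), np.sin(theta)
        score = cx * age + cy * bmi
        if score.std() == 0:
            continue
        auc = _rank_auc(score, y)
        if auc > best[0]:
            best = (auc, cx, cy)
    _, cx, cy = best
    res = roc_auc(cx * age + cy * bmi, y)
    if abs(cx) > 1e-12:
        # rescale for comparability; the ROC reported is that of the raw
        # maximizing direction (rescaling by a negative factor flips the
        # score's orientation, whose AUC is 1 - auc)
        x_out, y_out = -1.0, cy * (-1.0 / cx)
    else:
        x_out, y_out = 0.0, float(np.sign(cy) or 1.0)
    return float(x_out), float(y_out), res


def evaluate_predictors(
    m_baseline,
    assoc: pd.DataFrame,
    pheno: pd.DataFrame,
    design: GroupDesign,
    thresholds: tuple[float, float] = (1e-3, 1e-4),
    grid: int = 721,
) -> pd.DataFrame:
    """AUC comparison of the 4 methylation scores and the age/BMI baseline.

    Success = responder-group membership from the design; evaluation is on
    the design's subjects only (one baseline sample each). The returned
    table carries a circularity note: predictor CpGs were selected on the
    same data they are evaluated on.
    """
    subjects = list(design.group_a_subjects) + list(design.group_b_subjects)
    labels = np.array([1] * len(design.group_a_subjects) + [0] * len(design.group_b_subjects))
    t0 = pheno[(pheno["timepoint"] == "T0") & pheno["subject_id"].isin(subjects)]
    t0 = t0.set_index("subject_id").loc[subjects]
    sample_ids = t0["sample_id"].tolist()
    sub = m_baseline.subset_samples([s for s in m_baseline.sample_ids if s in set(sample_ids)])
    sub = sub.subset_samples(sample_ids)

    rows = []
    for spec in build_predictor_sets(assoc, thresholds):
        score = methylation_score(sub, spec).to_numpy() * spec.orientation
        res = roc_auc(score, labels)
        rows.append(
            {
                "predictor": spec.name,
                "kind": "methylation",
                "n_cpgs": len(spec.cpg_ids),
                "auc": res.auc,
            }
        )
    x, yc, res = fit_age_bmi_predictor(
        t0["age"].to_numpy(), t0["bmi"].to_numpy(), labels, grid=grid
    )
    rows.append(
        {
            "predictor": f"age_bmi(x={x:.2f},y={yc:.2f})",
            "kind": "clinical",
            "n_cpgs": 0,
            "auc": res.auc,
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["caveat"] = (
        "methylation predictor CpGs were selected on the same samples they are "
        "evaluated on; AUCs measure in-sample separation, not generalization"
    )
    return out


# ---------------------------------------------------------------------------
# model-style wrapper


class WeightLossPrediction:
    """Prediction model: methylation scores vs age/BMI baseline on one design."""

    def __init__(
        self,
        m_baseline,
        assoc: pd.DataFrame,
        pheno: pd.DataFrame,
        design: GroupDesign,
        thresholds: tuple[float, float] = (1e-3, 1e-4),
        grid: int = 721,
    ):
        self.m_baseline = m_baseline
        self.assoc = assoc
        self.pheno = pheno
        self.design = design
        self.thresholds = thresholds
        self.grid = grid

    def fit(self) -> "WeightLossPredictionResults":
        table = evaluate_predictors(
            self.m_baseline, self.assoc, self.pheno, self.design, self.thresholds, self.grid
        )
        return WeightLossPredictionResults(self, table)


class WeightLossPredictionResults:
    def __init__(self, model: WeightLossPrediction, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        lines = [
            "Weight-loss success prediction (ROC/AUC)",
            "=" * 41,
            self.table.round(4).to_string(index=False),
            f"note: {self.table.attrs['caveat']}",
        ]
        return "\n".join(lines)
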