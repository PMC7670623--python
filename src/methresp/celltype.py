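"""Reference-based cell-type deconvolution and composition adjustment.

Whole-blood methylation is a mixture over leukocyte subtypes; each sample's
subtype proportions are estimated by constrained projection of its marker
betas onto reference mean profiles (non-negative least squares followed by
renormalization onto the simplex — the Houseman-style constrained
projection). Composition differences between timepoints are tested with
paired Wilcoxon signed-rank tests, and betas can be residualized on the
estimated proportions so downstream contrasts are not driven by composition.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import wilcoxon

from .containers import ConsistencyError, MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CellReference",
    "estimate_cell_proportions",
    "compare_composition",
    "adjust_for_composition",
    "CellTypeDeconvolution",
    "CellTypeResults",
]


@dataclasses.dataclass
class CellReference:
    """Marker-probe x cell-type matrix of reference mean betas."""

    profile: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profile.shape[1] < 2:
            raise ValueError("need at least two cell types")
        vals = self.profile.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("reference profiles must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profile.columns)

    @property
    def marker_ids(self) -> pd.Index:
        return self.profile.index


def estimate_cell_proportions(m: MethylationMatrix, ref: CellReference) -> pd.DataFrame:
    """Estimate sample x cell-type proportions by constrained least squares.

    Per sample, proportions minimize the squared error between observed
    marker betas and the reference-profile mixture subject to non-negativity,
    then are renormalized to sum to one. Deterministic given inputs.
    """
    shared = ref.marker_ids.intersection(m.probe_ids)
    k = len(ref.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"under-determined: {len(shared)} shared marker probes for {k} cell types"
        )
    A = ref.profile.loc[shared].to_numpy()
    B = m.beta.loc[shared].to_numpy()
    out = np.zeros((m.n_samples, k))
    for j in range(m.n_samples):
        w, _ = nnls(A, B[:, j])
        total = w.sum()
        out[j] = w / total if total > 0 else np.full(k, 1.0 / k)
    return pd.DataFrame(out, index=m.sample_ids, columns=ref.cell_types)


def compare_composition(
    props: pd.DataFrame,
    pheno: pd.DataFrame,
    pairing: str = "subject_id",
    timepoints: tuple[str, str] = ("T0", "T18"),
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank test of composition change per cell type.

    Zero paired differences are dropped (standard signed-rank convention);
    the exact null distribution is used for n <= 25 pairs, the normal
    approximation with continuity correction above. If all differences are
    zero the p-value is 1.
    """
    t0, t1 = timepoints
    ph = pheno.set_index("sample_id")
    for tp in (t0, t1):
        counts = ph[ph["timepoint"] == tp].groupby(pairing).size()
        if (counts != 1).any():
            bad = counts[counts != 1].index.tolist()
            raise ConsistencyError(f"subjects without exactly one {tp} sample: {bad}")
    a = ph[ph["timepoint"] == t0].reset_index().set_index(pairing)
    b = ph[ph["timepoint"] == t1].reset_index().set_index(pairing)
    subjects = a.index.intersection(b.index)
    if not a.index.symmetric_difference(b.index).empty:
        missing = list(a.index.symmetric_difference(b.index))
        raise ConsistencyError(f"unpaired subjects: {missing}")
    rows = []
    for ct in props.columns:
        d = (
            props.loc[b.loc[subjects, "sample_id"], ct].to_numpy()
            - props.loc[a.loc[subjects, "sample_id"], ct].to_numpy()
        )
        nz = d[d != 0]
        if len(nz) == 0:
            stat, p = 0.0, 1.0
        else:
            method = "exact" if len(nz) <= 25 else "approx"
            res = wilcoxon(nz, zero_method="wilcox", correction=True, method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "cell_type": ct,
                "median_diff": float(np.median(d)),
                "n_pairs": len(d),
                "n_nonzero": len(nz),
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def adjust_for_composition(m: MethylationMatrix, props: pd.DataFrame) -> MethylationMatrix:
    """Residualize betas on cell-type proportions, keeping per-probe means.

    Per probe, the beta vector across samples is replaced by the residual of
    an OLS fit on (intercept + all-but-one proportion columns) plus the
    probe's grand mean, then clipped to [0, 1].
    """
    if set(props.index) != set(m.sample_ids):
        raise ConsistencyError("proportion samples differ from matrix samples")
    P = props.loc[m.sample_ids].to_numpy()
    X = np.column_stack([np.ones(len(P)), P[:, :-1]])  # drop one column: simplex
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient composition covariates; using minimum-norm fit")
    B = m.beta.to_numpy().T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, B, rcond=None)
    resid = B - X @ coef
    adjusted = resid.T + m.beta.to_numpy().mean(axis=1, keepdims=True)
    beta = pd.DataFrame(
        np.clip(adjusted, 0.0, 1.0), index=m.probe_ids, columns=m.sample_ids
    )
    return MethylationMatrix(beta, m.detection_p)


# ---------------------------------------------------------------------------
# model-style wrapper


class CellTypeDeconvolution:
    """Deconvolution model: estimate proportions, test changes, adjust betas.

    Parameters
    ----------
    m : MethylationMatrix
    ref : CellReference
    pheno : phenotype table with sample_id / subject_id / timepoint, used for
        the paired composition comparison (optional).
    """

    def __init__(self, m: MethylationMatrix, ref: CellReference, pheno: pd.DataFrame | None = None):
        self.m = m
        self.ref = ref
        self.pheno = pheno

    def fit(self) -> "CellTypeResults":
        props = estimate_cell_proportions(self.m, self.ref)
        comparison = None
        if self.pheno is not None:
            comparison = compare_composition(props, self.pheno)
        return CellTypeResults(self, props, comparison)


class CellTypeResults:
    def __init__(self, model: CellTypeDeconvolution, proportions: pd.DataFrame, comparison):
        self.model = model
        self.proportions = proportions
        self.comparison = comparison

    def adjusted_matrix(self) -> MethylationMatrix:
        return adjust_for_composition(self.model.m, self.proportions)

    def summary(self) -> str:
        lines = ["Cell-type deconvolution", "=" * 23]
        lines.append(f"samples: {len(self.proportions)}  cell types: {list(self.proportions.columns)}")
        lines.append("mean proportions:")
        lines.append(self.proportions.mean().round(4).to_string())
        if self.comparison is not None:
            lines.append("paired T0 vs T18 Wilcoxon:")
            lines.append(self.comparison.round(4).to_string())
        return "\n".join(lines)
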