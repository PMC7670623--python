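"""Probe-level QC and quantile normalization of beta values.

QC excludes probes whose detection p-value fails in more than a configurable
fraction of samples; known cross-reactive and SNP-overlapping probes are
flagged but never removed, so they can be reported alongside every result.
Normalization is plain column-wise quantile normalization on the beta
matrix: every sample is mapped onto the across-sample mean of the order
statistics, ties within a sample receiving the mean of their tied ranks'
reference values. Probe chemistry types are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .containers import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = ["QCReport", "filter_probes_by_detection", "flag_probes", "quantile_normalize"]


@dataclasses.dataclass
class QCReport:
    n_probes_in: int
    n_probes_excluded: int
    excluded_probe_ids: list[str]
    p_detect: float
    max_fail_fraction: float

    def __post_init__(self) -> None:
        assert self.n_probes_excluded == len(self.excluded_probe_ids) <= self.n_probes_in

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"excluded_probe_id": self.excluded_probe_ids})


def filter_probes_by_detection(
    m: MethylationMatrix,
    p_detect: float = 0.01,
    max_fail_fraction: float = 0.01,
) -> tuple[MethylationMatrix, QCReport]:
    """Drop probes failing detection in more than ``max_fail_fraction`` of samples.

    A probe fails in a sample when detection_p > ``p_detect``; it is excluded
    iff its failing-sample fraction strictly exceeds ``max_fail_fraction``
    (the boundary case is retained). Probe order is preserved.
    """
    if m.detection_p is None:
        raise ValueError("detection_p matrix required for detection filtering")
    fail_frac = (m.detection_p.to_numpy() > p_detect).mean(axis=1)
    drop = fail_frac > max_fail_fraction
    excluded = list(m.probe_ids[drop])
    kept = m.probe_ids[~drop]
    report = QCReport(
        n_probes_in=m.n_probes,
        n_probes_excluded=len(excluded),
        excluded_probe_ids=excluded,
        p_detect=p_detect,
        max_fail_fraction=max_fail_fraction,
    )
    logger.info("detection filter: excluded %d / %d probes", len(excluded), m.n_probes)
    return m.subset_probes(kept), report


def flag_probes(
    manifest: pd.DataFrame,
    cross_reactive_ids=(),
    snp_ids=(),
) -> pd.DataFrame:
    """Set cross-reactive / SNP flags on a manifest without removing probes.

    Ids absent from the manifest are ignored; their count is logged and
    stored in ``result.attrs['n_unknown_flag_ids']``.
    """
    out = manifest.copy()
    cross = set(cross_reactive_ids)
    snp = set(snp_ids)
    known = set(out.index)
    unknown = (cross - known) | (snp - known)
    if unknown:
        logger.warning("%d flag ids not present in manifest; ignored", len(unknown))
    if cross:
        out.loc[out.index.isin(cross), "cross_reactive"] = 1
    if snp:
        out.loc[out.index.isin(snp), "snp"] = 1
    out.attrs["n_unknown_flag_ids"] = len(unknown)
    return out


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Column-wise quantile normalization with tie-averaged reference values."""
    n, s = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    ref = sorted_x.mean(axis=1)  # mean k-th order statistic across samples
    out = np.empty_like(x, dtype=float)
    for j in range(s):
        col_sorted = sorted_x[:, j]
        vals = ref.copy()
        # average reference values over runs of tied input values
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    vals[start:i] = vals[start:i].mean()
                start = i
        out[order[:, j], j] = vals
    return out


def quantile_normalize(m: MethylationMatrix) -> MethylationMatrix:
    """Quantile-normalize betas so all samples share one value distribution.

    Missing values are disallowed; a single-sample matrix is returned
    unchanged with a warning.
    """
    x = m.beta.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing beta values; impute before normalization")
    if m.n_samples < 2:
        warnings.warn("quantile normalization skipped: single-sample matrix")
        return MethylationMatrix(m.beta.copy(), m.detection_p)
    out = _quantile_normalize_array(x)
    beta = pd.DataFrame(np.clip(out, 0.0, 1.0), index=m.probe_ids, columns=m.sample_ids)
    return MethylationMatrix(beta, m.detection_p)


def impute_probe_mean(m: MethylationMatrix) -> MethylationMatrix:
    """Optional pre-normalization step: replace missing betas by the probe mean."""
    beta = m.beta.copy()
    row_mean = beta.mean(axis=1)
    for col in beta.columns:
        mask = beta[col].isna()
        beta.loc[mask, col] = row_mean[mask]
    return MethylationMatrix(beta, m.detection_p)
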