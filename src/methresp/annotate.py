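"""Chromatin-state annotation and probe-bias-corrected gene-set enrichment.

Features (DMRs or single CpGs) are intersected with user-supplied
chromatin-state segmentations (BED-style, one per tissue) and summarized
per tissue group by the majority state. Gene-set enrichment of hit probes
resamples probes (not genes) uniformly from the array universe, so genes
covered by many probes are drawn proportionally more often — this is the
correction for the probe-per-gene abundance bias of methylation arrays.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .differential import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "StateSegmentation",
    "EnrichmentResult",
    "intersect_states",
    "gene_set_enrichment",
]


@dataclasses.dataclass
class StateSegmentation:
    """Chromatin-state intervals for one tissue (0-based half-open)."""

    tissue_label: str
    intervals: pd.DataFrame  # columns: chrom, start, end, state

    def __post_init__(self) -> None:
        iv = self.intervals
        if (iv["start"] >= iv["end"]).any():
            raise ValueError(f"{self.tissue_label}: empty or inverted interval")
        for chrom, sub in iv.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"{self.tissue_label}: overlapping intervals on {chrom}")

    def tree(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for _, row in self.intervals.iterrows():
            trees.setdefault(row["chrom"], IntervalTree()).addi(
                int(row["start"]), int(row["end"]), row["state"]
            )
        return trees


@dataclasses.dataclass
class EnrichmentResult:
    gene_set: str
    n_hit_genes: int
    n_set_genes: int
    p_resampled: float
    q: float = np.nan


def intersect_states(
    features: pd.DataFrame,
    segmentations: list[StateSegmentation],
    tissue_groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-feature, per-tissue overlapping states with bp overlap.

    ``features`` uses 1-based inclusive coordinates (columns chrom, start,
    end; CpGs have start == end) and is converted internally to the
    segmentations' 0-based half-open convention. Per tissue group the
    majority state across member tissues is reported ('.' when a feature's
    chromosome is absent; ties multi-reported joined by '|').
    """
    if (features["start"] > features["end"]).any():
        raise ValueError("feature end < start: coordinate convention mismatch")
    trees = {seg.tissue_label: seg.tree() for seg in segmentations}
    rows = []
    for fi, f in features.reset_index(drop=True).iterrows():
        f0, f1 = int(f["start"]) - 1, int(f["end"])  # to 0-based half-open
        for tissue, tr in trees.items():
            chrom_tree = tr.get(f["chrom"])
            if chrom_tree is None:
                rows.append({"feature": fi, "tissue": tissue, "state": ".", "bp": 0})
                continue
            hits = chrom_tree.overlap(f0, f1)
            if not hits:
                rows.append({"feature": fi, "tissue": tissue, "state": ".", "bp": 0})
            for iv in sorted(hits, key=lambda iv: iv.begin):
                bp = min(iv.end, f1) - max(iv.begin, f0)
                rows.append({"feature": fi, "tissue": tissue, "state": iv.data, "bp": int(bp)})
    per_tissue = pd.DataFrame(rows, columns=["feature", "tissue", "state", "bp"])
    if tissue_groups is None:
        return per_tissue

    group_rows = []
    for fi in per_tissue["feature"].unique():
        sub = per_tissue[per_tissue["feature"] == fi]
        for group, members in tissue_groups.items():
            g = sub[sub["tissue"].isin(members) & (sub["state"] != ".")]
            if g.empty:
                group_rows.append({"feature": fi, "group": group, "majority_state": "."})
                continue
            # majority by summed bp overlap across member tissues
            votes = g.groupby("state")["bp"].sum()
            top = votes[votes == votes.max()]
            group_rows.append(
                {
                    "feature": fi,
                    "group": group,
                    "majority_state": "|".join(sorted(top.index)),
                }
            )
    out = pd.DataFrame(group_rows)
    out.attrs["per_tissue"] = per_tissue
    return out


def _genes_of(probes, manifest: pd.DataFrame) -> set[str]:
    genes: set[str] = set()
    for g in manifest.loc[list(probes), "genes"]:
        for name in str(g).split(";"):
            if name:
                genes.add(name)
    return genes


def gene_set_enrichment(
    hit_probes,
    universe: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_resample: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe-resampling gene-set enrichment controlling probe-per-gene bias.

    The null draws |hit_probes| probes uniformly from the manifest universe
    (so heavily probed genes appear in null draws proportionally often),
    maps them to genes and counts the overlap with each set;
    p = (1 + #{null >= observed}) / (n_resample + 1), BH-adjusted across
    sets. Empty gene sets are skipped with a warning.
    """
    hit_probes = list(hit_probes)
    unknown = [p for p in hit_probes if p not in universe.index]
    if unknown:
        raise ValueError(f"hit probes outside universe: {unknown}")
    rng = np.random.default_rng(seed)
    hit_genes = _genes_of(hit_probes, universe)

    sets = {}
    for sid, genes in gene_sets.items():
        genes = [g for g in genes if g]
        if not genes:
            logger.warning("gene set %s is empty; skipped", sid)
            continue
        sets[sid] = set(genes)
    observed = {sid: len(hit_genes & genes) for sid, genes in sets.items()}

    n_hit = len(hit_probes)
    universe_ids = universe.index.to_numpy()
    exceed = {sid: 0 for sid in sets}
    for _ in range(n_resample):
        draw = rng.choice(universe_ids, size=n_hit, replace=False)
        null_genes = _genes_of(draw, universe)
        for sid, genes in sets.items():
            if len(null_genes & genes) >= observed[sid]:
                exceed[sid] += 1
    rows = [
        EnrichmentResult(
            gene_set=sid,
            n_hit_genes=observed[sid],
            n_set_genes=len(sets[sid]),
            p_resampled=(1 + exceed[sid]) / (n_resample + 1),
        )
        for sid in sets
    ]
    out = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if len(out):
        out["q"] = bh_adjust(out["p_resampled"].to_numpy())
    return out
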