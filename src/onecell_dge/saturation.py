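"""Sequencing-depth saturation (rarefaction) analysis.

Detected genes and the UMI-unified rate are recomputed on uniform random
subsamples of a sample's mapped, gene-assigned reads.  Both statistics are
non-decreasing in expectation with depth: deeper sampling finds more genes
and revisits more duplicate molecules.  Subsampling is without replacement
from the fixed set of mapped reads (interpolation only — no extrapolation
of library complexity beyond the observed depth).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import unify_umis

__all__ = ["SaturationCurve", "subsample_reads", "saturation_curve"]


def subsample_reads(assignments: pd.DataFrame, depth: int,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Uniform sample of exactly ``depth`` gene-assigned reads, without replacement."""
    n = len(assignments)
    if not 0 <= depth <= n:
        raise ValueError(f"depth {depth} outside [0, {n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n, size=depth, replace=False)
    return assignments.iloc[np.sort(idx)]


@dataclass
class SaturationCurve:
    """Per depth × replicate saturation statistics.

    ``table`` columns: depth, replicate, detected_genes, umi_unified_rate.
    ``summary`` aggregates mean and sd per depth.
    """

    table: pd.DataFrame
    replicates: int
    seed: int

    @property
    def depths(self) -> list[int]:
        return sorted(self.table["depth"].unique())

    @property
    def summary(self) -> pd.DataFrame:
        return (self.table.groupby("depth")[["detected_genes", "umi_unified_rate"]]
                .agg(["mean", "std"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _stats_at(subset: pd.DataFrame) -> tuple[int, float]:
    depth = len(subset)
    if depth == 0:
        return 0, 0.0
    counts, _ = unify_umis(subset)
    umi_total = int(counts.sum())
    return int((counts > 0).sum()), (depth - umi_total) / depth


def saturation_curve(assignments: pd.DataFrame, depths: Sequence[int],
                     replicates: int = 5, seed: int = 0) -> SaturationCurve:
    """Recompute detected genes and UMI-unified rate on read subsamples.

    For each depth and replicate an independent without-replacement sample
    of mapped reads is drawn and unified.  At full depth the subsample is
    the identity, so that row reproduces the unsubsampled statistics
    exactly (and is not resampled across replicates).
    """
    depths = sorted(int(d) for d in depths)
    n = len(assignments)
    if depths and (depths[0] < 0 or depths[-1] > n):
        raise ValueError(f"depths must lie in [0, {n}]")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(depths) * replicates))
    rows = []
    for depth in depths:
        for rep in range(replicates):
            child = next(children)
            if depth == n:
                subset = assignments  # identity: full depth is deterministic
            else:
                subset = subsample_reads(assignments, depth,
                                         np.random.default_rng(child))
            detected, rate = _stats_at(subset)
            rows.append({"depth": depth, "replicate": rep,
                         "detected_genes": detected, "umi_unified_rate": rate})
    table = pd.DataFrame(rows)
    return SaturationCurve(table=table, replicates=replicates, seed=seed)
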