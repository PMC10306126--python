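"""Correlation connectome construction and module detection.

Counts are variance-stabilized as log10(count + 1); regions are correlated
across the subjects of each condition (Pearson); Euclidean distances between
correlation-matrix rows feed agglomerative hierarchical clustering; modules
are the subtrees below half the maximum merge height of the dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .io import FosCountTable, RunConfig, ValidationError

logger = logging.getLogger("fosnet")


@dataclass
class NormalizedTable:
    """log10(count + 1) values, same region x subject layout as the counts."""

    values: pd.DataFrame
    group_of_subject: dict[str, str]

    def subjects_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of_subject[s] == group]


@dataclass
class CorrelationMatrix:
    """Region x region Pearson correlations for one condition."""

    group: str
    r: pd.DataFrame

    @property
    def regions(self) -> list[str]:
        return list(self.r.index)

    def to_long(self) -> pd.DataFrame:
        """Unordered region pairs with their correlation (long format)."""
        regions = self.regions
        rows = [
            (regions[i], regions[j], self.r.iat[i, j])
            for i in range(len(regions))
            for j in range(i + 1, len(regions))
        ]
        return pd.DataFrame(rows, columns=["region_a", "region_b", "r"])


@dataclass
class ModulePartition:
    """Region -> module assignment from the dendrogram cut.

    ``dendrogram`` is the scipy linkage matrix (children + merge heights);
    ``cut_height`` = cut_fraction x maximum merge height.  Module ids are
    renumbered 1..n_modules in dendrogram leaf order.
    """

    module_of_region: dict[str, int]
    cut_height: float
    dendrogram: np.ndarray | None

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of_region.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": list(self.module_of_region), "module": list(self.module_of_region.values())}
        )


def normalize(counts: FosCountTable) -> NormalizedTable:
    """Elementwise log10(count + 1)."""
    return NormalizedTable(
        values=np.log10(counts.counts + 1.0),
        group_of_subject=dict(counts.group_of_subject),
    )


def correlate(norm: NormalizedTable, group: str) -> CorrelationMatrix:
    """Pearson correlation between regions across one group's subjects.

    Regions with zero variance within the group are excluded with a logged
    warning (their correlation is undefined).
    """
    subjects = norm.subjects_in(group)
    if len(subjects) < 2:
        raise ValidationError(f"group {group!r} has {len(subjects)} subject(s); >=2 required")
    sub = norm.values[subjects]
    sd = sub.std(axis=1, ddof=0)
    # tolerance absorbs float epsilon from the log transform of constant counts
    flat = sd[sd <= 1e-12 * np.maximum(1.0, sub.abs().mean(axis=1))].index
    if len(flat):
        logger.warning(
            "group %r: excluding %d zero-variance region(s): %s", group, len(flat), list(flat)
        )
        sub = sub.drop(index=flat)
    if sub.empty:
        raise ValidationError(f"group {group!r}: all regions have zero variance")
    r = sub.T.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(group=group, r=r)


def distance_matrix(corr: CorrelationMatrix) -> pd.DataFrame:
    """Euclidean distance between rows of the correlation matrix (each region
    embedded as its vector of correlations to every region, unit diagonal
    included)."""
    d = squareform(pdist(corr.r.to_numpy(float), metric="euclidean"))
    return pd.DataFrame(d, index=corr.r.index, columns=corr.r.index)


def cluster_and_cut(dist: pd.DataFrame, cfg: RunConfig) -> ModulePartition:
    """Agglomerative clustering of the distance matrix with the configured
    linkage, cut at ``cut_fraction`` x the maximum merge height.

    A single region yields one module with cut height 0.  Modules are the
    connected subtrees strictly below the cut; ids follow dendrogram leaf
    order.
    """
    regions = list(dist.index)
    if len(regions) == 1:
        return ModulePartition(module_of_region={regions[0]: 1}, cut_height=0.0, dendrogram=None)
    condensed = squareform(dist.to_numpy(float), checks=False)
    Z = linkage(condensed, method=cfg.linkage_method)
    cut_height = cfg.cut_fraction * Z[:, 2].max()
    labels = fcluster(Z, t=cut_height, criterion="distance")
    # renumber so module ids increase with first appearance in leaf order
    order = leaves_list(Z)
    remap: dict[int, int] = {}
    for leaf in order:
        remap.setdefault(labels[leaf], len(remap) + 1)
    module_of_region = {regions[i]: remap[labels[i]] for i in range(len(regions))}
    logger.info(
        "half-height cut at %.4g: %d modules over %d regions",
        cut_height, len(remap), len(regions),
    )
    return ModulePartition(module_of_region=module_of_region, cut_height=cut_height, dendrogram=Z)


def build_connectome(
    counts: FosCountTable, group: str, cfg: RunConfig
) -> tuple[CorrelationMatrix, ModulePartition]:
    """Convenience composition: normalize -> correlate -> distances -> modules."""
    corr = correlate(normalize(counts), group)
    part = cluster_and_cut(distance_matrix(corr), cfg)
    return corr, part
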