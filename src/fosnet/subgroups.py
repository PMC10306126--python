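"""Cholinergic-subsystem correlation analyses.

The seven long-range cholinergic cell groups imaged here split into a basal
forebrain subsystem {MA, NDB, SI} and a brainstem-thalamic subsystem
{MS, PPN, MH, LH}.  This module enumerates the within- and between-subsystem
region pairs (3, 6 and 12 unordered pairs respectively), averages raw Pearson
r over pair sets per condition, profiles each cholinergic region's mean
correlation with the nine anatomic groups, extracts minimal addiction
networks, and runs the two-way ANOVA (type-II sums of squares) with Tukey HSD
on the pair-level correlations.

MS sits anatomically between the two subsystems; it is assigned to the
brainstem-thalamic set by default (configurable through the metadata table),
which is the assignment under which the pair counts above hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .connectome import CorrelationMatrix
from .io import ANATOMIC_GROUPS, RegionMetadata, ValidationError
from .metrics import ThresholdedNetwork

WITHIN_BASAL_FOREBRAIN = "within_basal_forebrain"
WITHIN_BRAINSTEM_THALAMIC = "within_brainstem_thalamic"
BETWEEN = "between"


def enumerate_pairs(meta: RegionMetadata) -> dict[str, list[tuple[str, str]]]:
    """Unordered region pairs per category: within each cholinergic
    subsystem and between the two (self-pairs excluded).

    With the default subsystems this yields 3 + 6 + 12 pairs.  A subsystem
    with fewer than two members produces an empty within-pair list.
    """
    bf = meta.subsystem_members("basal_forebrain")
    bt = meta.subsystem_members("brainstem_thalamic")
    import warnings

    for name, members in ((WITHIN_BASAL_FOREBRAIN, bf), (WITHIN_BRAINSTEM_THALAMIC, bt)):
        if len(members) < 2:
            warnings.warn(f"{name}: fewer than 2 members ({members}); no within pairs")
    return {
        WITHIN_BASAL_FOREBRAIN: list(combinations(bf, 2)),
        WITHIN_BRAINSTEM_THALAMIC: list(combinations(bt, 2)),
        BETWEEN: list(product(bf, bt)),
    }


def pair_r_values(corr: CorrelationMatrix, pairs: list[tuple[str, str]]) -> list[float]:
    missing = sorted({r for p in pairs for r in p} - set(corr.regions))
    if missing:
        raise ValidationError(f"pair member(s) absent from correlation matrix: {missing}")
    return [float(corr.r.at[a, b]) for a, b in pairs]


def average_subgroup_r(corr: CorrelationMatrix, pairs: list[tuple[str, str]]) -> float:
    """Arithmetic mean of raw r over a pair list (no Fisher transform)."""
    if not pairs:
        raise ValidationError("cannot average over an empty pair list")
    return float(np.mean(pair_r_values(corr, pairs)))


def pair_sample_frame(
    corrs: dict[str, CorrelationMatrix], meta: RegionMetadata
) -> pd.DataFrame:
    """Long-format pair-level correlations: one row per (treatment, category,
    pair) with its r value — the observation layout of the two-way ANOVA."""
    pairs = enumerate_pairs(meta)
    rows = []
    for treatment, corr in corrs.items():
        for category, plist in pairs.items():
            for (a, b), r in zip(plist, pair_r_values(corr, plist)):
                rows.append(
                    {"treatment": treatment, "category": category,
                     "region_a": a, "region_b": b, "r": r}
                )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Two-way ANOVA table (type-II SS) plus Tukey HSD over the factor cells."""

    table: pd.DataFrame       # index: treatment, category, interaction, residual
    cell_means: pd.DataFrame
    tukey: pd.DataFrame

    def effect(self, name: str) -> dict[str, float]:
        row = self.table.loc[name]
        return {"F": float(row["F"]), "p": float(row["PR(>F)"]),
                "df": float(row["df"]), "df_resid": float(self.table.loc["residual", "df"])}


def anova_two_way(
    samples: pd.DataFrame,
    *,
    value: str = "r",
    factor_a: str = "treatment",
    factor_b: str = "category",
) -> AnovaResult:
    """Two-factor ANOVA on pair-level observations with Tukey post hoc.

    Type-II sums of squares accommodate the (possibly unbalanced) layout.
    Tukey HSD compares all factor-combination cells.  Every cell must be
    occupied.
    """
    for fac in (factor_a, factor_b):
        if samples[fac].nunique() < 2:
            raise ValidationError(f"factor {fac!r} needs >=2 levels")
    counts = samples.groupby([factor_a, factor_b], sort=False)[value].count()
    full = pd.MultiIndex.from_product(
        [samples[factor_a].unique(), samples[factor_b].unique()], names=[factor_a, factor_b]
    )
    empty = [c for c in full if c not in counts.index or counts.get(c, 0) == 0]
    if empty:
        raise ValidationError(f"empty ANOVA cell(s): {empty}")

    model = smf.ols(
        f"{value} ~ C({factor_a}) * C({factor_b})", data=samples
    ).fit()
    raw = sm.stats.anova_lm(model, typ=2)
    rename = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": "interaction",
        "Residual": "residual",
    }
    table = raw.rename(index=rename)
    # a zero-variance effect is "no effect", not an undefined (or epsilon) ratio
    y = samples[value].to_numpy(float)
    zero = (table["sum_sq"] == 0) & (table.index != "residual")
    if np.ptp(y) == 0:
        zero |= table.index != "residual"
    table.loc[zero, "F"] = 0.0
    table.loc[zero, "PR(>F)"] = 1.0

    cell_means = (
        samples.groupby([factor_a, factor_b], sort=False)[value].mean().rename("mean").reset_index()
    )
    labels = samples[factor_a].astype(str) + ":" + samples[factor_b].astype(str)
    tk = pairwise_tukeyhsd(samples[value].to_numpy(float), labels.to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return AnovaResult(table=table, cell_means=cell_means, tukey=tukey)


def cholinergic_anatomy_profile(
    corr: CorrelationMatrix, meta: RegionMetadata
) -> pd.DataFrame:
    """Mean correlation of each cholinergic region with every anatomic group.

    Long format: (cholinergic_region, anatomic_group, mean_r, n_partners).
    The cholinergic region itself is excluded from its own group's partners;
    groups with no remaining partner in the matrix yield a missing cell.
    """
    chol = [r for r in meta.cholinergic_regions() if r in corr.regions]
    rows = []
    for region in chol:
        for group in ANATOMIC_GROUPS:
            partners = [
                p for p in meta.anatomic_group_members(group)
                if p != region and p in corr.regions
            ]
            rows.append(
                {
                    "cholinergic_region": region,
                    "anatomic_group": group,
                    "mean_r": float(corr.r.loc[region, partners].mean()) if partners else np.nan,
                    "n_partners": len(partners),
                }
            )
    return pd.DataFrame(rows)


def anatomy_pair_frame(
    corrs: dict[str, CorrelationMatrix], meta: RegionMetadata
) -> pd.DataFrame:
    """Pair-level cholinergic-region x anatomic-group partner correlations
    per treatment, the observation layout for the brain-wide two-way ANOVA."""
    rows = []
    for treatment, corr in corrs.items():
        chol = [r for r in meta.cholinergic_regions() if r in corr.regions]
        for region in chol:
            for group in ANATOMIC_GROUPS:
                for p in meta.anatomic_group_members(group):
                    if p == region or p not in corr.regions:
                        continue
                    rows.append(
                        {"treatment": treatment, "category": group,
                         "cholinergic_region": region, "partner": p,
                         "r": float(corr.r.at[region, p])}
                    )
    return pd.DataFrame(rows)


def minimal_network(
    net: ThresholdedNetwork, corr: CorrelationMatrix, keep: list[str]
) -> ThresholdedNetwork:
    """Induced subnetwork on ``keep`` (isolated kept regions retained)."""
    unknown = sorted(set(keep) - set(net.regions))
    if unknown:
        raise ValidationError(f"unknown region(s) in keep list: {unknown}")
    sub = nx.Graph(net.graph.subgraph(keep))
    return ThresholdedNetwork(graph=sub, threshold=net.threshold)
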