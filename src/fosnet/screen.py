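"""Brain-wide screen correlating baseline gene expression with Fos change.

For each gene, the regional baseline expression density ("percentage of
pixels", averaged across its in-situ experiments after per-experiment
centering and scaling) is correlated with the per-region log-fold change of
Fos between withdrawal and control.  Two-sided p-values come from the
Pearson correlation t-test (t = r*sqrt((n-2)/(1-r^2)) on n-2 df); the
Benjamini-Hochberg step-up converts them to q-values controlling the false
discovery rate, 5% by default.  The frontal pole is excluded as an outlier
by default configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import NormalizedTable, normalize
from .io import CONTROL, TREATMENT, FosCountTable, RunConfig, ValidationError

logger = logging.getLogger("fosnet")


def fos_lfc(norm: NormalizedTable, excluded_regions: tuple[str, ...] = ()) -> pd.Series:
    """Per-region log-fold change of Fos: mean log10(count+1) over treatment
    subjects minus the control mean.  Excluded regions are dropped."""
    trt = norm.subjects_in(TREATMENT)
    ctrl = norm.subjects_in(CONTROL)
    if not trt or not ctrl:
        raise ValidationError("both groups must be present to compute a log-fold change")
    lfc = norm.values[trt].mean(axis=1) - norm.values[ctrl].mean(axis=1)
    lfc = lfc.drop(index=[r for r in excluded_regions if r in lfc.index])
    lfc.name = "lfc"
    return lfc


def aggregate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """One regional profile per gene from long-format expression data.

    ``expr`` has columns (gene_id, experiment_id, region_id, density).  Each
    experiment's vector over the shared region set is centered to mean 0 and
    scaled to unit standard deviation, then the gene's experiments are
    averaged.  Zero-variance experiments are dropped with a warning; genes
    left without a usable experiment are excluded (logged).
    """
    required = {"gene_id", "experiment_id", "region_id", "density"}
    if not required.issubset(expr.columns):
        raise ValidationError(f"expression table must have columns {sorted(required)}")
    wide = expr.pivot_table(
        index=["gene_id", "experiment_id"], columns="region_id", values="density"
    )
    if wide.isna().any().any():
        raise ValidationError("every experiment must cover the shared region set")
    vals = wide.to_numpy(float)
    sd = vals.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        dropped = wide.index[flat]
        logger.warning("dropping %d zero-variance experiment(s): %s",
                       flat.sum(), list(dropped.get_level_values("experiment_id"))[:10])
        wide = wide.loc[~flat]
        vals = vals[~flat]
        sd = sd[~flat]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    zdf = pd.DataFrame(z, index=wide.index, columns=wide.columns)
    genes_before = expr["gene_id"].nunique()
    out = zdf.groupby(level="gene_id").mean()
    if len(out) < genes_before:
        logger.warning("%d gene(s) excluded: no usable experiment", genes_before - len(out))
    return out


def correlate_gene(gene_vec: pd.Series, lfc: pd.Series) -> tuple[float, float, int]:
    """Pearson r of a gene's profile against the LFC over shared regions,
    with the two-sided t-test p-value.  Returns (r, p, n); a zero-variance
    input yields (nan, nan, n) and the gene is untestable."""
    shared = gene_vec.index.intersection(lfc.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared regions; >=3 required")
    x = gene_vec.loc[shared].to_numpy(float)
    y = lfc.loc[shared].to_numpy(float)
    n = len(shared)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def bh_fdr(p_values: pd.Series, level: float) -> pd.DataFrame:
    """Benjamini-Hochberg step-up: q_i = min_{j >= rank(i)} m * p_(j) / j,
    significant iff q <= level."""
    if len(p_values) == 0:
        return pd.DataFrame(columns=["p", "q", "significant"])
    rejected, q, _, _ = multipletests(p_values.to_numpy(float), alpha=level, method="fdr_bh")
    return pd.DataFrame(
        {"p": p_values, "q": q, "significant": q <= level}, index=p_values.index
    )


@dataclass
class ScreenResult:
    """Per-gene screen output plus the realized |r| significance frontier."""

    table: pd.DataFrame  # r, p, q, significant, n_regions_used; sorted by |r| desc
    frontier: float      # smallest |r| among significant genes (nan if none)
    n_regions_used: int

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def run_screen(
    expr: pd.DataFrame, counts: FosCountTable, cfg: RunConfig
) -> ScreenResult:
    """Full screen: LFC -> per-gene aggregation -> correlation tests -> BH.

    Untestable (zero-variance) genes are excluded before the FDR correction
    so the BH denominator counts testable genes only.
    """
    lfc = fos_lfc(normalize(counts), cfg.excluded_regions)
    profiles = aggregate_expression(expr)
    shared = profiles.columns.intersection(lfc.index)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} regions shared between expression and counts; >=3 required"
        )
    lfc = lfc.loc[shared]
    rows = {}
    for gene, vec in profiles.iterrows():
        r, p, n = correlate_gene(vec.loc[shared], lfc)
        rows[gene] = (r, p, n)
    res = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p", "n_regions_used"])
    untestable = res["p"].isna()
    if untestable.any():
        logger.warning("%d untestable gene(s) excluded from FDR", int(untestable.sum()))
    testable = res[~untestable]
    fdr = bh_fdr(testable["p"], cfg.fdr_level)
    out = testable.join(fdr[["q", "significant"]])
    out = out.sort_values("r", key=lambda s: s.abs(), ascending=False)
    sig = out[out["significant"]]
    frontier = float(sig["r"].abs().min()) if len(sig) else float("nan")
    logger.info(
        "screen: %d genes tested over %d regions; %d significant at q<=%.3g; "
        "|r| frontier %.4g",
        len(out), len(shared), len(sig), cfg.fdr_level, frontier,
    )
    return ScreenResult(table=out, frontier=frontier, n_regions_used=int(len(shared)))
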