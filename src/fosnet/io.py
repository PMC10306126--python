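"""Tabular and graph I/O, run configuration, and input validation.

The pipeline's raw signal is a table of Fos-positive cell counts per brain
region and subject, produced upstream by cleared-brain light-sheet imaging and
automated atlas registration.  This module reads such tables from delimited
text, validates them (fail-fast: every validation error raises before any
computation starts), reads region metadata including the long-range
cholinergic annotations, and writes thresholded networks to edge-list CSV and
GraphML.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("fosnet")

#: Closed vocabulary of major anatomic groups.
ANATOMIC_GROUPS = (
    "cortical plate",
    "cortical subplate",
    "striatum",
    "pallidum",
    "thalamus",
    "hypothalamus",
    "midbrain",
    "hindbrain",
    "cerebellum",
)

#: Long-range cholinergic cell-group labels (Ch1-Ch7 plus the lateral habenula).
CHOLINERGIC_GROUPS = (
    "Ch1(MS)",
    "Ch2/3(NDB)",
    "Ch4(MA)",
    "Ch4(SI)",
    "Ch5(PPN)",
    "Ch7(MH)",
    "LH",
)

#: Default split of the cholinergic regions into the two subsystems.
BASAL_FOREBRAIN = ("MA", "NDB", "SI")
BRAINSTEM_THALAMIC = ("MS", "PPN", "MH", "LH")

#: Regions critical to nicotine addiction, used for the minimal network.
ADDICTION_REGIONS = (
    "ACA", "ILA", "PL", "DP", "CP", "ACB", "BST", "BLA", "CEA", "VTA", "IPN",
)

CONTROL = "control"
TREATMENT = "treatment"


class ValidationError(ValueError):
    """Raised when an input table violates an invariant."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters.

    correlation_threshold
        Pearson r above which (strictly) two regions are considered
        functionally connected.  Default 0.75.
    linkage_method
        Agglomeration rule for hierarchical clustering of correlation-row
        distances ("complete", "single", "average", "ward").
    cut_fraction
        Dendrogram cut height as a fraction of the maximum merge height;
        0.5 is the half-height cut that defines modules.
    hub_top_k
        Size of the top lists (degree, betweenness, participation) that enter
        hub calls; ties with the k-th value are included.
    fdr_level
        Benjamini-Hochberg false-discovery-rate level for the gene screen.
    excluded_regions
        Regions dropped before the gene screen ("FRP", the frontal pole, is
        excluded by default as an outlier).
    """

    correlation_threshold: float = 0.75
    linkage_method: str = "complete"
    cut_fraction: float = 0.5
    hub_top_k: int = 20
    fdr_level: float = 0.05
    excluded_regions: tuple[str, ...] = ("FRP",)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold < 1.0:
            raise ValidationError(
                f"correlation_threshold must be in (0, 1), got {self.correlation_threshold}"
            )
        if not 0.0 < self.cut_fraction < 1.0:
            raise ValidationError(f"cut_fraction must be in (0, 1), got {self.cut_fraction}")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValidationError(f"fdr_level must be in (0, 1), got {self.fdr_level}")
        if self.hub_top_k < 1:
            raise ValidationError(f"hub_top_k must be >= 1, got {self.hub_top_k}")
        if self.linkage_method not in ("complete", "single", "average", "ward"):
            raise ValidationError(f"unknown linkage_method {self.linkage_method!r}")
        object.__setattr__(self, "excluded_regions", tuple(self.excluded_regions))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (keyed by field name)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "correlation_threshold": self.correlation_threshold,
            "linkage_method": self.linkage_method,
            "cut_fraction": self.cut_fraction,
            "hub_top_k": self.hub_top_k,
            "fdr_level": self.fdr_level,
            "excluded_regions": list(self.excluded_regions),
            "rng_seed": self.rng_seed,
        }


@dataclass
class FosCountTable:
    """Region x subject matrix of Fos-positive cell counts with group labels.

    ``counts`` is a DataFrame indexed by region acronym with one integer
    column per subject; ``group_of_subject`` maps every subject to
    ``"control"`` or ``"treatment"``.
    """

    counts: pd.DataFrame
    group_of_subject: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate region id(s): {dupes}")
        cols = self.counts.columns
        if cols.duplicated().any():
            raise ValidationError(f"duplicate subject id(s): {sorted(cols[cols.duplicated()])}")
        missing = [s for s in cols if s not in self.group_of_subject]
        if missing:
            raise ValidationError(f"subject(s) without a group label: {missing}")
        bad_groups = {g for g in self.group_of_subject.values() if g not in (CONTROL, TREATMENT)}
        if bad_groups:
            raise ValidationError(
                f"group labels must be {CONTROL!r} or {TREATMENT!r}, got {sorted(bad_groups)}"
            )
        for col in cols:
            series = self.counts[col]
            if series.isna().any():
                rows = list(self.counts.index[series.isna()])
                raise ValidationError(f"missing count(s) in subject {col!r}, region(s) {rows}")
            if (series < 0).any():
                rows = list(self.counts.index[series < 0])
                raise ValidationError(f"negative count(s) in subject {col!r}, region(s) {rows}")
            if not (series == series.round()).all():
                rows = list(self.counts.index[series != series.round()])
                raise ValidationError(f"non-integral count(s) in subject {col!r}, region(s) {rows}")
        self.counts = self.counts.astype(int)
        for grp in (CONTROL, TREATMENT):
            n = len(self.subjects_in(grp))
            if 0 < n < 2:
                raise ValidationError(f"group {grp!r} has {n} subject(s); >=2 required")
            if 2 <= n < 4:
                warnings.warn(f"group {grp!r} has only {n} subjects; correlations will be noisy")

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subjects_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of_subject[s] == group]

    def to_csv(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith(".tsv") else ","
        self.counts.rename_axis("region_id").to_csv(path, sep=sep)


@dataclass
class RegionMetadata:
    """Per-region annotations: name, anatomic group, cholinergic membership.

    ``table`` is indexed by region acronym with columns ``name``,
    ``anatomic_group``, ``cholinergic_group`` (empty when not a long-range
    cholinergic region) and ``subsystem`` (``basal_forebrain`` /
    ``brainstem_thalamic``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError(
                f"duplicate region id(s) in metadata: "
                f"{sorted(self.table.index[self.table.index.duplicated()].unique())}"
            )
        bad = set(self.table["anatomic_group"].dropna()) - set(ANATOMIC_GROUPS)
        if bad:
            raise ValidationError(
                f"unknown anatomic_group value(s) {sorted(bad)}; allowed: {list(ANATOMIC_GROUPS)}"
            )
        chol = self.table.get("cholinergic_group")
        sub = self.table.get("subsystem")
        if sub is not None and chol is not None:
            orphan = self.table.index[sub.notna() & chol.isna()]
            if len(orphan):
                raise ValidationError(
                    f"subsystem set without cholinergic_group for region(s) {list(orphan)}"
                )
        if not self.cholinergic_regions():
            warnings.warn("metadata has no cholinergic annotations; subsystem analyses disabled")

    def cholinergic_regions(self) -> list[str]:
        col = self.table.get("cholinergic_group")
        if col is None:
            return []
        return list(self.table.index[col.notna() & (col.astype(str).str.len() > 0)])

    def subsystem_members(self, subsystem: str) -> list[str]:
        col = self.table.get("subsystem")
        if col is None:
            return []
        return list(self.table.index[col == subsystem])

    def anatomic_group_members(self, group: str) -> list[str]:
        return list(self.table.index[self.table["anatomic_group"] == group])


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def read_count_table(path: str | Path, group_map: Mapping[str, str]) -> FosCountTable:
    """Read a region x subject count table from CSV/TSV.

    The first column holds region acronyms; every remaining column is one
    subject.  ``group_map`` assigns each subject column to ``"control"`` or
    ``"treatment"``.  Rows whose counts are all missing are rejected.
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need one region column plus >=1 subject column")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        raise ValidationError(f"{path}: region(s) with all counts missing: {list(df.index[all_missing])}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric count in column {col!r}, region(s) {list(bad_rows)}"
            )
    table = FosCountTable(counts=df, group_of_subject=dict(group_map))
    logger.info("read %d regions x %d subjects from %s", *df.shape, path)
    return table


def read_region_metadata(path: str | Path) -> RegionMetadata:
    """Read region metadata (region_id, name, anatomic_group, cholinergic
    annotations) from CSV/TSV."""
    df = _read_delimited(path)
    df.columns = [c.strip() for c in df.columns]
    required = {"region_id", "anatomic_group"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: metadata must have columns {sorted(required)}")
    df = df.set_index("region_id")
    df.index = df.index.astype(str).str.strip()
    for col in ("name", "anatomic_group", "cholinergic_group", "subsystem"):
        if col in df.columns:
            df[col] = df[col].astype("string").str.strip()
            df.loc[df[col].fillna("") == "", col] = pd.NA
        else:
            df[col] = pd.NA
    return RegionMetadata(table=df[["name", "anatomic_group", "cholinergic_group", "subsystem"]])


def default_cholinergic_metadata() -> pd.DataFrame:
    """Rows for the seven long-range cholinergic regions with default
    subsystem assignment (a convenience for assembling metadata tables)."""
    rows = [
        ("MS", "medial septal nucleus", "pallidum", "Ch1(MS)", "brainstem_thalamic"),
        ("NDB", "diagonal band nucleus", "pallidum", "Ch2/3(NDB)", "basal_forebrain"),
        ("MA", "magnocellular nucleus", "pallidum", "Ch4(MA)", "basal_forebrain"),
        ("SI", "substantia innominata", "pallidum", "Ch4(SI)", "basal_forebrain"),
        ("PPN", "pedunculopontine nucleus", "midbrain", "Ch5(PPN)", "brainstem_thalamic"),
        ("MH", "medial habenula", "thalamus", "Ch7(MH)", "brainstem_thalamic"),
        ("LH", "lateral habenula", "thalamus", "LH", "brainstem_thalamic"),
    ]
    return pd.DataFrame(
        rows, columns=["region_id", "name", "anatomic_group", "cholinergic_group", "subsystem"]
    ).set_index("region_id")


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write a thresholded network as an edge-list CSV plus GraphML.

    ``path`` names the CSV; the GraphML sibling gets suffix ``.graphml``.
    Node attributes (module, degree, betweenness, participation, hub flags)
    travel in the GraphML; edge weights are the correlation values.
    """
    path = Path(path)
    rows = [
        {"region_a": a, "region_b": b, "r": data.get("r", 1.0)}
        for a, b, data in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["region_a", "region_b", "r"]).to_csv(path, index=False)
    nx.write_graphml(graph, path.with_suffix(".graphml"))


def read_network(path: str | Path) -> nx.Graph:
    """Read back a network written by :func:`write_network` (from GraphML,
    which carries the node attributes)."""
    return nx.read_graphml(Path(path).with_suffix(".graphml"))
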