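"""Core containers and file I/O for the pipeline.

Expression matrices are log2-scale intensities, features x samples, each
feature tagged with an RNA class (mRNA | lncRNA | miRNA). All on-disk
formats are plain TSV (or GMT for gene sets); every reader/writer pair
round-trips losslessly.

File dialects
-------------
Expression TSV : first column ``feature_id``, optional second column
    ``feature_class``, remaining columns one per sample.
Group TSV      : ``sample_id<TAB>group`` with group in {case, control}.
Interaction TSV: ``regulator<TAB>target<TAB>regulator_class<TAB>target_class<TAB>source``.
GMT            : set name, description, then member ids, tab-separated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
INTERACTION_CLASSES = RNA_CLASSES + ("TF",)


class DataModelError(ValueError):
    """Raised on malformed input files or invariant violations."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2-scale intensities, features x samples, with per-feature RNA class.

    Duplicate feature ids are permitted (probe-level data) until
    :func:`collapse_duplicates` is applied; all other invariants are
    enforced at construction.
    """

    values: pd.DataFrame
    feature_class: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataModelError("expression matrix contains non-finite values")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataModelError(f"duplicate sample ids: {dups}")
        fc = self.feature_class
        if isinstance(fc, pd.Series) and not fc.index.equals(self.values.index):
            fc = fc.reindex(self.values.index)
        self.feature_class = pd.Series(
            np.asarray(fc, dtype=object), index=self.values.index, dtype=object
        )
        bad = ~self.feature_class.isin(RNA_CLASSES)
        if bad.any():
            rows = self.values.index[np.asarray(bad)].tolist()[:10]
            raise DataModelError(f"unknown/missing feature_class for rows: {rows}")

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def features_of_class(self, cls: str) -> list[str]:
        return self.values.index[self.feature_class == cls].tolist()

    def row(self, feature_id: str) -> np.ndarray:
        v = self.values.loc[feature_id]
        if isinstance(v, pd.DataFrame):
            raise DataModelError(f"feature id {feature_id!r} is duplicated")
        return v.to_numpy()

    def subset_features(self, ids) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(self.values.loc[ids], self.feature_class.loc[ids])


@dataclass
class GroupDesign:
    """Sample -> group map with exactly two groups, 'case' and 'control'."""

    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups, dtype=object)
        labels = set(self.groups.unique())
        if labels != {"case", "control"}:
            raise DataModelError(
                f"group labels must be exactly {{'case','control'}}, got {sorted(labels)}"
            )
        for g in ("case", "control"):
            if int((self.groups == g).sum()) < 2:
                raise DataModelError(f"group {g!r} has fewer than 2 samples")

    @property
    def case_samples(self) -> list[str]:
        return self.groups.index[self.groups == "case"].tolist()

    @property
    def control_samples(self) -> list[str]:
        return self.groups.index[self.groups == "control"].tolist()

    def check_covers(self, m: ExpressionMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.groups.index]
        if missing:
            raise DataModelError(f"samples without group label: {missing}")


@dataclass
class InteractionTable:
    """De-duplicated (regulator, target) records with class tags and source db."""

    records: pd.DataFrame  # columns: regulator, target, regulator_class, target_class, source

    COLUMNS = ("regulator", "target", "regulator_class", "target_class", "source")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        if (df["regulator"] == df["target"]).any():
            bad = df.loc[df["regulator"] == df["target"], "regulator"].tolist()[:5]
            raise DataModelError(f"self-interactions not allowed: {bad}")
        for col in ("regulator_class", "target_class"):
            unknown = set(df[col]) - set(INTERACTION_CLASSES)
            if unknown:
                raise DataModelError(f"unknown {col} values: {sorted(unknown)}")
        df = df.drop_duplicates(subset=["regulator", "target"], keep="first")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def of_regulator_class(self, cls: str) -> pd.DataFrame:
        return self.records[self.records["regulator_class"] == cls]

    def has_edge(self, regulator: str, target: str) -> bool:
        r = self.records
        return bool(((r["regulator"] == regulator) & (r["target"] == target)).any())


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (ordered, unique members)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))
            if not uniq:
                raise DataModelError(f"gene set {name!r} is empty")
            clean[name] = uniq
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SignatureMatrix:
    """Linear-scale reference profiles, marker genes x cell types."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        self.profiles = self.profiles.astype(float)
        if (self.profiles.to_numpy() < 0).any():
            raise DataModelError("signature entries must be non-negative")
        if self.profiles.shape[1] < 2:
            raise DataModelError("signature needs at least 2 cell types")
        cols = self.profiles.T.duplicated()
        if cols.any():
            raise DataModelError(
                f"identical signature columns: {self.profiles.columns[cols].tolist()}"
            )

    @property
    def marker_genes(self) -> list[str]:
        return self.profiles.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.profiles.columns.tolist()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def collapse_duplicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows sharing a feature id (multi-probe collapse).

    Each output row is the arithmetic mean of its probe rows; output order
    is the first occurrence of each id. Idempotent. A repeated id with
    conflicting feature_class is an error.
    """
    idx = m.values.index
    if not idx.duplicated().any():
        return ExpressionMatrix(m.values.copy(), m.feature_class.copy())
    cls = m.feature_class.groupby(level=0, sort=False).nunique()
    conflicts = cls.index[cls > 1].tolist()
    if conflicts:
        raise DataModelError(f"conflicting feature_class for ids: {conflicts}")
    order = idx[~idx.duplicated()]
    values = m.values.groupby(level=0, sort=False).mean().loc[order]
    fclass = m.feature_class.groupby(level=0, sort=False).first().loc[order]
    return ExpressionMatrix(values, fclass)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise DataModelError(f"empty file: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, header=0)


def read_expression(path, class_map=None) -> ExpressionMatrix:
    """Read an expression TSV.

    Feature classes come from a ``feature_class`` column if present,
    otherwise from `class_map` (a two-column TSV feature_id<TAB>class).
    """
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise DataModelError(f"empty file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    has_class_col = samples and samples[0] == "feature_class"
    if has_class_col:
        samples = samples[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise DataModelError(f"duplicate sample id in header: {s!r}")
        seen.add(s)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    raw.columns = header[1:]
    fclass = None
    if has_class_col:
        fclass = raw["feature_class"]
        raw = raw.drop(columns=["feature_class"])
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any() or raw.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise DataModelError(
            f"non-numeric value at row {values.index[r]!r}, column {values.columns[c]!r}"
        )
    if fclass is None:
        if class_map is None:
            raise DataModelError(
                "no feature_class column and no class_map given; feature class is mandatory"
            )
        cm = pd.read_csv(class_map, sep="\t", dtype=str, header=None, index_col=0)
        fclass = values.index.to_series().map(cm.iloc[:, 0])
        missing = values.index[fclass.isna()].tolist()
        if missing:
            raise DataModelError(f"class_map lacks entries for rows: {missing[:10]}")
    return ExpressionMatrix(values, fclass)


def write_expression(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.insert(0, "feature_class", m.feature_class.to_numpy())
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_groups(path) -> GroupDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] != 2:
        raise DataModelError("group TSV must have exactly 2 columns")
    return GroupDesign(pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0]))


def write_groups(d: GroupDesign, path) -> None:
    out = d.groups.rename("group")
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_interactions(path) -> InteractionTable:
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"no such file: {path}")
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(InteractionTable.COLUMNS):
            raise DataModelError(
                f"interaction TSV header must be {list(InteractionTable.COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise DataModelError(f"malformed interaction line {lineno}: {line!r}")
            rows.append(parts)
    return InteractionTable(pd.DataFrame(rows, columns=list(InteractionTable.COLUMNS)))


def write_interactions(it: InteractionTable, path) -> None:
    it.records.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"no such file: {path}")
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataModelError(f"malformed GMT line {lineno}: {line!r}")
            name, description, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise DataModelError(f"duplicate set name at line {lineno}: {name!r}")
            sets[name] = [m for m in members if m]
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_edges(edges: pd.DataFrame, path, graphml_path=None) -> None:
    """Export a network edge table as TSV (and optionally GraphML)."""
    edges.to_csv(path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        g = nx.from_pandas_edgelist(edges, source=edges.columns[0], target=edges.columns[1])
        nx.write_graphml(g, graphml_path)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
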