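"""Reading, validation, filtering, normalisation and fusion of feature tables.

A :class:`FeatureTable` is a features x sampling-points matrix: OTU read
counts (or relative abundances) for one rRNA domain, or one block of chemical
measurements (element concentrations in ppm, FT-IR region-of-interest
integrals, 1H-NMR bucket integrals).  The operations here implement the table
processing that precedes correlation analysis:

* removal of OTUs represented by a single read over all sampling points,
* per-domain conversion of counts to relative abundances (each sampling
  point's reads divided by that point's total),
* fusion of the domain tables into the community matrix and of the chemical
  blocks into the chemicals matrix, aligned on an identical ordered set of
  sampling points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

COMMUNITY_BLOCKS = ("archaea", "16S", "18S", "fused_community")
CHEMICAL_BLOCKS = ("icp", "ftir", "nmr", "fused_chemicals")
VALUE_KINDS = ("counts", "relative_abundance", "concentration_ppm", "integral", "mixed")

#: separator used to make feature ids globally unique when tables are fused
BLOCK_SEP = "|"

#: default value kind per block
_DEFAULT_KIND = {
    "archaea": "counts",
    "16S": "counts",
    "18S": "counts",
    "fused_community": "relative_abundance",
    "icp": "concentration_ppm",
    "ftir": "integral",
    "nmr": "integral",
    "fused_chemicals": "mixed",
}


@dataclass
class FeatureTable:
    """Features x sampling-points matrix with block label and optional taxonomy.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
    block
        One of ``archaea, 16S, 18S, fused_community`` (community) or
        ``icp, ftir, nmr, fused_chemicals`` (chemical).
    value_kind
        ``counts``, ``relative_abundance``, ``concentration_ppm``,
        ``integral`` or ``mixed`` (fused chemicals).
    taxonomy
        Optional mapping feature id -> ordered lineage (domain ... species),
        only meaningful for community blocks.
    """

    data: pd.DataFrame
    block: str
    value_kind: str
    taxonomy: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.block not in COMMUNITY_BLOCKS + CHEMICAL_BLOCKS:
            raise ValueError(f"unknown block label {self.block!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate feature id(s): {sorted(set(dup))}")
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id(s): {sorted(set(dup))}")
        if not np.issubdtype(self.data.values.dtype, np.number):
            raise ValueError("feature table values must be numeric")
        if np.isnan(self.data.values.astype(float)).any():
            raise ValueError("missing values are not permitted in feature tables")
        if self.value_kind == "counts":
            vals = self.data.values
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.data = self.data.round().astype(np.int64)
        if self.value_kind == "relative_abundance":
            vals = self.data.values.astype(float)
            if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
                raise ValueError("relative abundances must lie in [0, 1]")
        if self.taxonomy is not None:
            missing = set(self.taxonomy) - set(self.data.index)
            if missing:
                raise ValueError(f"taxonomy keys not in table: {sorted(missing)[:5]}")
            self.taxonomy = {k: tuple(v) for k, v in self.taxonomy.items()}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def is_community(self) -> bool:
        return self.block in COMMUNITY_BLOCKS

    def drop_features(self, names: Sequence[str]) -> "FeatureTable":
        """Return a copy without the named features (used e.g. to exclude pH)."""
        keep = [f for f in self.feature_ids if f not in set(names)]
        tax = None
        if self.taxonomy is not None:
            tax = {k: v for k, v in self.taxonomy.items() if k in set(keep)}
        return FeatureTable(self.data.loc[keep], self.block, self.value_kind, tax)


@dataclass
class FusedDataset:
    """The two matrices the typing pipeline consumes, on shared sampling points."""

    community: FeatureTable
    chemicals: FeatureTable
    sample_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.community.sample_ids != self.chemicals.sample_ids:
            raise ValueError(
                "community and chemicals matrices must share identical ordered "
                f"sampling points; community={self.community.sample_ids} "
                f"chemicals={self.chemicals.sample_ids}"
            )
        self.sample_ids = self.community.sample_ids


def _parse_lineage(raw) -> tuple[str, ...]:
    """Normalise a taxonomy annotation to an ordered tuple of rank names."""
    if raw is None:
        return ()
    if isinstance(raw, (list, tuple)):
        parts = [str(p) for p in raw]
    else:
        parts = str(raw).split(";")
    return tuple(p.strip() for p in parts if p.strip())


def _read_tsv(path: Path, orientation: str) -> tuple[pd.DataFrame, dict | None]:
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, engine="python")
    raw.index = raw.index.astype(str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate feature id(s) {sorted(set(dup))}")
    taxonomy = None
    if len(raw.columns) and raw.columns[-1].strip().lower() == "taxonomy":
        taxonomy = {fid: _parse_lineage(v) for fid, v in raw.iloc[:, -1].items()}
        raw = raw.iloc[:, :-1]
    if raw.isna().any().any():
        r, c = np.argwhere(raw.isna().values)[0]
        raise ValueError(f"{path}: missing/ragged cell at row {raw.index[r]!r}, column {raw.columns[c]!r}")
    def _to_float(v):
        # builtin float() is correctly rounded; pandas' fast parser is not
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    num = raw.apply(lambda col: col.map(_to_float))
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().values)[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    if orientation == "auto":
        # transpose only when the id-column header declares sample rows
        first = (raw.index.name or "").strip().lower()
        if first in {"sample", "samples", "sample_id", "sampling_point", "sampling_points"}:
            num = num.T
            taxonomy = None
    elif orientation != "features_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return num, taxonomy


def _read_biom(path: Path) -> tuple[pd.DataFrame, dict | None]:
    """Read a BIOM 1.0 JSON table (dense or sparse) into a features x samples frame."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise ValueError(f"{path}: not a BIOM 1.0 JSON table (missing {key!r})")
    n_rows, n_cols = doc["shape"]
    if len(doc["rows"]) != n_rows or len(doc["columns"]) != n_cols:
        raise ValueError(f"{path}: BIOM shape {doc['shape']} does not match row/column lists")
    row_ids = [str(r["id"]) for r in doc["rows"]]
    col_ids = [str(c["id"]) for c in doc["columns"]]
    if doc["matrix_type"] == "dense":
        mat = np.asarray(doc["data"], dtype=float)
        if mat.shape != (n_rows, n_cols):
            raise ValueError(f"{path}: dense data shape {mat.shape} != declared {doc['shape']}")
    elif doc["matrix_type"] == "sparse":
        mat = np.zeros((n_rows, n_cols))
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise ValueError(f"{path}: unsupported matrix_type {doc['matrix_type']!r}")
    taxonomy = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        if isinstance(meta, dict) and "taxonomy" in meta:
            taxonomy[str(r["id"])] = _parse_lineage(meta["taxonomy"])
    return pd.DataFrame(mat, index=row_ids, columns=col_ids), taxonomy or None


def read_feature_table(
    path: str | Path,
    fmt: str = "tsv",
    block: str = "16S",
    value_kind: str | None = None,
    orientation: str = "features_as_rows",
) -> FeatureTable:
    """Read a TSV or BIOM 1.0 JSON feature table.

    TSV dialect: UTF-8, tab-delimited, header row of sample ids, first column
    feature ids, optional final column ``taxonomy`` holding a semicolon
    delimited lineage.  ``orientation="auto"`` transposes only when the id
    column header names samples; otherwise rows are taken as features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    if fmt == "tsv":
        frame, taxonomy = _read_tsv(path, orientation)
    elif fmt == "biom":
        frame, taxonomy = _read_biom(path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'biom')")
    kind = value_kind or _DEFAULT_KIND[block]
    if block in CHEMICAL_BLOCKS:
        taxonomy = None
    return FeatureTable(frame, block=block, value_kind=kind, taxonomy=taxonomy)


def write_feature_table(t: FeatureTable, path: str | Path) -> Path:
    """Write a table as TSV with full-precision decimals (round-trips exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = t.data.copy()
    if t.taxonomy is not None:
        out["taxonomy"] = [";".join(t.taxonomy.get(f, ())) for f in t.feature_ids]
    out.index.name = "feature_id"
    # 17 significant digits always round-trip a float64 exactly
    out.to_csv(path, sep="\t", float_format="%.17g")
    return path


def filter_singleton_otus(t: FeatureTable, min_total: int = 2) -> FeatureTable:
    """Drop OTUs represented by fewer than ``min_total`` reads over all points.

    The default removes singletons (total reads over all sampling points < 2):
    a sequence read only once cannot show any abundance trend, so it carries
    no correlation signal.  Idempotent; preserves row order.
    """
    if t.value_kind != "counts":
        raise ValueError(f"singleton filtering requires counts, got {t.value_kind!r}")
    totals = t.data.sum(axis=1)
    keep = totals[totals >= min_total].index
    tax = None
    if t.taxonomy is not None:
        tax = {k: v for k, v in t.taxonomy.items() if k in set(keep)}
    return FeatureTable(t.data.loc[keep], t.block, t.value_kind, tax)


def to_relative_abundance(t: FeatureTable) -> FeatureTable:
    """Divide each OTU's reads by its sampling point's total reads.

    Performed within a single domain table at a time, so each domain
    contributes a composition summing to 1 at every sampling point.
    """
    if t.value_kind != "counts":
        raise ValueError(f"relative-abundance conversion requires counts, got {t.value_kind!r}")
    totals = t.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sampling point(s): {list(zero.index)}")
    rel = t.data.astype(float) / totals.astype(float)
    return FeatureTable(rel, t.block, "relative_abundance", t.taxonomy)


def fuse_tables(tables: Sequence[FeatureTable], target_block: str) -> FeatureTable:
    """Row-concatenate tables sharing identical ordered sampling points.

    Feature ids are made globally unique by prefixing with the source block
    (``archaea|OTU_17``); taxonomy maps are merged under the prefixed ids.
    """
    if not tables:
        raise ValueError("no tables to fuse")
    if target_block not in ("fused_community", "fused_chemicals"):
        raise ValueError(f"target_block must be a fused label, got {target_block!r}")
    ref = tables[0].sample_ids
    for t in tables[1:]:
        if t.sample_ids != ref:
            raise ValueError(
                "sampling points differ between fused tables: "
                f"{ref} vs {t.sample_ids} (block {t.block})"
            )
    frames = []
    taxonomy: dict[str, tuple[str, ...]] = {}
    for t in tables:
        f = t.data.copy()
        f.index = [f"{t.block}{BLOCK_SEP}{fid}" for fid in t.feature_ids]
        frames.append(f.astype(float))
        if t.taxonomy is not None:
            taxonomy.update({f"{t.block}{BLOCK_SEP}{k}": v for k, v in t.taxonomy.items()})
    fused = pd.concat(frames, axis=0)
    kinds = {t.value_kind for t in tables}
    kind = kinds.pop() if len(kinds) == 1 else "mixed"
    return FeatureTable(fused, target_block, kind, taxonomy or None)


def block_of(feature_id: str) -> str:
    """Source block of a fused feature id (prefix before the separator)."""
    return feature_id.split(BLOCK_SEP, 1)[0] if BLOCK_SEP in feature_id else ""
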