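"""Preprocessing of mixed clinical/omics tables.

Pipeline: drop features with too many missing values, mean-impute the
rest, one-hot encode categoricals, z-score, and build the feature->group
map in which every molecular feature of a gene (expression, copy number,
protein level, mutation score, ...) shares one group while each clinical
feature forms a singleton group.

The table is a pandas DataFrame (samples x columns); column metadata is a
second DataFrame with columns (column, type, gene_id, layer) where type is
"numeric" or "categorical" and gene_id is empty for clinical columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "clean",
    "impute_mean",
    "encode_categorical",
    "zscore",
    "build_group_map",
    "preprocess",
    "PreprocessResult",
]

logger = logging.getLogger(__name__)


def _meta_lookup(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"column", "type"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    return meta.set_index("column")


def clean(table: pd.DataFrame, missing_threshold: float = 0.8) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns whose missing fraction is >= the threshold (inclusive).

    Returns the reduced table and the names of the dropped columns.
    """
    if not 0 < missing_threshold <= 1:
        raise ValueError("missing_threshold must lie in (0, 1]")
    frac = table.isna().mean()
    dropped = list(frac.index[frac >= missing_threshold])
    kept = table.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all columns dropped by the missingness filter")
    if dropped:
        logger.info("dropped %d columns for missingness >= %g: %s",
                    len(dropped), missing_threshold, dropped)
    return kept, dropped


def impute_mean(table: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing numeric cell with its column mean."""
    out = table.copy()
    for col in out.columns:
        if not pd.api.types.is_numeric_dtype(out[col]):
            raise ValueError(f"column {col!r} is not numeric; encode categoricals first")
        if out[col].isna().all():
            raise ValueError(
                f"column {col!r} has no observed values; it should have been removed by clean()"
            )
        out[col] = out[col].fillna(out[col].mean())
    return out


def encode_categorical(
    table: pd.DataFrame,
    categorical_columns: list[str],
    max_levels: int = 50,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot expansion with deterministic lexicographic level order.

    Returns the expanded table plus a map parent column -> expanded
    indicator columns (used to propagate group assignments).  Missing
    categorical cells yield all-zero indicator rows; they are left for the
    numeric imputation that follows.
    """
    out = table.copy()
    expansion: dict[str, list[str]] = {}
    for col in categorical_columns:
        levels = sorted(out[col].dropna().astype(str).unique())
        if len(levels) > max_levels:
            raise ValueError(
                f"column {col!r} has {len(levels)} levels (> {max_levels}); likely an id column"
            )
        new_cols = []
        observed = out[col].notna()
        for lv in levels:
            name = f"{col}={lv}"
            ind = (out[col].astype(str) == lv).astype(float)
            ind[~observed] = np.nan
            out[name] = ind
            new_cols.append(name)
        out = out.drop(columns=[col])
        expansion[col] = new_cols
        if len(levels) == 1:
            logger.warning("column %r has a single level; its indicator is constant "
                           "and will be dropped at normalization", col)
    return out, expansion


def zscore(table: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each column to mean 0, sd 1 (sample sd, ddof=1).

    Zero-variance columns cannot be standardized and are dropped with a
    warning; their names are returned.
    """
    if table.isna().any().any():
        raise ValueError("impute before z-scoring")
    sd = table.std(ddof=ddof)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        logger.warning("dropping %d zero-variance columns: %s", len(constant), constant)
    kept = table.drop(columns=constant)
    out = (kept - kept.mean()) / kept.std(ddof=ddof)
    return out, constant


def build_group_map(columns: list[str], meta: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Feature -> group assignment: one group per gene, singletons for clinical.

    ``columns`` may contain one-hot expanded names (``parent=level``); the
    parent's metadata applies.  Returns (integer group id per column, a
    table of group id / label / size).  Molecular columns lacking a gene id
    are rejected.
    """
    lut = _meta_lookup(meta)
    labels = []
    for col in columns:
        # exact name first, then the pre-expansion parent of "col=level"
        parent = col if col in lut.index else col.split("=", 1)[0]
        if parent not in lut.index:
            raise ValueError(f"column {col!r} missing from metadata")
        row = lut.loc[parent]
        gene = row.get("gene_id", None)
        is_molecular = isinstance(gene, str) and gene != ""
        if not is_molecular and str(row.get("layer", "")) not in ("", "clinical", "nan"):
            raise ValueError(f"molecular column {col!r} has no gene id")
        labels.append(gene if is_molecular else f"clinical:{col}")
    uniq = sorted(set(labels))
    gid = {g: i for i, g in enumerate(uniq)}
    group_map = np.array([gid[g] for g in labels], dtype=int)
    sizes = np.bincount(group_map, minlength=len(uniq))
    groups = pd.DataFrame({"group_id": np.arange(len(uniq)), "label": uniq, "size": sizes})
    return group_map, groups


@dataclass
class PreprocessResult:
    table: pd.DataFrame
    group_map: np.ndarray
    groups: pd.DataFrame
    dropped_missing: list[str]
    dropped_constant: list[str]


def preprocess(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    missing_threshold: float = 0.8,
    zscore_clinical: bool = True,
) -> PreprocessResult:
    """Full pipeline: clean -> encode -> impute -> z-score -> group map.

    Sample order is preserved; the output table is fully numeric with no
    missing cells and (unless ``zscore_clinical=False``) every column
    standardized.  Idempotent: a second pass through the numeric stages is
    the identity up to floating-point tolerance.
    """
    lut = _meta_lookup(meta)
    cleaned, dropped = clean(table, missing_threshold)
    cats = [c for c in cleaned.columns if c in lut.index and lut.loc[c, "type"] == "categorical"]
    encoded, _ = encode_categorical(cleaned, cats)
    imputed = impute_mean(encoded)
    if zscore_clinical:
        standardized, constant = zscore(imputed)
    else:
        is_clin = [
            not (isinstance(lut.loc[c.split("=", 1)[0]].get("gene_id"), str)
                 and lut.loc[c.split("=", 1)[0]].get("gene_id"))
            for c in imputed.columns
        ]
        mol = imputed.loc[:, [not f for f in is_clin]]
        clin = imputed.loc[:, is_clin]
        standardized_mol, constant = zscore(mol)
        standardized = pd.concat([standardized_mol, clin], axis=1)
    group_map, groups = build_group_map(list(standardized.columns), meta)
    return PreprocessResult(
        table=standardized,
        group_map=group_map,
        groups=groups,
        dropped_missing=dropped,
        dropped_constant=constant,
    )
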