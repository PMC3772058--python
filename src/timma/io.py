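"""Reading, scaling, binarization and filtering of drug efficacy and drug-target data.

Conventions used throughout the package:

* Drug-target matrices are :class:`pandas.DataFrame` objects with drugs as
  rows (index = drug identifiers) and targets as columns, either quantitative
  (Kd in nM, or scaled affinities in [0, 1]) or binary 0/1 inhibition
  profiles.
* Drug efficacy panels are :class:`pandas.Series` indexed by drug identifier.
  Raw efficacies may be IC50-derived scores, activity areas (AA) or drug
  sensitivity scores (DSS); :func:`scale_efficacy` maps them onto [0, 1].
* Missing affinities mean "not binding" (Kd = +inf / scaled affinity 0).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_efficacy_table",
    "read_target_matrix",
    "scale_efficacy",
    "inverse_scale_kd",
    "binarize_global",
    "binarize_drug_specific",
    "filter_targets",
    "collapse_identical_targets",
    "expand_meta_targets",
    "write_matrix",
    "write_report",
    "import_xlsx_sheet",
    "load_reference_dataset",
]

#: Maximal assay concentration (nM) used for inverse log-scaling of Kd values.
DEFAULT_MAX_CONC_NM = 10_000.0


def _resolve_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_efficacy_table(
    path: str | Path,
    drug_col: str | None = None,
    efficacy_col: str | None = None,
    sep: str | None = None,
) -> pd.Series:
    """Read a delimited drug-efficacy table into a Series indexed by drug id.

    The file must have a header row. By default the first column is taken as
    the drug identifier and the second as the efficacy score.

    Raises
    ------
    ValueError
        On a missing column, a duplicated drug identifier, or a non-numeric
        efficacy value; the message names the offending row/id.
    """
    df = pd.read_csv(path, sep=_resolve_sep(path, sep))
    if drug_col is None:
        drug_col = df.columns[0]
    if efficacy_col is None:
        remaining = [c for c in df.columns if c != drug_col]
        if not remaining:
            raise ValueError(f"{path}: no efficacy column besides {drug_col!r}")
        efficacy_col = remaining[0]
    for col in (drug_col, efficacy_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    drugs = df[drug_col].astype(str)
    dups = drugs[drugs.duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"{path}: duplicate drug id(s): {', '.join(dups)}")
    values = pd.to_numeric(df[efficacy_col], errors="coerce")
    bad = values.isna() & df[efficacy_col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric efficacy {df[efficacy_col].iloc[row]!r} "
            f"for drug {drugs.iloc[row]!r} (row {row + 2})"
        )
    if values.isna().any():
        missing = drugs[values.isna()].tolist()
        raise ValueError(f"{path}: missing efficacy for drug(s): {', '.join(missing)}")
    out = pd.Series(values.to_numpy(dtype=float), index=pd.Index(drugs, name="drug"))
    out.name = "efficacy"
    return out


def read_target_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a drug x target matrix (first column = drug id) from delimited text."""
    df = pd.read_csv(path, sep=_resolve_sep(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "drug"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate drug id(s): {', '.join(dups)}")
    return df.apply(pd.to_numeric)


def scale_efficacy(efficacy: pd.Series) -> pd.Series:
    """Min-max scale raw efficacies onto [0, 1].

    The least efficacious drug in the panel maps to 0 and the most
    efficacious to 1; the transform is idempotent. A constant panel is
    degenerate and rejected.
    """
    values = np.asarray(efficacy, dtype=float)
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        raise ValueError("degenerate panel: all efficacies identical, cannot scale")
    scaled = (values - lo) / (hi - lo)
    if isinstance(efficacy, pd.Series):
        return pd.Series(scaled, index=efficacy.index, name="scaled_efficacy")
    return pd.Series(scaled, name="scaled_efficacy")


def inverse_scale_kd(kd_nm, max_conc: float = DEFAULT_MAX_CONC_NM):
    """Inversely log-scale dissociation constants to affinities in [0, 1].

    ``s = 1 - log10(Kd) / log10(max_conc)``, clipped to [0, 1], so that a
    high scaled value implies a high binding affinity: ``s = 1`` at 1 nM and
    ``s = 0`` at the maximal assay concentration (10 uM by default).
    Missing (NaN) Kd values map to affinity 0 (not binding).
    """
    arr = np.asarray(kd_nm, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("Kd values must be positive (nM)")
    with np.errstate(invalid="ignore"):
        s = 1.0 - np.log10(arr) / np.log10(max_conc)
    s = np.clip(s, 0.0, 1.0)
    s = np.where(np.isnan(arr), 0.0, s)
    if isinstance(kd_nm, pd.DataFrame):
        return pd.DataFrame(s, index=kd_nm.index, columns=kd_nm.columns)
    if isinstance(kd_nm, pd.Series):
        return pd.Series(s, index=kd_nm.index)
    if np.isscalar(kd_nm):
        return float(s)
    return s


def binarize_global(affinity: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Binarize a scaled-affinity matrix with a single global threshold.

    ``x_ij = 1`` iff the scaled affinity ``s_ij >= threshold`` (ties count
    as inhibited). Missing values count as affinity 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    values = affinity.fillna(0.0)
    if (values.to_numpy() < 0).any() or (values.to_numpy() > 1).any():
        raise ValueError("affinities must be scaled to [0, 1] before global binarization")
    return (values >= threshold).astype(np.int8)


def binarize_drug_specific(kd: pd.DataFrame, fold: float = 50.0) -> pd.DataFrame:
    """Binarize a Kd (nM) matrix with a drug-specific threshold.

    For each drug, targets with ``Kd <= fold * min(Kd)`` over that drug's
    measured targets are marked inhibited (ties inhibited). Missing Kd
    values are treated as not binding.
    """
    if fold < 1:
        raise ValueError(f"fold must be >= 1, got {fold}")
    arr = kd.to_numpy(dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("Kd values must be positive (nM)")
    row_min = np.nanmin(np.where(np.isnan(arr), np.inf, arr), axis=1)
    empty = ~np.isfinite(row_min)
    if empty.any():
        bad = kd.index[empty].tolist()
        raise ValueError(f"drug(s) with no measured Kd: {', '.join(map(str, bad))}")
    cutoff = fold * row_min
    binary = np.where(np.isnan(arr), 0, (arr <= cutoff[:, None]).astype(np.int8))
    return pd.DataFrame(binary.astype(np.int8), index=kd.index, columns=kd.columns)


def filter_targets(
    X: pd.DataFrame, min_drugs: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Drop target columns inhibited by fewer than ``min_drugs`` drugs.

    Targets hit by too few drugs carry no information on target
    interactions. Returns the filtered matrix and the list of dropped
    target ids.
    """
    counts = X.sum(axis=0)
    keep = counts >= min_drugs
    dropped = [str(c) for c in X.columns[~keep]]
    out = X.loc[:, keep]
    if out.shape[1] == 0:
        raise ValueError(
            f"no target is inhibited by at least {min_drugs} drugs; nothing left"
        )
    return out, dropped


def collapse_identical_targets(
    X: pd.DataFrame, sep: str = "/"
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Merge target columns with identical inhibition patterns into meta-targets.

    Targets inhibited by exactly the same set of drugs are indistinguishable
    by set-theoretic prediction rules and are collapsed into a single
    meta-target named by joining the member names with ``sep`` in original
    column order. Returns the collapsed matrix and a map
    ``meta-target -> member targets``.
    """
    groups: dict[tuple, list[str]] = {}
    for col in X.columns:
        key = tuple(X[col].to_numpy().tolist())
        groups.setdefault(key, []).append(str(col))
    meta_map: dict[str, list[str]] = {}
    data = {}
    for key, members in groups.items():
        name = sep.join(members)
        meta_map[name] = members
        data[name] = np.asarray(key, dtype=X.dtypes.iloc[0] if len(X.dtypes) else np.int8)
    out = pd.DataFrame(data, index=X.index)
    return out, meta_map


def expand_meta_targets(X: pd.DataFrame, meta_map: dict[str, list[str]]) -> pd.DataFrame:
    """Inverse of :func:`collapse_identical_targets`: re-duplicate member columns."""
    data = {}
    for meta, members in meta_map.items():
        for member in members:
            data[member] = X[meta]
    return pd.DataFrame(data, index=X.index)


def write_matrix(X: pd.DataFrame, path: str | Path) -> None:
    """Write a drug x target matrix as CSV (drugs as first column)."""
    X.to_csv(path, index_label="drug")


def write_report(report: dict, path: str | Path) -> None:
    """Write a filtering/collapsing/run report as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def import_xlsx_sheet(
    xlsx_path: str | Path, out_csv: str | Path, sheet: int | str = 0
) -> Path:
    """Convert one sheet of an XLSX workbook (e.g. a published supplementary
    dataset) to the CSV layout the library reads. Requires openpyxl."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    out = Path(out_csv)
    df.to_csv(out, index=False)
    return out


def load_reference_dataset(
    name: str, data_dir: str | Path = "data/reference"
) -> tuple[pd.DataFrame, pd.Series]:
    """Load an imported reference dataset (drug-target matrix + efficacies).

    Expects ``<data_dir>/<name>_targets.csv`` (drug x target, Kd in nM or
    scaled affinities) and ``<data_dir>/<name>_efficacy.csv`` (drug,
    efficacy), produced by :func:`import_xlsx_sheet` from the corresponding
    published supplementary workbook. These workbooks are not distributed
    with the package.
    """
    data_dir = Path(data_dir)
    matrix_path = data_dir / f"{name}_targets.csv"
    efficacy_path = data_dir / f"{name}_efficacy.csv"
    for p in (matrix_path, efficacy_path):
        if not p.exists():
            raise FileNotFoundError(
                f"reference dataset file {p} not found; import the published "
                f"supplementary workbook with timma.io.import_xlsx_sheet first"
            )
    X = read_target_matrix(matrix_path)
    y = read_efficacy_table(efficacy_path)
    return X, y.reindex(X.index)
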