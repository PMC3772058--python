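"""Processing of single and pairwise siRNA viability screens.

The validation pipeline for model-predicted target combinations: replicate
quality control with an edge-well exclusion rule, normalization of single
knockdowns against the doubles that contain them, synergy scoring of
measured knockdowns with the same independence null as the model
predictions, and the predicted-vs-measured comparison (rank correlation and
grouped rank-sum tests).

Input is a long-format table with columns ``gene_a, gene_b, replicate,
inhibition_pct`` (``gene_b`` empty for single knockdowns) plus either an
``edge`` boolean column or plate-position columns ``plate, row, col``.
Inhibition values are percentages on the 0-100 scale; conversions to the
[0, 1] model scale are centralized here so the two scales are never mixed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import bliss_null

__all__ = [
    "annotate_edge_wells",
    "qc_and_average",
    "normalize_single_knockdown",
    "sirna_synergy",
    "compare_predicted_measured",
]


def _pair_key(a, b):
    if b is None or (isinstance(b, float) and np.isnan(b)) or b == "":
        return (str(a), None)
    return tuple(sorted((str(a), str(b))))


def annotate_edge_wells(
    records: pd.DataFrame, n_rows: int = 16, n_cols: int = 24
) -> pd.DataFrame:
    """Add an ``edge`` column: wells in the first/last plate row or column."""
    out = records.copy()
    out["edge"] = (
        (out["row"] == 1)
        | (out["row"] == n_rows)
        | (out["col"] == 1)
        | (out["col"] == n_cols)
    )
    return out


def qc_and_average(
    records: pd.DataFrame, max_discordance: float = 15.0
) -> pd.DataFrame:
    """Average replicate inhibition percentages per knockdown with edge QC.

    Replicates of the same (single or double) knockdown are averaged. When
    exactly two replicates disagree by more than ``max_discordance``
    percentage points, the replicate located at the plate edge is dropped;
    if neither or both replicates are edge wells, both are kept and a
    warning is issued (data are never dropped silently).
    """
    if "edge" not in records.columns:
        if {"row", "col"}.issubset(records.columns):
            records = annotate_edge_wells(records)
        else:
            records = records.assign(edge=False)
    rows = []
    gene_b = records["gene_b"] if "gene_b" in records.columns else None
    keys = [
        _pair_key(a, None if gene_b is None else gene_b.iloc[i])
        for i, a in enumerate(records["gene_a"])
    ]
    records = records.assign(_key=keys)
    for key, grp in records.groupby("_key", sort=False):
        vals = grp["inhibition_pct"].to_numpy(dtype=float)
        edges = grp["edge"].to_numpy(dtype=bool)
        used = np.ones(len(vals), dtype=bool)
        note = ""
        if len(vals) == 2 and abs(vals[0] - vals[1]) > max_discordance:
            if edges.sum() == 1:
                used = ~edges
                note = "edge replicate excluded"
            else:
                warnings.warn(
                    f"discordant replicates for {key} without a unique edge "
                    "well; keeping both",
                    stacklevel=2,
                )
                note = "discordant, kept both"
        if not used.any():
            value = np.nan
        else:
            value = float(vals[used].mean())
        rows.append(
            {
                "gene_a": key[0],
                "gene_b": key[1],
                "inhibition_pct": value,
                "n_replicates_used": int(used.sum()),
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def normalize_single_knockdown(
    singles: pd.Series, doubles: pd.DataFrame
) -> pd.Series:
    """Normalize single-knockdown inhibitions against weaker doubles.

    For a gene with single-knockdown inhibition ``s``, the normalized value
    is the mean of ``s`` and the inhibitions of all double knockdowns that
    include the gene with a value *below* ``s``. This never increases a
    single-knockdown value and makes singles and doubles comparable.
    """
    out = {}
    for gene, s in singles.items():
        mask = (doubles["gene_a"] == gene) | (doubles["gene_b"] == gene)
        vals = doubles.loc[mask, "inhibition_pct"].to_numpy(dtype=float)
        lower = vals[vals < s]
        out[gene] = float(np.mean(np.concatenate([[s], lower])))
    return pd.Series(out, name="inhibition_pct")


def sirna_synergy(
    singles: pd.Series, doubles: pd.DataFrame, null: str = "bliss"
) -> pd.DataFrame:
    """Synergy scores for measured double knockdowns, on the percentage scale.

    Inhibition percentages are rescaled to [0, 1], scored against the same
    independence null as the model predictions, and reported back on the
    0-100 scale. Pairs with a missing single knockdown get NaN.
    """
    rows = []
    for _, rec in doubles.iterrows():
        a, b = rec["gene_a"], rec["gene_b"]
        d = rec["inhibition_pct"] / 100.0
        if a not in singles.index or b not in singles.index:
            score = np.nan
        else:
            sa, sb = singles[a] / 100.0, singles[b] / 100.0
            expected = bliss_null(sa, sb) if null == "bliss" else sa * sb
            score = 100.0 * (d - expected)
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "inhibition_pct": rec["inhibition_pct"],
                "synergy_pct": score,
            }
        )
    return pd.DataFrame(rows)


def compare_predicted_measured(
    predicted: pd.DataFrame,
    measured: pd.DataFrame,
    mapping: pd.DataFrame | None = None,
) -> dict:
    """Compare model-predicted and siRNA-measured synergies per node pair.

    ``predicted`` has columns ``node_a, node_b, predicted_efficacy,
    predicted_synergy``; ``measured`` has ``gene_a, gene_b,
    synergy_pct`` (plus optionally ``inhibition_pct``); ``mapping`` maps
    gene pairs to node pairs (columns ``gene_a, gene_b, node_a, node_b``).
    When no mapping is given genes are assumed to already be node names.

    Measured synergies are averaged within each node pair; the association
    with the predictions is summarized by the Kendall rank correlation
    (tau-b). Node pairs are additionally split into High/Low groups at the
    mean predicted efficacy and compared by Wilcoxon rank-sum tests with
    Bonferroni adjustment.
    """
    measured = measured.copy()
    if mapping is not None:
        key = ["gene_a", "gene_b"]
        measured = measured.merge(mapping, on=key, how="inner")
    else:
        measured = measured.rename(columns={"gene_a": "node_a", "gene_b": "node_b"})
    measured["_pair"] = [
        tuple(sorted((a, b))) for a, b in zip(measured["node_a"], measured["node_b"])
    ]
    mean_measured = measured.groupby("_pair")["synergy_pct"].mean()

    pred = predicted.copy()
    pred["_pair"] = [
        tuple(sorted((a, b))) for a, b in zip(pred["node_a"], pred["node_b"])
    ]
    pred = pred.set_index("_pair")
    common = [p for p in pred.index if p in mean_measured.index]
    report: dict = {"n_pairs": len(common)}
    if len(common) < 3:
        report["kendall_tau"] = float("nan")
        report["kendall_p"] = float("nan")
        return report
    x = pred.loc[common, "predicted_synergy"].to_numpy(dtype=float)
    m = mean_measured.loc[common].to_numpy(dtype=float)
    tau, p = stats.kendalltau(x, m)
    report["kendall_tau"] = float(tau)
    report["kendall_p"] = float(p)

    if "predicted_efficacy" in pred.columns:
        eff = pred.loc[common, "predicted_efficacy"].to_numpy(dtype=float)
        cut = float(np.mean(eff))
        high, low = m[eff >= cut], m[eff < cut]
        report["efficacy_cutoff"] = cut
        report["n_high"], report["n_low"] = int(high.size), int(low.size)
        if high.size and low.size:
            stat, p_rs = stats.mannwhitneyu(high, low, alternative="greater")
            report["high_vs_low_p_bonferroni"] = float(min(1.0, p_rs * 2))
            report["high_mean_measured"] = float(high.mean())
            report["low_mean_measured"] = float(low.mean())
    return report
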