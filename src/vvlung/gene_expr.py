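"""Relative gene expression by the 2^-ddCt method.

Quantification cycles (Ct) from triplicate qPCR runs are collapsed to
per-(animal, gene) means; each gene is normalized to the 36B4 housekeeping
gene (acidic ribosomal phosphoprotein P0), dCt = Ct_gene - Ct_ref; the
sample dCt is then calibrated to the mean dCt of the non-ventilated (NV)
reference lungs of the *matching lung side* (left = injured, right =
contralateral), ddCt = dCt - mean dCt(calibrator, same side); relative
expression is the fold change 2^-ddCt. Group results are summarized as
median (IQR), the conventional nonparametric presentation.

Replicates are never auto-rejected; a QC flag marks (animal, gene) cells
whose replicate SD exceeds 0.5 cycles or that lost replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MissingCalibratorError

__all__ = [
    "REFERENCE_GENE",
    "collapse_replicates",
    "fold_change_ddct",
    "summarize_folds",
]

REFERENCE_GENE = "REF36B4"
CT_COLUMNS = ["animal_id", "group", "lung_side", "gene", "replicate", "ct"]


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidArgumentError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise InvalidArgumentError("Ct values must be positive and finite")
    return table


def collapse_replicates(table: pd.DataFrame, sd_qc_threshold: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (animal, group, lung_side, gene) with replicate-SD QC.

    Missing replicates are tolerated down to one; such cells and cells with
    replicate SD above ``sd_qc_threshold`` cycles are flagged, not dropped.
    """
    table = _validate_ct_table(table)
    g = table.groupby(["animal_id", "group", "lung_side", "gene"], sort=True)["ct"]
    out = g.agg(ct_mean="mean", ct_sd="std", n_replicates="count").reset_index()
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    out["qc_flag"] = (out["ct_sd"] > sd_qc_threshold) | (out["n_replicates"] < 3)
    return out


def fold_change_ddct(
    mean_ct: pd.DataFrame,
    calibrator_group=("NV-Sham", "NV-IR"),
    reference_gene: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """Per-(animal, gene, side) fold change 2^-ddCt vs the calibrator group.

    ``mean_ct`` is the output of :func:`collapse_replicates`.
    ``calibrator_group`` may be a single group label or a collection of
    labels pooled into one calibrator (default: both non-ventilated
    groups); calibration is always restricted to the matching lung side.
    """
    if isinstance(calibrator_group, str):
        calibrator_group = (calibrator_group,)
    calibrator_group = tuple(calibrator_group)

    ref = mean_ct[mean_ct["gene"] == reference_gene][
        ["animal_id", "lung_side", "ct_mean"]
    ].rename(columns={"ct_mean": "ct_ref"})
    genes = mean_ct[mean_ct["gene"] != reference_gene].copy()
    if ref.empty:
        raise InvalidArgumentError(f"reference gene {reference_gene!r} absent from table")

    merged = genes.merge(ref, on=["animal_id", "lung_side"], how="left")
    if merged["ct_ref"].isna().any():
        bad = merged.loc[merged["ct_ref"].isna(), "animal_id"].unique()
        raise InvalidArgumentError(f"reference gene missing for animals: {list(bad)}")
    merged["dct"] = merged["ct_mean"] - merged["ct_ref"]

    cal = merged[merged["group"].isin(calibrator_group)]
    cal_means = cal.groupby(["gene", "lung_side"], sort=True)["dct"].mean().rename("dct_cal")
    for side in merged["lung_side"].unique():
        if side not in cal["lung_side"].unique():
            raise MissingCalibratorError(f"no calibrator animals for lung side {side!r}")

    out = merged.merge(cal_means.reset_index(), on=["gene", "lung_side"], how="left")
    if out["dct_cal"].isna().any():
        bad = out.loc[out["dct_cal"].isna(), ["gene", "lung_side"]].drop_duplicates()
        raise MissingCalibratorError(f"missing calibrator for: {bad.to_dict('records')}")
    out["ddct"] = out["dct"] - out["dct_cal"]
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out[
        ["animal_id", "group", "lung_side", "gene", "ct_mean", "ct_ref", "dct", "ddct", "fold_change"]
    ]


def summarize_folds(folds: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) fold change per (group, lung_side, gene)."""
    g = folds.groupby(["group", "lung_side", "gene"], sort=True)["fold_change"]
    out = g.agg(
        median="median",
        q1=lambda s: float(np.percentile(s, 25)),
        q3=lambda s: float(np.percentile(s, 75)),
        n="count",
    ).reset_index()
    return out
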