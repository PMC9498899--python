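"""Expression arithmetic: qPCR 2^(-ddCt) fold changes and the heatmap transform.

The comparative-Ct method normalises a target gene's cycle threshold to a
reference gene (dCt = Ct_target - Ct_reference, e.g. alpha-tubulin), then to
a control condition (ddCt = dCt_condition - dCt_control) and reports
relative expression as 2^(-ddCt). The RNA-seq heatmap transform is
elementwise log2(FPKM + 0.01) followed by per-row z-scoring ("row scale").
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CT_COLUMNS = ["gene", "condition", "replicate", "ct_target", "ct_reference"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table TSV with columns gene, condition, replicate, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {missing}")
    return df


def _validate_ct(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    for col in ("ct_target", "ct_reference"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] <= 0).any():
            raise ValueError(f"non-positive Ct values in {col}")
    return df


def relative_expression(
    table: pd.DataFrame,
    control_condition: str,
    mode: str = "mean_dct",
) -> pd.DataFrame:
    """Per-(gene, condition) relative expression by the 2^(-ddCt) method.

    ``mode="mean_dct"`` (default) computes ddCt from the mean dCt of each
    condition; ``mode="per_replicate_fold"`` averages replicate-level folds
    instead. Either way the replicate-level fold mean and standard deviation
    are reported alongside. The control condition's fold is 1 by
    construction in the default mode.

    Returns a DataFrame with columns gene, condition, fold, fold_mean,
    fold_sd, n.
    """
    if mode not in ("mean_dct", "per_replicate_fold"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _validate_ct(table)
    df["dct"] = df["ct_target"] - df["ct_reference"]
    control = df[df["condition"] == control_condition]
    genes_without_control = set(df["gene"]) - set(control["gene"])
    if genes_without_control:
        raise ValueError(
            f"control condition {control_condition!r} missing for genes "
            f"{sorted(genes_without_control)}"
        )
    control_mean = control.groupby("gene")["dct"].mean()
    rows = []
    for (gene, condition), grp in df.groupby(["gene", "condition"], sort=False):
        ddct = grp["dct"].mean() - control_mean[gene]
        rep_folds = 2.0 ** -(grp["dct"] - control_mean[gene])
        fold = float(rep_folds.mean()) if mode == "per_replicate_fold" else float(2.0 ** -ddct)
        rows.append(
            {
                "gene": gene,
                "condition": condition,
                "fold": fold,
                "fold_mean": float(rep_folds.mean()),
                "fold_sd": float(rep_folds.std(ddof=1)) if len(grp) > 1 else 0.0,
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)


def read_fpkm_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x conditions FPKM matrix TSV (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column labels")
    return df


def heatmap_transform(matrix: pd.DataFrame, pseudo: float = 0.01) -> pd.DataFrame:
    """log2(FPKM + pseudo), then per-row z-score (mean 0, sd 1, ddof=1).

    Constant rows (zero variance after the log) map to all-zero with a
    warning, matching how row-scaled heatmaps render flat genes.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    logged = np.log2(values + pseudo)
    means = logged.mean(axis=1, keepdims=True)
    sds = logged.std(axis=1, ddof=1, keepdims=True)
    flat = (sds == 0).ravel()
    if flat.any():
        warnings.warn(
            f"constant rows scaled to zero: {list(matrix.index[flat])}"
        )
    sds[sds == 0] = 1.0
    scaled = (logged - means) / sds
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def write_fold_table(folds: pd.DataFrame, path: str | Path) -> None:
    folds.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_heatmap(scaled: pd.DataFrame, path: str | Path) -> None:
    """Optional PNG rendering of a row-scaled matrix (requires seaborn)."""
    import seaborn as sns  # deferred: plotting extra

    ax = sns.heatmap(scaled, cmap="coolwarm", center=0)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
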