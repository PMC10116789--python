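"""qPCR relative quantification against a single housekeeping gene.

Assays are run in duplicate; duplicates are collapsed to a mean Ct with a
discordance flag, and expression is quantified as 2^-dCt against the
housekeeping gene (L19 by default), assuming perfect amplification
efficiency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "HOUSEKEEPING_GENE",
    "DISCORDANCE_CT",
    "collapse_duplicates",
    "relative_expression",
    "quantify",
    "fold_change",
]

HOUSEKEEPING_GENE = "L19"

#: Replicate Ct range above which a well pair is flagged as discordant.
DISCORDANCE_CT = 0.5

_CT_COLUMNS = ("sample_id", "gene", "replicate", "ct")


def _check_ct_table(ct: pd.DataFrame) -> None:
    missing = [c for c in _CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if len(ct) == 0:
        raise ValueError("Ct table is empty")
    vals = ct["ct"].astype(float)
    if not np.isfinite(vals).all():
        raise ValueError("Ct values must be finite")


def collapse_duplicates(
    ct: pd.DataFrame, discordance_threshold: float = DISCORDANCE_CT
) -> pd.DataFrame:
    """Collapse replicate wells to one row per sample x gene.

    Returns columns ``sample_id, gene, ct, n_replicates, discordant``; the
    collapsed Ct is the replicate mean and ``discordant`` is True when the
    replicate range exceeds ``discordance_threshold`` cycles.  Discordant
    pairs are flagged, never dropped.
    """
    _check_ct_table(ct)
    grouped = ct.groupby(["sample_id", "gene"], sort=True)["ct"]
    out = grouped.agg(
        ct="mean", n_replicates="size", ct_range=lambda s: s.max() - s.min()
    ).reset_index()
    out["discordant"] = out["ct_range"] > discordance_threshold
    return out.drop(columns="ct_range")


def relative_expression(ct_gene: float, ct_housekeeping: float) -> float:
    """Relative expression 2^-(Ct_gene - Ct_housekeeping)."""
    ct_gene = float(ct_gene)
    ct_housekeeping = float(ct_housekeeping)
    if not (np.isfinite(ct_gene) and np.isfinite(ct_housekeeping)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_gene - ct_housekeeping))


def quantify(
    ct: pd.DataFrame, housekeeping: str = HOUSEKEEPING_GENE
) -> pd.DataFrame:
    """Convert a replicate-level Ct table to a sample x gene expression table.

    Duplicates are collapsed first; every sample must carry housekeeping
    rows.  Returns a wide frame with ``sample_id`` as the first column and
    one strictly positive expression column per non-housekeeping gene.
    """
    collapsed = collapse_duplicates(ct)
    hk = collapsed[collapsed["gene"] == housekeeping].set_index("sample_id")["ct"]
    genes = collapsed[collapsed["gene"] != housekeeping]
    missing = sorted(set(genes["sample_id"]) - set(hk.index))
    if missing:
        raise ValueError(
            f"samples missing housekeeping gene {housekeeping!r}: {missing}"
        )
    dct = genes["ct"].to_numpy() - hk.loc[genes["sample_id"]].to_numpy()
    genes = genes.assign(expression=2.0 ** -dct)
    wide = genes.pivot(index="sample_id", columns="gene", values="expression")
    wide.columns.name = None
    return wide.reset_index()


def fold_change(
    expression: pd.DataFrame,
    reference_group: str,
    group_col: str = "group",
) -> pd.DataFrame:
    """Express each gene relative to the reference group's mean.

    ``expression`` is a wide table with metadata columns (``sample_id``,
    ``group_col``, ...) and numeric gene columns.  The reference group's
    mean fold-change is 1 for every gene by construction.
    """
    if group_col not in expression.columns:
        raise ValueError(f"missing group column {group_col!r}")
    ref_mask = expression[group_col] == reference_group
    if not ref_mask.any():
        raise ValueError(f"reference group {reference_group!r} is empty")
    gene_cols = [
        c
        for c in expression.columns
        if c != group_col and pd.api.types.is_numeric_dtype(expression[c])
    ]
    ref_means = expression.loc[ref_mask, gene_cols].mean(axis=0)
    if (ref_means <= 0).any():
        bad = list(ref_means.index[ref_means <= 0])
        raise ValueError(f"non-positive reference mean for genes: {bad}")
    out = expression.copy()
    out[gene_cols] = expression[gene_cols] / ref_means
    return out
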