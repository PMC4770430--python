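"""Differential-expression integration.

Differential expression is consumed, not computed: the contract is a TSV per
tumor group with gene_id, log2fc (tumor vs normal), p_value and either a
precomputed ``n_low_expr_samples`` column or per-sample log2-cpm columns
(prefix ``logcpm``) from which it is derived.  Genes with log2-cpm below
zero (cpm < 1) in more than 150 samples are excluded; a DEG is p < 0.05 with
|log2FC| > 0.5, the sign giving the direction.  Both inequalities are
strict, so boundary genes (log2fc = 0.5, 150 low samples) are retained /
unflagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEG_P_THRESHOLD = 0.05
DEG_MIN_ABS_LOG2FC = 0.5
MAX_LOW_EXPR_SAMPLES = 150


@dataclass(frozen=True)
class DegSet:
    """Up- and down-regulated gene sets for one tumor group."""

    tumor_group: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down


def load_de_table(path, tumor_group: str | None = None) -> pd.DataFrame:
    """Load one DE table; returns columns gene_id, log2fc, p_value, n_low_expr_samples.

    Per-sample ``logcpm*`` columns, when present instead of
    ``n_low_expr_samples``, are reduced to the count of samples below zero.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for required in ("gene_id", "log2fc", "p_value"):
        if required not in cols:
            raise ValueError(f"{path}: missing mandatory column {required!r}")
    out = pd.DataFrame({
        "gene_id": df[cols["gene_id"]].astype(str).str.upper(),
        "log2fc": pd.to_numeric(df[cols["log2fc"]], errors="raise"),
        "p_value": pd.to_numeric(df[cols["p_value"]], errors="raise"),
    })
    if "n_low_expr_samples" in cols:
        out["n_low_expr_samples"] = pd.to_numeric(
            df[cols["n_low_expr_samples"]], errors="raise").astype(int)
    else:
        logcpm_cols = [c for c in df.columns if c.lower().startswith("logcpm")]
        if not logcpm_cols:
            raise ValueError(
                f"{path}: need n_low_expr_samples or per-sample logcpm columns")
        out["n_low_expr_samples"] = (df[logcpm_cols].to_numpy(dtype=float) < 0).sum(axis=1)
    if ((out["p_value"] < 0) | (out["p_value"] > 1)).any():
        raise ValueError(f"{path}: p_value outside [0, 1]")
    if tumor_group is not None:
        out.insert(1, "tumor_group", tumor_group)
    return out


def filter_low_expression(records: pd.DataFrame,
                          max_low_samples: int = MAX_LOW_EXPR_SAMPLES) -> pd.DataFrame:
    """Drop genes low-expressed (log2-cpm < 0) in more than ``max_low_samples`` samples."""
    keep = records["n_low_expr_samples"] <= max_low_samples
    return records.loc[keep].reset_index(drop=True)


def flag_degs(records: pd.DataFrame, tumor_group: str,
              p_threshold: float = DEG_P_THRESHOLD,
              min_abs_log2fc: float = DEG_MIN_ABS_LOG2FC) -> DegSet:
    """Flag DEGs: up iff p < 0.05 and log2fc > 0.5; down iff p < 0.05 and log2fc < -0.5."""
    sig = records["p_value"] < p_threshold
    up = records.loc[sig & (records["log2fc"] > min_abs_log2fc), "gene_id"]
    down = records.loc[sig & (records["log2fc"] < -min_abs_log2fc), "gene_id"]
    return DegSet(tumor_group=tumor_group, up=frozenset(up), down=frozenset(down))


def cross_tabulate(
    deg_sets: Mapping[str, DegSet],
    label_gene_sets: Mapping[str, Mapping[str, set[str]]],
    expression_universe: set[str],
) -> pd.DataFrame:
    """Count DEGs inside each CDMP label's gene set, per tumor group.

    ``label_gene_sets`` maps label -> tumor group -> genes carrying that
    label in any comparison for that group.  Only genes present in both the
    methylation labels and the expression data are counted.  Returns columns
    label, tumor_group, n_labeled, n_deg, n_up, n_down.
    """
    universe = {g.upper() for g in expression_universe}
    rows = []
    for label, by_group in label_gene_sets.items():
        for tg, genes in sorted(by_group.items()):
            overlap = {g.upper() for g in genes} & universe
            degs = deg_sets.get(tg)
            if degs is None:
                n_up = n_down = 0
            else:
                n_up = len(overlap & degs.up)
                n_down = len(overlap & degs.down)
            rows.append((label, tg, len(overlap), n_up + n_down, n_up, n_down))
    return pd.DataFrame(rows, columns=["label", "tumor_group", "n_labeled",
                                       "n_deg", "n_up", "n_down"])


def risk_unique_degs(
    deg_sets: Mapping[str, DegSet],
    restrict_to: set[str] | None = None,
) -> dict[str, set[str]]:
    """DEGs exclusive to one risk group (Venn exclusive zones).

    ``restrict_to`` optionally intersects every group's DEG set with a CDMP
    label's gene set before taking exclusive zones.
    """
    pool = {}
    for tg, ds in deg_sets.items():
        genes = set(ds.all)
        if restrict_to is not None:
            genes &= {g.upper() for g in restrict_to}
        pool[tg] = genes
    out = {}
    for tg in pool:
        others = set().union(*(pool[o] for o in pool if o != tg)) if len(pool) > 1 else set()
        out[tg] = pool[tg] - others
    return out
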