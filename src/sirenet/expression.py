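"""Expression preprocessing, differential expression, and ILP discretization.

Expression data lives in an :class:`anndata.AnnData` (cells in ``obs``, genes
in ``var``) with two required ``obs`` columns: ``condition`` (two labels,
control vs. case) and ``cell_type``.  The stage order mirrors a standard
single-nucleus workflow:

- :func:`qc_filter` keeps nuclei expressing at least 500 genes with under 5 %
  of UMIs from flagged (mitochondrial/ribosomal) genes;
- :func:`normalize_log` rescales each cell to a common total and applies
  ``log(1 + x)``;
- :func:`differential_expression` contrasts case vs. control per gene within
  one cell type with a two-sided Welch t-test on the log-normalized values
  (log2FC is the difference of group means on the log scale);
- :func:`call_degs` applies the strict DEG thresholds |log2FC| > 0.3 and
  p < 0.05, assigning a direction in {-1, 0, +1};
- :func:`discretize_measurements` restricts DEG directions to the nodes of a
  network, producing the ternary measurement vector the ILP consumes.

No multiple-testing correction is applied by default (the pipeline filters on
raw p-values); a Benjamini–Hochberg option is available via ``correct="bh"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "InsufficientReplicationError",
    "qc_filter",
    "normalize_log",
    "differential_expression",
    "call_degs",
    "discretize_measurements",
    "wilcoxon_two_group",
]

#: variance floor added to the squared standard error (zero-variance guard)
_VAR_EPS = 1e-9


class InsufficientReplicationError(ValueError):
    """A condition has fewer than two cells for the requested cell type."""


@dataclass(frozen=True)
class QCThresholds:
    """Nucleus-level quality-control bounds.

    ``min_genes`` — minimum number of genes with nonzero counts (inclusive);
    ``max_flagged_fraction`` — strict upper bound on the fraction of total
    UMIs from flagged genes.
    """

    min_genes: int = 500
    max_flagged_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_flagged_fraction <= 1.0:
            raise ValueError("max_flagged_fraction must be in [0, 1]")


def _dense(adata: AnnData) -> np.ndarray:
    x = adata.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def qc_filter(
    adata: AnnData,
    thresholds: QCThresholds = QCThresholds(),
    flagged_genes: set[str] | frozenset[str] = frozenset(),
) -> AnnData:
    """Drop cells failing the gene-count or flagged-UMI-fraction criteria."""
    unknown = frozenset(flagged_genes) - set(adata.var_names)
    if unknown:
        raise KeyError(f"flagged genes absent from the matrix: {sorted(unknown)}")
    x = _dense(adata)
    n_genes = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)
    flagged_mask = adata.var_names.isin(flagged_genes)
    flagged_sum = x[:, flagged_mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, flagged_sum / np.where(totals > 0, totals, 1.0), 0.0)
    keep = (n_genes >= thresholds.min_genes) & (frac < thresholds.max_flagged_fraction)
    if not keep.any():
        logger.warning("qc_filter removed every cell")
    return adata[keep].copy()


def normalize_log(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Total-count normalization followed by log(1 + x).

    Each value becomes ``log(1 + scale * x / cell_total)``; cells with zero
    total stay all-zero.
    """
    x = _dense(adata)
    totals = x.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    out = adata.copy()
    out.X = np.log1p(scale * x / safe)
    return out


def _welch(case: np.ndarray, ctl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test per gene (columns)."""
    n1, n2 = case.shape[0], ctl.shape[0]
    m1, m2 = case.mean(axis=0), ctl.mean(axis=0)
    v1, v2 = case.var(axis=0, ddof=1), ctl.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2 + _VAR_EPS
    t = (m1 - m2) / np.sqrt(se2)
    denom = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    # Welch–Satterthwaite; degenerate (both variances ~0) falls back to pooled df
    df = np.where(denom > 0, se2**2 / np.where(denom > 0, denom, 1.0), n1 + n2 - 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return m1 - m2, p


def differential_expression(
    adata: AnnData,
    cell_type: str,
    condition_key: str = "condition",
    ctl_label: str = "CTL",
    case_label: str = "CASE",
    cell_type_key: str = "cell_type",
) -> pd.DataFrame:
    """Per-gene case-vs-control contrast within one cell type.

    Returns a DataFrame with columns ``gene``, ``cell_type``, ``log2fc``,
    ``p_value`` (direction is unset until :func:`call_degs`).  Input values
    are expected to be log-normalized; log2FC is the case-minus-control
    difference of group means.
    """
    mask = adata.obs[cell_type_key] == cell_type
    sub = adata[mask]
    case = _dense(sub[sub.obs[condition_key] == case_label])
    ctl = _dense(sub[sub.obs[condition_key] == ctl_label])
    for name, grp in ((case_label, case), (ctl_label, ctl)):
        if grp.shape[0] < 2:
            raise InsufficientReplicationError(
                f"cell type {cell_type!r}: condition {name!r} has "
                f"{grp.shape[0]} cell(s); at least 2 required"
            )
    log2fc, p = _welch(case, ctl)
    return pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "cell_type": cell_type,
            "log2fc": log2fc,
            "p_value": p,
        }
    )


def call_degs(
    records: pd.DataFrame,
    fc_threshold: float = 0.3,
    p_threshold: float = 0.05,
    correct: str | None = None,
) -> pd.DataFrame:
    """Assign DEG direction: sign(log2FC) iff |log2FC| > fc and p < p, else 0.

    Both inequalities are strict.  ``correct="bh"`` applies Benjamini–Hochberg
    to the p-values before thresholding (off by default).
    """
    out = records.copy()
    p = out["p_value"].to_numpy(dtype=float)
    if correct == "bh":
        p = stats.false_discovery_control(p, method="bh")
        out["p_adjusted"] = p
    elif correct is not None:
        raise ValueError(f"unknown correction {correct!r}")
    fc = out["log2fc"].to_numpy(dtype=float)
    is_deg = (np.abs(fc) > fc_threshold) & (p < p_threshold)
    out["direction"] = np.where(is_deg, np.sign(fc), 0.0).astype(int)
    return out


def discretize_measurements(
    degs: pd.DataFrame, network_nodes: set[str] | frozenset[str]
) -> dict[str, int]:
    """Ternary measurement vector over network nodes from called DEGs.

    Every network node gets its DEG direction; nodes without a DEG record (or
    with direction 0) map to 0.  DEG genes outside the network are ignored.
    """
    measurement = {node: 0 for node in network_nodes}
    for gene, direction in zip(degs["gene"], degs["direction"]):
        if gene in measurement:
            measurement[gene] = int(direction)
        elif direction != 0:
            logger.debug("DEG %s not in network; ignored", gene)
    return measurement


def wilcoxon_two_group(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two samples.

    Exact enumeration for untied samples up to n = 50 per group; mid-rank
    normal approximation (with tie correction) beyond that or when ties are
    present.  Returns 1.0 when all values across both groups are identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "asymptotic" if has_ties or max(a.size, b.size) > 50 else "exact"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
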