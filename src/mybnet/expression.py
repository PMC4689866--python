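"""Expression matrix preparation: probe collapsing and differential-expression calls.

The matrix is assumed to hold normalized, log2-scale intensities (the
post-RMA object of a typical microarray workflow).  Differential expression
is a per-gene two-sample Student t-test (pooled variance — with 2-3
replicates per group a Welch-style estimated df is far too unstable) with
Benjamini--Hochberg adjustment across genes; a gene is called DE when
|log2 fold change| >= ``fc_threshold`` and adjusted P < ``p_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a sample design table.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene (or probe) id, columns by sample id; log2 units.
    design : pandas.DataFrame
        Indexed by sample id with columns ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    design: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene ids: {dups[:5]}")
        if self.design is not None:
            missing = set(self.values.columns) - set(self.design.index)
            if missing:
                raise ValueError(f"samples absent from design: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        if self.design is None:
            raise ValueError("no design table attached")
        return list(self.design.index[self.design["condition"] == condition])


def collapse_probes(probe_matrix: ExpressionMatrix, mapping: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by per-sample averaging.

    Genes represented by several probes get the unweighted mean of their
    probes in every sample; probes absent from ``mapping`` are dropped (the
    count is logged).
    """
    if not mapping:
        raise ValueError("empty probe-to-gene mapping")
    missing = [p for p in mapping if p not in probe_matrix.values.index]
    if missing:
        raise ValueError(f"mapped probes absent from matrix: {missing[:5]}")
    mapped = probe_matrix.values.index.intersection(list(mapping))
    n_dropped = len(probe_matrix.values.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = probe_matrix.values.loc[mapped]
    gene_of = pd.Series([mapping[p] for p in mapped], index=mapped)
    collapsed = sub.groupby(gene_of).mean()
    collapsed.index.name = probe_matrix.values.index.name
    return ExpressionMatrix(values=collapsed, design=probe_matrix.design)


def call_degs(
    matrix: ExpressionMatrix,
    control: str,
    treatment: str,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene pooled two-sample t-test (treatment vs control) with BH adjustment.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (treatment
    minus control mean), ``p``, ``adj_p``, ``is_de``, ``direction`` and
    ``reason`` (non-empty when a gene could not be tested).  Genes with zero
    variance in both groups get an undefined P and are flagged not-DE.
    """
    ctrl_cols = matrix.samples_for(control)
    trt_cols = matrix.samples_for(treatment)
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >=2 replicates per condition for the t-test")
    ctrl = matrix.values[ctrl_cols].to_numpy(float)
    trt = matrix.values[trt_cols].to_numpy(float)
    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=True)
    zero_var = (ctrl.var(axis=1) == 0) & (trt.var(axis=1) == 0)
    p = np.asarray(p, float)
    p[zero_var] = np.nan
    testable = ~np.isnan(p)
    adj_p = np.full_like(p, np.nan)
    if testable.any():
        adj_p[testable] = multipletests(p[testable], method="fdr_bh")[1]
    is_de = testable & (np.abs(log2fc) >= fc_threshold) & (adj_p < p_threshold)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "adj_p": adj_p,
            "is_de": is_de,
            "direction": np.where(log2fc >= 0, "+", "-"),
            "reason": np.where(zero_var, "zero variance in both groups", ""),
        },
        index=matrix.values.index,
    )
    out.index.name = "gene"
    return out
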