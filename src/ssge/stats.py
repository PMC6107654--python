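"""Group-level statistics for composite-index experiments.

One-way ANOVA across groups, per-group two-sample t-tests against the
control with Benjamini-Hochberg correction, Cohen's d with the pooled SD
defined as sqrt((SD1^2 + SD2^2)/2) (sample SDs), and a first-principal-
component separation diagnostic on panel-gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .paneldesign import GenePanel

__all__ = [
    "AnovaResult",
    "SeparationReport",
    "StatsError",
    "cohens_d",
    "oneway_anova",
    "bh_adjust",
    "posthoc_vs_control",
    "pc1_separation",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class SeparationReport:
    """PC1 scores and between-set overlap along the first component."""

    scores: pd.Series            # PC1 score per animal
    overlap: int                 # animals inside the other set's PC1 range
    variance_explained: float    # fraction of total variance on PC1
    set_a: tuple[str, ...]
    set_b: tuple[str, ...]


def cohens_d(control, stress) -> float:
    """Standardized mean difference (stress - control) / D_pooled.

    D_pooled = sqrt((SD1^2 + SD2^2)/2) with sample (n-1) standard
    deviations, the unweighted root-mean-square of the two group SDs.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(stress, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0.0:
        raise StatsError("pooled SD is zero; effect size undefined")
    return float((b.mean() - a.mean()) / pooled)


def oneway_anova(values, labels) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise StatsError("values and labels must align")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise StatsError("every group needs at least 2 observations")
    if all(np.ptp(g) == 0 for g in groups):
        raise StatsError("zero within-group variance in every group")
    F, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = values.size - len(groups)
    return AnovaResult(float(F), df1, df2, float(p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def posthoc_vs_control(
    index: pd.DataFrame,
    control_group: str = "C",
    equal_var: bool = True,
) -> tuple[AnovaResult, pd.DataFrame]:
    """Omnibus ANOVA plus per-group comparisons against the control.

    Each non-control group gets a two-sample t-test versus the control
    (pooled-variance by default, Welch with ``equal_var=False``), BH
    correction across the family of group-vs-control tests, and Cohen's d
    signed as group mean minus control mean.  Groups with fewer than two
    animals are skipped with a warning rather than failing the family.
    """
    if "group" not in index.columns or "index" not in index.columns:
        raise StatsError("index frame needs 'group' and 'index' columns")
    ctrl = index.loc[index["group"] == control_group, "index"].to_numpy()
    if ctrl.size == 0:
        raise StatsError(f"control group {control_group!r} not present")
    counts = index.groupby("group").size()
    small = [g for g in counts.index if counts[g] < 2]
    if small:
        warnings.warn(f"groups with n < 2 skipped: {small}")
        index = index[~index["group"].isin(small)]
    omnibus = oneway_anova(index["index"].to_numpy(), index["group"].to_numpy())

    rows = []
    for grp in pd.unique(index["group"]):
        if grp == control_group:
            continue
        vals = index.loc[index["group"] == grp, "index"].to_numpy()
        t, p = sps.ttest_ind(vals, ctrl, equal_var=equal_var)
        rows.append(
            {
                "comparison": f"{grp} vs {control_group}",
                "group": grp,
                "n": int(vals.size),
                "mean_diff": float(vals.mean() - ctrl.mean()),
                "t": float(t),
                "p": float(p),
                "d": cohens_d(ctrl, vals),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["padj"] = bh_adjust(table["p"].to_numpy())
    return omnibus, table


def pc1_separation(
    expr: pd.DataFrame,
    panel: GenePanel,
    set_a_ids,
    set_b_ids,
    log_scale: bool = True,
    scale: bool = True,
) -> SeparationReport:
    """Separation of two animal sets along PC1 of panel-gene expression.

    Genes are log2-transformed (optional) and centered; with ``scale=True``
    (default) they are also scaled to unit variance, i.e. PC1 comes from the
    eigendecomposition of the gene-gene correlation matrix — appropriate
    when genes live on heterogeneous scales.  ``scale=False`` uses the
    covariance matrix instead, letting high-variance genes dominate.  PC1
    is oriented so set B (stress) scores higher.  Overlap counts animals
    lying inside the other set's [min, max] PC1 interval — zero means the
    two sets are perfectly separated by the first component.
    """
    a_ids, b_ids = list(set_a_ids), list(set_b_ids)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise StatsError("each set needs at least 2 animals")
    sub = expr.set_index("animal_id").loc[a_ids + b_ids, panel.genes]
    X = sub.to_numpy(dtype=float)
    if log_scale:
        if (X <= 0).any():
            raise StatsError("log-scale PCA requires strictly positive expression")
        X = np.log2(X)
    sd = X.std(axis=0, ddof=1)
    flat = [g for g, s in zip(panel.genes, sd) if s == 0]
    if flat:
        raise StatsError(f"constant gene(s) across animals: {flat}")
    Z = (X - X.mean(axis=0)) / (sd if scale else 1.0)
    evals, evecs = np.linalg.eigh(np.cov(Z, rowvar=False))
    pc1 = Z @ evecs[:, -1]
    var_explained = float(evals[-1] / evals.sum())
    scores = pd.Series(pc1, index=sub.index, name="pc1")
    if scores.loc[b_ids].mean() < scores.loc[a_ids].mean():
        scores = -scores
    a, b = scores.loc[a_ids], scores.loc[b_ids]
    overlap = int(((a >= b.min()) & (a <= b.max())).sum()) + int(
        ((b >= a.min()) & (b <= a.max())).sum()
    )
    return SeparationReport(scores, overlap, var_explained, tuple(a_ids), tuple(b_ids))
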