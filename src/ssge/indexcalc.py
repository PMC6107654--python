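"""The composite stress index: expression ratios, normalization, averaging.

For animal j and panel gene i with control-group mean expression C_i, the
direction-aware expression ratio is

    x_ji = log2(C_i / y_ji) + 1   for down-regulated genes
    x_ji = log2(y_ji / C_i) + 1   for up-regulated genes

so that stress moves every gene's ratio upward regardless of its sign of
regulation, and a control animal at the baseline sits at 1.  Ratios are
then shifted additively per gene so that the control-group mean of each
gene's ratio is exactly unity (the shift preserves between-animal
differences, and hence effect sizes, exactly), and averaged across the
panel to give the per-animal index I_j.  The control-group mean of I_j is
exactly 1 by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .paneldesign import GenePanel

__all__ = [
    "IndexError_",
    "expression_ratio",
    "compute_ratio_matrix",
    "control_normalize",
    "compute_index",
    "subpanel_index",
]


class IndexError_(ValueError):
    """Invalid input to index computation (name avoids the builtin)."""


def expression_ratio(y, control_mean: float, direction: str):
    """Direction-aware log2 expression ratio of one gene.

    Down-regulated genes use log2(C/y) + 1, up-regulated log2(y/C) + 1;
    the two are mirror images summing to exactly 2 for any y, C.
    """
    y = np.asarray(y, dtype=float)
    if control_mean <= 0:
        raise IndexError_(f"control mean must be > 0, got {control_mean!r}")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise IndexError_("expression values must be finite and > 0")
    if direction == "down":
        out = np.log2(control_mean / y) + 1.0
    elif direction == "up":
        out = np.log2(y / control_mean) + 1.0
    else:
        raise IndexError_(f"direction must be 'up' or 'down', got {direction!r}")
    return float(out) if out.ndim == 0 else out


def _check_expr(expr: pd.DataFrame, genes: list[str]) -> None:
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise IndexError_(f"expression table lacks panel genes: {missing}")
    block = expr[genes]
    if block.isna().any().any():
        bad = [
            (row["animal_id"], g)
            for _, row in expr.iterrows()
            for g in genes
            if pd.isna(row[g])
        ]
        raise IndexError_(f"missing expression values (animal, gene): {bad}")


def compute_ratio_matrix(expr: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Raw (un-normalized) ratio matrix: animals x panel genes.

    Index = animal_id; a 'group' column is carried through when present.
    """
    genes = panel.genes
    _check_expr(expr, genes)
    out = pd.DataFrame(index=pd.Index(expr["animal_id"], name="animal_id"))
    if "group" in expr.columns:
        out["group"] = expr["group"].to_numpy()
    for pg in panel:
        out[pg.name] = expression_ratio(
            expr[pg.name].to_numpy(), pg.control_mean, pg.direction
        )
    return out


def control_normalize(
    ratios: pd.DataFrame, control_ids
) -> tuple[pd.DataFrame, pd.Series]:
    """Shift each gene's ratios so the control-animal mean is exactly 1.

    The additive per-gene offset ``1 - mean(control ratios)`` leaves every
    between-animal difference — and therefore every standardized effect
    size — unchanged.  Returns the shifted matrix and the offsets applied.
    """
    control_ids = list(control_ids)
    if len(control_ids) < 2:
        raise IndexError_("need at least 2 control animals to normalize")
    missing = [a for a in control_ids if a not in ratios.index]
    if missing:
        raise IndexError_(f"control animals absent from ratio matrix: {missing}")
    genes = [c for c in ratios.columns if c != "group"]
    offsets = 1.0 - ratios.loc[control_ids, genes].mean(axis=0)
    out = ratios.copy()
    out[genes] = ratios[genes] + offsets
    return out, offsets.rename("offset")


def _control_ids(expr: pd.DataFrame, control_group: str) -> list[str]:
    if "group" not in expr.columns:
        raise IndexError_("expression table needs a 'group' column")
    ids = list(expr.loc[expr["group"] == control_group, "animal_id"])
    if not ids:
        raise IndexError_(f"no animals in control group {control_group!r}")
    return ids


def compute_index(
    expr: pd.DataFrame,
    panel: GenePanel,
    control_group: str = "C",
    control_ids=None,
) -> pd.DataFrame:
    """Per-animal composite index: ratio, normalize, average across the panel.

    Returns a frame (animal_id, group, index) whose ``attrs`` carry the
    per-gene normalization offsets and the panel gene list.  The control
    group's mean index is exactly 1 (to floating-point round-off).
    """
    if control_ids is None:
        control_ids = _control_ids(expr, control_group)
    ratios = compute_ratio_matrix(expr, panel)
    normed, offsets = control_normalize(ratios, control_ids)
    genes = panel.genes
    idx = normed[genes].mean(axis=1)
    out = pd.DataFrame({"animal_id": idx.index, "index": idx.to_numpy()})
    if "group" in expr.columns:
        out.insert(1, "group", expr.set_index("animal_id").loc[out["animal_id"], "group"].to_numpy())
    out.attrs["offsets"] = offsets
    out.attrs["panel_genes"] = list(genes)
    return out


def subpanel_index(
    expr: pd.DataFrame,
    panel: GenePanel,
    subset,
    control_group: str = "C",
    control_ids=None,
) -> pd.DataFrame:
    """Index restricted to a subset of the panel, renormalized on the subset."""
    subset = list(subset)
    if not subset:
        raise IndexError_("subset must contain at least one gene")
    unknown = [g for g in subset if g not in panel.genes]
    if unknown:
        raise IndexError_(f"genes not in panel: {unknown}")
    sub = panel.restrict(subset)
    return compute_index(expr, sub, control_group=control_group, control_ids=control_ids)
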