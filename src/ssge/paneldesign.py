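"""Marker-panel selection from differential-expression tables.

Candidate genes come from the overlap of two stress-vs-control contrasts
(or a single stress-vs-stress contrast for the modality panel).  Selection
keeps protein-coding genes whose fold changes agree in sign and magnitude
across contrasts and whose control-group expression is stable, then ranks
by effect size and takes the top k.  The numeric cut-offs behind
"similar", "stable" and "largest" are configurable package choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "PanelGene",
    "GenePanel",
    "SelectionCriteria",
    "SelectionError",
    "prefilter_counts",
    "common_and_specific",
    "select_ssge_panel",
    "select_modality_panel",
]

DE_COLUMNS = ("gene_id", "baseMean", "log2FoldChange", "pvalue", "padj", "biotype")


class SelectionError(ValueError):
    """Panel selection could not satisfy its contract."""


@dataclass(frozen=True)
class PanelGene:
    name: str
    direction: str                # "up" or "down" under stress
    control_mean: float           # C_i, linear-scale control-group mean

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"{self.name}: direction must be 'up' or 'down'")
        if self.control_mean <= 0:
            raise ValueError(f"{self.name}: control mean must be > 0")


@dataclass(frozen=True)
class GenePanel:
    """Ordered marker panel defining a composite index."""

    members: tuple[PanelGene, ...]
    name: str = "panel"

    def __iter__(self) -> Iterator[PanelGene]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> list[str]:
        return [m.name for m in self.members]

    @property
    def directions(self) -> dict[str, str]:
        return {m.name: m.direction for m in self.members}

    @property
    def control_means(self) -> dict[str, float]:
        return {m.name: m.control_mean for m in self.members}

    def restrict(self, genes) -> "GenePanel":
        keep = [m for m in self.members if m.name in set(genes)]
        if not keep:
            raise SelectionError("restricted panel would be empty")
        return GenePanel(tuple(keep), name=f"{self.name}[{len(keep)}]")

    @classmethod
    def from_controls(
        cls, genes, directions: dict[str, str], controls: pd.DataFrame, name: str = "panel"
    ) -> "GenePanel":
        """Build a panel taking each C_i as the control-table mean."""
        members = tuple(
            PanelGene(g, directions[g], float(controls[g].mean())) for g in genes
        )
        return cls(members, name=name)


@dataclass(frozen=True)
class SelectionCriteria:
    """Numeric rendering of the published selection criteria.

    ``similarity_tol`` bounds the relative discrepancy of the two
    contrasts' log2 fold changes, |lfcA - lfcB| / max(|lfcA|, |lfcB|);
    ``control_cv_max`` caps the coefficient of variation of control-group
    expression; both default values are package choices, not reported
    numbers.
    """

    fdr: float = 0.05
    k: int = 6
    similarity_tol: float = 0.5
    control_cv_max: float = 0.35
    coding_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr <= 1.0):
            raise ValueError("fdr must be in (0, 1]")
        if self.k < 1:
            raise ValueError("panel size k must be >= 1")
        if self.similarity_tol < 0 or self.control_cv_max <= 0:
            raise ValueError("similarity_tol must be >= 0 and control_cv_max > 0")


def _validate_de(de: pd.DataFrame, label: str) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise SelectionError(f"DE table {label}: missing columns {missing}")
    if de["gene_id"].duplicated().any():
        dup = de.loc[de["gene_id"].duplicated(), "gene_id"].tolist()
        raise SelectionError(f"DE table {label}: duplicate gene ids {dup[:5]}")
    padj = de["padj"].to_numpy(dtype=float)
    ok = np.isnan(padj) | ((padj >= 0) & (padj <= 1))
    if not ok.all():
        raise SelectionError(f"DE table {label}: padj outside [0, 1]")
    return de.set_index("gene_id")


def prefilter_counts(counts: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """Keep only genes whose count is >= ``min_count`` in every sample.

    Mirrors the pre-filter applied to raw RNA-seq count matrices before
    differential-expression testing.  Gene order is preserved and the
    operation is idempotent.
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (arr >= min_count).all(axis=1)
    return counts.loc[keep]


def common_and_specific(
    de_a: pd.DataFrame, de_b: pd.DataFrame, fdr: float = 0.05
) -> tuple[set[str], set[str], set[str]]:
    """Venn split of the two contrasts' significant genes at one FDR.

    Returns (A-only, B-only, common); significance is padj <= fdr with NaN
    padj treated as not significant (DESeq2 convention for filtered genes).
    """
    if not (0.0 < fdr <= 1.0):
        raise ValueError("fdr must be in (0, 1]")
    a = _validate_de(de_a, "A")
    b = _validate_de(de_b, "B")
    sig_a = set(a.index[a["padj"].to_numpy(dtype=float) <= fdr])
    sig_b = set(b.index[b["padj"].to_numpy(dtype=float) <= fdr])
    common = sig_a & sig_b
    return sig_a - common, sig_b - common, common


def _control_stats(controls: pd.DataFrame, genes) -> pd.DataFrame:
    missing = [g for g in genes if g not in controls.columns]
    if missing:
        raise SelectionError(f"control table lacks candidate genes: {missing}")
    block = controls[list(genes)]
    mean = block.mean(axis=0)
    cv = block.std(axis=0, ddof=1) / mean
    return pd.DataFrame({"control_mean": mean, "control_cv": cv})


def _rank_and_take(cand: pd.DataFrame, k: int, casualties: dict[str, int]) -> pd.DataFrame:
    if len(cand) < k:
        detail = ", ".join(f"{c}: {n}" for c, n in casualties.items())
        raise SelectionError(
            f"only {len(cand)} genes survive selection, need {k} ({detail})"
        )
    # rank by effect size, ties broken lexicographically by gene id
    cand = cand.sort_values(
        ["effect", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return cand.head(k)


def select_ssge_panel(
    common,
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    controls: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
) -> GenePanel:
    """Select the stress-index panel from the genes significant in both contrasts.

    Drops non-coding genes, genes whose fold changes conflict in sign or
    differ by more than ``similarity_tol`` between the contrasts, and genes
    with unstable control expression; ranks survivors by mean |log2FC|
    across the contrasts and takes the top k.  Direction is the shared
    fold-change sign; C_i is the arithmetic mean of control expression.
    """
    crit = criteria or SelectionCriteria()
    a = _validate_de(de_a, "A")
    b = _validate_de(de_b, "B")
    genes = sorted(common)
    missing = [g for g in genes if g not in a.index or g not in b.index]
    if missing:
        raise SelectionError(f"common genes absent from a DE table: {missing}")

    casualties = {"non_coding": 0, "sign_conflict": 0, "dissimilar": 0, "unstable": 0}
    cstats = _control_stats(controls, genes)
    rows = []
    for g in genes:
        la = float(a.loc[g, "log2FoldChange"])
        lb = float(b.loc[g, "log2FoldChange"])
        if crit.coding_only and not (
            a.loc[g, "biotype"] == "protein_coding" and b.loc[g, "biotype"] == "protein_coding"
        ):
            casualties["non_coding"] += 1
            continue
        if la * lb <= 0:
            casualties["sign_conflict"] += 1
            continue
        denom = max(abs(la), abs(lb))
        if denom == 0 or abs(la - lb) / denom > crit.similarity_tol:
            casualties["dissimilar"] += 1
            continue
        if float(cstats.loc[g, "control_cv"]) > crit.control_cv_max:
            casualties["unstable"] += 1
            continue
        rows.append(
            {
                "gene_id": g,
                "effect": 0.5 * (abs(la) + abs(lb)),
                "direction": "up" if la > 0 else "down",
                "control_mean": float(cstats.loc[g, "control_mean"]),
            }
        )
    top = _rank_and_take(pd.DataFrame(rows), crit.k, casualties)
    members = tuple(
        PanelGene(r.gene_id, r.direction, r.control_mean) for r in top.itertuples()
    )
    return GenePanel(members, name=f"ssge_k{crit.k}")


def select_modality_panel(
    contrast: pd.DataFrame,
    controls: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
) -> GenePanel:
    """Select the stress-modality panel from a single stress-vs-stress contrast.

    Same machinery as the stress panel on one table (no cross-contrast
    similarity or sign checks); the default FDR is the looser 0.1 used for
    that contrast, panel size 5, direction the sign of the contrast's
    log2 fold change.
    """
    crit = criteria or SelectionCriteria(fdr=0.1, k=5)
    de = _validate_de(contrast, "contrast")
    sig = de[de["padj"].to_numpy(dtype=float) <= crit.fdr]
    genes = sorted(sig.index)
    if not genes:
        raise SelectionError(f"no genes significant at FDR {crit.fdr}")
    casualties = {"non_coding": 0, "unstable": 0}
    cstats = _control_stats(controls, genes)
    rows = []
    for g in genes:
        lfc = float(de.loc[g, "log2FoldChange"])
        if crit.coding_only and de.loc[g, "biotype"] != "protein_coding":
            casualties["non_coding"] += 1
            continue
        if float(cstats.loc[g, "control_cv"]) > crit.control_cv_max:
            casualties["unstable"] += 1
            continue
        rows.append(
            {
                "gene_id": g,
                "effect": abs(lfc),
                "direction": "up" if lfc > 0 else "down",
                "control_mean": float(cstats.loc[g, "control_mean"]),
            }
        )
    top = _rank_and_take(pd.DataFrame(rows), crit.k, casualties)
    members = tuple(
        PanelGene(r.gene_id, r.direction, r.control_mean) for r in top.itertuples()
    )
    return GenePanel(members, name=f"modality_k{crit.k}")
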