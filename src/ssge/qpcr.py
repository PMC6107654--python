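"""Quantification of qPCR amplification curves.

Each well's fluorescence-by-cycle series is baseline-subtracted, the
quantification cycle Cq is called where the curve first crosses a
threshold (fractional cycle by log-linear interpolation), Cq is converted
to a relative expression value via the amplification efficiency, and each
sample's target-gene values are normalized to the mean of its 18S and 28S
rRNA reference wells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import REFERENCE_GENES

__all__ = [
    "CqResult",
    "QpcrConfig",
    "QpcrError",
    "call_cq",
    "expression_from_cq",
    "normalize_to_rrna",
    "build_expression_table",
]


class QpcrError(ValueError):
    """Invalid qPCR input or parameters."""


@dataclass(frozen=True)
class CqResult:
    """Threshold-crossing call for one well."""

    sample: str
    gene: str
    cq: float | None          # fractional cycle, None when never crossed
    threshold: float          # baseline-subtracted threshold actually used

    @property
    def crossed(self) -> bool:
        return self.cq is not None


@dataclass(frozen=True)
class QpcrConfig:
    """Quantification settings for a plate.

    ``threshold_policy`` is either ``"fraction"`` (threshold = ``threshold``
    x the well's baseline-subtracted plateau, scale-invariant) or
    ``"absolute"`` (threshold is a raw fluorescence value).  ``rrna_mean``
    selects arithmetic (default, the literal reading of averaging the two
    rRNA expression values) or geometric reference-gene averaging.
    """

    threshold_policy: str = "fraction"
    threshold: float = 0.1
    baseline_cycles: tuple[int, int] = (3, 8)
    efficiency: float = 2.0
    scale: float = 1.0
    reference_genes: tuple[str, str] = REFERENCE_GENES
    rrna_mean: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.threshold_policy not in ("fraction", "absolute"):
            raise QpcrError(f"unknown threshold policy {self.threshold_policy!r}")
        if not (1.0 < self.efficiency <= 2.0):
            raise QpcrError("efficiency must be in (1, 2]")
        if self.rrna_mean not in ("arithmetic", "geometric"):
            raise QpcrError(f"unknown rRNA averaging {self.rrna_mean!r}")


def call_cq(
    cycles,
    fluorescence,
    threshold_policy: str = "fraction",
    threshold: float = 0.1,
    baseline_cycles: tuple[int, int] = (3, 8),
    sample: str = "",
    gene: str = "",
) -> CqResult:
    """Call the quantification cycle for one well.

    The baseline is the mean fluorescence over ``baseline_cycles``
    (inclusive).  Under the ``fraction`` policy the threshold is that
    fraction of the baseline-subtracted plateau (the series maximum); under
    ``absolute`` it is a raw fluorescence value, so the effective threshold
    is that value minus the baseline.  Cq is the fractional cycle at which
    baseline-subtracted fluorescence first reaches the threshold, by linear
    interpolation of log fluorescence between the flanking cycles.
    """
    cycles = np.asarray(cycles, dtype=float)
    fl = np.asarray(fluorescence, dtype=float)
    if cycles.shape != fl.shape or cycles.size < 5:
        raise QpcrError("need matching cycle/fluorescence series of length >= 5")
    if not np.all(np.diff(cycles) > 0):
        raise QpcrError("cycles must be strictly increasing")
    if not np.all(np.isfinite(fl)):
        raise QpcrError("fluorescence must be finite")

    lo, hi = baseline_cycles
    base_mask = (cycles >= lo) & (cycles <= hi)
    if not base_mask.any():
        raise QpcrError("baseline window contains no cycles")
    baseline = fl[base_mask].mean()
    sub = fl - baseline
    plateau = sub.max()

    if threshold_policy == "fraction":
        if not (0.0 < threshold < 1.0):
            raise QpcrError("fractional threshold must be in (0, 1)")
        if plateau <= 0.0:  # flat well: no amplification, nothing to cross
            return CqResult(sample, gene, None, 0.0)
        thr = threshold * plateau
    elif threshold_policy == "absolute":
        thr = threshold - baseline
    else:
        raise QpcrError(f"unknown threshold policy {threshold_policy!r}")
    if thr <= 0.0:
        raise QpcrError("threshold is not above baseline")

    above = sub >= thr
    if not above.any():
        return CqResult(sample, gene, None, thr)
    k = int(np.argmax(above))
    if k == 0:
        return CqResult(sample, gene, float(cycles[0]), thr)
    f0, f1 = sub[k - 1], sub[k]
    if f0 > 0.0 and f1 > 0.0:
        frac = (np.log(thr) - np.log(f0)) / (np.log(f1) - np.log(f0))
    else:  # pre-threshold reading at/below baseline: fall back to linear
        frac = (thr - f0) / (f1 - f0)
    cq = float(cycles[k - 1] + frac * (cycles[k] - cycles[k - 1]))
    return CqResult(sample, gene, cq, thr)


def expression_from_cq(cq: float | None, efficiency: float = 2.0, scale: float = 1.0) -> float:
    """Relative expression ``scale * efficiency**(-cq)``; 0.0 when not crossed."""
    if not (1.0 < efficiency <= 2.0):
        raise QpcrError("efficiency must be in (1, 2]")
    if cq is None:
        return 0.0
    if not np.isfinite(cq):
        raise QpcrError("cq must be finite")
    return float(scale * efficiency ** (-cq))


def normalize_to_rrna(raw, rrna_18s: float, rrna_28s: float, mean: str = "arithmetic"):
    """Divide a sample's expression values by its averaged rRNA expression."""
    if rrna_18s <= 0 or rrna_28s <= 0:
        raise QpcrError(
            f"non-positive rRNA expression (18S={rrna_18s!r}, 28S={rrna_28s!r})"
        )
    if mean == "arithmetic":
        ref = 0.5 * (rrna_18s + rrna_28s)
    elif mean == "geometric":
        ref = float(np.sqrt(rrna_18s * rrna_28s))
    else:
        raise QpcrError(f"unknown rRNA averaging {mean!r}")
    if isinstance(raw, dict):
        return {k: v / ref for k, v in raw.items()}
    return raw / ref


def call_plate(curves: pd.DataFrame, config: QpcrConfig | None = None) -> pd.DataFrame:
    """Call Cq for every well of a long-format plate.

    Returns one row per well: sample, gene, cq (NaN when not crossed),
    threshold, crossed.
    """
    config = config or QpcrConfig()
    out = []
    for (well, sample, gene), grp in curves.groupby(
        ["well", "sample", "gene"], sort=False
    ):
        res = call_cq(
            grp["cycle"].to_numpy(),
            grp["fluorescence"].to_numpy(),
            threshold_policy=config.threshold_policy,
            threshold=config.threshold,
            baseline_cycles=config.baseline_cycles,
            sample=str(sample),
            gene=str(gene),
        )
        out.append(
            {
                "well": well,
                "sample": res.sample,
                "gene": res.gene,
                "cq": np.nan if res.cq is None else res.cq,
                "threshold": res.threshold,
                "crossed": res.crossed,
            }
        )
    return pd.DataFrame(out)


def build_expression_table(
    curves: pd.DataFrame,
    config: QpcrConfig | None = None,
    groups: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Quantify a plate into an ExpressionTable (one row per animal).

    Every sample must carry both rRNA reference wells; target genes are
    quantified from Cq, normalized per sample to the averaged rRNA
    expression, and pivoted to one column per gene.  An animal with any
    not-crossed target well gets NaN for that gene and ``flagged=True`` —
    missing panel values are surfaced, never imputed.
    """
    config = config or QpcrConfig()
    if curves.empty:
        return pd.DataFrame(columns=["animal_id", "group", "flagged"])
    calls = call_plate(curves, config)
    ref_a, ref_b = config.reference_genes

    missing = []
    for sample, grp in calls.groupby("sample", sort=False):
        have = set(grp["gene"])
        if ref_a not in have or ref_b not in have:
            missing.append(str(sample))
    if missing:
        raise QpcrError(f"samples missing rRNA reference wells: {sorted(missing)}")

    calls["expression"] = [
        expression_from_cq(None if np.isnan(c) else c, config.efficiency, config.scale)
        for c in calls["cq"]
    ]
    rows = []
    target_genes = [g for g in calls["gene"].unique() if g not in config.reference_genes]
    for sample, grp in calls.groupby("sample", sort=False):
        by_gene = grp.set_index("gene")
        r18 = float(by_gene.loc[ref_a, "expression"])
        r28 = float(by_gene.loc[ref_b, "expression"])
        if r18 <= 0 or r28 <= 0:
            raise QpcrError(f"sample {sample!r}: non-positive rRNA expression")
        row: dict = {"animal_id": str(sample)}
        flagged = False
        for gene in target_genes:
            if gene not in by_gene.index:
                row[gene] = np.nan
                flagged = True
                continue
            if not bool(by_gene.loc[gene, "crossed"]):
                row[gene] = np.nan
                flagged = True
                continue
            row[gene] = normalize_to_rrna(
                float(by_gene.loc[gene, "expression"]), r18, r28, config.rrna_mean
            )
        row["flagged"] = flagged
        rows.append(row)
    table = pd.DataFrame(rows)
    if groups is not None:
        table.insert(1, "group", table["animal_id"].map(dict(groups)))
    cols = ["animal_id"] + (["group"] if groups is not None else [])
    cols += [g for g in target_genes] + ["flagged"]
    return table[cols]
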