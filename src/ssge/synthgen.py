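"""Synthetic cohorts, amplification curves and differential-expression fixtures.

The generator emulates the structure of a multi-protocol chronic-stress
study in rats: seven experimental groups (control plus six stress
protocols), a six-gene stress-responsive qPCR panel with known directions,
a five-gene stress-modality panel tied to isolation housing, plate-level
amplification curves consistent with the simulated expression, and
DESeq2-style differential-expression tables with a fixed Venn structure.

Everything is calibrated in *index units*: a group's true effect size d and
the within-group index standard deviation determine the per-gene log2
displacement and noise SD analytically (independent equal-variance genes),
so downstream parameter-recovery tests have a known ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GroupSpec",
    "CohortDesign",
    "GroupEffect",
    "AmpCurveParams",
    "DEFixtureParams",
    "SimConfig",
    "calibrate_preset",
    "paper_design",
    "modality_design",
    "duration_design",
    "simulate_cohort",
    "simulate_amp_curves",
    "make_de_fixture",
    "make_selection_fixture",
    "make_modality_fixture",
    "make_count_fixture",
    "SSGE_GENES",
    "SSGE_DIRECTIONS",
    "MODALITY_GENES",
    "REFERENCE_GENES",
    "PAPER_GROUP_SIZES",
    "PAPER_EFFECT_SIZES",
    "MODALITY_EFFECT_SIZES",
    "DURATION_EFFECT_SIZES",
    "INDEX_SD",
]

# --- study constants -------------------------------------------------------

#: Six-gene stress panel: direction of regulation under chronic stress.
SSGE_DIRECTIONS: dict[str, str] = {
    "Pah": "down",
    "Slc9a3": "down",
    "Cdh8": "down",
    "Cd36": "down",
    "Thrsp": "up",
    "Scd": "up",
}
SSGE_GENES: tuple[str, ...] = tuple(SSGE_DIRECTIONS)

#: Five-gene modality panel (chronic shock vs chronic variable stress).
MODALITY_GENES: tuple[str, ...] = ("Cbarp", "Dgat1", "Eprs", "Ldah", "Plat")

#: rRNA reference genes used to normalize qPCR expression per sample.
REFERENCE_GENES: tuple[str, str] = ("Rn18s", "Rn28s")

#: Group sizes of the seven-group experiment (N = 112, ANOVA df (6, 105)).
PAPER_GROUP_SIZES: dict[str, int] = {
    "C": 36, "SI": 18, "SD": 9, "GH": 8, "ID": 8, "CS": 16, "CVS": 17,
}

#: Housing of each group; the modality signal follows isolation housing.
GROUP_HOUSING: dict[str, str] = {
    "C": "social", "SI": "isolated", "SD": "social", "GH": "isolated",
    "ID": "isolated", "CS": "isolated", "CVS": "social",
}

#: Reported SSGE-index effect sizes (Cohen's d) vs control, 3-week protocols.
PAPER_EFFECT_SIZES: dict[str, float] = {
    "SI": 1.2, "SD": 1.5, "GH": 2.8, "ID": 2.8, "CS": 4.5, "CVS": 4.9,
}

#: Reported modality-index effect sizes vs control (isolation-housed groups
#: shift; the socially housed SD and CVS groups do not).
MODALITY_EFFECT_SIZES: dict[str, float] = {
    "SI": 0.7, "SD": 0.0, "GH": 3.2, "ID": 1.6, "CS": 3.1, "CVS": 0.0,
}

#: CVS-duration experiment effect sizes: 3-week, 1-week, 1-week + 2-week delay.
DURATION_EFFECT_SIZES: dict[str, float] = {
    "CVS": 5.3, "CVS_1wk": 2.9, "CVS_1wk_delay": 2.7,
}

#: Reported average within-group SD of the six-gene index.
INDEX_SD: float = 0.39

#: Control-group mean expression per gene, arbitrary rRNA-normalized units.
#: Values are plausible adrenal baselines; the analysis is scale-free.
DEFAULT_BASELINES: dict[str, float] = {
    "Pah": 12.0, "Slc9a3": 0.8, "Cdh8": 2.5, "Cd36": 30.0,
    "Thrsp": 5.0, "Scd": 80.0,
    "Cbarp": 1.6, "Dgat1": 22.0, "Eprs": 9.0, "Ldah": 3.2, "Plat": 14.0,
}

_VENN = {"a_only": 80, "b_only": 152, "common": 44}  # CVS-only / CS-only / both


# --- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: name, number of animals, housing condition."""

    name: str
    n_animals: int
    housing: str = "social"

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError(f"group {self.name!r}: n_animals must be >= 1")
        if self.housing not in ("social", "isolated"):
            raise ValueError(f"group {self.name!r}: unknown housing {self.housing!r}")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: groups, gene panel with directions, control baselines."""

    groups: tuple[GroupSpec, ...]
    genes: tuple[str, ...]
    directions: dict[str, str]
    baselines: dict[str, float]
    control: str = "C"

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if self.control not in names:
            raise ValueError(f"control group {self.control!r} not among groups")
        for g in self.genes:
            d = self.directions.get(g)
            if d not in ("up", "down"):
                raise ValueError(f"gene {g!r}: direction must be 'up' or 'down', got {d!r}")
            if self.baselines.get(g, 0.0) <= 0.0:
                raise ValueError(f"gene {g!r}: control baseline must be strictly positive")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def n_total(self) -> int:
        return sum(g.n_animals for g in self.groups)


@dataclass(frozen=True)
class GroupEffect:
    """True effect of one group in index units.

    ``delta`` displaces the group's mean index by that amount (each panel
    gene shifts by ``delta`` in its stress direction in log2 space);
    ``sigma`` is the per-gene log2 noise SD shared by all panel genes.
    """

    group_name: str
    delta: float
    sigma: float
    gene_shifts: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("per-gene noise SD sigma must be > 0")


@dataclass(frozen=True)
class AmpCurveParams:
    """Parameters of the saturating amplification-curve model.

    Baseline-subtracted fluorescence follows ``plateau * A / (A + K)`` with
    template amount ``A = expression * template_scale * efficiency**cycle``;
    the threshold-crossing cycle is therefore ``-log_E`` of expression plus
    a plate-wide constant, so expression ratios map exactly to Cq spacing.
    """

    efficiency: float = 2.0
    baseline: float = 0.5
    plateau: float = 100.0
    half_saturation: float = 1.0
    template_scale: float = 1e-10
    noise_sd: float = 0.0
    n_cycles: int = 50

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")
        if self.plateau <= 0 or self.half_saturation <= 0 or self.template_scale <= 0:
            raise ValueError("plateau, half_saturation and template_scale must be > 0")


@dataclass(frozen=True)
class DEFixtureParams:
    """Stratum sizes and statistic distributions for the DE-table fixture."""

    n_a_only: int = _VENN["a_only"]
    n_b_only: int = _VENN["b_only"]
    n_common: int = _VENN["common"]
    n_background: int = 2000
    sig_padj_log10_range: tuple[float, float] = (-6.0, -1.4)
    bg_padj_range: tuple[float, float] = (0.11, 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to regenerate a cohort byte-identically.

    The same config plus the same seed always produces identical outputs;
    each generator draws from a named substream so stages are independently
    reproducible.
    """

    design: CohortDesign
    effects: tuple[GroupEffect, ...]
    amp: AmpCurveParams = field(default_factory=AmpCurveParams)
    de: DEFixtureParams = field(default_factory=DEFixtureParams)
    seed: int = 0

    def effect_for(self, group: str) -> GroupEffect:
        for e in self.effects:
            if e.group_name == group:
                return e
        raise KeyError(f"no GroupEffect defined for group {group!r}")


# --- seeding ---------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named stage, derived from one master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# --- calibration -----------------------------------------------------------

def calibrate_preset(target_d: float, sd_index: float, k_genes: int) -> GroupEffect:
    """Translate a target Cohen's d into generator parameters.

    With ``k_genes`` independent panel genes of equal log2 noise SD
    ``sigma``, the k-gene index has SD ``sigma / sqrt(k)``.  Calibrating the
    index SD to ``sd_index`` gives ``sigma = sd_index * sqrt(k)``; the mean
    displacement needed for effect size d is ``delta = d * sd_index``
    because both groups share the same index SD.
    """
    if sd_index <= 0:
        raise ValueError("sd_index must be > 0")
    if k_genes < 1:
        raise ValueError("k_genes must be >= 1")
    return GroupEffect(
        group_name="preset",
        delta=float(target_d) * float(sd_index),
        sigma=float(sd_index) * float(np.sqrt(k_genes)),
    )


def _effects_from_d(
    d_by_group: dict[str, float],
    group_names: list[str],
    control: str,
    sd_index: float,
    k_genes: int,
) -> tuple[GroupEffect, ...]:
    effects = []
    for name in group_names:
        d = 0.0 if name == control else d_by_group.get(name, 0.0)
        effects.append(replace(calibrate_preset(d, sd_index, k_genes), group_name=name))
    return tuple(effects)


def paper_design(sd_index: float = INDEX_SD) -> SimConfig:
    """Seven-group, six-gene cohort calibrated to the reported effect sizes."""
    design = CohortDesign(
        groups=tuple(
            GroupSpec(n, PAPER_GROUP_SIZES[n], GROUP_HOUSING[n]) for n in PAPER_GROUP_SIZES
        ),
        genes=SSGE_GENES,
        directions=dict(SSGE_DIRECTIONS),
        baselines={g: DEFAULT_BASELINES[g] for g in SSGE_GENES},
        control="C",
    )
    effects = _effects_from_d(PAPER_EFFECT_SIZES, design.group_names, "C", sd_index, len(SSGE_GENES))
    return SimConfig(design=design, effects=effects)


def modality_design(sd_index: float = INDEX_SD) -> SimConfig:
    """Seven-group cohort on the five modality genes.

    Only isolation-housed groups (SI, GH, ID, CS) are displaced; all five
    genes respond upward, mirroring the excess of genes upregulated under
    chronic shock relative to chronic variable stress.
    """
    design = CohortDesign(
        groups=tuple(
            GroupSpec(n, PAPER_GROUP_SIZES[n], GROUP_HOUSING[n]) for n in PAPER_GROUP_SIZES
        ),
        genes=MODALITY_GENES,
        directions={g: "up" for g in MODALITY_GENES},
        baselines={g: DEFAULT_BASELINES[g] for g in MODALITY_GENES},
        control="C",
    )
    effects = _effects_from_d(
        MODALITY_EFFECT_SIZES, design.group_names, "C", sd_index, len(MODALITY_GENES)
    )
    return SimConfig(design=design, effects=effects)


def duration_design(sd_index: float = INDEX_SD) -> SimConfig:
    """CVS-duration experiment: control, 3-week, 1-week, 1-week + 2-week delay.

    Group sizes give N = 52 (ANOVA df (3, 48)); the per-protocol sizes are
    an assumption documented in the methods note, not a reported fact.
    """
    sizes = {"C": 17, "CVS": 17, "CVS_1wk": 9, "CVS_1wk_delay": 9}
    design = CohortDesign(
        groups=tuple(GroupSpec(n, k, "social") for n, k in sizes.items()),
        genes=SSGE_GENES,
        directions=dict(SSGE_DIRECTIONS),
        baselines={g: DEFAULT_BASELINES[g] for g in SSGE_GENES},
        control="C",
    )
    effects = _effects_from_d(
        DURATION_EFFECT_SIZES, design.group_names, "C", sd_index, len(SSGE_GENES)
    )
    return SimConfig(design=design, effects=effects)


# --- cohort simulation -----------------------------------------------------

def simulate_cohort(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort as an ExpressionTable (animal_id, group, gene columns).

    Per animal j and panel gene i, log2 expression is drawn around
    ``log2(baseline_i)`` with the group displacement applied in the gene's
    stress direction (down genes shift negative, up genes positive) plus
    lognormal animal-to-animal noise (normal in log2 space, genes
    independent).  The direction-aware expression ratio of every gene then
    has mean ``1 + delta_g`` and SD ``sigma_g``, and the k-gene index has SD
    ``sigma_g / sqrt(k)``.
    """
    if seed is None:
        seed = config.seed
    rng = substream(seed, "cohort")
    design = config.design
    sign = np.array(
        [1.0 if design.directions[g] == "up" else -1.0 for g in design.genes]
    )
    log_base = np.log2([design.baselines[g] for g in design.genes])

    rows: list[pd.DataFrame] = []
    animal = 0
    for grp in design.groups:
        eff = config.effect_for(grp.name)
        shift = np.full(len(design.genes), eff.delta)
        if eff.gene_shifts:
            for i, g in enumerate(design.genes):
                if g in eff.gene_shifts:
                    shift[i] = eff.gene_shifts[g]
        noise = rng.normal(0.0, eff.sigma, size=(grp.n_animals, len(design.genes)))
        log_expr = log_base + sign * shift + noise
        df = pd.DataFrame(2.0 ** log_expr, columns=list(design.genes))
        df.insert(0, "group", grp.name)
        df.insert(0, "animal_id", [f"A{animal + i:03d}" for i in range(grp.n_animals)])
        animal += grp.n_animals
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# --- amplification curves --------------------------------------------------

def _fluorescence(expression: np.ndarray, cycles: np.ndarray, p: AmpCurveParams) -> np.ndarray:
    amount = expression[:, None] * p.template_scale * p.efficiency ** cycles[None, :]
    return p.baseline + p.plateau * amount / (amount + p.half_saturation)


def simulate_amp_curves(
    expr: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Emit a long-format qPCR plate for a simulated cohort.

    One well per animal per panel gene plus two rRNA reference wells
    (18S/28S) per animal at constant expression 1.0, so rRNA normalization
    of the quantified plate returns the simulated expression values
    directly.  A well with non-positive expression stays at baseline and
    never crosses threshold.  Additive Gaussian measurement noise with SD
    ``config.amp.noise_sd`` is applied to every fluorescence reading.
    """
    if seed is None:
        seed = config.seed
    rng = substream(seed, "amp")
    p = config.amp
    genes = [g for g in expr.columns if g not in ("animal_id", "group")]
    cycles = np.arange(1, p.n_cycles + 1, dtype=float)

    records = []
    well = 0
    for _, row in expr.iterrows():
        for gene in genes + list(REFERENCE_GENES):
            value = 1.0 if gene in REFERENCE_GENES else float(row[gene])
            records.append((f"W{well:04d}", row["animal_id"], gene, max(value, 0.0)))
            well += 1
    values = np.array([r[3] for r in records])
    fl = _fluorescence(values, cycles, p)
    if p.noise_sd > 0:
        fl = fl + rng.normal(0.0, p.noise_sd, size=fl.shape)

    n = len(records)
    out = pd.DataFrame(
        {
            "well": np.repeat([r[0] for r in records], p.n_cycles),
            "sample": np.repeat([r[1] for r in records], p.n_cycles),
            "gene": np.repeat([r[2] for r in records], p.n_cycles),
            "cycle": np.tile(cycles.astype(int), n),
            "fluorescence": fl.ravel(),
        }
    )
    return out


# --- DE-table fixtures -----------------------------------------------------

_DE_COLUMNS = ["gene_id", "baseMean", "log2FoldChange", "pvalue", "padj", "biotype"]

#: Mean |log2FC| of the six panel genes: the four largest-effect genes come
#: first so the k=4 subpanel is the rank prefix of the k=6 panel.
_SSGE_LFC = {"Pah": 3.0, "Slc9a3": 2.9, "Thrsp": 2.8, "Scd": 2.7, "Cdh8": 2.4, "Cd36": 2.3}

#: Decoy genes planted in the common stratum, one family per selection
#: criterion: non-coding, cross-protocol sign conflict, cross-protocol
#: dissimilar magnitude, unstable in controls.
_DECOYS_NONCODING = ("NcDecoy1", "NcDecoy2", "NcDecoy3")
_DECOYS_SIGN = ("SignDecoy1", "SignDecoy2", "SignDecoy3")
_DECOYS_DISSIMILAR = ("DissimDecoy1", "DissimDecoy2", "DissimDecoy3")
_DECOYS_UNSTABLE = ("UnstableDecoy1", "UnstableDecoy2", "UnstableDecoy3")


def _sig_padj(rng: np.random.Generator, n: int, params: DEFixtureParams) -> np.ndarray:
    lo, hi = params.sig_padj_log10_range
    return 10.0 ** rng.uniform(lo, hi, n)


def _bg_padj(rng: np.random.Generator, n: int, params: DEFixtureParams) -> np.ndarray:
    lo, hi = params.bg_padj_range
    return rng.uniform(lo, hi, n)


def _de_frame(rng, gene_ids, lfc, padj, biotype) -> pd.DataFrame:
    n = len(gene_ids)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseMean": np.round(2.0 ** rng.uniform(4, 12, n), 3),
            "log2FoldChange": np.round(lfc, 4),
            "pvalue": np.round(padj * rng.uniform(0.05, 0.8, n), 10),
            "padj": np.round(padj, 10),
            "biotype": biotype,
        }
    )


def make_de_fixture(
    preset: str = "paper_de_structure",
    seed: int = 0,
    params: DEFixtureParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two stress-vs-control DE tables (CVS first, CS second) over one universe.

    The ``paper_de_structure`` preset reproduces the published Venn
    structure at FDR 0.05 — 124 significant genes in the CVS contrast, 196
    in the CS contrast, 44 in both — and plants the six panel genes in the
    common stratum with the largest, direction-consistent fold changes,
    alongside decoy genes that each fail exactly one selection criterion.
    The ``empty`` preset sets every padj to 1.
    """
    if preset not in ("paper_de_structure", "empty"):
        raise ValueError(f"unknown DE fixture preset {preset!r}")
    params = params or DEFixtureParams()
    rng = substream(seed, f"defixture:{preset}")

    n_other_common = params.n_common - len(SSGE_GENES) - 3 * 4
    if n_other_common < 0:
        raise ValueError("n_common too small for panel genes plus decoys")

    ids, lfc_a, lfc_b, padj_a, padj_b, biotype = [], [], [], [], [], []

    def add(gene, la, lb, pa, pb, bio="protein_coding"):
        ids.append(gene)
        lfc_a.append(la)
        lfc_b.append(lb)
        padj_a.append(pa)
        padj_b.append(pb)
        biotype.append(bio)

    # six panel genes: large, similar, direction-consistent
    for g, mag in _SSGE_LFC.items():
        s = 1.0 if SSGE_DIRECTIONS[g] == "up" else -1.0
        wiggle = rng.uniform(0.95, 1.05, 2)
        add(g, s * mag * wiggle[0], s * mag * wiggle[1],
            _sig_padj(rng, 1, params)[0], _sig_padj(rng, 1, params)[0])
    # decoys: each family fails one criterion, all otherwise competitive
    for g in _DECOYS_NONCODING:
        m = rng.uniform(3.2, 3.8)
        add(g, m, m * rng.uniform(0.95, 1.05),
            _sig_padj(rng, 1, params)[0], _sig_padj(rng, 1, params)[0], bio="lincRNA")
    for g in _DECOYS_SIGN:
        m = rng.uniform(2.6, 3.2)
        add(g, m, -m * rng.uniform(0.9, 1.1),
            _sig_padj(rng, 1, params)[0], _sig_padj(rng, 1, params)[0])
    for g in _DECOYS_DISSIMILAR:
        m = rng.uniform(2.8, 3.4)
        add(g, m, m * rng.uniform(0.15, 0.3),
            _sig_padj(rng, 1, params)[0], _sig_padj(rng, 1, params)[0])
    for g in _DECOYS_UNSTABLE:
        m = rng.uniform(2.5, 3.1)
        add(g, m, m * rng.uniform(0.95, 1.05),
            _sig_padj(rng, 1, params)[0], _sig_padj(rng, 1, params)[0])
    # remaining common genes: smaller effects than any panel gene
    for i in range(n_other_common):
        m = rng.uniform(0.3, 2.0) * rng.choice([-1.0, 1.0])
        add(f"Common{i:03d}", m, m * rng.uniform(0.8, 1.2),
            _sig_padj(rng, 1, params)[0], _sig_padj(rng, 1, params)[0])
    # contrast-specific strata
    for i in range(params.n_a_only):
        add(f"CvsOnly{i:03d}", rng.uniform(0.3, 2.5) * rng.choice([-1, 1]),
            rng.normal(0, 0.2), _sig_padj(rng, 1, params)[0], _bg_padj(rng, 1, params)[0])
    for i in range(params.n_b_only):
        add(f"CsOnly{i:03d}", rng.normal(0, 0.2),
            rng.uniform(0.3, 2.5) * rng.choice([-1, 1]),
            _bg_padj(rng, 1, params)[0], _sig_padj(rng, 1, params)[0])
    for i in range(params.n_background):
        add(f"Bg{i:04d}", rng.normal(0, 0.15), rng.normal(0, 0.15),
            _bg_padj(rng, 1, params)[0], _bg_padj(rng, 1, params)[0],
            bio="protein_coding" if rng.uniform() < 0.8 else "lincRNA")

    if preset == "empty":
        padj_a = [1.0] * len(ids)
        padj_b = [1.0] * len(ids)

    de_a = _de_frame(rng, ids, np.array(lfc_a), np.array(padj_a), biotype)
    de_b = _de_frame(rng, ids, np.array(lfc_b), np.array(padj_b), biotype)
    return de_a, de_b


def _control_expression(
    rng: np.random.Generator, genes: list[str], unstable: set[str], n_controls: int
) -> pd.DataFrame:
    """Control-group qPCR expression for candidate genes.

    Stable genes get a log2 SD of ~0.2 (CV ~ 0.14); genes flagged unstable
    get ~0.8 (CV ~ 0.6), which trips the default control-CV ceiling.
    """
    data = {"animal_id": [f"A{i:03d}" for i in range(n_controls)], "group": "C"}
    for g in genes:
        base = DEFAULT_BASELINES.get(g, float(2.0 ** rng.uniform(0, 6)))
        sd = 0.8 if g in unstable else 0.2
        data[g] = base * 2.0 ** rng.normal(0.0, sd, n_controls)
    return pd.DataFrame(data)


def make_selection_fixture(
    preset: str = "paper_de_structure", seed: int = 0, n_controls: int = 36
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DE tables plus the matching control ExpressionTable for panel selection.

    The control table covers every gene significant in both contrasts; the
    'unstable' decoys carry high animal-to-animal variability so the
    control-stability criterion has real casualties.
    """
    de_a, de_b = make_de_fixture(preset, seed)
    sig = set(de_a.loc[de_a["padj"] <= 0.05, "gene_id"]) & set(
        de_b.loc[de_b["padj"] <= 0.05, "gene_id"]
    )
    genes = sorted(sig) or list(SSGE_GENES)
    rng = substream(seed, "selection-controls")
    controls = _control_expression(rng, genes, set(_DECOYS_UNSTABLE), n_controls)
    return de_a, de_b, controls


def make_modality_fixture(
    seed: int = 0, n_controls: int = 36
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single CS-vs-CVS DE table (FDR 0.1) plus matching control expression.

    The five modality genes are the top coding, control-stable genes by
    |log2FC| (all upregulated in chronic shock); decoys cover the
    non-coding and control-instability exclusions.
    """
    params = DEFixtureParams()
    rng = substream(seed, "modality-fixture")
    ids, lfc, padj, biotype = [], [], [], []

    def add(g, m, p, bio="protein_coding"):
        ids.append(g)
        lfc.append(m)
        padj.append(p)
        biotype.append(bio)

    for g in MODALITY_GENES:
        add(g, rng.uniform(2.2, 3.0), 10.0 ** rng.uniform(-5, -1.2))
    for g in ("McNcDecoy1", "McNcDecoy2"):
        add(g, rng.uniform(3.2, 3.8), 10.0 ** rng.uniform(-5, -1.2), bio="lincRNA")
    for g in ("McUnstable1", "McUnstable2"):
        add(g, rng.uniform(2.4, 3.0), 10.0 ** rng.uniform(-5, -1.2))
    for i in range(40):
        add(f"McSig{i:02d}", rng.uniform(0.3, 1.8) * rng.choice([-1, 1]),
            10.0 ** rng.uniform(-4, -1.1))
    for i in range(800):
        add(f"McBg{i:03d}", rng.normal(0, 0.15), rng.uniform(0.12, 1.0))

    de = _de_frame(rng, ids, np.array(lfc), np.array(padj), biotype)
    sig_genes = sorted(de.loc[de["padj"] <= 0.1, "gene_id"])
    controls = _control_expression(
        substream(seed, "modality-controls"), sig_genes,
        {"McUnstable1", "McUnstable2"}, n_controls,
    )
    return de, controls


def make_count_fixture(
    seed: int = 0, n_genes: int = 200, n_samples: int = 6, frac_low: float = 0.3
) -> pd.DataFrame:
    """Integer count matrix (gene_id index, one column per sample).

    ``frac_low`` of the genes get at least one sample below the default
    prefilter floor of 10 counts, so the prefilter has work to do.
    """
    rng = substream(seed, "counts")
    mu = 2.0 ** rng.uniform(5, 12, n_genes)
    counts = rng.poisson(mu[:, None] * rng.uniform(0.7, 1.3, (n_genes, n_samples)))
    low = rng.uniform(size=n_genes) < frac_low
    for i in np.flatnonzero(low):
        counts[i, rng.integers(n_samples)] = rng.integers(0, 10)
    return pd.DataFrame(
        counts,
        index=pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene_id"),
        columns=[f"S{j}" for j in range(n_samples)],
    )
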