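"""Effect sizes, ANOVA, BH correction and PC1 separation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssge import synthgen as sg
from ssge.paneldesign import GenePanel, PanelGene
from ssge.stats import (
    StatsError,
    bh_adjust,
    cohens_d,
    oneway_anova,
    pc1_separation,
    posthoc_vs_control,
)

# --- independent oracles ---------------------------------------------------

def bh_stepup_oracle(p):
    """Brute-force BH: sort, p*m/rank, enforce monotonicity from the largest."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def anova_ss_oracle(values, labels):
    """F from explicit between/within sums of squares."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    ssb = ssw = 0.0
    k = 0
    for g in np.unique(labels):
        v = values[labels == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
        k += 1
    df1, df2 = k - 1, values.size - k
    return (ssb / df1) / (ssw / df2)


# --- Cohen's d -------------------------------------------------------------

class TestCohensD:
    def test_identical_groups_are_zero(self):
        assert cohens_d([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 0.0

    def test_unit_sd_shift_of_two(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_unequal_variances_use_rms_pooling(self):
        # means 1 and 3, sample variances 2 and 8 -> d = 2/sqrt(5)
        assert cohens_d([0, 2], [1, 5]) == pytest.approx(2 / np.sqrt(5))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(StatsError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        b=st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    def test_antisymmetry_shift_and_scale(self, a, b, shift, scale):
        a = [round(x, 2) for x in a]
        b = [round(x, 2) for x in b]
        pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
        if pooled < 0.01:  # near-degenerate inputs make the ratio meaningless
            return
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d, rel=1e-9, abs=1e-12)
        sa = [x + shift for x in a]
        sb = [x + shift for x in b]
        assert cohens_d(sa, sb) == pytest.approx(d, rel=1e-6, abs=1e-9)
        ma = [x * scale for x in a]
        mb = [x * scale for x in b]
        assert cohens_d(ma, mb) == pytest.approx(d, rel=1e-6, abs=1e-9)


# --- ANOVA -----------------------------------------------------------------

class TestOnewayAnova:
    def test_seven_group_design_degrees_of_freedom(self, cohort, panel):
        from ssge import compute_index

        idx = compute_index(cohort, panel)
        res = oneway_anova(idx["index"], idx["group"])
        assert (res.df1, res.df2) == (6, 105)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(a, b, equal_var=True)
        res = oneway_anova(np.r_[a, b], np.r_[["a"] * 12, ["b"] * 9])
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(2, 6)
            labels = np.repeat([f"g{i}" for i in range(k)], rng.integers(3, 9, k))
            values = rng.normal(rng.normal(0, 1, 1), 1.0, labels.size)
            res = oneway_anova(values, labels)
            assert res.F == pytest.approx(anova_ss_oracle(values, labels), rel=1e-10)

    def test_null_f_mean_near_one(self):
        rng = np.random.default_rng(2)
        fs = []
        for _ in range(300):
            values = rng.normal(0, 1, 60)
            labels = np.repeat(list("abcd"), 15)
            fs.append(oneway_anova(values, labels).F)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)

    def test_degenerate_constant_groups_rejected(self):
        with pytest.raises(StatsError):
            oneway_anova([1, 1, 2, 2], ["a", "a", "b", "b"])


# --- Benjamini-Hochberg ----------------------------------------------------

class TestBhAdjust:
    def test_textbook_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    @settings(max_examples=300, deadline=None)
    @given(
        p=st.lists(
            st.sampled_from([0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 0.77, 1.0]),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_brute_force_stepup_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_elementwise_dominance_and_cap(self, p):
        out = bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.5])


# --- post-hoc family -------------------------------------------------------

class TestPosthocVsControl:
    def test_identical_groups_give_zero_d(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(1, 0.3, 20)
        idx = pd.DataFrame(
            {"animal_id": range(40), "group": ["C"] * 20 + ["S"] * 20,
             "index": np.r_[vals, vals]}
        )
        _, comps = posthoc_vs_control(idx)
        assert comps.loc[0, "d"] == pytest.approx(0.0, abs=1e-12)
        assert comps.loc[0, "p"] == pytest.approx(1.0)

    def test_small_group_skipped_with_warning_not_failure(self):
        idx = pd.DataFrame(
            {"animal_id": range(8), "group": ["C"] * 4 + ["S"] + ["T"] * 3,
             "index": [1.0, 1.2, 0.9, 1.1, 5.0, 2.0, 2.2, 2.1]}
        )
        with pytest.warns(UserWarning, match="n < 2"):
            _, comps = posthoc_vs_control(idx)
        assert list(comps["group"]) == ["T"]

    def test_family_type_one_error_near_nominal(self):
        """Under a global null the BH family rejects at ~ the nominal 0.05 rate."""
        sim = sg.paper_design()
        null_effects = tuple(
            sg.GroupEffect(e.group_name, 0.0, e.sigma) for e in sim.effects
        )
        null = sg.SimConfig(design=sim.design, effects=null_effects)
        from ssge import compute_index

        genes = list(sim.design.genes)
        any_reject = 0
        n_rep = 500
        for rep in range(n_rep):
            expr = sg.simulate_cohort(null, seed=40_000 + rep)
            pan = GenePanel.from_controls(genes, sim.design.directions,
                                          expr[expr["group"] == "C"])
            idx = compute_index(expr, pan)
            _, comps = posthoc_vs_control(idx)
            any_reject += int((comps["padj"] <= 0.05).any())
        rate = any_reject / n_rep
        # binomial SE at p=0.05, n=500 is ~0.010
        assert rate == pytest.approx(0.05, abs=0.03)


# --- PC1 separation --------------------------------------------------------

class TestPc1Separation:
    def _stress_sets(self, cohort):
        a = list(cohort.loc[cohort["group"] == "C", "animal_id"])
        b = list(cohort.loc[cohort["group"].isin(["CS", "CVS"]), "animal_id"])
        return a, b

    def test_calibrated_cohorts_typically_separate_completely(self, paper_sim):
        """Control vs the two most intense protocols: PC1 separates the sets
        with zero overlap in the typical cohort (median over replicates)."""
        overlaps = []
        genes = list(paper_sim.design.genes)
        for rep in range(30):
            expr = sg.simulate_cohort(paper_sim, seed=60_000 + rep)
            pan = GenePanel.from_controls(genes, paper_sim.design.directions,
                                          expr[expr["group"] == "C"])
            a, b = self._stress_sets(expr)
            rep_out = pc1_separation(expr, pan, a, b)
            overlaps.append(rep_out.overlap)
        assert np.median(overlaps) == 0
        assert np.mean(overlaps) < 2.0

    def test_null_sets_overlap_with_high_probability(self, paper_sim):
        sim = sg.paper_design()
        null = sg.SimConfig(
            design=sim.design,
            effects=tuple(sg.GroupEffect(e.group_name, 0.0, e.sigma) for e in sim.effects),
        )
        expr = sg.simulate_cohort(null, seed=8)
        pan = GenePanel.from_controls(list(sim.design.genes), sim.design.directions,
                                      expr[expr["group"] == "C"])
        a, b = self._stress_sets(expr)
        assert pc1_separation(expr, pan, a, b).overlap > 0

    def test_single_informative_gene_dominates_pc1(self):
        rng = np.random.default_rng(4)
        n = 40
        signal = np.r_[rng.normal(0, 0.2, n // 2), rng.normal(3, 0.2, n // 2)]
        expr = pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(n)],
                "group": ["C"] * (n // 2) + ["S"] * (n // 2),
                "g1": 2.0 ** signal,
                "g2": 2.0 ** rng.normal(0, 0.05, n),
                "g3": 2.0 ** rng.normal(0, 0.05, n),
            }
        )
        pan = GenePanel((PanelGene("g1", "up", 1.0), PanelGene("g2", "up", 1.0),
                         PanelGene("g3", "up", 1.0)))
        rep = pc1_separation(expr, pan, expr["animal_id"][: n // 2], expr["animal_id"][n // 2:],
                             scale=False)
        z = (signal - signal.mean()) / signal.std(ddof=1)
        corr = np.corrcoef(rep.scores.to_numpy(), z)[0, 1]
        assert abs(corr) > 0.99

    def test_constant_gene_is_an_error_naming_it(self, cohort, panel):
        broken = cohort.copy()
        broken["Pah"] = 2.0
        with pytest.raises(StatsError, match="Pah"):
            a = list(broken.loc[broken["group"] == "C", "animal_id"])
            b = list(broken.loc[broken["group"] == "CVS", "animal_id"])
            pc1_separation(broken, panel, a, b)
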