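"""ANCOVA battery, Scheffe post-hoc, Bonferroni gate, site ANOVA."""

import numpy as np
import pandas as pd
import pytest

from ccmorph.errors import ValidationError
from ccmorph.io import REGION_NAMES
from ccmorph.stats import (
    ancova,
    ancova_group,
    bonferroni_gate,
    interaction_f,
    scheffe_posthoc,
    site_anova,
    stats_battery,
)
from ccmorph.synthetic import (
    CohortSpec,
    GroupSpec,
    ISTHMUS_CELLS,
    simulate_area_table,
    simulate_cell_table,
)


def _table_from_values(values_by_cell, region="splenium", rng=None, ages=None):
    """Build a one-region table with exact given values per (group, sex).

    ``ages`` fixes one age sequence reused in every cell (so covariate
    adjustment is identical across cells); default is random ages.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    i = 0
    for (g, s), vals in values_by_cell.items():
        for j, v in enumerate(vals):
            i += 1
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "group": g,
                    "sex": s,
                    "age": float(ages[j]) if ages is not None
                    else float(rng.uniform(19, 63)),
                    "site": f"site{i % 3}",
                    "linear_scale": 1.0,
                    "region": region,
                    "stereotaxic_area_mm2": float(v),
                    "native_area_mm2": float(v),
                }
            )
    return pd.DataFrame(rows)


def _moment_matched(rng, mean, sd, n):
    """A sample with exactly the requested mean and SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestAncova:
    def test_identical_groups_give_null_f(self):
        vals = np.linspace(200, 260, 14)
        # same ages in every cell, not collinear with the area values
        ages = np.random.default_rng(1).permutation(np.linspace(20, 60, 14))
        table = _table_from_values(
            {("CB", "M"): vals, ("NC", "M"): vals, ("CB", "F"): vals,
             ("NC", "F"): vals},
            ages=ages,
        )
        res = ancova_group(table, "splenium")
        assert res.f == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.999

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        cells = {
            ("CB", "M"): rng.normal(225, 30, 14),
            ("NC", "M"): rng.normal(260, 40, 14),
        }
        t1 = _table_from_values(cells)
        shifted = {k: v + 1000.0 for k, v in cells.items()}
        t2 = _table_from_values(shifted)
        f1 = ancova_group(t1, "splenium").f
        f2 = ancova_group(t2, "splenium").f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_age_centering_does_not_change_f(self):
        table = simulate_cell_table(ISTHMUS_CELLS, 5)
        f1 = interaction_f(table, "isthmus").f
        centered = table.copy()
        centered["age"] = centered["age"] - centered["age"].mean()
        f2 = interaction_f(centered, "isthmus").f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_sex_relabel_symmetry(self):
        table = simulate_cell_table(ISTHMUS_CELLS, 9)
        f1 = interaction_f(table, "isthmus").f
        swapped = table.copy()
        swapped["sex"] = swapped["sex"].map({"M": "F", "F": "M"})
        f2 = interaction_f(swapped, "isthmus").f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_matches_statsmodels_type3_anova(self):
        """Full-vs-reduced under sum coding equals anova_lm(typ=3)."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        table = simulate_cell_table(ISTHMUS_CELLS, 13)
        ours = ancova(table, "isthmus", ("age",), ("group", "sex"))
        df = table.rename(columns={"stereotaxic_area_mm2": "y"})
        fit = smf.ols("y ~ C(group, Sum) * C(sex, Sum) + age", df).fit()
        ref = anova_lm(fit, typ=3)
        assert ours["group"].f == pytest.approx(ref.loc["C(group, Sum)", "F"])
        assert ours["sex"].f == pytest.approx(ref.loc["C(sex, Sum)", "F"])
        assert ours["group:sex"].f == pytest.approx(
            ref.loc["C(group, Sum):C(sex, Sum)", "F"]
        )
        assert ours["age"].f == pytest.approx(ref.loc["age", "F"])

    def test_df_bookkeeping(self):
        """One factor + age on n=56: denominator df is 53; the two-factor
        interaction model loses two more."""
        groups = {
            "CB": GroupSpec(28, 16, (330, 95, 107, 79, 226), (45, 15, 21, 16, 31),
                            109.6, 4.9),
            "NC": GroupSpec(28, 16, (330, 95, 90, 64, 261), (45, 15, 16, 10, 41),
                            113.4, 5.7),
        }
        table = simulate_area_table(CohortSpec(groups=groups, seed=2))
        assert ancova_group(table, "splenium").df2 == 53
        assert interaction_f(table, "isthmus").df2 == 51

    def test_empty_cell_rejected(self):
        table = _table_from_values(
            {
                ("CB", "M"): [1.0, 2.0],
                ("CB", "F"): [1.0, 2.0],
                ("NC", "M"): [1.0, 2.0],
            }
        )
        with pytest.raises(ValidationError, match="cell"):
            ancova(table, "splenium", ("age",), ("group", "sex"))

    def test_parallel_group_effects_give_null_interaction(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 10, 14)
        table = _table_from_values(
            {
                ("CB", "M"): 100 + base,
                ("CB", "F"): 90 + base,
                ("NC", "M"): 80 + base,
                ("NC", "F"): 70 + base,
            },
            region="isthmus",
            ages=np.linspace(20, 60, 14),
        )
        # group effect +20 in both sexes: interaction exactly 0
        assert interaction_f(table, "isthmus").f == pytest.approx(0.0, abs=1e-9)


class TestScheffe:
    def test_printed_cell_pattern_blind_males_larger(self):
        """With the four isthmus cells moment-matched to their reported
        means/SDs at the reported n, the blind-male cell exceeds every other
        cell and no other contrast is significant."""
        rng = np.random.default_rng(17)
        cells = {
            cell: _moment_matched(rng, m, s, n)
            for cell, (m, s, n) in ISTHMUS_CELLS.items()
        }
        table = _table_from_values(cells, region="isthmus")
        ph = scheffe_posthoc(table, "isthmus")
        sig = ph.significant_pairs()
        cbm = ("CB", "M")
        expected = {
            tuple(sorted((cbm, other)))
            for other in [("CB", "F"), ("NC", "M"), ("NC", "F")]
        }
        assert set(sig) == expected

    def test_equal_cells_nothing_significant(self):
        vals = np.linspace(60, 70, 12)
        table = _table_from_values(
            {c: vals for c in ISTHMUS_CELLS}, region="isthmus"
        )
        ph = scheffe_posthoc(table, "isthmus")
        assert ph.significant_pairs() == []

    def test_scheffe_p_is_conservative(self):
        from scipy import stats as sps

        table = simulate_cell_table(ISTHMUS_CELLS, 23)
        ph = scheffe_posthoc(table, "isthmus")
        for c in ph.contrasts:
            p_unadjusted = sps.f.sf(c["f_contrast"], 1, 51)
            assert c["p_scheffe"] >= p_unadjusted - 1e-12

    def test_pair_order_symmetry(self):
        table = simulate_cell_table(ISTHMUS_CELLS, 29)
        ph = scheffe_posthoc(table, "isthmus")
        seen = {}
        for c in ph.contrasts:
            key = frozenset((c["cell_a"], c["cell_b"]))
            assert key not in seen
            seen[key] = c["p_scheffe"]
        assert len(seen) == 6


class TestSiteAnova:
    def _spec(self, seed):
        groups = {
            "CB": GroupSpec(14, 7, (330, 95, 107, 79, 226), (45, 15, 21, 16, 31),
                            109.6, 4.9),
            "NC": GroupSpec(14, 7, (330, 95, 90, 64, 261), (45, 15, 16, 10, 41),
                            113.4, 5.7),
        }
        return CohortSpec(groups=groups, seed=seed)

    def test_null_site_p_values_are_uniform(self):
        """Sites drawn from one distribution: p-values pass a KS test
        against Uniform(0, 1) over replicates."""
        from scipy import stats as sps

        ps = []
        for seed in range(500):
            table = simulate_area_table(self._spec(seed))
            ps.append(site_anova(table).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_site_detected(self):
        table = simulate_area_table(self._spec(0))
        shift = table["site"] == "siteA"
        table.loc[shift, "native_area_mm2"] += 500.0  # ~ +3 SD of total
        res = site_anova(table)
        assert res.p < 0.001 and res.f > 20

    def test_two_sites_df(self):
        table = simulate_area_table(self._spec(1))
        table["site"] = np.where(
            table["subject_id"].str.contains("1"), "siteA", "siteB"
        )
        res = site_anova(table)
        assert res.df1 == 1

    def test_single_site_rejected(self):
        table = simulate_area_table(self._spec(2))
        table["site"] = "siteA"
        with pytest.raises(ValidationError):
            site_anova(table)


class TestBonferroniGate:
    def test_inclusive_boundary(self):
        ps = [0.010, 0.011, 0.5, 0.0001, 0.02]
        flags = bonferroni_gate(ps)
        assert flags[REGION_NAMES[0]] is True  # p = 0.010 inclusive
        assert flags[REGION_NAMES[1]] is False  # p = 0.011
        assert flags[REGION_NAMES[3]] is True
        assert sum(flags.values()) == 2

    def test_all_null_no_flags(self):
        assert sum(bonferroni_gate([0.5] * 5).values()) == 0

    def test_wrong_count_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_gate([0.5] * 4)


class TestCalibration:
    def test_type_one_error_near_nominal(self):
        """Identical populations: the group ANCOVA rejects at ~5% over
        2000 replicates (within 1.5 percentage points)."""
        g = dict(
            region_means_mm2=(330.0, 95.0, 90.0, 64.0, 261.0),
            region_sds_mm2=(45.0, 15.0, 16.51, 10.31, 41.7),
            angle_mean_deg=113.4,
            angle_sd_deg=5.7,
        )
        rejections = 0
        n_rep = 2000
        for seed in range(n_rep):
            spec = CohortSpec(
                groups={"CB": GroupSpec(10, 5, **g), "NC": GroupSpec(10, 5, **g)},
                seed=seed,
            )
            table = simulate_area_table(spec)
            if ancova_group(table, "splenium").p <= 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.015


def test_stats_battery_structure():
    groups = {
        "CB": GroupSpec(14, 8, (330, 95, 107.26, 79.4, 225.64),
                        (45, 15, 21.67, 16.66, 31.7), 109.6, 4.9),
        "NC": GroupSpec(14, 8, (330, 95, 89.64, 64.16, 260.84),
                        (45, 15, 16.51, 10.31, 41.7), 113.4, 5.7),
    }
    table = simulate_area_table(CohortSpec(groups=groups, seed=5))
    tidy, extras = stats_battery(table)
    assert set(extras["bonferroni"]) == set(REGION_NAMES)
    regions = set(tidy["region"])
    assert regions >= set(REGION_NAMES) | {"total", "bending_angle"}
    assert {"F", "df1", "df2", "p", "significant"} <= set(tidy.columns)
    from ccmorph.stats import render_report

    report = render_report(tidy, extras)
    assert "Bonferroni" in report and "splenium" in report
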