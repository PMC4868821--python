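"""X-dosage statistics: trends, ratios, tracks, totals and the X0 screen."""

import numpy as np
import pandas as pd
import pytest

from embryolin.simulate import SimConfig, simulate_experiment
from embryolin.xdosage import (fixed_expressed_gene_set, fm_ratio_per_gene,
                               gene_fraction_above, gene_time_trend,
                               moving_average_track, total_x_output,
                               x0_screen)

from conftest import build_dataset


def sexed(ds, truth):
    out = ds.copy()
    out.cells["sex"] = truth.cells["sex"]
    return out


@pytest.fixture(scope="module")
def dampening_sim():
    return simulate_experiment(SimConfig(seed=8, dosage_mode="dampening"))


class TestGeneTimeTrend:
    def test_linear_decrease_has_rho_minus_one(self):
        days = [4, 5, 6, 7] * 6
        vals = np.vstack([[8.0 - d for d in days],
                          np.full(24, 5.0)])
        sexes = (["female"] * 12 + ["male"] * 12)
        ds = build_dataset(vals, days=days, sexes=sexes,
                           chroms=["chr1", "chr2"])
        res = gene_time_trend(ds)
        assert res["table"].loc["g0", "rho_female"] == pytest.approx(-1.0)
        assert np.isnan(res["table"].loc["g1", "rho_female"])

    def test_dampening_makes_female_x_trends_negative(self, dampening_sim):
        ds, _, truth = dampening_sim
        res = gene_time_trend(sexed(ds, truth))
        t = res["table"]
        x = t[t["chrom_class"] == "chrX"].dropna()
        a = t[t["chrom_class"] == "autosome"].dropna()
        assert x["rho_female"].median() < 0
        assert x["rho_female"].median() < x["rho_male"].median()
        assert res["tests"]["p_x_female_vs_male"] < 0.01
        assert abs(a["rho_female"].median()) < 0.1


class TestFmRatio:
    def test_identical_sexes_give_unit_ratios(self):
        rng = np.random.default_rng(0)
        col = np.abs(rng.normal(10, 3, 20))
        vals = np.column_stack([col] * 8)
        ds = build_dataset(vals, sexes=["female"] * 4 + ["male"] * 4,
                           chroms=["chrX"] * 10 + ["chr1"] * 10)
        res = fm_ratio_per_gene(ds, 5)
        assert np.allclose(res["table"]["ratio"], 1.0)

    def test_two_active_x_doubles_and_autosomes_stay_flat(self,
                                                          sim_dataset,
                                                          sim_truth):
        ds = sexed(sim_dataset, sim_truth)
        res = fm_ratio_per_gene(ds, 4)
        assert 1.8 <= res["chrX_median"] <= 2.2
        assert 0.9 <= res["autosome_median"] <= 1.1

    def test_dampened_e7_ratio_near_one_point_one(self, dampening_sim):
        ds, _, truth = dampening_sim
        res = fm_ratio_per_gene(sexed(ds, truth), 7)
        assert 0.95 <= res["chrX_median"] <= 1.3
        assert 0.9 <= res["autosome_median"] <= 1.1

    def test_empty_stratum_rejected(self, sim_dataset):
        ds = sim_dataset.copy()
        ds.cells["sex"] = "female"
        with pytest.raises(ValueError):
            fm_ratio_per_gene(ds, 5)

    def test_stronger_dampening_strictly_lowers_the_ratio(self):
        medians = []
        for d in (1.0, 0.8, 0.55):
            cfg = SimConfig(seed=11, dosage_mode="dampening",
                            dampening_schedule={k: d for k in range(3, 8)},
                            n_embryos_per_day={7: 10},
                            cells_per_embryo=(10, 12))
            ds, _, truth = simulate_experiment(cfg)
            medians.append(fm_ratio_per_gene(sexed(ds, truth),
                                             7)["chrX_median"])
        assert medians[0] > medians[1] > medians[2]


class TestMovingAverageTrack:
    def test_equal_sexes_give_flat_track(self):
        rng = np.random.default_rng(0)
        col = np.abs(rng.normal(10, 3, 40))
        vals = np.column_stack([col] * 6)
        ds = build_dataset(vals, sexes=["female"] * 3 + ["male"] * 3,
                           chroms=["chrX"] * 40,
                           starts=np.arange(1, 41) * 1000)
        track = moving_average_track(ds, "chrX", 5, window=5)
        assert np.allclose(track.ratio, 1.0)

    def test_matches_brute_force_window_oracle(self, sim_dataset,
                                               sim_truth):
        ds = sexed(sim_dataset, sim_truth)
        track = moving_average_track(ds, "chrX", 5, window=25)
        bio = ds.biological()
        cells = ds.cells.index[ds.cells["day"] == 5]
        sex = ds.cells.loc[cells, "sex"]
        f = bio.values.loc[track.gene_ids,
                           sex.index[sex == "female"]].mean(axis=1)
        m = bio.values.loc[track.gene_ids,
                           sex.index[sex == "male"]].mean(axis=1)
        n = len(track.gene_ids)
        w = 25
        half = (w - 1) // 2
        for i in range(n):                      # O(n*w) oracle
            lo = min(max(0, i - half), n - w)
            wf = f.iloc[lo:lo + w].mean()
            wm = m.iloc[lo:lo + w].mean()
            assert track.ratio[i] == pytest.approx((wf + 1) / (wm + 1),
                                                   rel=1e-12)

    def test_dampened_segment_dips_only_locally(self):
        # female:male 2x everywhere except a dampened positional block
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(20, 4, 120))
        female = base * 2.0
        female[40:80] = base[40:80] * 1.0       # dampened block
        vals = np.column_stack([female] * 5 + [base] * 5)
        ds = build_dataset(vals, sexes=["female"] * 5 + ["male"] * 5,
                           chroms=["chrX"] * 120,
                           starts=np.arange(1, 121) * 1000)
        track = moving_average_track(ds, "chrX", 5, window=15)
        inside = track.ratio[50:70]
        outside = np.concatenate([track.ratio[:25], track.ratio[-25:]])
        assert inside.max() < 1.4
        assert outside.min() > 1.6

    def test_too_few_genes_rejected(self):
        ds = build_dataset(np.ones((5, 4)), sexes=["female"] * 2
                           + ["male"] * 2, chroms=["chrX"] * 5)
        with pytest.raises(ValueError):
            moving_average_track(ds, "chrX", 5, window=25)


class TestTotalXOutput:
    def test_single_gene_sum_is_the_value(self):
        ds = build_dataset([[3.5, 4.0]], chroms=["chrX"])
        res = total_x_output(ds, ["g0"])
        assert list(res["table"]["x_sum"]) == [3.5, 4.0]

    def test_female_output_drops_under_dampening_male_flat(self,
                                                           dampening_sim):
        ds, _, truth = dampening_sim
        ds = sexed(ds, truth)
        res = total_x_output(ds, fixed_expressed_gene_set(ds))
        t = res["table"]
        f4 = t.query("sex == 'female' and day == 4")["x_sum"].median()
        f7 = t.query("sex == 'female' and day == 7")["x_sum"].median()
        m4 = t.query("sex == 'male' and day == 4")["x_sum"].median()
        m7 = t.query("sex == 'male' and day == 7")["x_sum"].median()
        assert f7 < 0.75 * f4
        assert abs(m7 - m4) / m4 < 0.15
        assert res["tests"]["p_female_e4_vs_e7"] < 0.01

    def test_empty_gene_set_rejected(self, sim_dataset):
        with pytest.raises(ValueError):
            total_x_output(sim_dataset, [])


class TestFractionAbove:
    def test_monotone_in_threshold_and_extremes(self, sim_dataset,
                                                sim_truth):
        ds = sexed(sim_dataset, sim_truth)
        out = gene_fraction_above(ds, "XIST", [0.0, 1.0, 5.0, 1e9])
        for (sex, day), grp in out.groupby(["sex", "day"]):
            fr = grp.sort_values("threshold")["fraction"].to_numpy()
            assert (np.diff(fr) <= 1e-12).all()
            assert fr[-1] == 0.0

    def test_female_xist_exceeds_male_from_e5(self, sim_dataset,
                                              sim_truth):
        ds = sexed(sim_dataset, sim_truth)
        out = gene_fraction_above(ds, "XIST", [1.0, 5.0])
        piv = out.pivot_table(index=["threshold", "day"], columns="sex",
                              values="fraction")
        late = piv[piv.index.get_level_values("day") >= 5]
        assert (late["female"] >= late["male"]).all()


@pytest.fixture(scope="module")
def x0_sim():
    return simulate_experiment(SimConfig(seed=4, n_x0_embryos=1))


class TestX0Screen:
    def test_single_x_female_embryo_is_flagged(self, x0_sim):
        ds, _, truth = x0_sim
        ds = sexed(ds, truth)
        embryo = truth.cells.loc[truth.cells["is_x0"],
                                 "embryo_id"].unique()[0]
        res = x0_screen(ds, embryo)
        assert res["applicable"] and res["flagged"]

    def test_normal_female_embryo_not_flagged(self, x0_sim):
        ds, _, truth = x0_sim
        ds = sexed(ds, truth)
        x0 = set(truth.cells.loc[truth.cells["is_x0"], "embryo_id"])
        sub = truth.cells[(truth.cells["day"] == 5)
                          & (truth.cells["sex"] == "female")
                          & (~truth.cells["embryo_id"].isin(x0))]
        res = x0_screen(ds, sub["embryo_id"].iloc[0])
        assert res["applicable"] and not res["flagged"]

    def test_male_embryo_skipped(self, x0_sim):
        ds, _, truth = x0_sim
        ds = sexed(ds, truth)
        male = truth.cells[truth.cells["sex"] == "male"]
        res = x0_screen(ds, male["embryo_id"].iloc[0])
        assert not res["applicable"]


def test_autosomal_ratio_parity_across_all_regimes():
    """Autosomes are the negative control in every dosage regime."""
    for mode, extra in [("two_active", {}),
                        ("dampening", {}),
                        ("xci", {})]:
        cfg = SimConfig(seed=9, dosage_mode=mode,
                        n_embryos_per_day={5: 8},
                        cells_per_embryo=(10, 12), **extra)
        ds, _, truth = simulate_experiment(cfg)
        ds = sexed(ds, truth)
        res = fm_ratio_per_gene(ds, 5)
        assert 0.9 <= res["autosome_median"] <= 1.1
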