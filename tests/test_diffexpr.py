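"""Differential expression, Stouffer combination, FDR and gene dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryolin.diffexpr import (bh_fdr, de_two_groups,
                                embryo_variability_regression,
                                lineage_specific, maintained_genes, sex_de,
                                stage_gene_correlations, stouffer)

from conftest import build_dataset


class TestDeTwoGroups:
    def test_identical_groups_find_nothing(self):
        rng = np.random.default_rng(0)
        vals = np.abs(rng.normal(10, 2, (50, 40)))
        ds = build_dataset(np.hstack([vals, vals]))
        a = list(ds.cells.index[:40])
        b = list(ds.cells.index[40:])
        de = de_two_groups(ds, a, b)
        assert (de["fdr"] <= 0.05).sum() == 0
        assert np.allclose(de["log2fc"], 0.0)

    def test_swapping_groups_negates_z_and_fold_change(self, sim_dataset,
                                                       sim_truth):
        d5 = sim_dataset.cells.index[sim_dataset.cells["day"] == 5]
        lin = sim_truth.cells.loc[d5, "lineage"]
        te = list(lin.index[lin == "TE"])
        icm = list(lin.index[lin.isin(["EPI", "PE"])])
        ab = de_two_groups(sim_dataset, te, icm)
        ba = de_two_groups(sim_dataset, icm, te)
        assert np.allclose(ab["z"], -ba["z"], atol=1e-8)
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)

    def test_active_program_genes_recalled(self, sim_dataset, sim_truth):
        d5 = sim_dataset.cells.index[sim_dataset.cells["day"] == 5]
        lin = sim_truth.cells.loc[d5, "lineage"]
        te = list(lin.index[lin == "TE"])
        icm = list(lin.index[lin.isin(["EPI", "PE"])])
        de = de_two_groups(sim_dataset, te, icm)
        genes = sim_truth.genes
        active = genes.index[(genes["program"] == "TE")
                             & genes["wave"].isin(["early", "mid"])]
        up = de.index[(de["fdr"] <= 0.05) & (de["z"] > 0)]
        assert len(set(up) & set(active)) / len(active) >= 0.9

    def test_small_group_rejected(self, sim_dataset):
        cells = list(sim_dataset.cells.index)
        with pytest.raises(ValueError):
            de_two_groups(sim_dataset, cells[:2], cells[2:20])


class TestStouffer:
    def test_hand_arithmetic(self):
        assert stouffer([1.96, 1.96]) == pytest.approx(3.92 / np.sqrt(2),
                                                       abs=1e-9)
        assert stouffer([1.96, 1.96]) == pytest.approx(2.772, abs=5e-4)

    def test_single_z_identity_and_cancellation(self):
        assert stouffer([1.7]) == pytest.approx(1.7)
        assert stouffer([2.3, -2.3]) == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stouffer([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-8, 8), min_size=1, max_size=12))
    def test_matches_brute_force_to_machine_precision(self, zs):
        brute = sum(zs) / np.sqrt(len(zs))
        assert stouffer(zs) == pytest.approx(brute, abs=1e-12)


def test_bh_fdr_matches_hand_computed_step_up():
    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042,
                  0.06, 0.074, 0.205, 0.212, 0.216])
    # textbook step-up: q_i = min_{j>=i} (p_j * n / j), computed by hand
    expected = np.array([0.01, 0.04, 0.084, 0.084, 0.084,
                         0.1, 0.105714285714285716, 0.216, 0.216, 0.216])
    assert np.allclose(bh_fdr(p), expected, atol=1e-12)
    assert (bh_fdr(p) >= p).all()


@pytest.fixture(scope="module")
def per_day(sim_dataset, sim_truth):
    calls = sim_truth.cells[["lineage", "te_subpop"]]
    return {d: lineage_specific(sim_dataset, calls, d)
            for d in (5, 6, 7)}


class TestLineageSpecific:
    def test_combined_z_matches_stored_contrasts(self, per_day):
        res = per_day[6]
        contrasts = res["contrasts"]
        # brute-force recomputation of the TE combined z from the two
        # stored pairwise contrasts
        frames = []
        for other in ("EPI", "PE"):
            key = ("TE", other) if ("TE", other) in contrasts \
                else (other, "TE")
            f = contrasts[key].copy()
            if key[0] != "TE":
                f["z"] *= -1
            frames.append(f)
        common = frames[0].index.intersection(frames[1].index)
        brute = (frames[0].loc[common, "z"] + frames[1].loc[common, "z"]) \
            / np.sqrt(2)
        combined = res["TE"].loc[common, "z"]
        assert np.allclose(combined, brute, atol=1e-10)

    def test_sign_logic_te_gene_up_in_te_down_elsewhere(self, per_day,
                                                        sim_truth):
        genes = sim_truth.genes
        te_genes = genes.index[(genes["program"] == "TE")
                               & (genes["wave"] == "early")]
        res = per_day[6]
        te_z = res["TE"]["z"].reindex(te_genes).dropna()
        epi_z = res["EPI"]["z"].reindex(te_genes).dropna()
        assert (te_z > 0).mean() > 0.95
        assert (epi_z < 0).mean() > 0.95

    def test_top_100_within_day_is_nearly_pure(self, per_day, sim_truth):
        prog = sim_truth.genes["program"]
        accepted = {"TE": ["TE", "polar"], "EPI": ["EPI"], "PE": ["PE"]}
        for lin in ("TE", "EPI", "PE"):
            top = per_day[6][lin].index[:100]
            assert prog.reindex(top).isin(accepted[lin]).sum() >= 90

    def test_maintained_combines_days_and_flags_te_precisely(
            self, per_day, sim_truth):
        prog = sim_truth.genes["program"]
        m = maintained_genes(per_day, "TE")
        sig = m.index[m["significant"]]
        assert len(sig) > 30
        precision = prog.reindex(sig).isin(["TE", "polar"]).mean()
        assert precision >= 0.9

    def test_sign_flipping_gene_cancels_across_days(self):
        frames = {5: {"L": pd.DataFrame({"z": [4.0]}, index=["g"])},
                  6: {"L": pd.DataFrame({"z": [-2.0]}, index=["g"])},
                  7: {"L": pd.DataFrame({"z": [-2.0]}, index=["g"])}}
        m = maintained_genes(frames, "L")
        assert m.loc["g", "z"] == pytest.approx(0.0, abs=1e-12)
        assert not m.loc["g", "significant"]

    def test_missing_lineage_rejected(self, sim_dataset, sim_truth):
        calls = sim_truth.cells[["lineage", "te_subpop"]]
        with pytest.raises(ValueError):
            lineage_specific(sim_dataset, calls, 3)


class TestEmbryoVariability:
    def test_constant_gene_scores_zero_slope(self):
        vals = np.full((3, 12), 8.0)
        ds = build_dataset(vals, embryos=["e1"] * 4 + ["e2"] * 4
                           + ["e3"] * 4)
        pt = pd.Series([7.5, 12.5, 17.5], index=["e1", "e2", "e3"])
        res = embryo_variability_regression(ds, pt)
        assert np.allclose(res["slope"], 0.0)

    def test_lineage_genes_peak_at_or_after_commitment(self, sim_dataset,
                                                       sim_truth):
        emb_t = sim_truth.cells.groupby("embryo_id")["t_true"].mean() * 2.5
        res = embryo_variability_regression(sim_dataset, emb_t)
        prog = sim_truth.genes["program"]
        lin = prog.index[prog.isin(["TE", "EPI", "PE"])]
        frac = (res.loc[lin, "peak_time"] >= 5.0 * 2.5).mean()
        assert frac >= 0.8

    def test_housekeeping_slopes_center_on_zero(self, sim_dataset,
                                                sim_truth):
        emb_t = sim_truth.cells.groupby("embryo_id")["t_true"].mean() * 2.5
        res = embryo_variability_regression(sim_dataset, emb_t)
        hk = sim_truth.genes.index[sim_truth.genes["program"]
                                   == "housekeeping"]
        assert abs(res.loc[hk, "slope"].median()) < 0.01


class TestStageCorrelations:
    def test_duplicated_gene_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        row = np.abs(rng.normal(10, 3, 12))
        vals = np.vstack([row, row, rng.normal(10, 3, 12)])
        ds = build_dataset(np.abs(vals))
        out = stage_gene_correlations(ds, ["g0", "g1", "g2"],
                                      {"s": list(ds.cells.index)})
        assert out["s"]["corr"].loc["g0", "g1"] == pytest.approx(1.0)

    def test_independent_genes_stay_unmerged(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(10, 3, (6, 200)))
        ds = build_dataset(vals)
        out = stage_gene_correlations(ds, list(ds.genes.index),
                                      {"s": list(ds.cells.index)})
        assert out["s"]["modules"].nunique() == 6

    def test_constant_gene_recorded_missing(self):
        vals = np.vstack([np.full(10, 4.0),
                          np.abs(np.random.default_rng(0).normal(5, 2,
                                                                 10))])
        ds = build_dataset(vals)
        out = stage_gene_correlations(ds, ["g0", "g1"],
                                      {"s": list(ds.cells.index)})
        assert np.isnan(out["s"]["corr"].loc["g0", "g1"])

    def test_same_lineage_correlation_rises_after_commitment(
            self, sim_dataset, sim_truth):
        prog = sim_truth.genes["program"]
        genes = list(prog.index[prog.isin(["TE", "EPI", "PE"])][:120])
        cells = sim_dataset.cells
        stages = {"pre": list(cells.index[cells["day"].isin([3, 4])]),
                  "post": list(cells.index[cells["day"].isin([6, 7])])}
        out = stage_gene_correlations(sim_dataset, genes, stages,
                                      gene_groups=prog)

        def median_same(stage):
            corr = out[stage]["corr"]
            vals = []
            for lin in ("TE", "EPI", "PE"):
                g = [x for x in genes if prog[x] == lin]
                sub = corr.loc[g, g].to_numpy()
                vals.extend(sub[np.triu_indices(len(g), 1)])
            return np.nanmedian(vals)

        assert median_same("post") > median_same("pre") + 0.2


class TestSexDE:
    def test_x_dominates_female_biased_genes_under_two_active(
            self, sim_dataset, sim_truth):
        ds = sim_dataset.copy()
        ds.cells["sex"] = sim_truth.cells["sex"]
        res = sex_de(ds, 5)
        counts = res["sig_counts"]
        assert counts["chrX"] > counts["autosome"]
        de = res["de"]
        x_up = de[(res["chrom_class"] == "chrX") & (de["fdr"] <= 0.05)]
        assert (x_up["z"] > 0).mean() > 0.9      # female-biased

    def test_y_genes_always_male_biased(self, sim_dataset, sim_truth):
        ds = sim_dataset.copy()
        ds.cells["sex"] = sim_truth.cells["sex"]
        res = sex_de(ds, 5)
        y = res["de"][res["chrom_class"] == "chrY"]
        assert (y["z"] < 0).all()

    def test_single_sex_stratum_rejected(self, sim_dataset, sim_truth):
        ds = sim_dataset.copy()
        ds.cells["sex"] = "female"
        with pytest.raises(ValueError):
            sex_de(ds, 5)


def test_permuted_labels_keep_false_discoveries_low(sim_dataset,
                                                    sim_truth):
    """DE on label-permuted data stays near the nominal FDR level."""
    d5 = sim_dataset.cells.index[sim_dataset.cells["day"] == 5]
    lin = sim_truth.cells.loc[d5, "lineage"]
    pool = list(lin.index[lin.isin(["TE", "EPI", "PE"])])
    n_a = (lin == "TE").sum()
    rng = np.random.default_rng(0)
    fracs = []
    for _ in range(20):
        perm = rng.permutation(len(pool))
        a = [pool[i] for i in perm[:n_a]]
        b = [pool[i] for i in perm[n_a:]]
        de = de_two_groups(sim_dataset, a, b)
        fracs.append((de["fdr"] <= 0.05).mean())
    assert np.mean(fracs) <= 0.07
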