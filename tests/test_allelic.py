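"""Allelic calls, biallelic fractions and regime discrimination."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from embryolin.allelic import (allelic_ratio_histogram, biallelic_fraction,
                               classify_snv, classify_table,
                               fisher_biallelic, gene_allele_barplot_data,
                               male_x_biallelic_zga,
                               relative_biallelic_ratio)
from embryolin.simulate import SimConfig, simulate_experiment


class TestClassifySNV:
    @pytest.mark.parametrize("ref,alt,call,ratio", [
        (0, 0, "undetected", None),
        (2, 0, "undetected", None),           # below min_reads
        (10, 10, "biallelic", 0.5),
        (20, 1, "mono_ref", 1 / 21),          # minor reads 1 < 2
        (1, 20, "mono_alt", 20 / 21),
        (27, 3, "biallelic", 0.1),            # exactly at the fraction
        (97, 3, "mono_ref", 0.03),            # 3 reads but < 10%
    ])
    def test_rule_arithmetic(self, ref, alt, call, ratio):
        got_call, got_ratio = classify_snv(ref, alt)
        assert got_call == call
        if ratio is None:
            assert got_ratio is None
        else:
            assert got_ratio == pytest.approx(ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_snv(-1, 5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_scaling_counts_never_flips_biallelic_to_monoallelic(
            self, ref, alt):
        call, _ = classify_snv(ref, alt)
        scaled, _ = classify_snv(ref * 10, alt * 10)
        if call == "biallelic":
            assert scaled == "biallelic"

    def test_vectorised_table_matches_scalar_rule(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 30, 200)
        alt = rng.integers(0, 30, 200)
        table = pd.DataFrame({"cell_id": "c", "snv_id": "s",
                              "chrom": "chr1", "pos": 1, "gene_id": "g",
                              "ref_reads": ref, "alt_reads": alt})
        out = classify_table(table)
        for i in range(200):
            assert out["call"].iloc[i] == classify_snv(ref[i], alt[i])[0]


class TestBiallelicFraction:
    def fixture_table(self, n_bi, n_mono, chrom="chrX", cell="c1"):
        rows = []
        for i in range(n_bi):
            rows.append((cell, f"b{i}", chrom, i + 1, f"g{i}", 10, 10))
        for i in range(n_mono):
            rows.append((cell, f"m{i}", chrom, 1000 + i, f"h{i}", 12, 0))
        return pd.DataFrame(rows, columns=["cell_id", "snv_id", "chrom",
                                           "pos", "gene_id", "ref_reads",
                                           "alt_reads"])

    def test_all_biallelic_is_one(self):
        cl = classify_table(self.fixture_table(30, 0))
        assert biallelic_fraction(cl, "c1", "chrX") == 1.0

    def test_hand_fixture_three_of_thirty(self):
        cl = classify_table(self.fixture_table(3, 27))
        assert biallelic_fraction(cl, "c1", "chrX") == pytest.approx(0.1)

    def test_below_min_snvs_is_missing(self):
        cl = classify_table(self.fixture_table(12, 12))
        assert biallelic_fraction(cl, "c1", "chrX", min_snvs=25) is None
        assert biallelic_fraction(cl, "c1", "chrX",
                                  min_snvs=24) is not None


def test_fisher_biallelic_matches_hypergeometric_oracle():
    cases = [(8, 20, 2, 20), (15, 30, 15, 30), (1, 10, 9, 10),
             (0, 12, 6, 12)]
    for ba, da, bb, db in cases:
        p = fisher_biallelic(ba, da, bb, db)
        # hypergeometric enumeration: sum probabilities <= observed
        M, n, N = da + db, ba + bb, da
        rv = scipy.stats.hypergeom(M, n, N)
        p_obs = rv.pmf(ba)
        oracle = sum(rv.pmf(k) for k in range(max(0, n - db),
                                              min(n, da) + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(oracle, rel=1e-6)


@pytest.fixture(scope="module")
def matched_sims():
    damp = SimConfig(seed=5, dosage_mode="dampening",
                     dampening_schedule={k: 0.55 for k in range(3, 8)},
                     n_embryos_per_day={7: 12},
                     cells_per_embryo=(12, 14))
    xci = SimConfig(seed=6, dosage_mode="xci",
                    xci_schedule={k: 0.9 for k in range(3, 8)},
                    n_embryos_per_day={7: 12},
                    cells_per_embryo=(12, 14))
    return simulate_experiment(damp), simulate_experiment(xci)


class TestRegimeDiscrimination:
    @staticmethod
    def female_ratios(sim, **kwargs):
        _, alleles, truth = sim
        rel = relative_biallelic_ratio(classify_table(alleles, **kwargs))
        fem = truth.cells.index[truth.cells["sex"] == "female"]
        return rel.reindex(fem).dropna()

    @pytest.mark.parametrize("minor_min_frac", [0.05, 0.1, 0.2])
    def test_dampening_vs_xci_auroc(self, matched_sims, minor_min_frac):
        from sklearn.metrics import roc_auc_score
        damp, xci = matched_sims
        rd = self.female_ratios(damp, minor_min_frac=minor_min_frac)
        rx = self.female_ratios(xci, minor_min_frac=minor_min_frac)
        y = np.r_[np.zeros(len(rx)), np.ones(len(rd))]
        assert roc_auc_score(y, np.r_[rx, rd]) >= 0.9

    def test_dampening_keeps_x_at_autosomal_levels(self, matched_sims):
        damp, _ = matched_sims
        rd = self.female_ratios(damp)
        assert 0.9 <= np.median(rd) <= 1.1

    def test_partial_xci_drops_the_ratio(self):
        cfg = SimConfig(seed=7, dosage_mode="xci",
                        xci_schedule={k: 0.6 for k in range(3, 8)},
                        n_embryos_per_day={7: 12},
                        cells_per_embryo=(12, 14))
        sim = simulate_experiment(cfg)
        rx = self.female_ratios(sim)
        assert np.median(rx) < 0.75


def test_male_x_histogram_piles_at_the_edges(sim_classified, sim_truth):
    male = sim_truth.cells.index[(sim_truth.cells["sex"] == "male")
                                 & (sim_truth.cells["day"] >= 4)]
    h = allelic_ratio_histogram(sim_classified, male, "chrX")
    outer = ((h["ratios"] <= 0.1) | (h["ratios"] >= 0.9)).mean()
    assert outer >= 0.95


def test_balanced_biallelic_histogram_modes_at_half(sim_classified,
                                                    sim_truth):
    fem = sim_truth.cells.index[sim_truth.cells["sex"] == "female"]
    h = allelic_ratio_histogram(sim_classified, fem, "chr1")
    centre = ((h["ratios"] > 0.3) & (h["ratios"] < 0.7)).mean()
    assert centre > 0.5


def test_empty_selection_gives_empty_histogram(sim_classified):
    h = allelic_ratio_histogram(sim_classified, [], "chrX")
    assert h["counts"].sum() == 0


class TestGeneBarplot:
    def test_rows_cover_every_cell_of_the_embryos(self, sim_alleles,
                                                  sim_truth):
        embryos = list(sim_truth.cells["embryo_id"].unique()[:2])
        out = gene_allele_barplot_data(sim_alleles, "XIST", embryos,
                                       sim_truth.cells)
        expected = (sim_truth.cells["embryo_id"].isin(embryos)).sum()
        assert len(out) == expected

    def test_xist_biallelic_in_expressing_female_cells(self, sim_alleles,
                                                       sim_truth):
        late_female = sim_truth.cells[
            (sim_truth.cells["sex"] == "female")
            & (sim_truth.cells["day"] >= 6)]
        out = gene_allele_barplot_data(
            sim_alleles, "XIST", late_female["embryo_id"].unique(),
            sim_truth.cells)
        out = out[out["cell_id"].isin(late_female.index)]
        expressed = out[(out["ref_reads"] + out["alt_reads"]) >= 5]
        both = ((expressed["ref_reads"] >= 2)
                & (expressed["alt_reads"] >= 2)).mean()
        assert both >= 0.8

    def test_male_cells_lack_xist_reads(self, sim_alleles, sim_truth):
        male = sim_truth.cells[sim_truth.cells["sex"] == "male"]
        out = gene_allele_barplot_data(sim_alleles, "XIST",
                                       male["embryo_id"].unique(),
                                       sim_truth.cells)
        out = out[out["cell_id"].isin(male.index)]
        totals = out["ref_reads"] + out["alt_reads"]
        assert totals.median() <= 2

    def test_gene_without_snv_rejected(self, sim_alleles, sim_truth):
        with pytest.raises(ValueError):
            gene_allele_barplot_data(sim_alleles, "NOT_A_GENE", ["E3.1"],
                                     sim_truth.cells)


def test_maternal_carryover_shows_in_male_e3_x(sim_classified, sim_truth):
    res = male_x_biallelic_zga(sim_classified, sim_truth.cells)
    e3 = np.median(res["chrX"][3])
    e4 = np.median(res["chrX"][4])
    assert e3 > e4
    assert res["p_e3_vs_e4"] < 0.01


def test_no_carryover_is_flat_at_the_noise_floor():
    cfg = SimConfig(seed=12, maternal_carryover=0.0,
                    n_embryos_per_day={3: 4, 4: 4},
                    cells_per_embryo=(10, 12))
    _, alleles, truth = simulate_experiment(cfg)
    res = male_x_biallelic_zga(classify_table(alleles), truth.cells)
    assert np.median(res["chrX"][3]) <= 0.05
    assert np.median(res["chrX"][4]) <= 0.05
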