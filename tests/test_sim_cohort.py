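"""Synthetic cohort generator: frequency/LD targets, phase rules, noise
calibration, phenotype linkage and determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from aeiscan.sim_cohort import (
    ConfigError,
    EffectModel,
    LdSpec,
    NoiseModel,
    PhenotypeModel,
    SnpSpec,
    assign_allelic_expression,
    generate_haplotypes,
    generate_phenotypes,
    r2_max,
    simulate_cohort,
    simulate_measurements,
    stanley_config,
)


def empirical_r2(haps, i, j):
    h = haps.reshape(-1, haps.shape[-1])
    pa, pb = h[:, i].mean(), h[:, j].mean()
    d = (h[:, i] * h[:, j]).mean() - pa * pb
    return d**2 / (pa * (1 - pa) * pb * (1 - pb))


class TestGenerateHaplotypes:
    def test_maf_converges(self):
        panel = [SnpSpec("s1", 0.5)]
        haps = generate_haplotypes(panel, [], 10000, seed=0)
        se = math.sqrt(0.5 * 0.5 / 20000)
        assert abs(haps.mean() - 0.5) < 3 * se

    def test_linkage_equilibrium_when_r2_zero(self):
        panel = [SnpSpec("a", 0.3), SnpSpec("b", 0.2)]
        haps = generate_haplotypes(panel, [LdSpec("a", "b", 0.0)], 10000, seed=1)
        assert empirical_r2(haps, 0, 1) < 0.01

    def test_target_r2_recovered(self):
        """Low-LD pair (r2 = 0.044) at the study's marker/causal MAFs."""
        panel = [SnpSpec("causal", 0.18, "causal"), SnpSpec("marker", 0.31, "marker")]
        haps = generate_haplotypes(
            panel, [LdSpec("causal", "marker", 0.044)], 20000, seed=2
        )
        assert empirical_r2(haps, 0, 1) == pytest.approx(0.044, abs=0.01)

    def test_infeasible_r2_raises_naming_maximum(self):
        panel = [SnpSpec("a", 0.05), SnpSpec("b", 0.5)]
        cap = r2_max(0.05, 0.5)
        with pytest.raises(ConfigError, match=f"{cap:.4f}"):
            generate_haplotypes(panel, [LdSpec("a", "b", 0.9)], 10, seed=0)

    def test_snp_in_two_ld_pairs_rejected(self):
        panel = [SnpSpec("c", 0.2, "causal"), SnpSpec("a", 0.3), SnpSpec("b", 0.3)]
        ld = [LdSpec("c", "a", 0.1), LdSpec("a", "b", 0.1)]
        with pytest.raises(ConfigError):
            generate_haplotypes(panel, ld, 10, seed=0)


PANEL = [SnpSpec("causal", 0.18, "causal"), SnpSpec("m1", 0.32, "marker")]
EFFECT = EffectModel(
    causal_snp_id="causal",
    fold_change_log_mean_by_state={"case": math.log(3.0)},
    fold_change_log_sd_by_state={"case": 0.0},
    penetrance_by_state={"case": 1.0},
)


class TestAssignAllelicExpression:
    def test_no_causal_minor_allele_means_no_imbalance(self):
        haps = np.zeros((5, 2, 2), dtype=np.int8)
        haps[:, 0, 1] = 1  # marker het in every subject, causal hom-major
        ratios, truth = assign_allelic_expression(
            haps, PANEL, EFFECT, ["case"] * 5, [f"s{i}" for i in range(5)], seed=0
        )
        assert (ratios["true_ratio"] == 1.0).all()
        assert (truth["fold_change"] == 1.0).all()

    def test_phase_forces_reciprocal_ratio(self):
        """Causal minor allele in cis with the marker *minor* allele: the
        major/minor marker ratio must be exactly 1/3 for a 3-fold effect."""
        haps = np.zeros((1, 2, 2), dtype=np.int8)
        haps[0, 0, 0] = 1  # causal minor on haplotype 0
        haps[0, 0, 1] = 1  # marker minor on the same haplotype
        ratios, _ = assign_allelic_expression(haps, PANEL, EFFECT, ["case"], ["s0"], seed=0)
        assert ratios["true_ratio"].iloc[0] == pytest.approx(1 / 3)

    def test_cis_with_major_allele_gives_fold(self):
        haps = np.zeros((1, 2, 2), dtype=np.int8)
        haps[0, 0, 0] = 1  # causal minor on haplotype 0
        haps[0, 1, 1] = 1  # marker minor on the other haplotype
        ratios, _ = assign_allelic_expression(haps, PANEL, EFFECT, ["case"], ["s0"], seed=0)
        assert ratios["true_ratio"].iloc[0] == pytest.approx(3.0)

    def test_direction_is_symmetric_under_linkage_equilibrium(self):
        """With marker and causal variant unlinked, observable ratios fall
        above and below 1 equally often (binomial phase assignment)."""
        rng_panel = [SnpSpec("causal", 0.5, "causal"), SnpSpec("m1", 0.5, "marker")]
        haps = generate_haplotypes(rng_panel, [], 10000, seed=3)
        ratios, _ = assign_allelic_expression(
            haps, rng_panel, EFFECT, ["case"] * 10000,
            [f"s{i}" for i in range(10000)], seed=4,
        )
        informative = ratios[ratios["true_ratio"] != 1.0]
        frac_up = (informative["true_ratio"] > 1).mean()
        se = math.sqrt(0.25 / len(informative))
        assert abs(frac_up - 0.5) < 3 * se

    def test_marker_homozygotes_contribute_no_ratio(self):
        haps = np.zeros((1, 2, 2), dtype=np.int8)
        haps[0, 0, 0] = 1  # causal het, marker hom
        ratios, _ = assign_allelic_expression(haps, PANEL, EFFECT, ["case"], ["s0"], seed=0)
        assert ratios.empty

    def test_unknown_diagnosis_rejected(self):
        haps = np.zeros((1, 2, 2), dtype=np.int8)
        with pytest.raises(ConfigError, match="penetrance"):
            assign_allelic_expression(haps, PANEL, EFFECT, ["mystery"], ["s0"], seed=0)


NOISE = NoiseModel(
    cdna_sd_by_marker={"m1": 0.12}, gdna_sd_by_marker={"m1": 0.05},
    n_replicates_cdna=3, n_replicates_gdna=2,
)


class TestSimulateMeasurements:
    def test_zero_noise_reproduces_truth_exactly(self):
        truth = pd.DataFrame(
            {"subject_id": ["a", "b"], "marker_id": ["m1", "m1"], "true_ratio": [2.5, 0.4]}
        )
        noise0 = NoiseModel({"m1": 0.0}, {"m1": 0.0})
        meas = simulate_measurements(truth, noise0, seed=0)
        cdna = meas[meas["source"] == "cDNA"].set_index("subject_id")
        assert (cdna.loc["a", "ratio"] == 2.5).all()
        assert (cdna.loc["b", "ratio"] == 0.4).all()
        assert (meas.loc[meas["source"] == "gDNA", "ratio"] == 1.0).all()

    def test_replicate_sd_matches_configured_assay_sd(self):
        """Linear-scale SD of replicates around a true ratio of 1 is the
        configured cDNA SD (the log-normal sigma calibration contract)."""
        truth = pd.DataFrame(
            {"subject_id": ["a"], "marker_id": ["m1"], "true_ratio": [1.0]}
        )
        big = NoiseModel({"m1": 0.12}, {"m1": 0.05}, n_replicates_cdna=10000)
        meas = simulate_measurements(truth, big, seed=5)
        sd = meas.loc[meas["source"] == "cDNA", "ratio"].std(ddof=1)
        assert sd == pytest.approx(0.12, rel=0.05)

    def test_gdna_centred_at_unity(self):
        truth = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(5000)],
             "marker_id": ["m1"] * 5000, "true_ratio": [1.0] * 5000}
        )
        meas = simulate_measurements(truth, NOISE, seed=6)
        g = meas.loc[meas["source"] == "gDNA", "ratio"]
        assert abs(g.mean() - 1.0) < 3 * g.std(ddof=1) / math.sqrt(len(g))

    def test_replicate_count_conservation(self, stanley_tables):
        """One cDNA row per marker-het subject per replicate, exactly."""
        cfg = stanley_tables.config
        n_pairs = stanley_tables.truth[
            [c for c in stanley_tables.truth.columns if c.startswith("true_ratio_")]
        ].notna().sum().sum()
        cdna = stanley_tables.measurements["source"] == "cDNA"
        assert cdna.sum() == n_pairs * cfg.noise.n_replicates_cdna

    def test_missing_noise_spec_rejected(self):
        truth = pd.DataFrame(
            {"subject_id": ["a"], "marker_id": ["mX"], "true_ratio": [1.0]}
        )
        with pytest.raises(ConfigError, match="mX"):
            simulate_measurements(truth, NOISE, seed=0)


class TestGeneratePhenotypes:
    def test_null_odds_ratio_balances_mafs(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.15, size=10000).astype(float)
        model = PhenotypeModel(odds_ratio_per_unit=1.0, model="dominant")
        ph = generate_phenotypes(d, model, [f"s{i}" for i in range(10000)], seed=9)
        maf_case = d[ph["trait"] == 1].mean() / 2
        maf_control = d[ph["trait"] == 0].mean() / 2
        assert maf_case == pytest.approx(maf_control, abs=0.01)

    def test_dominant_odds_ratio_recovered(self):
        """OR 2.7 for carriers at baseline prevalence 0.15 comes back from a
        2x2 carrier-by-trait table within 10%."""
        rng = np.random.default_rng(10)
        d = rng.binomial(2, 0.15, size=20000).astype(float)
        model = PhenotypeModel(
            baseline_prevalence=0.15, model="dominant", odds_ratio_per_unit=2.7
        )
        ph = generate_phenotypes(d, model, [f"s{i}" for i in range(20000)], seed=11)
        carrier = d > 0
        t = ph["trait"].to_numpy()
        a = ((carrier) & (t == 1)).sum()
        b = ((carrier) & (t == 0)).sum()
        c = ((~carrier) & (t == 1)).sum()
        dd = ((~carrier) & (t == 0)).sum()
        assert (a * dd) / (b * c) == pytest.approx(2.7, rel=0.10)

    def test_zero_count_slope_decorrelates_episodes(self):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.2, size=10000).astype(float)
        model = PhenotypeModel(count_trait_log_rate_per_allele=0.0)
        ph = generate_phenotypes(d, model, [f"s{i}" for i in range(10000)], seed=13)
        r = np.corrcoef(d, ph["episode_count"])[0, 1]
        assert abs(r) < 3 / math.sqrt(10000)


class TestDeterminism:
    def test_identical_config_gives_byte_identical_tables(self):
        a = simulate_cohort(stanley_config(seed=42))
        b = simulate_cohort(stanley_config(seed=42))
        assert a.measurements.to_csv() == b.measurements.to_csv()
        assert a.genotypes.dosage.to_csv() == b.genotypes.dosage.to_csv()
        assert a.phenotypes.to_csv() == b.phenotypes.to_csv()

    def test_different_seeds_differ(self):
        a = simulate_cohort(stanley_config(seed=1))
        b = simulate_cohort(stanley_config(seed=2))
        assert a.measurements.to_csv() != b.measurements.to_csv()


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        SnpSpec("x", 0.6)
    with pytest.raises(ConfigError):
        LdSpec("a", "a", 0.1)
    with pytest.raises(ConfigError):
        NoiseModel({"m": 0.1}, {"m": 0.1}, n_replicates_cdna=2)
    with pytest.raises(ConfigError):
        PhenotypeModel(model="codominant")
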