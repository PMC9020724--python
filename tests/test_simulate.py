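import numpy as np
import pytest

from specphos.pipeline import preprocess_panel
from specphos.ratios import compute_ratios, correlate_with_trait
from specphos.simulate import (
    ConfigError, PanelConfig, SyntheticGwasConfig, default_decay_link,
    generate_gwas, generate_panel,
)
from specphos.spectra import WavelengthGrid


def _noiseless_config(**kw):
    return PanelConfig(
        n_accessions=6, n_blocks=1, plants_per_accession_per_treatment=2,
        accession_effect_sd=0.0, spectral_accession_sd=0.0,
        spectral_plant_sd=0.0, block_effect_sd=0.0,
        technical_noise_sd=0.0, uv_noise_sd=0.0, seed=5, **kw,
    )


class TestGeneratePanel:
    def test_same_seed_identical_panels(self):
        cfg = PanelConfig(n_accessions=5, n_blocks=1, seed=42)
        a = generate_panel(cfg)
        b = generate_panel(PanelConfig(n_accessions=5, n_blocks=1, seed=42))
        assert a.spectra.data.equals(b.spectra.data)
        assert a.phenotypes.equals(b.phenotypes)

    def test_noiseless_spectra_follow_decay_law(self):
        panel = generate_panel(_noiseless_config())
        link = panel.truth["decay_link"]
        refl = panel.spectra.reflectance
        pi = panel.phenotypes.set_index("sample_id")["pi_content"]
        for i, sid in enumerate(panel.spectra.data["sample_id"]):
            expected = link.reflectance(pi[sid])[0]
            assert np.allclose(refl[i], np.clip(expected, 1e-4, 0.999), atol=1e-12)

    def test_p5_sample_mean_matches_configured_mean(self):
        # >= 500 plants in the P5 cell
        cfg = PanelConfig(n_accessions=172, n_blocks=3,
                          plants_per_accession_per_treatment=1, seed=9)
        panel = generate_panel(cfg)
        p5 = panel.phenotypes.query("treatment == 'P5'")["pi_content"]
        mean, sd = cfg.treatment_pi_params["P5"]
        se = p5.std(ddof=1) / np.sqrt(len(p5))
        assert len(p5) >= 500
        assert abs(p5.mean() - mean) < 3 * se + 1e-9

    def test_reflectance_in_unit_interval_and_pi_positive(self, small_panel):
        refl = small_panel.spectra.reflectance
        assert refl.min() > 0 and refl.max() < 1
        assert (small_panel.phenotypes["pi_content"] > 0).all()

    def test_one_phenotype_per_averaged_spectrum(self, small_panel):
        n_pheno = len(small_panel.phenotypes)
        n_samples = small_panel.spectra.data["sample_id"].nunique()
        assert n_pheno == n_samples

    def test_smooth_noiseless_component(self):
        """Adjacent channels of each noiseless spectrum nearly coincide."""
        panel = generate_panel(_noiseless_config())
        refl = panel.spectra.reflectance
        for row in refl:
            assert np.corrcoef(row[:-1], row[1:])[0, 1] >= 0.99

    @pytest.mark.parametrize("field,value", [
        ("n_accessions", 0),
        ("technical_noise_sd", -0.1),
        ("pi_scale", "cauchy"),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = PanelConfig(**{field: value})
        with pytest.raises(ConfigError):
            generate_panel(cfg)

    def test_treatment_ordering_enforced(self):
        cfg = PanelConfig(treatment_pi_params={
            "P100": (0.1, 0.01), "P5": (0.22, 0.07), "P0.25": (0.07, 0.03)})
        with pytest.raises(ConfigError, match="ordered"):
            generate_panel(cfg)

    def test_ratio_correlates_with_pi_on_default_panel(self, default_panel):
        """R740/R560 tracks Pi in the deficient treatments (screening target)."""
        sset, pheno = preprocess_panel(default_panel)
        deficient = pheno["treatment"].isin(["P5", "P0.25"]).to_numpy()
        ratios = compute_ratios(sset)[["R740/R560"]]
        rho = correlate_with_trait(ratios[deficient],
                                   pheno.loc[deficient, "pi_content"])
        assert rho["R740/R560"] > 0.6


class TestDecayLink:
    def test_vis_rises_nir_falls_under_deficiency(self):
        link = default_decay_link(WavelengthGrid())
        wl = link.wavelengths
        severe = link.reflectance(0.07)[0]
        sufficient = link.reflectance(3.6)[0]
        green = (wl >= 530) & (wl <= 640)
        nir = (wl >= 740) & (wl <= 790)
        assert (severe[green] > sufficient[green]).all()
        assert (severe[nir] < sufficient[nir]).all()


class TestGenerateGwas:
    def test_null_pvalues_uniform(self):
        from specphos.gwas import naive_assoc

        cfg = SyntheticGwasConfig(n_snps=1000, n_chromosomes=2,
                                  n_accessions=150, seed=3)
        snp_info, genotypes, trait, _ = generate_gwas(cfg)
        assoc = naive_assoc(genotypes, trait, snp_info)
        frac = (assoc["p_wald"] < 0.05).mean()
        # binomial 3-sigma band around 0.05 (correlated SNPs widen it a bit)
        assert abs(frac - 0.05) < 0.035

    def test_planted_effect_attains_min_p(self):
        from specphos.gwas import naive_assoc

        cfg = SyntheticGwasConfig(n_snps=500, n_chromosomes=2,
                                  planted_loci=[(1, 5_000_000, 2.0)],
                                  trait_noise_sd=0.5, n_accessions=150, seed=4)
        snp_info, genotypes, trait, _ = generate_gwas(cfg)
        assoc = naive_assoc(genotypes, trait, snp_info)
        top = assoc.loc[assoc["p_wald"].idxmin(), "rs"]
        planted = snp_info.attrs["planted_snps"][0]
        # lead may be the planted SNP or a near-perfect LD proxy in its block
        top_row = assoc[assoc["rs"] == top].iloc[0]
        planted_row = assoc[assoc["rs"] == planted].iloc[0]
        assert top_row["chr"] == planted_row["chr"]
        assert abs(top_row["ps"] - planted_row["ps"]) <= 300_000

    def test_seed_reproducibility(self):
        cfg = SyntheticGwasConfig(n_snps=200, seed=11)
        _, g1, t1, _ = generate_gwas(cfg)
        _, g2, t2, _ = generate_gwas(SyntheticGwasConfig(n_snps=200, seed=11))
        assert g1.equals(g2)
        assert np.allclose(t1, t2)

    def test_planted_locus_on_low_maf_snp_warns(self):
        cfg = SyntheticGwasConfig(n_snps=50, n_chromosomes=1,
                                  maf_range=(0.05, 0.06),
                                  planted_loci=[(1, 1_000_000, 1.0)],
                                  n_accessions=30, seed=2)
        # with a tiny panel the observed MAF of some SNP will dip below 0.05
        with pytest.warns(UserWarning, match="MAF"):
            for trial_seed in range(20):
                cfg.seed = trial_seed
                generate_gwas(cfg)

    def test_invalid_maf_range(self):
        with pytest.raises(ConfigError):
            generate_gwas(SyntheticGwasConfig(maf_range=(0.0, 0.5)))

    def test_planted_position_outside_chromosome(self):
        with pytest.raises(ConfigError):
            generate_gwas(SyntheticGwasConfig(
                planted_loci=[(1, 10**9, 1.0)]))
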