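"""Synthetic rice panel generator.

Emulates the measurement campaign the analysis pipeline expects: a diversity
panel of rice accessions grown hydroponically under three phosphate supplies
(P100 overly sufficient, P5 mildly deficient, P0.25 severely deficient), with
per-plant leaf reflectance spectra (380-790 nm, 2-nm steps, two technical
replicates per leaf), leaf inorganic-phosphate (Pi) content, shoot biomass,
and — separately — genotype/association fixtures with planted trait loci.

The spectral link is an exponential decay in Pi per waveband,

    R(lambda, Pi) = a(lambda) + b(lambda) * exp(-c(lambda) * Pi),

with b > 0 in the visible range (chlorophyll loss raises VIS reflectance as
Pi drops) and b < 0 in the NIR (thinner deficient leaves scatter less).  The
offset curve a(lambda) is a fixed smooth leaf-like baseline (blue and red
troughs, green bump, red edge, NIR plateau); it is what a well-fed leaf looks
like, since exp(-c*Pi) is negligible at P100 Pi levels.

Default treatment Pi distributions are lognormal with mean/SD
(3.60, 1.74), (0.22, 0.07) and (0.07, 0.03) nmol/mm^2 for P100/P5/P0.25.
Accession effects are multiplicative on Pi and additive (per spectral block)
on reflectance amplitude; plant effects and channelwise technical noise sit
below them.  The 380-410 nm channels receive extra independent noise to
emulate the device's unstable short-wavelength end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .spectra import SpectrumSet, TREATMENTS, WavelengthGrid


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


# ---------------------------------------------------------------------------
# spectral link
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class DecayLink:
    """Per-waveband (a, b, c) of the reflectance-vs-Pi decay law."""

    wavelengths: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def reflectance(self, pi: float | np.ndarray) -> np.ndarray:
        """Noiseless reflectance curve(s) at Pi content ``pi`` (nmol/mm^2)."""
        pi = np.atleast_1d(np.asarray(pi, dtype=float))
        return self.a + self.b * np.exp(-self.c * pi[:, None])


def leaf_baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth healthy-leaf reflectance baseline a(lambda).

    Low blue/red reflectance from chlorophyll absorption, a green bump near
    550 nm, a sharp red edge near 710 nm and an NIR plateau around 0.45.
    """
    green = 0.07 * np.exp(-(((wl - 550.0) / 35.0) ** 2))
    red_edge = 0.40 * _sigmoid((wl - 712.0) / 12.0)
    return 0.05 + green + red_edge


def vis_sensitivity(wl: np.ndarray) -> np.ndarray:
    """Weight of the VIS reflectance rise under deficiency (green-yellow +
    red-edge bands; zero in the NIR)."""
    w = np.exp(-(((wl - 560.0) / 60.0) ** 2)) + 0.9 * np.exp(-(((wl - 705.0) / 18.0) ** 2))
    return w * _sigmoid((726.0 - wl) / 4.0)


def nir_sensitivity(wl: np.ndarray) -> np.ndarray:
    """Weight of the NIR reflectance loss under deficiency (730-790 nm)."""
    return _sigmoid((wl - 728.0) / 6.0)


def nuisance_shapes(wl: np.ndarray) -> np.ndarray:
    """Spectral shapes of accession/plant/block nuisance variation.

    Three components with shapes distinct from the deficiency signature:
    a broadband albedo offset, a linear tilt across the range, and a green
    pigment-bump rescaling (weighted below the albedo component: pigment
    variation between healthy plants is subtler than surface/structure
    variation).  Rows: (offset, tilt, green).
    """
    offset = np.ones_like(wl)
    tilt = (wl - wl.mean()) / (wl.max() - wl.min())
    green = 0.6 * np.exp(-(((wl - 550.0) / 40.0) ** 2))
    return np.vstack([offset, tilt, green])


def default_decay_link(
    grid: WavelengthGrid,
    vis_gain: float = 0.08,
    nir_loss: float = 0.07,
    rate: float = 12.0,
) -> DecayLink:
    """Default decay law: VIS b>0, NIR b<0, common rate c per nmol/mm^2.

    ``rate`` = 12 puts the sensitive zone below ~0.2 nmol/mm^2: the deviation
    term is 43% of full scale at severely deficient Pi (0.07), 7% at mildly
    deficient Pi (0.22) and numerically zero at sufficient Pi (3.6), matching
    the observation that only severe deficiency reshapes the spectrum.
    """
    wl = grid.wavelengths
    b = vis_gain * vis_sensitivity(wl) - nir_loss * nir_sensitivity(wl)
    return DecayLink(wl, leaf_baseline(wl), b, np.full(len(wl), rate))


# ---------------------------------------------------------------------------
# panel configuration
# ---------------------------------------------------------------------------

#: Treatment-level Pi mean/SD in nmol/mm^2 (lognormal scale parameters are
#: derived from these arithmetic moments).
DEFAULT_PI_PARAMS: dict[str, tuple[float, float]] = {
    "P100": (3.60, 1.74),
    "P5": (0.22, 0.07),
    "P0.25": (0.07, 0.03),
}

#: Treatment-level shoot dry weight mean/SD in g.
DEFAULT_BIOMASS_PARAMS: dict[str, tuple[float, float]] = {
    "P100": (0.32, 0.06),
    "P5": (0.29, 0.05),
    "P0.25": (0.16, 0.03),
}


@dataclass
class PanelConfig:
    n_accessions: int = 172
    plants_per_accession_per_treatment: int = 3
    n_blocks: int = 3
    n_replicates: int = 2
    treatment_pi_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PI_PARAMS)
    )
    pi_scale: str = "lognormal"  # or "normal"
    accession_effect_sd: float = 0.20   # multiplicative (log-scale SD) on Pi
    spectral_accession_sd: float = 0.010  # per-accession block amplitude, reflectance units
    spectral_plant_sd: float = 0.020      # per-plant block amplitude, reflectance units
    block_effect_sd: float = 0.002        # per-experiment-block amplitude
    technical_noise_sd: float = 0.004     # channelwise i.i.d., reflectance units
    uv_noise_sd: float = 0.02             # extra noise below 412 nm
    biomass_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BIOMASS_PARAMS)
    )
    areal_dry_mass: float = 0.05  # mg/mm^2, leaf-disc dry mass per area
    decay_link: DecayLink | None = None
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_accessions", "plants_per_accession_per_treatment",
                     "n_blocks", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("accession_effect_sd", "spectral_accession_sd",
                     "spectral_plant_sd", "block_effect_sd",
                     "technical_noise_sd", "uv_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        missing = [t for t in TREATMENTS if t not in self.treatment_pi_params]
        if missing:
            raise ConfigError(f"treatment_pi_params missing treatments {missing}")
        means = [self.treatment_pi_params[t][0] for t in TREATMENTS]
        if not (means[0] > means[1] > means[2]):
            raise ConfigError(
                "treatment_pi_params means must be ordered P100 > P5 > P0.25"
            )
        for t, (m, s) in self.treatment_pi_params.items():
            if m <= 0 or s < 0:
                raise ConfigError(f"treatment_pi_params[{t}] needs mean > 0, SD >= 0")
        if self.pi_scale not in ("lognormal", "normal"):
            raise ConfigError("pi_scale must be 'lognormal' or 'normal'")
        if self.areal_dry_mass <= 0:
            raise ConfigError("areal_dry_mass must be > 0")


@dataclass
class SyntheticPanel:
    """Generated spectra + phenotypes + the truth that generated them."""

    spectra: SpectrumSet
    phenotypes: pd.DataFrame
    truth: dict


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with given arithmetic mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Simulate the full panel.

    Deterministic for a fixed seed.  Pi is drawn per plant from the treatment
    distribution with the accession multiplier folded in so that the marginal
    per-treatment moments match the configured (mean, SD); spectra follow the
    decay law at each plant's Pi plus accession/plant/block amplitude effects
    and technical replicate noise.
    """
    config.validate()
    link = config.decay_link or default_decay_link(config.grid)
    wl = config.grid.wavelengths
    if len(link.wavelengths) != len(wl) or not np.allclose(link.wavelengths, wl):
        raise ConfigError("decay_link wavelengths do not match grid")

    root = np.random.SeedSequence(config.seed)
    rng_acc, rng_pi, rng_spec, rng_phen = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]

    n_acc = config.n_accessions
    acc_ids = [f"ACC{i + 1:04d}" for i in range(n_acc)]
    # accession effects: multiplicative on Pi, additive on block amplitudes
    acc_log_pi = rng_acc.normal(0.0, config.accession_effect_sd, n_acc)
    # nuisance spectral effects (albedo / tilt / green-bump) per level
    acc_coefs = rng_acc.normal(0.0, config.spectral_accession_sd, (n_acc, 3))
    acc_biomass = rng_acc.normal(0.0, 0.10, n_acc)  # log-scale biomass effect
    block_coefs = rng_acc.normal(0.0, config.block_effect_sd, (config.n_blocks, 3))

    shapes = nuisance_shapes(wl)
    uv_mask = wl <= 410.0

    meta_rows: list[dict] = []
    pheno_rows: list[dict] = []
    spectra_rows: list[np.ndarray] = []

    n_plants = config.plants_per_accession_per_treatment
    for t in TREATMENTS:
        mean, sd = config.treatment_pi_params[t]
        if config.pi_scale == "lognormal":
            mu, sigma_tot = _lognormal_params(mean, sd)
            # accession multiplier is part of the marginal lognormal spread
            sigma_plant = np.sqrt(max(sigma_tot**2 - config.accession_effect_sd**2, 1e-8))
        bm_mean, bm_sd = config.biomass_params.get(t, (0.25, 0.05))
        bm_mu, bm_sigma = _lognormal_params(bm_mean, bm_sd)
        for b in range(config.n_blocks):
            for ai, acc in enumerate(acc_ids):
                for p in range(n_plants):
                    if config.pi_scale == "lognormal":
                        pi = float(np.exp(
                            mu + acc_log_pi[ai] + rng_pi.normal(0.0, sigma_plant)
                        ))
                    else:
                        pi = float(max(
                            rng_pi.normal(mean * np.exp(acc_log_pi[ai]), sd), 1e-4
                        ))
                    sample_id = f"{acc}_{t}_b{b + 1}_p{p + 1}"
                    clean = link.a + link.b * np.exp(-link.c * pi)
                    coefs = (acc_coefs[ai] + block_coefs[b]
                             + rng_spec.normal(0.0, config.spectral_plant_sd, 3))
                    plant_curve = clean + coefs @ shapes
                    for r in range(config.n_replicates):
                        noise = rng_spec.normal(0.0, config.technical_noise_sd, len(wl))
                        noise[uv_mask] += rng_spec.normal(
                            0.0, config.uv_noise_sd, int(uv_mask.sum()))
                        refl = np.clip(plant_curve + noise, 1e-4, 0.999)
                        meta_rows.append({
                            "sample_id": sample_id, "accession_id": acc,
                            "treatment": t, "block": b + 1, "replicate": r + 1,
                        })
                        spectra_rows.append(refl)
                    biomass = float(np.exp(
                        bm_mu + acc_biomass[ai] + rng_phen.normal(0.0, bm_sigma * 0.7)
                    ))
                    pheno_rows.append({
                        "sample_id": sample_id, "accession_id": acc, "treatment": t,
                        "block": b + 1, "pi_content": pi, "biomass": biomass,
                        "areal_dry_mass": config.areal_dry_mass
                        * float(np.exp(rng_phen.normal(0.0, 0.05))),
                    })

    data = pd.concat(
        [pd.DataFrame(meta_rows),
         pd.DataFrame(np.array(spectra_rows), columns=config.grid.columns())],
        axis=1,
    )
    spectra = SpectrumSet(config.grid, data)
    phenotypes = pd.DataFrame(pheno_rows)
    truth = {
        "decay_link": link,
        "accession_log_pi_effect": dict(zip(acc_ids, acc_log_pi)),
        "config": config,
    }
    return SyntheticPanel(spectra, phenotypes, truth)


# ---------------------------------------------------------------------------
# GWAS fixtures
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGwasConfig:
    n_snps: int = 2000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 30_000_000
    planted_loci: list[tuple[int, int, float]] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_accessions: int = 172
    block_size: int = 10        # SNPs per LD block
    within_block_recomb: float = 0.1  # chance a block SNP re-draws independently
    trait_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1 or self.n_chromosomes < 1 or self.n_accessions < 2:
            raise ConfigError("n_snps, n_chromosomes >= 1 and n_accessions >= 2 required")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        for chrom, pos, _ in self.planted_loci:
            if not (1 <= chrom <= self.n_chromosomes):
                raise ConfigError(f"planted locus chromosome {chrom} out of range")
            if not (1 <= pos <= self.chromosome_length_bp):
                raise ConfigError(f"planted locus position {pos} outside chromosome")


def generate_gwas(
    config: SyntheticGwasConfig,
    trait_link: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Simulate genotypes with LD-block structure, a quantitative trait, and LD.

    Returns ``(snp_info, genotypes, trait, ld_pairs)``: SNP metadata in
    association-table dialect order (chr, rs, ps, af), a 0/1/2 genotype
    DataFrame (accessions x SNPs), the trait vector, and pairwise LD r^2 for
    SNPs within 300 kb on the same chromosome.

    Planted loci contribute additive effects ``effect * genotype``; adjacent
    SNPs in the same LD block inherit the signal through linkage, so locus
    grouping downstream sees realistic clustered peaks.
    """
    import warnings

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_accessions
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1

    rows, genos = [], []
    for ci in range(config.n_chromosomes):
        m = int(per_chrom[ci])
        pos = np.sort(rng.integers(1, config.chromosome_length_bp + 1, m))
        mafs = rng.uniform(*config.maf_range, m)
        hap_a = hap_b = None
        block_start_pos = None
        block_count = 0
        for j in range(m):
            # blocks are bounded in SNP count and physical span (<= 200 kb)
            new_block = (
                block_start_pos is None
                or block_count >= config.block_size
                or pos[j] - block_start_pos > 200_000
            )
            if new_block:
                block_start_pos = pos[j]
                block_count = 0
            block_count += 1
            redraw = new_block or (rng.random() < config.within_block_recomb)
            if redraw or hap_a is None:
                hap_a = (rng.random(n) < mafs[j]).astype(np.int8)
                hap_b = (rng.random(n) < mafs[j]).astype(np.int8)
            g = hap_a + hap_b
            genos.append(g)
            obs_af = g.mean() / 2.0
            rows.append({
                "chr": ci + 1,
                "rs": f"snp_{ci + 1}_{int(pos[j])}",
                "ps": int(pos[j]),
                "af": float(min(obs_af, 1 - obs_af)),
            })
    snp_info = pd.DataFrame(rows)
    G = np.array(genos, dtype=float).T  # accessions x snps
    genotypes = pd.DataFrame(G, columns=snp_info["rs"])

    # trait: planted additive effects + configured extra links + noise
    effects = np.zeros(len(snp_info))
    planted_ids = []
    for chrom, pos, eff in config.planted_loci:
        on_chr = snp_info.index[snp_info["chr"] == chrom]
        j = int(on_chr[np.argmin(np.abs(snp_info.loc[on_chr, "ps"] - pos))])
        if snp_info.loc[j, "af"] < 0.05:  # conventional MAF filter cutoff
            warnings.warn(
                f"planted effect at {snp_info.loc[j, 'rs']} sits on a SNP with "
                f"observed MAF {snp_info.loc[j, 'af']:.3f} below the 0.05 filter"
            )
        effects[j] += eff
        planted_ids.append(snp_info.loc[j, "rs"])
    if trait_link:
        id_index = {r: i for i, r in enumerate(snp_info["rs"])}
        for rs, eff in trait_link.items():
            effects[id_index[rs]] += eff
    trait = G @ effects + rng.normal(0.0, config.trait_noise_sd, n)

    ld_pairs = _ld_table(snp_info, G, max_dist=300_000)
    snp_info.attrs["planted_snps"] = planted_ids
    return snp_info, genotypes, trait, ld_pairs


def _ld_table(snp_info: pd.DataFrame, G: np.ndarray, max_dist: int) -> pd.DataFrame:
    """Pairwise genotype r^2 for same-chromosome SNPs within ``max_dist`` bp."""
    recs = []
    chrs = snp_info["chr"].to_numpy()
    pos = snp_info["ps"].to_numpy()
    rs = snp_info["rs"].to_numpy()
    sd = G.std(axis=0)
    for i in range(len(snp_info)):
        j = i + 1
        while (j < len(snp_info) and chrs[j] == chrs[i]
               and pos[j] - pos[i] <= max_dist):
            if sd[i] > 0 and sd[j] > 0:
                r = np.corrcoef(G[:, i], G[:, j])[0, 1]
                recs.append({"snp_a": rs[i], "snp_b": rs[j], "r2": float(r * r)})
            j += 1
    return pd.DataFrame(recs, columns=["snp_a", "snp_b", "r2"])
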