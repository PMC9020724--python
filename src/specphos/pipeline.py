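"""End-to-end orchestration: simulate -> preprocess -> indices -> fits ->
models -> summaries -> GWAS post-processing, with a run manifest.

Also houses the dataset-preparation helpers shared by the CLI, the tests and
the acceptance script: replicate averaging, noisy-band exclusion,
train/val/test splitting and train-statistics standardization, with labels
(treatment class) or targets (log10 Pi) attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decay import fit_by_level
from .gwas import (
    bonferroni_log_threshold, call_significant, group_loci, loci_table,
    maf_filter, manhattan_data, naive_assoc, qq_data,
)
from .net import (
    DataSplits, ModelConfig, SplitSpec, TrainConfig, build_model, split_data,
    train,
)
from .phenotypes import accession_phenotype_means, descriptive_table
from .ratios import (
    accession_ratio_means, compute_ratios, correlate_with_trait,
    normalize_sr_traits,
)
from .simulate import (
    PanelConfig, SyntheticGwasConfig, SyntheticPanel, generate_gwas,
    generate_panel,
)
from .spectra import (
    TREATMENTS, average_replicates, exclude_noisy_band, write_spectra,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dataset preparation for the CNN
# ---------------------------------------------------------------------------

def preprocess_panel(panel: SyntheticPanel,
                     keep_start: float = 420.0, keep_stop: float = 790.0):
    """Replicate-averaged, band-trimmed spectra joined with phenotypes."""
    sset = exclude_noisy_band(average_replicates(panel.spectra),
                              keep_start, keep_stop)
    pheno = panel.phenotypes.set_index("sample_id").loc[sset.data["sample_id"]]
    return sset, pheno.reset_index()


def prepare_dataset(
    panel: SyntheticPanel,
    task: str = "classify",
    split: SplitSpec | None = None,
) -> DataSplits:
    """Standardized spectra + targets + split indices for training.

    Classification uses all three treatments (labels = treatment index);
    regression uses log10 Pi on P5 + P0.25 plants only, with accession-grouped
    splits so no accession straddles sets.  Standardization statistics come
    from the training split alone.
    """
    sset, pheno = preprocess_panel(panel)
    if task == "classify":
        split = split or SplitSpec(group_by_accession=False)
        mask = np.ones(len(sset), dtype=bool)
        y = np.array([TREATMENTS.index(t) for t in pheno["treatment"]])
    elif task == "regress":
        split = split or SplitSpec(group_by_accession=True)
        mask = pheno["treatment"].isin(["P5", "P0.25"]).to_numpy()
        pi = pheno["pi_content"].to_numpy(dtype=float)
        bad = mask & (pi <= 0)
        if bad.any():
            logger.warning("prepare_dataset: excluding %d non-positive Pi plants",
                           int(bad.sum()))
            mask &= pi > 0
        y = np.log10(np.where(pi > 0, pi, 1.0))
    else:
        raise ValueError(f"unknown task '{task}'")

    refl = sset.reflectance[mask]
    y = y[mask]
    acc = pheno["accession_id"].to_numpy()[mask]
    tr, va, te = split_data(len(refl), split, accessions=acc)

    mean = refl[tr].mean(axis=0)
    sd = refl[tr].std(axis=0, ddof=0)
    sd[sd < 1e-12] = 1.0
    X = (refl - mean) / sd
    return DataSplits(X=X, y=y, train_idx=tr, val_idx=va, test_idx=te,
                      channel_scale=sd)


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    out_dir: str = "specphos_run"
    seed: int = 0
    # stage toggles
    do_train: bool = False
    do_gwas: bool = True
    # module configs (paper-constant defaults surfaced here)
    panel: PanelConfig = field(default_factory=PanelConfig)
    gwas_fixture: SyntheticGwasConfig = field(default_factory=SyntheticGwasConfig)
    keep_start: float = 420.0
    keep_stop: float = 790.0
    trim_below: float = 0.02
    maf_threshold: float = 0.05
    alpha: float = 0.05
    locus_window: int = 300_000
    ld_dist: int = 100_000
    ld_r2_min: float = 0.50
    selected_ratios: tuple[str, str] = ("R750/R700", "R740/R560")
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()
                    if not isinstance(v, np.ndarray)}
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    payload = asdict(config)
    payload.pop("out_dir", None)  # hash covers the science, not the paths
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig) -> Path:
    """Execute the pipeline; returns the run directory.

    Writes per-stage TSV/CSV/JSON artifacts plus ``manifest.json`` recording
    the package version, seeds and a config hash.  A failing stage leaves a
    ``<stage>.failed`` marker and re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    t0 = time.time()

    def stage(name):
        def deco(fn):
            try:
                t = time.time()
                fn()
                manifest["stages"][name] = {"status": "ok",
                                            "seconds": round(time.time() - t, 2)}
            except Exception as exc:
                (out / f"{name}.failed").write_text(repr(exc))
                manifest["stages"][name] = {"status": "failed", "error": repr(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        cfg = PanelConfig(**{**config.panel.__dict__, "seed": config.seed})
        state["panel"] = generate_panel(cfg)
        write_spectra(state["panel"].spectra, out / "spectra.csv")
        state["panel"].phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    @stage("preprocess")
    def _preprocess():
        sset, pheno = preprocess_panel(state["panel"], config.keep_start,
                                       config.keep_stop)
        state["spectra"], state["pheno"] = sset, pheno
        write_spectra(sset, out / "spectra_preprocessed.csv")

    @stage("indices")
    def _indices():
        sset, pheno = state["spectra"], state["pheno"]
        ratios = compute_ratios(sset)
        state["ratios"] = ratios
        ratios.to_csv(out / "ratios.tsv", sep="\t")
        deficient = pheno["treatment"].isin(["P5", "P0.25"]).to_numpy()
        rho = correlate_with_trait(ratios[deficient],
                                   pheno.loc[deficient, "pi_content"])
        rho.round(2).to_csv(out / "ratio_pi_spearman.tsv", sep="\t")
        state["rho"] = rho
        m025 = accession_ratio_means(ratios, pheno, "P0.25")
        m100 = accession_ratio_means(ratios, pheno, "P100")
        sr = normalize_sr_traits(m025, m100)
        sr.to_csv(out / "sr_traits.tsv", sep="\t")
        state["sr_traits"] = sr

    @stage("decayfit")
    def _decayfit():
        pheno, ratios = state["pheno"], state["ratios"]
        results = {}
        df = pheno[["accession_id", "treatment", "pi_content"]].copy()
        deficient = df["treatment"].isin(["P5", "P0.25"])
        for name in config.selected_ratios:
            df[name] = ratios[name].to_numpy()
            for level in ("individual", "accession"):
                fit = fit_by_level(df[deficient], name, level=level,
                                   trim_below=config.trim_below)
                results[f"{name} [{level}]"] = fit.to_dict()
        (out / "decay_fits.json").write_text(json.dumps(results, indent=2))
        state["decay_fits"] = results

    @stage("summarize")
    def _summarize():
        pheno, ratios = state["pheno"], state["ratios"]
        acc = accession_phenotype_means(state["panel"].phenotypes)
        table = descriptive_table(acc, ["pi_content", "biomass", "pute"])
        rat = ratios.copy()
        rat["treatment"] = pheno["treatment"].to_numpy()
        rat["accession_id"] = pheno["accession_id"].to_numpy()
        rmeans = (rat.groupby(["accession_id", "treatment"], sort=False)
                  [list(config.selected_ratios)].mean().reset_index())
        table = pd.concat(
            [table, descriptive_table(rmeans, list(config.selected_ratios))],
            ignore_index=True,
        )
        table.to_csv(out / "descriptive_table.tsv", sep="\t", index=False)
        state["summary"] = table

    if config.do_train:
        @stage("train")
        def _train():
            data = prepare_dataset(state["panel"], task="classify",
                                   split=SplitSpec(seed=config.seed))
            model = build_model(ModelConfig(**{
                **config.model.__dict__,
                "input_channels": data.X.shape[1],
                "seed": config.seed,
            }))
            result = train(model, data,
                           TrainConfig(**{**config.training.__dict__,
                                          "seed": config.seed}))
            metrics = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in result.metrics.items()}
            (out / "train_metrics.json").write_text(json.dumps(metrics, indent=2))
            state["train_result"] = result

    if config.do_gwas:
        @stage("gwaspost")
        def _gwaspost():
            gcfg = SyntheticGwasConfig(**{**config.gwas_fixture.__dict__,
                                          "seed": config.seed})
            snp_info, genotypes, trait, ld = generate_gwas(gcfg)
            assoc = naive_assoc(genotypes, trait, snp_info)
            assoc = maf_filter(assoc, config.maf_threshold)
            assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
            ld.to_csv(out / "ld.tsv", sep="\t", index=False)
            thr = bonferroni_log_threshold(len(assoc), config.alpha)
            sig = call_significant(assoc, thr)
            loci = group_loci(sig, config.locus_window, trait="Trait")
            loci_table(loci).to_csv(out / "loci.tsv", sep="\t", index=False)
            manhattan_data(assoc).to_csv(out / "manhattan.tsv", sep="\t", index=False)
            qq_data(assoc["p_wald"].to_numpy()).to_csv(out / "qq.tsv", sep="\t",
                                                       index=False)
            state["loci"] = loci
            state["bonferroni"] = thr

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete in %.1f s -> %s", time.time() - t0, out)
    return out
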