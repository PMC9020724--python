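"""NIR/VIS reflectance ratio indices.

A ratio index R_NIR / R_VIS condenses a leaf spectrum into one number per
band pair.  The screening grid pairs 7 NIR bands (730, 740, ..., 790 nm)
with 31 VIS bands (420, 430, ..., 720 nm), giving 217 indices per sample.
These are screened against traits with Spearman correlation and, for
association mapping, summarized per accession as the deficient-treatment mean
divided by the control mean ("mean-normalized SR traits").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .spectra import SpectraError, SpectrumSet

NIR_BANDS = tuple(range(730, 791, 10))   # 7 bands
VIS_BANDS = tuple(range(420, 721, 10))   # 31 bands

RatioKey = tuple[int, int]  # (nir_nm, vis_nm)


def build_ratio_grid() -> list[RatioKey]:
    """All (NIR, VIS) band pairs, lexicographically ordered: 7 x 31 = 217."""
    return [(n, v) for n in NIR_BANDS for v in VIS_BANDS]


def ratio_name(key: RatioKey) -> str:
    return f"R{key[0]}/R{key[1]}"


def compute_ratios(sset: SpectrumSet, keys: list[RatioKey] | None = None) -> pd.DataFrame:
    """Per-sample ratio table: sample_id index, one column per ratio key.

    Requires the set's grid to cover 420-790 nm.  Raises on a zero VIS
    denominator, naming the wavelength.
    """
    keys = keys or build_ratio_grid()
    refl = sset.reflectance
    cols = {}
    for key in keys:
        nir_i = sset.grid.index_of(float(key[0]))
        vis_i = sset.grid.index_of(float(key[1]))
        denom = refl[:, vis_i]
        if np.any(denom == 0):
            raise SpectraError(f"zero reflectance denominator at {key[1]} nm")
        cols[ratio_name(key)] = refl[:, nir_i] / denom
    out = pd.DataFrame(cols, index=sset.data["sample_id"])
    out.index.name = "sample_id"
    return out


def correlate_with_trait(
    ratios: pd.DataFrame, trait: np.ndarray | pd.Series, method: str = "spearman"
) -> pd.Series:
    """Correlation of each ratio column with a trait vector.

    The default screen uses Spearman's rank correlation (average ranks on
    ties), so it is invariant to any strictly monotone transform of the trait.
    """
    trait = np.asarray(trait, dtype=float)
    if len(trait) != len(ratios):
        raise SpectraError(
            f"trait length {len(trait)} != {len(ratios)} samples"
        )
    if len(trait) < 3:
        raise SpectraError("need at least 3 paired samples")
    out = {}
    for col in ratios.columns:
        x = ratios[col].to_numpy(dtype=float)
        if method == "spearman":
            rho, _ = spearmanr(x, trait)
        elif method == "pearson":
            rho = np.corrcoef(x, trait)[0, 1]
        else:
            raise SpectraError(f"unknown method '{method}'")
        out[col] = float(rho)
    return pd.Series(out, name=f"{method}_rho")


def correlation_heatmap_table(rhos: pd.Series) -> pd.DataFrame:
    """Reshape a 217-long correlation series to the VIS-rows x NIR-columns
    layout used for screening heatmaps."""
    mat = pd.DataFrame(index=list(VIS_BANDS), columns=list(NIR_BANDS), dtype=float)
    for (nir, vis) in build_ratio_grid():
        mat.loc[vis, nir] = rhos[ratio_name((nir, vis))]
    mat.index.name = "vis_nm"
    mat.columns.name = "nir_nm"
    return mat


def accession_ratio_means(
    ratios: pd.DataFrame, meta: pd.DataFrame, treatment: str
) -> pd.DataFrame:
    """Mean of each ratio per accession within one treatment.

    Mean-of-ratios (plants pooled across experiment blocks), computed after
    technical-replicate averaging upstream.
    """
    m = meta.set_index("sample_id").loc[ratios.index]
    sel = m["treatment"] == treatment
    if not sel.any():
        raise SpectraError(f"no samples in treatment {treatment}")
    grouped = ratios[sel.to_numpy()].groupby(m.loc[sel, "accession_id"].to_numpy())
    out = grouped.mean()
    out.index.name = "accession_id"
    return out


def normalize_sr_traits(
    means_deficient: pd.DataFrame, means_control: pd.DataFrame
) -> pd.DataFrame:
    """Mean-normalized SR traits: deficient accession mean / control mean.

    A value of 1 means the ratio did not change under deficiency.  Both
    tables must cover the same accessions and ratio columns.
    """
    missing = sorted(set(means_deficient.index) ^ set(means_control.index))
    if missing:
        raise SpectraError(f"accessions missing on one side: {missing[:10]}")
    if list(means_deficient.columns) != list(means_control.columns):
        raise SpectraError("ratio columns differ between treatments")
    ctl = means_control.loc[means_deficient.index]
    return means_deficient / ctl
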