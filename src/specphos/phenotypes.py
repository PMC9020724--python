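"""Derived phenotypes and descriptive statistics.

Leaf Pi is measured as nmol per mm^2 of leaf area; converting to a
mass-fraction concentration (mg Pi per g leaf dry weight) uses the molar
mass of the orthophosphate ion and the areal dry mass of the sampled leaf
discs.  Phosphorus utilization efficiency (PUtE) is shoot biomass divided by
that concentration — grams of shoot produced per unit of tissue P.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: molar mass of PO4^3- in g/mol
MW_PHOSPHATE = 94.97


class PhenotypeError(ValueError):
    pass


def pi_to_mg_per_g(
    pi_nmol_mm2, areal_dry_mass_mg_mm2, mw: float = MW_PHOSPHATE
):
    """Convert areal Pi (nmol/mm^2) to concentration (mg Pi per g dry weight).

    nmol/mm^2 * (mw g/mol) = mw * 1e-6 mg/mm^2 of Pi; dividing by the disc
    areal dry mass (mg/mm^2) gives mg/mg, i.e. *1000 for mg/g.
    Linear in Pi, inverse-linear in areal dry mass.
    """
    pi = np.asarray(pi_nmol_mm2, dtype=float)
    adm = np.asarray(areal_dry_mass_mg_mm2, dtype=float)
    if np.any(adm <= 0):
        raise PhenotypeError("areal dry mass must be > 0")
    out = pi * mw * 1e-6 / adm * 1000.0
    return float(out) if out.ndim == 0 else out


def compute_pute(biomass_g, pi_mg_per_g):
    """PUtE = shoot biomass (g) / Pi concentration (mg/g)."""
    bm = np.asarray(biomass_g, dtype=float)
    conc = np.asarray(pi_mg_per_g, dtype=float)
    if np.any(conc <= 0):
        raise PhenotypeError("Pi concentration must be > 0 for PUtE")
    out = bm / conc
    return float(out) if out.ndim == 0 else out


def fold_change(
    values_high: pd.Series, values_low: pd.Series, pairing: str = "accession"
) -> float:
    """Mean fold decrease between two conditions, paired by index.

    Each pair contributes high/low; zero-denominator pairs are excluded with
    a logged count.  Pairing is on the series index (accession by default;
    callers doing per-plant pairing index by plant).
    """
    common = values_high.index.intersection(values_low.index)
    if len(common) == 0:
        raise PhenotypeError(f"no common {pairing} pairs")
    hi = values_high.loc[common].to_numpy(dtype=float)
    lo = values_low.loc[common].to_numpy(dtype=float)
    ok = lo != 0
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("fold_change: excluded %d zero-denominator pairs", dropped)
    if not ok.any():
        raise PhenotypeError("all pairs have zero denominator")
    return float(np.mean(hi[ok] / lo[ok]))


def descriptive_table(
    df: pd.DataFrame,
    value_cols: list[str],
    group_cols: list[str] = ("treatment",),
) -> pd.DataFrame:
    """Mean, SD (n-1), range and CV% per trait x group cell.

    CV% = 100 * SD / mean; reported as NaN when the cell mean is 0.  Cells
    with fewer than 2 values raise, since an SD is undefined there.
    """
    rows = []
    for keys, sub in df.groupby(list(group_cols), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                raise PhenotypeError(
                    f"cell {dict(zip(group_cols, keys))} x {col}: need >= 2 values"
                )
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            cv = 100.0 * sd / mean if mean != 0 else float("nan")
            rows.append({
                **dict(zip(group_cols, keys)),
                "trait": col, "n": len(vals), "mean": mean, "sd": sd,
                "min": float(vals.min()), "max": float(vals.max()), "cv_pct": cv,
            })
    return pd.DataFrame(rows)


def accession_phenotype_means(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Accession x treatment means of Pi, biomass and PUtE.

    PUtE at P100 is computed but flagged ``exclude_from_mapping`` — Pi pools
    at over-sufficient supply are dominated by vacuolar storage and are not
    physiologically tied to growth, so that cell is left out of association
    scans.
    """
    df = phenotypes.copy()
    df["pi_mg_per_g"] = pi_to_mg_per_g(df["pi_content"], df["areal_dry_mass"])
    df["pute"] = compute_pute(df["biomass"], df["pi_mg_per_g"])
    out = (
        df.groupby(["accession_id", "treatment"], sort=False)[
            ["pi_content", "biomass", "pute"]
        ]
        .mean()
        .reset_index()
    )
    out["exclude_from_mapping"] = (out["treatment"] == "P100")
    return out
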