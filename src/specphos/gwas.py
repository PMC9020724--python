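"""GWAS post-processing: from per-SNP association results to called loci.

The association scan itself (mixed-model with kinship correction) is run by
external software; this module consumes its per-SNP output table — GEMMA
``.assoc`` dialect with columns ``chr, rs, ps, af, p_wald`` — and applies the
downstream calling rules:

* drop SNPs with minor allele frequency below 0.05 (boundary kept),
* Bonferroni significance on the -log10 scale (boundary significant),
* chain significant SNPs within 300 kb on a chromosome into one locus
  (single-linkage on the gap), lead SNP = lowest p,
* candidate window around a lead SNP: within 100 kb AND LD r^2 strictly
  above 0.50.

A naive per-SNP OLS association engine is included so synthetic fixtures can
be run end-to-end without the external solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ASSOC_COLUMNS = ["chr", "rs", "ps", "af", "p_wald"]


class GwasError(ValueError):
    pass


@dataclass
class Locus:
    name: str
    chromosome: int
    snp_ids: list[str]
    lead_snp: str
    lead_position: int
    span: tuple[int, int]
    minus_log10_p: float
    lead_maf: float

    @property
    def n_significant(self) -> int:
        return len(self.snp_ids)


def read_assoc(path) -> pd.DataFrame:
    """Read a GEMMA-dialect association TSV; validates required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise GwasError(f"{path}: missing association columns {missing}")
    return validate_assoc(df)


def validate_assoc(df: pd.DataFrame) -> pd.DataFrame:
    p = df["p_wald"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise GwasError("p_wald values must lie in (0, 1]")
    if np.any(df["ps"].to_numpy() < 1):
        raise GwasError("positions must be >= 1 (1-based bp)")
    return df


def read_ld(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("snp_a", "snp_b", "r2") if c not in df.columns]
    if missing:
        raise GwasError(f"{path}: missing LD columns {missing}")
    return df


def maf_filter(records: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Remove SNPs with MAF < threshold; the boundary value is kept."""
    return records[records["af"] >= threshold].reset_index(drop=True)


def bonferroni_log_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n_tests): familywise significance on the -log10 scale."""
    if n_tests < 1:
        raise GwasError(f"n_tests must be >= 1, got {n_tests}")
    return float(-np.log10(alpha / n_tests))


def call_significant(records: pd.DataFrame, log_threshold: float) -> pd.DataFrame:
    """Keep SNPs with -log10(p) >= threshold (boundary significant)."""
    if log_threshold < 0:
        raise GwasError("threshold must be >= 0")
    validate_assoc(records)
    keep = -np.log10(records["p_wald"].to_numpy(dtype=float)) >= log_threshold
    return records[keep].reset_index(drop=True)


def group_loci(
    significant: pd.DataFrame, window: int = 300_000, trait: str = ""
) -> list[Locus]:
    """Chain significant SNPs into loci.

    Single-linkage on genomic gaps: consecutive significant SNPs on a
    chromosome at most ``window`` bp apart belong to one locus.  Lead SNP is
    the member with the lowest p (ties: lower position).  Names follow
    ``q<TRAIT><chr>`` with a positional ``-k`` suffix when a chromosome has
    several loci.
    """
    loci: list[Locus] = []
    for chrom, sub in significant.groupby("chr", sort=True):
        sub = sub.sort_values(["ps", "rs"]).reset_index(drop=True)
        groups: list[list[int]] = []
        for i in range(len(sub)):
            if groups and sub.loc[i, "ps"] - sub.loc[groups[-1][-1], "ps"] <= window:
                groups[-1].append(i)
            else:
                groups.append([i])
        chrom_loci = []
        for idx in groups:
            members = sub.loc[idx]
            order = members.sort_values(["p_wald", "ps"])
            lead = order.iloc[0]
            chrom_loci.append(Locus(
                name="",  # assigned below once counts per chromosome are known
                chromosome=int(chrom),
                snp_ids=list(members["rs"]),
                lead_snp=str(lead["rs"]),
                lead_position=int(lead["ps"]),
                span=(int(members["ps"].min()), int(members["ps"].max())),
                minus_log10_p=float(-np.log10(lead["p_wald"])),
                lead_maf=float(lead["af"]),
            ))
        for k, locus in enumerate(chrom_loci, start=1):
            suffix = f"-{k}" if len(chrom_loci) > 1 else ""
            locus.name = f"q{trait}{locus.chromosome}{suffix}"
        loci.extend(chrom_loci)
    return loci


def group_loci_oracle(significant: pd.DataFrame, window: int = 300_000) -> list[set]:
    """Brute-force transitive closure of the pairwise <= window relation.

    Quadratic reference used to verify :func:`group_loci`; returns member
    rs-id sets without naming or lead selection.
    """
    groups: list[set] = []
    for chrom, sub in significant.groupby("chr"):
        rs = list(sub["rs"])
        pos = sub["ps"].to_numpy()
        parent = list(range(len(rs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                if abs(int(pos[i]) - int(pos[j])) <= window:
                    parent[find(i)] = find(j)
        by_root: dict[int, set] = {}
        for i in range(len(rs)):
            by_root.setdefault(find(i), set()).add(rs[i])
        groups.extend(by_root.values())
    return groups


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Summary table of called loci (one row per locus)."""
    return pd.DataFrame([
        {
            "locus": l.name, "chr": l.chromosome,
            "n_significant_snps": l.n_significant,
            "lead_snp": l.lead_snp, "lead_position": l.lead_position,
            "minus_log10_p": l.minus_log10_p, "maf": l.lead_maf,
            "span_start": l.span[0], "span_end": l.span[1],
        }
        for l in loci
    ])


def ld_candidate_window(
    lead: pd.Series | dict,
    all_snps: pd.DataFrame,
    ld: pd.DataFrame,
    dist: int = 100_000,
    r2_min: float = 0.50,
) -> list[str]:
    """SNPs within ``dist`` bp of the lead AND with LD r^2 > r2_min (strict).

    Pairs absent from the LD table are treated as below threshold (logged).
    The lead itself is always included.
    """
    lead_rs, lead_chr, lead_ps = lead["rs"], lead["chr"], lead["ps"]
    r2_map: dict[str, float] = {}
    sel = (ld["snp_a"] == lead_rs) | (ld["snp_b"] == lead_rs)
    for _, row in ld[sel].iterrows():
        other = row["snp_b"] if row["snp_a"] == lead_rs else row["snp_a"]
        r2_map[other] = max(r2_map.get(other, 0.0), float(row["r2"]))
    near = all_snps[
        (all_snps["chr"] == lead_chr)
        & (np.abs(all_snps["ps"] - lead_ps) <= dist)
    ]
    out = []
    n_missing = 0
    for rs in near["rs"]:
        if rs == lead_rs:
            out.append(rs)
        elif rs in r2_map:
            if r2_map[rs] > r2_min:
                out.append(rs)
        else:
            n_missing += 1
    if n_missing:
        logger.info("ld_candidate_window: %d nearby SNPs missing from LD table "
                    "(treated as below threshold)", n_missing)
    return out


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10(p) pairs for a QQ plot.

    Observed p sorted ascending; expected quantiles -log10(i / (n + 1)).
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if len(p) < 1:
        raise GwasError("need at least one p-value")
    n = len(p)
    expected = -np.log10(np.arange(1, n + 1) / (n + 1))
    observed = -np.log10(p)
    return pd.DataFrame({"expected": expected, "observed": observed})


def manhattan_data(records: pd.DataFrame,
                   chrom_lengths: dict[int, int] | None = None) -> pd.DataFrame:
    """Add a cumulative genome coordinate for Manhattan plotting.

    Chromosome offsets are the cumulative sums of chromosome lengths
    (inferred from the max position per chromosome when not supplied); SNP
    order within the table is preserved.
    """
    chroms = sorted(records["chr"].unique())
    if chrom_lengths is None:
        chrom_lengths = {
            int(c): int(records.loc[records["chr"] == c, "ps"].max())
            for c in chroms
        }
    offsets, cum = {}, 0
    for c in chroms:
        offsets[int(c)] = cum
        cum += int(chrom_lengths[int(c)])
    out = records.copy()
    out["cum_pos"] = out["ps"] + out["chr"].map(offsets)
    out["minus_log10_p"] = -np.log10(out["p_wald"])
    out.attrs["chrom_offsets"] = offsets
    return out


def naive_assoc(genotypes: pd.DataFrame, trait: np.ndarray,
                snp_info: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP simple linear regression of trait on 0/1/2 genotype.

    Slope t-test p-values (no kinship correction — suitable only for
    synthetic fixtures without population structure).  Monomorphic SNPs get
    p = 1, logged.
    """
    y = np.asarray(trait, dtype=float)
    G = genotypes.to_numpy(dtype=float)
    n = len(y)
    if G.shape[0] != n:
        raise GwasError("genotype rows must match trait length")
    gm = G.mean(axis=0)
    gc = G - gm
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    syy = float((yc**2).sum())
    sxy = gc.T @ yc
    mono = sxx <= 0
    if mono.any():
        logger.warning("naive_assoc: %d monomorphic SNPs set to p=1", int(mono.sum()))
    p = np.ones(G.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mono | (syy == 0), 0.0, sxy / np.sqrt(np.where(sxx > 0, sxx, 1) * max(syy, 1e-300)))
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    dof = n - 2
    t = r * np.sqrt(dof / (1 - r**2))
    ok = ~mono & (syy > 0)
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = snp_info[["chr", "rs", "ps", "af"]].copy()
    out["p_wald"] = p
    return out
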