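"""Reflectance spectra: containers, I/O and preprocessing.

Spectra are leaf reflectance curves measured on a fixed wavelength grid
(380-790 nm in 2-nm steps for the handheld device emulated here).  A
:class:`SpectrumSet` couples a :class:`WavelengthGrid` with a pandas DataFrame
holding one row per measurement: identity metadata columns followed by one
reflectance column per wavelength (``R380``, ``R382``, ...).

Reflectance is stored as a fraction in [0, 1].  Percent-scale input is
auto-detected (any value > 1.5) and divided by 100 with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

TREATMENTS = ("P100", "P5", "P0.25")

#: metadata columns, in canonical order
META_COLUMNS = ["sample_id", "accession_id", "treatment", "block", "replicate"]


class SpectraError(ValueError):
    """Raised for malformed spectra input or invalid preprocessing requests."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm."""

    start: float = 380.0
    stop: float = 790.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise SpectraError(f"grid step must be > 0, got {self.step}")
        if self.stop <= self.start:
            raise SpectraError("grid stop must exceed start")
        n_steps = (self.stop - self.start) / self.step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise SpectraError(
                f"(stop-start)={self.stop - self.start} not divisible by step={self.step}"
            )

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self))

    def columns(self) -> list[str]:
        """Column names of the wide-format table (``R420`` style)."""
        return [f"R{w:g}" for w in self.wavelengths]

    def index_of(self, nm: float) -> int:
        idx = (nm - self.start) / self.step
        if idx < 0 or idx > len(self) - 1 or abs(idx - round(idx)) > 1e-9:
            raise SpectraError(f"wavelength {nm} nm not on grid {self}")
        return int(round(idx))


@dataclass
class SpectrumSet:
    """A collection of spectra sharing one wavelength grid.

    ``data`` carries the metadata columns of :data:`META_COLUMNS` plus one
    reflectance column per grid wavelength.
    """

    grid: WavelengthGrid
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        cols = self.grid.columns()
        missing = [c for c in META_COLUMNS + cols if c not in self.data.columns]
        if missing:
            raise SpectraError(f"missing columns: {missing[:5]}")
        refl = self.data[cols].to_numpy(dtype=float)
        if not np.isfinite(refl).all():
            raise SpectraError("non-finite reflectance values")
        # standardized sets are allowed to be negative; raw sets are validated
        # at read/generation time instead.
        self.data = self.data[META_COLUMNS + cols].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def reflectance(self) -> np.ndarray:
        """(n_samples, n_channels) float array aligned to the grid."""
        return self.data[self.grid.columns()].to_numpy(dtype=float)

    @property
    def meta(self) -> pd.DataFrame:
        return self.data[META_COLUMNS]

    def with_reflectance(self, values: np.ndarray) -> "SpectrumSet":
        if values.shape != (len(self), len(self.grid)):
            raise SpectraError(
                f"reflectance shape {values.shape} incompatible with "
                f"({len(self)}, {len(self.grid)})"
            )
        out = self.data.copy()
        out[self.grid.columns()] = values
        return SpectrumSet(self.grid, out)


def _coerce_percent(refl: np.ndarray) -> np.ndarray:
    if np.nanmax(refl) > 1.5:
        logger.warning("reflectance looks percent-scaled (max %.3g); dividing by 100",
                       np.nanmax(refl))
        refl = refl / 100.0
    return refl


def read_spectra(path, grid: WavelengthGrid | None = None) -> SpectrumSet:
    """Read a wide-format spectra CSV.

    The header must declare the wavelengths (``R420`` style columns).  If
    ``grid`` is given the file's wavelength columns must match it exactly;
    otherwise the grid is inferred from the header.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise SpectraError(f"{path}: no records")
    wl_cols = [c for c in df.columns if c.startswith("R") and c[1:].replace(".", "").isdigit()]
    if not wl_cols:
        raise SpectraError(f"{path}: header declares no wavelength columns")
    wls = np.array([float(c[1:]) for c in wl_cols])
    order = np.argsort(wls)
    wls, wl_cols = wls[order], [wl_cols[i] for i in order]
    if grid is None:
        steps = np.diff(wls)
        if len(steps) == 0 or not np.allclose(steps, steps[0]):
            raise SpectraError(f"{path}: wavelength columns not on a uniform grid")
        grid = WavelengthGrid(wls[0], wls[-1], steps[0])
    else:
        expected = grid.wavelengths
        if len(wls) != len(expected) or not np.allclose(wls, expected):
            raise SpectraError(
                f"{path}: wavelength grid mismatch — file has {len(wls)} channels "
                f"{wls[0]:g}-{wls[-1]:g}, expected {len(expected)} at "
                f"{grid.start:g}-{grid.stop:g}/{grid.step:g}"
            )
    for col in META_COLUMNS:
        if col not in df.columns:
            if col == "block":
                df[col] = 0
            elif col == "replicate":
                df[col] = 0
            elif col == "accession_id":
                df[col] = df["sample_id"]
            else:
                raise SpectraError(f"{path}: missing metadata column '{col}'")
    bad = df[wl_cols].map(lambda v: not np.isreal(v) or pd.isna(v))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SpectraError(f"{path}: non-numeric cell at row {r + 2}, column {wl_cols[c]}")
    dup = df.duplicated(subset=["sample_id", "replicate"])
    if dup.any():
        raise SpectraError(
            f"{path}: duplicate sample_id+replicate at row {int(np.argmax(dup.to_numpy())) + 2}"
        )
    refl = _coerce_percent(df[wl_cols].to_numpy(dtype=float))
    if (refl < 0).any():
        raise SpectraError(f"{path}: negative reflectance")
    out = pd.concat(
        [df[META_COLUMNS].reset_index(drop=True),
         pd.DataFrame(refl, columns=grid.columns())],
        axis=1,
    )
    return SpectrumSet(grid, out)


def write_spectra(sset: SpectrumSet, path) -> None:
    sset.data.to_csv(path, index=False)


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Average technical replicates channelwise, one record per sample_id.

    Single-replicate samples pass through unchanged; the operation is
    idempotent.  Row order follows first appearance of each sample_id.
    """
    cols = sset.grid.columns()
    grouped = (
        sset.data.groupby("sample_id", sort=False)
        .agg({**{c: "first" for c in META_COLUMNS if c != "sample_id"},
              **{c: "mean" for c in cols}})
        .reset_index()
    )
    grouped["replicate"] = 0
    return SpectrumSet(sset.grid, grouped)


def exclude_noisy_band(
    sset: SpectrumSet, keep_start: float = 420.0, keep_stop: float = 790.0
) -> SpectrumSet:
    """Truncate spectra to [keep_start, keep_stop] nm.

    The short-wavelength end of the device range (380-410 nm) fluctuates
    strongly between adjacent channels and is dropped before any analysis;
    420-790 nm at 2-nm steps leaves 186 channels.
    """
    if keep_start > keep_stop:
        raise SpectraError(f"empty keep range [{keep_start}, {keep_stop}]")
    g = sset.grid
    if keep_start < g.start - 1e-9 or keep_stop > g.stop + 1e-9:
        raise SpectraError("keep range outside grid")
    new_grid = WavelengthGrid(keep_start, keep_stop, g.step)
    keep_cols = new_grid.columns()
    out = sset.data[META_COLUMNS + keep_cols].copy()
    return SpectrumSet(new_grid, out)


def standardize(
    train_set: SpectrumSet, apply_set: SpectrumSet | None = None
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Per-channel zero-mean unit-variance scaling with train statistics.

    Returns the transformed ``apply_set`` (default: the train set itself) and a
    DataFrame of the channel means and SDs used, so that validation/test data
    are always scaled with training statistics.
    """
    if len(train_set) == 0:
        raise SpectraError("empty training set")
    refl = train_set.reflectance
    mean = refl.mean(axis=0)
    sd = refl.std(axis=0, ddof=0)
    zero = sd < 1e-12
    if zero.any():
        wl = train_set.grid.wavelengths[zero][0]
        raise SpectraError(f"zero-variance channel at {wl:g} nm")
    target = train_set if apply_set is None else apply_set
    if len(target.grid) != len(train_set.grid):
        raise SpectraError("apply_set grid differs from train grid")
    z = (target.reflectance - mean) / sd
    stats = pd.DataFrame(
        {"wavelength": train_set.grid.wavelengths, "mean": mean, "sd": sd}
    )
    return target.with_reflectance(z), stats


def within_spectrum_correlation(
    sset: SpectrumSet, method: str = "spearman"
) -> pd.DataFrame:
    """Wavelength x wavelength correlation across samples.

    Quantifies the two-block structure of leaf spectra: channels within the
    visible range move together (pigment absorption) and NIR channels move
    together (leaf structure), with weak coupling across the two blocks.
    """
    if len(sset) < 3:
        raise SpectraError("need at least 3 records for correlation")
    refl = sset.reflectance
    if method == "spearman":
        corr, _ = spearmanr(refl)
    elif method == "pearson":
        corr = np.corrcoef(refl, rowvar=False)
    else:
        raise SpectraError(f"unknown method '{method}'")
    wl = sset.grid.wavelengths
    return pd.DataFrame(np.asarray(corr), index=wl, columns=wl)
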