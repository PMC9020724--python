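"""Constrained exponential-decay calibration of reflectance against Pi.

The calibration model is

    response = a + b * exp(-c * Pi)

with box constraints a >= -1 (reflectance-like responses are positive) and
c >= 0 (decay, not growth); b is free, so the same model covers responses
that rise (b < 0) or fall (b > 0) with decreasing Pi.  Points with
Pi < 0.02 nmol/mm^2 are trimmed before fitting — at that level the wet-lab
Pi determination is mostly noise.

Fits run at the individual-plant level or at the accession level, where Pi
and the response are first averaged within accession x treatment cells;
averaging removes plant-level scatter, so accession-level R^2 is typically
much higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import spearmanr


class DecayFitError(ValueError):
    pass


@dataclass
class DecayFitResult:
    a: float
    b: float
    c: float
    covariance: np.ndarray  # 3x3, order (a, b, c)
    r_squared: float
    n_used: int
    level: str = "individual"  # or "accession"

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    @property
    def coef_variation(self) -> np.ndarray:
        """SE/estimate per parameter (reported as a fraction)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.abs(self.standard_errors / self.params)

    def predict(self, pi: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.exp(-self.c * np.asarray(pi, dtype=float))

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "se": self.standard_errors.tolist(),
            "cv": self.coef_variation.tolist(),
            "r_squared": self.r_squared, "n_used": self.n_used,
            "level": self.level,
        }


def _model(params: np.ndarray, pi: np.ndarray) -> np.ndarray:
    a, b, c = params
    return a + b * np.exp(-c * pi)


def fit_decay(
    pi: np.ndarray,
    response: np.ndarray,
    trim_below: float = 0.02,
    level: str = "individual",
) -> DecayFitResult:
    """Bounded least-squares fit of ``response = a + b exp(-c Pi)``.

    Multi-start: the decay-rate initial guess 1/median(Pi) is tried along
    with a tenfold slower and faster rate, keeping the solution with the
    lowest residual sum of squares (the model is non-convex in c).
    The covariance comes from the final Jacobian, scaled by the residual
    variance with n - 3 degrees of freedom.
    """
    pi = np.asarray(pi, dtype=float)
    response = np.asarray(response, dtype=float)
    if pi.shape != response.shape:
        raise DecayFitError("pi and response lengths differ")
    keep = np.isfinite(pi) & np.isfinite(response) & (pi >= trim_below)
    pi, response = pi[keep], response[keep]
    n = len(pi)
    if n < 4:
        raise DecayFitError(f"only {n} points after trimming; need >= 4")
    if pi.max() - pi.min() < 1e-6:
        raise DecayFitError("degenerate Pi range (max - min < 1e-6)")

    rho = spearmanr(pi, response)[0]
    sign = -1.0 if (rho is not None and not np.isnan(rho) and rho > 0) else 1.0
    # response increasing in Pi  =>  b < 0 (decay term subtracts at low Pi)
    rng_resp = response.max() - response.min()
    a0 = float(response[np.argmax(pi)])  # asymptote ~ response at largest Pi
    a0 = max(a0, -1.0)
    b0 = sign * max(rng_resp, 1e-3)
    c_base = 1.0 / max(np.median(pi), 1e-6)

    lower = np.array([-1.0, -np.inf, 0.0])
    upper = np.array([np.inf, np.inf, np.inf])
    best = None
    for c0 in (c_base / 10.0, c_base, c_base * 10.0):
        x0 = np.array([a0, b0, c0])
        try:
            sol = least_squares(
                lambda p: _model(p, pi) - response, x0,
                bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise DecayFitError("optimizer failed from all starts")

    resid = best.fun
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((response - response.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    J = best.jac
    dof = max(n - 3, 1)
    s2 = ss_res / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)

    a, b, c = best.x
    return DecayFitResult(float(a), float(b), float(c), cov, r2, n, level)


def fit_by_level(
    samples: pd.DataFrame,
    response_col: str,
    pi_col: str = "pi_content",
    level: str = "individual",
    trim_below: float = 0.02,
) -> DecayFitResult:
    """Fit at plant or accession level.

    ``samples`` needs columns ``accession_id``, ``treatment``, the Pi column
    and the response column.  At accession level, Pi and the response are
    averaged within accession x treatment cells before fitting (each cell
    contributes one point), so pooled P5 + P0.25 data yields two points per
    accession.
    """
    if level not in ("individual", "accession"):
        raise DecayFitError(f"unknown level '{level}'")
    df = samples
    if level == "accession":
        df = (
            samples.groupby(["accession_id", "treatment"], sort=False)[
                [pi_col, response_col]
            ]
            .mean()
            .reset_index()
        )
    return fit_decay(
        df[pi_col].to_numpy(), df[response_col].to_numpy(),
        trim_below=trim_below, level=level,
    )


def grid_search_oracle(
    pi: np.ndarray,
    response: np.ndarray,
    a_grid: np.ndarray,
    b_grid: np.ndarray,
    c_grid: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Dense brute-force (a, b, c) search; returns (best params, best SS_res).

    Independent check of the bounded optimizer: its SS_res must never exceed
    the best grid point's.  Only practical for small instances.
    """
    pi = np.asarray(pi, dtype=float)
    response = np.asarray(response, dtype=float)
    best_ss, best_p = np.inf, None
    for c in c_grid:
        e = np.exp(-c * pi)
        for b in b_grid:
            be = b * e
            for a in a_grid:
                r = a + be - response
                ss = float(r @ r)
                if ss < best_ss:
                    best_ss, best_p = ss, np.array([a, b, c])
    return best_p, best_ss
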