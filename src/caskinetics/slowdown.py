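"""The seed-composition slowdown expression and its single-constant refit.

A symbolic-regression analysis of measured kinetic ratios against seed
composition features yielded the closed-form relation

    r(f_R, f_U) = exp[ exp(f_U) + f_U / (f_R - c) ],    c = 1.0423962,

where f_R is the purine fraction and f_U the uracil fraction of the 8-nt
seed.  This module evaluates that expression family, refits its one free
constant c by scalar least squares, and joins predictions against measured
ratios.  The expression *search* is not reproduced here — only the printed
functional form, with c as the refittable parameter.

For c > 1 and f_R in [0, 1] the denominator is strictly negative, so the
two f_U-dependent terms pull in opposite directions; monotonicity in f_U
depends on f_R and is checked numerically on a grid, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DomainError, FitError, JoinError

DEFAULT_C = 1.0423962
FORM = "exp[exp(f_U) + f_U/(f_R - c)]"


@dataclass(frozen=True)
class SlowdownExpression:
    """The printed expression family with its dimensionless constant c."""

    c: float = DEFAULT_C
    form: str = FORM


def eval_slowdown(f_R, f_U, c: float = DEFAULT_C):
    """Predicted kinetic ratio exp(exp(f_U) + f_U/(f_R - c)).

    Accepts scalars or arrays on the unit square; any (f_R, f_U) pair in
    [0,1]^2 is admitted (the two fractions are not constrained to a
    realisable four-letter composition).  Singular at f_R = c.
    """
    f_R = np.asarray(f_R, dtype=float)
    f_U = np.asarray(f_U, dtype=float)
    if np.any((f_R < 0) | (f_R > 1)) or np.any((f_U < 0) | (f_U > 1)):
        raise DomainError("fractions must lie in [0, 1]")
    if np.any(np.isclose(f_R, c, rtol=0, atol=1e-12)):
        raise DomainError(f"expression singular at f_R = c = {c}")
    out = np.exp(np.exp(f_U) + f_U / (f_R - c))
    return float(out) if out.ndim == 0 else out


def fu_monotonicity_grid(f_R: float, c: float = DEFAULT_C, n: int = 201) -> bool:
    """Grid check: is the expression increasing in f_U on (0,1) at this f_R?

    Not an analytic claim — exp(f_U) grows while f_U/(f_R - c) falls (the
    denominator is negative), so the net direction flips with f_R.
    """
    f_U = np.linspace(0.0, 1.0, n)
    vals = eval_slowdown(np.full(n, f_R), f_U, c)
    return bool(np.all(np.diff(vals) > 0))


def refit_constant(data: pd.DataFrame, bounds: tuple[float, float] = (1.0, 3.0),
                   xatol: float = 1e-10) -> tuple[float, float]:
    """Refit c by 1-D least squares on (f_R, f_U, r) rows.

    Returns (c, residual_norm).  Deterministic: bounded scalar
    minimization of the mean squared error over c in (1, 3].
    """
    required = {"f_R", "f_U", "r"}
    if not required.issubset(data.columns):
        raise FitError(f"data must have columns {sorted(required)}")
    if len(data) < 3:
        raise FitError("need at least 3 rows to refit c")
    if data[["f_R", "f_U", "r"]].drop_duplicates().shape[0] < 2:
        raise FitError("degenerate data: all rows identical")
    f_R = data["f_R"].to_numpy(dtype=float)
    f_U = data["f_U"].to_numpy(dtype=float)
    r = data["r"].to_numpy(dtype=float)
    if np.any(f_R >= bounds[0]):
        raise FitError(f"all f_R must lie below the search interval start {bounds[0]}")

    def mse(c):
        pred = np.exp(np.exp(f_U) + f_U / (f_R - c))
        return float(np.mean((pred - r) ** 2))

    # open at the left end: nudge the lower bracket above max(f_R) <= 1
    lo = np.nextafter(bounds[0], bounds[1])
    res = minimize_scalar(mse, bounds=(lo, bounds[1]), method="bounded",
                          options={"xatol": xatol})
    if not res.success:
        raise FitError(f"scalar minimization failed: {res.message}")
    c_hat = float(res.x)
    residual_norm = float(np.sqrt(np.sum((eval_slowdown(f_R, f_U, c_hat) - r) ** 2)))
    return c_hat, residual_norm


def feature_ratio_table(features: pd.DataFrame, ratios: pd.DataFrame,
                        c: float = DEFAULT_C) -> pd.DataFrame:
    """Join seed features with measured ratios; add predictions and residuals.

    ``features`` needs columns (name, seed_f_R, seed_f_U) as produced by
    :func:`caskinetics.sequence_features.feature_table`; ``ratios`` needs
    (grna, r_mean, r_sd) as produced by
    :func:`caskinetics.trace_analysis.analyze_plate`.  The name-keyed join
    must be total; unmatched names raise with the offending list.
    """
    if features.empty and ratios.empty:
        return pd.DataFrame(columns=["name", "f_R", "f_U", "r_observed",
                                     "r_sd", "r_predicted", "residual"])
    feat = features.rename(columns={"seed_f_R": "f_R", "seed_f_U": "f_U"})
    rat = ratios.rename(columns={"grna": "name", "r_mean": "r_observed"})
    missing = sorted(set(rat["name"]) ^ set(feat["name"]))
    if missing:
        raise JoinError(f"unmatched gRNA names in join: {missing}", missing=missing)
    merged = feat.merge(rat, on="name", how="inner")
    merged["r_predicted"] = eval_slowdown(merged["f_R"].to_numpy(),
                                          merged["f_U"].to_numpy(), c)
    merged["residual"] = merged["r_observed"] - merged["r_predicted"]
    cols = ["name", "f_R", "f_U", "r_observed", "r_sd", "r_predicted", "residual"]
    return merged[[col for col in cols if col in merged.columns]]
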