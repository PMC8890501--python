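"""Dose-response analysis: Hill titration fits and fitness-decay fits.

Each genotype's fitness across the magnesium titration is fit to the Hill
equation ``W(m) = wmax * m**h / (k**h + m**h)`` — the midpoint k (mM)
reflects how much magnesium the variant needs to fold and is the
per-genotype readout of structural stability.  Filters retain only
well-behaved fits (0.15 < wmax < 3, h < 5, k < 16 mM).

The average shape of the landscape is summarized by fitting
``W(n) = exp(-alpha * n**beta)`` to the mean fitness at each mutational
distance n; alpha is the average deleterious effect of single mutations and
beta the direction of epistasis (beta > 1: predominantly negative epistasis,
combined mutations worse than additive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fitness import FitnessLandscape
from .genotypes import LibrarySpec, hamming_distance
from .synthetic import hill_activity

__all__ = [
    "HillFit",
    "fit_hill",
    "fit_hill_landscape",
    "filter_hill_fits",
    "midpoints_by_distance",
    "DecayFit",
    "fit_decay",
    "fit_decay_landscape",
]

HILL_BOUNDS = ([0.0, 1e-3, 1e-2], [1e6, 1e4, 50.0])


@dataclass(frozen=True)
class HillFit:
    """One genotype's Hill-equation fit (wmax dimensionless, k in mM)."""

    wmax: float
    k: float
    h: float
    residual: float
    converged: bool
    reason: str | None = None
    genotype: str | None = None


def _half_max_interp(mg: np.ndarray, w: np.ndarray) -> float:
    """mg at half the maximum observed fitness, by linear interpolation."""
    half = 0.5 * w.max()
    above = np.nonzero(w >= half)[0]
    if above.size == 0 or above[0] == 0:
        return float(mg[0])
    i = above[0]
    w0, w1 = w[i - 1], w[i]
    if w1 == w0:
        return float(mg[i])
    frac = (half - w0) / (w1 - w0)
    return float(mg[i - 1] + frac * (mg[i] - mg[i - 1]))


def fit_hill(
    mg_levels,
    profile,
    sigma=None,
    genotype: str | None = None,
    rtol_flat: float = 1e-3,
) -> HillFit:
    """Bounded nonlinear least squares of one fitness-vs-magnesium profile.

    Multi-start initialization (h in {0.5, 1, 2, 4}; k from the half-max
    crossing and the median mg) keeps the fit deterministic and robust.
    When per-point standard errors ``sigma`` are supplied (count-derived
    fitness values have strongly heteroscedastic noise), residuals are
    inverse-variance weighted.  All-zero and flat profiles are flagged
    rather than raised: a constant profile carries no information about k
    or h.
    """
    mg = np.asarray(mg_levels, dtype=float)
    w = np.asarray(profile, dtype=float)
    keep = np.isfinite(w)
    if sigma is not None:
        sig_all = np.asarray(sigma, dtype=float)
        keep &= np.isfinite(sig_all) & (sig_all > 0)
    mg, w = mg[keep], w[keep]
    sig = None if sigma is None else np.asarray(sigma, dtype=float)[keep]
    if mg.size < 4:
        return HillFit(np.nan, np.nan, np.nan, np.nan, False, "too_few_points", genotype)
    if np.any(mg <= 0):
        raise ValueError("mg levels must be positive")
    if np.all(w <= 0):
        return HillFit(0.0, np.nan, np.nan, 0.0, False, "no_activity", genotype)
    span = w.max() - w.min()
    if span <= rtol_flat * max(w.max(), 1e-12):
        return HillFit(
            float(w.mean()), np.nan, np.nan, float(np.std(w)), False,
            "degenerate_flat", genotype,
        )

    def resid(theta):
        r = hill_activity(mg, *theta) - w
        return r if sig is None else r / sig

    wmax0 = float(w.max())
    k_half = _half_max_interp(mg, w)
    k_starts = {k_half, float(np.median(mg))}
    best = None
    for h0 in (0.5, 1.0, 2.0, 4.0):
        for k0 in k_starts:
            x0 = np.clip(
                [wmax0, k0, h0], HILL_BOUNDS[0], HILL_BOUNDS[1]
            )
            try:
                sol = least_squares(
                    resid, x0, bounds=HILL_BOUNDS, xtol=1e-12, ftol=1e-12, gtol=1e-12
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.nan, False, "solver_failure", genotype)
    wmax, k, h = best.x
    residual = float(np.sqrt(2 * best.cost))
    at_bound = k >= 0.99 * HILL_BOUNDS[1][1] or h >= 0.99 * HILL_BOUNDS[1][2]
    converged = bool(best.success) and not at_bound
    return HillFit(
        float(wmax), float(k), float(h), residual, converged,
        None if converged else "at_bound", genotype,
    )


def fit_hill_landscape(
    landscape: FitnessLandscape, spec: LibrarySpec, genotypes=None
) -> pd.DataFrame:
    """Hill fits for every genotype's replicate-mean titration profile.

    Genotypes with a missing (NaN) mean in any mg condition are excluded
    (no imputation).  Returns a DataFrame indexed by genotype with columns
    wmax, k, h, residual, converged, reason, distance.
    """
    profiles = landscape.profiles()
    mg = profiles.columns.to_numpy(dtype=float)
    if genotypes is not None:
        profiles = profiles.loc[list(genotypes)]
    complete = profiles.dropna()
    wt = spec.wild_type_alleles
    rows = {}
    for genotype, profile in complete.iterrows():
        fit = fit_hill(mg, profile.to_numpy(), genotype=genotype)
        rows[genotype] = {
            "wmax": fit.wmax,
            "k": fit.k,
            "h": fit.h,
            "residual": fit.residual,
            "converged": fit.converged,
            "reason": fit.reason,
            "distance": hamming_distance(genotype, wt),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genotype"
    return df


def filter_hill_fits(
    fits: pd.DataFrame,
    wmax_range: tuple[float, float] = (0.15, 3.0),
    max_slope: float = 5.0,
    max_midpoint: float = 16.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep fits with 0.15 < wmax < 3, h < 5 and k < 16 mM that converged.

    Returns the input with ``kept`` and ``exclusion_reason`` columns plus a
    tally of exclusions by (first matching) reason.
    """
    df = fits.copy()
    reasons = pd.Series("", index=df.index, dtype=object)
    checks = [
        ("not_converged", ~df["converged"].astype(bool)),
        ("wmax_low", df["wmax"] <= wmax_range[0]),
        ("wmax_high", df["wmax"] >= wmax_range[1]),
        ("slope_high", df["h"] >= max_slope),
        ("midpoint_high", df["k"] >= max_midpoint),
    ]
    tally: dict[str, int] = {}
    for name, mask in checks:
        mask = mask.fillna(True)
        newly = mask & (reasons == "")
        reasons[newly] = name
        tally[name] = int(newly.sum())
    df["kept"] = reasons == ""
    df["exclusion_reason"] = reasons.replace("", None)
    tally["kept"] = int(df["kept"].sum())
    return df, tally


def midpoints_by_distance(fits: pd.DataFrame) -> pd.DataFrame:
    """Summary of Hill parameters per mutational distance class.

    Expects a fits DataFrame with ``distance, k, h, wmax`` columns (normally
    the filtered fits).  Distance classes absent from the input are reported
    with count 0.
    """
    max_d = int(fits["distance"].max()) if len(fits) else 0
    records = []
    for d in range(0, max_d + 1):
        sub = fits[fits["distance"] == d]
        rec = {"distance": d, "count": int(len(sub))}
        for col in ("k", "h", "wmax"):
            rec[f"mean_{col}"] = float(sub[col].mean()) if len(sub) else np.nan
            rec[f"median_{col}"] = float(sub[col].median()) if len(sub) else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("distance")


@dataclass(frozen=True)
class DecayFit:
    """Fit of W(n) = exp(-alpha * n**beta) to mean fitness by distance."""

    alpha: float
    beta: float
    residual: float
    method: str  # "log" or "direct"


def decay_curve(n, alpha, beta):
    n = np.asarray(n, dtype=float)
    return np.exp(-alpha * n**beta)


def fit_decay(distances, means) -> DecayFit:
    """Constrained least squares of the decay law over per-distance means.

    Fits in log-fitness space when all means are positive (falls back to the
    direct space otherwise, flagged in ``method``).  n = 0 is excluded: the
    model predicts W(0) = 1 by construction.
    """
    n = np.asarray(distances, dtype=float)
    w = np.asarray(means, dtype=float)
    keep = (n >= 1) & np.isfinite(w)
    n, w = n[keep], w[keep]
    if n.size < 2:
        raise ValueError("need means for at least two distance classes n >= 1")
    bounds = ([1e-6, 1e-6], [100.0, 100.0])
    log_domain = bool(np.all(w > 0))

    # init from the linearization log(-log w) = log(alpha) + beta*log(n),
    # using only informative points (w < 1).
    mask = (w > 0) & (w < 1)
    if mask.sum() >= 2:
        yy = np.log(-np.log(w[mask]))
        xx = np.log(n[mask])
        beta0, log_alpha0 = np.polyfit(xx, yy, 1)
        x0 = np.clip([np.exp(log_alpha0), beta0], bounds[0], bounds[1])
    else:
        x0 = np.array([0.5, 1.0])

    if log_domain:
        def resid(theta):
            return (-theta[0] * n ** theta[1]) - np.log(w)
        method = "log"
    else:
        def resid(theta):
            return decay_curve(n, *theta) - w
        method = "direct"
    sol = least_squares(resid, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    direct_resid = decay_curve(n, *sol.x) - w
    return DecayFit(
        alpha=float(sol.x[0]),
        beta=float(sol.x[1]),
        residual=float(np.sqrt(np.mean(direct_resid**2))),
        method=method,
    )


def mean_fitness_by_distance(
    fitness: pd.Series, spec: LibrarySpec
) -> pd.Series:
    """Mean fitness of all genotypes at each mutational distance from wild-type."""
    wt = spec.wild_type_alleles
    dist = pd.Series(
        [hamming_distance(g, wt) for g in fitness.index], index=fitness.index
    )
    return fitness.groupby(dist).mean().rename_axis("distance")


def fit_decay_landscape(
    landscape: FitnessLandscape, spec: LibrarySpec
) -> pd.DataFrame:
    """Decay fit per mg level, on the per-distance means of replicate-mean fitness."""
    rows = []
    for mg in landscape.mg_levels:
        means = mean_fitness_by_distance(landscape.slice(mg), spec)
        fit = fit_decay(means.index.to_numpy(), means.to_numpy())
        rows.append(
            {
                "mg_mM": mg,
                "alpha": fit.alpha,
                "beta": fit.beta,
                "residual": fit.residual,
                "method": fit.method,
            }
        )
    return pd.DataFrame(rows).set_index("mg_mM")
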