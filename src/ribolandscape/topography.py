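"""Landscape topography: epistasis squares, ruggedness, roughness/slope.

A *square* is a set of four genotypes {g, g+A, g+B, g+A+B} that differ by two
single substitutions (at positions i and j) and their combination.  With
fitness values W0, WA, WB, WAB the square is epistasis-free when
``WAB + W0 - WA - WB = 0``; otherwise two sign conditions decide the class:

    Condition 1: |WA - W0 + WAB - WB| = |WA - W0| + |WAB - WB|
    Condition 2: |WB - W0 + WAB - WA| < |WB - W0| + |WAB - WA|

Condition 1 holds iff mutation A's effect has the same sign in both
backgrounds; Condition 2 holds iff mutation B's effect flips sign.  Squares
with Condition 1 true and Condition 2 false are magnitude epistasis, those
with Condition 1 false and Condition 2 true are reciprocal sign epistasis,
and the remainder (exactly one effect flipping) are sign epistasis.
Landscape ruggedness is ``2*f_RS + f_S`` over the classified squares.

The roughness-to-slope ratio r/s measures deviation from additivity: fitness
is least-squares fit to an additive model (intercept + one coefficient per
non-reference allele per position); r is the RMS residual and s the mean
absolute additive coefficient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    RNA_ALPHABET,
    ALLELE_INDEX,
    LibrarySpec,
    build_library,
    genotype_digit_matrix,
    hamming_distance,
    neighbors,
)

__all__ = [
    "EPISTASIS_CLASSES",
    "classify_square",
    "classify_squares",
    "enumerate_squares",
    "square_corner_indices",
    "RuggednessResult",
    "ruggedness",
    "RoughnessSlope",
    "roughness_slope",
    "TrendResult",
    "ruggedness_trend",
    "hamming_distance",
    "neighbors",
]

#: Class codes used by the vectorized classifier, in code order 0..3.
EPISTASIS_CLASSES = ("none", "magnitude", "sign", "reciprocal_sign")


def classify_squares(w0, wa, wb, wab, eps: float = 0.0) -> np.ndarray:
    """Vectorized epistasis classification -> integer codes 0..3.

    ``eps`` is an absolute tolerance: interaction magnitudes and sign
    agreements within ``eps`` count as equalities, so zero-magnitude
    single-mutation effects are treated as sign-agreeing.
    """
    w0, wa, wb, wab = (np.asarray(x, dtype=float) for x in (w0, wa, wb, wab))
    if not all(np.all(np.isfinite(x)) for x in (w0, wa, wb, wab)):
        raise ValueError("fitness values must be finite")
    interaction = wab + w0 - wa - wb
    da0, da1 = wa - w0, wab - wb  # effect of mutation A in each background
    db0, db1 = wb - w0, wab - wa  # effect of mutation B in each background
    a_keeps_sign = np.abs(da0 + da1) + eps >= np.abs(da0) + np.abs(da1)
    b_keeps_sign = np.abs(db0 + db1) + eps >= np.abs(db0) + np.abs(db1)
    cls = np.full(np.broadcast(w0, wa, wb, wab).shape, 2, dtype=np.int8)  # sign
    cls[a_keeps_sign & b_keeps_sign] = 1  # magnitude
    cls[~a_keeps_sign & ~b_keeps_sign] = 3  # reciprocal sign
    cls[np.abs(interaction) <= eps] = 0  # no epistasis
    return cls


def classify_square(w0, wa, wb, wab, eps: float = 0.0) -> str:
    """Classify one square -> 'none' | 'magnitude' | 'sign' | 'reciprocal_sign'."""
    code = classify_squares(
        np.array([w0]), np.array([wa]), np.array([wb]), np.array([wab]), eps
    )[0]
    return EPISTASIS_CLASSES[code]


def enumerate_squares(spec: LibrarySpec) -> Iterator[tuple[str, int, int, str, str]]:
    """Yield every geometric square exactly once, canonically anchored.

    Yields ``(reference, i, j, a, b)`` where the reference genotype is the
    lexicographically smallest corner, ``i < j`` are the two varying
    positions, and ``a``/``b`` are the alternative alleles at ``i``/``j``
    (lexicographically greater than the reference's).  Deterministic order.
    """
    L = spec.n_positions
    for ref in build_library(spec):
        for i, j in itertools.combinations(range(L), 2):
            for a in RNA_ALPHABET[ALLELE_INDEX[ref[i]] + 1 :]:
                for b in RNA_ALPHABET[ALLELE_INDEX[ref[j]] + 1 :]:
                    yield ref, i, j, a, b


@lru_cache(maxsize=4)
def square_corner_indices(n_positions: int) -> np.ndarray:
    """(n_squares, 4) int array of library indices (W0, WA, WB, WAB).

    Covers every unique square once; ordering matches the canonical
    anchoring of :func:`enumerate_squares` up to permutation.
    """
    L = n_positions
    digits = genotype_digit_matrix(L)
    idx = np.arange(4**L, dtype=np.int64)
    blocks = []
    for i, j in itertools.combinations(range(L), 2):
        pv_i = 4 ** (L - 1 - i)
        pv_j = 4 ** (L - 1 - j)
        for a0, a1 in itertools.combinations(range(4), 2):
            for b0, b1 in itertools.combinations(range(4), 2):
                base = idx[(digits[:, i] == a0) & (digits[:, j] == b0)]
                w0 = base
                wa = base + (a1 - a0) * pv_i
                wb = base + (b1 - b0) * pv_j
                wab = base + (a1 - a0) * pv_i + (b1 - b0) * pv_j
                blocks.append(np.stack([w0, wa, wb, wab], axis=1))
    return np.concatenate(blocks, axis=0)


@dataclass(frozen=True)
class RuggednessResult:
    """Epistasis class fractions and the ruggedness score ``2*f_RS + f_S``."""

    f_none: float
    f_magnitude: float
    f_sign: float
    f_reciprocal_sign: float
    ruggedness: float
    n_squares: int
    n_skipped: int = 0


def ruggedness(
    fitness: pd.Series | np.ndarray, spec: LibrarySpec, eps: float = 0.0
) -> RuggednessResult:
    """Classify every square of a landscape slice and score its ruggedness.

    ``fitness`` is indexed by genotype (or an array in lexicographic library
    order).  Squares with any non-finite corner are skipped and tallied in
    ``n_skipped``; fractions are over classified squares only.
    """
    if isinstance(fitness, pd.Series):
        library = build_library(spec)
        values = fitness.reindex(library).to_numpy(dtype=float)
    else:
        values = np.asarray(fitness, dtype=float)
    if values.size != spec.library_size:
        raise ValueError(
            f"fitness must cover the full library ({spec.library_size} genotypes)"
        )
    corners = square_corner_indices(spec.n_positions)
    w = values[corners]
    valid = np.isfinite(w).all(axis=1)
    n_skipped = int((~valid).sum())
    w = w[valid]
    if w.shape[0] == 0:
        raise ValueError("no classifiable squares (all have missing corners)")
    codes = classify_squares(w[:, 0], w[:, 1], w[:, 2], w[:, 3], eps)
    n = codes.size
    counts = np.bincount(codes, minlength=4)
    f_none, f_mag, f_sign, f_rs = (counts / n).tolist()
    return RuggednessResult(
        f_none=f_none,
        f_magnitude=f_mag,
        f_sign=f_sign,
        f_reciprocal_sign=f_rs,
        ruggedness=2.0 * f_rs + f_sign,
        n_squares=n,
        n_skipped=n_skipped,
    )


def classified_squares_table(
    fitness: pd.Series, spec: LibrarySpec, eps: float = 0.0
) -> pd.DataFrame:
    """Per-square table: corner genotypes, fitness values and class label.

    One row per unique square (774,144 for the full library — large); rows
    with a missing corner carry class 'skipped'.
    """
    library = build_library(spec)
    values = fitness.reindex(library).to_numpy(dtype=float)
    corners = square_corner_indices(spec.n_positions)
    w = values[corners]
    valid = np.isfinite(w).all(axis=1)
    labels = np.full(corners.shape[0], "skipped", dtype=object)
    if valid.any():
        codes = classify_squares(
            w[valid, 0], w[valid, 1], w[valid, 2], w[valid, 3], eps
        )
        labels[valid] = np.asarray(EPISTASIS_CLASSES, dtype=object)[codes]
    names = np.asarray(library, dtype=object)
    return pd.DataFrame(
        {
            "g0": names[corners[:, 0]],
            "gA": names[corners[:, 1]],
            "gB": names[corners[:, 2]],
            "gAB": names[corners[:, 3]],
            "W0": w[:, 0],
            "WA": w[:, 1],
            "WB": w[:, 2],
            "WAB": w[:, 3],
            "class": labels,
        }
    )


@dataclass(frozen=True)
class RoughnessSlope:
    """Additive-model fit summary: RMS residual r, mean |coefficient| s, r/s."""

    roughness: float
    slope: float
    ratio: float
    intercept: float
    coefficients: pd.Series


def roughness_slope(
    fitness: pd.Series,
    spec: LibrarySpec,
    reference_genotype: str | None = None,
) -> RoughnessSlope:
    """Least-squares additive fit of fitness on indicator-coded alleles.

    The design has an intercept plus, for each position, one indicator per
    allele other than the reference genotype's (default: wild-type).
    ``r`` is the RMS residual over the fitted genotypes, ``s`` the mean
    absolute value of the allele coefficients; their ratio is 0 for exactly
    additive landscapes.  Genotypes with missing fitness are excluded.
    """
    ref = reference_genotype or spec.wild_type_alleles
    if len(ref) != spec.n_positions:
        raise ValueError("reference genotype length mismatch")
    library = build_library(spec)
    values = fitness.reindex(library).to_numpy(dtype=float)
    keep = np.isfinite(values)
    digits = genotype_digit_matrix(spec.n_positions)[keep]
    y = values[keep]

    columns = []
    names = []
    for p in range(spec.n_positions):
        ref_code = ALLELE_INDEX[ref[p]]
        for code, allele in enumerate(RNA_ALPHABET):
            if code == ref_code:
                continue
            columns.append((digits[:, p] == code).astype(float))
            names.append(f"pos{p}:{allele}")
    X = np.column_stack([np.ones(y.size)] + columns)
    if y.size < X.shape[1]:
        raise ValueError(
            f"need at least {X.shape[1]} genotypes with fitness, got {y.size}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    r = float(np.sqrt(np.mean(resid**2)))
    s = float(np.mean(np.abs(coef[1:])))
    ratio = r / s if s > 0 else float("nan")
    return RoughnessSlope(
        roughness=r,
        slope=s,
        ratio=ratio,
        intercept=float(coef[0]),
        coefficients=pd.Series(coef[1:], index=names),
    )


@dataclass(frozen=True)
class TrendResult:
    rho: float
    pvalue: float
    n: int


def ruggedness_trend(mg_values, ruggedness_values) -> TrendResult:
    """Spearman correlation of ruggedness against magnesium concentration.

    Replicates enter as separate points.  Constant input yields NaN rho
    (undefined ranks) rather than an exception.
    """
    mg = np.asarray(mg_values, dtype=float)
    rug = np.asarray(ruggedness_values, dtype=float)
    if mg.size != rug.size:
        raise ValueError("mg and ruggedness vectors must have equal length")
    if mg.size < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.allclose(rug, rug[0]) or np.allclose(mg, mg[0]):
        return TrendResult(rho=float("nan"), pvalue=float("nan"), n=mg.size)
    res = stats.spearmanr(mg, rug)
    return TrendResult(
        rho=float(res.statistic), pvalue=float(res.pvalue), n=mg.size
    )
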