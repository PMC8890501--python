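"""Synthetic ground truth and simulated selection/sequencing experiments.

This module emulates the in vitro selection experiment end to end so that the
whole analysis pipeline can be exercised, and its estimates checked against a
known truth, without the original raw reads.  Each genotype's catalytic
activity follows a Hill titration curve in magnesium,

    a(m) = wmax * m**h / (k**h + m**h),

with genotype-specific maximum activity ``wmax`` and midpoint ``k`` (mM).
Mutations act on ``log(wmax)`` (mostly deleterious) and shift ``k`` upward
(mostly destabilizing: more magnesium needed to fold), with sparse pairwise
interaction terms on both scales.  The midpoint interactions are what make
epistasis magnesium-dependent: a compensatory pair that restores folding
stability matters at low magnesium but is silenced once magnesium saturates
folding — the mechanism by which landscape ruggedness relaxes at high
magnesium.  The wild-type is treated as the stability optimum of this local
landscape: midpoints are clipped below at the wild-type baseline
(``k_min = k_baseline``), so compensatory interactions can at best restore,
never exceed, wild-type folding stability — which is what confines
fitter-than-wild-type variants to saturating magnesium.  The default Hill
slope (3) reflects the cooperative magnesium dependence of group I intron
folding.

Selection is modeled as proportional enrichment: the post-selection expected
proportion of a genotype is its pre-selection proportion weighted by its
activity at the given magnesium concentration, renormalized.  Sequencing is
multinomial sampling of both pools at a configurable depth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import (
    RNA_ALPHABET,
    ALLELE_INDEX,
    LibrarySpec,
    build_library,
    genotype_digit_matrix,
    rna_to_dna,
)

__all__ = [
    "GeneratorParams",
    "hill_activity",
    "sample_truth",
    "sample_pool",
    "selection_weights",
    "post_selection_proportions",
    "simulate_counts",
    "write_fastq",
    "simulate_experiment",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic truth and sequencing model.

    Scales: activity effects and their pairwise interactions act on
    ``log(wmax)``; midpoint shifts and their interactions act on ``k`` in mM.
    Sparsity values are the probability that a given pairwise term is active.
    """

    effect_mean: float = -0.4
    effect_sd: float = 0.35
    epistasis_mean: float = -0.1
    epistasis_sd: float = 0.2
    epistasis_sparsity: float = 0.2
    kshift_mean: float = 2.0
    kshift_sd: float = 1.5
    kshift_floor: float = -0.5
    k_epistasis_mean: float = -0.5
    k_epistasis_sd: float = 1.5
    k_epistasis_sparsity: float = 0.15
    dead_fraction: float = 0.05
    read_depth: int = 1_000_000
    pool_concentration: float = 5.0
    k_baseline: float = 2.0
    h_baseline: float = 3.0
    k_min: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        for fld in ("effect_sd", "epistasis_sd", "kshift_sd", "k_epistasis_sd"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be >= 0")
        for fld in ("epistasis_sparsity", "k_epistasis_sparsity", "dead_fraction"):
            if not 0.0 <= getattr(self, fld) <= 1.0:
                raise ValueError(f"{fld} must be in [0, 1]")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.pool_concentration <= 0:
            raise ValueError("pool_concentration must be > 0")
        if self.k_baseline <= 0 or self.k_min <= 0 or self.h_baseline <= 0:
            raise ValueError("k_baseline, k_min and h_baseline must be > 0")


def hill_activity(m, wmax, k, h):
    """Hill titration curve ``wmax * m**h / (k**h + m**h)``."""
    m = np.asarray(m, dtype=float)
    return wmax * m**h / (k**h + m**h)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_truth(
    spec: LibrarySpec, params: GeneratorParams, rng=None
) -> pd.DataFrame:
    """Draw a ground-truth table for every genotype in the library.

    Returns a DataFrame indexed by genotype with columns ``wmax_true``
    (dimensionless, wild-type = 1), ``k_true`` (mM), ``h_true`` and ``dead``.
    The wild-type row is fixed at (1, k_baseline, h_baseline, False); a
    mutant's ``log(wmax_true)`` is the sum of its mutations' effects plus any
    active pairwise interaction terms, and its ``k_true`` is the baseline plus
    the analogous midpoint sums, clipped below at ``k_min``.  Fully
    reproducible from the supplied seed.
    """
    rng = _as_rng(params.rng_seed if rng is None else rng)
    L = spec.n_positions
    wt = np.array([ALLELE_INDEX[c] for c in spec.wild_type_alleles])
    digits = genotype_digit_matrix(L)
    n = 4**L

    # Per-(position, allele) single-mutation terms; wild-type allele -> 0.
    effects = rng.normal(params.effect_mean, params.effect_sd, size=(L, 4))
    kshifts = rng.normal(params.kshift_mean, params.kshift_sd, size=(L, 4))
    kshifts = np.maximum(kshifts, params.kshift_floor)
    effects[np.arange(L), wt] = 0.0
    kshifts[np.arange(L), wt] = 0.0

    log_wmax = np.zeros(n)
    k_true = np.full(n, params.k_baseline)
    for p in range(L):
        log_wmax += effects[p, digits[:, p]]
        k_true += kshifts[p, digits[:, p]]

    # Sparse pairwise terms over (position i allele a, position j allele b).
    for i, j in itertools.combinations(range(L), 2):
        active_w = rng.random(size=(4, 4)) < params.epistasis_sparsity
        vals_w = rng.normal(params.epistasis_mean, params.epistasis_sd, size=(4, 4))
        active_k = rng.random(size=(4, 4)) < params.k_epistasis_sparsity
        vals_k = rng.normal(
            params.k_epistasis_mean, params.k_epistasis_sd, size=(4, 4)
        )
        for arr, act in ((vals_w, active_w), (vals_k, active_k)):
            arr *= act
            arr[wt[i], :] = 0.0  # interactions require a mutation at both sites
            arr[:, wt[j]] = 0.0
        log_wmax += vals_w[digits[:, i], digits[:, j]]
        k_true += vals_k[digits[:, i], digits[:, j]]

    dead = rng.random(n) < params.dead_fraction
    wt_index = int(np.sum((wt * 4 ** np.arange(L - 1, -1, -1))))
    dead[wt_index] = False

    wmax = np.exp(log_wmax)
    wmax[dead] = 0.0
    wmax[wt_index] = 1.0
    k_true = np.maximum(k_true, params.k_min)
    k_true[wt_index] = params.k_baseline

    return pd.DataFrame(
        {
            "wmax_true": wmax,
            "k_true": k_true,
            "h_true": np.full(n, params.h_baseline),
            "dead": dead,
        },
        index=pd.Index(build_library(spec), name="genotype"),
    )


def sample_pool(spec: LibrarySpec, params: GeneratorParams, rng=None) -> pd.Series:
    """Pre-selection pool proportions from a symmetric Dirichlet.

    Emulates uneven library synthesis; lower ``pool_concentration`` means a
    more uneven pool.
    """
    rng = _as_rng(params.rng_seed if rng is None else rng)
    library = build_library(spec)
    props = rng.dirichlet(np.full(len(library), params.pool_concentration))
    return pd.Series(props, index=pd.Index(library, name="genotype"))


def selection_weights(truth: pd.DataFrame, mg: float) -> pd.Series:
    """Per-genotype activity at ``mg`` mM (dead genotypes contribute 0)."""
    if mg <= 0:
        raise ValueError("mg must be > 0")
    act = hill_activity(mg, truth["wmax_true"], truth["k_true"], truth["h_true"])
    return act.where(~truth["dead"], 0.0)


def post_selection_proportions(
    truth: pd.DataFrame, mg: float, pool: pd.Series
) -> pd.Series:
    """Expected post-selection proportions: pool weighted by activity, renormalized."""
    weights = pool * selection_weights(truth.loc[pool.index], mg)
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("no genotype in the pool has activity at this mg")
    return weights / total


def simulate_counts(
    truth: pd.DataFrame, mg: float, depth: int, pool: pd.Series, rng
) -> tuple[pd.Series, pd.Series]:
    """Multinomial read counts for the pre- and post-selection pools.

    ``pre ~ Multinomial(depth, pool)`` and
    ``post ~ Multinomial(depth, pool * activity(mg) renormalized)``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = _as_rng(rng)
    pool_p = np.asarray(pool, dtype=float)
    if not np.isclose(pool_p.sum(), 1.0, atol=1e-8):
        raise ValueError("pool proportions must sum to 1")
    pool_p = pool_p / pool_p.sum()
    post_p = post_selection_proportions(truth, mg, pool).to_numpy()
    pre = rng.multinomial(depth, pool_p)
    post = rng.multinomial(depth, post_p)
    return (
        pd.Series(pre, index=pool.index, name="count"),
        pd.Series(post, index=pool.index, name="count"),
    )


def write_fastq(
    counts: pd.Series,
    spec: LibrarySpec,
    path,
    contaminant_fraction: float = 0.0,
    rng=None,
    quality: int = 40,
) -> int:
    """Write one FASTQ record per read (DNA alphabet, constant quality).

    Each read is the reference sequence with the genotype's alleles
    substituted at the variable positions.  A ``contaminant_fraction`` of
    reads additionally carry one random substitution outside the variable
    positions, which the counting stage must reject.  Returns the number of
    records written.
    """
    if not 0.0 <= contaminant_fraction <= 1.0:
        raise ValueError("contaminant_fraction must be in [0, 1]")
    rng = _as_rng(0 if rng is None else rng)
    fixed_positions = [
        i
        for i in range(len(spec.reference_sequence))
        if i not in set(spec.variable_positions)
    ]
    dna_alphabet = "ACGT"

    def records():
        read_no = 0
        for genotype, count in counts.items():
            if count <= 0:
                continue
            base = rna_to_dna(spec.full_sequence(genotype))
            for _ in range(int(count)):
                read_no += 1
                seq = base
                if contaminant_fraction and rng.random() < contaminant_fraction:
                    pos = int(rng.choice(fixed_positions))
                    alts = [c for c in dna_alphabet if c != base[pos]]
                    seq = base[:pos] + str(rng.choice(alts)) + base[pos + 1 :]
                rec = SeqRecord(
                    Seq(seq), id=f"read{read_no}", description=""
                )
                rec.letter_annotations["phred_quality"] = [quality] * len(seq)
                yield rec

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        return SeqIO.write(records(), handle, "fastq")


def simulate_experiment(
    spec: LibrarySpec,
    params: GeneratorParams,
    seed: int | None = None,
    depth: int | None = None,
) -> dict:
    """Full synthetic experiment at the count-table level.

    Draws one truth table and one pre-selection pool, then for every
    (mg level, replicate) draws an independent pre/post multinomial count
    pair.  Returns ``{"truth": DataFrame, "pool": Series, "counts": {(mg,
    replicate, phase): Series}}`` with phase in {"pre", "post"}.  All
    randomness flows from one seed.
    """
    seed = params.rng_seed if seed is None else seed
    depth = params.read_depth if depth is None else depth
    root = np.random.SeedSequence(seed)
    s_truth, s_pool, s_counts = root.spawn(3)
    truth = sample_truth(spec, params, rng=np.random.default_rng(s_truth))
    pool = sample_pool(spec, params, rng=np.random.default_rng(s_pool))
    counts: dict[tuple[float, int, str], pd.Series] = {}
    count_rng = np.random.default_rng(s_counts)
    for mg in spec.mg_levels:
        for rep in range(1, spec.replicates + 1):
            pre, post = simulate_counts(truth, mg, depth, pool, count_rng)
            counts[(mg, rep, "pre")] = pre
            counts[(mg, rep, "post")] = post
    return {"truth": truth, "pool": pool, "counts": counts}
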