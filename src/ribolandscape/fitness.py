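"""Relative fitness from pre/post-selection proportions.

Fitness of genotype g is its enrichment ratio normalized to the wild-type:

    W(g) = [post(g) / pre(g)] / [post(wt) / pre(wt)],

so the wild-type has fitness 1 exactly in every condition and replicate.
Genotypes absent before selection are *missing* (NaN), not zero — their
enrichment is undefined; genotypes present before but absent after selection
have fitness 0.  No pseudocounts are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationError",
    "compute_fitness",
    "aggregate_replicates",
    "FitnessLandscape",
]


class NormalizationError(ValueError):
    """Wild-type absent pre- or post-selection; fitness cannot be normalized."""


def compute_fitness(
    pre: pd.Series, post: pd.Series, wild_type: str
) -> pd.Series:
    """Per-genotype relative fitness from one pre/post proportion pair.

    Returns a float Series aligned to ``pre``'s index: NaN where ``pre == 0``
    (missing), 0 where ``pre > 0`` and ``post == 0``.
    """
    pre = pre.astype(float)
    post = post.reindex(pre.index).fillna(0.0).astype(float)
    if wild_type not in pre.index:
        raise NormalizationError(f"wild-type {wild_type!r} absent from tables")
    wt_pre = float(pre.loc[wild_type])
    wt_post = float(post.loc[wild_type])
    if wt_pre <= 0 or wt_post <= 0:
        raise NormalizationError(
            f"wild-type {wild_type!r} has zero proportion "
            f"(pre={wt_pre}, post={wt_post}); cannot normalize"
        )
    wt_ratio = wt_post / wt_pre
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = post / pre
    fitness = ratio / wt_ratio
    fitness[pre == 0] = np.nan
    fitness.name = "fitness"
    return fitness


def aggregate_replicates(replicates: Mapping[int, pd.Series]) -> pd.DataFrame:
    """Replicate mean and coefficient of variation per genotype.

    ``mean_fitness`` is the arithmetic mean of the per-replicate fitness
    values (missing replicates excluded; ``n_reps`` reports how many were
    used); ``cv`` is the sample (ddof=1) standard deviation over the mean,
    defined only where the mean is positive and at least two replicates are
    present.  Genotypes missing in every replicate keep NaN mean.
    """
    frame = pd.DataFrame(dict(replicates))
    n = frame.notna().sum(axis=1)
    mean = frame.mean(axis=1, skipna=True)
    sd = frame.std(axis=1, ddof=1, skipna=True)
    cv = sd / mean
    cv[(mean <= 0) | (n < 2)] = np.nan
    out = pd.DataFrame(
        {"mean_fitness": mean, "cv": cv, "n_reps": n.astype(int)}
    )
    out.index.name = "genotype"
    return out


class FitnessLandscape:
    """Per-condition, per-replicate fitness values in long form.

    Wraps a DataFrame with columns ``genotype, mg_mM, replicate, fitness``
    and provides slices as genotype-indexed Series.
    """

    COLUMNS = ["genotype", "mg_mM", "replicate", "fitness"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.table = table[self.COLUMNS].copy()

    @classmethod
    def from_slices(
        cls, slices: Mapping[tuple[float, int], pd.Series]
    ) -> "FitnessLandscape":
        """Build from ``{(mg, replicate): fitness Series}``."""
        rows = []
        for (mg, rep), fit in slices.items():
            df = fit.rename("fitness").rename_axis("genotype").reset_index()
            df["mg_mM"] = mg
            df["replicate"] = rep
            rows.append(df)
        return cls(pd.concat(rows, ignore_index=True))

    @property
    def mg_levels(self) -> list[float]:
        return sorted(self.table["mg_mM"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.table["replicate"].unique())

    def slice(self, mg: float, replicate: int | None = None) -> pd.Series:
        """Fitness Series at one mg level: one replicate, or replicate mean."""
        sub = self.table[self.table["mg_mM"] == mg]
        if sub.empty:
            raise KeyError(f"no data at mg={mg}")
        if replicate is not None:
            sub = sub[sub["replicate"] == replicate]
            if sub.empty:
                raise KeyError(f"no data at mg={mg}, replicate={replicate}")
            return sub.set_index("genotype")["fitness"]
        return sub.groupby("genotype")["fitness"].mean()

    def aggregate(self, mg: float) -> pd.DataFrame:
        sub = self.table[self.table["mg_mM"] == mg]
        reps = {
            rep: grp.set_index("genotype")["fitness"]
            for rep, grp in sub.groupby("replicate")
        }
        return aggregate_replicates(reps)

    def profile(self, genotype: str) -> pd.Series:
        """Replicate-mean fitness across mg levels for one genotype (mg-indexed)."""
        sub = self.table[self.table["genotype"] == genotype]
        return sub.groupby("mg_mM")["fitness"].mean()

    def profiles(self) -> pd.DataFrame:
        """Wide matrix genotype x mg of replicate-mean fitness."""
        return self.table.pivot_table(
            index="genotype", columns="mg_mM", values="fitness", aggfunc="mean"
        )

    def to_tsv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FitnessLandscape":
        return cls(pd.read_csv(path, sep="\t"))
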