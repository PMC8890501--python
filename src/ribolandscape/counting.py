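"""Variant counting: merged amplicon reads -> per-genotype count tables.

Reads are matched against the wild-type reference with wildcards at the
variable positions, exactly as the selection experiment's counting step:
a read is accepted only if it equals the reference everywhere outside the
variable positions (substitution-only, exact length; reads with indels,
ambiguous bases, or off-target mutations are rejected) and the alleles at the
variable positions identify its genotype.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .genotypes import LibrarySpec, build_library, dna_to_rna, rna_to_dna

__all__ = [
    "Matcher",
    "CountTable",
    "CountingError",
    "EmptyPoolError",
    "compile_matcher",
    "count_reads",
    "proportions",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CountingError(RuntimeError):
    pass


class EmptyPoolError(ValueError):
    """No read matched any library genotype; proportions are undefined."""


@dataclass(frozen=True)
class Matcher:
    """Compiled wildcard matcher for one library design.

    ``match`` returns the genotype (RNA alleles at the variable positions) of
    an accepted read, or None for a rejected one.  Matching is
    case-insensitive and U/T-equivalent; with ``allow_reverse_complement``
    the reverse-complement orientation is also tried.
    """

    spec: LibrarySpec
    allow_reverse_complement: bool = False
    _regex: re.Pattern = field(init=False, repr=False)

    def __post_init__(self):
        ref = rna_to_dna(self.spec.reference_sequence)
        var = set(self.spec.variable_positions)
        pattern = "".join(
            "([ACGT])" if i in var else re.escape(c) for i, c in enumerate(ref)
        )
        object.__setattr__(self, "_regex", re.compile(pattern))

    def match(self, read: str) -> str | None:
        seq = rna_to_dna(read)
        m = self._regex.fullmatch(seq)
        if m is None and self.allow_reverse_complement:
            m = self._regex.fullmatch(seq.translate(_COMPLEMENT)[::-1])
        if m is None:
            return None
        return dna_to_rna("".join(m.groups()))


@dataclass
class CountTable:
    """Per-genotype read counts for one condition (mg level, replicate, phase)."""

    counts: pd.Series
    total_matched: int
    total_rejected: int
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if int(self.counts.sum()) != self.total_matched:
            raise ValueError("sum of counts must equal total_matched")

    @property
    def total_reads(self) -> int:
        return self.total_matched + self.total_rejected

    def proportions(self) -> pd.Series:
        return proportions(self)

    def to_tsv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = self.counts.rename("count").rename_axis("genotype").reset_index()
        df.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {
                "total_matched": self.total_matched,
                "total_rejected": self.total_rejected,
                "condition": self.condition,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2)
            )

    @classmethod
    def from_tsv(cls, path, condition: dict | None = None) -> "CountTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        counts = df.set_index("genotype")["count"]
        meta_path = path.with_suffix(path.suffix + ".json")
        rejected = 0
        meta_condition = {}
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            rejected = int(meta.get("total_rejected", 0))
            meta_condition = meta.get("condition", {})
        return cls(
            counts=counts,
            total_matched=int(counts.sum()),
            total_rejected=rejected,
            condition=condition or meta_condition,
        )

    @classmethod
    def from_series(
        cls, counts: pd.Series, condition: dict | None = None, rejected: int = 0
    ) -> "CountTable":
        return cls(
            counts=counts.astype(int),
            total_matched=int(counts.sum()),
            total_rejected=rejected,
            condition=condition or {},
        )


def compile_matcher(
    spec: LibrarySpec, allow_reverse_complement: bool = False
) -> Matcher:
    return Matcher(spec=spec, allow_reverse_complement=allow_reverse_complement)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_reads(
    fastq_path, matcher: Matcher, condition: dict | None = None
) -> CountTable:
    """Stream a FASTQ file into a CountTable (order-independent result).

    Every accepted read increments exactly one genotype; rejected reads are
    tallied.  The returned counts cover the full library (zeros included).
    """
    spec = matcher.spec
    tallies: dict[str, int] = {}
    rejected = 0
    record_index = 0
    try:
        with _open_maybe_gzip(fastq_path) as handle:
            for record in SeqIO.parse(handle, "fastq"):
                record_index += 1
                genotype = matcher.match(str(record.seq))
                if genotype is None:
                    rejected += 1
                else:
                    tallies[genotype] = tallies.get(genotype, 0) + 1
    except ValueError as exc:
        raise CountingError(
            f"malformed FASTQ record near record {record_index + 1} "
            f"in {fastq_path}: {exc}"
        ) from exc
    library = build_library(spec)
    counts = pd.Series(
        [tallies.get(g, 0) for g in library],
        index=pd.Index(library, name="genotype"),
        name="count",
    )
    return CountTable(
        counts=counts,
        total_matched=int(counts.sum()),
        total_rejected=rejected,
        condition=condition or {},
    )


def proportions(table: CountTable | pd.Series) -> pd.Series:
    """Counts divided by the total matched to any variant (sums to 1)."""
    counts = table.counts if isinstance(table, CountTable) else table
    total = int(counts.sum())
    if total == 0:
        raise EmptyPoolError("no reads matched any library genotype")
    return counts / total
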