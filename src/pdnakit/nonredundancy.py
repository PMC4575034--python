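"""Superfamily-non-redundant resampling of protein–DNA complex collections.

A single non-redundant subset (one representative domain per superfamily)
is too small to represent a large collection, so many random subsets are
drawn and statistics are aggregated across them. The number of subsets
needed to hit the best solution with confidence is approximated by
x = -ln(p)/f, where p is the accepted miss probability and f the fraction
of subsets that are best; p = f = 0.01 gives 461, rounded up from 460.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DomainAssignment",
    "SubsetSpec",
    "required_subsets",
    "interacting_superfamilies",
    "sample_subsets",
    "kmer_jaccard",
    "homology_filter",
    "aggregate_subsets",
]


@dataclass(frozen=True)
class DomainAssignment:
    """One domain of one chain, labelled with its superfamily."""

    complex_id: str
    chain_id: str
    start: int
    end: int
    superfamily_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain range inverted: {self.start} > {self.end}")

    def contains(self, chain_id: str, seq_number: int) -> bool:
        return self.chain_id == chain_id and self.start <= seq_number <= self.end


@dataclass(frozen=True)
class SubsetSpec:
    """One sampled non-redundant subset, reproducible from its seed."""

    subset_index: int
    complex_ids: frozenset[str]
    seed: int


def required_subsets(p: float, f: float) -> int:
    """Number of random subsets needed: ceil(-ln(p)/f)."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if not (0 < f <= 1):
        raise ValueError("f must be in (0, 1]")
    return math.ceil(-math.log(p) / f)


def interacting_superfamilies(
    records: Iterable,
    assignments: Iterable[DomainAssignment],
) -> tuple[dict[str, set[str]], set[str]]:
    """Map each complex to the superfamilies of its DNA-contacting domains.

    A complex is *excluded* (second return value) when any of its contacting
    residues falls outside every assigned domain — the removal rule for
    proteins with unassigned interacting regions.
    """
    by_complex: dict[str, list[DomainAssignment]] = {}
    for a in assignments:
        by_complex.setdefault(a.complex_id, []).append(a)

    mapping: dict[str, set[str]] = {}
    excluded: set[str] = set()
    for rec in records:
        cid = rec.complex_id
        if cid in excluded:
            continue
        domains = by_complex.get(cid, [])
        hits = {d.superfamily_id for d in domains if d.contains(rec.aa_chain, rec.aa_seq)}
        if hits:
            mapping.setdefault(cid, set()).update(hits)
        else:
            excluded.add(cid)
            mapping.pop(cid, None)
    return mapping, excluded


def sample_subsets(
    complex_sfs: Mapping[str, set[str]],
    n_subsets: int,
    seed: int,
) -> list[SubsetSpec]:
    """Draw maximal random subsets with no superfamily represented twice.

    Each subset shuffles the complexes and greedily admits any complex that
    introduces no already-seen superfamily; a complex spanning several
    superfamilies blocks all of them. Deterministic under ``seed``.
    """
    if not complex_sfs:
        raise ValueError("empty complex collection")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    ids = sorted(complex_sfs)
    children = np.random.SeedSequence(seed).spawn(n_subsets)
    subsets = []
    for index, child in enumerate(children):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(ids))
        seen: set[str] = set()
        members = []
        for k in order:
            cid = ids[k]
            sfs = complex_sfs[cid]
            if sfs and not (sfs & seen):
                members.append(cid)
                seen.update(sfs)
        subsets.append(SubsetSpec(index, frozenset(members), seed))
    return subsets


def kmer_jaccard(seq_a: str, seq_b: str, k: int = 5) -> float:
    """Jaccard similarity of the k-mer sets of two protein sequences.

    A cheap stand-in for a pairwise homology search: it scores highly when
    the sequences share long identical segments (as homologous domains do)
    and near zero for unrelated sequences.
    """
    if len(seq_a) < k or len(seq_b) < k:
        return 1.0 if seq_a == seq_b else 0.0
    kmers_a = {seq_a[i:i + k] for i in range(len(seq_a) - k + 1)}
    kmers_b = {seq_b[i:i + k] for i in range(len(seq_b) - k + 1)}
    union = kmers_a | kmers_b
    return len(kmers_a & kmers_b) / len(union) if union else 0.0


def homology_filter(
    subset: SubsetSpec,
    sequences: Mapping[str, str],
    similar: Callable[[str, str], bool] | None = None,
    threshold: float = 0.5,
) -> bool:
    """True (keep) iff no member pair is similar; False means drop the subset.

    ``similar`` is a pluggable pairwise predicate on sequences; the default
    flags pairs whose 5-mer Jaccard similarity exceeds ``threshold``.
    """
    if similar is None:
        similar = lambda a, b: kmer_jaccard(a, b) > threshold
    members = sorted(subset.complex_ids)
    for i, ci in enumerate(members):
        for cj in members[i + 1:]:
            if similar(sequences[ci], sequences[cj]):
                return False
    return True


def aggregate_subsets(per_subset_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cell-wise mean and population SD of count tables across subsets.

    Returns a DataFrame with a two-level column index (statistic, original
    column). With fewer than two subsets the SD is undefined and reported
    as zero with a warning.
    """
    if not per_subset_tables:
        raise ValueError("no tables to aggregate")
    stacked = np.stack([t.values.astype(float) for t in per_subset_tables])
    mean = stacked.mean(axis=0)
    if len(per_subset_tables) < 2:
        warnings.warn("fewer than 2 subsets: SD undefined, reported as 0")
        sd = np.zeros_like(mean)
    else:
        sd = stacked.std(axis=0, ddof=0)
    template = per_subset_tables[0]
    out = pd.concat(
        {
            "mean": pd.DataFrame(mean, index=template.index, columns=template.columns),
            "sd": pd.DataFrame(sd, index=template.index, columns=template.columns),
        },
        axis=1,
    )
    return out
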