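"""Gene-set collections and genomic co-location window sets.

Three kinds of collections feed the gene-pair enrichment analysis:
functional sets (GO-like, carried as GMT), gene-family sets (GMT) and
genomic co-location sets built here from gene coordinates by tiling each
chromosome with 1 Mb windows every 500 kb, so adjacent windows overlap by
half and a co-expressed cluster of physically adjacent genes always falls
entirely inside at least one window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import ConfigError, DataError


@dataclass
class GeneSetCollection:
    """Named gene sets with provenance.

    ``kind`` is one of ``functional``, ``family``, ``genomic``.  For
    genomic window sets the description encodes ``chrom:start-end``.
    """

    sets: dict[str, frozenset[str]]
    kind: str = "functional"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return sorted(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def window_gene_sets(
    ann: pd.DataFrame,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    min_genes: int = 3,
) -> GeneSetCollection:
    """Build co-location gene sets from sliding genomic windows.

    Windows start at 0, step_bp, 2*step_bp, ... on every chromosome; a gene
    belongs to a window iff its start coordinate lies in
    ``[w, w + window_bp)``.  With the 1 Mb / 500 kb defaults every gene
    belongs to exactly two windows except within the first step of a
    chromosome.  Windows with fewer than ``min_genes`` members are dropped.
    """
    if not (window_bp > step_bp > 0):
        raise ConfigError("require window_bp > step_bp > 0")
    if ann is None or len(ann) == 0:
        raise DataError("empty gene annotation")
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    n_steps_per_window = -(-window_bp // step_bp)  # ceil
    for row in ann.itertuples(index=False):
        start = int(row.start)
        # windows whose interval [w, w+window_bp) contains `start`
        last = (start // step_bp) * step_bp
        first = max(0, last - (n_steps_per_window - 1) * step_bp)
        w = first
        while w <= last:
            if w <= start < w + window_bp:
                name = f"{row.chromosome}:{w}-{w + window_bp}"
                sets.setdefault(name, set()).add(row.gene_id)
                descriptions[name] = name
            w += step_bp
    kept = {
        name: frozenset(members)
        for name, members in sets.items()
        if len(members) >= min_genes
    }
    return GeneSetCollection(
        sets=kept,
        kind="genomic",
        descriptions={name: descriptions[name] for name in kept},
    )


def filter_collection(
    c: GeneSetCollection,
    min_genes: int = 3,
    max_genes: int | None = None,
    universe: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Intersect sets with ``universe`` first, then apply size filters.

    The intersection-first order matters: enrichment p-values must count
    only genes that can actually appear in the analysis.  Empty sets are
    dropped; ``max_genes`` is an exclusive upper bound (a "< 1000 genes"
    style filter).
    """
    if min_genes < 1:
        raise ConfigError("min_genes must be >= 1")
    uni = None if universe is None else frozenset(universe)
    sets: dict[str, frozenset[str]] = {}
    for name, members in c.sets.items():
        if uni is not None:
            members = members & uni
        if len(members) < min_genes:
            continue
        if max_genes is not None and len(members) >= max_genes:
            continue
        sets[name] = members
    return GeneSetCollection(
        sets=sets,
        kind=c.kind,
        descriptions={n: c.descriptions.get(n, c.kind) for n in sets},
    )
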