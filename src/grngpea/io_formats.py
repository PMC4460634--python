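"""On-disk formats and expression-matrix preprocessing primitives.

Formats
-------
* expression matrices: TSV, header row of sample ids, first column gene ids
* gene sets: GMT (name, description, tab-separated members)
* gene coordinates: BED-like TSV (chrom, start, end, gene_id), 0-based
  half-open internally; 1-based inclusive inputs are converted at the
  boundary
* networks: 2-4 column TSV edge lists (gene_a, gene_b[, weight[, pvalue_adj]])

All writers emit a leading ``#`` comment with the tool version and the
parameters of the write, and no timestamps, so outputs are byte-identical
across reruns.

Preprocessing primitives: ``log1p_transform`` (natural log of 1+count),
``drop_zero_sd_genes`` (constant genes carry no dependency information and
break the correlation-based estimator) and ``collapse_duplicate_genes``
(per-sample median over rows sharing a gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError, FormatError
from .genesets import GeneSetCollection
from .network import Network, canonical_edge

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with identifier bookkeeping.

    Duplicate gene ids are tolerated in the container (they occur in raw
    probe-level data) and resolved by :func:`collapse_duplicate_genes`;
    missing values are rejected outright.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if self.values.size == 0:
            raise DataError("empty expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_genes(self, keep_rows: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(keep_rows)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
        )


def read_expression(path, collapse: str = "error") -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix.

    ``collapse`` controls duplicate gene ids: ``"error"`` rejects them,
    ``"median"`` collapses duplicates to the per-sample median.
    """
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    sample_ids: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if sample_ids is None:
                sample_ids = [f.strip() for f in fields[1:]]
                if not sample_ids:
                    raise FormatError(f"{path}:{lineno}: header has no sample ids")
                continue
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"found {len(fields)} (ragged row)"
                )
            gene_ids.append(fields[0].strip())
            row = []
            for col, cell in enumerate(fields[1:], start=2):
                cell = cell.strip()
                if not cell:
                    raise FormatError(
                        f"{path}:{lineno}: blank cell in column {col} "
                        f"(gene {fields[0]!r}, sample {sample_ids[col - 2]!r})"
                    )
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                    ) from None
            rows.append(row)
    if sample_ids is None or not rows:
        raise FormatError(f"{path}: empty expression matrix")
    m = ExpressionMatrix(gene_ids, sample_ids, np.asarray(rows, dtype=float))
    if len(set(m.gene_ids)) != len(m.gene_ids):
        if collapse == "median":
            m = collapse_duplicate_genes(m, stat="median")
        elif collapse == "error":
            raise FormatError(f"{path}: duplicate gene ids (set collapse='median')")
        else:
            raise ConfigError(f"unknown collapse policy {collapse!r}")
    return m


def write_expression(m: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grn-gpea v{__version__} expression matrix "
                 f"genes={m.n_genes} samples={m.n_samples}\n")
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def log1p_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each value x by log_e(1 + x); negative inputs are a domain error."""
    if np.any(m.values < 0):
        raise DataError("log1p_transform requires non-negative values")
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), np.log1p(m.values))


def drop_zero_sd_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose expression is constant across samples.

    Constant genes have an undefined correlation with every other gene and
    are removed before inference; row order is otherwise preserved.
    """
    sd = m.values.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    if keep.size == 0:
        raise DataError("all genes have zero standard deviation")
    if keep.size == m.n_genes:
        return m
    logger.info("drop_zero_sd_genes: removed %d of %d genes",
                m.n_genes - keep.size, m.n_genes)
    return m.subset_genes(keep)


def collapse_duplicate_genes(m: ExpressionMatrix, stat: str = "median") -> ExpressionMatrix:
    """Collapse rows sharing a gene id to one row via the per-sample median.

    The median is the only supported statistic (the rule used for multiple
    probe sets mapping to one gene); first-occurrence row order is kept.
    """
    if stat != "median":
        raise ConfigError(f"unsupported collapse statistic {stat!r}")
    if len(set(m.gene_ids)) == len(m.gene_ids):
        return m
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, gid in enumerate(m.gene_ids):
        if gid not in groups:
            groups[gid] = []
            order.append(gid)
        groups[gid].append(i)
    values = np.vstack([np.median(m.values[groups[g]], axis=0) for g in order])
    return ExpressionMatrix(order, list(m.sample_ids), values)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path, kind: str = "functional") -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, kind=kind, descriptions=descriptions)


def write_gmt(c: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grn-gpea v{__version__} gene sets kind={c.kind} n={len(c.sets)}\n")
        for name in sorted(c.sets):
            desc = c.descriptions.get(name, c.kind)
            fh.write("\t".join([name, desc, *sorted(c.sets[name])]) + "\n")


# ---------------------------------------------------------------------------
# Network edge lists
# ---------------------------------------------------------------------------


def read_network(path) -> Network:
    """Read a 2-4 column TSV edge list into a canonical simple graph.

    Reversed duplicate rows merge keeping the maximum weight; self-loop
    rows are dropped (count reported through the module logger).
    """
    net = Network()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or len(fields) > 4:
                raise FormatError(f"{path}:{lineno}: expected 2-4 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if fields[0].strip() == "gene_a":  # optional header row
                continue
            if a == b:
                n_self += 1
                continue
            try:
                weight = float(fields[2]) if len(fields) > 2 else 1.0
                pval = (
                    float(fields[3])
                    if len(fields) > 3 and fields[3].strip() not in ("", "NA")
                    else None
                )
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric weight/p-value") from None
            net.add_edge(a, b, weight=weight, pvalue_adj=pval, merge="max")
    if n_self:
        logger.warning("read_network: dropped %d self-loop rows from %s", n_self, path)
    return net


def write_network(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grn-gpea v{__version__} network nodes={net.n_nodes} "
                 f"edges={net.n_edges} B={net.B}\n")
        fh.write("gene_a\tgene_b\tweight\tpvalue_adj\n")
        for (a, b) in sorted(net.edges()):
            data = net.edges()[(a, b)]
            pv = "NA" if data.pvalue_adj is None else repr(float(data.pvalue_adj))
            fh.write(f"{a}\t{b}\t{repr(float(data.weight))}\t{pv}\n")


# ---------------------------------------------------------------------------
# Gene coordinates (BED-like)
# ---------------------------------------------------------------------------


def read_annotation(path, dialect: str = "bed0") -> pd.DataFrame:
    """Read chrom/start/end/gene_id coordinates.

    ``dialect="bed0"`` is 0-based half-open (the internal convention);
    ``dialect="one_based"`` converts 1-based inclusive coordinates.
    """
    if dialect not in ("bed0", "one_based"):
        raise ConfigError(f"unknown coordinate dialect {dialect!r}")
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected chrom, start, end, gene_id")
            chrom, start_s, end_s, gid = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
            if dialect == "one_based":
                start -= 1
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            records.append((chrom, start, end, gid))
    if not records:
        raise FormatError(f"{path}: empty annotation")
    return pd.DataFrame(records, columns=["chromosome", "start", "end", "gene_id"])


def write_annotation(ann: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grn-gpea v{__version__} gene coordinates (0-based half-open) "
                 f"n={len(ann)}\n")
        for row in ann.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.start}\t{row.end}\t{row.gene_id}\n")
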