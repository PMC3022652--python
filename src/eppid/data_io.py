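"""Tabular input/output and expression preprocessing.

Expression matrices are TSV files with a header row of sample identifiers and
gene identifiers in the first column; empty, ``NA`` or ``NaN`` cells are
treated as missing.  Protein-interaction networks are two-column TSV edge
lists.  Per-gene attribute tables are TSV with a mandatory ``gene_id`` column.

Preprocessing follows the standard microarray recipe: genes missing in more
than a fraction of samples are dropped, remaining holes are filled by
K-nearest-neighbour imputation over gene profiles (Euclidean distance on
mutually observed samples), and technical replicates (spot repeats, dye
swaps) are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: cell contents interpreted as missing (case-insensitive)
_MISSING_TOKENS = {"", "na", "nan", "null"}

ATTRIBUTE_COLUMNS = (
    "dN",
    "mRNA_abundance",
    "protein_abundance",
    "CAI",
    "dispensability",
    "pleiotropy",
    "interface_count",
)


# ---------------------------------------------------------------------------
# Expression datasets
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """One gene-expression matrix (genes x samples) with missing values as NaN.

    The sample count ``n`` of a dataset enters the Fisher z-transform of
    correlation coefficients downstream, so it is owned here.

    Parameters
    ----------
    dataset_id
        Short label for the dataset.
    values
        DataFrame indexed by gene id with sample ids as columns; ``NaN``
        encodes a missing measurement.
    replicate_groups
        Optional mapping ``sample_id -> group_id``; samples sharing a group
        are technical replicates and are averaged during preprocessing.
    """

    dataset_id: str
    values: pd.DataFrame
    replicate_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(
                f"{self.dataset_id}: duplicate gene ids {list(map(str, dupes[:5]))}"
            )
        if self.values.columns.has_duplicates:
            raise ValidationError(f"{self.dataset_id}: duplicate sample ids")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index


def read_expression_matrix(path, dataset_id: str) -> ExpressionDataset:
    """Parse a TSV expression matrix, recording missing cells.

    Raises
    ------
    ParseError
        If a row's field count disagrees with the header (the message names
        the 1-based line number).
    ValidationError
        On duplicate gene identifiers.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header must contain at least one sample column")
        samples = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(samples) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(samples) + 1} fields, "
                    f"got {len(parts)}"
                )
            genes.append(parts[0])
            rows.append(
                [
                    np.nan if cell.strip().lower() in _MISSING_TOKENS else float(cell)
                    for cell in parts[1:]
                ]
            )
    values = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=samples)
    return ExpressionDataset(dataset_id=dataset_id, values=values)


def write_expression_matrix(ds: ExpressionDataset, path) -> None:
    """Write a dataset back to TSV; round-trips values bit-identically."""
    ds.values.rename_axis("gene_id").to_csv(path, sep="\t", na_rep="NA")


def read_replicate_groups(path) -> dict[str, str]:
    """Read a two-column sidecar TSV mapping sample_id -> replicate group."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    return dict(zip(table["sample_id"], table["group"]))


def preprocess_expression(
    ds: ExpressionDataset,
    max_missing_frac: float = 0.30,
    k_impute: int = 10,
) -> ExpressionDataset:
    """Filter, impute and replicate-average an expression dataset.

    Genes missing in strictly more than ``max_missing_frac`` of samples are
    removed (a gene at exactly the threshold is retained).  Remaining missing
    cells are imputed as the mean of that sample's value over the
    ``k_impute`` nearest gene profiles, with Euclidean distance computed over
    mutually observed samples and rescaled by the shared-sample count.
    Technical replicates are then averaged.  The result has no missing
    values and is a fixed point of this function.
    """
    if k_impute < 1:
        raise ValidationError("k_impute must be >= 1")
    if not 0 <= max_missing_frac <= 1:
        raise ValidationError("max_missing_frac must be in [0, 1]")

    frac = ds.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: removed %d genes missing in >%.0f%% of samples",
            ds.dataset_id, n_dropped, 100 * max_missing_frac,
        )
    values = ds.values.loc[keep]
    if values.empty:
        raise ValidationError(f"{ds.dataset_id}: no genes left after missingness filter")

    all_missing_samples = values.columns[values.isna().all(axis=0)]
    if len(all_missing_samples):
        raise ValidationError(
            f"{ds.dataset_id}: samples with no observed values: "
            f"{list(all_missing_samples)}"
        )

    if values.isna().any().any():
        n_candidates = len(values) - 1
        k = k_impute
        if n_candidates < k:
            logger.warning(
                "%s: only %d candidate neighbour genes; imputing with K=%d",
                ds.dataset_id, n_candidates, n_candidates,
            )
            k = max(1, n_candidates)
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        values = pd.DataFrame(
            imputer.fit_transform(values.to_numpy()),
            index=values.index,
            columns=values.columns,
        )

    if ds.replicate_groups:
        groups = [ds.replicate_groups.get(s, s) for s in values.columns]
        # preserve first-occurrence column order
        order = list(dict.fromkeys(groups))
        averaged = values.T.groupby(pd.Series(groups, index=values.columns)).mean().T
        values = averaged[order]

    return ExpressionDataset(dataset_id=ds.dataset_id, values=values)


# ---------------------------------------------------------------------------
# Protein-interaction networks
# ---------------------------------------------------------------------------


@dataclass
class InteractionNetwork:
    """Undirected protein-protein interaction network.

    Wraps a :class:`networkx.Graph`; guarantees no self-loops and no
    duplicate edges regardless of pair orientation.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "InteractionNetwork":
        """Build a network from an iterable of (a, b) pairs.

        Self-loops are dropped and duplicate pairs collapsed, with a logged
        count of each.  ``nodes`` may add isolated proteins.
        """
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        n_self = 0
        n_dupe = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dupe += 1
                continue
            g.add_edge(a, b)
        if n_self or n_dupe:
            logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dupe)
        return cls(graph=g)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene) -> bool:
        return gene in self.graph

    def degree(self, gene) -> int:
        if gene not in self.graph:
            raise LookupError(f"gene {gene!r} not in network")
        return self.graph.degree(gene)

    def partners(self, gene) -> set:
        """``PPI_g``: the set of interaction partners of ``gene``."""
        if gene not in self.graph:
            raise LookupError(f"gene {gene!r} not in network")
        return set(self.graph.neighbors(gene))


def read_interaction_network(path, header: bool = False) -> InteractionNetwork:
    """Read a two-or-more-column TSV edge list (extra columns ignored)."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        if header:
            fh.readline()
        for lineno, line in enumerate(fh, start=2 if header else 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >=2 fields")
            edges.append((parts[0], parts[1]))
    if not edges:
        raise ValidationError(f"{path}: empty edge list")
    return InteractionNetwork.from_edges(edges)


def write_interaction_network(net: InteractionNetwork, path) -> None:
    pd.DataFrame(net.edges, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Gene attribute tables
# ---------------------------------------------------------------------------


def validate_attributes(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-gene attribute table indexed by gene_id.

    dN must be non-negative; pleiotropy and interface_count must be
    non-negative integers where present.
    """
    if table.index.has_duplicates:
        raise ValidationError("duplicate gene ids in attribute table")
    if "dN" in table and (table["dN"].dropna() < 0).any():
        bad = table.index[table["dN"] < 0][:5]
        raise ValidationError(f"negative dN for genes {list(map(str, bad))}")
    for col in ("pleiotropy", "interface_count"):
        if col in table:
            vals = table[col].dropna()
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValidationError(f"{col} must be a non-negative integer")
    return table


def read_attributes(path) -> pd.DataFrame:
    """Read a per-gene attribute TSV (mandatory ``gene_id`` column)."""
    table = pd.read_csv(path, sep="\t", na_values=["NA", "NaN", ""])
    if "gene_id" not in table.columns:
        raise ParseError(f"{path}: missing mandatory column 'gene_id'")
    table = table.set_index("gene_id")
    return validate_attributes(table)


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    """Write an output table as TSV with floats at 6 significant digits."""
    table.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA", index=index)
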