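"""Per-protein network metrics: PPID, ePPI, ePPID, APCC, betweenness.

PPID is a protein's interaction-partner count.  ePPI_g(i) counts, within
one expression dataset i, the partners of g declared significantly
positively co-expressed with g; ePPID is the maximum of ePPI_g(i) over all
expression datasets, an estimate of how many partners a protein interacts
with *permanently*.  APCC is the average Pearson correlation between a
protein's expression profile and those of its partners — the classical
date/party-hub score, computed here for comparison.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import CoexpressionNetwork
from .data_io import ExpressionDataset, InteractionNetwork
from .errors import ValidationError

logger = logging.getLogger(__name__)


def ppid(net: InteractionNetwork, gene) -> int:
    """Protein-protein interaction degree: number of interaction partners."""
    return net.degree(gene)


def eppi(net: InteractionNetwork, coexnet: CoexpressionNetwork, gene) -> int:
    """Count of partners of ``gene`` co-expressed with it in one dataset.

    Partners absent from the expression dataset count as not co-expressed.
    """
    coexpressed = coexnet.partners_of(gene)
    return len(net.partners(gene) & coexpressed)


def eppid(net: InteractionNetwork, coexnets, gene) -> int:
    """ePPID: maximal per-dataset co-expressed partner count."""
    coexnets = list(coexnets)
    if not coexnets:
        raise ValidationError("need at least one co-expression network")
    return max(eppi(net, cn, gene) for cn in coexnets)


def apcc(net: InteractionNetwork, ds: ExpressionDataset, gene) -> float:
    """Average Pearson correlation between ``gene`` and its partners in ``ds``.

    Returns NaN when the gene or all of its partners are absent from the
    dataset, or when a profile is constant.
    """
    if gene not in ds:
        return float("nan")
    partners = sorted(p for p in net.partners(gene) if p in ds)
    if not partners:
        return float("nan")
    x = ds.values.loc[gene].to_numpy(dtype=float)
    if np.std(x) == 0:
        return float("nan")
    rs = []
    for p in partners:
        y = ds.values.loc[p].to_numpy(dtype=float)
        if np.std(y) == 0:
            continue
        with np.errstate(invalid="ignore"):
            rs.append(np.corrcoef(x, y)[0, 1])
    return float(np.mean(rs)) if rs else float("nan")


def betweenness(net: InteractionNetwork) -> dict:
    """Shortest-path betweenness per protein (unnormalized, endpoints excluded).

    Multiple shortest paths between a pair contribute fractionally to each
    intermediate, so the contributions over intermediates sum to one per
    pair.  Disconnected components are handled naturally: unreachable pairs
    contribute nothing.
    """
    return nx.betweenness_centrality(net.graph, normalized=False)


def edge_coexpression_status(net: InteractionNetwork, coexnets) -> pd.DataFrame:
    """Label each PPI edge as co-expressed (declared in >=1 dataset) or not."""
    rows = []
    coexnets = list(coexnets)
    for a, b in net.edges:
        status = any(cn.is_coexpressed(a, b) for cn in coexnets)
        rows.append((a, b, status))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "coexpressed"])


def noncoexpressed_fraction(edge_status: pd.DataFrame) -> float:
    """Fraction of PPI edges not co-expressed in any dataset (in percent /100)."""
    if edge_status.empty:
        raise ValidationError("no edges")
    return float(1.0 - edge_status["coexpressed"].mean())


def compute_metric_table(
    net: InteractionNetwork,
    coexnets,
    datasets,
    require_expression: bool = True,
) -> pd.DataFrame:
    """Assemble the per-protein metric table.

    Columns: ``ppid``, one ``eppi_<dataset>`` per co-expression network,
    ``eppid``, ``apcc`` (mean of per-dataset APCC over datasets where
    defined), ``betweenness``, and an ``expressed`` flag (gene measured in
    at least one expression dataset).  With ``require_expression`` the table
    is restricted to expressed proteins, mirroring analyses limited to genes
    measurable on the arrays.
    """
    coexnets = list(coexnets)
    datasets = list(datasets)
    if not coexnets:
        raise ValidationError("need at least one co-expression network")
    genes = net.nodes
    bw = betweenness(net)

    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    table["ppid"] = [net.degree(g) for g in genes]
    for cn in coexnets:
        table[f"eppi_{cn.dataset_id}"] = [eppi(net, cn, g) for g in genes]
    eppi_cols = [f"eppi_{cn.dataset_id}" for cn in coexnets]
    table["eppid"] = table[eppi_cols].max(axis=1)
    apcc_per_ds = np.column_stack(
        [[apcc(net, ds, g) for g in genes] for ds in datasets]
    ) if datasets else np.full((len(genes), 1), np.nan)
    defined = np.isfinite(apcc_per_ds)
    with np.errstate(invalid="ignore"):
        sums = np.where(defined, apcc_per_ds, 0.0).sum(axis=1)
        counts = defined.sum(axis=1)
        table["apcc"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table["betweenness"] = [bw[g] for g in genes]
    measured = set()
    for ds in datasets:
        measured.update(ds.gene_ids)
    table["expressed"] = [g in measured for g in genes]
    if require_expression:
        n_dropped = int((~table["expressed"]).sum())
        if n_dropped:
            logger.info("excluding %d proteins absent from all expression datasets", n_dropped)
        table = table[table["expressed"]]
    return table
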