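"""Thresholded gene co-expression networks.

Two genes are declared co-expressed in one expression dataset when the
Fisher z-score of their Pearson correlation passes BOTH a
Benjamini-Hochberg FDR cut on the one-sided (positive-correlation) p-value
and a percentile cut placing the pair among the top ``per`` fraction of all
pairwise correlations in the dataset.  Only positive correlations are
considered; negative correlation is treated as absence of co-expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)

_ATANH_CLIP = 1.0 - 1e-15


def fisher_z(r, n: int):
    """Fisher transform of a Pearson correlation into an approximate z-score.

    ``z = sqrt(n - 3) * atanh(r)``, which under independence of the two
    profiles approximately follows a standard normal distribution; ``n`` is
    the sample count of the expression dataset.

    Accepts scalars or arrays; requires ``|r| < 1`` and ``n >= 4``.
    """
    if n < 4:
        raise ValidationError(f"sample count n={n} < 4; Fisher transform needs n-3 > 0")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValidationError("correlation magnitude must be < 1")
    z = math.sqrt(n - 3) * np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def positive_coexpression_pvalue(z):
    """One-sided p-value for the null of no *positive* correlation.

    Upper-tail standard normal probability of the Fisher z-score.
    """
    p = stats.norm.sf(np.asarray(z, dtype=float))
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues, m: int | None = None):
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adjusted_i = min_{j: p_j >= p_i} m * p_j / rank(p_j)``, clipped to 1.
    ``m`` defaults to ``len(pvalues)`` but may be larger, e.g. when the
    supplied p-values are a computed subset of a known-size test family.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m_total = p.size if m is None else int(m)
    if m_total < p.size:
        raise ValidationError("m must be at least len(pvalues)")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m_total / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adjusted, 0.0, 1.0, out=adjusted)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


@dataclass
class CoexpressionNetwork:
    """Declared significantly positively co-expressed gene pairs of one dataset."""

    dataset_id: str
    n: int
    pairs: frozenset
    fdr_threshold: float
    per_threshold: float
    z_percentile_cut: float
    table: pd.DataFrame = field(repr=False, default=None)
    n_zero_variance: int = 0
    _adjacency: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        adjacency: dict = {}
        for a, b in self.pairs:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        self._adjacency = adjacency

    def __len__(self) -> int:
        return len(self.pairs)

    def is_coexpressed(self, a, b) -> bool:
        return tuple(sorted((a, b))) in self.pairs

    def partners_of(self, gene) -> set:
        return set(self._adjacency.get(gene, ()))


def _pair_index_to_ij(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode linear upper-triangle pair codes into (i, j) with i < j."""
    # row i starts at offset i*n - i*(i+1)/2 - i - ... ; invert by quadratic formula
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8 * codes)) / 2).astype(np.int64)
    row_start = i * n - (i * (i + 1)) // 2  # code of pair (i, i+1)... minus (i+1)
    j = codes - row_start + i + 1
    return i, j


def build_coexpression_network(
    ds: ExpressionDataset,
    fdr: float = 0.001,
    per: float = 0.10,
    percentile_mode: str = "exact",
    sample_pairs: int = 100_000,
    seed: int | None = None,
    genes=None,
) -> CoexpressionNetwork:
    """Build the per-dataset co-expression network.

    All pairwise Pearson correlations among the dataset's genes are
    computed; each pair gets a Fisher z-score and a one-sided p-value which
    is BH-adjusted over the full family of C(G, 2) tests.  The percentile
    cut is the ``1 - per`` quantile of all pairwise z-scores, either by
    exact enumeration or, in ``sampled`` mode, estimated from at least
    ``sample_pairs`` uniformly drawn pairs under ``seed``.

    Zero-variance gene profiles yield undefined correlations; their pairs
    are treated as non-co-expressed and counted in ``n_zero_variance``.

    Parameters
    ----------
    genes
        Optional restriction of the pair universe to a gene subset (e.g.
        genes present in a PPI dataset).
    """
    if not ds.is_complete:
        raise ValidationError(f"{ds.dataset_id}: dataset has missing values; preprocess first")
    if not 0 < fdr <= 1 or not 0 < per <= 1:
        raise ValidationError("fdr and per thresholds must lie in (0, 1]")
    if percentile_mode not in ("exact", "sampled"):
        raise ValidationError(f"unknown percentile_mode {percentile_mode!r}")

    values = ds.values
    if genes is not None:
        values = values.loc[values.index.intersection(list(genes))]
    gene_ids = values.index.to_numpy()
    n_genes = len(gene_ids)
    if n_genes < 2:
        raise ValidationError(f"{ds.dataset_id}: need at least 2 genes")
    n = values.shape[1]
    if n < 4:
        raise ValidationError(f"{ds.dataset_id}: need at least 4 samples")

    arr = values.to_numpy(dtype=float)
    stds = arr.std(axis=1)
    zero_var = stds == 0.0
    n_zero_variance = int(zero_var.sum())
    if n_zero_variance:
        logger.info(
            "%s: %d zero-variance gene profiles treated as non-co-expressed",
            ds.dataset_id, n_zero_variance,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)

    iu, ju = np.triu_indices(n_genes, k=1)
    r = corr[iu, ju]
    valid = np.isfinite(r)
    r_valid = np.clip(r[valid], -_ATANH_CLIP, _ATANH_CLIP)
    z = fisher_z(r_valid, n)
    p = positive_coexpression_pvalue(z)
    m = n_genes * (n_genes - 1) // 2
    p_adj = bh_adjust(p, m=m)

    if percentile_mode == "exact":
        z_cut = float(np.quantile(z, 1.0 - per)) if per < 1.0 else float(np.min(z))
    else:
        rng = np.random.default_rng(seed)
        k = min(max(sample_pairs, 100_000), m)
        codes = rng.integers(0, m, size=k)
        si, sj = _pair_index_to_ij(codes.astype(np.int64), n_genes)
        rs = corr[si, sj]
        rs = np.clip(rs[np.isfinite(rs)], -_ATANH_CLIP, _ATANH_CLIP)
        zs = fisher_z(rs, n)
        z_cut = float(np.quantile(zs, 1.0 - per)) if per < 1.0 else float(np.min(zs))

    declared = (r_valid > 0) & (p_adj <= fdr) & (z >= z_cut)

    vi = iu[valid][declared]
    vj = ju[valid][declared]
    table = pd.DataFrame(
        {
            "gene_a": gene_ids[vi],
            "gene_b": gene_ids[vj],
            "r": r[valid][declared],
            "z": z[declared],
            "p": p[declared],
            "p_adj": p_adj[declared],
        }
    )
    pairs = frozenset(
        tuple(sorted((a, b))) for a, b in zip(table["gene_a"], table["gene_b"])
    )
    return CoexpressionNetwork(
        dataset_id=ds.dataset_id,
        n=n,
        pairs=pairs,
        fdr_threshold=fdr,
        per_threshold=per,
        z_percentile_cut=z_cut,
        table=table,
        n_zero_variance=n_zero_variance,
    )


def read_coexpression_pairs(path, dataset_id: str, n: int = 0) -> CoexpressionNetwork:
    """Rehydrate a declared-pair table written by the pipeline."""
    table = pd.read_csv(path, sep="\t")
    pairs = frozenset(
        tuple(sorted((a, b))) for a, b in zip(table["gene_a"], table["gene_b"])
    )
    return CoexpressionNetwork(
        dataset_id=dataset_id,
        n=n,
        pairs=pairs,
        fdr_threshold=float("nan"),
        per_threshold=float("nan"),
        z_percentile_cut=float("nan"),
        table=table,
    )
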