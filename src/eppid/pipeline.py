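"""End-to-end orchestration: preprocess -> coexpress -> metrics -> classify -> analyze.

`analyze` is the library entry point used by the CLI, the test suite and
the acceptance script; `run` adds file IO, logging and a run manifest on
top of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification, coexpression, data_io, evo_stats, network_metrics
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    network_path: str = ""
    expression_paths: list = field(default_factory=list)
    attributes_path: str = ""
    output_dir: str = "eppid_out"
    fdr: float = 0.001
    per: float = 0.10
    percentile_mode: str = "exact"
    sample_pairs: int = 100_000
    max_missing_frac: float = 0.30
    k_impute: int = 10
    ratio_threshold: float = 0.5
    high_frac: float = 0.20
    singlish_max: int = 2
    min_partners: int = 5
    dn_constant: float = 0.001
    count_constant: float = 0.1
    require_expression: bool = True
    pair_universe: str = "all"  # or "ppi"
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not 0 < self.fdr <= 1 or not 0 < self.per <= 1:
            raise ValidationError("fdr and per must lie in (0, 1]")
        if not 0 < self.ratio_threshold <= 1 or not 0 < self.high_frac < 1:
            raise ValidationError("ratio_threshold in (0,1], high_frac in (0,1)")
        if self.pair_universe not in ("all", "ppi"):
            raise ValidationError("pair_universe must be 'all' or 'ppi'")
        return self


def analyze(
    net: data_io.InteractionNetwork,
    datasets: list[data_io.ExpressionDataset],
    attributes: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs.

    Datasets are preprocessed if they still contain missing values.
    Returns a dict of DataFrames: ``metrics`` (with class labels),
    ``coexpression_summary``, ``edge_status``, ``correlations``,
    ``variance``, ``pcr``, ``group_tests`` plus the per-dataset
    co-expression networks under ``coexnets``.
    """
    cfg = (config or RunConfig()).validate()

    processed = [
        ds if ds.is_complete else data_io.preprocess_expression(
            ds, max_missing_frac=cfg.max_missing_frac, k_impute=cfg.k_impute
        )
        for ds in datasets
    ]
    restrict = set(net.nodes) if cfg.pair_universe == "ppi" else None
    coexnets = [
        coexpression.build_coexpression_network(
            ds,
            fdr=cfg.fdr,
            per=cfg.per,
            percentile_mode=cfg.percentile_mode,
            sample_pairs=cfg.sample_pairs,
            seed=cfg.seed + i,
            genes=restrict,
        )
        for i, ds in enumerate(processed)
    ]
    summary = pd.DataFrame(
        {
            "dataset": [cn.dataset_id for cn in coexnets],
            "n_samples": [cn.n for cn in coexnets],
            "n_pairs_declared": [len(cn) for cn in coexnets],
            "fdr": [cn.fdr_threshold for cn in coexnets],
            "per": [cn.per_threshold for cn in coexnets],
            "z_percentile_cut": [cn.z_percentile_cut for cn in coexnets],
            "n_zero_variance_genes": [cn.n_zero_variance for cn in coexnets],
        }
    )

    metrics = network_metrics.compute_metric_table(
        net, coexnets, processed, require_expression=cfg.require_expression
    )
    labeled = classification.annotate(
        metrics,
        attributes,
        ratio_threshold=cfg.ratio_threshold,
        high_frac=cfg.high_frac,
        singlish_max=cfg.singlish_max,
        min_partners=cfg.min_partners,
    )
    edge_status = network_metrics.edge_coexpression_status(net, coexnets)

    table = labeled.join(attributes, how="inner")
    correlations = _correlation_table(table)
    variance = _variance_table(table, cfg)
    pcr_table = _pcr_table(table, cfg)
    group = _group_test_table(table)

    return {
        "metrics": labeled,
        "coexpression_summary": summary,
        "coexnets": coexnets,
        "edge_status": edge_status,
        "correlations": correlations,
        "variance": variance,
        "pcr": pcr_table,
        "group_tests": group,
    }


def _correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman and abundance-controlled partial Spearman vs dN per metric."""
    rows = []
    for metric in ("ppid", "eppid", "betweenness"):
        sub = table[[metric, "dN", "protein_abundance"]].dropna()
        if len(sub) < 5:
            continue
        plain = evo_stats.spearman(sub[metric], sub["dN"])
        partial = evo_stats.partial_spearman(
            sub[metric], sub["dN"], sub["protein_abundance"],
            ctrl_name="protein_abundance",
        )
        rows.append(
            {
                "metric": metric,
                "n": plain.n,
                "rho": plain.rho,
                "p": plain.p,
                "rho_ctrl_abundance": partial.rho,
                "p_ctrl_abundance": partial.p,
            }
        )
    return pd.DataFrame(rows)


def _variance_table(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Percent dN variance explained, raw and controlling for log abundance."""
    rows = []
    for metric in ("ppid", "eppid", "betweenness"):
        sub = table[[metric, "dN", "protein_abundance"]].dropna()
        if len(sub) < 5:
            continue
        pct, p = evo_stats.variance_explained(sub[metric], sub["dN"])
        pct_c, p_c = evo_stats.variance_explained_controlled(
            sub[metric], sub["dN"], np.log(sub["protein_abundance"])
        )
        rows.append(
            {
                "metric": metric,
                "n": len(sub),
                "pct_variance": pct,
                "p": p,
                "pct_variance_ctrl_abundance": pct_c,
                "p_ctrl_abundance": p_c,
            }
        )
    return pd.DataFrame(rows)


PCR_PREDICTORS = (
    "mRNA_abundance",
    "protein_abundance",
    "dispensability",
    "pleiotropy",
    "eppid",
    "betweenness",
)


def _pcr_table(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Principal-component-regression summary in the conventional layout."""
    cols = [c for c in PCR_PREDICTORS if c in table.columns]
    data = table[cols + ["dN"]].dropna()
    if len(data) < len(cols) + 2:
        return pd.DataFrame()
    result = evo_stats.pcr(
        data[cols],
        data["dN"],
        constants={"eppid": cfg.count_constant, "betweenness": cfg.count_constant},
        response_constant=cfg.dn_constant,
    )
    k = len(cols)
    out = pd.DataFrame(index=["pct_variance_dN", "p_value", "significance"] + cols)
    for j in range(k):
        out[f"PC{j + 1}"] = (
            [result.component_variance_pct[j], result.component_pvalues[j],
             result.significance_codes()[j]]
            + list(result.contribution_pct[f"PC{j + 1}"])
        )
    out["All"] = [result.total_variance_pct, float("nan"), ""] + [float("nan")] * k
    out.index.name = f"n={result.n}"
    return out


def _group_test_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-bin co-expressed vs non-co-expressed dN comparisons (+ SIN tests)."""
    rows = []
    classified = table[table["coexpr_class"].notna() & table["dN"].notna()]
    for bin_name in ("low", "medium", "high"):
        sub = classified[classified["ppid_bin"] == bin_name]
        co = sub.loc[sub["coexpr_class"] == classification.COEXPRESSED, "dN"]
        nc = sub.loc[sub["coexpr_class"] == classification.NON_COEXPRESSED, "dN"]
        if len(co) == 0 or len(nc) == 0:
            continue
        rows.append(
            {
                "comparison": f"{bin_name}_bin_coexpressed_lower",
                "n_lower": len(co),
                "n_higher": len(nc),
                "p": evo_stats.wilcoxon_one_sided(co, nc),
            }
        )
    if "four_class" in classified.columns:
        four = classified[classified["four_class"].notna()]
        cm = four.loc[four["four_class"] == "C-M", "dN"]
        for other in ("NC-S", "NC-M", "C-S"):
            grp = four.loc[four["four_class"] == other, "dN"]
            if len(cm) >= 3 and len(grp) >= 3:
                rows.append(
                    {
                        "comparison": f"C-M_lower_than_{other}",
                        "n_lower": len(cm),
                        "n_higher": len(grp),
                        "p": evo_stats.wilcoxon_one_sided(cm, grp),
                    }
                )
        if "interface_class" in four.columns and len(four) >= 8:
            counts = pd.crosstab(
                four["coexpr_class"] == classification.COEXPRESSED,
                four["interface_class"] == "multi",
            )
            if counts.shape == (2, 2):
                rows.append(
                    {
                        "comparison": "coexpressed_x_multi_interface_fisher",
                        "n_lower": int(counts.to_numpy().sum()),
                        "n_higher": 0,
                        "p": evo_stats.fisher_exact_2x2(counts.to_numpy()),
                    }
                )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> Path:
    """File-based pipeline run; writes all result tables plus a manifest."""
    cfg = config.validate()
    for path in [cfg.network_path, cfg.attributes_path, *cfg.expression_paths]:
        if not Path(path).exists():
            raise ValidationError(f"input file not found: {path}")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = data_io.read_interaction_network(cfg.network_path)
    datasets = [
        data_io.read_expression_matrix(p, dataset_id=Path(p).stem)
        for p in cfg.expression_paths
    ]
    attributes = data_io.read_attributes(cfg.attributes_path)
    logger.info(
        "inputs: %d proteins, %d edges, %d expression datasets, %d attribute rows",
        len(net.nodes), net.n_edges, len(datasets), len(attributes),
    )

    results = analyze(net, datasets, attributes, cfg)

    data_io.write_table(results["metrics"], outdir / "metrics.tsv")
    data_io.write_table(results["coexpression_summary"], outdir / "coexpression_summary.tsv", index=False)
    for cn in results["coexnets"]:
        data_io.write_table(cn.table, outdir / f"coexpression_pairs_{cn.dataset_id}.tsv", index=False)
    data_io.write_table(results["edge_status"], outdir / "edge_status.tsv", index=False)
    data_io.write_table(results["correlations"], outdir / "correlations.tsv", index=False)
    data_io.write_table(results["variance"], outdir / "variance.tsv", index=False)
    data_io.write_table(results["pcr"], outdir / "pcr.tsv")
    data_io.write_table(results["group_tests"], outdir / "group_tests.tsv", index=False)

    manifest = asdict(cfg)
    manifest["n_proteins"] = len(net.nodes)
    manifest["n_edges"] = net.n_edges
    manifest["n_pairs_declared"] = [len(cn) for cn in results["coexnets"]]
    manifest["n_analyzed"] = int(len(results["metrics"]))
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("wrote results to %s", outdir)
    return outdir
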