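"""End-to-end orchestration: quantify -> normalize -> classify -> coexpr ->
ordinate -> BEST, with plain-TSV intermediates and a re-derivable report.

Every stage's output is persisted as TSV in the configured output
directory so each number in the report can be traced to an inspectable
intermediate; re-running an identical configuration reproduces the report
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import coexpression as cx
from . import ordination as ordn
from .quantify import quantify as quantify_sams, write_audit_tsv
from . import simulate as sim
from . import state as st
from . import transform as tf
from .containers import CountMatrix, DataError
from .genes import GeneModelSet

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Full parameterization of one pipeline run.

    Either ``simulate`` is set (synthetic inputs are generated) or
    ``counts_tsv``/``sam_paths`` plus ``env_tsv`` point at real inputs.
    ``seed`` is mandatory: every random stage derives its stream from it.
    """

    outdir: str = "phagestate_run"
    seed: Optional[int] = None

    # inputs (exactly one source of counts)
    simulate: Optional[dict[str, Any]] = None
    counts_tsv: Optional[str] = None
    sam_paths: Optional[dict[str, str]] = None
    gene_models_gff3: Optional[str] = None
    env_tsv: Optional[str] = None

    # quantification
    min_length_fraction: float = 0.9
    min_identity_fraction: float = 0.9
    tie_policy: str = "random_best"
    containment: str = "both_within"

    # classification
    rpob_gene: str = "rpoB"
    lytic_marker: str = "gp091"
    lysogeny_markers: tuple[str, ...] = ("gp135", "gp136")
    min_total_pairs: int = 10
    tie_band: float = 0.0

    # co-expression
    run_collapse: bool = True
    linkage: str = "average"
    collapse_alpha: float = 0.05
    collapse_n_perm: int = 999
    edge_p: float = 0.1
    k_clusters: int = 3

    # ordination / BEST
    nmds_restarts: int = 50
    envfit_n_perm: int = 999
    best_max_subset_size: int = 6
    best_n_perm: int = 99

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineConfigError("config must set an explicit seed")
        sources = sum(
            x is not None for x in (self.simulate, self.counts_tsv, self.sam_paths)
        )
        if sources != 1:
            raise PipelineConfigError(
                "exactly one of simulate / counts_tsv / sam_paths must be set"
            )
        if self.sam_paths is not None and self.gene_models_gff3 is None:
            raise PipelineConfigError("sam_paths input requires gene_models_gff3")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "lysogeny_markers" in data and data["lysogeny_markers"] is not None:
            data["lysogeny_markers"] = tuple(data["lysogeny_markers"])
        sim_cfg = data.get("simulate")
        if sim_cfg and "library_size_range" in sim_cfg:
            sim_cfg["library_size_range"] = tuple(sim_cfg["library_size_range"])
        return cls(**data)


def summarize_by_group(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int = 0,
    n_perm: int = 2000,
) -> dict[str, Any]:
    """Cross-tabulate state calls by station and by month.

    Reports a chi-square independence statistic per grouping; when any
    expected cell is below 5 the p-value comes from a seeded permutation
    of the state labels instead of the asymptotic reference.
    """
    unmatched = [s for s in calls.index if s not in metadata.index]
    if unmatched:
        raise DataError(f"samples missing from metadata: {unmatched}")
    keep = calls[calls["state"] != "excluded"]
    out: dict[str, Any] = {}
    rng = np.random.default_rng(seed)
    for group in ("station", "month"):
        g = metadata.loc[keep.index, group]
        table = pd.crosstab(keep["state"], g)
        entry: dict[str, Any] = {"table": table}
        if table.shape[0] < 2 or table.shape[1] < 2:
            entry.update(chi2=0.0, p_value=1.0, method="degenerate")
        else:
            chi2, p_asym, dof, expected = stats.chi2_contingency(table)
            if (expected < 5).any():
                # permutation reference: shuffle state labels, recompute the
                # (uncorrected) chi-square statistic with fixed margins
                s_codes, s_levels = pd.factorize(keep["state"])
                g_codes, g_levels = pd.factorize(g)
                S, G = len(s_levels), len(g_levels)
                col_tot = np.bincount(g_codes, minlength=G)
                n_tot = len(s_codes)

                def chi2_stat(sc: np.ndarray) -> float:
                    obs_t = np.bincount(sc * G + g_codes, minlength=S * G).reshape(S, G)
                    exp_t = np.outer(np.bincount(sc, minlength=S), col_tot) / n_tot
                    mask = exp_t > 0
                    return float(((obs_t - exp_t)[mask] ** 2 / exp_t[mask]).sum())

                obs = chi2_stat(s_codes)
                exceed = 0
                for _ in range(n_perm):
                    exceed += chi2_stat(rng.permutation(s_codes)) >= obs
                entry.update(
                    chi2=float(chi2),
                    p_value=float((1 + exceed) / (n_perm + 1)),
                    method=f"permutation(B={n_perm})",
                )
            else:
                entry.update(chi2=float(chi2), p_value=float(p_asym), method="asymptotic")
        out[group] = entry
    return out


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Resolve counts, env table and metadata from the configured source."""
    truth = None
    if config.simulate is not None:
        simcfg = sim.SimConfig(**{**config.simulate, "seed": config.seed})
        models, truth, counts = sim.simulate_dataset(simcfg)
        env = truth.env_table
        metadata = truth.metadata
        models.write_gff3(outdir / "gene_models.gff3")
        truth.state_per_sample.to_frame().to_csv(outdir / "truth_states.tsv", sep="\t")
        env.rename_axis("sample").to_csv(
            outdir / "env.tsv", sep="\t", float_format="%.10g"
        )
        phage_genes = [g.gene_id for g in models if g.genome_id == sim.PHAGE_GENOME]
    elif config.sam_paths is not None:
        models = GeneModelSet.read_gff3(config.gene_models_gff3)
        counts = quantify_sams(
            config.sam_paths,
            models,
            config.min_length_fraction,
            config.min_identity_fraction,
            config.tie_policy,
            config.containment,
            seed=config.seed,
        )
        write_audit_tsv(counts, outdir / "exclusion_audit.tsv")
        env = pd.read_csv(config.env_tsv, sep="\t", index_col=0) if config.env_tsv else None
        metadata = None
        phage_genes = [g.gene_id for g in models if g.genome_id != sim.HOST_GENOME]
    else:
        counts = CountMatrix.read_tsv(config.counts_tsv)
        env = pd.read_csv(config.env_tsv, sep="\t", index_col=0) if config.env_tsv else None
        metadata = None
        phage_genes = [g for g in counts.genes if g != config.rpob_gene and not str(g).startswith("host_")]
    if metadata is None:
        # parse T{month}_{station} labels when present, else one group
        months, stations = [], []
        for s in counts.samples:
            name = str(s)
            try:
                m, stn = name.split("_", 1)
                months.append(int(m.lstrip("T")))
                stations.append(int(stn.split("r")[0]))
            except ValueError:
                months.append(0)
                stations.append(0)
        metadata = pd.DataFrame({"station": stations, "month": months}, index=counts.samples)
    return counts, env, metadata, phage_genes, truth


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the run report (also persisted).

    Stage order: (simulate|quantify|load) -> negligible-sample exclusion
    -> normalizations -> state classification + marker correlations ->
    co-expression clustering (+ optional collapse) -> Bray-Curtis + nMDS
    + envfit + BEST -> grouped state summary.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stages": []}

    def stage(name: str, **params):
        report["stages"].append({"stage": name, "params": params})
        logger.info("stage %s: %s", name, params)

    counts, env, metadata, phage_genes, truth = _load_inputs(config, outdir)
    stage("inputs", n_genes=len(counts.genes), n_samples=len(counts.samples))
    counts.write_tsv(outdir / "counts.tsv")

    markers = st.MarkerSet(config.lytic_marker, tuple(config.lysogeny_markers))
    excluded = st.flag_negligible(
        counts, phage_genes, config.rpob_gene, config.min_total_pairs
    )
    stage("flag_negligible", min_total_pairs=config.min_total_pairs, excluded=excluded)
    kept = counts.drop_samples(list(excluded))

    # classification path: rpoB-normalized marker expression
    expr_rpob = tf.rpob_normalize(kept, config.rpob_gene)
    calls = st.classify_state(expr_rpob, markers, config.tie_band, excluded)
    st.write_state_calls(calls, outdir / "state_calls.tsv")
    stage("classify_state", tie_band=config.tie_band)

    # marker correlations on log2(x+10) absolute abundance
    expr_log = tf.log2_shift_matrix(kept)
    corr = st.marker_correlations(expr_log, markers)
    corr_df = st.correlations_frame(corr)
    corr_df.to_csv(outdir / "marker_correlations.tsv", sep="\t", index=False,
                   float_format="%.10g")
    stage("marker_correlations", method="t")

    # co-expression on phage genes, library-size normalized + log2(x+10)
    expr_cpm = tf.libsize_normalize(kept)
    phage_expr = tf.log2_shift_matrix(expr_cpm)
    phage_expr.values = phage_expr.values.loc[
        [g for g in phage_genes if g in phage_expr.values.index]
    ]
    assoc = cx.gene_association(phage_expr)
    dend = cx.cluster_genes(assoc, linkage=config.linkage)
    dend.write_newick(outdir / "dendrogram.nwk")
    if config.run_collapse:
        groups = cx.collapse_indistinguishable(
            dend,
            phage_expr,
            alpha=config.collapse_alpha,
            n_perm=config.collapse_n_perm,
            seed=config.seed,
        )
        cx.collapsed_groups_frame(groups).to_csv(
            outdir / "collapsed_branches.tsv", sep="\t", index=False
        )
    cluster_report = cx.summarize_clusters(
        dend, assoc, markers.all, k=min(config.k_clusters, len(dend.gene_ids)),
        edge_p=config.edge_p,
    )
    cluster_report.to_csv(outdir / "cluster_report.tsv", sep="\t")
    stage("coexpression", linkage=config.linkage, k=config.k_clusters,
          collapse=config.run_collapse)

    # ordination on sqrt(library-size normalized) phage expression
    expr_sqrt = tf.sqrt_transform(expr_cpm)
    expr_sqrt.values = expr_sqrt.values.loc[phage_expr.values.index]
    dist = ordn.bray_curtis(expr_sqrt)
    dist.write_tsv(outdir / "bray_curtis.tsv")
    ord_ = ordn.nmds(dist, n_restarts=config.nmds_restarts, seed=config.seed)
    ord_.coordinates.rename_axis("sample").to_csv(
        outdir / "nmds_coordinates.tsv", sep="\t", float_format="%.10g"
    )
    ordn.similarity_groups(dist).rename_axis("sample").to_csv(
        outdir / "similarity_groups.tsv", sep="\t"
    )
    stage("nmds", stress=ord_.stress, restarts=config.nmds_restarts,
          converged=ord_.converged)

    best_summary = None
    env_summary = None
    if env is not None:
        env_kept = env.loc[[s for s in dist.labels if s in env.index]]
        fit = ordn.envfit(ord_, env_kept, n_perm=config.envfit_n_perm, seed=config.seed)
        fit.to_csv(outdir / "envfit_vectors.tsv", sep="\t", float_format="%.10g")
        best = ordn.best_bioenv(
            dist,
            env_kept,
            max_subset_size=config.best_max_subset_size,
            n_perm=config.best_n_perm,
            seed=config.seed,
        )
        best.to_frame().to_csv(outdir / "best_report.tsv", sep="\t",
                               float_format="%.10g")
        best_summary = {
            "best_subset": list(best.best_subset),
            "rho": best.rho,
            "p_global": best.p_global,
        }
        env_summary = {
            "top_vectors": fit.sort_values("R2", ascending=False).head(5).index.tolist()
        }
        stage("best_bioenv", max_subset_size=config.best_max_subset_size,
              n_perm=config.best_n_perm)

    grouped = summarize_by_group(calls, metadata, seed=config.seed)
    state_counts = calls["state"].value_counts().to_dict()

    report.update(
        {
            "excluded_samples": excluded,
            "state_calls": state_counts,
            "state_by_station": grouped["station"]["table"].to_dict(),
            "state_by_month": grouped["month"]["table"].to_dict(),
            "group_tests": {
                g: {k: v for k, v in grouped[g].items() if k != "table"}
                for g in grouped
            },
            "marker_correlations": corr_df.to_dict(orient="records"),
            "clusters": cluster_report.drop(columns="genes").to_dict(orient="index"),
            "nmds_stress": ord_.stress,
            "best": best_summary,
            "envfit": env_summary,
        }
    )
    if truth is not None:
        merged = calls.join(truth.state_per_sample.rename("true_state"))
        comparable = merged[merged["state"].isin(["lytic", "lysogenic"])]
        acc = float((comparable["state"] == comparable["true_state"]).mean())
        report["state_call_accuracy_vs_truth"] = acc

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_default)
    )
    return report
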