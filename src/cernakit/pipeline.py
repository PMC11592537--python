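"""End-to-end pipeline: simulate -> preprocess -> DE -> network -> hubs ->
cohort statistics -> biomarker evaluation.

Stages communicate through files in the output directory, so any stage
can be re-run on its own, and every artifact carries the configuration
hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cernakit import io
from cernakit.blueprint import StudyBlueprint, paper_scale_blueprint
from cernakit.biomarker import comparison_report
from cernakit.clinical import fit_logistic, summarize_cohort
from cernakit.expression import (
    combat_adjust,
    de_directions,
    differential_expression,
    enrichment_test,
    intersect_gene_sets,
    quantile_normalize,
)
from cernakit.network import (
    build_cerna_network,
    centrality_table,
    extract_subnetwork,
    filter_by_confidence,
    select_hub_genes,
    write_node_attributes,
    write_sif,
)
from cernakit.simulate import (
    simulate_array,
    simulate_batched_expression,
    simulate_cohort,
    simulate_interactions,
    simulate_ppi,
)

log = logging.getLogger("cernakit.pipeline")


@dataclass
class RunConfig:
    """Thresholds, seed and outputs of one pipeline run."""

    blueprint: StudyBlueprint = field(default_factory=paper_scale_blueprint)
    outdir: str | Path = "cerna_run"
    fc_circ: float = 1.5
    fc_gene: float = 1.2
    p_threshold: float = 0.05
    ppi_score_cutoff: float = 0.4
    mir_gene_confidence: str = "very high"
    de_method: str = "student"

    def __post_init__(self) -> None:
        if self.fc_circ < 1 or self.fc_gene < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.ppi_score_cutoff <= 1:
            raise ValueError("ppi_score_cutoff must be in [0, 1]")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (Path, np.integer, np.floating)):
                return str(o)
            if isinstance(o, dict):
                return {str(k): v for k, v in o.items()}
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # the hash identifies the analysis, not its location
        payload = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run summary dict.

    Artifacts (TSV/CSV/SIF/JSON) are written under ``config.outdir``; a
    failure in any stage aborts with a stage-named error while earlier
    artifacts remain on disk.
    """
    bp = config.blueprint
    outdir = io.ensure_dir(config.outdir)
    cfg_hash = config.config_hash()
    summary: dict = {"seed": bp.seed, "config_hash": cfg_hash}
    logfile = outdir / "run.log"
    handler = logging.FileHandler(logfile)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        import cernakit

        log.info("cernakit %s; seed=%s; config=%s", cernakit.__version__, bp.seed, cfg_hash)

        stage = "simulate"
        try:
            array = simulate_array(bp)
            batched = simulate_batched_expression(bp)
            circ_mir, mir_gene = simulate_interactions(bp)
            ppi = simulate_ppi(bp)
            cohort = simulate_cohort(bp)
            io.write_expression(array, outdir / "circ_matrix.tsv", outdir / "circ_meta.tsv")
            io.write_expression(batched, outdir / "gene_matrix.tsv", outdir / "gene_meta.tsv")
            io.write_interactions(circ_mir, outdir / "circ_mir.tsv")
            io.write_interactions(mir_gene, outdir / "mir_gene.tsv")
            io.write_interactions(ppi, outdir / "ppi.tsv")
            io.write_cohort(cohort, outdir / "cohort.csv")
            with open(outdir / "immune_genes.txt", "w") as fh:
                fh.write("\n".join(bp.immune_gene_ids()) + "\n")

            stage = "circ_de"
            circ_norm = quantile_normalize(array)
            circ_de = differential_expression(
                circ_norm, config.fc_circ, config.p_threshold, config.de_method
            )
            circ_de.to_csv(outdir / "circ_de.tsv", sep="\t", index=False)
            circ_hits = de_directions(circ_de)
            summary["n_de_circ"] = len(circ_hits)
            summary["n_de_circ_up"] = sum(d == "up" for d in circ_hits.values())
            summary["n_de_circ_down"] = sum(d == "down" for d in circ_hits.values())

            # the merged expression sets arrive already normalised from
            # their source processing; batch adjustment is the remaining step
            stage = "gene_de"
            adjusted = combat_adjust(batched)
            gene_de = differential_expression(
                adjusted, config.fc_gene, config.p_threshold, config.de_method
            )
            gene_de.to_csv(outdir / "gene_de.tsv", sep="\t", index=False)
            gene_hits = de_directions(gene_de)
            immune = set(bp.immune_gene_ids())
            deirgs = intersect_gene_sets(gene_hits, immune)
            summary["n_deg"] = len(gene_hits)
            summary["n_deg_up"] = sum(d == "up" for d in gene_hits.values())
            summary["n_deg_down"] = sum(d == "down" for d in gene_hits.values())
            summary["n_deirg"] = len(deirgs)

            stage = "enrichment"
            enrich = enrichment_test(
                set(gene_hits),
                {"immune_related": immune},
                set(bp.gene_feature_ids()),
            )
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["immune_enrichment_p"] = float(enrich["p"].iloc[0])

            stage = "cerna_network"
            mir_gene_kept = filter_by_confidence(mir_gene, config.mir_gene_confidence)
            if circ_mir.empty or mir_gene_kept.empty:
                warnings.warn("empty interaction tables: ceRNA network is empty")
            deirg_dirs = dict(deirgs) if isinstance(deirgs, dict) else {}
            net = build_cerna_network(
                circ_mir[circ_mir["source"].isin(circ_hits)],
                mir_gene_kept[mir_gene_kept["target"].isin(deirg_dirs)],
                circ_hits,
                deirg_dirs,
            )
            write_sif(net, outdir / "cerna_network.sif")
            summary["cerna"] = net.composition()

            stage = "hubs"
            ppi_kept = filter_by_confidence(ppi, config.ppi_score_cutoff)
            cent = centrality_table(ppi_kept) if not ppi_kept.empty else pd.DataFrame()
            hubs = select_hub_genes(ppi_kept) if not ppi_kept.empty else pd.DataFrame()
            hub_ids = [] if hubs.empty else list(hubs["id"])
            hub_ids = [h for h in hub_ids if h in set(net.genes)]
            summary["ppi"] = {
                "n_nodes": 0 if ppi_kept.empty else int(
                    pd.unique(ppi_kept[["source", "target"]].values.ravel()).size
                ),
                "n_edges": int(len(ppi_kept)),
            }
            summary["hub_genes"] = hub_ids
            if not cent.empty:
                cent.to_csv(outdir / "ppi_centralities.tsv", sep="\t", index=False)

            stage = "subnetwork"
            sub = extract_subnetwork(net, hub_ids)
            write_sif(sub, outdir / "subnetwork.sif")
            write_node_attributes(sub, outdir / "subnetwork_nodes.tsv")
            summary["subnetwork"] = sub.composition()
            candidate_circs = sub.circrnas
            summary["candidate_circrnas"] = candidate_circs

            stage = "cohort_stats"
            binary = sorted(bp.covariate_prevalences)
            continuous = ["PLR", "NLR", "MLR", "hs_CRP"]
            cohort_summary = summarize_cohort(cohort, binary, continuous)
            cohort_summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
            summary["cohort_tests"] = {
                r["variable"]: {"statistic": r["statistic"], "p": r["p"]}
                for _, r in cohort_summary.iterrows()
            }

            markers = [m for m in bp.marker_effects if m in cohort.columns]
            y = (cohort["group"] == "CHD").astype(int)
            logistic_rows = []
            for marker in markers:
                x_uni = pd.DataFrame({marker: np.log2(cohort[marker])})
                uni = fit_logistic(y, x_uni)
                x_adj = pd.concat([x_uni, cohort[binary].astype(float)], axis=1)
                adj = fit_logistic(y, x_adj)
                logistic_rows.append(
                    {
                        "marker": marker,
                        "or_univariate": uni.odds_ratio(marker) if uni.converged else np.nan,
                        "p_univariate": float(uni.table.loc[marker, "p"]) if uni.converged else np.nan,
                        "or_adjusted": adj.odds_ratio(marker) if adj.converged else np.nan,
                        "p_adjusted": float(adj.table.loc[marker, "p"]) if adj.converged else np.nan,
                    }
                )
            logistic_table = pd.DataFrame(logistic_rows)
            logistic_table.to_csv(outdir / "marker_logistic.tsv", sep="\t", index=False)
            summary["marker_logistic"] = logistic_rows

            stage = "biomarker_eval"
            informative = [
                m for m in markers if bp.marker_effects.get(m, 1.0) != 1.0
            ] or markers[:1]
            marker_sets = {f"CM + {m}": [m] for m in informative}
            if len(informative) > 1:
                marker_sets[f"CM + {len(informative)} markers"] = informative
            report = comparison_report(cohort, binary, marker_sets)
            report.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
            summary["model_comparison"] = report.to_dict(orient="records")
        except Exception as exc:
            log.exception("stage %s failed", stage)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        header = {"config_hash": cfg_hash, "seed": bp.seed}
        with open(outdir / "summary.json", "w") as fh:
            json.dump({**header, **summary}, fh, indent=2, sort_keys=True, default=float)
        log.info("pipeline complete: %s", outdir / "summary.json")
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary
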