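"""End-to-end orchestration: DE → directional MCNs → hubs → replication.

The pipeline mirrors the discovery order of a network-based expression
study: fit differential expression on the discovery cohort, split the
significant genes by direction (up- and down-regulated networks are built
separately and never merged — co-regulated transcripts sub-connect), extract
and permutation-test each direction's minimal connected network, profile the
subnetworks' topology and select hub genes, and — when a validation cohort
is supplied — test hub replication under whole-list and restricted-list FDR.

A single global seed is fanned out to independent per-stage child seeds, so
stages are reproducible yet statistically independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import DETable, ExpressionMatrix, fit_de, quantile_normalize, split_by_direction
from .interactome import GeneList, read_edge_list, write_graph
from .replication import replicate_hubs
from .subnetwork import extract_mcn, permutation_test
from .topology import classify_nodes, profile_graph, select_hubs

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_expression"]


@dataclass
class PipelineConfig:
    """Inputs and tuning knobs of a full pipeline run.

    FDR defaults follow the two-cohort design this pipeline serves: 5% for
    the discovery dataset and a more lenient 10% for the validation cohort;
    10,000 permutations for the network null.
    """

    expression: str
    design: str
    interactome: str
    outdir: str
    validation_expression: str | None = None
    validation_design: str | None = None
    fdr_discovery: float = 0.05
    fdr_validation: float = 0.10
    n_perm: int = 10_000
    mcn_mode: str = "direct"
    mcn_statistic: str = "largest_component_frac"
    k_rescue: float = 1.0
    seed: int = 0
    quantile_norm: bool = True
    covariates: tuple[str, ...] = ()
    validation_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("fdr_discovery", "fdr_validation"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        self.covariates = tuple(self.covariates)
        self.validation_covariates = tuple(self.validation_covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def read_expression(expr_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Load an expression TSV (first column gene ID, header of sample IDs)
    and its design TSV (columns sample_id, group[, family_id, batch])."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id", dtype=str)
    return ExpressionMatrix(values=values, design=design)


def _write_detable(t: DETable, path: Path) -> None:
    out = t.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest of written artifacts.

    Writes (under ``cfg.outdir``): the DE table, per-direction subnetwork SIF
    files and permutation JSONs, per-direction topology/hub TSVs, a combined
    hub table, a replication TSV when validation data are given, a run log,
    and ``manifest.json`` listing every artifact.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    stage_seed = {
        "mcn_up": int(seeds[0].generate_state(1)[0] % (2**31)),
        "mcn_down": int(seeds[1].generate_state(1)[0] % (2**31)),
    }
    manifest: dict[str, object] = {"outputs": [], "seed": cfg.seed, "version": __version__}
    log_lines = [f"netpipe {__version__} seed={cfg.seed}"]

    def emit(name: str, path: Path) -> None:
        manifest["outputs"].append({"name": name, "path": str(path.relative_to(outdir))})

    def stage(name: str):
        log_lines.append(f"stage: {name}")
        log.info("stage: %s", name)

    try:
        stage("load")
        expr = read_expression(cfg.expression, cfg.design)
        graph = read_edge_list(cfg.interactome)
        if cfg.quantile_norm:
            expr = quantile_normalize(expr)

        stage("differential_expression")
        de = fit_de(expr, covariates=cfg.covariates, fdr_q=cfg.fdr_discovery)
        _write_detable(de, outdir / "detable.tsv")
        emit("de_table", outdir / "detable.tsv")
        up, down = split_by_direction(de, fdr_q=cfg.fdr_discovery)
        log_lines.append(f"DE: {len(up)} up, {len(down)} down at FDR {cfg.fdr_discovery}")

        all_hubs: list = []
        hub_rows = []
        for direction, genes in (("up", up), ("down", down)):
            stage(f"network_{direction}")
            if len(genes.as_set & graph.nodes) < 2:
                log_lines.append(f"{direction}: <2 mapped genes, network stage skipped")
                continue
            sub = extract_mcn(graph, genes, mode=cfg.mcn_mode)
            perm = permutation_test(
                graph,
                genes,
                n_perm=cfg.n_perm,
                seed=stage_seed[f"mcn_{direction}"],
                mode=cfg.mcn_mode,
                which=cfg.mcn_statistic,
            )
            sif = outdir / f"mcn_{direction}.sif"
            write_graph(sub.to_interactome(), sif, format="sif")
            emit(f"mcn_{direction}_sif", sif)
            pj = outdir / f"mcn_{direction}.json"
            pj.write_text(
                json.dumps(
                    {
                        "direction": direction,
                        "observed_stat": perm.observed_stat,
                        "statistic": perm.statistic,
                        "p_value": perm.p_value,
                        "n_perm": perm.n_perm,
                        "seed": perm.seed,
                        "n_members": len(sub.member_nodes),
                        "n_linkers": len(sub.linker_nodes),
                        "n_edges": len(sub.edges),
                    },
                    indent=2,
                )
            )
            emit(f"mcn_{direction}_result", pj)
            log_lines.append(
                f"{direction}: MCN {len(sub.member_nodes)} members, p={perm.p_value:.4g}"
            )

            stage(f"topology_{direction}")
            subnet = sub.to_interactome()
            if subnet.n_nodes < 2:
                log_lines.append(f"{direction}: subnetwork too small for topology")
                continue
            profile = profile_graph(subnet)
            classes = classify_nodes(profile.degree)
            hubs = select_hubs(profile, classes, k_rescue=cfg.k_rescue)
            prof_df = pd.DataFrame(
                {
                    "gene": profile.nodes,
                    "degree": [profile.degree[n] for n in profile.nodes],
                    "betweenness": [profile.betweenness[n] for n in profile.nodes],
                    "class": [classes[n] for n in profile.nodes],
                    "is_hub": [n in set(hubs.genes) for n in profile.nodes],
                }
            )
            ppath = outdir / f"topology_{direction}.tsv"
            prof_df.to_csv(ppath, sep="\t", index=False, float_format="%.6g")
            emit(f"topology_{direction}", ppath)
            for h in hubs:
                hub_rows.append(
                    {
                        "gene": h.gene,
                        "direction": direction,
                        "reason": h.reason,
                        "degree": h.degree,
                        "betweenness": h.betweenness,
                    }
                )
            all_hubs.extend(hubs.hubs)
            log_lines.append(f"{direction}: {len(hubs)} hub genes")

        hub_df = pd.DataFrame(
            hub_rows, columns=["gene", "direction", "reason", "degree", "betweenness"]
        )
        hpath = outdir / "hubs.tsv"
        hub_df.to_csv(hpath, sep="\t", index=False, float_format="%.6g")
        emit("hubs", hpath)

        if cfg.validation_expression and cfg.validation_design:
            stage("replication")
            val = read_expression(cfg.validation_expression, cfg.validation_design)
            if cfg.quantile_norm:
                val = quantile_normalize(val)
            hub_list = GeneList(list(dict.fromkeys(h.gene for h in all_hubs)), label="hubs")
            directions = {
                r["gene"]: ("up" if r["direction"] == "up" else "down") for r in hub_rows
            }
            if len(hub_list):
                rep = replicate_hubs(
                    val,
                    hub_list,
                    fdr_q=cfg.fdr_validation,
                    covariates=cfg.validation_covariates,
                    discovery_directions=directions,
                )
                rpath = outdir / "replication.tsv"
                rep.table.to_csv(rpath, sep="\t", float_format="%.6g")
                emit("replication", rpath)
                log_lines.append(
                    f"replication: {int(rep.table['sig_restricted'].fillna(False).sum())} "
                    f"hubs significant at restricted FDR {cfg.fdr_validation}"
                )
            else:
                log_lines.append("replication skipped: no hubs selected")
        else:
            log_lines.append("replication skipped: no validation inputs")
    except Exception as exc:  # annotate which stage failed, then re-raise
        failed = log_lines[-1] if log_lines else "unknown"
        raise RuntimeError(f"pipeline failed during [{failed}]: {exc}") from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    emit("run_log", outdir / "run.log")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
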