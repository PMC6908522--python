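"""End-to-end orchestration of the meta-analysis from a single config.

Stage order: normalization -> per-study SAM -> cross-study consensus
(winner genes) -> enrichment of the winner lists -> coexpression network of
the designated network study restricted to winners (+ supplied TF
candidates) -> one network per LD study -> CCP per (network study, LD)
pair -> survival report per requested gene. Every stage's outputs are
written as deterministic TSV/GraphML files and recorded, with SHA-256
hashes, in a JSON manifest alongside the config echo, seeds and stage
timings.

All stage outputs are pure functions of (inputs, config, root seed): the
root seed spawns per-study SAM permutation seeds by the same fixed
splitting rule the synthetic generator uses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .consensus import ConsensusTable, direction_matrix, winner_genes, winner_support
from .datatypes import ExpressionStudy, GeneSetCollection
from .errors import CoexmetaError, ConfigurationError
from .network import (GeneNetwork, build_network, ccp_intersection,
                      connected_components, hub_rank, select_threshold,
                      similarity_matrix, threshold_scan)
from .normalization import normalize_study
from .sam import SamResult, sam_analyze
from .simulate import SimulationConfig, SimulationTruth, gen_study_collection
from .survival import SurvivalCohort, gene_survival_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs.

    Studies come either from ``synthetic`` (a :class:`SimulationConfig`) or
    from ``study_files`` (list of ``(matrix_path, annotation_path)``).
    ``network_study`` designates the study whose winner-gene network anchors
    the CCP comparisons (default: the first LC study).
    """

    output_dir: str | Path
    synthetic: SimulationConfig | None = None
    study_files: list[tuple[str, str]] | None = None
    q_threshold: float = 0.01
    fdr_ceiling: float = 0.15
    permutations: int = 200
    min_total: int = 7
    min_lc: int = 5
    network_grid: tuple[float, float, float] = (0.50, 0.99, 0.01)
    network_window: int = 5
    network_min_edges: int = 10
    tf_candidates: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    survival_cohort_path: str | None = None
    survival_genes: list[str] = field(default_factory=list)
    network_study: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.study_files is None):
            raise ConfigurationError(
                "exactly one of synthetic / study_files must be given"
            )
        if not 0 < self.q_threshold < 1:
            raise ConfigurationError("q_threshold must lie in (0, 1)")
        if not 0 < self.fdr_ceiling <= 1:
            raise ConfigurationError("fdr_ceiling must lie in (0, 1]")
        if self.permutations < 50:
            raise ConfigurationError("permutations must be >= 50")
        if self.min_total < 1 or self.min_lc < 0:
            raise ConfigurationError("consensus thresholds out of range")


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the manifest."""

    studies: list[ExpressionStudy]
    truths: list[SimulationTruth] | None
    sam_results: dict[str, SamResult]
    consensus: ConsensusTable
    winner_up: set[str]
    winner_down: set[str]
    enrichment: dict[str, pd.DataFrame]
    networks: dict[str, GeneNetwork]
    thresholds: dict[str, float]
    ccps: dict[str, GeneNetwork]
    ccp_report: pd.DataFrame
    survival_reports: pd.DataFrame
    manifest: dict
    manifest_path: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_studies(config: PipelineConfig):
    if config.synthetic is not None:
        sim = dataclasses.replace(config.synthetic, seed=config.seed)
        pairs = gen_study_collection(sim)
        return [s for s, _ in pairs], [t for _, t in pairs]
    studies = [cio.read_expression_tsv(m, a) for m, a in config.study_files]
    return studies, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage; halt on the first stage error, keeping partial output."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "stages": {},
        "files": {},
        "halted_at": None,
    }
    t_all = time.perf_counter()
    stage = "load"
    try:
        t0 = time.perf_counter()
        studies, truths = _load_studies(config)
        n_lc = sum(s.disease_class == "LC" for s in studies)
        if n_lc < 1:
            raise ConfigurationError("pipeline requires >= 1 LC study")
        manifest["stages"]["load"] = round(time.perf_counter() - t0, 3)

        stage = "normalization"
        t0 = time.perf_counter()
        normalized = [normalize_study(s) for s in studies]
        for s in normalized:
            mpath = out / f"norm_{s.study_id}.tsv"
            apath = out / f"norm_{s.study_id}_samples.tsv"
            cio.write_expression_tsv(s, mpath, apath)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "sam"
        t0 = time.perf_counter()
        sam_seeds = np.random.SeedSequence(config.seed).spawn(len(normalized))
        sam_results: dict[str, SamResult] = {}
        for s, seed in zip(normalized, sam_seeds):
            res = sam_analyze(
                s, q_threshold=config.q_threshold,
                fdr_ceiling=config.fdr_ceiling,
                B=config.permutations, seed=seed,
            )
            sam_results[s.study_id] = res
            cio.write_table(res.table, out / f"degs_{s.study_id}.tsv",
                            index_label="feature")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "consensus"
        t0 = time.perf_counter()
        gene_results = {
            s.study_id: (sam_results[s.study_id].table, s.disease_class)
            for s in normalized
        }
        table = direction_matrix(gene_results, q_threshold=config.q_threshold)
        winner_up, winner_down = winner_genes(
            table, min_total=config.min_total, min_lc=config.min_lc
        )
        cio.write_table(table.directions, out / "consensus.tsv",
                        index_label="gene")
        cio.write_table(winner_support(table), out / "winners.tsv",
                        index_label="gene")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "enrichment"
        t0 = time.perf_counter()
        enrichment: dict[str, pd.DataFrame] = {}
        if config.gmt_path:
            collection = cio.read_gmt(config.gmt_path)
            universe = set(table.genes)
            for name, genes in (("up", winner_up), ("down", winner_down)):
                if genes:
                    enr = enrich_safe(genes, collection, universe)
                    enrichment[name] = enr
                    cio.write_table(enr, out / f"enrichment_{name}.tsv")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "network"
        t0 = time.perf_counter()
        net_sid = config.network_study or next(
            s.study_id for s in normalized if s.disease_class == "LC"
        )
        anchor = next(s for s in normalized if s.study_id == net_sid)
        gene_list = sorted((winner_up | winner_down | set(config.tf_candidates)))
        lo, hi, step = config.network_grid
        grid = np.round(np.arange(lo, hi + step / 2, step), 6)
        networks: dict[str, GeneNetwork] = {}
        thresholds: dict[str, float] = {}
        net_studies = [anchor] + [s for s in normalized if s.disease_class == "LD"]
        for s in net_studies:
            sim = similarity_matrix(s, gene_list)
            scan = threshold_scan(sim, grid)
            tau = select_threshold(scan, window=config.network_window,
                                   min_edges=config.network_min_edges)
            net = build_network(sim, tau)
            networks[s.study_id] = net
            thresholds[s.study_id] = tau
            cio.write_table(scan.frame(), out / f"scan_{s.study_id}.tsv")
            cio.write_graph(net, "edge-tsv", out / f"net_{s.study_id}.edges.tsv")
            cio.write_graph(net, "graphml", out / f"net_{s.study_id}.graphml",
                            similarity=sim)
        cio.write_table(hub_rank(networks[net_sid]),
                        out / f"hubs_{net_sid}.tsv", index_label="gene")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "ccp"
        t0 = time.perf_counter()
        ccps: dict[str, GeneNetwork] = {}
        rows = []
        for s in normalized:
            if s.disease_class != "LD":
                continue
            pair = f"{net_sid}_vs_{s.study_id}"
            ccp = ccp_intersection(networks[net_sid], networks[s.study_id])
            ccps[pair] = ccp
            comps = connected_components(ccp)
            rows.append({
                "pair": pair,
                "n_nodes": ccp.n_nodes,
                "n_edges": ccp.n_edges,
                "n_components": len(comps),
                "largest_component": len(comps[0]) if comps else 0,
            })
            cio.write_graph(ccp, "edge-tsv", out / f"ccp_{pair}.edges.tsv")
        ccp_report = pd.DataFrame(
            rows, columns=["pair", "n_nodes", "n_edges", "n_components",
                           "largest_component"])
        cio.write_table(ccp_report, out / "ccp_report.tsv")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "survival"
        t0 = time.perf_counter()
        surv_rows = []
        if config.survival_cohort_path and config.survival_genes:
            cohort_df = pd.read_csv(config.survival_cohort_path, sep="\t",
                                    index_col=0)
            cohort = SurvivalCohort(
                cohort_df[[c for c in cohort_df.columns
                           if c in ("time", "event")]].assign(
                    **{c: cohort_df[c] for c in cohort_df.columns
                       if c not in ("time", "event")})
            )
            for gene in config.survival_genes:
                if gene not in cohort_df.columns:
                    raise ConfigurationError(
                        f"survival gene {gene!r} missing from cohort columns"
                    )
                rep = gene_survival_report(gene, cohort_df[gene], cohort)
                surv_rows.append({
                    "gene": gene, "hazard_ratio": rep.hazard_ratio,
                    "ci_lower": rep.ci_lower, "ci_upper": rep.ci_upper,
                    "logrank_chi2": rep.logrank_chi2,
                    "logrank_p": rep.logrank_p,
                    "n_high": rep.n_high, "n_low": rep.n_low,
                })
        survival_reports = pd.DataFrame(
            surv_rows, columns=["gene", "hazard_ratio", "ci_lower", "ci_upper",
                                "logrank_chi2", "logrank_p", "n_high", "n_low"])
        if surv_rows:
            cio.write_table(survival_reports, out / "survival_report.tsv")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        manifest["halted_at"] = stage
        manifest["error"] = str(exc)
        _finalize_manifest(manifest, out, t_all)
        raise CoexmetaError(f"pipeline halted at stage {stage!r}: {exc}") from exc

    manifest_path = _finalize_manifest(manifest, out, t_all)
    return PipelineResult(
        studies=normalized, truths=truths, sam_results=sam_results,
        consensus=table, winner_up=winner_up, winner_down=winner_down,
        enrichment=enrichment, networks=networks, thresholds=thresholds,
        ccps=ccps, ccp_report=ccp_report, survival_reports=survival_reports,
        manifest=manifest, manifest_path=manifest_path,
    )


def enrich_safe(genes, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Enrichment restricted to list members present in the universe."""
    from .enrichment import enrich_collection

    genes = set(genes) & set(universe)
    return enrich_collection(genes, collection, universe)


def _finalize_manifest(manifest: dict, out: Path, t_all: float) -> Path:
    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
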