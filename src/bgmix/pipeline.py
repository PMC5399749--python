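"""End-to-end run: load data, anneal, EM-refine, report, write artifacts."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from .em import posterior_assignments, run_em
from .io import (
    load_mixed_dataset,
    write_assignments,
    write_model,
    write_responsibilities,
    write_trace,
)
from .model import PenaltySpec, count_parameters, log_likelihood_mixture, objective
from .report import clear_clusters, edges_to_frame, network_edges, reports_to_frame
from .search import AnnealSchedule, anneal_restarts

__all__ = ["PipelineConfig", "parse_penalty", "run_pipeline"]

logger = logging.getLogger(__name__)


def parse_penalty(text: str) -> PenaltySpec:
    """Parse a penalty name: aic, const:<lam>, bic, hq, caic."""
    text = text.strip().lower()
    if text == "aic":
        return PenaltySpec("constant", 2.0)
    if text.startswith("const:"):
        return PenaltySpec("constant", float(text.split(":", 1)[1]))
    if text == "bic":
        return PenaltySpec("bic")
    if text == "hq":
        return PenaltySpec("hannan_quinn")
    if text == "caic":
        return PenaltySpec("caic")
    raise ValueError(f"unknown penalty {text!r}")


@dataclass
class PipelineConfig:
    binary_path: str | None = None
    continuous_path: str | None = None
    out_dir: str = "bgmix_out"
    penalty: str = "aic"
    seed: int = 0
    binarize_pvalues: bool = False
    binding_threshold: float = 0.001
    normalize: bool = False
    r_threshold: float = 0.5
    b_threshold: float = 0.5
    restarts: int = 3
    k_init: int | None = None
    p_floor: float = 1e-3
    sigma_floor: float = 0.01
    t_init: float = 10.0
    t_final: float = 0.01
    cooling: float = 0.95
    moves_per_temperature: int = 50
    max_no_improve: int = 20
    em_tol: float = 1e-6
    em_max_iter: int = 500

    @staticmethod
    def from_file(path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key/value config file (YAML-compatible ``key: value`` lines);
        keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts under
    ``config.out_dir``.  Returns a summary dict (also logged)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("bgmix")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        run_id = f"run-{int(time.time())}-{config.seed}"
        logger.info("run id %s", run_id)
        logger.info("config: %s", yaml.safe_dump(vars(config), sort_keys=True).strip())
        stage = "load"
        data = load_mixed_dataset(
            config.binary_path,
            config.continuous_path,
            binarize_pvalues=config.binarize_pvalues,
            binding_threshold=config.binding_threshold,
            normalize=config.normalize,
        )
        logger.info("loaded %d entities, %d binary + %d continuous variables",
                    data.n, data.n_r, data.n_e)
        stage = "search"
        spec = parse_penalty(config.penalty)
        schedule = AnnealSchedule(
            t_init=config.t_init, t_final=config.t_final,
            cooling=config.cooling,
            moves_per_temperature=config.moves_per_temperature,
            max_no_improve=config.max_no_improve, seed=config.seed,
        )
        result = anneal_restarts(
            data, spec, schedule, k_init=config.k_init,
            n_restarts=config.restarts,
            p_floor=config.p_floor, sigma_floor=config.sigma_floor,
        )
        logger.info(
            "search: N_m=%d, classification objective=%.4f",
            result.best_clustering.n_clusters, result.best_objective,
        )
        stage = "refine"
        em = run_em(result.best_model, data, tol=config.em_tol,
                    max_iter=config.em_max_iter,
                    p_floor=config.p_floor, sigma_floor=config.sigma_floor)
        assign = posterior_assignments(em.gamma)
        final_loglik = log_likelihood_mixture(em.model, data)
        k = count_parameters(em.model.n_components, data.n_r, data.n_e)
        final_obj = objective(final_loglik, k, spec, data.n)
        logger.info(
            "EM: %d iterations, converged=%s, mixture loglik=%.4f, "
            "mixture objective=%.4f, N_m=%d",
            em.n_iter, em.converged, final_loglik, final_obj,
            em.model.n_components,
        )
        stage = "report"
        reports = clear_clusters(
            em.model, assign, data,
            r_threshold=config.r_threshold, b_threshold=config.b_threshold,
        )
        edges = network_edges(reports, em.model, data.binary_names,
                              b_threshold=config.b_threshold)
        stage = "write"
        write_assignments(assign, data.entity_ids, out / "assignments.tsv")
        write_model(em.model, data.binary_names, data.continuous_names,
                    out / "model_params.tsv")
        write_responsibilities(em.gamma.gamma, data.entity_ids,
                               out / "responsibilities.tsv")
        reports_to_frame(reports).to_csv(out / "cluster_report.tsv",
                                         sep="\t", index=False)
        edges_to_frame(edges).to_csv(out / "network_edges.tsv",
                                     sep="\t", index=False)
        write_trace(result.trace, out / "search_trace.tsv")
        summary = {
            "run_id": run_id,
            "n_entities": data.n,
            "n_clusters_search": result.best_clustering.n_clusters,
            "objective_search": result.best_objective,
            "n_clusters_final": em.model.n_components,
            "loglik_final": final_loglik,
            "objective_final": final_obj,
            "n_clear_clusters": sum(r.is_clear for r in reports),
            "n_edges": len(edges),
        }
        logger.info("summary: %s", summary)
        return summary
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
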