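"""End-to-end orchestration: preprocessing → pLDR → transfer → spGMM.

The pipeline is a DAG of pure transforms: each stage consumes the previous
stage's output and never mutates it.  A single top-level seed fans out to
per-stage seeds through ``numpy.random.SeedSequence`` so every stage can be
re-run in isolation with the seed the full run would have given it.  Every
selected hyperparameter and all defaults are echoed into a JSON run report.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import core_io, evaluate, pldr, spgmm, transfer
from .core_io import ExpressionMatrix, LabeledSource, SpatialCoords

_STAGES = ("pldr", "transfer", "spgmm")


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one sub-2^31 seed per stage from the top-level seed."""
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Flat configuration for a full TransST run."""

    source_expr: str = ""
    source_labels: str = ""
    target_expr: str = ""
    target_coords: str = ""
    expr_format: str = "csv"
    orientation: str = "spots_by_genes"
    q: int = 15
    n_hvg: int = 2000
    normalize: bool = True
    k_neighbors: int = 5
    lam: Any = "auto"                 # "auto" or a nonnegative float
    beta_grid: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 10) for i in range(11)]
    )
    K: Any = "auto"                   # "auto" or an int
    K_range: list[int] = field(default_factory=lambda: [2, 8])
    seed: int = 0
    out_dir: str = "transst_out"
    truth_labels: str = ""            # optional, enables ARI in the report

    def __post_init__(self) -> None:
        if self.q < 1 or self.k_neighbors < 1:
            raise ValueError("q and k_neighbors must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required; unseeded runs are not allowed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class RunResult:
    labels: np.ndarray
    factors: np.ndarray
    row_ids: list[str]
    report: dict


def run_pipeline_arrays(
    source: LabeledSource,
    target: ExpressionMatrix,
    coords: SpatialCoords,
    q: int = 15,
    k_neighbors: int = 5,
    lam: Any = "auto",
    beta_grid=None,
    K: Any = "auto",
    K_range=(2, 8),
    seed: int = 0,
    truth: np.ndarray | None = None,
) -> RunResult:
    """Run the three modeling stages on in-memory, already-preprocessed data.

    This is the computational core of :func:`run_pipeline`; file handling
    and preprocessing happen in the caller.
    """
    seeds = stage_seeds(seed)
    report: dict[str, Any] = {
        "seed": seed, "stage_seeds": seeds, "q": q,
        "k_neighbors": k_neighbors,
        "versions": {"python": sys.version.split()[0], "numpy": np.__version__},
    }

    t0 = time.time()
    pldr_fit = pldr.fit_pldr(source, q=q, seed=seeds["pldr"])
    report["pldr"] = {
        "n_iter": pldr_fit.n_iter,
        "converged": pldr_fit.converged,
        "final_loglik": float(pldr_fit.loglik_trace[-1]),
        "seconds": round(time.time() - t0, 3),
    }

    t0 = time.time()
    if lam == "auto":
        lam_star, cv_table = transfer.select_lambda(
            target, pldr_fit.W0, seed=seeds["transfer"]
        )
    else:
        lam_star, cv_table = float(lam), None
    tr_fit = transfer.fit_transfer(target, pldr_fit.W0, lam_star)
    tr_fit.cv_table = cv_table
    report["transfer"] = {
        "lambda": lam_star,
        "cv_table": cv_table,
        "n_iter": tr_fit.n_iter,
        "converged": tr_fit.converged,
        "final_objective": float(tr_fit.objective_trace[-1]),
        "seconds": round(time.time() - t0, 3),
    }

    # cluster in the variance-carrying parameterization of the fitted span
    factors = transfer.orthonormal_factors(target, tr_fit.W)

    t0 = time.time()
    graph = spgmm.build_knn_graph(coords, k=k_neighbors)
    criterion_table = None
    if K == "auto":
        K_lo, K_hi = int(min(K_range)), int(max(K_range))
        K_hat, criterion_table, fits = spgmm.select_K(
            factors, graph, range(K_lo, K_hi + 1),
            beta_grid=beta_grid, seed=seeds["spgmm"],
        )
        fit = fits[K_hat]
    else:
        K_hat = int(K)
        fit = spgmm.fit_spgmm(
            factors, graph, K_hat, beta_grid=beta_grid, seed=seeds["spgmm"]
        )
    report["spgmm"] = {
        "K": K_hat,
        "beta": fit.beta,
        "beta_table": fit.beta_table,
        "criterion_table": criterion_table,
        "pseudo_loglik": fit.pseudo_loglik,
        "n_iter": fit.n_iter,
        "seconds": round(time.time() - t0, 3),
    }
    if truth is not None:
        report["ari_vs_truth"] = evaluate.adjusted_rand_index(fit.labels, truth)

    return RunResult(
        labels=fit.labels,
        factors=factors,
        row_ids=list(target.row_ids),
        report=report,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Full file-to-file run; returns the JSON-serializable run report.

    Reads the four inputs, harmonizes the gene spaces, runs all three
    stages, and writes ``labels.tsv``, ``factors.tsv`` and ``report.json``
    into ``cfg.out_dir``.  On a stage failure the report (with the failing
    stage named) and any partial outputs are still written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": _jsonable(asdict(cfg)), "stage": "io"}
    try:
        target_raw = core_io.read_expression(
            cfg.target_expr, cfg.expr_format, cfg.orientation
        )
        coords = core_io.read_coords(cfg.target_coords, target_raw.row_ids)
        src_expr = core_io.read_expression(
            cfg.source_expr, cfg.expr_format, cfg.orientation
        )
        src_labels = core_io.read_labels(cfg.source_labels, src_expr.row_ids)

        report["stage"] = "preprocess"
        target = core_io.preprocess(
            target_raw, n_hvg=cfg.n_hvg, normalize=cfg.normalize
        )
        source, combine_report = core_io.align_and_combine_sources(
            [(src_expr, src_labels)], target.gene_ids, normalize=cfg.normalize
        )
        source, target = core_io.harmonize_gene_spaces(source, target)
        report["n_genes_used"] = target.n_genes
        report["zero_filled_genes"] = {
            str(k): v for k, v in combine_report.missing_genes.items()
        }

        report["stage"] = "model"
        truth = (
            core_io.read_labels(cfg.truth_labels, target.row_ids)
            if cfg.truth_labels
            else None
        )
        result = run_pipeline_arrays(
            source, target, coords,
            q=cfg.q, k_neighbors=cfg.k_neighbors, lam=cfg.lam,
            beta_grid=cfg.beta_grid, K=cfg.K, K_range=cfg.K_range,
            seed=cfg.seed, truth=truth,
        )
        report.update(result.report)
        report["stage"] = "done"

        core_io.write_labels(result.row_ids, result.labels, out / "labels.tsv")
        factors = pd.DataFrame(
            result.factors,
            index=result.row_ids,
            columns=[f"factor{j + 1}" for j in range(result.factors.shape[1])],
        )
        factors.insert(0, "cluster", result.labels)
        factors.to_csv(out / "factors.tsv", sep="\t")
    except Exception as exc:
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
        raise
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
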