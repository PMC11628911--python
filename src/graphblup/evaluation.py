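"""Cross-validation protocol and model benchmarking.

The evaluation protocol is 10 independent random partitions, each
assigning 20% of the lines to a testing set whose phenotypes are masked
during fitting; APC, NRMSE, MAAPE and Best20 are computed per partition
and averaged.

Five model presets are compared:

========== ===============================================
C          genotype kernel G only (conventional GBLUP)
GM_KNN_P1  network kernel GA from the KNN graph, alone
GM_KNN_P2  G plus the KNN-graph GA
GM_T_P1    network kernel GA from the thresholding graph, alone
GM_T_P2    G plus the thresholding-graph GA
========== ===============================================

Kernels are built once per dataset from the markers (available for all
lines) and shared across partitions; one CVPlan is shared across models
so comparisons are paired.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import graph_kernel, knn_adjacency, threshold_adjacency
from .io import MarkerMatrix, PhenotypeTable
from .kinship import RelationshipKernel, genomic_similarity, similarity_to_distance, vanraden_g
from .metrics import best20, maape, nrmse, pearson
from .mixed_model import BayesKernelBLUP, REMLKernelBLUP

__all__ = [
    "CVPlan",
    "ModelSpec",
    "MODEL_NAMES",
    "make_cv_plan",
    "build_model_specs",
    "run_benchmark",
    "EvaluationReport",
]

MODEL_NAMES = ("C", "GM_KNN_P1", "GM_KNN_P2", "GM_T_P1", "GM_T_P2")


@dataclass(frozen=True)
class CVPlan:
    """Independent random train/test splits (not folds): each partition is a
    fresh draw of round(test_fraction * n) test lines."""

    n: int
    n_partitions: int
    test_fraction: float
    seed: int
    assignments: list[np.ndarray]  # per-partition sorted test indices

    def train_mask(self, partition: int) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.assignments[partition]] = False
        return mask


def make_cv_plan(n: int, n_partitions: int = 10, test_fraction: float = 0.20, seed: int = 0) -> CVPlan:
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if n_partitions < 1:
        raise ValueError("need at least one partition")
    n_test = round(test_fraction * n)
    if n_test < 1:
        raise ValueError("test set would be empty")
    if n_test >= n:
        raise ValueError("test set would contain all lines")
    rng = np.random.default_rng(seed)
    assignments = [np.sort(rng.choice(n, size=n_test, replace=False)) for _ in range(n_partitions)]
    return CVPlan(n, n_partitions, test_fraction, seed, assignments)


@dataclass(frozen=True)
class ModelSpec:
    """A labelled predictor: one or two covariance kernels over the lines."""

    label: str
    kernels: list[RelationshipKernel]

    def __post_init__(self) -> None:
        if not 1 <= len(self.kernels) <= 2:
            raise ValueError("a model uses 1 or 2 kernels")


def build_model_specs(
    m: MarkerMatrix,
    models=MODEL_NAMES,
    k: int = 10,
    quantile_level: float = 0.65,
    scale_ga: bool = False,
) -> list[ModelSpec]:
    """Construct the requested preset models' kernels from a marker matrix.

    Similarity, graphs and kernels are computed once and shared between
    presets that need them.
    """
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown model name(s): {sorted(unknown)}")
    need_g = any(name in ("C", "GM_KNN_P2", "GM_T_P2") for name in models)
    need_knn = any(name.startswith("GM_KNN") for name in models)
    need_thr = any(name.startswith("GM_T") for name in models)

    G = vanraden_g(m) if need_g else None
    ga_knn = ga_thr = None
    if need_knn or need_thr:
        S = genomic_similarity(m)
        if need_thr:
            ga_thr = graph_kernel(threshold_adjacency(S, quantile_level), scale=scale_ga)
        if need_knn:
            ga_knn = graph_kernel(knn_adjacency(similarity_to_distance(S), k), scale=scale_ga)

    table = {
        "C": lambda: [G],
        "GM_KNN_P1": lambda: [ga_knn],
        "GM_KNN_P2": lambda: [G, ga_knn],
        "GM_T_P1": lambda: [ga_thr],
        "GM_T_P2": lambda: [G, ga_thr],
    }
    return [ModelSpec(name, table[name]()) for name in models]


@dataclass
class EvaluationReport:
    """Tidy per-partition metrics plus across-partition means and SEs."""

    results: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        metrics = ["apc", "nrmse", "maape", "best20"]
        g = self.results.groupby(["model", "trait", "env"])[metrics]
        mean = g.mean()
        se = g.sem()
        out = mean.join(se, rsuffix="_se").reset_index()
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out_dir / "report.csv", index=False)
        self.summary().to_csv(out_dir / "summary.csv", index=False)


def _fit_predict(kernels, y_masked, method, seed, mcmc):
    if method == "reml":
        return REMLKernelBLUP().fit([k.K for k in kernels], y_masked)
    if method == "bayes":
        est = BayesKernelBLUP(random_state=seed, **mcmc)
        return est.fit([k.K for k in kernels], y_masked)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    m: MarkerMatrix,
    ph: PhenotypeTable,
    plan: CVPlan,
    models: list[ModelSpec],
    method: str = "bayes",
    mcmc: dict | None = None,
    seed: int = 0,
    best_direction: str | dict = "larger_is_better",
) -> EvaluationReport:
    """Fit every model on every partition of every trait/env and score it.

    Test phenotypes are masked (NaN) during fitting so prediction follows
    the whole-kernel NA convention. ``best_direction`` may be a single
    rule or a per-trait dict (disease scores are smaller-is-better).
    Bit-reproducible given (plan.seed, seed).
    """
    mcmc = dict(mcmc or {})
    if plan.n != m.n_lines:
        raise ValueError("CV plan size does not match number of lines")
    rows = []
    combos = ph.data[["trait", "env"]].drop_duplicates().itertuples(index=False)
    for trait, env in combos:
        y = ph.vector(trait, env, line_order=list(m.line_ids))
        if np.isnan(y).any():
            raise ValueError(f"trait {trait!r} env {env!r} lacks phenotypes for some lines")
        direction = (
            best_direction.get(trait, "larger_is_better")
            if isinstance(best_direction, dict)
            else best_direction
        )
        for spec in models:
            for part in range(plan.n_partitions):
                entropy = [seed, zlib.crc32(f"{trait}|{env}|{spec.label}".encode()), part]
                fit_seed = int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
                test_idx = plan.assignments[part]
                y_masked = y.copy()
                y_masked[test_idx] = np.nan
                fm = _fit_predict(spec.kernels, y_masked, method, fit_seed, mcmc)
                yhat = fm.predict(test_idx)
                y_test = y[test_idx]
                if np.std(y_test) == 0:
                    warnings.warn(
                        f"partition {part}: degenerate test variance, metrics flagged missing",
                        stacklevel=2,
                    )
                    vals = dict(apc=np.nan, nrmse=np.nan, maape=np.nan, best20=np.nan)
                else:
                    vals = dict(
                        apc=pearson(y_test, yhat),
                        nrmse=nrmse(y_test, yhat),
                        maape=maape(y_test, yhat),
                        best20=best20(y_test, yhat, direction=direction),
                    )
                rows.append({"model": spec.label, "trait": trait, "env": env, "partition": part, **vals})
    return EvaluationReport(pd.DataFrame(rows))
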