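"""Synthetic genotypes and phenotypes with known generative structure.

Markers are independent biallelic sites in Hardy-Weinberg proportions:
marker j draws a minor-allele frequency q_j ~ Uniform(maf_range) and
each line's dosage is Binomial(2, q_j). Phenotypes follow the combined
mixed model y = mu + g + gA + e with g ~ N(0, s2g G), gA ~ N(0, s2ga GA)
and iid Gaussian noise, where G is the VanRaden kernel of the simulated
markers and GA comes from the chosen graph construction.

Variance components are set so that the *targeted* variance fractions
equal h2_g and h2_net: inside the generator (only) each kernel is
divided by its mean diagonal, making the targets interpretable as
heritabilities; the analysis pipeline still sees unscaled kernels.

An optional AR(1) mode correlates adjacent markers for extra realism;
the default generator has no linkage disequilibrium.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .graph import graph_kernel, knn_adjacency, threshold_adjacency
from .io import MarkerMatrix, PhenotypeTable
from .kinship import genomic_similarity, similarity_to_distance, vanraden_g

__all__ = ["SimConfig", "simulate_markers", "simulate_phenotypes", "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    n_lines: int = 300
    n_markers: int = 300
    maf_range: tuple[float, float] = (0.1, 0.5)
    h2_g: float = 0.5
    h2_net: float = 0.0
    mu: float = 10.0
    graph_source: str = "none"  # "threshold" | "knn" | "none"
    k: int = 10
    quantile_level: float = 0.65
    ld_rho: float = 0.0  # AR(1) marker correlation; 0 = independent markers
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.h2_g < 1.0 and 0.0 <= self.h2_net < 1.0):
            raise ValueError("heritabilities must lie in [0, 1)")
        if self.h2_g + self.h2_net >= 1.0:
            raise ValueError("h2_g + h2_net must be < 1")
        if self.h2_net > 0 and self.graph_source == "none":
            raise ValueError("h2_net > 0 requires a graph_source")


def simulate_markers(cfg: SimConfig) -> MarkerMatrix:
    """Draw 0/1/2 dosages; HWE, independent markers (or AR(1) if ld_rho > 0)."""
    rng = np.random.default_rng(cfg.seed)
    q = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    if cfg.ld_rho > 0:
        # latent Gaussian copula: AR(1)-correlated normals thresholded to
        # per-allele Bernoulli draws, two gametes per line
        dosages = np.zeros((cfg.n_lines, cfg.n_markers))
        thresh = np.array([_norm_ppf(qj) for qj in q])
        for _ in range(2):
            z = rng.standard_normal((cfg.n_lines, cfg.n_markers))
            for j in range(1, cfg.n_markers):
                z[:, j] = cfg.ld_rho * z[:, j - 1] + np.sqrt(1 - cfg.ld_rho**2) * z[:, j]
            dosages += (z < thresh).astype(float)
    else:
        dosages = rng.binomial(2, q, size=(cfg.n_lines, cfg.n_markers)).astype(float)
    line_ids = [f"L{i:04d}" for i in range(cfg.n_lines)]
    marker_ids = [f"M{j:05d}" for j in range(cfg.n_markers)]
    return MarkerMatrix(line_ids, marker_ids, dosages)


def _norm_ppf(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def _mvn_from_kernel(rng: np.random.Generator, K: np.ndarray, var: float) -> np.ndarray:
    """Draw N(0, var*K) through the eigendecomposition (K may be singular)."""
    lam, Gamma = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(lam.size)
    return Gamma @ (np.sqrt(var * lam) * z)


def simulate_phenotypes(
    m: MarkerMatrix, cfg: SimConfig, trait: str = "trait1"
) -> tuple[PhenotypeTable, dict]:
    """Phenotypes from the combined model, with ground truth.

    Returns the table and a truth dict holding the per-line genetic and
    network effects and the variance components actually used (on the
    mean-diagonal-normalised kernel scale).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = m.n_lines
    sigma_e2 = 1.0  # residual variance sets the unit

    total_h2 = cfg.h2_g + cfg.h2_net
    s2g = sigma_e2 * cfg.h2_g / (1.0 - total_h2)
    s2ga = sigma_e2 * cfg.h2_net / (1.0 - total_h2)

    g = np.zeros(n)
    if cfg.h2_g > 0:
        G = vanraden_g(m).K
        G_norm = G / max(float(np.trace(G) / n), 1e-12)
        g = _mvn_from_kernel(rng, G_norm, s2g)

    gA = np.zeros(n)
    if cfg.graph_source != "none":
        S = genomic_similarity(m)
        if cfg.graph_source == "threshold":
            A = threshold_adjacency(S, cfg.quantile_level)
        elif cfg.graph_source == "knn":
            A = knn_adjacency(similarity_to_distance(S), cfg.k)
        else:
            raise ValueError(f"unknown graph_source {cfg.graph_source!r}")
        GA = graph_kernel(A).K
        if cfg.h2_net > 0:
            GA_norm = GA / max(float(np.trace(GA) / n), 1e-12)
            gA = _mvn_from_kernel(rng, GA_norm, s2ga)

    eps = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    y = cfg.mu + g + gA + eps

    import pandas as pd

    table = PhenotypeTable(
        pd.DataFrame({"line_id": m.line_ids, "trait": trait, "env": "-", "value": y})
    )
    truth = {
        "g": g,
        "gA": gA,
        "sigma2_g": s2g,
        "sigma2_net": s2ga,
        "sigma2_e": sigma_e2,
        "h2_g": cfg.h2_g,
        "h2_net": cfg.h2_net,
        "mu": cfg.mu,
    }
    return table, truth


def write_dataset(cfg: SimConfig, out_dir: str | Path, trait: str = "trait1") -> None:
    """Simulate and write markers.csv, phenotypes.csv and truth.json."""
    from .io import write_markers

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = simulate_markers(cfg)
    ph, truth = simulate_phenotypes(m, cfg, trait=trait)
    write_markers(m, out / "markers.csv")
    ph.data.to_csv(out / "phenotypes.csv", index=False)
    serializable = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()
    }
    serializable["config"] = asdict(cfg)
    (out / "truth.json").write_text(json.dumps(serializable, indent=1))
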