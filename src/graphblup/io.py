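"""Marker-matrix and phenotype I/O.

Genotypes are biallelic dosages coded 0/1/2 (count of the alternate
allele; heterozygotes are 1). Markers arrive either as a CSV with a
``line_id`` column plus one column per marker, or as a VCF whose GT
fields are converted to dosages. Phenotypes are long-format CSV:
``line_id,trait[,env],value``.

The line ordering of a :class:`MarkerMatrix` is canonical: every kernel
and phenotype vector downstream follows it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "PhenotypeTable",
    "read_markers",
    "write_markers",
    "read_phenotypes",
    "impute_missing",
    "align",
]


@dataclass(frozen=True)
class MarkerMatrix:
    """n lines x p markers of allele dosages.

    ``dosages`` is float to admit NaN (missing) before imputation and
    fractional values after mean imputation; otherwise entries lie in
    {0, 1, 2}.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # (n, p) float64, NaN = missing

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        n, p = d.shape
        if n < 2:
            raise ValueError(f"need at least 2 lines, got {n}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lists do not match dosage shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        obs = d[~np.isnan(d)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2] (or NaN)")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format continuous trait records, one per (line, trait, env)."""

    data: pd.DataFrame = field(repr=False)  # columns: line_id, trait, env, value

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "env" not in df.columns:
            df["env"] = "-"
        df["env"] = df["env"].fillna("-")
        required = ["line_id", "trait", "env", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        df = df[required]
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("phenotype values must be finite")
        if df.duplicated(["line_id", "trait", "env"]).any():
            raise ValueError("duplicate (line, trait, env) records")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def line_ids(self) -> list[str]:
        return list(pd.unique(self.data["line_id"]))

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.data["trait"]))

    def vector(self, trait: str, env: str = "-", line_order: list[str] | None = None) -> np.ndarray:
        """Trait values as a vector following ``line_order`` (NaN where absent)."""
        sub = self.data[(self.data["trait"] == trait) & (self.data["env"] == env)]
        lut = dict(zip(sub["line_id"], sub["value"]))
        order = line_order if line_order is not None else self.line_ids
        return np.array([lut.get(l, np.nan) for l in order], dtype=float)


def _markers_from_frame(df: pd.DataFrame) -> MarkerMatrix:
    line_ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(line_ids)) != len(line_ids):
        raise ValueError("duplicate line ids in marker file")
    marker_ids = [str(c) for c in df.columns[1:]]
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    obs = vals[~np.isnan(vals)]
    if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
        bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
        raise ValueError(f"dosage {bad!r} outside {{0,1,2,missing}}")
    return MarkerMatrix(line_ids, marker_ids, vals)


def _read_vcf(path: str | Path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(cyvcf2 gt_types uses 3), 2=unknown
        gts = rec.genotypes  # [[a, b, phased], ...]
        col = np.full(len(line_ids), np.nan)
        for i, g in enumerate(gts):
            alleles = [a for a in g[:-1] if a >= 0]
            if alleles:
                col[i] = float(sum(alleles))
        marker_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        cols.append(col)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic VCF site(s)", stacklevel=3)
    if not cols:
        raise ValueError("no usable biallelic sites in VCF")
    return MarkerMatrix(line_ids, marker_ids, np.column_stack(cols))


def read_markers(path: str | Path, format: str = "csv") -> MarkerMatrix:
    """Read a marker matrix from CSV (``line_id`` + marker columns) or VCF.

    VCF dosage is the alternate-allele count; multiallelic sites are
    skipped with a warning; missing genotypes become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _markers_from_frame(pd.read_csv(path))
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def write_markers(m: MarkerMatrix, path: str | Path) -> None:
    df = m.to_frame()
    # integers render without a decimal point so CSV round-trips exactly
    df.index.name = "line_id"
    df.to_csv(path, float_format="%.17g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


def impute_missing(m: MarkerMatrix, strategy: str = "marker_mean") -> MarkerMatrix:
    """Fill missing dosages per marker.

    ``marker_mean`` replaces NaN with the mean of that marker's observed
    dosages; markers with no observed values are dropped with a warning.
    ``drop_marker`` removes every marker containing any missing value.
    """
    if not m.has_missing:
        return m
    d = m.dosages
    if strategy == "drop_marker":
        keep = ~np.isnan(d).any(axis=0)
        if not keep.any():
            raise ValueError("all markers dropped")
        return MarkerMatrix(m.line_ids, [mid for mid, k in zip(m.marker_ids, keep) if k], d[:, keep])
    if strategy == "marker_mean":
        all_missing = np.isnan(d).all(axis=0)
        if all_missing.any():
            warnings.warn(
                f"dropping {int(all_missing.sum())} marker(s) with no observed dosages",
                stacklevel=2,
            )
        keep = ~all_missing
        d = d[:, keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), means, d)
        return MarkerMatrix(m.line_ids, [mid for mid, k in zip(m.marker_ids, keep) if k], d)
    raise ValueError(f"unknown strategy {strategy!r}")


def align(m: MarkerMatrix, ph: PhenotypeTable) -> tuple[MarkerMatrix, PhenotypeTable]:
    """Restrict markers and phenotypes to their common lines.

    The surviving MarkerMatrix order (a subsequence of the input order)
    is canonical for both outputs.
    """
    common = set(m.line_ids) & set(ph.data["line_id"])
    if not common:
        raise ValueError("no lines shared between markers and phenotypes")
    keep_idx = [i for i, l in enumerate(m.line_ids) if l in common]
    order = [m.line_ids[i] for i in keep_idx]
    m2 = MarkerMatrix(order, m.marker_ids, m.dosages[keep_idx])
    sub = ph.data[ph.data["line_id"].isin(common)].copy()
    rank = {l: i for i, l in enumerate(order)}
    sub = sub.sort_values(["trait", "env", "line_id"], key=lambda s: s.map(rank) if s.name == "line_id" else s)
    return m2, PhenotypeTable(sub)
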