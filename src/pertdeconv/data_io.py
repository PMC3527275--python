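"""Reading, writing and preparing expression matrices for deconvolution.

Expression tables are genes x samples matrices of non-negative intensities.
Before probability-model fitting, mixed profiles are digitized into integer
counts at a common depth (``discretize``) and reference profiles are
converted to discrete gene distributions on the simplex
(``reference_to_distributions``).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "GeneIndex",
    "ExpressionTable",
    "DigitalMixture",
    "ReferenceDistributions",
    "read_expression_table",
    "align_genes",
    "discretize",
    "reference_to_distributions",
    "log2_transform",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when in-memory data violate a domain invariant."""


@dataclass(frozen=True)
class GeneIndex:
    """Ordered, unique gene/probe identifiers shared by aligned matrices."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise ValidationError("gene index must be non-empty")
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Index(self.ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ExpressionTable:
    """Genes x samples matrix of non-negative, finite intensities.

    ``is_log2`` flags tables carrying log2-scale values; the probability
    models require linear scale while NNLS requires log2 scale, and the
    flag lets the fitters enforce that contract.
    """

    genes: GeneIndex
    sample_names: tuple[str, ...]
    values: np.ndarray  # shape (G, S)
    is_log2: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.genes), len(self.sample_names)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.sample_names)} samples"
            )
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValidationError("sample names must be unique")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.genes.ids[g]!r}, "
                f"sample {self.sample_names[s]!r}"
            )
        if not self.is_log2 and np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative intensity at gene {self.genes.ids[g]!r}, "
                f"sample {self.sample_names[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.genes.ids), columns=list(self.sample_names)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, is_log2: bool = False) -> "ExpressionTable":
        return cls(
            genes=GeneIndex(tuple(str(g) for g in frame.index)),
            sample_names=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
            is_log2=is_log2,
        )


@dataclass
class DigitalMixture:
    """Per-sample integer gene counts: D samples x G genes.

    ``totals`` are the per-sample observation counts N_d; with the default
    digitization depth they are on the order of 1e7, mirroring how intensity
    units are chosen so each sample contributes ~1e7 discrete observations.
    """

    genes: GeneIndex
    sample_names: tuple[str, ...]
    counts: np.ndarray  # shape (D, G), integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_names),
            len(self.genes),
        ):
            raise ValidationError("counts must have shape (D, G)")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValidationError("every sample must have a positive total count")

    @property
    def totals(self) -> np.ndarray:
        """N_d: total observations per sample."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]


@dataclass
class ReferenceDistributions:
    """K reference populations as discrete gene distributions beta_k.

    Each row lies on the G-simplex: beta[k, g] is the probability that one
    unit of expression from population k lands on gene g. ``totals`` keep
    the original (un-floored) intensity sums N_k of the source profiles.
    """

    genes: GeneIndex
    population_names: tuple[str, ...]
    beta: np.ndarray  # shape (K, G), rows on the simplex
    totals: np.ndarray  # N_k per population
    zero_floor: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if self.beta.shape != (len(self.population_names), len(self.genes)):
            raise ValidationError("beta must have shape (K, G)")
        if np.any(self.beta < 0):
            raise ValidationError("beta entries must be non-negative")
        if not np.allclose(self.beta.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise ValidationError("each beta row must sum to 1 within 1e-12")

    @property
    def n_populations(self) -> int:
        return self.beta.shape[0]


def read_expression_table(path: str | os.PathLike, format: str = "tsv") -> ExpressionTable:
    """Read a genes x samples intensity table from TSV or GCT 1.2.

    TSV: first column holds gene identifiers, header row holds sample names.
    GCT 1.2: ``#1.2`` line, a ``rows<TAB>cols`` line, then a matrix whose
    first two columns are Name and Description.
    """
    if format not in ("tsv", "gct"):
        raise FormatError(f"unknown format {format!r}; expected 'tsv' or 'gct'")
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    else:
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"not a GCT 1.2 file (first line {version!r})")
            dims = fh.readline().split("\t")
            try:
                n_rows, n_cols = int(dims[0]), int(dims[1])
            except (ValueError, IndexError) as exc:
                raise FormatError("malformed GCT dimension line") from exc
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" not in frame.columns[:1]:
            raise FormatError("GCT matrix must have a Description column")
        frame = frame.drop(columns=frame.columns[0])
        if frame.shape != (n_rows, n_cols):
            raise FormatError(
                f"GCT declares {n_rows} x {n_cols} but matrix is "
                f"{frame.shape[0]} x {frame.shape[1]}"
            )
    if frame.index.has_duplicates:
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValidationError(f"duplicate gene identifiers in {path}: {dupes[:5]}")
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValidationError(
            f"non-numeric value in column {col!r} at gene {row!r}"
        )
    return ExpressionTable.from_frame(frame)


def write_expression_table(table: ExpressionTable, path: str | os.PathLike) -> None:
    """Write a table as TSV with gene IDs in the first column."""
    frame = table.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.6f")


def align_genes(
    reference: ExpressionTable, mixture: ExpressionTable
) -> tuple[ExpressionTable, ExpressionTable]:
    """Restrict both tables to their shared genes, in reference order.

    Reference and mixed profiles routinely come from different platforms,
    so their probe/gene spaces must be intersected before deconvolution.
    """
    ref_ids = reference.genes.ids
    mix_set = set(mixture.genes.ids)
    shared = [g for g in ref_ids if g in mix_set]
    logger.info(
        "gene alignment: %d reference x %d mixture -> %d shared",
        len(ref_ids), len(mixture.genes.ids), len(shared),
    )
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} shared genes between reference and mixture"
        )
    if shared == list(ref_ids) and shared == list(mixture.genes.ids):
        return reference, mixture
    ref_pos = {g: i for i, g in enumerate(ref_ids)}
    mix_pos = {g: i for i, g in enumerate(mixture.genes.ids)}
    idx = GeneIndex(tuple(shared))
    ref_out = ExpressionTable(
        genes=idx,
        sample_names=reference.sample_names,
        values=reference.values[[ref_pos[g] for g in shared], :],
        is_log2=reference.is_log2,
    )
    mix_out = ExpressionTable(
        genes=idx,
        sample_names=mixture.sample_names,
        values=mixture.values[[mix_pos[g] for g in shared], :],
        is_log2=mixture.is_log2,
    )
    return ref_out, mix_out


def _apportion(proportions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer apportionment with index tie-break."""
    raw = proportions * total
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        frac = raw - base
        # stable sort on -frac: equal remainders resolved by ascending index
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def discretize(mixture: ExpressionTable, target_total: float = 1e7) -> DigitalMixture:
    """Digitize intensities into integer counts at a fixed per-sample depth.

    Every sample is rescaled so its counts sum exactly to
    ``round(target_total)`` using floor-then-largest-remainder
    apportionment (ties broken by ascending gene index). The default depth
    of 1e7 mirrors choosing intensity units so N_d is on the order of 1e7,
    and makes log-likelihoods comparable across samples and runs.
    """
    if mixture.is_log2:
        raise ValidationError("discretize expects linear-scale intensities")
    total = int(round(target_total))
    if total < 1:
        raise ValidationError("target_total must be >= 1")
    col_sums = mixture.values.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = mixture.sample_names[int(np.argmax(col_sums <= 0))]
        raise ValidationError(f"sample {bad!r} has zero total intensity")
    counts = np.empty((mixture.n_samples, mixture.n_genes), dtype=np.int64)
    for s in range(mixture.n_samples):
        counts[s] = _apportion(mixture.values[:, s] / col_sums[s], total)
    return DigitalMixture(
        genes=mixture.genes, sample_names=mixture.sample_names, counts=counts
    )


def reference_to_distributions(
    reference: ExpressionTable, zero_floor: float = 1e-12
) -> ReferenceDistributions:
    """Convert reference intensity profiles v_k to distributions beta_k.

    beta[k, g] = v[k, g] / N_k with N_k = sum_g v[k, g]; zero intensities
    are floored at ``zero_floor * N_k`` before normalization so that a
    mixture count on a gene absent from every reference cannot drive the
    log-likelihood to -inf. ``totals`` record the un-floored N_k.
    """
    if reference.is_log2:
        raise ValidationError("reference distributions require linear-scale intensities")
    if zero_floor < 0:
        raise ValidationError("zero_floor must be non-negative")
    v = reference.values.T  # (K, G)
    totals = v.sum(axis=1)
    if np.any(totals <= 0):
        bad = reference.sample_names[int(np.argmax(totals <= 0))]
        raise ValidationError(f"reference {bad!r} has zero total intensity")
    floored = np.maximum(v, zero_floor * totals[:, None])
    beta = floored / floored.sum(axis=1, keepdims=True)
    return ReferenceDistributions(
        genes=reference.genes,
        population_names=reference.sample_names,
        beta=beta,
        totals=totals,
        zero_floor=zero_floor,
    )


def write_results(result, out_dir: str | os.PathLike) -> list[str]:
    """Write a fit to ``out_dir``: proportions.tsv, optional rho.tsv /
    gamma.tsv, and run metadata as YAML. Returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    props = result.proportions
    frame = pd.DataFrame(
        np.round(props.theta, 6),
        index=list(props.sample_names),
        columns=list(props.population_names),
    )
    frame.index.name = "sample"
    path = os.path.join(out_dir, "proportions.tsv")
    frame.to_csv(path, sep="\t", float_format="%.6f")
    written.append(path)

    if result.perturbation is not None:
        rho = result.perturbation
        ids = rho.gene_ids if rho.gene_ids is not None else [
            str(i) for i in range(len(rho.rho))
        ]
        pd.DataFrame({"gene": list(ids), "rho": rho.rho}).to_csv(
            p := os.path.join(out_dir, "rho.tsv"), sep="\t", index=False,
            float_format="%.6f",
        )
        written.append(p)
    if result.new_population is not None:
        npop = result.new_population
        ids = npop.gene_ids if npop.gene_ids is not None else [
            str(i) for i in range(len(npop.gamma))
        ]
        pd.DataFrame({"gene": list(ids), "probability": npop.gamma}).to_csv(
            p := os.path.join(out_dir, "gamma.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
        written.append(p)

    meta = {
        "model": result.model,
        "loglik": float(result.loglik),
        "logpost": float(result.logpost),
        "n_iter": int(result.n_iter),
        "converged": bool(result.converged),
        "n_obs": int(result.n_obs),
        "seed": int(result.seed) if result.seed is not None else None,
    }
    if result.kappa is not None:
        meta["kappa"] = float(result.kappa)
    if result.alpha is not None:
        meta["alpha"] = [float(a) for a in np.atleast_1d(result.alpha)]
    path = os.path.join(out_dir, "run.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    written.append(path)
    return written


def log2_transform(table: ExpressionTable) -> ExpressionTable:
    """Return log2(1 + intensity); the +1 offset keeps zeros finite."""
    if table.is_log2:
        raise ValidationError("table is already log2-scale")
    return dataclasses.replace(table, values=np.log2(1.0 + table.values), is_log2=True)
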