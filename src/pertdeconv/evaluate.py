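"""Evaluation statistics for deconvolution fits.

Accuracy against an external benchmark (flow cytometry or simulation
truth) is summarised two ways: the proportion of variance R^2 explained by
the predictions (square of Pearson's r over per-lineage proportions, with
the usual t-statistic t = r*sqrt(n-2)/sqrt(1-r^2)), and the averaged
absolute difference between predicted and measured proportions. Competing
fits on the same data are compared by BIC = -2*lnL + p*ln(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
import yaml

from .data_io import ValidationError
from .models import PerturbationEstimate

__all__ = [
    "EvaluationReport",
    "avg_abs_difference",
    "correlation_stats",
    "bic",
    "count_free_parameters",
    "flag_perturbed_genes",
    "wilcoxon_signed_rank",
    "write_report",
    "export_gene_list",
]


@dataclass
class EvaluationReport:
    pearson_r: float | None = None
    r_squared: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    n_points: int | None = None
    avg_abs_diff: float | None = None
    sd_abs_diff: float | None = None
    bic: float | None = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            out[k] = int(v) if k == "n_points" else float(v)
        return out


def avg_abs_difference(predicted, measured) -> tuple[float, float]:
    """Mean and sd (ddof=1) over lineages of |predicted - measured|."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1:
        raise ValidationError("predicted and measured must be 1-D and equal length")
    diff = np.abs(p - m)
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return float(diff.mean()), sd


def correlation_stats(predicted, measured) -> EvaluationReport:
    """Pearson r, R^2 = r^2, and t = r*sqrt(n-2)/sqrt(1-r^2) with df = n-2.

    The two-sided p-value matches R's cor.test().
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1:
        raise ValidationError("predicted and measured must be 1-D and equal length")
    n = p.size
    if n < 3:
        raise ValidationError("need at least 3 paired points for the t-statistic")
    if p.std() == 0 or m.std() == 0:
        raise ValidationError("zero variance: Pearson correlation undefined")
    r = float(scipy.stats.pearsonr(p, m).statistic)
    t, pval = t_stat_from_r(r, n)
    return EvaluationReport(
        pearson_r=r, r_squared=r * r, t_stat=t, p_value=pval, n_points=n
    )


def t_stat_from_r(r: float, n: int) -> tuple[float, float]:
    """t-statistic and two-sided p-value for a Pearson r at n points."""
    if n < 3:
        raise ValidationError("n must be >= 3")
    if abs(r) >= 1.0:
        return math.inf if r > 0 else -math.inf, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    pval = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
    return t, pval


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion: -2*lnL + p*ln(N)."""
    if n_obs < 1:
        raise ValidationError("n_obs must be >= 1")
    if n_params < 0:
        raise ValidationError("n_params must be non-negative")
    return -2.0 * loglik + n_params * math.log(n_obs)


def count_free_parameters(model: str, K: int, D: int, G: int = 0) -> dict:
    """Free-parameter breakdown per block under this package's convention.

    theta rows are simplex-constrained, so each contributes K-1 free values
    (K values for the K+1-population nnml_np model); rho is identified up
    to anchoring but its scale is pinned by the prior, so it counts G; the
    new-population distribution gamma counts G-1; omega counts K-1; the
    prior strengths kappa and the per-sample concentrations alpha count 1
    and D.
    """
    if K < 1 or D < 1 or G < 0:
        raise ValidationError("K, D must be >= 1 and G >= 0")
    blocks: dict[str, int] = {}
    if model == "nnml":
        blocks["theta"] = (K - 1) * D
    elif model == "nnml_np":
        blocks["theta"] = K * D
        blocks["gamma"] = max(G - 1, 0)
        blocks["omega"] = K - 1
        blocks["kappa"] = 1
        blocks["alpha"] = D
    elif model == "pert":
        blocks["theta"] = (K - 1) * D
        blocks["rho"] = G
        blocks["kappa"] = 1
        blocks["alpha"] = D
    else:
        raise ValidationError(f"unknown model {model!r}")
    blocks["total"] = sum(blocks.values())
    return blocks


def flag_perturbed_genes(
    rho: PerturbationEstimate | np.ndarray, fold: float = 2.0,
    gene_ids=None,
) -> dict[str, list[str]]:
    """Genes perturbed by more than ``fold``: rho < 1/fold (down) or
    rho > fold (up), strict inequalities; boundary values are not flagged."""
    if fold <= 1:
        raise ValidationError("fold must be > 1")
    if isinstance(rho, PerturbationEstimate):
        if gene_ids is None:
            gene_ids = rho.gene_ids
        rho = rho.rho
    rho = np.asarray(rho, dtype=float)
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(rho.size)]
    gene_ids = list(gene_ids)
    up = [g for g, r in zip(gene_ids, rho) if r > fold]
    down = [g for g, r in zip(gene_ids, rho) if r < 1.0 / fold]
    return {"up": up, "down": down, "flagged": sorted(set(up) | set(down))}


def wilcoxon_signed_rank(errors_a, errors_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired error comparisons
    between two models (utility; not an acceptance quantity)."""
    res = scipy.stats.wilcoxon(np.asarray(errors_a), np.asarray(errors_b))
    return float(res.pvalue)


def write_report(report: EvaluationReport, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=False)


def export_gene_list(gene_ids, path) -> None:
    """Plain-text export, one identifier per line (for enrichment tools)."""
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")
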