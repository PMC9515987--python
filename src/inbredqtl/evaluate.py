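"""Evaluation layer: genomic inflation, cis-level calls, power and type-I error.

Significance is declared per SNP at the cis-only Bonferroni threshold
alpha / q_cis (q_cis = number of cis-SNPs for the gene); a gene is
"called" when at least one of its cis-SNPs is significant.  A called
gene with at least one truly nonzero cis effect is a true positive even
if the significant SNP is not the causal one — linkage disequilibrium
makes SNP-level attribution meaningless without fine mapping.  Type-I
error is therefore defined only at the gene-level global null (no cis-
SNP causal).  Power is additionally stratified by realized
cis-heritability, the share of phenotypic variance due to cis-SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "genomic_inflation",
    "cis_calls",
    "confusion",
    "stratify_by_cis_h2",
    "EvaluationSummary",
    "evaluate_scan",
    "DEFAULT_STRATA",
]

DEFAULT_STRATA = (0.0, 0.1, 0.25, 0.4, 0.6, 0.8, 1.0)
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.454936...
_TINY = np.nextafter(0.0, 1.0)


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor (lambda_GC).

    Each p-value is converted to its 1-df chi-square quantile; the GIF
    is the median of those statistics over the chi-square-1 median
    (~0.4549).  Well-calibrated p-values give 1; inflation from
    unmodelled relatedness pushes it above 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("p-values of 0 floored at the smallest positive float")
        p = np.maximum(p, _TINY)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def cis_calls(results: pd.DataFrame, truth: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Gene-level calls at the cis-only Bonferroni threshold.

    ``results`` is a scan table (gene_id, is_cis, p_value, ...);
    ``truth`` the per-gene truth table carrying q_cis.  Genes with
    q_cis = 0 are excluded (no cis test is possible).  Returns one row
    per evaluable gene: q_cis, min cis p, threshold, called.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if len(results):
        cis = results[results["is_cis"].astype(bool)]
        min_p = cis.groupby("gene_id")["p_value"].min()
    else:  # no tested SNP at all: every gene is uncalled
        min_p = pd.Series(dtype=float)
    rows = []
    for gene_id, t in truth.iterrows():
        q = int(t["q_cis"])
        if q < 1:
            continue
        thr = alpha / q
        p = float(min_p.get(gene_id, np.nan))
        rows.append(
            {
                "gene_id": gene_id,
                "q_cis": q,
                "min_cis_p": p,
                "threshold": thr,
                "called": bool(p < thr) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def confusion(truth: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Gene-level power and global-null type-I error.

    Power = TP / (TP + FN) over genes with >= 1 truly nonzero cis
    effect; type-I = FP / (FP + TN) over global-null genes.  A category
    with no evaluable genes yields ``None`` for its rate.
    """
    joined = calls.join(truth[["has_cis_effect"]], how="inner")
    pos = joined[joined["has_cis_effect"]]
    neg = joined[~joined["has_cis_effect"]]
    power = float(pos["called"].mean()) if len(pos) else None
    type1 = float(neg["called"].mean()) if len(neg) else None
    return {
        "n_positive": len(pos),
        "n_null": len(neg),
        "tp": int(pos["called"].sum()),
        "fp": int(neg["called"].sum()),
        "power": power,
        "type1": type1,
    }


def stratify_by_cis_h2(
    truth: pd.DataFrame, calls: pd.DataFrame, breaks=DEFAULT_STRATA
) -> pd.DataFrame:
    """Power within realized cis-heritability strata.

    Genes are binned by cis_h2 (= h2_realized * cis_fraction_realized)
    into intervals (b_k, b_{k+1}]; empty strata report NaN power.  Only
    truth-positive genes enter power; the table also carries per-bin
    gene counts (the bubble sizes of a power-vs-heritability plot).
    """
    breaks = np.asarray(breaks, dtype=float)
    if len(breaks) < 2 or np.any(np.diff(breaks) <= 0):
        raise ParameterError("breaks must be strictly increasing with >= 2 edges")
    joined = calls.join(truth[["has_cis_effect", "cis_h2"]], how="inner")
    pos = joined[joined["has_cis_effect"]].copy()
    pos["stratum"] = pd.cut(pos["cis_h2"], bins=breaks, include_lowest=True)
    grouped = pos.groupby("stratum", observed=False)["called"]
    out = pd.DataFrame(
        {"n_genes": grouped.size(), "power": grouped.mean()}
    ).reset_index()
    return out


@dataclass
class EvaluationSummary:
    """Bundle of gene-level evaluation outputs for one method."""

    method: str
    per_gene: pd.DataFrame  # calls joined with truth
    overall: dict  # confusion() output
    strata: pd.DataFrame  # stratify_by_cis_h2() output
    gif_per_gene: pd.Series | None = None

    @property
    def power(self):
        return self.overall["power"]

    @property
    def type1(self):
        return self.overall["type1"]

    def power_above(self, cis_h2_min: float):
        """Power among truth-positive genes with cis_h2 > ``cis_h2_min``."""
        pg = self.per_gene
        sel = pg[pg["has_cis_effect"] & (pg["cis_h2"] > cis_h2_min)]
        return float(sel["called"].mean()) if len(sel) else None


def evaluate_scan(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    alpha: float = 0.05,
    breaks=DEFAULT_STRATA,
    compute_gif: bool = True,
) -> EvaluationSummary:
    """Run calls, confusion and stratification for one scan table."""
    method = results["method"].iloc[0] if len(results) else "unknown"
    calls = cis_calls(results, truth, alpha)
    per_gene = calls.join(truth.drop(columns=["q_cis"]), how="inner")
    gif = None
    if compute_gif and len(results):
        gif = results.groupby("gene_id")["p_value"].apply(genomic_inflation)
        gif.name = "gif"
    return EvaluationSummary(
        method=method,
        per_gene=per_gene,
        overall=confusion(truth, calls),
        strata=stratify_by_cis_h2(truth, calls, breaks),
        gif_per_gene=gif,
    )
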