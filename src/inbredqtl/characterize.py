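"""Expression-trait characterization: heritability and modality.

Broad-sense heritability of a replicated expression trait is the R^2 of
a one-way ANOVA with strain as the factor — the share of variance
between strain means.  Its null distribution comes from permuting
strain labels across samples.  Narrow-sense (SNP-based) heritability is
the mixed model's PVE (:mod:`.lmm`).

Modality of a trait across strains is assessed by fitting univariate
normal mixtures with one, two or three components and a *shared*
within-component variance, selecting the component count by minimum
BIC.  Strongly bimodal expression suggests one or a few large-effect
variants (typically cis), so modality and SNP-based heritability tend
to associate; :func:`modality_vs_h2` tests that with a one-way ANOVA of
PVE on modality class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InbredQTLError, ParameterError

__all__ = [
    "ReplicatePhenotype",
    "ModalityCall",
    "anova_r2",
    "permutation_null",
    "fit_modality",
    "modality_vs_h2",
]


@dataclass
class ReplicatePhenotype:
    """Per-sample measurements with per-sample strain labels."""

    values: np.ndarray
    strain_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.strain_labels = np.asarray(self.strain_labels)
        if self.values.shape != self.strain_labels.shape:
            raise ParameterError("values and strain_labels must align")
        if len(np.unique(self.strain_labels)) < 2:
            raise ParameterError("need at least 2 distinct strains")


def anova_r2(phenotype: ReplicatePhenotype) -> float:
    """One-way ANOVA R^2 with strain as predictor (broad-sense H^2).

    R^2 = SS_between / SS_total; invariant to shifting or rescaling the
    measurements.
    """
    y = phenotype.values
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ParameterError("all values identical: R^2 undefined")
    ssb = 0.0
    for s in np.unique(phenotype.strain_labels):
        grp = y[phenotype.strain_labels == s]
        ssb += len(grp) * (grp.mean() - y.mean()) ** 2
    return float(ssb / sst)


def permutation_null(
    phenotype: ReplicatePhenotype, n_perms: int, seed=None
) -> np.ndarray:
    """Null distribution of the ANOVA R^2 by permuting strain labels."""
    if n_perms < 1:
        raise ParameterError("n_perms must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perms)
    labels = phenotype.strain_labels
    for i in range(n_perms):
        out[i] = anova_r2(
            ReplicatePhenotype(phenotype.values, rng.permutation(labels))
        )
    return out


@dataclass
class ModalityCall:
    """Selected component count and the per-k equal-variance mixture fits."""

    n_components: int
    bic: dict
    means: np.ndarray
    variance: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ParameterError("shared variance must be positive")


def _em_equal_variance(
    x: np.ndarray, k: int, max_iter: int = 500, tol: float = 1e-8, n_restarts: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray, float, np.ndarray] | None:
    """EM for a univariate k-component normal mixture with shared variance.

    Initialization: quantile split of the sorted data into k blocks,
    plus random restarts.  Returns (loglik, means, variance, weights)
    of the best run, or None if no run converged.
    """
    n = len(x)
    rng = np.random.default_rng(seed)
    best = None
    var_floor = max(x.var() * 1e-8, 1e-12)
    for restart in range(n_restarts):
        if restart == 0:
            blocks = np.array_split(np.sort(x), k)
            mu = np.array([b.mean() for b in blocks])
        else:
            mu = rng.choice(x, size=k, replace=False)
        var = max(x.var() / max(k, 1), var_floor)
        w = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            logpdf = stats.norm.logpdf(x[:, None], mu[None, :], np.sqrt(var))
            logw = np.log(np.maximum(w, 1e-300))
            joint = logpdf + logw[None, :]
            m = joint.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
            ll = float(lse.sum())
            resp = np.exp(joint - lse[:, None])
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                break  # empty component; this run failed
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = float((resp * (x[:, None] - mu[None, :]) ** 2).sum() / n)
            var = max(var, var_floor)
            if ll - ll_prev < tol and ll_prev > -np.inf:
                converged = True
                break
            ll_prev = ll
        if converged and (best is None or ll > best[0]):
            order = np.argsort(mu)
            best = (ll, mu[order], var, w[order])
    return best


def fit_modality(strain_means, k_max: int = 3, seed: int = 0) -> ModalityCall:
    """Select 1, 2 or 3 modes by minimum BIC over equal-variance mixtures.

    BIC = -2*loglik + params*log(n) with params = 2k (k means, k-1 free
    weights, 1 shared variance); the k = 1 fit is the closed-form
    normal MLE.
    """
    x = np.asarray(strain_means, dtype=float)
    if len(x) < 10:
        raise ParameterError("need at least 10 values")
    if not np.isfinite(x).all():
        raise ParameterError("values must be finite")
    n = len(x)
    fits: dict[int, tuple] = {}
    bics: dict[int, float] = {}
    # k=1: closed form
    var1 = float(x.var())
    if var1 <= 0:
        raise ParameterError("zero variance: modality undefined")
    ll1 = float(stats.norm.logpdf(x, x.mean(), np.sqrt(var1)).sum())
    fits[1] = (ll1, np.array([x.mean()]), var1, np.array([1.0]))
    bics[1] = -2.0 * ll1 + 2.0 * np.log(n)
    for k in range(2, k_max + 1):
        fit = _em_equal_variance(x, k, seed=seed)
        if fit is None:
            import warnings

            warnings.warn(f"EM failed to converge for k={k}; model excluded")
            continue
        fits[k] = fit
        bics[k] = -2.0 * fit[0] + 2.0 * k * np.log(n)
    if not bics:
        raise InbredQTLError("no mixture model could be fit")
    k_best = min(bics, key=bics.get)
    ll, mu, var, w = fits[k_best]
    return ModalityCall(
        n_components=k_best, bic=bics, means=np.atleast_1d(mu), variance=var,
        weights=np.atleast_1d(w),
    )


def modality_vs_h2(modality_k, pve) -> dict:
    """One-way ANOVA of SNP-based heritability on modality class.

    Returns the omnibus F and p plus per-class means and Welch pairwise
    contrasts; with a single class present the omnibus is undefined
    (reported as None).
    """
    k = np.asarray(modality_k)
    h = np.asarray(pve, dtype=float)
    if k.shape != h.shape:
        raise ParameterError("modality and PVE vectors must align")
    classes = np.unique(k)
    groups = {int(c): h[k == c] for c in classes}
    means = {c: float(v.mean()) for c, v in groups.items()}
    if len(classes) < 2:
        return {"f_stat": None, "p_value": None, "class_means": means, "pairwise": {}}
    f, p = stats.f_oneway(*groups.values())
    pairwise = {}
    cl = sorted(groups)
    for i in range(len(cl)):
        for j in range(i + 1, len(cl)):
            a, b = groups[cl[i]], groups[cl[j]]
            if len(a) > 1 and len(b) > 1:
                t, pt = stats.ttest_ind(a, b, equal_var=False)
                pairwise[(cl[i], cl[j])] = float(pt)
    return {
        "f_stat": float(f),
        "p_value": float(p),
        "class_means": means,
        "pairwise": pairwise,
    }
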