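"""Exact single-random-effect linear mixed model for inbred-panel association.

Model:  y = X b + u + e,  u ~ N(0, sg2 * K),  e ~ N(0, se2 * I),
with K the allele-sharing kinship.  Writing lam = sg2/se2 and
eigendecomposing K = U diag(d) U', rotation by U' diagonalizes the
covariance: Var(U'y) = se2 * diag(lam*d + 1).  For fixed lam the ML
estimates of b and se2 are weighted least squares in the rotated data,
so the likelihood is profiled down to a one-dimensional search over
lam — a coarse log-spaced grid followed by bounded Brent refinement,
the strategy popularized by exact mixed-model association solvers.

Maximum likelihood (not REML) is used throughout because p-values are
likelihood-ratio tests; REML is available via ``method="reml"`` for
variance-component sensitivity checks.  With unit kinship diagonal the
proportion of variance explained (PVE, the SNP-based heritability
estimate) is lam/(lam + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ParameterError, StructuralError
from .kinship import KinshipMatrix

__all__ = ["Rotation", "KinshipLMM", "KinshipLMMResults", "eigendecompose"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Rotation:
    """Eigendecomposition K = U diag(d) U' with d non-increasing."""

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n(self) -> int:
        return len(self.eigenvalues)


def eigendecompose(kinship: KinshipMatrix | np.ndarray, atol: float = 1e-8) -> Rotation:
    """Eigendecompose a (regularized) kinship matrix.

    Raises on asymmetric input; returns eigenvalues sorted descending.
    """
    values = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise StructuralError("kinship must be square")
    if not np.allclose(values, values.T, atol=atol):
        raise StructuralError("kinship must be symmetric")
    w, v = np.linalg.eigh(values)
    order = np.argsort(w)[::-1]
    return Rotation(eigenvectors=v[:, order], eigenvalues=w[order])


def _profile(lam, yt, Xt, d, reml: bool = False):
    """Profiled ML (or REML) log-likelihood and GLS estimates at fixed lam.

    Vectorized over an array of lam values; returns (loglik, beta, se2)
    with loglik shaped like lam.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    n, p = Xt.shape
    h = lam[:, None] * d[None, :] + 1.0  # (L, n)
    w = 1.0 / h
    # normal equations per lam: (X' W X) beta = X' W y
    XtW = Xt[None, :, :] * w[:, :, None]  # (L, n, p)
    A = np.einsum("lnp,nq->lpq", XtW, Xt)
    c = np.einsum("lnp,n->lp", XtW, yt)
    beta = np.linalg.solve(A, c[:, :, None])[:, :, 0]  # (L, p)
    resid = yt[None, :] - beta @ Xt.T  # (L, n)
    rss = np.einsum("ln,ln->l", w * resid, resid)
    logdet_h = np.log(h).sum(axis=1)
    if reml:
        dof = n - p
        se2 = rss / dof
        sign, logdet_A = np.linalg.slogdet(A)
        _, logdet_xx = np.linalg.slogdet(Xt.T @ Xt)
        ll = -0.5 * (
            dof * _LOG2PI + dof * np.log(se2) + dof + logdet_h + logdet_A - logdet_xx
        )
    else:
        se2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n * np.log(se2) + n + logdet_h)
    return ll, beta, se2


class KinshipLMM:
    """Linear mixed model with a single kinship-structured random effect.

    Parameters
    ----------
    endog : array (n,)
        Phenotype, one value per strain.
    exog : array (n, p)
        Fixed-effect design matrix; must contain an intercept column.
    kinship : KinshipMatrix or ndarray, optional
        Relationship matrix (regularize first if pairwise-complete).
    rotation : Rotation, optional
        Precomputed eigendecomposition; supply instead of ``kinship``
        when fitting many phenotypes against one matrix.
    """

    def __init__(self, endog, exog, kinship=None, rotation: Rotation | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise StructuralError("endog and exog have different numbers of strains")
        if np.isnan(self.endog).any() or np.isnan(self.exog).any():
            raise ParameterError("endog/exog must not contain missing values")
        if np.var(self.endog) == 0:
            raise ParameterError("phenotype has zero variance")
        if rotation is None:
            if kinship is None:
                raise ParameterError("supply kinship or rotation")
            rotation = eigendecompose(kinship)
        if rotation.n != len(self.endog):
            raise StructuralError("rotation dimension does not match data")
        self.rotation = rotation
        self._yt = rotation.eigenvectors.T @ self.endog
        self._Xt = rotation.eigenvectors.T @ self.exog

    @classmethod
    def from_formula(cls, formula: str, data, kinship=None, rotation=None) -> "KinshipLMM":
        """Build from a patsy-style formula against a DataFrame.

        Only simple additive formulas (``y ~ x1 + x2``) are supported;
        an intercept is always included.
        """
        lhs, rhs = (side.strip() for side in formula.split("~"))
        y = data[lhs].to_numpy(dtype=float)
        terms = [t.strip() for t in rhs.split("+") if t.strip() not in ("1", "")]
        X = np.column_stack(
            [np.ones(len(y))] + [data[t].to_numpy(dtype=float) for t in terms]
        )
        model = cls(y, X, kinship=kinship, rotation=rotation)
        model._param_names = ["Intercept"] + terms
        return model

    def loglike(self, lam: float, method: str = "ml") -> float:
        """Profiled log-likelihood at a fixed variance ratio lam."""
        ll, _, _ = _profile(lam, self._yt, self._Xt, self.rotation.eigenvalues,
                            reml=(method == "reml"))
        return float(ll[0])

    def fit(
        self,
        lambda_bounds: tuple[float, float] = (1e-5, 1e5),
        grid_points: int = 50,
        method: str = "ml",
        xtol: float = 1e-6,
    ) -> "KinshipLMMResults":
        """Maximize the profiled likelihood over the variance ratio.

        Coarse log-uniform grid on ``lambda_bounds`` then Brent
        refinement of log10(lambda) in the best grid bracket; the
        boundary lam -> 0 (pure OLS) is always a candidate.
        """
        if method not in ("ml", "reml"):
            raise ParameterError("method must be 'ml' or 'reml'")
        reml = method == "reml"
        d = self.rotation.eigenvalues
        lo, hi = np.log10(lambda_bounds[0]), np.log10(lambda_bounds[1])
        grid = np.logspace(lo, hi, grid_points)
        ll_grid, _, _ = _profile(grid, self._yt, self._Xt, d, reml=reml)
        best = int(np.argmax(ll_grid))

        def neg_ll(log10_lam):
            ll, _, _ = _profile(10.0 ** log10_lam, self._yt, self._Xt, d, reml=reml)
            return -ll[0]

        a = np.log10(grid[max(best - 1, 0)])
        b = np.log10(grid[min(best + 1, grid_points - 1)])
        converged = True
        if a < b:
            res = optimize.minimize_scalar(
                neg_ll, bounds=(a, b), method="bounded",
                options={"xatol": xtol},
            )
            converged = bool(res.success)
            lam_hat = float(10.0 ** res.x)
            ll_hat = -float(res.fun)
        else:  # degenerate bracket (single grid point)
            lam_hat, ll_hat = float(grid[best]), float(ll_grid[best])
        # boundary candidate: no genetic variance at all
        ll_zero, _, _ = _profile(0.0, self._yt, self._Xt, d, reml=reml)
        if ll_zero[0] >= ll_hat:
            lam_hat, ll_hat = 0.0, float(ll_zero[0])

        ll, beta, se2 = _profile(lam_hat, self._yt, self._Xt, d, reml=reml)
        w = 1.0 / (lam_hat * d + 1.0)
        cov = se2[0] * np.linalg.inv(self._Xt.T @ (self._Xt * w[:, None]))
        return KinshipLMMResults(
            model=self,
            lambda_hat=lam_hat,
            loglik=float(ll[0]),
            params=beta[0],
            cov_params=cov,
            sigma_e2=float(se2[0]),
            method=method,
            converged=converged,
        )


@dataclass
class KinshipLMMResults:
    """ML fit of :class:`KinshipLMM`: variance components, fixed effects,
    their covariance and the maximized log-likelihood."""

    model: KinshipLMM
    lambda_hat: float
    loglik: float
    params: np.ndarray
    cov_params: np.ndarray
    sigma_e2: float
    method: str
    converged: bool

    @property
    def sigma_g2(self) -> float:
        return self.lambda_hat * self.sigma_e2

    @property
    def pve(self) -> float:
        """Proportion of variance explained by the kinship random effect
        (narrow-sense heritability estimate; kinship diagonal is 1)."""
        return self.lambda_hat / (self.lambda_hat + 1.0)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    def lr_test(self, null: "KinshipLMMResults") -> tuple[float, float]:
        """Likelihood-ratio test against a nested null fit (1 df).

        The statistic is clamped at zero (boundary/optimizer noise); a
        zero statistic gives p = 1.
        """
        stat = max(2.0 * (self.loglik - null.loglik), 0.0)
        return stat, float(stats.chi2.sf(stat, df=1))

    def summary(self) -> str:
        names = getattr(self.model, "_param_names", None) or [
            f"x{i}" for i in range(len(self.params))
        ]
        lines = [
            "Kinship linear mixed model (" + self.method.upper() + ")",
            "=" * 46,
            f"No. strains:        {self.model.rotation.n}",
            f"Log-likelihood:     {self.loglik:.4f}",
            f"lambda (sg2/se2):   {self.lambda_hat:.6g}",
            f"sigma_g2:           {self.sigma_g2:.6g}",
            f"sigma_e2:           {self.sigma_e2:.6g}",
            f"PVE (heritability): {self.pve:.4f}",
            f"Converged:          {self.converged}",
            "-" * 46,
            f"{'term':<12}{'coef':>10}{'se':>10}{'z':>10}",
        ]
        for name, b, se, t in zip(names, self.params, self.bse, self.tvalues):
            lines.append(f"{name:<12}{b:>10.4f}{se:>10.4f}{t:>10.3f}")
        lines.append("=" * 46)
        return "\n".join(lines)
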