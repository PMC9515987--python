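"""Expression-phenotype simulation under sparse point-normal architectures.

A simulated transcript's phenotype is a linear combination of SNP
effects plus normal noise.  Effects follow a point-normal law (a point
mass at zero mixed with a normal), in one of three architectures:

``no_cis``
    every SNP, cis or trans, is causal with probability 0.10 and all
    nonzero effects share one normal distribution — no SNP is singled
    out, so phenotypes tend to stay unimodal;
``one_cis``
    exactly one cis-SNP carries a nonzero effect;
``multi_cis``
    the number of nonzero cis effects is a zero-truncated Poisson with
    conditional mean 2 (capped at the number of cis-SNPs).

In the cis architectures 10% of trans-SNPs are causal and the cis share
of genetic variance is fixed between 0.7 and 0.9.  Component scaling is
*empirical*: the realized genetic variance exactly equals the target
heritability and the realized cis share exactly equals the drawn cis
fraction, because each component is centered, orthogonalized against
the preceding ones, and rescaled to its target variance before summing.
cis-SNPs are SNPs within 1 Mb of the gene body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigurationError, DegenerateComponentError, ParameterError
from .panel import GenotypePanel, MarkerMap

__all__ = [
    "CisRegion",
    "EffectVector",
    "SimulatedPhenotype",
    "cis_region",
    "draw_effects_no_cis",
    "draw_effects_cis",
    "rescale_components",
    "assign_target_heritabilities",
    "simulate_genes",
    "place_genes",
]

DEFAULT_CIS_WINDOW_BP = 1_000_000
DEFAULT_CAUSAL_PROB = 0.10
SETTINGS = ("no_cis", "one_cis", "multi_cis")


@dataclass(frozen=True)
class CisRegion:
    """A gene's location and the indices of its cis-SNPs.

    cis-SNPs are map SNPs on the gene's chromosome whose position falls
    within ``window_bp`` of the gene body [start_bp, end_bp].
    """

    gene_id: str
    chromosome: object
    start_bp: int
    end_bp: int
    window_bp: int = DEFAULT_CIS_WINDOW_BP
    cis_snp_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def q_cis(self) -> int:
        """Number of cis-SNPs — the cis multiplicity correction divisor."""
        return len(self.cis_snp_index)


def cis_region(
    marker_map: MarkerMap,
    gene_id: str,
    chromosome,
    start_bp: int,
    end_bp: int,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> CisRegion:
    """Locate a gene's cis-SNPs on the map."""
    if end_bp < start_bp:
        raise ParameterError("end_bp < start_bp")
    on_chrom = marker_map.chromosome == chromosome
    within = (marker_map.pos_bp >= start_bp - window_bp) & (
        marker_map.pos_bp <= end_bp + window_bp
    )
    return CisRegion(
        gene_id=gene_id,
        chromosome=chromosome,
        start_bp=start_bp,
        end_bp=end_bp,
        window_bp=window_bp,
        cis_snp_index=np.flatnonzero(on_chrom & within),
    )


@dataclass
class EffectVector:
    """True per-SNP effects for one simulated gene."""

    beta: np.ndarray
    causal_mask: np.ndarray
    setting: str

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ParameterError(f"unknown setting {self.setting!r}")
        if np.any(self.beta[~self.causal_mask] != 0):
            raise ParameterError("beta must be 0 where causal_mask is False")

    def n_causal_cis(self, gene: CisRegion) -> int:
        return int(self.causal_mask[gene.cis_snp_index].sum())


@dataclass
class SimulatedPhenotype:
    """A simulated per-strain phenotype with its generating truth."""

    gene: CisRegion
    y: np.ndarray
    effects: EffectVector
    h2_target: float
    h2_realized: float
    cis_fraction_realized: float | None


def draw_effects_no_cis(
    panel: GenotypePanel,
    gene: CisRegion,
    causal_prob: float = DEFAULT_CAUSAL_PROB,
    seed=None,
) -> EffectVector:
    """Point-normal effects with one shared distribution for all SNPs."""
    if not 0 < causal_prob <= 1:
        raise ParameterError("causal_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(panel.n_snps) < causal_prob
    beta = np.zeros(panel.n_snps)
    beta[mask] = rng.normal(0.0, 1.0, size=int(mask.sum()))
    return EffectVector(beta=beta, causal_mask=mask, setting="no_cis")


def _truncated_poisson_lambda(conditional_mean: float) -> float:
    """Rate lam with E[X | X >= 1] = conditional_mean for X ~ Poisson(lam)."""
    if conditional_mean <= 1:
        raise ParameterError("conditional mean must exceed 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - conditional_mean
    return float(optimize.brentq(f, 1e-9, 10.0 * conditional_mean))


def draw_effects_cis(
    panel: GenotypePanel,
    gene: CisRegion,
    setting: str,
    causal_prob_trans: float = DEFAULT_CAUSAL_PROB,
    mean_cis_effects: float = 2.0,
    seed=None,
) -> EffectVector:
    """Point-normal effects with a designated cis architecture.

    ``one_cis``: one cis-SNP chosen uniformly.  ``multi_cis``: the
    nonzero-cis count is Poisson conditioned on being >= 1 with
    conditional mean ``mean_cis_effects``, truncated at q_cis.  Trans
    SNPs are causal with ``causal_prob_trans``.  The raw normal scales
    of the two groups are immaterial: :func:`rescale_components` fixes
    the cis/trans variance split empirically.
    """
    if setting not in ("one_cis", "multi_cis"):
        raise ParameterError("setting must be 'one_cis' or 'multi_cis'")
    if gene.q_cis < 1:
        raise ConfigurationError(
            f"gene {gene.gene_id!r} has no cis-SNPs; such genes are excluded"
        )
    rng = np.random.default_rng(seed)
    if setting == "one_cis":
        n_cis = 1
    else:
        lam = _truncated_poisson_lambda(mean_cis_effects)
        n_cis = 0
        while n_cis == 0:  # zero-truncated Poisson by rejection
            n_cis = int(rng.poisson(lam))
        n_cis = min(n_cis, gene.q_cis)
    cis_hits = rng.choice(gene.cis_snp_index, size=n_cis, replace=False)

    mask = np.zeros(panel.n_snps, dtype=bool)
    trans = np.ones(panel.n_snps, dtype=bool)
    trans[gene.cis_snp_index] = False
    mask[trans] = rng.random(int(trans.sum())) < causal_prob_trans
    mask[cis_hits] = True
    beta = np.zeros(panel.n_snps)
    beta[cis_hits] = rng.normal(0.0, 1.0, size=n_cis)
    trans_hits = trans & mask
    beta[trans_hits] = rng.normal(0.0, 1.0, size=int(trans_hits.sum()))
    return EffectVector(beta=beta, causal_mask=mask, setting=setting)


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _residualize(v: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Residual of v after projecting out the span of {1} U others."""
    n = len(v)
    basis = np.column_stack([np.ones(n)] + others)
    coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
    return v - basis @ coef


def _scale_to_variance(v: np.ndarray, target_var: float) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise DegenerateComponentError("component has zero empirical variance")
    return v * np.sqrt(target_var) / sd


def rescale_components(
    panel: GenotypePanel,
    gene: CisRegion,
    effects: EffectVector,
    h2_target: float,
    cis_fraction: float | None = None,
    seed=None,
) -> SimulatedPhenotype:
    """Assemble the phenotype with exact empirical variance shares.

    The cis genetic value is scaled to variance ``h2_target *
    cis_fraction``; the trans genetic value is residualized against the
    cis value then scaled so total genetic variance is ``h2_target``;
    the error is residualized against both and scaled to ``1 -
    h2_target``.  The realized heritability therefore equals the target
    exactly.  Missing genotypes are mean-imputed for generation only.
    """
    if not 0 <= h2_target < 1:
        raise ParameterError("h2_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = panel.n_strains
    X = panel.mean_imputed()
    eps = rng.normal(size=n)

    if effects.setting == "no_cis":
        components: list[np.ndarray] = []
        if h2_target > 0:
            g = _center(X @ effects.beta)
            g = _scale_to_variance(g, h2_target)
            components.append(g)
        e = _residualize(eps, components)
        e = _scale_to_variance(e, 1.0 - h2_target) if h2_target < 1 else e * 0
        y = sum(components, np.zeros(n)) + e
        cis_var = (
            _center(X[:, gene.cis_snp_index] @ effects.beta[gene.cis_snp_index]).var()
            if h2_target > 0 and effects.n_causal_cis(gene) > 0
            else 0.0
        )
        cis_frac = cis_var / h2_target if h2_target > 0 else None
        return SimulatedPhenotype(
            gene=gene, y=y, effects=effects, h2_target=h2_target,
            h2_realized=h2_target, cis_fraction_realized=cis_frac,
        )

    if cis_fraction is None:
        cis_fraction = rng.uniform(0.7, 0.9)
    if not 0 < cis_fraction <= 1:
        raise ParameterError("cis_fraction must be in (0, 1]")

    cis_idx = gene.cis_snp_index
    trans_idx = np.setdiff1d(np.arange(panel.n_snps), cis_idx)
    beta = effects.beta.copy()
    components = []
    if h2_target > 0:
        g_cis = _center(X[:, cis_idx] @ beta[cis_idx])
        scaled = _scale_to_variance(g_cis, h2_target * cis_fraction)
        beta[cis_idx] *= scaled.std() / g_cis.std() if g_cis.std() > 0 else 0.0
        components.append(scaled)
        g_trans = X[:, trans_idx] @ beta[trans_idx]
        if np.any(beta[trans_idx] != 0) and cis_fraction < 1:
            g_trans = _residualize(g_trans, components)
            g_trans = _scale_to_variance(g_trans, h2_target * (1.0 - cis_fraction))
            components.append(g_trans)
        else:
            cis_fraction = 1.0  # no trans variance available
    e = _residualize(eps, components)
    e = _scale_to_variance(e, 1.0 - h2_target)
    y = sum(components, np.zeros(n)) + e
    return SimulatedPhenotype(
        gene=gene,
        y=y,
        effects=EffectVector(beta=beta, causal_mask=effects.causal_mask,
                             setting=effects.setting),
        h2_target=h2_target,
        h2_realized=h2_target,
        cis_fraction_realized=cis_fraction if h2_target > 0 else None,
    )


def assign_target_heritabilities(
    n_genes: int, mode: str = "fixed_grid", params=None, seed=None
) -> np.ndarray:
    """Per-gene target heritabilities.

    ``fixed_grid`` cycles through a grid (default 0.05, 0.1, ..., 0.9)
    so every heritability stratum is populated; ``uniform`` and
    ``beta`` draw i.i.d. targets.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "fixed_grid":
        grid = np.asarray(
            params if params is not None else np.concatenate(([0.05], np.arange(1, 10) / 10.0))
        )
        out = np.resize(grid, n_genes)
    elif mode == "uniform":
        lo, hi = params if params is not None else (0.0, 1.0)
        out = rng.uniform(lo, hi, size=n_genes)
    elif mode == "beta":
        a, b = params if params is not None else (2.0, 2.0)
        out = rng.beta(a, b, size=n_genes)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    if np.any(out < 0) or np.any(out >= 1):
        raise ParameterError("heritability targets must lie in [0, 1)")
    return out


def place_genes(
    marker_map: MarkerMap,
    n_genes: int,
    gene_length_bp: int = 50_000,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
    seed=None,
    require_cis: bool = False,
    panel: GenotypePanel | None = None,
) -> list[CisRegion]:
    """Place gene bodies uniformly along the map's chromosome spans.

    With ``require_cis`` only windows containing >= 1 cis-SNP are kept
    (genes without cis-SNPs are excluded from cis-eQTL evaluation);
    passing ``panel`` additionally requires a *polymorphic* cis-SNP, so
    a cis effect can actually be simulated and mapped.
    """
    rng = np.random.default_rng(seed)
    chroms = marker_map.chromosomes
    spans = {c: int(marker_map.pos_bp[marker_map.chromosome == c].max()) for c in chroms}
    poly = None
    if panel is not None:
        with np.errstate(invalid="ignore"):
            poly = np.nanstd(panel.genotypes, axis=0) > 0
    genes = []
    i = 0
    while len(genes) < n_genes:
        c = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, max(spans[c] - gene_length_bp, 2)))
        region = cis_region(
            marker_map, f"gene_{i:05d}", c, start, start + gene_length_bp, window_bp
        )
        i += 1
        if require_cis:
            if region.q_cis == 0:
                continue
            if poly is not None and not poly[region.cis_snp_index].any():
                continue
        genes.append(region)
    return genes


def simulate_genes(
    panel: GenotypePanel,
    genes: list[CisRegion],
    setting: str,
    h2_targets,
    causal_prob: float = DEFAULT_CAUSAL_PROB,
    mean_cis_effects: float = 2.0,
    cis_fraction_bounds: tuple[float, float] = (0.7, 0.9),
    seed=None,
    max_retries: int = 20,
) -> list[SimulatedPhenotype]:
    """Simulate one phenotype per gene under a single architecture.

    Degenerate draws (e.g. a monomorphic causal cis-SNP, which leaves
    the cis component with zero variance) are resampled up to
    ``max_retries`` times before raising.
    """
    if setting not in SETTINGS:
        raise ParameterError(f"unknown setting {setting!r}")
    h2_targets = np.asarray(h2_targets, dtype=float)
    if len(h2_targets) != len(genes):
        raise ParameterError("need one h2 target per gene")
    rng = np.random.default_rng(seed)
    out = []
    for gene, h2 in zip(genes, h2_targets):
        for attempt in range(max_retries):
            try:
                if setting == "no_cis":
                    eff = draw_effects_no_cis(panel, gene, causal_prob, rng)
                    sim = rescale_components(panel, gene, eff, h2, seed=rng)
                else:
                    eff = draw_effects_cis(
                        panel, gene, setting, causal_prob, mean_cis_effects, rng
                    )
                    frac = rng.uniform(*cis_fraction_bounds)
                    sim = rescale_components(panel, gene, eff, h2, frac, seed=rng)
                out.append(sim)
                break
            except DegenerateComponentError:
                if attempt == max_retries - 1:
                    raise
    return out


def phenotype_frame(sims: list[SimulatedPhenotype], strain_ids: list[str]) -> pd.DataFrame:
    """Genes x strains phenotype matrix."""
    return pd.DataFrame(
        np.vstack([s.y for s in sims]),
        index=[s.gene.gene_id for s in sims],
        columns=strain_ids,
    )


def truth_frame(sims: list[SimulatedPhenotype]) -> pd.DataFrame:
    """Per-gene ground truth used by the evaluation layer."""
    rows = []
    for s in sims:
        n_cis = s.effects.n_causal_cis(s.gene)
        cis_frac = s.cis_fraction_realized
        rows.append(
            {
                "gene_id": s.gene.gene_id,
                "setting": s.effects.setting,
                "chromosome": s.gene.chromosome,
                "start_bp": s.gene.start_bp,
                "end_bp": s.gene.end_bp,
                "q_cis": s.gene.q_cis,
                "n_causal_cis": n_cis,
                "has_cis_effect": n_cis > 0,
                "h2_target": s.h2_target,
                "h2_realized": s.h2_realized,
                "cis_fraction_realized": np.nan if cis_frac is None else cis_frac,
                "cis_h2": (0.0 if cis_frac is None else cis_frac * s.h2_realized),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
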