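"""Genome-wide per-gene association scans.

Four mapping strategies over a panel of inbred strains:

``ols``
    single-SNP ordinary least squares, valid only when strains are
    exchangeable — with real panel structure its test statistics are
    inflated (see the genomic inflation factor in :mod:`.evaluate`);
``lmm``
    kinship linear mixed model, p-values from 1-df likelihood-ratio
    tests with the variance ratio re-optimized under the alternative;
``lmm_loco``
    the same model with a leave-one-chromosome-out kinship per tested
    SNP's chromosome;
``subpop_meta``
    separate mixed models per subpopulation (RI vs classic inbred)
    combined by Stouffer's signed z-score method.

SNPs enter a scan only after quality control: minor allele frequency
above ``maf_min`` and missingness below ``miss_max`` among the analyzed
strains; the meta-analysis requires QC to pass in *both* groups.
Missing genotype calls at a tested SNP are mean-imputed by default
(matching standard exact mixed-model association tools); a ``drop``
policy that removes those strains and refits the null on the same
subset is available per test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParameterError
from .kinship import KinshipMatrix, compute_kinship, loco_set, regularize
from .lmm import KinshipLMM, Rotation, eigendecompose
from .panel import GenotypePanel
from .phenotypes import CisRegion

__all__ = [
    "QcReport",
    "SnpTest",
    "snp_qc",
    "improbable_recomb_filter",
    "ols_test",
    "lmm_test",
    "run_scan",
    "subpop_meta",
    "stouffer_combine",
    "METHODS",
]

METHODS = ("ols", "lmm", "lmm_loco", "subpop_meta")

_P_FLOOR = 1e-300  # keep p in (0, 1] when a statistic underflows


@dataclass
class QcReport:
    """Per-SNP disposition of the quality-control step."""

    snps_input: int
    snps_removed_maf: int
    snps_removed_missing: int
    snps_removed_recomb: int
    snps_retained: int
    disposition: pd.DataFrame  # snp_id -> status

    def __post_init__(self) -> None:
        total = (
            self.snps_removed_maf
            + self.snps_removed_missing
            + self.snps_removed_recomb
            + self.snps_retained
        )
        if total != self.snps_input:
            raise ParameterError("QC counts are inconsistent")


@dataclass
class SnpTest:
    """One SNP's association test result."""

    snp_id: str
    beta_hat: float
    stat: float
    p_value: float


def snp_qc(
    panel: GenotypePanel,
    maf_min: float = 0.10,
    miss_max: float = 0.05,
    strains_in_analysis=None,
) -> tuple[QcReport, GenotypePanel]:
    """Filter SNPs on MAF and missingness among the analyzed strains.

    A SNP is removed if its minor allele frequency (over non-missing
    strains) is <= ``maf_min`` or its missingness is >= ``miss_max``.
    Missingness is checked first, so a SNP failing both is counted
    under missingness.
    """
    if not 0 <= maf_min <= 0.5:
        raise ParameterError("maf_min must be in [0, 0.5]")
    if not 0 <= miss_max <= 1:
        raise ParameterError("miss_max must be in [0, 1]")
    sub = panel if strains_in_analysis is None else panel.subset_strains(strains_in_analysis)
    miss = np.isnan(sub.genotypes).mean(axis=0)
    maf = sub.minor_allele_frequency()
    maf = np.where(np.isnan(maf), 0.0, maf)  # fully missing SNP: treated as MAF 0

    status = np.full(panel.n_snps, "retained", dtype=object)
    fail_miss = miss >= miss_max
    fail_maf = (maf <= maf_min) & ~fail_miss
    status[fail_miss] = "removed_missing"
    status[fail_maf] = "removed_maf"
    keep = status == "retained"
    if not keep.any():
        raise ConfigurationError("quality control removed every SNP")
    report = QcReport(
        snps_input=panel.n_snps,
        snps_removed_maf=int(fail_maf.sum()),
        snps_removed_missing=int(fail_miss.sum()),
        snps_removed_recomb=0,
        snps_retained=int(keep.sum()),
        disposition=pd.DataFrame({"snp_id": panel.map.snp_id, "status": status}),
    )
    return report, panel.subset_snps(keep)


def improbable_recomb_filter(maps, gap_cM: float = 20.0) -> list[str]:
    """SNPs implying improbable recombination on the genetic map.

    An interior SNP is flagged when *both* adjacent same-chromosome gaps
    are >= ``gap_cM``; a chromosome-terminal SNP when its single gap is.
    ``maps`` may be a single map or a mapping of RI-population name ->
    map; the union of flagged SNPs across populations is returned.
    """
    if not isinstance(maps, dict):
        maps = {"all": maps}
    removed: set[str] = set()
    for m in maps.values():
        for chrom in m.chromosomes:
            idx = m.chromosome_indices(chrom)
            cm = m.pos_cM[idx]
            if len(idx) == 1:
                continue  # no neighbour to measure a gap against
            gaps = np.diff(cm)
            for k, snp_pos in enumerate(idx):
                left = gaps[k - 1] if k > 0 else None
                right = gaps[k] if k < len(gaps) else None
                flagged = (
                    (left is None and right >= gap_cM)
                    or (right is None and left >= gap_cM)
                    or (left is not None and right is not None
                        and left >= gap_cM and right >= gap_cM)
                )
                if flagged:
                    removed.add(m.snp_id[snp_pos])
    return sorted(removed)


def ols_test(y: np.ndarray, snp_genotypes: np.ndarray, snp_id: str = "") -> SnpTest:
    """Single-SNP ordinary least squares, likelihood-ratio p-value.

    The 1-df statistic n*log(RSS0/RSS1) matches the mixed-model LRT at
    identity kinship exactly, which makes the two methods directly
    comparable.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(snp_genotypes, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 3:
        raise ParameterError("need at least 3 strains with observed genotype")
    if np.all(x == x[0]):
        raise ParameterError(f"SNP {snp_id or '<unnamed>'} is monomorphic")
    xc = x - x.mean()
    yc = y - y.mean()
    beta = float(xc @ yc / (xc @ xc))
    rss1 = float(yc @ yc - beta * (xc @ yc) * 1.0)
    rss0 = float(yc @ yc)
    rss1 = max(rss1, 0.0)
    if rss1 == 0.0:
        return SnpTest(snp_id=snp_id, beta_hat=beta, stat=np.inf, p_value=_P_FLOOR)
    stat = n * np.log(rss0 / rss1)
    p = float(stats.chi2.sf(stat, df=1))
    return SnpTest(snp_id=snp_id, beta_hat=beta, stat=stat, p_value=max(p, _P_FLOOR))


class _NullCache:
    """Null-model fits keyed by (kinship identity, strain subset).

    Missing genotypes force per-SNP strain subsets; the null model must
    be refit on exactly the strains entering the alternative model, so
    fits (and subset eigendecompositions) are memoized.
    """

    def __init__(self, y: np.ndarray, kinship: KinshipMatrix, eigen_floor: float = 1e-8):
        self.y = y
        self.kinship = regularize(kinship, eigen_floor)
        self._cache: dict[bytes, tuple[Rotation, object]] = {}

    def get(self, keep: np.ndarray):
        key = keep.tobytes()
        hit = self._cache.get(key)
        if hit is None:
            k = self.kinship.values[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))]
            rot = eigendecompose(k)
            y = self.y[keep]
            null = KinshipLMM(y, np.ones((keep.sum(), 1)), rotation=rot).fit()
            hit = (rot, null)
            self._cache[key] = hit
        return hit


def lmm_test(
    y: np.ndarray,
    snp_genotypes: np.ndarray,
    cache: _NullCache,
    snp_id: str = "",
    missing: str = "impute",
) -> SnpTest:
    """Mixed-model LRT for one SNP.

    ``missing="impute"`` (default, matching standard exact mixed-model
    association tools) replaces missing genotype calls with the SNP
    mean so every strain stays in the model and all SNPs share one null
    fit; ``missing="drop"`` removes those strains and refits the null
    on the same subset, keeping the LRT strictly nested at the cost of
    per-SNP strain sets.
    """
    x = np.asarray(snp_genotypes, dtype=float)
    obs = ~np.isnan(x)
    if np.all(x[obs] == x[obs][0]):
        raise ParameterError(f"SNP {snp_id or '<unnamed>'} is monomorphic")
    if missing == "impute":
        xk = np.where(obs, x, x[obs].mean())
        keep = np.ones(len(x), dtype=bool)
    elif missing == "drop":
        xk = x[obs]
        keep = obs
    else:
        raise ParameterError("missing must be 'impute' or 'drop'")
    rot, null = cache.get(keep)
    yk = cache.y[keep]
    X = np.column_stack([np.ones(len(xk)), xk])
    alt = KinshipLMM(yk, X, rotation=rot).fit()
    stat, p = alt.lr_test(null)
    return SnpTest(
        snp_id=snp_id, beta_hat=float(alt.params[1]), stat=stat,
        p_value=max(p, _P_FLOOR),
    )


def run_scan(
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    genes: list[CisRegion],
    method: str,
    kinship: KinshipMatrix | None = None,
    loco_kinships: dict | None = None,
    maf_min: float = 0.10,
    miss_max: float = 0.05,
    cis_only: bool = False,
    subpop_groups: dict | None = None,
    eigen_floor: float = 1e-8,
    missing: str = "impute",
) -> tuple[pd.DataFrame, QcReport]:
    """Scan every gene's phenotype against QC-passing SNPs.

    ``genes`` carry cis-SNP indices *into the unfiltered panel*; they
    are re-derived on the QC-filtered panel internally.  Rows come back
    sorted by (gene, chromosome, position) with columns gene_id,
    method, snp_id, chromosome, pos_bp, is_cis, beta_hat, stat,
    p_value.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}")
    if method == "subpop_meta":
        return subpop_meta(
            panel, phenotypes, genes,
            groups=subpop_groups, maf_min=maf_min, miss_max=miss_max,
            cis_only=cis_only, eigen_floor=eigen_floor, missing=missing,
        )
    if method in ("lmm",) and kinship is None:
        raise ConfigurationError("method 'lmm' requires a kinship matrix")
    if method == "lmm_loco":
        if loco_kinships is None:
            raise ConfigurationError("method 'lmm_loco' requires per-chromosome kinships")
        absent = set(panel.map.chromosomes) - set(loco_kinships)
        if absent:
            raise ConfigurationError(f"no LOCO kinship for chromosomes {sorted(absent)}")

    report, fpanel = snp_qc(panel, maf_min, miss_max)
    snp_pos = {s: i for i, s in enumerate(fpanel.map.snp_id)}
    # remap cis indices onto the filtered panel
    id_by_orig = panel.map.snp_id
    rows = []
    for gene in genes:
        y = phenotypes.loc[gene.gene_id].to_numpy(dtype=float)
        cis_ids = id_by_orig[gene.cis_snp_index]
        cis_idx_f = np.array(
            [snp_pos[s] for s in cis_ids if s in snp_pos], dtype=int
        )
        test_idx = cis_idx_f if cis_only else np.arange(fpanel.n_snps)
        cis_set = set(cis_idx_f)

        caches: dict[object, _NullCache] = {}
        for j in test_idx:
            chrom = fpanel.map.chromosome[j]
            if method == "ols":
                t = ols_test(y, fpanel.genotypes[:, j], fpanel.map.snp_id[j])
            else:
                if method == "lmm":
                    key, kin = "all", kinship
                else:
                    key, kin = chrom, loco_kinships[chrom]
                cache = caches.get(key)
                if cache is None:
                    cache = caches[key] = _NullCache(y, kin, eigen_floor)
                t = lmm_test(y, fpanel.genotypes[:, j], cache, fpanel.map.snp_id[j],
                             missing=missing)
            rows.append(
                (gene.gene_id, method, t.snp_id, chrom, fpanel.map.pos_bp[j],
                 j in cis_set, t.beta_hat, t.stat, t.p_value)
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "method", "snp_id", "chromosome", "pos_bp",
                 "is_cis", "beta_hat", "stat", "p_value"],
    ).sort_values(["gene_id", "chromosome", "pos_bp"], kind="mergesort", ignore_index=True)
    return out, report


def stouffer_combine(p_values, betas, weights=None) -> tuple[float, float]:
    """Stouffer's method on direction-signed z-scores.

    Each two-sided p becomes z = sign(beta) * Phi^-1(1 - p/2); the
    combined z is the (optionally weighted) sum over groups divided by
    the root sum of squared weights, and the meta p-value is two-sided.
    """
    p = np.asarray(p_values, dtype=float)
    b = np.asarray(betas, dtype=float)
    if weights is None:
        weights = np.ones_like(p)
    w = np.asarray(weights, dtype=float)
    z = np.sign(b) * stats.norm.isf(p / 2.0)
    z_meta = float((w * z).sum() / np.sqrt((w**2).sum()))
    p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    return z_meta, min(max(p_meta, _P_FLOOR), 1.0)


def default_subpop_groups(panel: GenotypePanel) -> dict:
    """RI strains vs everything else (classic inbreds and, in the real
    panel, the RI progenitors)."""
    ri = np.isin(panel.subpopulation, ("RI1", "RI2"))
    return {"RI": np.flatnonzero(ri), "CLASSIC": np.flatnonzero(~ri)}


def subpop_meta(
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    genes: list[CisRegion],
    groups: dict | None = None,
    maf_min: float = 0.10,
    miss_max: float = 0.05,
    cis_only: bool = False,
    min_group_size: int = 10,
    eigen_floor: float = 1e-8,
    missing: str = "impute",
) -> tuple[pd.DataFrame, QcReport]:
    """Per-subpopulation mixed models combined by Stouffer's method.

    Only SNPs passing QC in *both* groups are analyzed; each group gets
    its own allele-sharing kinship estimated from its own strains.
    """
    if groups is None:
        groups = default_subpop_groups(panel)
    if len(groups) != 2:
        raise ConfigurationError("subpopulation meta-analysis needs exactly 2 groups")
    for name, idx in groups.items():
        if len(idx) < min_group_size:
            raise ConfigurationError(
                f"group {name!r} has {len(idx)} strains (< {min_group_size})"
            )

    subpanels, reports = {}, {}
    keep_ids: set[str] | None = None
    for name, idx in groups.items():
        rep, sub = snp_qc(panel.subset_strains(idx), maf_min, miss_max)
        subpanels[name] = sub
        reports[name] = rep
        ids = set(sub.map.snp_id)
        keep_ids = ids if keep_ids is None else keep_ids & ids
    assert keep_ids is not None
    if not keep_ids:
        raise ConfigurationError("no SNP passed quality control in both groups")

    # harmonize: both subpanels restricted to the intersection
    for name in subpanels:
        sp = subpanels[name]
        subpanels[name] = sp.subset_snps(np.isin(sp.map.snp_id, sorted(keep_ids)))
    names = list(subpanels)
    ref = subpanels[names[0]]
    kinships = {name: compute_kinship(sp) for name, sp in subpanels.items()}

    status = np.where(
        np.isin(panel.map.snp_id, sorted(keep_ids)), "retained", "removed_subpop_qc"
    ).astype(object)
    n_retained = int((status == "retained").sum())
    report = QcReport(
        snps_input=panel.n_snps,
        # SNPs failing either group's QC, folded into one bucket
        snps_removed_maf=panel.n_snps - n_retained,
        snps_removed_missing=0,
        snps_removed_recomb=0,
        snps_retained=n_retained,
        disposition=pd.DataFrame({"snp_id": panel.map.snp_id, "status": status}),
    )

    snp_pos = {s: i for i, s in enumerate(ref.map.snp_id)}
    rows = []
    for gene in genes:
        cis_ids = panel.map.snp_id[gene.cis_snp_index]
        cis_idx = np.array([snp_pos[s] for s in cis_ids if s in snp_pos], dtype=int)
        test_idx = cis_idx if cis_only else np.arange(ref.n_snps)
        cis_set = set(cis_idx)
        caches = {
            name: _NullCache(
                phenotypes.loc[gene.gene_id, list(sp.strain_ids)].to_numpy(dtype=float),
                kinships[name],
                eigen_floor,
            )
            for name, sp in subpanels.items()
        }
        for j in test_idx:
            ps, bs = [], []
            ok = True
            for name, sp in subpanels.items():
                x = sp.genotypes[:, j]
                obs = x[~np.isnan(x)]
                if obs.size == 0 or np.all(obs == obs[0]):
                    ok = False  # monomorphic within this group for this SNP
                    break
                t = lmm_test(caches[name].y, x, caches[name], sp.map.snp_id[j],
                             missing=missing)
                ps.append(t.p_value)
                bs.append(t.beta_hat)
            if not ok:
                continue
            z, p = stouffer_combine(ps, bs)
            rows.append(
                (gene.gene_id, "subpop_meta", ref.map.snp_id[j],
                 ref.map.chromosome[j], ref.map.pos_bp[j], j in cis_set,
                 float(np.mean(bs)), z, p)
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "method", "snp_id", "chromosome", "pos_bp",
                 "is_cis", "beta_hat", "stat", "p_value"],
    ).sort_values(["gene_id", "chromosome", "pos_bp"], kind="mergesort", ignore_index=True)
    return out, report
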