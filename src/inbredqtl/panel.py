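"""Synthetic inbred-panel genotypes.

Real rodent diversity panels combine recombinant-inbred (RI) subpanels —
fixed homozygous mosaics of two founder haplotypes — with a set of
divergent classic inbred strains.  Nothing downstream of this module
should care whether genotypes came from a file or from these generators,
so both produce the same :class:`GenotypePanel` container: a strains ×
SNPs matrix of homozygous allele codes 0/1 (``nan`` = missing call) plus
a marker map carrying physical (bp) and genetic (cM) coordinates.

The generators are deliberately simple stand-ins for real genotype data:
RI chromosomes recombine as a Poisson process on the genetic map with a
map-expansion factor (~4 for sib-mated RI lines), and classic inbreds
are Li–Stephens-style mosaics over a small pool of ancestral haplotypes.
They reproduce the qualitative kinship structure (high within-RI
relatedness, lower relatedness to divergent inbreds) rather than any
particular real panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegeneratePanelError, ParameterError, StructuralError

__all__ = [
    "MarkerMap",
    "GenotypePanel",
    "make_map",
    "simulate_ri_subpanel",
    "simulate_classic_subpanel",
    "assemble_panel",
    "inject_missingness",
]

SUBPOPULATIONS = ("RI1", "RI2", "CLASSIC")


@dataclass(frozen=True)
class MarkerMap:
    """Per-SNP map coordinates: chromosome, physical (bp), genetic (cM)."""

    snp_id: np.ndarray
    chromosome: np.ndarray
    pos_bp: np.ndarray
    pos_cM: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        for name in ("chromosome", "pos_bp", "pos_cM"):
            if len(getattr(self, name)) != n:
                raise StructuralError(f"map field {name!r} has wrong length")
        if len(np.unique(self.snp_id)) != n:
            raise StructuralError("duplicate snp_ids in map")
        if np.any(self.pos_cM < 0):
            raise StructuralError("negative cM position")
        for chrom in np.unique(self.chromosome):
            sel = self.chromosome == chrom
            bp, cm = self.pos_bp[sel], self.pos_cM[sel]
            if np.any(np.diff(bp) <= 0):
                raise StructuralError(f"pos_bp not strictly increasing on chromosome {chrom}")
            if np.any(np.diff(cm) < 0):
                raise StructuralError(f"pos_cM decreasing on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def chromosomes(self) -> np.ndarray:
        """Chromosome labels in order of first appearance."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return self.chromosome[np.sort(idx)]

    def chromosome_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.chromosome == chrom)

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            snp_id=self.snp_id[indices],
            chromosome=self.chromosome[indices],
            pos_bp=self.pos_bp[indices],
            pos_cM=self.pos_cM[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "pos_bp": self.pos_bp,
                "pos_cM": self.pos_cM,
            }
        )

    def __eq__(self, other) -> bool:  # dataclass eq fails on arrays
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return (
            np.array_equal(self.snp_id, other.snp_id)
            and np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.pos_bp, other.pos_bp)
            and np.array_equal(self.pos_cM, other.pos_cM)
        )


@dataclass
class GenotypePanel:
    """Homozygous biallelic genotypes for a panel of fully inbred strains.

    ``genotypes`` is a float array of shape (n_strains, n_snps) with
    entries in {0.0, 1.0, nan}; strains are haploid-equivalent because
    every strain is fully inbred.
    """

    strain_ids: list[str]
    subpopulation: np.ndarray
    genotypes: np.ndarray
    map: MarkerMap
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self._skip_validation:
            return
        if len(self.strain_ids) < 1:
            raise StructuralError("panel needs at least 1 strain")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise StructuralError("duplicate strain ids")
        if self.genotypes.shape != (len(self.strain_ids), len(self.map)):
            raise StructuralError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.map)} SNPs"
            )
        if len(self.subpopulation) != len(self.strain_ids):
            raise StructuralError("subpopulation labels do not match strains")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise StructuralError("non-missing genotypes must be 0 or 1 (inbred, homozygous)")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_snps(self) -> int:
        return len(self.map)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.genotypes)

    def allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of allele 1 among non-missing strains."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def subset_strains(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return GenotypePanel(
            strain_ids=[self.strain_ids[i] for i in indices],
            subpopulation=self.subpopulation[indices],
            genotypes=self.genotypes[indices],
            map=self.map,
            _skip_validation=True,
        )

    def subset_snps(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return GenotypePanel(
            strain_ids=list(self.strain_ids),
            subpopulation=self.subpopulation,
            genotypes=self.genotypes[:, indices],
            map=self.map.subset(indices),
            _skip_validation=True,
        )

    def mean_imputed(self) -> np.ndarray:
        """Genotypes with per-SNP mean imputation of missing calls."""
        g = self.genotypes.copy()
        miss = np.isnan(g)
        if miss.any():
            with np.errstate(invalid="ignore"):
                means = np.nanmean(g, axis=0)
            means = np.where(np.isnan(means), 0.5, means)  # fully missing SNP
            g[miss] = np.broadcast_to(means, g.shape)[miss]
        return g


def make_map(
    n_chromosomes: int,
    snps_per_chromosome: int,
    chrom_length_cM: float = 100.0,
    chrom_length_bp: float = 100e6,
    seed: int | np.random.Generator | None = None,
) -> MarkerMap:
    """Random marker map: uniform SNP placement, cM proportional to bp."""
    if n_chromosomes < 1 or snps_per_chromosome < 1:
        raise ParameterError("counts must be >= 1")
    if chrom_length_cM <= 0 or chrom_length_bp <= 0:
        raise ParameterError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    snp_id, chrom, bp, cm = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(
            rng.choice(int(chrom_length_bp), size=snps_per_chromosome, replace=False)
        ) + 1  # 1-based, strictly increasing
        snp_id.extend(f"chr{c}_snp{i}" for i in range(snps_per_chromosome))
        chrom.extend([c] * snps_per_chromosome)
        bp.append(pos)
        cm.append(pos / chrom_length_bp * chrom_length_cM)
    return MarkerMap(
        snp_id=np.array(snp_id),
        chromosome=np.array(chrom),
        pos_bp=np.concatenate(bp),
        pos_cM=np.concatenate(cm),
    )


def _switch_count(pos_cM: np.ndarray, rate_per_cM: float, rng) -> tuple[int, np.ndarray]:
    lo, hi = pos_cM[0], pos_cM[-1]
    if rate_per_cM <= 0 or hi <= lo:
        return 0, np.empty(0)
    n = int(rng.poisson(rate_per_cM * (hi - lo)))
    return n, np.sort(rng.uniform(lo, hi, size=n))


def _alternating_origins(
    pos_cM: np.ndarray, rate_per_cM: float, start: int, rng: np.random.Generator
) -> np.ndarray:
    """Founder origin along an RI chromosome: breakpoints form a Poisson
    process on the genetic map and *alternate* between the two founders."""
    n_bp, bp_pos = _switch_count(pos_cM, rate_per_cM, rng)
    if n_bp == 0:
        return np.full(len(pos_cM), start)
    crossed = np.searchsorted(bp_pos, pos_cM, side="right")
    return (start + crossed) % 2


def _mosaic_origins(
    pos_cM: np.ndarray, rate_per_cM: float, n_sources: int, start: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-SNP source index for one chromosome of a Li–Stephens mosaic.

    Switch points form a Poisson process with ``rate_per_cM`` on the
    genetic map; at each switch a new source is drawn uniformly from the
    pool (possibly the same one, as in Li–Stephens copying models).
    """
    n_switch, switch_pos = _switch_count(pos_cM, rate_per_cM, rng)
    if n_switch == 0:
        return np.full(len(pos_cM), start)
    sources = np.concatenate(([start], rng.integers(n_sources, size=n_switch)))
    segment = np.searchsorted(switch_pos, pos_cM, side="right")
    return sources[segment]


def simulate_ri_subpanel(
    marker_map: MarkerMap,
    n_strains: int,
    founder_a_haplotype: np.ndarray,
    founder_b_haplotype: np.ndarray,
    expansion_factor: float = 4.0,
    seed: int | np.random.Generator | None = None,
    subpopulation: str = "RI1",
    strain_prefix: str | None = None,
) -> GenotypePanel:
    """Recombinant-inbred subpanel: founder-haplotype mosaics.

    Each strain chromosome starts from either founder with probability
    1/2 and accumulates breakpoints as a Poisson process with rate
    ``expansion_factor`` per Morgan on the cM scale — the classical map
    expansion of a sib-mated RI panel relative to a single meiosis.
    """
    if n_strains < 1:
        raise ParameterError("n_strains must be >= 1")
    if expansion_factor < 0:
        raise ParameterError("expansion_factor must be >= 0")
    a = np.asarray(founder_a_haplotype, dtype=float)
    b = np.asarray(founder_b_haplotype, dtype=float)
    if a.shape != (len(marker_map),) or b.shape != (len(marker_map),):
        raise StructuralError("founder haplotypes must match map length")
    for h, name in ((a, "founder_a"), (b, "founder_b")):
        if not np.isin(h, (0.0, 1.0)).all():
            raise ParameterError(f"{name} must be a 0/1 vector")
    if np.array_equal(a, b):
        raise DegeneratePanelError("founders identical everywhere: panel would be monomorphic")

    rng = np.random.default_rng(seed)
    founders = np.stack([a, b])
    genotypes = np.empty((n_strains, len(marker_map)))
    rate = expansion_factor / 100.0  # per cM
    for s in range(n_strains):
        for chrom in marker_map.chromosomes:
            idx = marker_map.chromosome_indices(chrom)
            start = int(rng.integers(2))  # either founder, prob 1/2 per chromosome
            origins = _alternating_origins(marker_map.pos_cM[idx], rate, start, rng)
            genotypes[s, idx] = founders[origins, idx]
    prefix = strain_prefix or subpopulation
    return GenotypePanel(
        strain_ids=[f"{prefix}_{i:03d}" for i in range(n_strains)],
        subpopulation=np.full(n_strains, subpopulation, dtype=object),
        genotypes=genotypes,
        map=marker_map,
    )


def draw_founder_haplotypes(
    marker_map: MarkerMap,
    n_haplotypes: int,
    freq_low: float = 0.1,
    freq_high: float = 0.9,
    seed: int | np.random.Generator | None = None,
    ld_decay_per_cM: float = 0.03,
) -> np.ndarray:
    """Pool of ancestral 0/1 haplotypes with realistic along-chromosome LD.

    Per-SNP allele frequencies are drawn from Uniform(freq_low,
    freq_high).  Within each haplotype, alleles persist along the
    genetic map: moving a distance d cM the allele is resampled from
    the local frequency with probability 1 - exp(-ld_decay_per_cM * d),
    otherwise copied from the previous SNP.  Inbred-strain haplotypes
    carry long shared segments, so neighbouring array SNPs are strongly
    correlated; ``ld_decay_per_cM = 0`` gives fully persistent
    (monotone) haplotypes, large values give independent SNPs.
    """
    rng = np.random.default_rng(seed)
    L = len(marker_map)
    freqs = rng.uniform(freq_low, freq_high, size=L)
    H = np.empty((n_haplotypes, L))
    for chrom in marker_map.chromosomes:
        idx = marker_map.chromosome_indices(chrom)
        cm = marker_map.pos_cM[idx]
        H[:, idx[0]] = rng.random(n_haplotypes) < freqs[idx[0]]
        for prev, cur, d in zip(idx[:-1], idx[1:], np.diff(cm)):
            resample = rng.random(n_haplotypes) < 1.0 - np.exp(-ld_decay_per_cM * d)
            fresh = (rng.random(n_haplotypes) < freqs[cur]).astype(float)
            H[:, cur] = np.where(resample, fresh, H[:, prev])
    return H


def simulate_classic_subpanel(
    marker_map: MarkerMap,
    n_strains: int,
    n_ancestral_haplotypes: int = 8,
    mosaic_switch_rate: float = 0.02,
    seed: int | np.random.Generator | None = None,
    subpopulation: str = "CLASSIC",
    strain_prefix: str | None = None,
    ancestral_haplotypes: np.ndarray | None = None,
    freq_range: tuple[float, float] = (0.1, 0.9),
) -> GenotypePanel:
    """Divergent classic-inbred subpanel.

    Strains are Li–Stephens-style mosaics (switch rate per cM) over a
    pool of ancestral haplotypes, then taken as homozygous — classic
    inbred lines are fixed, so the mosaic is the strain genome.
    """
    if n_strains < 1:
        raise ParameterError("n_strains must be >= 1")
    if n_ancestral_haplotypes < 2:
        raise ParameterError("need at least 2 ancestral haplotypes")
    if mosaic_switch_rate < 0:
        raise ParameterError("mosaic_switch_rate must be >= 0")
    rng = np.random.default_rng(seed)
    if ancestral_haplotypes is None:
        pool = draw_founder_haplotypes(
            marker_map, n_ancestral_haplotypes, freq_range[0], freq_range[1], rng
        )
    else:
        pool = np.asarray(ancestral_haplotypes, dtype=float)
        if pool.shape != (n_ancestral_haplotypes, len(marker_map)):
            raise StructuralError("ancestral haplotype pool has wrong shape")

    genotypes = np.empty((n_strains, len(marker_map)))
    # chromosome boundaries behave like a wide (50 cM) unobserved gap:
    # at switch rate 0 a strain copies a single ancestor genome-wide
    p_boundary = 1.0 - np.exp(-mosaic_switch_rate * 50.0)
    for s in range(n_strains):
        current = int(rng.integers(len(pool)))
        for ci, chrom in enumerate(marker_map.chromosomes):
            idx = marker_map.chromosome_indices(chrom)
            if ci > 0 and rng.random() < p_boundary:
                current = int(rng.integers(len(pool)))
            origins = _mosaic_origins(
                marker_map.pos_cM[idx], mosaic_switch_rate, len(pool), current, rng
            )
            genotypes[s, idx] = pool[origins, idx]
            current = int(origins[-1])
    prefix = strain_prefix or subpopulation
    return GenotypePanel(
        strain_ids=[f"{prefix}_{i:03d}" for i in range(n_strains)],
        subpopulation=np.full(n_strains, subpopulation, dtype=object),
        genotypes=genotypes,
        map=marker_map,
    )


def assemble_panel(*subpanels: GenotypePanel) -> GenotypePanel:
    """Concatenate subpanels sharing one map, keeping subpopulation labels."""
    if not subpanels:
        raise ParameterError("need at least one subpanel")
    first = subpanels[0]
    for sp in subpanels[1:]:
        if sp.map != first.map:
            raise StructuralError("subpanels have different marker maps")
    ids = [sid for sp in subpanels for sid in sp.strain_ids]
    if len(set(ids)) != len(ids):
        raise StructuralError("strain ids collide across subpanels")
    return GenotypePanel(
        strain_ids=ids,
        subpopulation=np.concatenate([sp.subpopulation for sp in subpanels]),
        genotypes=np.vstack([sp.genotypes for sp in subpanels]),
        map=first.map,
    )


def inject_missingness(
    panel: GenotypePanel, rate: float, seed: int | np.random.Generator | None = None
) -> GenotypePanel:
    """Set each genotype entry missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ParameterError("missingness rate must be in [0, 1)")
    if rate == 0:
        return panel
    rng = np.random.default_rng(seed)
    g = panel.genotypes.copy()
    g[rng.random(g.shape) < rate] = np.nan
    return replace(panel, genotypes=g)
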