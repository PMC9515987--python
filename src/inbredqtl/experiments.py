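"""Seeded end-to-end simulation experiments.

Two designs mirror the two study layouts:

* the **43-strain design** — one RI subpanel of 30 strains plus 13
  divergent classic inbreds — compares the standard mixed model, the
  LOCO mixed model and the subpopulation meta-analysis on identical
  phenotypes;
* the **subpopulation design** — two RI subpanels (33 and 30 strains)
  plus 29 classic inbreds, 92 strains in all — runs the LOCO mixed
  model on each subpopulation and on the full panel.

Every stochastic step draws its generator from a
``numpy.random.SeedSequence`` spawned from the master seed, so a config
plus master seed reproduces an experiment bit for bit.  Default sizes
(hundreds of genes, a few thousand SNPs on 5 chromosomes) are desk
scale: large enough for stable power and error estimates at the strata
of interest, small enough to run in minutes on one core.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .evaluate import DEFAULT_STRATA, EvaluationSummary, evaluate_scan
from .kinship import compute_kinship, loco_set
from .panel import (
    GenotypePanel,
    assemble_panel,
    draw_founder_haplotypes,
    inject_missingness,
    make_map,
    simulate_classic_subpanel,
    simulate_ri_subpanel,
)
from .phenotypes import (
    assign_target_heritabilities,
    phenotype_frame,
    place_genes,
    simulate_genes,
    truth_frame,
)
from .scan import run_scan

__all__ = ["ExperimentConfig", "build_panel", "simulate_study", "run_43strain", "run_subpop"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulation experiment."""

    # panel: genome dimensions mirror a 20-autosome rodent genome
    # (~2.6 Gb, ~1500 cM) typed on an ~18k-SNP array (~7 SNPs/Mb)
    ri_sizes: list = field(default_factory=lambda: [30])
    classic_size: int = 13
    n_chromosomes: int = 20
    snps_per_chromosome: int = 900
    chrom_length_cM: float = 75.0
    chrom_length_bp: float = 130e6
    expansion_factor: float = 4.0
    n_ancestral_haplotypes: int = 8
    mosaic_switch_rate: float = 0.02
    missingness: float = 0.02
    # phenotypes
    setting: str = "one_cis"
    n_genes: int = 200
    h2_mode: str = "fixed_grid"
    h2_params: list | None = None
    causal_prob: float = 0.10
    mean_cis_effects: float = 2.0
    cis_fraction_bounds: tuple = (0.7, 0.9)
    gene_length_bp: int = 50_000
    window_bp: int = 1_000_000
    # analysis
    methods: list = field(default_factory=lambda: ["lmm", "lmm_loco", "subpop_meta"])
    alpha: float = 0.05
    maf_min: float = 0.10
    miss_max: float = 0.05
    strata_breaks: list = field(default_factory=lambda: list(DEFAULT_STRATA))
    cis_only: bool = True
    # reproducibility
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0 <= self.maf_min <= 0.5:
            raise ParameterError("maf_min must be in [0, 0.5]")
        if self.n_genes < 1 or not self.ri_sizes:
            raise ParameterError("need at least one gene and one RI subpanel")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cis_fraction_bounds"] = list(d["cis_fraction_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "cis_fraction_bounds" in d:
            d["cis_fraction_bounds"] = tuple(d["cis_fraction_bounds"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _spawn(master_seed: int, stage: int, n: int):
    """Per-stage child seeds; stage keys keep panel and phenotype streams apart."""
    return np.random.SeedSequence((master_seed, stage)).spawn(n)


def build_panel(config: ExperimentConfig) -> GenotypePanel:
    """Panel per the config: RI subpanels plus a classic-inbred subpanel."""
    seeds = _spawn(config.master_seed, 0, 3 + 2 * len(config.ri_sizes))
    marker_map = make_map(
        config.n_chromosomes,
        config.snps_per_chromosome,
        config.chrom_length_cM,
        config.chrom_length_bp,
        seed=seeds[0],
    )
    subpanels = []
    for i, n_ri in enumerate(config.ri_sizes):
        founders = draw_founder_haplotypes(marker_map, 2, seed=seeds[1 + 2 * i])
        subpanels.append(
            simulate_ri_subpanel(
                marker_map, n_ri, founders[0], founders[1],
                expansion_factor=config.expansion_factor,
                seed=seeds[2 + 2 * i], subpopulation=f"RI{i + 1}",
            )
        )
    if config.classic_size > 0:
        subpanels.append(
            simulate_classic_subpanel(
                marker_map, config.classic_size,
                n_ancestral_haplotypes=config.n_ancestral_haplotypes,
                mosaic_switch_rate=config.mosaic_switch_rate,
                seed=seeds[1 + 2 * len(config.ri_sizes)],
            )
        )
    panel = assemble_panel(*subpanels)
    if config.missingness > 0:
        panel = inject_missingness(
            panel, config.missingness, seed=seeds[2 + 2 * len(config.ri_sizes)]
        )
    return panel


def simulate_study(config: ExperimentConfig):
    """Panel, genes, phenotype matrix and truth table for one experiment."""
    panel = build_panel(config)
    seeds = _spawn(config.master_seed, 1, 3)
    genes = place_genes(
        panel.map, config.n_genes, config.gene_length_bp, config.window_bp,
        seed=seeds[0], require_cis=(config.setting != "no_cis"), panel=panel,
    )
    if config.h2_mode == "pve_like":
        h2 = pve_like_targets(panel, config.n_genes, seed=seeds[1])
    else:
        h2 = assign_target_heritabilities(
            config.n_genes, config.h2_mode, config.h2_params, seed=seeds[1]
        )
    sims = simulate_genes(
        panel, genes, config.setting, h2,
        causal_prob=config.causal_prob,
        mean_cis_effects=config.mean_cis_effects,
        cis_fraction_bounds=tuple(config.cis_fraction_bounds),
        seed=seeds[2],
    )
    return panel, genes, phenotype_frame(sims, panel.strain_ids), truth_frame(sims)


def pve_like_targets(
    panel: GenotypePanel,
    n_genes: int,
    seed=None,
    latent_h2_range: tuple[float, float] = (0.0, 0.8),
) -> np.ndarray:
    """Heritability targets distributed like estimated PVEs.

    The study anchors each simulated gene's heritability at the mixed
    model's PVE *estimate* for the corresponding real trait.  Estimated
    PVEs on small inbred panels are right-skewed with a point mass at
    zero (the variance ratio often hits its boundary), so a grid or
    uniform draw over-represents high heritabilities.  This helper
    reproduces the estimate distribution self-consistently: draw latent
    traits with kinship-structured genetic variance, estimate each
    trait's PVE with the package's own mixed model, and return the
    estimates as targets.
    """
    from .lmm import KinshipLMM, eigendecompose

    reg = regularize_kinship(panel)
    rot = eigendecompose(reg)
    n = reg.n_strains
    L = np.linalg.cholesky(reg.values + 1e-8 * np.eye(n))
    rng = np.random.default_rng(seed)
    ones = np.ones((n, 1))
    out = np.empty(n_genes)
    for i in range(n_genes):
        h2 = rng.uniform(*latent_h2_range)
        y = np.sqrt(h2) * (L @ rng.normal(size=n)) + np.sqrt(1.0 - h2) * rng.normal(size=n)
        out[i] = KinshipLMM(y, ones, rotation=rot).fit().pve
    return np.clip(out, 0.0, 0.99)


def regularize_kinship(panel: GenotypePanel):
    from .kinship import regularize

    return regularize(compute_kinship(panel))


def _scan_kwargs(method: str, panel: GenotypePanel):
    if method == "lmm":
        return {"kinship": compute_kinship(panel)}
    if method == "lmm_loco":
        return {"loco_kinships": loco_set(panel)}
    return {}


def run_43strain(config: ExperimentConfig) -> dict[str, EvaluationSummary]:
    """43-strain design: all configured methods on identical phenotypes."""
    panel, genes, phenos, truth = simulate_study(config)
    out: dict[str, EvaluationSummary] = {}
    for method in config.methods:
        results, _ = run_scan(
            panel, phenos, genes, method,
            maf_min=config.maf_min, miss_max=config.miss_max,
            cis_only=config.cis_only, **_scan_kwargs(method, panel),
        )
        out[method] = evaluate_scan(
            results, truth, alpha=config.alpha, breaks=config.strata_breaks
        )
    return out


def null_false_positive_study(
    seed: int, n_genes: int = 1500, methods=("lmm", "lmm_loco", "subpop_meta")
) -> dict:
    """Gene-level false-positive study on the 43-strain design.

    Simulates the no-cis-effect architecture (every SNP causal with
    probability 0.10, heritability targets distributed like estimated
    PVEs), keeps the global-null genes — those whose cis window holds
    no causal SNP — and measures, for each mapping method, the share of
    null genes with at least one cis-SNP below the cis-Bonferroni
    threshold at alpha = 0.05.
    """
    cfg = ExperimentConfig(
        ri_sizes=[30], classic_size=13, setting="no_cis", n_genes=n_genes,
        h2_mode="pve_like", methods=list(methods), master_seed=seed,
    )
    panel, genes, phenos, truth = simulate_study(cfg)
    null_ids = set(truth[(truth["n_causal_cis"] == 0) & (truth["q_cis"] >= 1)].index)
    null_genes = [g for g in genes if g.gene_id in null_ids]
    null_truth = truth.loc[sorted(null_ids)]
    out = {"n_null_genes": len(null_genes)}
    for method in cfg.methods:
        results, _ = run_scan(
            panel, phenos, null_genes, method,
            maf_min=cfg.maf_min, miss_max=cfg.miss_max, cis_only=True,
            **_scan_kwargs(method, panel),
        )
        summary = evaluate_scan(results, null_truth, alpha=cfg.alpha, compute_gif=False)
        out[method] = summary.type1
    return out


def power_study_43(seed: int, n_genes: int = 450) -> dict:
    """Power of the standard and LOCO mixed models on the 43-strain design.

    One-cis-effect architecture with heritability targets on a fixed
    grid so every cis-heritability stratum is populated; reports power
    overall and within the stratum of realized cis-heritability > 0.4.
    """
    cfg = ExperimentConfig(
        ri_sizes=[30], classic_size=13, setting="one_cis", n_genes=n_genes,
        h2_mode="fixed_grid", methods=["lmm", "lmm_loco"], master_seed=seed,
    )
    summaries = run_43strain(cfg)
    out = {}
    for method, s in summaries.items():
        sel = s.per_gene[s.per_gene["has_cis_effect"] & (s.per_gene["cis_h2"] > 0.4)]
        out[method] = {
            "power_overall": s.power,
            "power_cis_h2_gt_0.4": s.power_above(0.4),
            "n_stratum": int(len(sel)),
        }
    return out


def power_study_92(seed: int, n_genes: int = 300) -> dict:
    """LOCO mixed-model power on the full 92-strain panel.

    Subpopulation design (33 + 30 RI, 29 classic); one-cis-effect
    architecture over the heritability grid; reports power among genes
    with realized cis-heritability > 0.25.
    """
    cfg = ExperimentConfig(
        ri_sizes=[33, 30], classic_size=29, setting="one_cis", n_genes=n_genes,
        h2_mode="fixed_grid", methods=["lmm_loco"], master_seed=seed,
    )
    panel, genes, phenos, truth = simulate_study(cfg)
    results, _ = run_scan(
        panel, phenos, genes, "lmm_loco", loco_kinships=loco_set(panel),
        maf_min=cfg.maf_min, miss_max=cfg.miss_max, cis_only=True,
    )
    s = evaluate_scan(results, truth, alpha=cfg.alpha, compute_gif=False)
    sel = s.per_gene[s.per_gene["has_cis_effect"] & (s.per_gene["cis_h2"] > 0.25)]
    return {
        "power_overall": s.power,
        "power_cis_h2_gt_0.25": s.power_above(0.25),
        "n_stratum": int(len(sel)),
    }


def run_subpop(config: ExperimentConfig) -> dict[str, EvaluationSummary]:
    """Subpopulation design: LOCO mixed model per subpopulation and overall.

    Phenotypes are simulated once on the full panel; each population's
    scan sees only its own strains' phenotype values, as a study
    restricted to that subpopulation would.
    """
    panel, genes, phenos, truth = simulate_study(config)
    populations: dict[str, np.ndarray] = {
        "FULL": np.arange(panel.n_strains)
    }
    for label in pd.unique(panel.subpopulation):
        populations[str(label)] = np.flatnonzero(panel.subpopulation == label)

    out: dict[str, EvaluationSummary] = {}
    for name, idx in populations.items():
        sub = panel.subset_strains(idx)
        results, _ = run_scan(
            sub, phenos[list(sub.strain_ids)], genes, "lmm_loco",
            loco_kinships=loco_set(sub),
            maf_min=config.maf_min, miss_max=config.miss_max,
            cis_only=config.cis_only,
        )
        summary = evaluate_scan(
            results, truth, alpha=config.alpha, breaks=config.strata_breaks
        )
        summary.method = f"lmm_loco[{name}]"
        out[name] = summary
    return out
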