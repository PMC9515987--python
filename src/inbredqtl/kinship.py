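"""Allele-sharing kinship for inbred panels.

The kinship coefficient between two fully inbred strains is the
proportion of shared alleles among SNPs that are non-missing for both
strains (pairwise-complete).  The diagonal is 1 by definition.  A
leave-one-chromosome-out (LOCO) variant excludes the tested SNP's
chromosome so the fixed effect and the polygenic random effect are
uncorrelated in the mixed model.

Pairwise-complete estimation with missing data can leave the matrix
slightly indefinite; :func:`regularize` floors the eigenvalues before
the matrix is eigendecomposed for the mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, KinshipEstimationError, ParameterError, StructuralError
from .panel import GenotypePanel

__all__ = ["KinshipMatrix", "compute_kinship", "loco_set", "regularize"]


@dataclass
class KinshipMatrix:
    """Symmetric strains x strains allele-sharing proportions in [0, 1]."""

    strain_ids: list[str]
    values: np.ndarray
    excluded_chromosome: object | None = None
    n_snps_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise StructuralError("kinship matrix shape does not match strain ids")
        if not np.allclose(self.values, self.values.T):
            raise StructuralError("kinship matrix must be symmetric")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_ids, columns=self.strain_ids)

    def subset(self, indices) -> "KinshipMatrix":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return KinshipMatrix(
            strain_ids=[self.strain_ids[i] for i in indices],
            values=self.values[np.ix_(indices, indices)],
            excluded_chromosome=self.excluded_chromosome,
            n_snps_used=None
            if self.n_snps_used is None
            else self.n_snps_used[np.ix_(indices, indices)],
        )


def compute_kinship(panel: GenotypePanel, exclude_chromosome=None) -> KinshipMatrix:
    """Pairwise-complete allele-sharing kinship.

    Entry (i, j) is the number of SNPs where strains i and j carry the
    same allele, divided by the number of SNPs non-missing in both,
    optionally skipping one chromosome.
    """
    if panel.n_strains < 2:
        raise ParameterError("kinship needs at least 2 strains")
    g = panel.genotypes
    if exclude_chromosome is not None:
        keep = panel.map.chromosome != exclude_chromosome
        if not keep.any():
            raise ConfigurationError(
                f"excluding chromosome {exclude_chromosome!r} leaves no SNPs"
            )
        g = g[:, keep]

    obs = ~np.isnan(g)
    ones = np.where(obs, g, 0.0)
    zeros = np.where(obs, 1.0 - g, 0.0)
    match = ones @ ones.T + zeros @ zeros.T
    joint = obs.astype(float) @ obs.astype(float).T

    empty = joint == 0
    if empty.any():
        i, j = np.argwhere(empty)[0]
        raise KinshipEstimationError(
            f"strains {panel.strain_ids[i]!r} and {panel.strain_ids[j]!r} "
            "share no jointly non-missing SNPs"
        )
    values = match / joint
    np.fill_diagonal(values, 1.0)  # self-sharing over non-missing SNPs
    values = 0.5 * (values + values.T)  # exact symmetry despite float noise
    return KinshipMatrix(
        strain_ids=list(panel.strain_ids),
        values=values,
        excluded_chromosome=exclude_chromosome,
        n_snps_used=joint.astype(int),
    )


def loco_set(panel: GenotypePanel, chromosomes=None) -> dict:
    """One kinship matrix per chromosome, each excluding that chromosome.

    A requested chromosome with no SNPs on the map yields the full-panel
    kinship (nothing to exclude).
    """
    if len(panel.map.chromosomes) < 2:
        raise ConfigurationError("LOCO kinship requires at least 2 chromosomes")
    if chromosomes is None:
        chromosomes = panel.map.chromosomes
    return {c: compute_kinship(panel, exclude_chromosome=c) for c in chromosomes}


def regularize(kinship: KinshipMatrix, eigen_floor: float = 1e-8) -> KinshipMatrix:
    """Floor the eigenvalues at ``eigen_floor`` (symmetry preserved)."""
    if eigen_floor < 0:
        raise ParameterError("eigen_floor must be >= 0")
    w, v = np.linalg.eigh(kinship.values)
    if w.min() >= eigen_floor:
        return kinship
    w = np.maximum(w, eigen_floor)
    values = (v * w) @ v.T
    values = 0.5 * (values + values.T)
    return KinshipMatrix(
        strain_ids=list(kinship.strain_ids),
        values=values,
        excluded_chromosome=kinship.excluded_chromosome,
        n_snps_used=kinship.n_snps_used,
    )
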