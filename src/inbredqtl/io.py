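"""Readers and writers for the package's plain-TSV dialects.

Native formats are tab-separated UTF-8 text with ``NA`` for missing
values and 1-based inclusive bp coordinates:

* genotype TSV — columns ``snp_id, chromosome, pos_bp, pos_cM`` then
  one 0/1/NA column per strain, one row per SNP;
* subpopulation TSV — ``strain_id, subpopulation``;
* phenotype TSV — gene x strain matrix with ``gene_id`` as first column;
* kinship TSV — square matrix, strain ids as header and first column.

Writers emit deterministic, full-precision output so that write/read
round-trips are bit-exact and checksums are stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, StructuralError
from .kinship import KinshipMatrix
from .panel import GenotypePanel, MarkerMap

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_kinship",
    "read_kinship",
    "write_run_manifest",
]

_MAP_COLS = ["snp_id", "chromosome", "pos_bp", "pos_cM"]


def write_genotypes(panel: GenotypePanel, genotype_path, subpop_path=None) -> None:
    miss = np.isnan(panel.genotypes)
    codes = np.where(miss, "NA", np.where(panel.genotypes == 1.0, "1", "0"))
    df = panel.map.to_frame()
    for i, sid in enumerate(panel.strain_ids):
        df[sid] = codes[i]
    df.to_csv(genotype_path, sep="\t", index=False, float_format="%.17g")
    if subpop_path is not None:
        pd.DataFrame(
            {"strain_id": panel.strain_ids, "subpopulation": panel.subpopulation}
        ).to_csv(subpop_path, sep="\t", index=False)


def read_genotypes(genotype_path, subpop_path=None) -> GenotypePanel:
    try:
        df = pd.read_csv(genotype_path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{genotype_path}: empty file") from exc
    if df.columns.tolist()[:4] != _MAP_COLS:
        raise ParseError(f"{genotype_path}: expected leading columns {_MAP_COLS}")
    strain_ids = df.columns.tolist()[4:]
    if not strain_ids:
        raise ParseError(f"{genotype_path}: no strain columns")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ParseError(f"{genotype_path}: duplicate snp_id {dup!r}")

    geno = np.empty((len(strain_ids), len(df)))
    for i, sid in enumerate(strain_ids):
        col = df[sid].to_numpy()
        bad = ~np.isin(col, ("0", "1", "NA"))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{genotype_path}: line {row + 2}: invalid genotype code "
                f"{col[row]!r} for strain {sid!r} (expected 0/1/NA)"
            )
        geno[i] = np.where(col == "NA", np.nan, np.where(col == "1", 1.0, 0.0))

    try:
        marker_map = MarkerMap(
            snp_id=df["snp_id"].to_numpy(),
            chromosome=pd.to_numeric(df["chromosome"]).to_numpy(),
            pos_bp=pd.to_numeric(df["pos_bp"]).to_numpy(),
            # strtod parse: bit-exact round trip of %.17g output
            pos_cM=np.array([float(v) for v in df["pos_cM"]]),
        )
    except (ValueError, StructuralError) as exc:
        raise ParseError(f"{genotype_path}: invalid map: {exc}") from exc

    if subpop_path is not None:
        sp = pd.read_csv(subpop_path, sep="\t", dtype=str).set_index("strain_id")
        missing = [s for s in strain_ids if s not in sp.index]
        if missing:
            raise ParseError(f"{subpop_path}: no subpopulation for strains {missing}")
        subpop = sp.loc[strain_ids, "subpopulation"].to_numpy(dtype=object)
    else:
        subpop = np.full(len(strain_ids), "UNKNOWN", dtype=object)
    return GenotypePanel(
        strain_ids=strain_ids, subpopulation=subpop, genotypes=geno, map=marker_map
    )


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.rename_axis("gene_id").to_csv(
        path, sep="\t", na_rep="NA", float_format="%.17g"
    )


def read_phenotypes(path, panel: GenotypePanel | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="gene_id", na_values=["NA"],
        float_precision="round_trip",
    )
    for gene_id, row in df.iterrows():
        bad = row[~row.isna() & pd.to_numeric(row, errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at gene "
                f"{gene_id!r}, strain {bad.index[0]!r}"
            )
    df = df.astype(float)
    if panel is not None:
        extra = [c for c in df.columns if c not in panel.strain_ids]
        absent = [s for s in panel.strain_ids if s not in df.columns]
        if extra or absent:
            raise StructuralError(
                f"{path}: strain mismatch with panel "
                f"(unknown: {extra or 'none'}; missing: {absent or 'none'})"
            )
        df = df[list(panel.strain_ids)]
    return df


def write_kinship(kinship: KinshipMatrix, path) -> None:
    kinship.to_frame().rename_axis("strain_id").to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="strain_id", float_precision="round_trip")
    if df.index.tolist() != df.columns.tolist():
        raise ParseError(f"{path}: kinship rows and columns must match")
    return KinshipMatrix(strain_ids=df.columns.tolist(), values=df.to_numpy(dtype=float))


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_manifest(
    out_dir, command: str, seed: int | None, config: dict | None, outputs: list
) -> Path:
    """JSON manifest recording what a CLI invocation produced and from what."""
    from . import __version__

    manifest = {
        "tool": "inbredqtl",
        "version": __version__,
        "command": command,
        "master_seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {str(p): _checksum(p) for p in outputs},
    }
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
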