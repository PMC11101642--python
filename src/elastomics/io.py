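"""Readers and writers for the on-disk formats the pipeline touches.

Gene counts travel as 10x-style triplet directories (MatrixMarket
``matrix.mtx`` plus ``features.tsv`` and ``barcodes.tsv``, optionally
gzipped); tag counts as wide or long CSV; DTD species catalogues,
ground truth and result tables as headed CSV; gene sets as GMT; run
configuration as YAML. All CSVs are UTF-8 and comma-delimited.
"""

from __future__ import annotations

import gzip
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.io import mmread, mmwrite

from .pore import DTDSpecies

__all__ = [
    "FormatError",
    "DatasetManifest",
    "read_matrix_triplet",
    "write_matrix_triplet",
    "read_tag_table",
    "write_tag_table",
    "read_species_catalogue",
    "write_species_catalogue",
    "read_gmt",
    "write_gmt",
    "load_config",
    "dump_config",
]


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_variant(directory: Path, stem: str) -> Path:
    for candidate in (directory / stem, directory / f"{stem}.gz"):
        if candidate.exists():
            return candidate
    raise FormatError(f"missing {stem}[.gz] in {directory}")


def read_matrix_triplet(directory) -> tuple[sparse.csr_matrix, pd.DataFrame, list[str]]:
    """Read a 10x-style triplet directory.

    Returns ``(matrix, features, barcodes)`` with the matrix sparse CSR
    of shape genes x cells (MatrixMarket 1-based indices become 0-based
    in memory). ``features`` has columns ``gene_id``, ``gene_name`` and
    ``mito`` (names starting with MT-/mt-).
    """
    directory = Path(directory)
    mtx_path = _find_variant(directory, "matrix.mtx")
    feat_path = _find_variant(directory, "features.tsv")
    bc_path = _find_variant(directory, "barcodes.tsv")

    try:
        with _open_maybe_gz(mtx_path, "rb" if mtx_path.suffix != ".gz" else "rt") as fh:
            matrix = mmread(fh)
    except Exception as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    matrix = sparse.csr_matrix(matrix)

    with _open_maybe_gz(feat_path) as fh:
        features = pd.read_csv(fh, sep="\t", header=None)
    if features.shape[1] < 2:
        features[1] = features[0]
    features = features.rename(columns={0: "gene_id", 1: "gene_name"})[["gene_id", "gene_name"]]
    features["mito"] = features["gene_name"].astype(str).str.upper().str.startswith("MT-")

    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if matrix.shape[0] != len(features):
        raise FormatError(
            f"{mtx_path}: matrix has {matrix.shape[0]} rows but "
            f"{feat_path.name} lists {len(features)} features"
        )
    if matrix.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: matrix has {matrix.shape[1]} columns but "
            f"{bc_path.name} lists {len(barcodes)} barcodes"
        )
    return matrix, features, barcodes


def write_matrix_triplet(directory, matrix, features: pd.DataFrame, barcodes) -> None:
    """Write a genes x cells sparse matrix as a 10x-style triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix = sparse.coo_matrix(matrix)
    if matrix.shape[0] != len(features):
        raise FormatError("feature table length does not match matrix rows")
    if matrix.shape[1] != len(barcodes):
        raise FormatError("barcode list length does not match matrix columns")
    mmwrite(str(directory / "matrix.mtx"), matrix, field="integer")
    features[["gene_id", "gene_name"]].to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{bc}\n" for bc in barcodes)


_LONG_COLUMNS = {"tag", "cell", "count"}


def read_tag_table(
    path, catalogue: list[DTDSpecies] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a tag x cell count table from wide or long CSV.

    Wide: first column tag identifiers, remaining columns one per cell
    barcode. Long: columns ``tag, cell, count``. Returns ``(counts,
    tag_metadata)`` where counts is a tags x cells integer DataFrame.
    When a species catalogue is given, 8-nt tag identifiers are matched
    against it; unknown tags are flagged (``known = False``) with a
    warning rather than dropped.
    """
    path = Path(path)
    head = pd.read_csv(path, nrows=0)
    if set(c.lower() for c in head.columns) == _LONG_COLUMNS:
        long = pd.read_csv(path)
        long.columns = [c.lower() for c in long.columns]
        counts = long.pivot_table(
            index="tag", columns="cell", values="count", fill_value=0, aggfunc="sum"
        )
        counts.columns.name = None
        counts.index.name = None
    else:
        counts = pd.read_csv(path, index_col=0)
        counts.index = counts.index.astype(str)
        counts.index.name = None

    values = counts.to_numpy()
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite tag counts")
    if np.any(values < 0):
        raise FormatError(f"{path}: negative tag counts")
    if np.any(values != np.round(values)):
        raise FormatError(f"{path}: tag counts must be integers")
    counts = counts.astype(np.int64)

    meta = pd.DataFrame(index=counts.index)
    meta["kind"] = ["dtd" if len(str(t)) == 8 and set(str(t)) <= set("ACGT") else "hashtag"
                    for t in counts.index]
    if catalogue is not None:
        known = {sp.barcode: sp for sp in catalogue}
        meta["known"] = [str(t) in known for t in counts.index]
        unknown = [t for t, k in zip(counts.index, meta["known"]) if not k and meta.loc[t, "kind"] == "dtd"]
        if unknown:
            warnings.warn(f"{path}: unknown DTD tag barcodes quarantined: {unknown}")
    return counts, meta


def write_tag_table(path, counts: pd.DataFrame) -> None:
    """Write a tags x cells count table as wide CSV (first column = tag)."""
    counts.to_csv(path, index_label="tag")


_SPECIES_COLUMNS = [
    "name",
    "barcode",
    "molecular_weight_kda",
    "stokes_radius_nm",
    "stokes_radius_sd_nm",
    "mobility_m2_per_vs",
    "concentration_mol_l",
]


def read_species_catalogue(path) -> list[DTDSpecies]:
    """Read a DTD species catalogue CSV (one row per dextran-oligo conjugate)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: species catalogue missing columns {sorted(missing)}")
    return [
        DTDSpecies(
            barcode=str(row.barcode),
            molecular_weight=float(row.molecular_weight_kda),
            stokes_radius=float(row.stokes_radius_nm),
            stokes_radius_sd=float(row.stokes_radius_sd_nm),
            mobility=float(row.mobility_m2_per_vs),
            concentration=float(row.concentration_mol_l),
            name=str(row.name),
        )
        for row in df.itertuples(index=False)
    ]


def write_species_catalogue(path, species: list[DTDSpecies]) -> None:
    pd.DataFrame(
        [
            {
                "name": sp.name,
                "barcode": sp.barcode,
                "molecular_weight_kda": sp.molecular_weight,
                "stokes_radius_nm": sp.stokes_radius,
                "stokes_radius_sd_nm": sp.stokes_radius_sd,
                "mobility_m2_per_vs": sp.mobility,
                "concentration_mol_l": sp.concentration,
            }
            for sp in species
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (set name, description, then member genes)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(path, gene_sets: dict[str, list[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def dump_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class DatasetManifest:
    """Paths (relative to ``root``) and checksums of one dataset's files."""

    root: Path
    files: dict[str, str] = field(default_factory=dict)  # relpath -> sha256

    @classmethod
    def create(cls, root, relpaths) -> "DatasetManifest":
        root = Path(root)
        manifest = cls(root=root)
        for rel in relpaths:
            target = root / rel
            if not target.exists():
                raise FormatError(f"manifest references missing file {target}")
            manifest.files[str(rel)] = _sha256(target)
        return manifest

    def save(self, path=None) -> Path:
        path = Path(path) if path else self.root / "manifest.yaml"
        dump_config(path, {"files": self.files})
        return path

    @classmethod
    def load(cls, root, path=None, verify: bool = True) -> "DatasetManifest":
        root = Path(root)
        path = Path(path) if path else root / "manifest.yaml"
        cfg = load_config(path)
        manifest = cls(root=root, files=dict(cfg.get("files", {})))
        for rel, checksum in manifest.files.items():
            target = root / rel
            if not target.exists():
                raise FormatError(f"manifest references missing file {target}")
            if verify and _sha256(target) != checksum:
                raise FormatError(f"checksum mismatch for {target}")
        return manifest
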