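"""Synthetic multimodal datasets with known mechanical ground truth.

Each simulated cell carries a latent surface tension (log-normal per
population), an adhesion area (gamma-distributed, optionally rank-
correlated with tension) that sets its number of membrane-facing
nanopores, DTD tag counts whose Poisson expectation follows the pore
import model (increasing in tension, decreasing in Stokes radius),
hashtag counts identifying its population, and negative-binomial gene
expression in which a small planted set of genes is coupled to
log-tension. The generator exercises every downstream stage — QC,
normalization, demultiplexing, correlation screen, enrichment and
elastic net — without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import io as eio
from .pore import (
    DTDSpecies,
    PoreModelParams,
    default_species_catalogue,
    expected_import_rate_table,
)
from .quantify import MultimodalCounts

__all__ = [
    "CellPopulationSpec",
    "PlantedGene",
    "GroundTruth",
    "PORE_DENSITY_PER_UM2",
    "DEFAULT_EXPOSURE",
    "simulate_cells",
    "simulate_dtd_counts",
    "simulate_hashtag_counts",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "default_populations",
]

#: track-etched membrane pore density (100-nm pores), per um^2
PORE_DENSITY_PER_UM2 = 6.04

#: counts per (pore x model rate) per run; sets the sequencing depth of the
#: tag library so that per-cell CLR values of the 4-kDa DTD land in the
#: 0-3 range typical of real tag libraries
DEFAULT_EXPOSURE = 6e10


@dataclass(frozen=True)
class CellPopulationSpec:
    """Generative parameters for one simulated cell population."""

    name: str
    n_cells: int
    tension_log10_mean: float  # log10 pN/um
    tension_log10_sd: float = 0.35
    adhesion_area_mean: float = 400.0  # um^2
    adhesion_area_cv: float = 0.3
    library_size_mean: float = 10_000.0  # UMI per cell
    library_size_dispersion: float = 0.3  # CV of per-cell library size
    hashtag_barcode: str = ""

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.tension_log10_sd < 0:
            raise ValueError(f"tension_log10_sd must be >= 0, got {self.tension_log10_sd}")
        if self.adhesion_area_mean <= 0:
            raise ValueError(f"adhesion_area_mean must be > 0, got {self.adhesion_area_mean}")
        if self.adhesion_area_cv < 0:
            raise ValueError(f"adhesion_area_cv must be >= 0, got {self.adhesion_area_cv}")
        if self.library_size_mean <= 0:
            raise ValueError(f"library_size_mean must be > 0, got {self.library_size_mean}")
        if not self.hashtag_barcode:
            object.__setattr__(self, "hashtag_barcode", f"HTO-{self.name}")


@dataclass(frozen=True)
class PlantedGene:
    """A gene whose log expression is coupled to log10 surface tension."""

    gene_id: str
    coupling: float  # d ln(mean) / d log10(tension)
    base_mean: float = 5.0  # counts at the population-mean tension
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError(f"base_mean must be > 0, got {self.base_mean}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")


@dataclass
class GroundTruth:
    """Latent per-cell state and, once expression is simulated, per-gene truth."""

    cells: pd.DataFrame  # index barcode: population, tension, adhesion_area, n_pores, library_size
    populations: pd.DataFrame  # index name: tension_log10_mean, hashtag_barcode, ...
    genes: pd.DataFrame | None = None  # index gene_id: coupling, base_mean, dispersion, mito


def default_populations(n_cells: int = 500) -> list[CellPopulationSpec]:
    """Two populations bracketing the 10-1000 pN/um physiological range."""
    return [
        CellPopulationSpec(name="soft", n_cells=n_cells, tension_log10_mean=1.7),
        CellPopulationSpec(name="stiff", n_cells=n_cells, tension_log10_mean=2.0),
    ]


def simulate_cells(
    specs: list[CellPopulationSpec],
    seed: int,
    tension_area_spearman: float = 0.3,
    tension_bounds: tuple[float, float] = (1.0, 10_000.0),
    pore_density: float = PORE_DENSITY_PER_UM2,
) -> GroundTruth:
    """Draw latent per-cell state for each population.

    Tensions are log-normal (truncated to ``tension_bounds``); adhesion
    areas gamma with the stated mean and CV, rank-correlated with
    tension through a Gaussian copula at the given Spearman rho
    (default 0.3 — tenser cells tend to spread more). Pore count is
    ``round(pore_density x area)``. Deterministic given ``seed``.
    """
    if not specs:
        raise ValueError("need at least one population spec")
    if not -1 < tension_area_spearman < 1:
        raise ValueError(f"tension_area_spearman must be in (-1, 1), got {tension_area_spearman}")
    rng = np.random.default_rng(seed)
    rho_gauss = 2.0 * np.sin(np.pi * tension_area_spearman / 6.0)
    cov = np.array([[1.0, rho_gauss], [rho_gauss, 1.0]])
    chol = np.linalg.cholesky(cov)

    frames = []
    for spec in specs:
        z = rng.standard_normal((spec.n_cells, 2)) @ chol.T
        log10_tension = spec.tension_log10_mean + spec.tension_log10_sd * z[:, 0]
        tension = np.clip(10.0**log10_tension, *tension_bounds)
        if spec.adhesion_area_cv > 0:
            shape = 1.0 / spec.adhesion_area_cv**2
            scale = spec.adhesion_area_mean * spec.adhesion_area_cv**2
            area = stats.gamma.ppf(stats.norm.cdf(z[:, 1]), a=shape, scale=scale)
        else:
            area = np.full(spec.n_cells, spec.adhesion_area_mean)
        if spec.library_size_dispersion > 0:
            ln_sd = np.sqrt(np.log1p(spec.library_size_dispersion**2))
            libsize = spec.library_size_mean * np.exp(
                ln_sd * rng.standard_normal(spec.n_cells) - 0.5 * ln_sd**2
            )
        else:
            libsize = np.full(spec.n_cells, spec.library_size_mean)
        frames.append(
            pd.DataFrame(
                {
                    "population": spec.name,
                    "tension": tension,
                    "adhesion_area": area,
                    "n_pores": np.maximum(np.round(pore_density * area), 0).astype(int),
                    "library_size": libsize,
                },
                index=[f"{spec.name}-{i:05d}" for i in range(spec.n_cells)],
            )
        )
    cells = pd.concat(frames)
    cells.index.name = "barcode"
    populations = pd.DataFrame(
        {
            "tension_log10_mean": [s.tension_log10_mean for s in specs],
            "tension_log10_sd": [s.tension_log10_sd for s in specs],
            "hashtag_barcode": [s.hashtag_barcode for s in specs],
            "n_cells": [s.n_cells for s in specs],
        },
        index=pd.Index([s.name for s in specs], name="population"),
    )
    return GroundTruth(cells=cells, populations=populations)


def expected_dtd_counts(
    truth: GroundTruth,
    species: list[DTDSpecies],
    model: PoreModelParams | None = None,
    exposure: float = DEFAULT_EXPOSURE,
) -> pd.DataFrame:
    """Noise-free expected tag counts: n_pores x rate(tension, species) x exposure."""
    model = model or PoreModelParams()
    tension = truth.cells["tension"].to_numpy()
    n_pores = truth.cells["n_pores"].to_numpy()
    rates = expected_import_rate_table(tension, species, model)
    return pd.DataFrame(
        rates * n_pores[None, :] * exposure,
        index=[sp.barcode for sp in species],
        columns=truth.cells.index,
    )


def simulate_dtd_counts(
    truth: GroundTruth,
    species: list[DTDSpecies],
    model: PoreModelParams | None = None,
    seed: int = 0,
    exposure: float = DEFAULT_EXPOSURE,
    overdispersion: float = 0.0,
) -> pd.DataFrame:
    """Poisson DTD counts around the pore-model expectation.

    ``overdispersion`` > 0 multiplies each cell-tag rate by a gamma
    variate of unit mean and the given squared-CV (default off: pure
    Poisson UMI counting). A species at zero concentration yields an
    all-zero row.
    """
    for sp in species:
        if sp.mobility < 0 or sp.concentration < 0:
            raise ValueError(f"species {sp.name or sp.barcode}: negative mobility/concentration")
    rng = np.random.default_rng(seed)
    expected = expected_dtd_counts(truth, species, model, exposure)
    lam = expected.to_numpy()
    if overdispersion > 0:
        lam = lam * rng.gamma(1.0 / overdispersion, overdispersion, size=lam.shape)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=expected.index, columns=expected.columns)


def simulate_hashtag_counts(
    truth: GroundTruth, seed: int = 0, depth: float = 300.0, background: float = 3.0
) -> pd.DataFrame:
    """Hashtag counts: Poisson(depth) for the cell's own tag, Poisson(background) otherwise."""
    rng = np.random.default_rng(seed)
    hashtags = truth.populations["hashtag_barcode"]
    lam = np.full((len(hashtags), len(truth.cells)), background, dtype=float)
    pop_of_cell = truth.cells["population"].to_numpy()
    for i, (pop, tag) in enumerate(hashtags.items()):
        lam[i, pop_of_cell == pop] = depth
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=hashtags.to_list(), columns=truth.cells.index)


def simulate_expression(
    truth: GroundTruth,
    planted: list[PlantedGene],
    n_background_genes: int,
    seed: int = 0,
    mito_gene_fraction: float = 0.05,
    target_mito_fraction: float = 0.05,
    background_mean_range: tuple[float, float] = (0.5, 50.0),
    background_dispersion_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[sparse.csr_matrix, pd.DataFrame]:
    """Negative-binomial gene counts with planted tension-coupled genes.

    A planted gene g in cell c has log mean
    ``ln(base_mean) + coupling x (log10 tension_c - population mean) +
    ln(library size offset)``, where the offset rescales every cell's
    expected total to its drawn library size (so ``base_mean`` is a
    relative abundance weight and the per-cell depth honours the
    population's ``library_size_mean``); background genes have
    coupling 0. A
    ``mito_gene_fraction`` of background genes is labelled
    mitochondrial (MT- prefix) with base means rescaled so the expected
    mitochondrial fraction is ``target_mito_fraction``, which makes the
    QC gates exercisable. Updates ``truth.genes`` in place and returns
    ``(gene x cell sparse counts, gene metadata)``.
    """
    if n_background_genes < 0:
        raise ValueError(f"n_background_genes must be >= 0, got {n_background_genes}")
    rng = np.random.default_rng(seed)
    n_cells = len(truth.cells)

    pop_mean = truth.populations["tension_log10_mean"]
    centred_log10 = (
        np.log10(truth.cells["tension"].to_numpy())
        - pop_mean.loc[truth.cells["population"]].to_numpy()
    )
    libsize = truth.cells["library_size"].to_numpy()

    records = []
    for g in planted:
        records.append((g.gene_id, g.coupling, g.base_mean, g.dispersion, False))
    if n_background_genes:
        n_mito = int(round(mito_gene_fraction * n_background_genes))
        lo, hi = background_mean_range
        means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_background_genes))
        disps = rng.uniform(*background_dispersion_range, size=n_background_genes)
        mito_flags = np.zeros(n_background_genes, dtype=bool)
        mito_flags[:n_mito] = True
        if n_mito and target_mito_fraction > 0:
            planted_sum = sum(g.base_mean for g in planted)
            other_sum = means[~mito_flags].sum() + planted_sum
            scale = (target_mito_fraction / (1 - target_mito_fraction)) * (
                other_sum / means[mito_flags].sum()
            )
            means[mito_flags] *= scale
        for i in range(n_background_genes):
            name = f"MT-BG{i:05d}" if mito_flags[i] else f"BG{i:05d}"
            records.append((name, 0.0, float(means[i]), float(disps[i]), bool(mito_flags[i])))

    genes = pd.DataFrame(
        records, columns=["gene_id", "coupling", "base_mean", "dispersion", "mito"]
    ).set_index("gene_id")
    truth.genes = genes

    if genes.empty or n_cells == 0:
        matrix = sparse.csr_matrix((len(genes), n_cells), dtype=np.int64)
        meta = genes.reset_index().rename(columns={"gene_id": "gene_name"})
        meta.insert(0, "gene_id", genes.index)
        return matrix, meta[["gene_id", "gene_name", "mito"]]

    coupling = genes["coupling"].to_numpy()[:, None]
    base = genes["base_mean"].to_numpy()[:, None]
    disp = genes["dispersion"].to_numpy()[:, None]
    mean = base * np.exp(coupling * centred_log10[None, :])
    colsum = mean.sum(axis=0)
    mean = mean * np.where(colsum > 0, libsize / np.maximum(colsum, 1e-300), 0.0)[None, :]
    shape = 1.0 / disp
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam)
    matrix = sparse.csr_matrix(counts.astype(np.int64))
    meta = pd.DataFrame(
        {"gene_id": genes.index, "gene_name": genes.index, "mito": genes["mito"].to_numpy()}
    )
    return matrix, meta


def simulate_dataset(
    specs: list[CellPopulationSpec] | None = None,
    planted: list[PlantedGene] | None = None,
    n_background_genes: int = 200,
    species: list[DTDSpecies] | None = None,
    model: PoreModelParams | None = None,
    seed: int = 0,
    exposure: float = DEFAULT_EXPOSURE,
    tension_area_spearman: float = 0.3,
    hashtag_depth: float = 300.0,
) -> tuple[MultimodalCounts, GroundTruth]:
    """One-call simulation of a complete paired dataset.

    Sub-stage seeds are derived deterministically from ``seed``.
    """
    specs = specs if specs is not None else default_populations()
    planted = planted or []
    species = species if species is not None else default_species_catalogue()
    model = model or PoreModelParams()
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)

    truth = simulate_cells(specs, int(seeds[0]), tension_area_spearman=tension_area_spearman)
    dtd = simulate_dtd_counts(truth, species, model, int(seeds[1]), exposure=exposure)
    hashtags = simulate_hashtag_counts(truth, int(seeds[2]), depth=hashtag_depth)
    gene_matrix, gene_meta = simulate_expression(truth, planted, n_background_genes, int(seeds[3]))

    tag_matrix = pd.concat([dtd, hashtags])
    tag_matrix.columns.name = None
    tag_matrix.index.name = None
    tag_meta = pd.DataFrame(index=tag_matrix.index)
    tag_meta["kind"] = ["dtd"] * len(dtd) + ["hashtag"] * len(hashtags)
    counts = MultimodalCounts(
        gene_matrix=gene_matrix,
        tag_matrix=tag_matrix,
        cell_barcodes=list(truth.cells.index),
        gene_metadata=gene_meta,
        tag_metadata=tag_meta,
    )
    return counts, truth


def write_dataset(
    counts: MultimodalCounts,
    truth: GroundTruth | None,
    out_dir,
    species: list[DTDSpecies] | None = None,
) -> Path:
    """Write a dataset as 10x-style triplets plus CSV tables.

    Emits ``genes/`` (matrix.mtx + features.tsv + barcodes.tsv),
    ``tags.csv`` (wide), optionally ``species.csv`` and the ground
    truth tables, and a checksum manifest. Refuses to write an empty
    cell set.
    """
    if counts.n_cells == 0:
        raise ValueError("refusing to write a dataset with zero cells")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    eio.write_matrix_triplet(
        out_dir / "genes", counts.gene_matrix, counts.gene_metadata, counts.cell_barcodes
    )
    eio.write_tag_table(out_dir / "tags.csv", counts.tag_matrix)
    written = ["genes/matrix.mtx", "genes/features.tsv", "genes/barcodes.tsv", "tags.csv"]
    if species is not None:
        eio.write_species_catalogue(out_dir / "species.csv", species)
        written.append("species.csv")
    if truth is not None:
        truth.cells.to_csv(out_dir / "ground_truth_cells.csv")
        truth.populations.to_csv(out_dir / "ground_truth_populations.csv")
        written += ["ground_truth_cells.csv", "ground_truth_populations.csv"]
        if truth.genes is not None:
            truth.genes.to_csv(out_dir / "ground_truth_genes.csv")
            written.append("ground_truth_genes.csv")
    eio.DatasetManifest.create(out_dir, written).save()
    return out_dir


def read_dataset(directory) -> MultimodalCounts:
    """Load a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    gene_matrix, features, barcodes = eio.read_matrix_triplet(directory / "genes")
    catalogue = None
    if (directory / "species.csv").exists():
        catalogue = eio.read_species_catalogue(directory / "species.csv")
    tags, tag_meta = eio.read_tag_table(directory / "tags.csv", catalogue)
    missing = [bc for bc in barcodes if bc not in tags.columns]
    if missing:
        import warnings

        warnings.warn(f"{len(missing)} cells missing from tag table; zero-filled")
        for bc in missing:
            tags[bc] = 0
        tag_meta = tag_meta  # unchanged; zero-filled columns only
    tags = tags[barcodes]
    return MultimodalCounts(
        gene_matrix=gene_matrix,
        tag_matrix=tags,
        cell_barcodes=list(barcodes),
        gene_metadata=features,
        tag_metadata=tag_meta,
    )
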