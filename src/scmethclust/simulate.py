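"""Synthetic sc-WGBS data with known epiclone structure.

The generator emulates a clonal population: cluster (epiclone) methylation
profiles arise from an ancestor-descendant chain in which each new clone
inherits its parent's profile and flips the methylation state of every
locus in ``n_diff_regions`` randomly chosen regions.  Cells are assigned to
clones from the clone frequency vector, optionally perturbed locus-wise
(cell-to-cell variability), corrupted by a symmetric per-entry error rate
(sequencing/misclassification error), and finally thinned by masking each
entry missing completely at random.  A matched pseudo-bulk is drawn
binomially from the cell population.

The default configuration is the simulation condition used throughout this
package's synthetic studies: 100 cells, 10,000 loci in 100 equal regions
(region size 100), 3 epiclones with balanced frequencies, missing
proportion 0.8, no cell-to-cell variability, one region different between
consecutive clones, error rate 0.01, bulk depth 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import MISSING, BulkProfile, CellMethylationMatrix, RegionSet

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_epigenotypes",
    "generate_cells",
    "generate_bulk",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_cells: int = 100
    n_loci: int = 10_000
    n_regions: int = 100
    n_clusters: int = 3
    cluster_freqs: tuple[float, ...] | None = None  # None -> balanced
    missing_prop: float = 0.8
    cell_variability: float = 0.0
    n_diff_regions: int = 1
    error_rate: float = 0.01
    bulk_depth: int = 60
    seed: int | None = None

    def __post_init__(self):
        if self.cluster_freqs is None:
            object.__setattr__(
                self,
                "cluster_freqs",
                tuple([1.0 / self.n_clusters] * self.n_clusters),
            )
        freqs = np.asarray(self.cluster_freqs, dtype=float)
        if len(freqs) != self.n_clusters:
            raise ValueError("cluster_freqs length must equal n_clusters")
        if not np.isclose(freqs.sum(), 1.0):
            raise ValueError("cluster_freqs must sum to 1")
        for name in ("missing_prop", "cell_variability", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_diff_regions > self.n_regions:
            raise ValueError("n_diff_regions cannot exceed n_regions")
        if self.n_cells < 1 or self.n_loci < 1 or self.n_clusters < 1:
            raise ValueError("n_cells, n_loci and n_clusters must be positive")

    @property
    def region_index(self) -> np.ndarray:
        """Column -> region assignment: equal blocks, last region padded."""
        base = self.n_loci // self.n_regions
        if base == 0:
            raise ValueError("fewer loci than regions")
        idx = np.minimum(np.arange(self.n_loci) // base, self.n_regions - 1)
        return idx


@dataclass
class SyntheticDataset:
    """Ground truth plus the observed sparse matrix and matched bulk."""

    config: SyntheticConfig
    true_labels: np.ndarray                  # N, values 0..K-1
    cluster_epigenotypes: np.ndarray         # K x M binary
    cell_epigenotypes: np.ndarray            # N x M binary
    observed: CellMethylationMatrix
    bulk: BulkProfile | None = None
    flipped_regions: list[np.ndarray] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.true_labels)

    def true_frequencies(self) -> np.ndarray:
        return np.bincount(
            self.true_labels, minlength=self.config.n_clusters
        ) / self.n_cells


def generate_epigenotypes(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Clone profiles from the chain phylogeny.

    The root profile draws each locus independently Bernoulli(0.5); clone
    ``k+1`` copies clone ``k`` and inverts every locus of
    ``n_diff_regions`` regions chosen uniformly without replacement.
    Returns the K x M profile matrix and the per-step flipped region lists.
    """
    M, K = config.n_loci, config.n_clusters
    ridx = config.region_index
    profiles = np.empty((K, M), dtype=np.int8)
    profiles[0] = rng.integers(0, 2, size=M, dtype=np.int8)
    flipped: list[np.ndarray] = []
    for k in range(1, K):
        regions = rng.choice(config.n_regions, size=config.n_diff_regions, replace=False)
        regions = np.sort(regions)
        flipped.append(regions)
        profiles[k] = profiles[k - 1]
        mask = np.isin(ridx, regions)
        profiles[k, mask] = 1 - profiles[k, mask]
    return profiles, flipped


def generate_cells(
    profiles: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    flipped_regions: list[np.ndarray] | None = None,
) -> SyntheticDataset:
    """Draw cells from the clone profiles and corrupt/thin the observations."""
    N, M = config.n_cells, config.n_loci
    K = config.n_clusters
    labels = rng.choice(K, size=N, p=np.asarray(config.cluster_freqs))

    cell_epi = profiles[labels].copy()
    n_flip = int(round(config.cell_variability * M))
    if n_flip > 0:
        for n in range(N):
            loci = rng.choice(M, size=n_flip, replace=False)
            cell_epi[n, loci] = 1 - cell_epi[n, loci]

    observed = cell_epi.copy()
    if config.error_rate > 0:
        errs = rng.random((N, M)) < config.error_rate
        observed[errs] = 1 - observed[errs]
    vals = observed.astype(np.int8)
    if config.missing_prop > 0:
        mask = rng.random((N, M)) < config.missing_prop
        vals[mask] = MISSING

    ridx = config.region_index
    region_ids = [f"region_{r:05d}" for r in range(config.n_regions)]
    # synthetic coordinates: one chromosome, CpGs every 10 bp
    pos = np.arange(1, M + 1) * 10
    starts = np.array(
        [pos[ridx == r].min() - 1 for r in range(config.n_regions)]
    )
    ends = np.array([pos[ridx == r].max() for r in range(config.n_regions)])
    regions = RegionSet(
        ("chrS", s, e, rid) for s, e, rid in zip(starts, ends, region_ids)
    )
    matrix = CellMethylationMatrix(
        cell_ids=[f"cell_{n:04d}" for n in range(N)],
        cpg_chrom=np.array(["chrS"] * M, dtype=object),
        cpg_pos=pos,
        region_index=ridx,
        region_ids=region_ids,
        values=vals,
        regions=regions,
    )
    return SyntheticDataset(
        config=config,
        true_labels=labels,
        cluster_epigenotypes=profiles,
        cell_epigenotypes=cell_epi,
        observed=matrix,
        flipped_regions=list(flipped_regions or []),
    )


def generate_bulk(
    dataset: SyntheticDataset,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> BulkProfile:
    """Pseudo-bulk counts: b_m ~ Binomial(D, methylated-cell fraction)."""
    if rng is None:
        rng = np.random.default_rng(dataset.config.seed)
    D = depth if depth is not None else dataset.config.bulk_depth
    frac = dataset.cell_epigenotypes.mean(axis=0)
    meth = rng.binomial(D, frac)
    return BulkProfile(
        chrom=dataset.observed.cpg_chrom,
        pos=dataset.observed.cpg_pos,
        meth=meth,
        total=np.full(len(frac), D),
    )


def simulate_dataset(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    with_bulk: bool = True,
    **overrides,
) -> SyntheticDataset:
    """One-call generator: profiles -> cells -> bulk, from a single seed."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    profiles, flipped = generate_epigenotypes(config, rng)
    ds = generate_cells(profiles, config, rng, flipped_regions=flipped)
    if with_bulk:
        ds.bulk = generate_bulk(ds, rng=rng)
    return ds
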