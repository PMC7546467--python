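"""Pipeline configuration: a single validated document mirroring every
stage's flags, with defaults matching the package's standard analysis
settings (Kmax = 10, 300 restarts for synthetic data, DIC decrease
threshold 0.2%, ELBO tolerance 1e-6)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_cells: int = 100
    n_loci: int = 10_000
    n_regions: int = 100
    n_clusters: int = 3
    cluster_freqs: list | None = None
    missing_prop: float = 0.8
    cell_variability: float = 0.0
    n_diff_regions: int = 1
    error_rate: float = 0.01
    bulk_depth: int = 60


@dataclass
class PreprocessConfig:
    calls_dir: str | None = None
    dialect: str = "bismark_cov"
    regions_bed: str | None = None
    mode: str = "frac_cells"
    min_region_coverage: float = 0.05
    min_cell_frac: float = 0.10
    max_mean_missing: float = 0.95
    target_loci: int | None = None
    min_iqr: float | None = None


@dataclass
class ClusterConfig:
    kmax: int = 10
    n_restarts: int = 300
    decrease_threshold: float = 0.002
    tol: float = 1e-6
    max_iters: int = 1000
    shared_region: bool = False
    alpha0: float = 1.0
    beta0: list = field(default_factory=lambda: [1.0, 1.0])
    gamma0: list = field(
        default_factory=lambda: [[99.0, 1.0], [1.0, 99.0]]
    )


@dataclass
class BulkRefineConfig:
    enabled: bool = False
    bulk_tsv: str | None = None
    n_iterations: int = 10
    accept_worse_prob: float = 0.2
    uncertain_threshold: float = 0.99
    candidate_floor: float = 0.01


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    bulk_refine: BulkRefineConfig = field(default_factory=BulkRefineConfig)
    evaluate: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "simulate": SimulateConfig,
    "preprocess": PreprocessConfig,
    "cluster": ClusterConfig,
    "bulk_refine": BulkRefineConfig,
}


def _build(cls, doc: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) under '{path}': {', '.join(sorted(unknown))}"
        )
    return cls(**doc)


def validate_config(document: dict | None) -> PipelineConfig:
    """Validate a (possibly partial) config document, filling defaults.

    Unknown keys are rejected by name; cross-field constraints (positive
    restart count, valid Kmax, threshold ranges) are checked.
    """
    document = dict(document or {})
    top_known = {f.name for f in fields(PipelineConfig)}
    unknown = set(document) - top_known
    if unknown:
        raise ConfigError(f"unknown key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        sub = document.pop(name, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"'{name}' must be a mapping")
        kwargs[name] = _build(cls, sub, name)
    kwargs.update(document)
    cfg = PipelineConfig(**kwargs)

    if cfg.cluster.n_restarts < 1:
        raise ConfigError("cluster.n_restarts must be >= 1")
    if cfg.cluster.kmax < 1:
        raise ConfigError("cluster.kmax must be >= 1")
    if not 0 <= cfg.cluster.decrease_threshold < 1:
        raise ConfigError("cluster.decrease_threshold must be in [0, 1)")
    if cfg.cluster.tol <= 0:
        raise ConfigError("cluster.tol must be > 0")
    if not cfg.simulate.enabled and cfg.preprocess.calls_dir is None:
        raise ConfigError("either simulate.enabled or preprocess.calls_dir is required")
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return validate_config(doc)
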