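"""Run and simulation configuration.

RunConfig holds the analysis thresholds (copy-loss call, FDR levels,
permutation count); SimConfig holds the generative model for the synthetic
panel. Both round-trip through YAML and validate on construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


@dataclass
class RunConfig:
    """Analysis-stage parameters.

    loss_threshold/gain_threshold are on the log2 relative copy-number
    scale; a sample is called copy-loss when log2 <= loss_threshold
    (the boundary itself is a loss). Setting gain_threshold to +inf
    reproduces a strict two-class loss/neutral scheme.
    """

    loss_threshold: float = -0.35
    gain_threshold: float = 0.35
    n_permutations: int = 10_000
    fdr_general: float = 0.25
    fdr_cyclops: float = 0.10
    fdr_splicing: float = 0.10
    seed: int = 0
    min_pairwise_samples: int = 20
    collapse_r_min: float = 0.9
    gene_loss_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.loss_threshold < self.gain_threshold:
            raise ValueError("loss_threshold must be below gain_threshold")
        for name in ("fdr_general", "fdr_cyclops", "fdr_splicing"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_pairwise_samples < 3:
            raise ValueError("min_pairwise_samples must be >= 3")
        if not 0.0 < self.gene_loss_overlap_fraction <= 1.0:
            raise ValueError("gene_loss_overlap_fraction must be in (0, 1]")


@dataclass
class SimConfig:
    """Synthetic-panel generative parameters.

    The defaults emulate the statistical structure of a pan-cancer cell-line
    screen: 179 lines across a handful of lineages, copy losses that are
    mostly arm-scale with some focal events, calibrated so the mean fraction
    of the genome lost per sample is ~0.16, single-copy losses near
    log2(1/2), and overdispersed splice-junction counts.
    """

    n_chromosomes: int = 10
    genes_per_arm: int = 25
    gene_span: int = 1_000_000  # bp per gene slot when tiling arms
    n_cell_lines: int = 179
    n_lineages: int = 4
    arm_loss_rate: float = 0.15  # per arm per sample
    focal_loss_rate: float = 0.1  # per arm per sample
    focal_fraction_range: tuple[float, float] = (0.05, 0.2)  # of the arm
    segment_noise_sd: float = 0.05  # log2 units, per segment
    gene_noise_sd: float = 0.05  # log2 units, per gene measurement
    mean_fraction_genome_lost_target: float = 0.16
    dependency_noise_sd: float = 0.3  # score units
    n_cyclops_genes: int = 10
    cyclops_delta: float = -1.15  # score units, loss-conditional shift
    n_trans_pairs: int = 5
    trans_delta: float = -0.9  # score units, loss-of-partner shift
    expression_noise_sd: float = 0.2  # sd of log expression noise
    cyclops_dispersion_factor: float = 0.5  # expression-noise shrink for CYCLOPS genes
    attenuation_cyclops: float = 0.28  # fractional expression drop upon loss
    attenuation_background: float = 0.18
    n_junctions: int = 2000
    junction_depth: float = 50.0  # mean reads per junction per sample
    junction_rho: float = 0.05  # beta-binomial overdispersion
    fraction_dysregulated: float = 0.10
    delta_psi: float = 0.30
    direction_bias: float = 0.9  # share of planted shifts up in the target group
    n_samples_per_group: int = 6  # junction-count samples per condition group
    per_lineage_rate_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arm_loss_rate", "focal_loss_rate", "fraction_dysregulated",
                     "direction_bias", "attenuation_cyclops", "attenuation_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.junction_rho < 1.0:
            raise ValueError("junction_rho must be in [0, 1)")
        if self.junction_depth <= 0:
            raise ValueError("junction_depth must be positive")
        for name in ("n_chromosomes", "genes_per_arm", "n_cell_lines", "n_lineages"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


def _as_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_hash(cfg) -> str:
    """Stable short hash of a config, for provenance headers."""
    payload = json.dumps(_as_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path, kind: str = "run"):
    """Load a RunConfig ('run') or SimConfig ('sim') from YAML.

    The YAML file may carry top-level 'run:' and 'sim:' sections or a flat
    mapping of fields for the requested kind.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if kind in raw:
        raw = raw[kind] or {}
    cls = RunConfig if kind == "run" else SimConfig
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {kind} config fields: {sorted(unknown)}")
    if "focal_fraction_range" in raw:
        raw["focal_fraction_range"] = tuple(raw["focal_fraction_range"])
    return cls(**raw)


def save_config(run: RunConfig, sim: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"run": _as_dict(run), "sim": _as_dict(sim)}, fh, sort_keys=True)
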