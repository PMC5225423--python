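"""Synthetic two-group miRNA microarray data with known ground truth.

The generator emulates the statistical structure of a serum miRNA
microarray study comparing a patient group against healthy controls:

* ~900 probes of log2 intensities with Gaussian noise,
* a planted set of up/down differentially expressed miRNAs with a
  specified log2 effect size,
* blocks of miRNAs tied to a shared latent factor so their pairwise
  Pearson correlation is controlled,
* completely-at-random missing values,
* a target/pathway annotation in which designated miRNA pairs share a
  block of co-target genes placed inside one pathway, so that the
  hypergeometric synergy test is expected to fire for exactly those pairs.

Correlation model
-----------------
A block row is ``baseline + noise_sd * (loading * f + sqrt(1 - loading^2) * eps)``
with ``f`` a per-sample latent factor and ``eps`` independent unit noise,
so every row keeps marginal standard deviation ``noise_sd`` and two rows of
the same block have expected Pearson correlation ``loading**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, ExpressionMatrix, PathwayAnnotation, TargetMap

__all__ = [
    "SimulationConfig",
    "AnnotationConfig",
    "GroundTruth",
    "generate_expression",
    "generate_annotation",
]


@dataclass
class SimulationConfig:
    """Parameters of the expression simulator.

    Defaults mirror the two study arms the pipeline is built around:
    38 cases vs 38 controls profiled on ~900 probes, differential effects
    at the |log2 fold change| >= 0.8 screening threshold and correlated
    blocks whose expected CE clears 0.8.
    """

    n_case: int = 38
    n_control: int = 38
    n_mirnas: int = 900
    n_de: int = 20
    effect_log2: float = 1.5
    corr_blocks: list[tuple[int, float]] = field(default_factory=list)
    missing_frac: float = 0.01
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_case, self.n_control, self.n_mirnas) <= 0:
            raise ValueError("n_case, n_control and n_mirnas must be positive")
        if self.n_de < 0 or self.n_de > self.n_mirnas:
            raise ValueError("n_de must lie in [0, n_mirnas]")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for size, loading in self.corr_blocks:
            if size < 2:
                raise ValueError("every correlated block needs size >= 2")
            if not 0 <= loading <= 1:
                raise ValueError("block loading must lie in [0, 1]")
        n_block_rows = sum(size for size, _ in self.corr_blocks)
        if self.n_de + n_block_rows > self.n_mirnas:
            raise ValueError("planted DE rows plus block rows exceed n_mirnas")


@dataclass
class AnnotationConfig:
    """Parameters of the target/pathway annotation simulator."""

    mirna_ids: list[str]
    n_genes: int = 5000
    targets_per_mirna: int = 50
    n_pathways: int = 40
    pathway_size: int = 60
    planted_synergy_pairs: list[tuple[str, str]] = field(default_factory=list)
    co_target_overlap: int = 10
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.targets_per_mirna, self.n_pathways, self.pathway_size) <= 0:
            raise ValueError("annotation dimensions must be positive")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size cannot exceed n_genes")
        if self.co_target_overlap > self.targets_per_mirna:
            raise ValueError("co_target_overlap cannot exceed targets_per_mirna")
        if self.co_target_overlap > self.pathway_size:
            raise ValueError("co_target_overlap cannot exceed pathway_size")
        known = set(self.mirna_ids)
        for a, b in self.planted_synergy_pairs:
            if a == b:
                raise ValueError(f"self-pair planted: {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"planted pair ({a!r}, {b!r}) references unknown miRNAs")


@dataclass
class GroundTruth:
    """What was planted, keyed by generated identifiers."""

    de_effects: dict[str, float] = field(default_factory=dict)
    correlated_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    synergy_pairs: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def de_ids(self) -> frozenset[str]:
        return frozenset(self.de_effects)

    def to_jsonable(self) -> dict:
        return {
            "de_effects": self.de_effects,
            "correlated_pairs": [[a, b, ce] for (a, b), ce in self.correlated_pairs.items()],
            "synergy_pairs": [[a, b, p] for (a, b), p in self.synergy_pairs.items()],
        }


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a two-group log2 expression matrix.

    Returns the matrix (rows ``miR-0000`` ... , columns ``case_00``/``ctrl_00``
    ...) and the ground truth of planted effects and correlated pairs.
    Identical config (including seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    width = max(4, len(str(config.n_mirnas - 1)))
    mirna_ids = [f"miR-{i:0{width}d}" for i in range(config.n_mirnas)]
    sample_ids = [f"case_{i:02d}" for i in range(config.n_case)] + [
        f"ctrl_{i:02d}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        [CASE] * config.n_case + [CONTROL] * config.n_control, index=sample_ids
    )

    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=config.n_mirnas)
    noise = rng.standard_normal((config.n_mirnas, n))
    values = baseline[:, None] + config.noise_sd * noise

    truth = GroundTruth()

    # planted DE rows come first, alternating up/down
    case_cols = np.arange(config.n_case)
    for i in range(config.n_de):
        sign = 1.0 if i % 2 == 0 else -1.0
        effect = sign * config.effect_log2
        values[i, case_cols] += effect
        truth.de_effects[mirna_ids[i]] = effect

    # correlated blocks occupy rows after the DE rows
    row = config.n_de
    for size, loading in config.corr_blocks:
        factor = rng.standard_normal(n)
        resid_scale = math.sqrt(max(0.0, 1.0 - loading**2))
        rows = range(row, row + size)
        for r in rows:
            eps = rng.standard_normal(n)
            values[r] = baseline[r] + config.noise_sd * (loading * factor + resid_scale * eps)
        ids = [mirna_ids[r] for r in rows]
        nominal_ce = loading**2
        for i in range(size):
            for j in range(i + 1, size):
                truth.correlated_pairs[_pair_key(ids[i], ids[j])] = nominal_ce
        row += size

    if config.missing_frac > 0:
        mask = rng.random(values.shape) < config.missing_frac
        values = np.where(mask, np.nan, values)

    frame = pd.DataFrame(values, index=mirna_ids, columns=sample_ids)
    return ExpressionMatrix(frame, groups), truth


def generate_annotation(
    config: AnnotationConfig,
) -> tuple[TargetMap, PathwayAnnotation, GroundTruth]:
    """Simulate miRNA->target tables and pathway gene sets.

    Each planted synergy pair shares exactly ``co_target_overlap`` genes,
    all placed inside one designated pathway; the remaining targets of the
    two partners are drawn disjointly so no extra co-targets arise for the
    planted pair.  Unrelated miRNAs receive uniform random target sets and
    share genes only by chance.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])

    pathway_sets: dict[str, frozenset[str]] = {}
    pathway_members: list[np.ndarray] = []
    for p in range(config.n_pathways):
        members = rng.choice(genes, size=config.pathway_size, replace=False)
        pathway_sets[f"path{p:03d}"] = frozenset(members.tolist())
        pathway_members.append(members)

    targets: dict[str, set[str]] = {}
    for m in config.mirna_ids:
        picked = rng.choice(genes, size=config.targets_per_mirna, replace=False)
        targets[m] = set(picked.tolist())

    truth = GroundTruth()
    # choose every pair's shared block first, from genes no other planted
    # pair uses, so cross-pair co-targets arise only by chance
    used: set[str] = set()
    shared_of: list[tuple[str, str, str, set[str]]] = []
    for idx, (a, b) in enumerate(config.planted_synergy_pairs):
        pid = f"path{idx % config.n_pathways:03d}"
        members = pathway_members[idx % config.n_pathways]
        available = np.array(sorted(set(members.tolist()) - used))
        if len(available) < config.co_target_overlap:
            raise ValueError(
                f"pathway {pid} has too few unused genes for pair ({a}, {b})"
            )
        shared = set(
            rng.choice(available, size=config.co_target_overlap, replace=False).tolist()
        )
        used |= shared
        shared_of.append((a, b, pid, shared))
    rest_needed = config.targets_per_mirna - config.co_target_overlap
    pool = np.array(sorted(set(genes.tolist()) - used))
    for a, b, pid, shared in shared_of:
        rest = rng.choice(pool, size=2 * rest_needed, replace=False)
        targets[a] = shared | set(rest[:rest_needed].tolist())
        targets[b] = shared | set(rest[rest_needed:].tolist())
        truth.synergy_pairs[_pair_key(a, b)] = pid

    target_map = TargetMap({m: frozenset(g) for m, g in targets.items()})
    pathways = PathwayAnnotation(pathway_sets)
    return target_map, pathways, truth
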