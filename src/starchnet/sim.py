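"""Synthetic two-group expression data with planted differential expression.

The generator emulates the study design every downstream stage assumes: a
small-replicate two-condition comparison (untreated diabetic controls ``CK``
versus resistant-starch treated ``RS``), summarized linear-scale intensities
with log-normal noise, a planted fraction of genes shifted up or down by
fixed linear fold changes in the treatment group, and matching pathway and
disease-gene annotations.  Every output is a pure function of the
configuration, including its single integer seed.

Intensity model: per gene a baseline ``b ~ Normal(baseline_log2_mean,
baseline_log2_sd)`` on the log2 scale; each replicate observes
``2**(b + effect + eps)`` with ``eps ~ Normal(0, noise_sd_log2)`` and
``effect = log2(true_fc)`` applied to the RS samples only, so the expected
RS/CK ratio of a planted gene equals its true fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import DiseaseGeneSet, ExpressionMatrix, PathwayCollection

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_pathways",
    "simulate_disease_genes",
    "preferential_attachment_edges",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: 3–4 biological replicates per
    condition, screening-relevant fold changes of 2× up and 0.5× down, and
    moderate post-summarization log2 noise.
    """

    n_genes: int = 1000
    n_per_group: int = 4
    frac_up: float = 0.05
    frac_down: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    seed: int = 0
    n_pathways: int = 38
    pathway_size_range: tuple[int, int] = (3, 15)
    frac_disease_genes: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def positive_int(name: str) -> None:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")

        for name in ("n_genes", "n_per_group", "n_pathways"):
            positive_int(name)
        for name in ("frac_up", "frac_down", "frac_disease_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.frac_up + self.frac_down >= 1.0:
            raise ConfigError("frac_up + frac_down must be < 1")
        if not self.fc_up > 1.0:
            raise ConfigError(f"fc_up must be > 1, got {self.fc_up!r}")
        if not 0.0 < self.fc_down < 1.0:
            raise ConfigError(f"fc_down must lie in (0, 1), got {self.fc_down!r}")
        if self.noise_sd_log2 < 0:
            raise ConfigError(f"noise_sd_log2 must be ≥ 0, got {self.noise_sd_log2!r}")
        if self.baseline_log2_sd < 0:
            raise ConfigError(f"baseline_log2_sd must be ≥ 0, got {self.baseline_log2_sd!r}")
        lo, hi = self.pathway_size_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))
                and 0 < lo <= hi):
            raise ConfigError(f"pathway_size_range must be 0 < lo ≤ hi, got {self.pathway_size_range!r}")
        if hi > self.n_genes:
            raise ConfigError(
                f"pathway_size_range upper bound {hi} exceeds n_genes {self.n_genes}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an expression matrix and its machine-readable truth table.

    Returns
    -------
    matrix
        ``n_genes`` × ``2 * n_per_group`` strictly positive intensities,
        samples ``CK1..CKn`` then ``RS1..RSn``.
    truth
        DataFrame indexed by ``gene_id`` with ``true_status`` ∈
        {``up``, ``down``, ``null``} and linear ``true_fc``
        (``true_fc == 1`` iff ``true_status == "null"``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = _gene_ids(n)

    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    order = rng.permutation(n)
    up_idx = order[:n_up]
    down_idx = order[n_up:n_up + n_down]

    status = np.array(["null"] * n, dtype=object)
    status[up_idx] = "up"
    status[down_idx] = "down"
    true_fc = np.ones(n)
    true_fc[up_idx] = config.fc_up
    true_fc[down_idx] = config.fc_down

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    k = config.n_per_group
    noise = rng.normal(0.0, config.noise_sd_log2, size=(n, 2 * k)) \
        if config.noise_sd_log2 > 0 else np.zeros((n, 2 * k))
    log2x = baseline[:, None] + noise
    log2x[:, k:] += np.log2(true_fc)[:, None]  # effect in RS columns only

    samples = [f"CK{i}" for i in range(1, k + 1)] + [f"RS{i}" for i in range(1, k + 1)]
    groups = pd.Series(["CK"] * k + ["RS"] * k, index=samples)
    values = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    truth = pd.DataFrame(
        {"true_status": status, "true_fc": true_fc},
        index=pd.Index(genes, name="gene_id"),
    )
    return ExpressionMatrix(values, groups), truth


def simulate_pathways(config: SimulationConfig, truth: pd.DataFrame) -> PathwayCollection:
    """Assign genes to ``n_pathways`` sets with sizes uniform in the
    configured range, guaranteeing that every planted DE gene belongs to at
    least one pathway (so network assembly always has anchors).

    The seed stream is offset from the expression stream so the same config
    yields reproducible but independent draws.
    """
    config.validate()
    if truth.empty:
        raise ConfigError("truth table is empty")
    rng = np.random.default_rng(config.seed + 1_000_003)
    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)

    genes = list(truth.index)
    de_genes = list(truth.index[truth["true_status"] != "null"])
    if len(de_genes) > sizes.sum():
        raise ConfigError(
            f"cannot place {len(de_genes)} DE genes in {int(sizes.sum())} pathway slots; "
            "increase n_pathways or pathway_size_range")

    members: list[list[str]] = [[] for _ in range(config.n_pathways)]
    capacity = sizes.copy()
    # seed every DE gene into a random pathway with spare capacity
    for g in rng.permutation(de_genes):
        open_ps = np.flatnonzero(capacity > 0)
        p = int(rng.choice(open_ps))
        members[p].append(str(g))
        capacity[p] -= 1
    # fill remaining slots with distinct random genes
    for p in range(config.n_pathways):
        have = set(members[p])
        pool = [g for g in genes if g not in have]
        extra = rng.choice(len(pool), size=int(capacity[p]), replace=False)
        members[p].extend(pool[i] for i in sorted(extra))

    entries = [
        (f"P{p + 1}", f"simulated pathway {p + 1}", members[p])
        for p in range(config.n_pathways)
    ]
    return PathwayCollection(entries)


def simulate_disease_genes(truth: pd.DataFrame, frac: float, seed: int) -> DiseaseGeneSet:
    """Sample ``ceil(frac * n_genes)`` distinct symbols as the disease set.

    The sample includes at least one planted DE gene and one null gene
    whenever both exist and the requested size allows it, so the mapping
    stage always has both hits and background to work with.
    """
    if not 0 < frac <= 1:
        raise ConfigError(f"frac must lie in (0, 1], got {frac!r}")
    rng = np.random.default_rng(seed + 2_000_003)
    genes = list(truth.index)
    k = math.ceil(frac * len(genes))
    de = [g for g in genes if truth.loc[g, "true_status"] != "null"]
    null = [g for g in genes if truth.loc[g, "true_status"] == "null"]

    chosen: list[str] = []
    if k >= 2 and de and null:
        chosen.append(str(rng.choice(de)))
        chosen.append(str(rng.choice(null)))
    rest = [g for g in genes if g not in set(chosen)]
    extra = rng.choice(len(rest), size=k - len(chosen), replace=False)
    chosen.extend(rest[i] for i in sorted(extra))
    # deterministic presentation order: original gene order
    pos = {g: i for i, g in enumerate(genes)}
    chosen.sort(key=pos.__getitem__)
    return DiseaseGeneSet(chosen)


def preferential_attachment_edges(n_nodes: int, m: int, seed: int) -> list[tuple[int, int]]:
    """Grow a preferential-attachment graph: each new node attaches to ``m``
    distinct existing nodes chosen with probability proportional to degree.

    Used as a scale-free positive control for the degree-distribution
    diagnostic; starts from a star on ``m + 1`` nodes.
    """
    if m < 1 or n_nodes <= m:
        raise ConfigError(f"need n_nodes > m ≥ 1, got n_nodes={n_nodes}, m={m}")
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = [(0, j) for j in range(1, m + 1)]
    targets: list[int] = [u for e in edges for u in e]  # degree-weighted urn
    for v in range(m + 1, n_nodes):
        picked: set[int] = set()
        while len(picked) < m:
            picked.add(targets[rng.integers(len(targets))])
        for u in picked:
            edges.append((u, v))
            targets.extend((u, v))
    return edges
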