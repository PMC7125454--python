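"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates a bulk tumor/control RNA-seq study: mRNA and miRNA
raw counts are drawn from a negative binomial with mean
``base_mean * lib_j * 2^(log2fc_i * [j is tumor])`` and variance
``mu + phi * mu^2`` (the edgeR-style mean-dispersion parameterization);
library-size factors are log-uniform so the normalization stage matters.
On top of the counts it plants the structure each downstream stage is
meant to detect:

* a set of DE genes and DE miRNAs at a fixed |log2FC| (half up, half down);
* a pathway collection in which designated "planted" pathway pairs are
  enriched in up-regulated DE genes (so they come out differentially
  active) and share at least one risk-eligible gene;
* a shared per-sample log-normal latent factor multiplied into the member
  genes of each planted pair, in BOTH conditions, so the pair's median
  scores correlate strongly in tumor and in control samples alike;
* a validated-interaction table containing the planted DE-miRNA -> DE-gene
  pairs — including a hub gene targeted by two miRNAs and placed in every
  planted pathway — plus random decoy interactions among non-DE features.

All randomness flows through generators derived from ``config.seed``; the
same config reproduces the same data bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .types import CONTROL, TUMOR, CountMatrix, GeneSetCollection, MiRNATargetTable

__all__ = [
    "HubSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_pathway_db",
    "simulate_correlated_pathway_signal",
    "simulate_target_table",
    "simulate_all",
]


@dataclass
class HubSpec:
    """A planted hub: one up-regulated DE gene targeted by ``n_mirnas``
    DE miRNAs and placed in ``n_pathways`` planted pathways."""

    n_pathways: int = 10
    n_mirnas: int = 2


@dataclass
class SimulationConfig:
    # cohort shape (desk-scale stand-in for a large tumor/adjacent design)
    n_genes: int = 2000
    n_mirnas: int = 300
    n_tumor: int = 60
    n_control: int = 30
    # planted differential expression
    n_de_genes: int = 200
    n_de_mirnas: int = 40
    de_log2fc: float = 2.0
    # NB noise model
    dispersion: float = 0.1
    base_mean: float = 100.0
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    # pathway database
    n_pathways: int = 150
    pathway_size_range: tuple[int, int] = (15, 25)
    de_member_frac: float = 0.75
    # planted correlated structure
    n_correlated_pairs: int = 5
    latent_sigma: float = 0.8
    # interaction table
    n_target_genes: int = 30
    decoy_rate: float = 0.002
    hub: HubSpec | None = field(default_factory=HubSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_tumor", "n_control", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_de_genes > self.n_genes or self.n_de_mirnas > self.n_mirnas:
            raise ValueError("planted DE counts exceed feature totals")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway size range exceeds gene universe")
        if self.hub is not None and self.hub.n_pathways < 2 * self.n_correlated_pairs:
            raise ValueError("hub must span both pathways of every planted pair")
        if self.n_target_genes > self.n_de_genes:
            raise ValueError("n_target_genes exceeds n_de_genes")
        if not 0 <= self.decoy_rate <= 1:
            raise ValueError("decoy_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    de_gene_ids: list[str]
    de_mirna_ids: list[str]
    true_log2fc: dict[str, float]
    target_gene_ids: list[str]
    planted_pairs: list[tuple[str, str]]  # (miRNA, gene)
    hub_gene_id: str | None
    correlated_pair_ids: list[tuple[str, str]] = field(default_factory=list)
    planted_pathway_members: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def _draw_counts(rng, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def _nb_matrix(rng, n_feat, log2fc, is_tumor, config) -> np.ndarray:
    lo, hi = config.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=is_tumor.size))
    mu = config.base_mean * lib[None, :] * 2.0 ** (log2fc[:, None] * is_tumor[None, :])
    return _draw_counts(rng, mu, config.dispersion)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Draw the mRNA and miRNA count matrices and fix the ground truth.

    DE features get log2FC ``+/- de_log2fc`` (half up, half down); the hub
    gene is an up-regulated DE gene; the planted miRNA->gene interactions
    (1-2 DE miRNAs per risk-eligible target gene, exactly ``hub.n_mirnas``
    for the hub) are decided here so later stages can agree on them.
    """
    rng = _rng(config, 0)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    mirnas = [f"mir{i:04d}" for i in range(config.n_mirnas)]
    samples = [f"s{j:03d}" for j in range(config.n_tumor + config.n_control)]
    is_tumor = np.array([1.0] * config.n_tumor + [0.0] * config.n_control)
    condition = pd.Series(
        [TUMOR] * config.n_tumor + [CONTROL] * config.n_control, index=samples, dtype=object
    )

    def plant(ids: list[str], n_de: int) -> tuple[list[str], np.ndarray]:
        chosen = sorted(rng.choice(len(ids), size=n_de, replace=False))
        lfc = np.zeros(len(ids))
        signs = np.where(np.arange(n_de) < n_de // 2, 1.0, -1.0)
        lfc[chosen] = signs * config.de_log2fc
        return [ids[i] for i in chosen], lfc

    de_genes, gene_lfc = plant(genes, config.n_de_genes)
    de_mirnas, mirna_lfc = plant(mirnas, config.n_de_mirnas)
    up_genes = [g for g in de_genes if gene_lfc[genes.index(g)] > 0]
    up_mirna_flags = {m: mirna_lfc[mirnas.index(m)] > 0 for m in de_mirnas}

    mrna = CountMatrix(
        pd.DataFrame(
            _nb_matrix(rng, config.n_genes, gene_lfc, is_tumor, config),
            index=genes, columns=samples,
        ),
        condition.copy(),
    )
    mirna = CountMatrix(
        pd.DataFrame(
            _nb_matrix(rng, config.n_mirnas, mirna_lfc, is_tumor, config),
            index=mirnas, columns=samples,
        ),
        condition.copy(),
    )

    hub_gene = None
    target_pool = list(de_genes)
    if config.hub is not None:
        hub_gene = up_genes[int(rng.integers(len(up_genes)))]
        target_pool.remove(hub_gene)
    extra = sorted(
        rng.choice(
            len(target_pool),
            size=config.n_target_genes - (1 if hub_gene else 0),
            replace=False,
        )
    )
    target_genes = ([hub_gene] if hub_gene else []) + [target_pool[i] for i in extra]

    planted_pairs: list[tuple[str, str]] = []
    for g in target_genes:
        if g == hub_gene:
            partners = rng.choice(len(de_mirnas), size=config.hub.n_mirnas, replace=False)
        else:
            partners = rng.choice(len(de_mirnas), size=int(rng.integers(1, 3)), replace=False)
        planted_pairs.extend((de_mirnas[i], g) for i in sorted(partners))

    truth = GroundTruth(
        de_gene_ids=de_genes,
        de_mirna_ids=de_mirnas,
        true_log2fc={
            **dict(zip(genes, gene_lfc)),
            **dict(zip(mirnas, mirna_lfc)),
        },
        target_gene_ids=target_genes,
        planted_pairs=sorted(set(planted_pairs)),
        hub_gene_id=hub_gene,
    )
    return mrna, mirna, truth


def simulate_pathway_db(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Build the pathway collection with the planted pair structure.

    Planted pathways (2 per correlated pair, the hub's pathways when a hub
    is configured) draw ``de_member_frac`` of their members from the
    up-regulated DE genes so that their median scores shift in tumor
    samples; every planted pair shares at least one risk-eligible gene
    (the hub, or an explicitly shared target gene).  Remaining pathways
    get uniformly random members.
    """
    rng = _rng(config, 1)
    genes = sorted(truth.true_log2fc)
    genes = [g for g in genes if not g.startswith("mir")]
    up_genes = [g for g in truth.de_gene_ids if truth.true_log2fc[g] > 0]
    non_de = [g for g in genes if g not in set(truth.de_gene_ids)]
    lo, hi = config.pathway_size_range

    n_planted = max(
        2 * config.n_correlated_pairs,
        config.hub.n_pathways if config.hub is not None else 0,
    )
    if n_planted > config.n_pathways:
        raise ValueError("more planted pathways than n_pathways")
    sets: dict[str, tuple[str, ...]] = {}
    planted_ids = [f"P{i:03d}" for i in range(n_planted)]
    # Disjoint up-gene blocks per planted pair: both pathways of a pair draw
    # their DE members from the same block, so within-pair sharing is allowed
    # but a gene never sits in planted pathways of two different pairs (which
    # would let one pair's latent factor bleed into another's scores).
    shuffled_up = [up_genes[i] for i in rng.permutation(len(up_genes))]
    if truth.hub_gene_id is not None:
        shuffled_up.remove(truth.hub_gene_id)
    n_blocks = max(config.n_correlated_pairs, 1)
    block_size = len(shuffled_up) // n_blocks
    blocks = [shuffled_up[b * block_size:(b + 1) * block_size] for b in range(n_blocks)]
    for k, pid in enumerate(planted_ids):
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        if config.hub is not None and k < config.hub.n_pathways:
            members.append(truth.hub_gene_id)
        block = blocks[(k // 2) % n_blocks]
        n_up_target = max(1, round(config.de_member_frac * (size - len(members))))
        if n_up_target > len(block):
            logger.warning(
                "pathway %s: only %d up-DE genes available for a target of %d; "
                "its median shift (and pathway DE call) may be weak",
                pid, len(block), n_up_target,
            )
        n_up = min(n_up_target, len(block))
        members += [block[i] for i in rng.choice(len(block), size=n_up, replace=False)]
        n_fill = size - len(members)
        members += [non_de[i] for i in rng.choice(len(non_de), size=n_fill, replace=False)]
        sets[pid] = tuple(members)

    pair_ids = []
    for k in range(config.n_correlated_pairs):
        x, y = planted_ids[2 * k], planted_ids[2 * k + 1]
        if config.hub is None and truth.target_gene_ids:
            shared = truth.target_gene_ids[k % len(truth.target_gene_ids)]
            for pid in (x, y):
                if shared not in sets[pid]:
                    sets[pid] = (shared,) + sets[pid][:-1]
        pair_ids.append((x, y))

    for i in range(n_planted, config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        sets[f"P{i:03d}"] = tuple(genes[j] for j in idx)

    truth.correlated_pair_ids = pair_ids
    truth.planted_pathway_members = {pid: sets[pid] for pid in planted_ids}
    return GeneSetCollection(sets)


def simulate_correlated_pathway_signal(
    config: SimulationConfig,
    m: CountMatrix,
    sets: GeneSetCollection,
    truth: GroundTruth,
) -> CountMatrix:
    """Multiply a shared per-sample latent factor into each planted pair.

    For every planted correlated pair, one log-normal(0, latent_sigma)
    factor per sample is applied to the counts of all member genes of both
    pathways, in tumor and control samples alike; a gene belonging to
    several planted pathways receives only its first pair's factor.  With
    sigma = 0 the matrix is returned unchanged.  Returns a modified copy.
    """
    rng = _rng(config, 2)
    counts = m.counts.to_numpy().astype(np.float64).copy()
    feature_pos = {g: i for i, g in enumerate(m.feature_ids)}
    assigned: set[str] = set()
    for x, y in truth.correlated_pair_ids:
        latent = rng.lognormal(mean=0.0, sigma=config.latent_sigma, size=counts.shape[1])
        members = [g for g in dict.fromkeys(sets.sets[x] + sets.sets[y]) if g in feature_pos]
        rows = [feature_pos[g] for g in members if g not in assigned]
        assigned.update(g for g in members)
        if config.latent_sigma == 0 or not rows:
            continue
        counts[rows, :] = counts[rows, :] * latent[None, :]
    return CountMatrix(
        pd.DataFrame(np.round(counts).astype(np.int64), index=m.feature_ids, columns=m.sample_ids),
        m.condition.copy(),
    )


def simulate_target_table(config: SimulationConfig, truth: GroundTruth) -> MiRNATargetTable:
    """Planted DE-miRNA -> DE-gene pairs plus random decoy interactions.

    Decoys connect non-DE miRNAs to non-DE genes; their number is
    Binomial(#possible pairs, decoy_rate), drawn without replacement.
    """
    rng = _rng(config, 3)
    rows = [(m, g, "planted") for m, g in truth.planted_pairs]
    genes = sorted(g for g in truth.true_log2fc if not g.startswith("mir"))
    mirnas = sorted(g for g in truth.true_log2fc if g.startswith("mir"))
    null_genes = [g for g in genes if g not in set(truth.de_gene_ids)]
    null_mirnas = [m for m in mirnas if m not in set(truth.de_mirna_ids)]
    n_possible = len(null_genes) * len(null_mirnas)
    n_decoys = int(rng.binomial(n_possible, config.decoy_rate)) if n_possible else 0
    flat = rng.choice(n_possible, size=n_decoys, replace=False)
    for f in sorted(flat):
        mi, gi = divmod(int(f), len(null_genes))
        rows.append((null_mirnas[mi], null_genes[gi], "decoy"))
    return MiRNATargetTable(pd.DataFrame(rows, columns=["mirna", "target", "source"]))


def simulate_all(config: SimulationConfig):
    """Run all four generator stages; returns (mrna, mirna, sets, targets, truth)."""
    mrna, mirna, truth = simulate_counts(config)
    sets = simulate_pathway_db(config, truth)
    mrna = simulate_correlated_pathway_signal(config, mrna, sets, truth)
    targets = simulate_target_table(config, truth)
    return mrna, mirna, sets, targets, truth
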