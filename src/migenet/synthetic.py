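"""Synthetic matched microbe/gene datasets with planted couplings.

The generator emulates the statistical shape of matched tumor multi-omics:
heavy-tailed nonnegative gene expression (log-normal, FPKM-like),
zero-inflated microbial abundance (Gaussian log-CPM with a Bernoulli zero
mask), identical sample columns across the two matrices, per-sample
early/late condition labels, and a planted set of microbe-gene statistical
couplings whose wiring can differ between the two conditions
(``rewire_fraction``).

A coupling makes the gene's latent value a noisy monotone, quadratic or
thresholded function of the microbe's *observed* (post zero-mask)
abundance within the samples of one condition, with the noise scaled so
the squared correlation between the transformed microbe signal and the
gene's latent value equals ``coupling_strength``; the latent value is then
mapped through the gene's log-normal link, so coupled genes keep the same
marginal family as null genes and at strength 0 the construction reduces
exactly to the null draw.  Couplings are assigned to microbes with
Zipf-like (rank-inverse) weights, so a few hub microbes accumulate many
coupled genes — mirroring the uneven microbial connectivity of real
microbe-gene networks — while each gene is the target of at most one
coupling per condition.

Default scale is reduced for desk-scale analysis: 300 genes x 80 microbes
over 60 + 60 samples with 150 couplings at strength 0.8 and full rewiring
between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from migenet.containers import OmicsMatrix
from migenet.enrichment import GeneSetCollection

STAGES = ("early", "late")
COUPLING_FORMS = ("monotone", "quadratic", "threshold")


class ConfigurationError(ValueError):
    """Invalid synthetic-dataset configuration."""


class Coupling(NamedTuple):
    microbe_id: str
    gene_id: str
    stage: str


@dataclass
class SynthConfig:
    """Study conditions for one synthetic matched dataset."""

    n_genes: int = 300
    n_microbes: int = 80
    n_samples_early: int = 60
    n_samples_late: int = 60
    n_couplings: int = 150
    coupling_strength: float = 0.8
    coupling_form: str = "monotone"
    rewire_fraction: float = 1.0
    zero_inflation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_microbes", "n_samples_early", "n_samples_late"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_couplings < 0:
            raise ConfigurationError("n_couplings must be nonnegative")
        if self.n_couplings > self.n_genes * self.n_microbes:
            raise ConfigurationError("n_couplings exceeds the number of pairs")
        if self.n_couplings > self.n_genes:
            raise ConfigurationError(
                "n_couplings exceeds n_genes: each gene is the target of at "
                "most one coupling per condition")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ConfigurationError("coupling_strength must be in [0, 1]")
        if self.coupling_form not in COUPLING_FORMS:
            raise ConfigurationError(
                f"coupling_form must be one of {COUPLING_FORMS}")
        if not (0.0 <= self.rewire_fraction <= 1.0):
            raise ConfigurationError("rewire_fraction must be in [0, 1]")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ConfigurationError("zero_inflation must be in [0, 1)")


@dataclass
class MatchedDataset:
    """Matched microbe/gene matrices with stage labels and planted truth."""

    gene_matrix: OmicsMatrix
    microbe_matrix: OmicsMatrix
    stage_labels: pd.Series  # index: sample id, values in {early, late}
    truth: list[Coupling]
    config: SynthConfig

    def samples_of(self, stage: str) -> list[str]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        return [s for s, v in self.stage_labels.items() if v == stage]

    def truth_pairs(self, stage: str) -> set[tuple[str, str]]:
        return {(c.microbe_id, c.gene_id) for c in self.truth if c.stage == stage}

    def write(self, out_dir) -> dict[str, str]:
        """Write matrices, labels and truth as TSV; returns the paths."""
        from migenet import io as mio

        return mio.write_dataset(self, out_dir)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _transform(x: np.ndarray, form: str, rng: np.random.Generator) -> np.ndarray:
    """Microbe signal driving a coupled gene, standardized."""
    if form == "monotone":
        return _standardize(x)
    if form == "quadratic":
        return _standardize((x - x.mean()) ** 2)
    if form == "threshold":
        return _standardize((x > np.median(x)).astype(float))
    raise ConfigurationError(f"unknown coupling form {form!r}")


def _assign_couplings(rng: np.random.Generator, config: SynthConfig,
                      microbe_ids: list[str], gene_ids: list[str]
                      ) -> list[Coupling]:
    """Draw the early truth set and rewire a fraction of it for late.

    Microbes are drawn with rank-inverse (Zipf-like) weights over a random
    microbe permutation; gene targets are drawn without replacement within
    each condition, and rewired couplings get genes untouched in the early
    condition whenever enough remain, so rewire_fraction = 1 yields
    disjoint truth sets.
    """
    m = config.n_microbes
    order = rng.permutation(m)
    weights = np.zeros(m)
    weights[order] = 1.0 / np.arange(1, m + 1)
    weights /= weights.sum()

    n_c = config.n_couplings
    early_genes = rng.choice(config.n_genes, size=n_c, replace=False)
    early_microbes = rng.choice(m, size=n_c, p=weights)
    truth = [Coupling(microbe_ids[mi], gene_ids[gi], "early")
             for mi, gi in zip(early_microbes, early_genes)]

    n_rewire = int(round(config.rewire_fraction * n_c))
    kept = truth[: n_c - n_rewire]
    truth.extend(Coupling(c.microbe_id, c.gene_id, "late") for c in kept)

    if n_rewire:
        fresh = np.setdiff1d(np.arange(config.n_genes), early_genes)
        rng.shuffle(fresh)
        if fresh.size >= n_rewire:
            new_genes = fresh[:n_rewire]
        else:  # not enough untouched genes; reuse early targets, avoid
            # re-planting the identical pair by redrawing the microbe
            reuse = rng.choice(early_genes, size=n_rewire - fresh.size,
                               replace=False)
            new_genes = np.concatenate([fresh, reuse])
        new_microbes = rng.choice(m, size=n_rewire, p=weights)
        early_pairs = {(c.microbe_id, c.gene_id) for c in truth
                       if c.stage == "early"}
        for mi, gi in zip(new_microbes, new_genes):
            pair = (microbe_ids[mi], gene_ids[gi])
            while pair in early_pairs:
                mi = rng.choice(m, p=weights)
                pair = (microbe_ids[mi], gene_ids[gi])
            truth.append(Coupling(pair[0], pair[1], "late"))
    return truth


def generate_matched_dataset(config: SynthConfig) -> MatchedDataset:
    """Generate one matched dataset under the given study conditions.

    Deterministic given ``config.seed``: one root seed drives a documented
    stream-splitting scheme (microbe draw, gene baseline, coupling
    assignment, coupling noise each get an independent child stream).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_microbe, rng_gene, rng_assign, rng_couple = (
        np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(4))

    n_samples = config.n_samples_early + config.n_samples_late
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    microbe_ids = [f"MB{i + 1:04d}" for i in range(config.n_microbes)]
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    stages = np.array(["early"] * config.n_samples_early
                      + ["late"] * config.n_samples_late, dtype=object)

    # microbial abundance: per-feature Gaussian log-CPM + Bernoulli zero mask
    m_mean = rng_microbe.uniform(1.0, 8.0, size=config.n_microbes)
    m_sd = rng_microbe.uniform(0.5, 2.0, size=config.n_microbes)
    microbe = rng_microbe.normal(m_mean[:, None], m_sd[:, None],
                                 size=(config.n_microbes, n_samples))
    zero_mask = rng_microbe.random((config.n_microbes, n_samples)) < config.zero_inflation
    microbe[zero_mask] = 0.0

    # gene expression: log-normal heavy tail; keep the latent z so couplings
    # can replace it without changing the marginal family
    g_mu = rng_gene.uniform(0.0, 3.0, size=config.n_genes)
    g_sigma = rng_gene.uniform(0.5, 1.5, size=config.n_genes)
    z = rng_gene.normal(size=(config.n_genes, n_samples))

    truth = _assign_couplings(rng_assign, config, microbe_ids, gene_ids)

    m_index = {m: i for i, m in enumerate(microbe_ids)}
    g_index = {g: i for i, g in enumerate(gene_ids)}
    stage_cols = {"early": np.where(stages == "early")[0],
                  "late": np.where(stages == "late")[0]}
    s = config.coupling_strength
    for c in truth:
        cols = stage_cols[c.stage]
        x = microbe[m_index[c.microbe_id], cols]
        t = _transform(x, config.coupling_form, rng_couple)
        eps = rng_couple.normal(size=cols.size)
        z[g_index[c.gene_id], cols] = math.sqrt(s) * t + math.sqrt(1.0 - s) * eps

    gene = np.exp(g_mu[:, None] + g_sigma[:, None] * z)

    gene_matrix = OmicsMatrix(
        pd.DataFrame(gene, index=gene_ids, columns=sample_ids), "gene")
    microbe_matrix = OmicsMatrix(
        pd.DataFrame(microbe, index=microbe_ids, columns=sample_ids), "microbe")
    labels = pd.Series(stages, index=sample_ids, name="stage")
    return MatchedDataset(gene_matrix, microbe_matrix, labels, truth, config)


def hub_microbe(truth: list[Coupling], stage: str | None = None) -> str:
    """The microbe with the most planted couplings (ties: id ascending)."""
    counts: dict[str, int] = {}
    for c in truth:
        if stage is None or c.stage == stage:
            counts[c.microbe_id] = counts.get(c.microbe_id, 0) + 1
    if not counts:
        raise ValueError("truth list has no couplings for the requested stage")
    return min(counts, key=lambda k: (-counts[k], k))


_DESC_VOCAB = [
    "regulation", "epithelial", "cell", "proliferation", "signaling",
    "response", "immune", "transport", "metabolic", "process", "adhesion",
    "migration", "apoptotic", "differentiation", "inflammatory", "binding",
    "membrane", "nuclear", "localization", "pathway",
]


def generate_gene_sets(
    gene_ids: list[str],
    n_sets: int,
    size_range: tuple[int, int],
    n_enriched: int,
    truth: list[Coupling],
    seed: int,
) -> GeneSetCollection:
    """Random gene sets, ``n_enriched`` of which overlap the hub's targets.

    Each enriched set draws at least half its members from the coupled-gene
    neighborhood of the hub microbe (the microbe with the most planted
    couplings), giving the over-representation analysis a known positive.
    Deterministic given ``seed``.
    """
    lo, hi = int(size_range[0]), int(size_range[1])
    if not (1 <= lo <= hi <= len(gene_ids)):
        raise ValueError(
            f"size_range {size_range} outside [1, {len(gene_ids)}]")
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = frozenset(gene_ids)
    gene_arr = np.asarray(gene_ids, dtype=object)

    hub_genes: list[str] = []
    if n_enriched:
        hub = hub_microbe(truth)
        hub_genes = sorted({c.gene_id for c in truth if c.microbe_id == hub})

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        desc = " ".join(rng.choice(_DESC_VOCAB, size=4, replace=False))
        if i < n_enriched and hub_genes:
            n_over = min(len(hub_genes), max(size - size // 2, 1))
            core = list(rng.choice(np.asarray(hub_genes, dtype=object),
                                   size=n_over, replace=False))
            rest_pool = np.asarray(sorted(universe - set(core)), dtype=object)
            rest = list(rng.choice(rest_pool, size=size - n_over, replace=False))
            members = frozenset(core + rest)
        else:
            members = frozenset(rng.choice(gene_arr, size=size, replace=False))
        sets[f"GS{i + 1:04d}"] = (desc, members)
    return GeneSetCollection(sets, universe)
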