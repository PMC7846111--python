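"""Synthetic-data generators for every pipeline input.

All generators are pure functions of (configuration, seed).  They emulate the
statistical structure the analysis assumes — a heavy-tailed per-gene mutation
frequency table over the 1,566-gene catalog, multimodal ATP-synthase
production fractions, and an expression counts matrix with aero-type
structure, planted pathway gene sets and duplicate-replicate noise — without
reproducing any measured sequence or read data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import InputError, ModelSpec, build_default_model
from .sampling import MutationFrequencyTable

__all__ = [
    "SyntheticConfig",
    "ExpressionDesign",
    "DEFAULT_FATPS_MEANS",
    "make_gene_catalog",
    "make_mutation_frequency_table",
    "make_fatps_samples",
    "make_expression_fixture",
]

#: the four non-zero modal values of f_ATPS used for synthetic draws
DEFAULT_FATPS_MEANS = (0.37, 0.53, 0.64, 0.71)

N_CATALOG_GENES = 1566
TOTAL_MUTATIONS = 266940
CATEGORY_SPLIT = {"snp": 245635, "deletion": 16591, "insertion": 4714}


@dataclass
class ExpressionDesign:
    """Layout of the synthetic expression fixture."""

    n_genes: int = 2000
    n_strains: int = 12
    n_replicates: int = 2
    n_signal_genes: int = 50  # planted aero-type-correlated genes (OXPHOS-like)
    n_tca_genes: int = 20  # planted TCA-like genes (same direction, weaker)
    n_ferm_genes: int = 30  # planted fermentation genes (opposite direction)
    effect_size: float = 1.0  # log2 units per unit aero-type score
    replicate_sd: float = 0.04  # log2 replicate noise; keeps replicate R2 > 0.97
    biological_sd: float = 0.25  # per-strain, per-gene noise (log2)
    depth: int = 2_000_000  # sequencing depth per sample


@dataclass
class SyntheticConfig:
    """Configuration for all generators, with the study defaults."""

    n_genes: int = N_CATALOG_GENES
    total_mutations: int = TOTAL_MUTATIONS
    category_split: dict[str, int] = field(
        default_factory=lambda: dict(CATEGORY_SPLIT)
    )
    nb_dispersion: float = 0.5  # gamma shape of the per-gene count law
    expression: ExpressionDesign = field(default_factory=ExpressionDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.category_split.values()) != self.total_mutations:
            raise InputError("category counts must sum to total_mutations")
        if any(v < 0 for v in self.category_split.values()):
            raise InputError("category counts must be non-negative")


def make_gene_catalog(n_genes: int = N_CATALOG_GENES, model: ModelSpec | None = None) -> list[str]:
    """Gene catalog: the coarse model's genes first, then synthetic filler ids."""
    model = model or build_default_model()
    genes = list(dict.fromkeys(g for e in model.enzymes for g in e.gene_ids))
    if n_genes < len(genes):
        raise InputError(f"catalog must hold at least the {len(genes)} model genes")
    filler = [f"y{k:04d}" for k in range(n_genes - len(genes))]
    return genes + filler


def make_mutation_frequency_table(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    gene_ids=None,
) -> MutationFrequencyTable:
    """Draw a heavy-tailed per-gene mutation-count table.

    Counts follow a negative-binomial law (small dispersion -> heavy tail)
    and are rescaled by largest-remainder rounding so they sum exactly to the
    configured mutation total; probabilities are count/total.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = list(gene_ids) if gene_ids is not None else make_gene_catalog(config.n_genes)
    n = len(genes)
    mean = config.total_mutations / n
    r = config.nb_dispersion
    raw = rng.negative_binomial(r, r / (r + mean), size=n).astype(float)
    raw += 1e-9  # avoid an all-zero pathological draw
    target = config.total_mutations
    scaled = raw * (target / raw.sum())
    counts = np.floor(scaled).astype(int)
    remainder = target - counts.sum()
    frac = scaled - np.floor(scaled)
    order = np.lexsort((np.arange(n), -frac))  # largest remainder, ties by index
    counts[order[:remainder]] += 1
    return MutationFrequencyTable.from_counts(dict(zip(genes, counts.tolist())))


def make_fatps_samples(
    means=DEFAULT_FATPS_MEANS,
    sds=0.02,
    weights=None,
    zero_weight: float = 0.0,
    n: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Draw ATP-synthase fractions from a zero point mass plus a Gaussian
    mixture, truncated to (0, 0.9]."""
    means = np.asarray(means, dtype=float)
    k = len(means)
    sds = np.full(k, sds, dtype=float) if np.isscalar(sds) else np.asarray(sds, float)
    if weights is None:
        weights = np.full(k, (1.0 - zero_weight) / k)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum() + zero_weight
    if abs(total - 1.0) > 1e-9 or np.any(weights < 0) or not (0 <= zero_weight <= 1):
        raise InputError("weights plus zero_weight must be a probability vector")
    if np.any((means <= 0) | (means >= 1)):
        raise InputError("component means must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = np.zeros(n)
    is_zero = rng.random(n) < zero_weight
    idx = np.flatnonzero(~is_zero)
    if len(idx):
        p = weights / weights.sum()
        comp = rng.choice(k, size=len(idx), p=p)
        draws = rng.normal(means[comp], sds[comp])
        # resample the rare draws falling outside the truncation interval
        bad = (draws <= 0) | (draws > 0.9)
        while bad.any():
            draws[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
            bad = (draws <= 0) | (draws > 0.9)
        out[idx] = draws
    return out


def make_expression_fixture(
    config: SyntheticConfig | None = None, seed: int | None = None
):
    """Generate a counts matrix with planted aero-type structure.

    Strains receive an aero-type score; planted OXPHOS/TCA-like genes move up
    with the score, fermentation genes down.  Biomass yield rises and acetate
    production falls with the score while the growth rate varies
    independently, so the planted genes correlate with q_ac and Y but not
    with mu.  Each strain is measured in duplicate with small replicate
    noise, and counts are generated by inverting the TPM transform at the
    configured depth.

    Returns (ExpressionMatrix-compatible parts, truth) where truth holds the
    planted gene sets, replicate pairs and the strain grouping.
    """
    from .expression import ExpressionMatrix

    config = config or SyntheticConfig()
    d = config.expression
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = [f"g{k:04d}" for k in range(d.n_genes)]
    sets = {
        "oxphos": set(genes[: d.n_signal_genes]),
        "tca": set(genes[d.n_signal_genes : d.n_signal_genes + d.n_tca_genes]),
        "fermentation": set(
            genes[
                d.n_signal_genes + d.n_tca_genes :
                d.n_signal_genes + d.n_tca_genes + d.n_ferm_genes
            ]
        ),
    }
    # strain phenotypes: two aero-type groups give a bimodal score that
    # drives Y up and q_ac down; the growth rate varies independently
    group = np.arange(d.n_strains) % 2
    score = (2.0 * group - 1.0) * 0.8 + rng.uniform(-0.15, 0.15, size=d.n_strains)
    Y = 0.40 + 0.08 * score + rng.normal(0, 0.004, d.n_strains)
    q_ac = 4.0 - 2.5 * score + rng.normal(0, 0.05, d.n_strains)
    mu = rng.uniform(0.4, 0.9, size=d.n_strains)
    q_glc = mu / (Y * 0.18016)
    q_o2 = 10.0 + 5.0 * score + rng.normal(0, 0.2, d.n_strains)

    base = rng.normal(6.0, 2.0, size=d.n_genes).clip(min=0.5)
    lengths = pd.Series(
        rng.integers(300, 3000, size=d.n_genes), index=genes, name="length"
    )
    direction = np.zeros(d.n_genes)
    for g in sets["oxphos"]:
        direction[genes.index(g)] = d.effect_size
    for g in sets["tca"]:
        direction[genes.index(g)] = 0.7 * d.effect_size
    for g in sets["fermentation"]:
        direction[genes.index(g)] = -d.effect_size

    columns, data, pairs, strain_of = [], [], [], {}
    annotations = {}
    for s in range(d.n_strains):
        strain_expr = (
            base
            + direction * score[s]
            + rng.normal(0, d.biological_sd, size=d.n_genes)
        )
        reps = []
        for rep in range(d.n_replicates):
            name = f"strain{s:02d}_r{rep + 1}"
            reps.append(name)
            log_int = strain_expr + rng.normal(0, d.replicate_sd, size=d.n_genes)
            intensity = np.power(2.0, log_int)
            # counts so that TPM recovers the intensity profile
            p = intensity * lengths.to_numpy()
            p = p / p.sum()
            data.append(rng.poisson(d.depth * p))
            columns.append(name)
            strain_of[name] = s
            annotations[name] = {
                "mu": mu[s], "Y": Y[s], "q_glc": q_glc[s],
                "q_o2": q_o2[s], "q_ac": q_ac[s],
            }
        for a, b in zip(reps[:-1], reps[1:]):
            pairs.append((a, b))
    counts = pd.DataFrame(np.array(data).T, index=genes, columns=columns)
    ann = pd.DataFrame(annotations).T
    matrix = ExpressionMatrix(counts=counts, lengths=lengths, annotations=ann)
    truth = {
        "gene_sets": sets,
        "replicate_pairs": pairs,
        "strain_of": strain_of,
        "score": dict(zip(range(d.n_strains), score)),
        "groups": {name: int(group[s]) for name, s in strain_of.items()},
    }
    return matrix, truth
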