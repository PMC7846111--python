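"""In-silico strain sampling over the mutation-frequency catalog.

Strains are built by a two-step procedure: (1) select genes to mutate by
independent per-gene Bernoulli draws with the observed mutation frequencies,
and (2) draw the molecular effect of each mutation — a catalytic-rate factor
that is log-symmetric and exponentially distributed in magnitude (many small
effects, few large ones) together with a uniform stability offset of the
opposite sign.  A temperature sweep (default 100 strains at each integer
temperature from 25 to 46 C, 2,200 solves) produces the sample table the
landscape statistics operate on.

Randomness is organized as one substream per (temperature, replicate) so that
changing a replicate index changes only that strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .atp import compute_fractions, phenotype_from_solution
from .model import (
    Condition,
    InputError,
    ModelSpec,
    SolverError,
    apply_genotype,
    solve_growth,
)

__all__ = [
    "MutationFrequencyTable",
    "StrainGenotype",
    "SamplerConfig",
    "SAMPLE_TABLE_COLUMNS",
    "select_mutated_genes",
    "draw_mutation_effect",
    "build_genotype",
    "sample_strains",
]

#: fixed, documented column order of the sample table CSV
SAMPLE_TABLE_COLUMNS = [
    "strain_id", "T", "feasible", "mu", "q_glc", "q_ac", "q_o2", "Y",
    "f_ATPS", "f_PGK", "f_PYK", "f_ACKr", "f_PPKr", "f_PPK2r", "f_SUCOAS",
    "f_PRPPS", "n_genes_expressed", "avg_subunits", "aerotype",
]


#: strains behind the observed mutation counts; sets the per-strain scale of
#: the mutation probabilities (mean load = total counts / panel size)
GENOME_PANEL_SIZE = 1765


@dataclass
class MutationFrequencyTable:
    """Per-gene probability of harboring a mutation in a sampled strain,
    together with the observed mutation counts it was derived from.

    The probability is the per-strain rate count / panel size (capped at 1),
    so a sampled strain carries on average total/panel mutated genes — the
    same order as the 10-30% fixed-fraction variants.
    """

    probabilities: dict[str, float]
    counts: dict[str, int]
    total: int
    n_strains: int = GENOME_PANEL_SIZE

    def __post_init__(self) -> None:
        for g, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise InputError(f"gene {g}: probability {p} outside [0, 1]")
        if sum(self.counts.values()) != self.total:
            raise InputError("mutation counts do not sum to the stated total")

    @property
    def genes(self) -> list[str]:
        return list(self.probabilities)

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], n_strains: int = GENOME_PANEL_SIZE
    ) -> "MutationFrequencyTable":
        total = int(sum(counts.values()))
        probs = {g: min(1.0, c / n_strains) for g, c in counts.items()}
        return cls(
            probabilities=probs, counts=dict(counts), total=total,
            n_strains=n_strains,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "mutation_count": [self.counts[g] for g in self.genes],
                "probability": [self.probabilities[g] for g in self.genes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationFrequencyTable":
        counts = dict(zip(df["gene_id"], df["mutation_count"].astype(int)))
        total = int(df["mutation_count"].sum())
        probs = dict(zip(df["gene_id"], df["probability"].astype(float)))
        return cls(probabilities=probs, counts=counts, total=total)


@dataclass
class StrainGenotype:
    """One sampled strain: per-gene catalytic factors and stability offsets
    plus optional enzyme knockouts."""

    strain_id: str
    mutations: list[tuple[str, float, float]] = field(default_factory=list)
    knockouts: set[str] = field(default_factory=set)
    seed_path: str = ""
    fold_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for gene, factor, offset in self.mutations:
            lnf = math.log(factor) if factor > 0 else 0.0
            if lnf != 0.0 and offset != 0.0 and math.copysign(1, lnf) != -math.copysign(1, offset):
                raise InputError(
                    f"mutation on {gene}: catalytic and stability effects "
                    "must have opposite sign"
                )


@dataclass
class SamplerConfig:
    """Knobs of the sampling procedure, with the study defaults."""

    n_per_temperature: int = 100
    temperatures: tuple[float, ...] = tuple(range(25, 47))
    selection_mode: str = "frequency"  # frequency | fixed_fraction | uniform
    fixed_fraction: float = 0.1  # used when selection_mode == fixed_fraction
    effect_mode: str = "both"  # both | keff_only | dG_only
    keff_fold_range: tuple[float, float] = (0.5, 2.0)
    dG_offset_max: float = 2.0  # kcal/mol
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_temperature < 1:
            raise InputError("n_per_temperature must be >= 1")
        lo, hi = self.keff_fold_range
        if not (lo < 1.0 < hi):
            raise InputError("keff fold range must bracket 1")
        if self.selection_mode not in ("frequency", "fixed_fraction", "uniform"):
            raise InputError(f"unknown selection mode {self.selection_mode!r}")
        if self.effect_mode not in ("both", "keff_only", "dG_only"):
            raise InputError(f"unknown effect mode {self.effect_mode!r}")


def _strain_rng(master_seed: int, t_index: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(t_index, replicate))
    return np.random.default_rng(ss)


def select_mutated_genes(
    freq: MutationFrequencyTable, rng: np.random.Generator
) -> list[str]:
    """Independent per-gene Bernoulli draws with the table's probabilities;
    a gene is mutated when its uniform draw falls below its frequency."""
    genes = freq.genes
    u = rng.random(len(genes))
    return [g for g, ui in zip(genes, u) if ui < freq.probabilities[g]]


_EXP_RATE = 5.0  # rate of the magnitude law on the log-factor scale


def draw_mutation_effect(
    config: SamplerConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (k_eff factor, dG offset) for one mutation.

    The log-factor magnitude follows an exponential law truncated at ln 2 and
    rescaled to the configured fold range, with an equiprobable sign; the
    stability offset is uniform in magnitude up to 2 kcal/mol with the
    opposite sign.  ``effect_mode`` suppresses the unused channel.
    """
    lo, hi = config.keff_fold_range
    sign = 1.0 if rng.random() < 0.5 else -1.0
    u = rng.random()
    ln2 = math.log(2.0)
    # inverse CDF of Exp(rate) truncated to [0, ln 2]
    e0 = -math.log1p(-u * (1.0 - math.exp(-_EXP_RATE * ln2))) / _EXP_RATE
    e = e0 * (math.log(hi) / ln2)
    mag = rng.uniform(0.0, config.dG_offset_max)
    factor = math.exp(sign * e)
    offset = -sign * mag
    if config.effect_mode == "keff_only":
        offset = 0.0
    elif config.effect_mode == "dG_only":
        factor = 1.0
    return factor, offset


def build_genotype(
    freq: MutationFrequencyTable,
    config: SamplerConfig,
    rng: np.random.Generator,
    strain_id: str,
    seed_path: str = "",
) -> StrainGenotype:
    """Select genes and draw effects for one strain."""
    genes = freq.genes
    if config.selection_mode == "frequency":
        mutated = select_mutated_genes(freq, rng)
    elif config.selection_mode == "fixed_fraction":
        k = int(len(genes) * config.fixed_fraction)
        mutated = [genes[i] for i in sorted(rng.choice(len(genes), size=k, replace=False))]
    else:  # uniform: same expected load as the frequency table, flat across genes
        p = min(1.0, sum(freq.probabilities.values()) / len(genes))
        u = rng.random(len(genes))
        mutated = [g for g, ui in zip(genes, u) if ui < p]
    mutations = []
    for g in mutated:
        factor, offset = draw_mutation_effect(config, rng)
        mutations.append((g, factor, offset))
    return StrainGenotype(
        strain_id=strain_id,
        mutations=mutations,
        seed_path=seed_path,
        fold_range=config.keff_fold_range,
    )


def sample_strains(
    model: ModelSpec,
    freq: MutationFrequencyTable,
    config: SamplerConfig,
    electron_acceptor: str = "oxygen",
    fatps_constraint: float | None = None,
    fixed_growth_rate: float | None = None,
    knockouts: set[str] | None = None,
    flux_columns: Sequence[str] | None = None,
    phi_columns: Sequence[str] | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> pd.DataFrame:
    """Run the temperature sweep: one genotype + growth solve per replicate.

    Returns the sample table with the fixed column order; infeasible strains
    are recorded with ``feasible = False`` and zero phenotype.  Optional
    ``flux_columns`` / ``phi_columns`` append per-reaction fluxes
    (``v_<reaction>``) and per-enzyme proteome fractions (``phi_<enzyme>``)
    after the fixed columns.  Fully reproducible from ``config.master_seed``.
    """
    rows = []
    n_total = len(config.temperatures) * config.n_per_temperature
    done = 0
    for ti, temp in enumerate(config.temperatures):
        for rep in range(config.n_per_temperature):
            rng = _strain_rng(config.master_seed, ti, rep)
            sid = f"s{ti:02d}_{rep:04d}"
            genotype = build_genotype(
                freq, config, rng, sid, seed_path=f"{config.master_seed}/{ti}/{rep}"
            )
            if knockouts:
                genotype.knockouts |= set(knockouts)
            mutant = apply_genotype(model, genotype)
            cond = Condition(
                temperature=temp,
                electron_acceptor=electron_acceptor,
                fixed_growth_rate=fixed_growth_rate,
                fatps_constraint=fatps_constraint,
            )
            try:
                sol = solve_growth(mutant, cond)
            except SolverError as exc:
                raise SolverError(f"strain {sid} at T={temp}: {exc}") from exc
            rows.append(
                _row_from_solution(
                    sid, temp, sol, mutant,
                    flux_columns=flux_columns, phi_columns=phi_columns,
                )
            )
            done += 1
            if progress is not None:
                progress(done, n_total)
    cols = list(SAMPLE_TABLE_COLUMNS)
    cols += [f"v_{r}" for r in (flux_columns or [])]
    cols += [f"phi_{e}" for e in (phi_columns or [])]
    return pd.DataFrame(rows, columns=cols)


def _row_from_solution(
    sid: str,
    temp: float,
    sol,
    mutant: ModelSpec,
    flux_columns: Sequence[str] | None = None,
    phi_columns: Sequence[str] | None = None,
) -> dict:
    from .landscape import proteome_complexity  # local import to avoid a cycle

    extras = {}
    for r in flux_columns or []:
        extras[f"v_{r}"] = sol.fluxes.get(r, 0.0) if sol.feasible else 0.0
    for e in phi_columns or []:
        extras[f"phi_{e}"] = sol.enzyme_phi.get(e, 0.0) if sol.feasible else 0.0
    if not sol.feasible:
        row = dict.fromkeys(SAMPLE_TABLE_COLUMNS, 0.0)
        row.update(strain_id=sid, T=temp, feasible=False, aerotype="", **extras)
        return row
    phen = phenotype_from_solution(sol, mutant)
    frac = compute_fractions(sol, mutant)
    comp = proteome_complexity(sol, mutant)
    return {
        "strain_id": sid,
        "T": temp,
        "feasible": True,
        "mu": sol.mu,
        "q_glc": phen.q_glc,
        "q_ac": phen.q_ac,
        "q_o2": phen.q_o2,
        "Y": phen.Y,
        **frac.as_dict(),
        "n_genes_expressed": comp.n_genes_expressed,
        "avg_subunits": comp.avg_subunits,
        "aerotype": "",
        **extras,
    }
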