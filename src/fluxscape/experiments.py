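"""Drivers for the in-silico experiments: the ETC knockout panel, sampling
with the ATP-synthase fraction pinned, fixed-growth-rate sampling, and the
anaerobic nitrate variant with its nitro-types."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import (
    NITROTYPE_LABELS,
    MixtureFit,
    annotate_aerotypes,
    fit_fatps_mixture,
)
from .model import Condition, InputError, ModelSpec, apply_genotype, solve_growth
from .sampling import (
    SAMPLE_TABLE_COLUMNS,
    MutationFrequencyTable,
    SamplerConfig,
    StrainGenotype,
    _row_from_solution,
    sample_strains,
)

__all__ = [
    "KnockoutPanelSpec",
    "DEFAULT_KNOCKOUT_PANEL",
    "GENE_ALIASES",
    "resolve_knockout_genes",
    "run_knockout_panel",
    "run_constrained_sampling",
    "run_fixed_growth_sampling",
    "run_nitrate_experiment",
    "FATPS_PEAK_VALUES",
    "FIXED_RELATIVE_RATES",
    "OXIDASE_FREE_KNOCKOUTS",
]

#: the five modal f_ATPS values used for the pinned-fraction experiment
FATPS_PEAK_VALUES = (0.0, 0.37, 0.53, 0.64, 0.71)

#: fixed growth rates, relative to the wild-type optimum at 37 C
FIXED_RELATIVE_RATES = (0.18, 0.22, 0.36, 0.44, 0.47, 0.65)

#: knockouts producing the oxidase-free (fermentative under oxygen) strain
OXIDASE_FREE_KNOCKOUTS = frozenset({"Cyd", "Cyo", "AppBC", "YgiN"})

# operon-style shorthands accepted by the knockout interface
GENE_ALIASES = {
    "cydAB": "cydB",
    "cyoABCD": "cyoB",
    "appBC": "appB",
    "nuoABCDEFGHIJKLMN": "nuoB",
}

#: the experimentally constructed single and double ETC knockouts
DEFAULT_KNOCKOUT_PANEL = (
    frozenset({"ndh"}),
    frozenset({"nuoB"}),
    frozenset({"cydB"}),
    frozenset({"cyoB"}),
    frozenset({"ndh", "cydB"}),
    frozenset({"ndh", "cyoB"}),
    frozenset({"nuoB", "cydB"}),
    frozenset({"nuoB", "cyoB"}),
)


@dataclass
class KnockoutPanelSpec:
    """A list of knockout gene sets evaluated under one condition."""

    knockout_sets: tuple[frozenset[str], ...] = DEFAULT_KNOCKOUT_PANEL
    temperatures: tuple[float, ...] = (37.0,)
    electron_acceptor: str = "oxygen"


def resolve_knockout_genes(model: ModelSpec, genes) -> set[str]:
    """Map knockout gene names (or operon shorthands) to model enzymes.

    Knocking out any subunit gene disables the whole complex.
    """
    gmap = model.gene_to_enzyme
    enzymes: set[str] = set()
    for g in genes:
        g2 = GENE_ALIASES.get(g, g)
        if g2 not in gmap:
            valid = sorted(set(gmap) | set(GENE_ALIASES))
            raise InputError(f"unknown knockout gene {g!r}; valid names: {valid}")
        enzymes.add(gmap[g2])
    return enzymes


def run_knockout_panel(
    model: ModelSpec,
    panel: KnockoutPanelSpec | None = None,
    fit: MixtureFit | None = None,
) -> pd.DataFrame:
    """Solve each knockout strain and report phenotype, fractions and (when a
    mixture fit is supplied) the predicted aero-type."""
    panel = panel or KnockoutPanelSpec()
    rows = []
    for ko_genes in panel.knockout_sets:
        enzymes = resolve_knockout_genes(model, ko_genes)
        genotype = StrainGenotype(
            strain_id="d" + "_d".join(sorted(ko_genes)) if ko_genes else "WT",
            knockouts=set(enzymes),
        )
        mutant = apply_genotype(model, genotype)
        for temp in panel.temperatures:
            sol = solve_growth(
                mutant,
                Condition(temperature=temp, electron_acceptor=panel.electron_acceptor),
            )
            row = _row_from_solution(genotype.strain_id, temp, sol, mutant)
            row["knockouts"] = "+".join(sorted(ko_genes)) or "none"
            rows.append(row)
    df = pd.DataFrame(rows, columns=SAMPLE_TABLE_COLUMNS + ["knockouts"])
    if fit is not None:
        df, _ = annotate_aerotypes(df, fit=fit)
    return df


def run_constrained_sampling(
    model: ModelSpec,
    freq: MutationFrequencyTable,
    p_values=FATPS_PEAK_VALUES,
    config: SamplerConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strain sampling with the ATP-synthase fraction pinned at each p.

    The fraction constraint is a strong one, so many genotype/temperature
    combinations become infeasible; those rows are kept in the raw table but
    excluded from the per-band statistics.  Returns (feasible table with a
    ``p`` column, per-band summary with the q-Y rank correlation).
    """
    config = config or SamplerConfig(n_per_temperature=24)
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise InputError(f"constraint value p={p} outside [0, 1]")
    frames = []
    for p in p_values:
        df = sample_strains(model, freq, config, fatps_constraint=p)
        df["p"] = p
        frames.append(df)
    full = pd.concat(frames, ignore_index=True)
    feasible = full[full["feasible"].astype(bool)].reset_index(drop=True)
    summaries = []
    for p, grp in feasible.groupby("p"):
        rho = np.nan
        if len(grp) >= 10:
            rho = float(stats.spearmanr(grp["q_glc"], grp["Y"]).statistic)
        summaries.append(
            {
                "p": p,
                "n_feasible": len(grp),
                "n_total": int((full["p"] == p).sum()),
                "mean_Y": float(grp["Y"].mean()) if len(grp) else np.nan,
                "mean_q_glc": float(grp["q_glc"].mean()) if len(grp) else np.nan,
                "spearman_q_Y": rho,
            }
        )
    return feasible, pd.DataFrame(summaries)


def run_fixed_growth_sampling(
    model: ModelSpec,
    freq: MutationFrequencyTable,
    rates=FIXED_RELATIVE_RATES,
    config: SamplerConfig | None = None,
    temperature: float = 30.0,
    n_per_rate: int = 61,
) -> tuple[pd.DataFrame, MixtureFit]:
    """Sampling along growth-rate isoclines at one temperature.

    Rates are relative to the wild-type optimum at 37 C.  Returns the pooled
    table (with ``mu_target`` and ``relative_rate`` columns) and the mixture
    fit of the pooled f_ATPS values.
    """
    wt = solve_growth(model, Condition(temperature=37.0))
    if not wt.feasible:
        raise InputError("wild-type reference solve infeasible at 37 C")
    frames = []
    for rate in rates:
        cfg = config or SamplerConfig()
        cfg = SamplerConfig(
            n_per_temperature=n_per_rate,
            temperatures=(temperature,),
            selection_mode=cfg.selection_mode,
            effect_mode=cfg.effect_mode,
            keff_fold_range=cfg.keff_fold_range,
            master_seed=cfg.master_seed + int(round(rate * 1000)),
        )
        target = rate * wt.mu
        df = sample_strains(model, freq, cfg, fixed_growth_rate=target)
        df["relative_rate"] = rate
        df["mu_target"] = target
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    feas = pooled[pooled["feasible"].astype(bool)]
    fit = fit_fatps_mixture(feas["f_ATPS"].to_numpy())
    return pooled, fit


def run_nitrate_experiment(
    model: ModelSpec,
    freq: MutationFrequencyTable,
    config: SamplerConfig | None = None,
) -> tuple[pd.DataFrame, MixtureFit]:
    """Anaerobic sampling with nitrate as terminal electron acceptor.

    All quinol oxidases (including the monooxygenase) are disabled, oxygen
    supply is closed and nitrate opened; the pooled f_ATPS distribution is
    fitted with the zero peak plus three Gaussians and rows are labeled with
    nitro-types i-iii by ascending component mean.
    """
    config = config or SamplerConfig(n_per_temperature=25)
    table = sample_strains(
        model,
        freq,
        config,
        electron_acceptor="nitrate",
        knockouts=set(OXIDASE_FREE_KNOCKOUTS),
        phi_columns=("NirB", "Nar", "Fdn", "Nuo", "Ndh"),
    )
    feas = table[table["feasible"].astype(bool)]
    fit = fit_fatps_mixture(feas["f_ATPS"].to_numpy(), n_components=3)
    table, _ = annotate_aerotypes(table, fit=fit, labels=NITROTYPE_LABELS)
    return table, fit
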