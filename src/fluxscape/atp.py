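"""ATP-production accounting, phenotype vector, yield and P/O ratio.

The central statistic is the vector of fractions of total cellular ATP
production carried by the eight ATP-producing reactions (ATP synthase,
phosphoglycerate kinase, pyruvate kinase, acetate kinase, the two
polyphosphate kinases, succinyl-CoA synthetase and PRPP synthetase); its
first element, f_ATPS, indexes the aero-type of a solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ATP_REGISTRY, Condition, FluxSolution, InputError, ModelSpec

__all__ = [
    "ATPFractions",
    "PhenotypeVector",
    "compute_fractions",
    "build_fatps_constraint",
    "compute_yield",
    "phenotype_distance",
    "compute_po_ratio",
    "phenotype_from_solution",
]


@dataclass(frozen=True)
class ATPFractions:
    """Fractions of total ATP production, in registry order; they sum to 1
    unless the solution produces no ATP at all (``degenerate``)."""

    f_ATPS: float
    f_PGK: float
    f_PYK: float
    f_ACKr: float
    f_PPKr: float
    f_PPK2r: float
    f_SUCOAS: float
    f_PRPPS: float
    degenerate: bool = False

    _ORDER = ("ATPS4rpp", "PGK", "PYK", "ACKr", "PPKr", "PPK2r", "SUCOAS", "PRPPS")

    def as_dict(self) -> dict[str, float]:
        return {
            "f_ATPS": self.f_ATPS,
            "f_PGK": self.f_PGK,
            "f_PYK": self.f_PYK,
            "f_ACKr": self.f_ACKr,
            "f_PPKr": self.f_PPKr,
            "f_PPK2r": self.f_PPK2r,
            "f_SUCOAS": self.f_SUCOAS,
            "f_PRPPS": self.f_PRPPS,
        }

    def as_array(self) -> np.ndarray:
        return np.array(list(self.as_dict().values()))


@dataclass(frozen=True)
class PhenotypeVector:
    """Exchange phenotype of one solution.

    ``Y = mu / (q_glc * m)`` (gDW per g substrate); oxygen uptake is carried
    along as an auxiliary but excluded from the phenotypic distance.
    """

    q_glc: float
    q_ac: float
    mu: float
    Y: float
    q_o2: float = 0.0


@dataclass(frozen=True)
class FatpsConstraint:
    """Eq-style linear coupling pinning the ATP-synthase production fraction.

    Encodes (1-p) * w_ATPS * V_ATPS4rpp = p * sum_r w_r * V_r over the other
    registry reactions, with w the ATP stoichiometric weights (all 1 in the
    default network).  Attach via ``Condition(fatps_constraint=p)``.
    """

    p: float


def build_fatps_constraint(p: float) -> FatpsConstraint:
    if not (0.0 <= p <= 1.0):
        raise InputError(f"f_ATPS constraint p={p} outside [0, 1]")
    return FatpsConstraint(p)


def compute_fractions(solution: FluxSolution, model: ModelSpec) -> ATPFractions:
    """ATP-production fractions of a feasible solution.

    Reversible registry reactions count ATP only in the producing (forward)
    direction; a solution with zero total production returns the zero vector
    with the degenerate flag set.
    """
    production = []
    for rid in model.atp_registry:
        if rid not in solution.fluxes:
            raise InputError(f"registry reaction {rid} missing from solution")
        w = model.reaction(rid).atp_produced
        production.append(w * max(0.0, solution.fluxes[rid]))
    total = float(sum(production))
    if total <= 0.0:
        return ATPFractions(0, 0, 0, 0, 0, 0, 0, 0, degenerate=True)
    f = [x / total for x in production]
    return ATPFractions(*f)


def compute_yield(mu: float, q_glc: float, m: float) -> float:
    """Biomass yield Y = mu / (q_glc * m) in gDW per g substrate."""
    if q_glc <= 0:
        raise InputError("yield undefined for non-positive substrate uptake")
    return mu / (q_glc * m)


def phenotype_from_solution(solution: FluxSolution, model: ModelSpec) -> PhenotypeVector:
    """Exchange phenotype (q_glc, q_ac, mu, Y, q_o2) of a feasible solution."""
    q_glc = solution.fluxes.get("EX_glc", 0.0)
    q_ac = solution.fluxes.get("EX_ac", 0.0)
    q_o2 = solution.fluxes.get("EX_o2", 0.0)
    y = compute_yield(solution.mu, q_glc, model.substrate_mw) if q_glc > 1e-9 else 0.0
    return PhenotypeVector(q_glc=q_glc, q_ac=q_ac, mu=solution.mu, Y=y, q_o2=q_o2)


def phenotype_distance(x: PhenotypeVector, ref: PhenotypeVector) -> float:
    """Euclidean distance of the 4-vector (q_glc, q_ac, mu, Y) after
    component-wise division by the reference (wild-type) phenotype, so the
    mixed units cancel.  Oxygen uptake is ignored."""
    rv = (ref.q_glc, ref.q_ac, ref.mu, ref.Y)
    if any(v <= 0 for v in rv):
        raise InputError("reference phenotype must have all-positive entries")
    xv = (x.q_glc, x.q_ac, x.mu, x.Y)
    return math.sqrt(sum((a / b - 1.0) ** 2 for a, b in zip(xv, rv)))


def compute_po_ratio(solution: FluxSolution) -> float:
    """P/O ratio: ATP made by the synthase per atom of oxygen reduced."""
    q_o2 = solution.fluxes.get("EX_o2", 0.0)
    if q_o2 <= 0:
        raise InputError("P/O ratio undefined without oxygen uptake")
    return solution.fluxes.get("ATPS4rpp", 0.0) / (2.0 * q_o2)
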