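"""Domain types and parameter handling for the protocell model.

The model tracks six molecular species in a single fatty-acid-bounded
protocell:

========  ====================================================
``fa``    fatty acids (the membrane; defines cell size)
``aa1``   amino acids that chelate FeS clusters and catalyse
          CO2 fixation
``aa2``   amino acids consumed by nucleotide synthesis
``s``     sugars (nucleotide precursor)
``e``     energy-currency molecules (acetyl-phosphate-like;
          consumed by nucleotide synthesis)
``n``     nucleotides ("naked" cofactors with catalytic roles)
========  ====================================================

Carbon enters as an activated two-carbon unit (C2) produced by
membrane-bound FeS-cluster catalysis of CO2 fixation and is divided
among the five biosynthetic branches according to thermodynamically
assigned baseline proportions (the lambda values).  All rates are per
day; counts are non-negative reals in the deterministic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "BRANCHES",
    "SpeciesCounts",
    "ModelParams",
    "ConfigurationError",
    "DegenerateCellError",
    "validate_params",
    "calibrated_k_fix",
    "table1",
    "default_initial_state",
]

#: canonical species ordering used by every array interface
SPECIES = ("fa", "aa1", "aa2", "s", "e", "n")

#: the five biosynthetic branches fed by fixed carbon
BRANCHES = ("fa", "aa1", "aa2", "s", "e")


class ConfigurationError(ValueError):
    """Raised when parameters or run configuration are invalid."""


class DegenerateCellError(ValueError):
    """Raised when an operation requires a cell with fa > 0."""


@dataclass(frozen=True)
class SpeciesCounts:
    """Molecule counts of the six tracked species in one protocell."""

    fa: float
    aa1: float
    aa2: float
    s: float
    e: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fa, self.aa1, self.aa2, self.s, self.e, self.n], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesCounts":
        return cls(*(float(v) for v in y))

    def validate(self) -> "SpeciesCounts":
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"non-finite species counts: {self}")
        if np.any(arr < 0):
            raise ConfigurationError(f"negative species counts: {self}")
        return self


# Baseline branch proportions of fixed carbon, from thermodynamic
# estimates under alkaline hydrothermal conditions: fatty acids and
# amino acids are strongly favoured over sugars; the energy currency is
# set at a minimal level reflecting scarce inorganic phosphate.  The
# amino-acid share is split evenly between the FeS-chelating set (aa1)
# and the nucleotide-precursor set (aa2).
LAMBDA_FA = 0.376
LAMBDA_AA1 = 0.282
LAMBDA_AA2 = 0.282
LAMBDA_S = 0.05
LAMBDA_E = 0.01

#: baseline steady AA1:FA count ratio implied by the lambda values
RHO_STAR = LAMBDA_AA1 / LAMBDA_FA


def calibrated_k_fix(k_m: float,
                     lambda_aa1: float = LAMBDA_AA1,
                     lambda_fa: float = LAMBDA_FA,
                     target_rate: float = 1.0) -> float:
    """Base fixation rate constant giving the null model ``target_rate``
    divisions per day.

    In the null model (no nucleotide catalysis) the AA1:FA ratio relaxes
    to ``rho* = lambda_aa1/lambda_fa`` and the cell then grows as a pure
    exponential with rate ``mu = lambda_fa * k_fix * rho*/(k_m + rho*)``,
    dividing every ``ln 2 / mu`` days.  Solving ``mu = target_rate*ln 2``
    for ``k_fix`` pins the null division rate exactly, making every
    reported rate interpretable as a multiple of the null model's.
    """
    rho = lambda_aa1 / lambda_fa
    return target_rate * math.log(2.0) * (k_m + rho) / (lambda_fa * rho)


def _zero_branch_map() -> dict[str, float]:
    return {b: 0.0 for b in BRANCHES}


def _unit_stoichiometry() -> dict[str, int]:
    return {b: 1 for b in BRANCHES}


@dataclass(frozen=True)
class ModelParams:
    """All rate constants, branch fractions, stoichiometries, cost and
    division settings.  Time unit: days.

    Concentration units are set by ``vol_per_fa`` (volume contributed
    per fatty-acid molecule).  The default volume scale makes the cell
    concentrated enough that the energy currency, not reaction kinetics,
    limits nucleotide synthesis; the steady nucleotide concentration is
    then of order 0.1-1 and the catalytic constants act at full
    strength.
    """

    # baseline branch fractions of C2 flux (unitless, sum to 1)
    lambda_fa: float = LAMBDA_FA
    lambda_aa1: float = LAMBDA_AA1
    lambda_aa2: float = LAMBDA_AA2
    lambda_s: float = LAMBDA_S
    lambda_e: float = LAMBDA_E

    # CO2 fixation
    k_fix: float = calibrated_k_fix(3.0)  # calibrated: null model = 1 division/day
    co2: float = 1.0                      # ambient CO2 availability multiplier
    k_m: float = 3.0                      # membrane-site half-saturation (AA1:FA ratio)

    # nucleotide catalysis
    k_cn: float = 1.0e3    # catalysis of CO2 fixation by nucleotides (KCN)
    k_in: Mapping[str, float] = field(default_factory=_zero_branch_map)
    k_sat: float = 0.03    # half-saturation of pathway catalysis in [N]

    # nucleotide synthesis
    k_ne: float = 2.0      # trimolecular base rate from AA2 + S + E (KNE)
    k_nn: float = 2.0      # autocatalysis strength (KNN)

    # cost coupling between pathway catalysis and fixation catalysis
    alpha: float = 0.0

    # carbon stoichiometry: C2 units consumed per molecule produced
    n_c2: Mapping[str, int] = field(default_factory=_unit_stoichiometry)

    # geometry / division
    vol_per_fa: float = 0.05
    fa_div: float = 1000.0

    def lambdas(self) -> np.ndarray:
        return np.array([self.lambda_fa, self.lambda_aa1, self.lambda_aa2,
                         self.lambda_s, self.lambda_e])

    def k_in_array(self) -> np.ndarray:
        return np.array([self.k_in[b] for b in BRANCHES])

    def n_c2_array(self) -> np.ndarray:
        return np.array([self.n_c2[b] for b in BRANCHES], dtype=float)

    def with_(self, **overrides) -> "ModelParams":
        """Return a validated copy with the given fields replaced.

        ``k_in`` and ``n_c2`` accept partial maps which are merged into
        the current values.
        """
        if "k_in" in overrides:
            merged = dict(self.k_in)
            merged.update(overrides["k_in"])
            overrides["k_in"] = merged
        if "n_c2" in overrides:
            merged = dict(self.n_c2)
            merged.update(overrides["n_c2"])
            overrides["n_c2"] = merged
        return validate_params(replace(self, **overrides))


def validate_params(raw: ModelParams) -> ModelParams:
    """Check every parameter invariant; reject (never clip) out-of-range
    values.

    The only sanctioned clip in the whole model is the one inside
    :func:`protoflux.rates.effective_fixation_catalysis`, which floors
    the catalysis-cost factor at zero.
    """
    lam = raw.lambdas()
    if np.any(lam < 0):
        names = ("lambda_fa", "lambda_aa1", "lambda_aa2", "lambda_s", "lambda_e")
        bad = [f"{n}={v}" for n, v in zip(names, lam) if v < 0]
        raise ConfigurationError(
            f"branch fractions must be non-negative: {', '.join(bad)}")
    total = float(lam.sum())
    if abs(total - 1.0) > 1e-12:
        raise ConfigurationError(
            f"branch fractions must sum to 1 (got {total!r}): "
            f"lambda_fa={raw.lambda_fa}, lambda_aa1={raw.lambda_aa1}, "
            f"lambda_aa2={raw.lambda_aa2}, lambda_s={raw.lambda_s}, "
            f"lambda_e={raw.lambda_e}"
        )
    for name in ("k_fix", "co2", "k_m", "k_cn", "k_sat", "k_ne", "k_nn",
                 "vol_per_fa", "fa_div"):
        v = getattr(raw, name)
        if not (np.isfinite(v) and v >= 0):
            raise ConfigurationError(f"{name} must be a finite non-negative number, got {v!r}")
    if raw.vol_per_fa <= 0:
        raise ConfigurationError(f"vol_per_fa must be positive, got {raw.vol_per_fa!r}")
    if raw.fa_div <= 0:
        raise ConfigurationError(f"fa_div must be positive, got {raw.fa_div!r}")
    if not 0.0 <= raw.alpha <= 1.0:
        raise ConfigurationError(f"alpha must lie in [0, 1], got {raw.alpha!r}")
    if set(raw.k_in) != set(BRANCHES):
        raise ConfigurationError(
            f"k_in must map exactly the branches {BRANCHES}, got keys {sorted(raw.k_in)}")
    for b, v in raw.k_in.items():
        if not (0.0 <= v < 1.0):
            raise ConfigurationError(f"k_in[{b!r}] must lie in [0, 1), got {v!r}")
    if set(raw.n_c2) != set(BRANCHES):
        raise ConfigurationError(
            f"n_c2 must map exactly the branches {BRANCHES}, got keys {sorted(raw.n_c2)}")
    for b, v in raw.n_c2.items():
        if not (isinstance(v, (int, np.integer)) and v >= 1):
            raise ConfigurationError(f"n_c2[{b!r}] must be an integer >= 1, got {v!r}")
    return raw


def table1(**overrides) -> ModelParams:
    """The default parameter preset (Table-1 values plus the calibration
    constants), optionally with field overrides."""
    return ModelParams().with_(**overrides) if overrides else validate_params(ModelParams())


def default_initial_state(p: ModelParams | None = None) -> SpeciesCounts:
    """Initial protocell: 100 fatty acids, other species in proportion
    to their baseline branch fractions, no nucleotides.

    ``fa_div`` defaults to 10x the initial fatty-acid count, so the cell
    completes a few rounds of near-doubling before its first division.
    """
    fa0 = 100.0
    lam_fa = p.lambda_fa if p is not None else LAMBDA_FA
    lams = (p.lambdas() if p is not None
            else np.array([LAMBDA_FA, LAMBDA_AA1, LAMBDA_AA2, LAMBDA_S, LAMBDA_E]))
    rel = lams / lam_fa * fa0
    return SpeciesCounts(fa=fa0, aa1=rel[1], aa2=rel[2], s=rel[3], e=rel[4], n=0.0)
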