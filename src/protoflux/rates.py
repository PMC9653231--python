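"""Reaction-rate laws composing the ODE right-hand side.

The protometabolic network couples four processes:

1. **CO2 fixation.**  Membrane-bound FeS clusters, chelated by AA1,
   reduce CO2 to an activated two-carbon unit (C2).  The rate is
   mass-action in the AA1 pool, corrected for the finite number of
   membrane sites the clusters can occupy (the membrane area is
   proportional to the fatty-acid count), and linearly boosted by
   nucleotide catalysis::

       flux = k_fix * co2 * fa * (rho / (k_m + rho)) * (1 + KCN_eff * [N])

   with ``rho = aa1/fa`` the cluster-to-membrane ratio.  When
   ``rho << k_m`` this reduces to the familiar law proportional to the
   AA1 count; as AA1 outgrows the membrane the sites saturate, so piling
   catalyst into a cell that cannot enlarge its membrane stops paying.

2. **Branch allocation.**  The finite C2 flux is divided among the five
   biosynthetic branches.  Each branch carries a baseline weight
   ``lambda_i``; nucleotide catalysis of branch *i* lowers that branch's
   kinetic barrier, scaling its weight by ``1/(1 - k_in[i] * sigma)``
   where ``sigma = [N]/(k_sat + [N])`` saturates in the nucleotide
   concentration.  ``k_in[i]`` in [0, 1) is the fraction of the barrier
   removed at full saturation, so weak catalysis perturbs the allocation
   mildly while strengths approaching 1 can divert nearly all flux into
   one branch.  Weights are renormalized: more of one species always
   means less of the others.

3. **Nucleotide synthesis.**  Trimolecular condensation of AA2, sugar
   and energy currency (all consumed 1:1:1 per nucleotide), with linear
   autocatalytic boost ``(1 + KNN * [N])``.

4. **Catalysis cost.**  When a single cofactor type performs both
   pathway catalysis and fixation catalysis (``alpha > 0``), engagement
   with pathway substrates competes with fixation: the effective KCN is
   scaled by ``1 - alpha * max_i k_in[i]``, floored at zero.

Counts are converted to concentrations with a cell volume proportional
to the fatty-acid count, ``V = vol_per_fa * fa``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import BRANCHES, DegenerateCellError, ModelParams, SpeciesCounts

__all__ = [
    "RateBreakdown",
    "NumericalStateError",
    "concentrations",
    "effective_fixation_catalysis",
    "fixation_flux",
    "branch_fractions",
    "nucleotide_rate",
    "rate_breakdown",
    "rhs",
]

# indices into the canonical species array
I_FA, I_AA1, I_AA2, I_S, I_E, I_N = range(6)


class NumericalStateError(RuntimeError):
    """Raised when the integrator hands the rate laws a non-finite or
    badly negative state."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class RateBreakdown:
    """Itemized account of the instantaneous fluxes at one state.

    Attributes
    ----------
    fixation_flux : float
        Total C2 production, in C2 units per day for the whole cell.
    branch_fractions : ndarray, shape (5,)
        Normalized share of the C2 flux allocated to each branch, in the
        order (fa, aa1, aa2, s, e).  Always sums to 1.
    production_rates : ndarray, shape (5,)
        Molecules produced per day per branch; branch *i* yields
        ``fixation_flux * fraction_i / n_c2[i]`` molecules because each
        molecule of species *i* costs ``n_c2[i]`` C2 units.
    nucleotide_rate : float
        Nucleotides synthesized per day.
    consumption_rates : ndarray, shape (3,)
        AA2, S and E consumed per day by nucleotide synthesis (equal to
        ``nucleotide_rate`` each, by the 1:1:1 stoichiometry).
    """

    fixation_flux: float
    branch_fractions: np.ndarray
    production_rates: np.ndarray
    nucleotide_rate: float
    consumption_rates: np.ndarray


def _as_array(state: SpeciesCounts | np.ndarray) -> np.ndarray:
    if isinstance(state, SpeciesCounts):
        return state.as_array()
    return np.asarray(state, dtype=float)


def concentrations(state: SpeciesCounts | np.ndarray, p: ModelParams) -> np.ndarray:
    """Per-species concentrations, ``count / (vol_per_fa * fa)``.

    The fatty-acid count is the proxy for cell size, so doubling every
    count (cell growth without composition change) leaves all
    concentrations unchanged.
    """
    y = _as_array(state)
    fa = y[I_FA]
    if fa <= 0:
        raise DegenerateCellError(f"cell volume undefined for fa={fa}")
    return y / (p.vol_per_fa * fa)


def effective_fixation_catalysis(p: ModelParams) -> float:
    """Effective KCN after the catalysis-cost trade-off.

    Returns ``k_cn * max(0, 1 - alpha * max_i k_in[i])``.  With
    ``alpha = 0`` (distinct cofactor types for each catalytic function)
    the fixation catalysis is untouched; with ``alpha = 1`` a cofactor
    fully committed to one pathway (strength near 1) contributes almost
    nothing to fixation.  The floor at zero is the one sanctioned clip
    in the model.
    """
    strengths = p.k_in_array()
    cost = 1.0 - p.alpha * float(strengths.max(initial=0.0))
    return p.k_cn * max(0.0, cost)


def _fixation_flux_from(y: np.ndarray, p: ModelParams, n_conc: float) -> float:
    fa, aa1 = y[I_FA], y[I_AA1]
    rho = max(aa1, 0.0) / fa
    occupancy = rho / (p.k_m + rho) if rho > 0 else 0.0
    boost = 1.0 + effective_fixation_catalysis(p) * n_conc
    return p.k_fix * p.co2 * fa * occupancy * boost


def fixation_flux(state: SpeciesCounts | np.ndarray, p: ModelParams) -> float:
    """Total C2 production rate for the whole cell (C2 units per day).

    Zero when the cell has no FeS-chelating amino acids; strictly
    increasing in the nucleotide concentration whenever the effective
    KCN is positive.
    """
    y = _as_array(state)
    if not np.all(np.isfinite(y)):
        raise NumericalStateError(f"non-finite state in fixation_flux: {y}", state=y)
    if y[I_FA] <= 0:
        raise DegenerateCellError(f"fixation undefined for fa={y[I_FA]}")
    n_conc = max(y[I_N], 0.0) / (p.vol_per_fa * y[I_FA])
    return _fixation_flux_from(y, p, n_conc)


def _branch_fractions_from(p: ModelParams, n_conc: float) -> np.ndarray:
    sigma = n_conc / (p.k_sat + n_conc) if n_conc > 0 else 0.0
    weights = p.lambdas() / (1.0 - p.k_in_array() * sigma)
    return weights / weights.sum()


def branch_fractions(state: SpeciesCounts | np.ndarray, p: ModelParams) -> np.ndarray:
    """Normalized allocation fractions of the C2 flux over
    (fa, aa1, aa2, s, e).

    With no pathway catalysis (all ``k_in`` zero) or no nucleotides the
    fractions equal the baseline lambda values exactly.
    """
    y = _as_array(state)
    n_conc = max(y[I_N], 0.0) / (p.vol_per_fa * y[I_FA]) if y[I_FA] > 0 else 0.0
    return _branch_fractions_from(p, n_conc)


def nucleotide_rate(state: SpeciesCounts | np.ndarray, p: ModelParams) -> float:
    """Nucleotide synthesis rate (molecules per day for the whole cell).

    Trimolecular in AA2, sugar and energy currency, with autocatalytic
    boost; each nucleotide consumes exactly one molecule of each
    substrate, so this is also the consumption rate of AA2, S and E.
    """
    y = _as_array(state)
    if y[I_FA] <= 0:
        raise DegenerateCellError(f"nucleotide rate undefined for fa={y[I_FA]}")
    vol = p.vol_per_fa * y[I_FA]
    conc = np.maximum(y, 0.0) / vol
    return (p.k_ne * conc[I_AA2] * conc[I_S] * conc[I_E]
            * (1.0 + p.k_nn * conc[I_N]) * vol)


def rate_breakdown(state: SpeciesCounts | np.ndarray, p: ModelParams) -> RateBreakdown:
    """Compute every flux component at one state (see class docstring)."""
    y = _as_array(state)
    flux = fixation_flux(y, p)
    fractions = branch_fractions(y, p)
    production = flux * fractions / p.n_c2_array()
    nuc = nucleotide_rate(y, p)
    return RateBreakdown(
        fixation_flux=flux,
        branch_fractions=fractions,
        production_rates=production,
        nucleotide_rate=nuc,
        consumption_rates=np.array([nuc, nuc, nuc]),
    )


def rhs(state: SpeciesCounts | np.ndarray, p: ModelParams) -> np.ndarray:
    """Time derivative of each species count.

    Branch production feeds all five synthesized species; nucleotide
    synthesis consumes one AA2, one sugar and one energy-currency
    molecule per nucleotide made.  Carbon is conserved exactly:
    ``sum_i production_i * n_c2[i] == fixation_flux`` at every state.
    """
    y = _as_array(state)
    if not np.all(np.isfinite(y)):
        raise NumericalStateError(f"non-finite state passed to rhs: {y}", state=y)
    if np.any(y < -1e-9 * max(1.0, y[I_FA])):
        raise NumericalStateError(f"negative species count beyond tolerance: {y}", state=y)
    b = rate_breakdown(y, p)
    dy = np.zeros(6)
    dy[:I_N] = b.production_rates
    dy[I_AA2] -= b.nucleotide_rate
    dy[I_S] -= b.nucleotide_rate
    dy[I_E] -= b.nucleotide_rate
    dy[I_N] = b.nucleotide_rate
    if not np.all(np.isfinite(dy)):
        raise NumericalStateError(f"non-finite derivative at state {y}", state=y)
    return dy
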