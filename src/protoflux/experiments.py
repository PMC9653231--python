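"""Parameter sweeps over the protocell model.

Each experiment is a pure function of (parameters, grids, base seed): it
runs lineages to steady state on a grid and returns a
:class:`SweepTable` (tidy DataFrame plus a provenance manifest) or a
:class:`HeatMap`.  Failed or non-dividing grid points are recorded with
their ``collapsed`` flag, never silently dropped.

The two reference strengths of fixation catalysis used by the pathway
sweeps are the ``slow`` (KCN = 10^0.9) and ``fast`` (KCN = 10^4)
presets; the division rate at pathway-catalysis zero under the same
preset is the baseline every pathway effect is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ConfigurationError, ModelParams, SpeciesCounts
from .rates import I_N
from .simulate import Lineage, run_lineage, steady_state_metrics

__all__ = [
    "SLOW_KCN",
    "FAST_KCN",
    "SweepTable",
    "HeatMap",
    "sweep_kcn",
    "sweep_pathway",
    "heatmap_autocatalysis",
    "initial_condition_scan",
    "stochastic_segregation_experiment",
    "sugar_cost_variant",
    "co2_scan",
]

#: "slow" and "fast" nucleotide catalysis of CO2 fixation
SLOW_KCN = 10.0 ** 0.9
FAST_KCN = 10.0 ** 4.0

#: pathway labels accepted by the sweeps; "AA" catalyses both amino-acid
#: branches simultaneously
PATHWAY_BRANCHES: Mapping[str, tuple[str, ...]] = {
    "AA": ("aa1", "aa2"),
    "FA": ("fa",),
    "S": ("s",),
    "E": ("e",),
}

#: default strengths: zero, weak, moderate, strong
KIN_GRID = (0.0, 0.33, 0.66, 0.99)

#: lineage settings shared by all experiments (desk scale)
LINEAGE_DEFAULTS = dict(max_divisions=80, t_budget=400.0, cycle_t_max=100.0)


@dataclass
class SweepTable:
    """Tidy sweep output: one row per grid point, plus provenance."""

    table: pd.DataFrame
    axes: dict[str, list]
    manifest: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class HeatMap:
    """Division rate and equilibrium nucleotide concentration on a
    log KNN x log KCN grid."""

    knn_grid: np.ndarray
    kcn_grid: np.ndarray
    division_rate: np.ndarray   # shape (len(knn), len(kcn))
    eq_n_conc: np.ndarray
    manifest: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, knn in enumerate(self.knn_grid):
            for j, kcn in enumerate(self.kcn_grid):
                rows.append(dict(k_nn=knn, k_cn=kcn,
                                 division_rate=self.division_rate[i, j],
                                 eq_n_conc=self.eq_n_conc[i, j]))
        return pd.DataFrame(rows)


def _evaluate(p: ModelParams, init: SpeciesCounts | None = None,
              **kwargs) -> dict:
    """Run one lineage to steady state and summarize it."""
    opts = {**LINEAGE_DEFAULTS, **kwargs}
    lineage = run_lineage(p, init=init, **opts)
    ss = steady_state_metrics(lineage, p)
    eq_n = (float(ss.eq_concentrations[I_N])
            if ss.eq_concentrations is not None else np.nan)
    return dict(division_rate=ss.division_rate, eq_n_conc=eq_n,
                collapsed=lineage.collapsed, converged=ss.converged,
                n_divisions=len(lineage.events))


def _manifest(p: ModelParams, **extra) -> dict:
    from dataclasses import asdict
    d = asdict(p)
    d["k_in"] = dict(d["k_in"])
    d["n_c2"] = dict(d["n_c2"])
    return dict(params=d, lineage_defaults=dict(LINEAGE_DEFAULTS), **extra)


def sweep_kcn(p: ModelParams, kcn_grid: Sequence[float],
              **kwargs) -> SweepTable:
    """Division rate as a function of the fixation-catalysis strength
    KCN (all else fixed).  With the default preset the rate is
    non-decreasing along the grid: nucleotide catalysis of CO2 fixation
    is a pure positive feedback."""
    grid = [float(k) for k in kcn_grid]
    if not grid:
        raise ConfigurationError("kcn_grid must be non-empty")
    rows = []
    for kcn in grid:
        rows.append(dict(k_cn=kcn, **_evaluate(p.with_(k_cn=kcn), **kwargs)))
    return SweepTable(pd.DataFrame(rows), axes={"k_cn": grid},
                      manifest=_manifest(p, experiment="sweep_kcn",
                                         kcn_grid=grid))


def _resolve_kcn(kcn) -> float:
    if isinstance(kcn, str):
        try:
            return {"slow": SLOW_KCN, "fast": FAST_KCN}[kcn]
        except KeyError:
            raise ConfigurationError(
                f"kcn preset must be 'slow' or 'fast', got {kcn!r}") from None
    return float(kcn)


def pathway_overrides(pathway: str, strength: float,
                      single_branch: str | None = None) -> dict[str, float]:
    """k_in override map for a named pathway sweep.

    ``single_branch`` restricts amino-acid catalysis to one of the two
    sets (the variant in which catalysis speeds the production of only
    one amino-acid type, leaving the other unchanged).
    """
    if pathway not in PATHWAY_BRANCHES:
        raise ConfigurationError(
            f"unknown pathway {pathway!r}; expected one of "
            f"{sorted(PATHWAY_BRANCHES)}")
    branches = PATHWAY_BRANCHES[pathway]
    if single_branch is not None:
        if single_branch not in branches:
            raise ConfigurationError(
                f"single_branch {single_branch!r} is not part of pathway "
                f"{pathway!r} ({branches})")
        branches = (single_branch,)
    return {b: strength for b in branches}


def sweep_pathway(p: ModelParams, pathway: str,
                  kin_grid: Sequence[float] = KIN_GRID,
                  kcn: float | str | None = None,
                  alpha: float | None = None,
                  single_branch: str | None = None,
                  **kwargs) -> SweepTable:
    """Division rate and equilibrium nucleotide concentration along a
    pathway-catalysis grid.

    The strength-zero row is the reference (fixation catalysis alone);
    the ``rate_vs_baseline`` column divides each rate by it.
    """
    grid = [float(c) for c in kin_grid]
    if not grid:
        raise ConfigurationError("kin_grid must be non-empty")
    base = p
    if kcn is not None:
        base = base.with_(k_cn=_resolve_kcn(kcn))
    if alpha is not None:
        base = base.with_(alpha=alpha)
    baseline = _evaluate(base.with_(k_in=pathway_overrides(pathway, 0.0,
                                                           single_branch)),
                         **kwargs)
    rows = []
    for c in grid:
        pc = base.with_(k_in=pathway_overrides(pathway, c, single_branch))
        res = _evaluate(pc, **kwargs)
        rows.append(dict(pathway=pathway, k_in=c, k_cn=base.k_cn,
                         alpha=base.alpha, **res,
                         baseline_rate=baseline["division_rate"],
                         baseline_eq_n=baseline["eq_n_conc"],
                         rate_vs_baseline=(res["division_rate"]
                                           / baseline["division_rate"]
                                           if baseline["division_rate"] > 0
                                           else np.inf)))
    return SweepTable(pd.DataFrame(rows), axes={"k_in": grid},
                      manifest=_manifest(base, experiment="sweep_pathway",
                                         pathway=pathway, kin_grid=grid,
                                         single_branch=single_branch))


def heatmap_autocatalysis(p: ModelParams,
                          logknn_grid: Sequence[float] | None = None,
                          logkcn_grid: Sequence[float] | None = None,
                          **kwargs) -> HeatMap:
    """Division rate and equilibrium [N] over a log-spaced
    autocatalysis (KNN) x fixation-catalysis (KCN) grid.

    Division is fastest where both feedbacks are strong; nucleotides
    accumulate where autocatalysis is strong but fixation catalysis is
    weak, because fast-dividing cells halve their nucleotide content at
    every division.
    """
    logknn = (np.asarray(logknn_grid, float) if logknn_grid is not None
              else np.linspace(-2.0, 4.0, 13))
    logkcn = (np.asarray(logkcn_grid, float) if logkcn_grid is not None
              else np.linspace(0.0, 4.0, 13))
    if logknn.size < 3 or logkcn.size < 3:
        raise ConfigurationError("heat-map grids need at least 3 points each")
    knn_grid, kcn_grid = 10.0 ** logknn, 10.0 ** logkcn
    rate = np.zeros((knn_grid.size, kcn_grid.size))
    eq_n = np.zeros_like(rate)
    for i, knn in enumerate(knn_grid):
        for j, kcn in enumerate(kcn_grid):
            res = _evaluate(p.with_(k_nn=float(knn), k_cn=float(kcn)), **kwargs)
            rate[i, j] = res["division_rate"]
            eq_n[i, j] = res["eq_n_conc"]
    return HeatMap(knn_grid, kcn_grid, rate, eq_n,
                   manifest=_manifest(p, experiment="heatmap_autocatalysis",
                                      logknn_grid=list(logknn),
                                      logkcn_grid=list(logkcn)))


def _convergence_time(lineage: Lineage, rel_tol: float = 1e-3,
                      k: int = 5) -> float:
    """Time of the first division after which the trailing k intervals
    agree to rel_tol (NaN if the lineage never settles)."""
    intervals = lineage.intervals()
    times = np.array([ev.time for ev in lineage.events])
    for j in range(k, intervals.size + 1):
        window = intervals[j - k:j]
        if (window.max() - window.min()) / window.mean() < rel_tol:
            return float(times[j - 1])
    return float("nan")


def initial_condition_scan(p: ModelParams,
                           scale_grid: Sequence[float] = (1.0, 0.25, 0.1),
                           composition_grid: Sequence[float] = (1.0, 0.25, 4.0),
                           **kwargs) -> SweepTable:
    """Steady state from perturbed initial conditions.

    ``scale`` multiplies every non-membrane count (diluting or
    concentrating the cell contents at fixed size); ``composition``
    multiplies only the amino-acid counts (skewing the initial ratio).
    The steady-state division rate and equilibrium concentrations are
    attractors, so all rows should agree; dilute starts take longer to
    converge (``t_converged`` column).
    """
    from .params import default_initial_state
    base = default_initial_state(p).as_array()
    rows = []
    for scale in scale_grid:
        for comp in composition_grid:
            y0 = base.copy()
            y0[1:] *= scale
            y0[1] *= comp
            y0[2] *= comp
            init = SpeciesCounts.from_array(y0)
            lineage = run_lineage(p, init=init, **{**LINEAGE_DEFAULTS, **kwargs})
            ss = steady_state_metrics(lineage, p)
            eq = ss.eq_concentrations
            rows.append(dict(
                scale=scale, composition=comp,
                division_rate=ss.division_rate,
                collapsed=lineage.collapsed, converged=ss.converged,
                t_converged=_convergence_time(lineage),
                **{f"eq_{name}": (float(eq[i]) if eq is not None else np.nan)
                   for i, name in enumerate(("fa", "aa1", "aa2", "s", "e", "n"))},
            ))
    return SweepTable(pd.DataFrame(rows),
                      axes={"scale": list(scale_grid),
                            "composition": list(composition_grid)},
                      manifest=_manifest(p, experiment="initial_condition_scan",
                                         scale_grid=list(scale_grid),
                                         composition_grid=list(composition_grid)))


def stochastic_segregation_experiment(p: ModelParams,
                                      noise_grid: Sequence[float] = (0.0, 0.25, 0.5, 1.0),
                                      n_seeds: int = 20,
                                      base_seed: int = 0,
                                      **kwargs) -> SweepTable:
    """Binomial segregation noise at division.

    At each noise level the division of every count is drawn
    binomial(count, 1/2) with the segregation variance scaled by
    noise^2; ``noise=0`` reproduces the deterministic model exactly.
    Rows report mean and standard error over seeds of the steady
    division rate and equilibrium nucleotide concentration.
    """
    if n_seeds < 2:
        raise ConfigurationError("n_seeds must be >= 2 to estimate a s.e.")
    rows = []
    for noise in noise_grid:
        if noise == 0.0:
            res = _evaluate(p, **kwargs)
            rows.append(dict(noise=0.0, n_seeds=1,
                             mean_rate=res["division_rate"], se_rate=0.0,
                             mean_eq_n=res["eq_n_conc"], se_eq_n=0.0,
                             n_collapsed=int(res["collapsed"])))
            continue
        rates, eq_ns, n_collapsed = [], [], 0
        for s in range(n_seeds):
            rng = np.random.default_rng([base_seed, int(noise * 1000), s])
            res = _evaluate(p, mode="stochastic", rng=rng, noise=noise, **kwargs)
            rates.append(res["division_rate"])
            eq_ns.append(res["eq_n_conc"])
            n_collapsed += int(res["collapsed"])
        rates, eq_ns = np.array(rates), np.array(eq_ns)
        rows.append(dict(noise=noise, n_seeds=n_seeds,
                         mean_rate=rates.mean(),
                         se_rate=rates.std(ddof=1) / np.sqrt(n_seeds),
                         mean_eq_n=eq_ns.mean(),
                         se_eq_n=eq_ns.std(ddof=1) / np.sqrt(n_seeds),
                         n_collapsed=n_collapsed))
    return SweepTable(pd.DataFrame(rows), axes={"noise": list(noise_grid)},
                      manifest=_manifest(p, experiment="stochastic_segregation",
                                         noise_grid=list(noise_grid),
                                         n_seeds=n_seeds, base_seed=base_seed))


def sugar_cost_variant(p: ModelParams,
                       n_c2_s_grid: Sequence[int] = (1, 2, 4, 8, 16, 32),
                       strong_kin: float = 0.99,
                       kcn: float | str | None = "slow",
                       **kwargs) -> SweepTable:
    """Effect of sugar-pathway catalysis as sugars become more expensive
    in carbon.

    At unit stoichiometry sugars are produced in excess of what
    nucleotide synthesis consumes, so catalysing them buys little and
    costs allocation; once each sugar costs several C2 units the supply
    becomes limiting and strong KSN turns beneficial.  The
    ``strong_ksn_beneficial`` flag marks strata where the strong-KSN
    rate exceeds the KSN=0 baseline of the same stratum.

    Runs under the slow fixation-catalysis preset by default: substrate
    supply limits nucleotide synthesis most cleanly in slowly dividing
    cells, which is the regime where the sugar-cost contrast lives.
    Pass ``kcn=None`` to keep the preset in ``p``.
    """
    if kcn is not None:
        p = p.with_(k_cn=_resolve_kcn(kcn))
    rows = []
    for nc in n_c2_s_grid:
        stratum = p.with_(n_c2={"s": int(nc)})
        base = _evaluate(stratum, **kwargs)
        strong = _evaluate(
            stratum.with_(k_in=pathway_overrides("S", strong_kin)), **kwargs)
        ratio = (strong["division_rate"] / base["division_rate"]
                 if base["division_rate"] > 0 else np.inf)
        rows.append(dict(n_c2_s=int(nc),
                         baseline_rate=base["division_rate"],
                         strong_ksn_rate=strong["division_rate"],
                         rate_vs_baseline=ratio,
                         baseline_eq_n=base["eq_n_conc"],
                         strong_ksn_eq_n=strong["eq_n_conc"],
                         strong_ksn_beneficial=bool(ratio > 1.0)))
    return SweepTable(pd.DataFrame(rows),
                      axes={"n_c2_s": [int(v) for v in n_c2_s_grid]},
                      manifest=_manifest(p, experiment="sugar_cost_variant",
                                         n_c2_s_grid=[int(v) for v in n_c2_s_grid],
                                         strong_kin=strong_kin))


def co2_scan(p: ModelParams, co2_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
             **kwargs) -> SweepTable:
    """Division rate versus ambient CO2 availability (fixation-flux
    multiplier); without carbon there is no growth at all."""
    rows = []
    for c in co2_grid:
        rows.append(dict(co2=float(c),
                         **_evaluate(p.with_(co2=float(c)), **kwargs)))
    return SweepTable(pd.DataFrame(rows), axes={"co2": list(co2_grid)},
                      manifest=_manifest(p, experiment="co2_scan",
                                         co2_grid=list(co2_grid)))
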