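"""Community flux balance with a two-stage cooperative-tradeoff objective.

An *n*-member community shares one medium compartment.  Member metabolites
are namespaced per organism and balanced individually; each medium-visible
metabolite gets one community exchange whose lower bound encodes the medium's
maximum uptake.  Member abundances are uniform (1/n) and weight both the
community growth objective and each member's contribution to the shared
medium rows.

Simulation proceeds in stages, all linear programs solved with HiGHS:

1. maximise community growth  ``g* = max sum_k a_k v_bio,k``;
2. constrain growth to at least ``tradeoff * g*`` and maximise community
   butyrate export ``b*`` — the reported butyrate flux;
3. at fixed ``b*``, re-maximise growth (unique reported growth value);
4. at fixed growth and butyrate, minimise total absolute flux, which
   resolves degenerate alternate optima so reported flux vectors are
   reproducible across solvers and platforms.

Stage 2 is the cooperative-tradeoff approximation of community simulators in
the MICOM family: the community must retain a fraction of its optimal growth
while metabolite export is probed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .netmodel import DEFAULT_FLUX_BOUND, DEFAULT_BUTYRATE_ID, Medium, MetabolicNetwork

__all__ = [
    "ConsortiumSpec",
    "CommunityModel",
    "SimulationResult",
    "build_community",
    "simulate",
    "single_member_growth",
    "simulate_training_labels",
    "DEFAULT_TRADEOFF",
    "MAX_CONSORTIUM_SIZE",
]

DEFAULT_TRADEOFF = 0.5
MAX_CONSORTIUM_SIZE = 13

#: Feasibility tolerance passed to the LP solver.
SOLVER_TOL = 1e-9
#: Tolerance for reported invariants (mass balance, growth bookkeeping).
CHECK_TOL = 1e-6
#: Slack used when fixing an earlier stage's optimum as a constraint.
FIX_SLACK = 1e-7


@dataclass(frozen=True)
class ConsortiumSpec:
    """Canonically ordered member set of a candidate consortium."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if len(set(members)) != len(members):
            raise ValueError(f"duplicate members in consortium: {members}")
        if list(members) != sorted(members):
            raise ValueError("members must be sorted lexicographically")
        if not 1 <= len(members) <= MAX_CONSORTIUM_SIZE:
            raise ValueError(
                f"consortium size must be 1..{MAX_CONSORTIUM_SIZE}, got {len(members)}"
            )
        object.__setattr__(self, "members", members)

    @classmethod
    def of(cls, members) -> "ConsortiumSpec":
        """Build a spec from members in any order."""
        return cls(members=tuple(sorted(members)))

    @property
    def size(self) -> int:
        return len(self.members)

    def key(self) -> str:
        return ";".join(self.members)


@dataclass
class CommunityModel:
    """Block-joined stoichiometry of a consortium sharing a medium."""

    members: tuple[str, ...]
    abundances: np.ndarray
    variables: list[tuple]            # ("member", org, rxn_id) | ("medium", met)
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    bounds: list[tuple[float, float]]
    growth_coeffs: np.ndarray         # objective row for community growth
    butyrate_var: int | None          # community butyrate exchange column
    biomass_vars: dict[str, int]      # organism -> biomass flux column
    member_exchange_vars: dict[tuple[str, str], int]  # (org, metabolite) -> column
    medium_vars: dict[str, int]

    @property
    def n_variables(self) -> int:
        return len(self.variables)


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of a two-stage community simulation.

    ``community_growth`` and ``member_growth`` are read off the final flux
    vector (so the abundance-weighted identity holds exactly), while
    ``growth_optimum`` records the unconstrained stage-1 maximum.
    """

    status: str
    community_growth: float = float("nan")
    growth_optimum: float = float("nan")
    butyrate_flux: float = float("nan")
    member_growth: Mapping[str, float] = field(default_factory=dict)
    fluxes: Mapping[tuple, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_community(
    pool: Sequence[MetabolicNetwork],
    spec: ConsortiumSpec,
    medium: Medium,
    butyrate_metabolite: str = DEFAULT_BUTYRATE_ID,
) -> CommunityModel:
    """Assemble the block stoichiometric model for ``spec`` members.

    Variable count is the sum of member reaction counts plus one community
    exchange per medium-visible metabolite (a metabolite some member can
    exchange).  Every member metabolite is balanced inside its own block;
    medium metabolites are balanced community-wide with abundance-weighted
    member exchange fluxes.
    """
    by_id = {n.organism_id: n for n in pool}
    missing = [m for m in spec.members if m not in by_id]
    if missing:
        raise KeyError(f"consortium members absent from pool: {missing}")
    members = spec.members
    n = len(members)
    abundances = np.full(n, 1.0 / n)

    variables: list[tuple] = []
    bounds: list[tuple[float, float]] = []
    rows: dict[tuple, int] = {}
    entries: list[tuple[int, int, float]] = []  # (row, col, coef)

    def row_of(key: tuple) -> int:
        if key not in rows:
            rows[key] = len(rows)
        return rows[key]

    medium_mets: list[str] = []
    seen_medium: set[str] = set()
    biomass_vars: dict[str, int] = {}
    member_exchange_vars: dict[tuple[str, str], int] = {}

    for org, abundance in zip(members, abundances):
        network = by_id[org]
        for rxn in network.reactions:
            col = len(variables)
            variables.append(("member", org, rxn.id))
            bounds.append((rxn.lower_bound, rxn.upper_bound))
            if rxn.id == network.biomass_reaction_id:
                biomass_vars[org] = col
            if rxn.is_exchange:
                met = rxn.exchanged_metabolite
                # positive flux drains the member pool into the medium
                entries.append((row_of(("member", org, met)), col, -1.0))
                entries.append((row_of(("medium", met)), col, abundance))
                member_exchange_vars[(org, met)] = col
                if met not in seen_medium:
                    seen_medium.add(met)
                    medium_mets.append(met)
            else:
                for met, coef in rxn.stoichiometry.items():
                    entries.append((row_of(("member", org, met)), col, coef))

    medium_vars: dict[str, int] = {}
    for met in sorted(medium_mets):
        col = len(variables)
        variables.append(("medium", met))
        cap = 0.0 if met == butyrate_metabolite else medium.cap(met)
        bounds.append((-cap, DEFAULT_FLUX_BOUND))
        entries.append((rows[("medium", met)], col, -1.0))
        medium_vars[met] = col

    n_rows, n_cols = len(rows), len(variables)
    r, c, v = zip(*entries)
    A_eq = sparse.csr_matrix((v, (r, c)), shape=(n_rows, n_cols))

    growth_coeffs = np.zeros(n_cols)
    for org, abundance in zip(members, abundances):
        growth_coeffs[biomass_vars[org]] = abundance

    butyrate_var = medium_vars.get(butyrate_metabolite)
    if butyrate_var is None:
        warnings.warn(
            f"no member of {spec.key()} exchanges {butyrate_metabolite}; "
            "simulated butyrate will be zero",
            stacklevel=2,
        )

    return CommunityModel(
        members=members,
        abundances=abundances,
        variables=variables,
        A_eq=A_eq,
        b_eq=np.zeros(n_rows),
        bounds=bounds,
        growth_coeffs=growth_coeffs,
        butyrate_var=butyrate_var,
        biomass_vars=biomass_vars,
        member_exchange_vars=member_exchange_vars,
        medium_vars=medium_vars,
    )


def _solve(
    c: np.ndarray,
    A_eq: sparse.csr_matrix,
    b_eq: np.ndarray,
    bounds,
    A_ub=None,
    b_ub=None,
):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL},
    )
    return res


def simulate(
    model: CommunityModel, tradeoff: float = DEFAULT_TRADEOFF
) -> SimulationResult:
    """Run the staged community optimisation (see module docstring)."""
    if not 0 < tradeoff <= 1:
        raise ValueError("tradeoff must be in (0, 1]")

    stage1 = _solve(-model.growth_coeffs, model.A_eq, model.b_eq, model.bounds)
    if stage1.status != 0:
        return SimulationResult(status="infeasible")
    g_star = max(-stage1.fun, 0.0)

    n = model.n_variables
    growth_row = sparse.csr_matrix(-model.growth_coeffs)
    ub_rows = [growth_row]
    ub_rhs = [-tradeoff * g_star]

    if model.butyrate_var is not None:
        c2 = np.zeros(n)
        c2[model.butyrate_var] = -1.0
        stage2 = _solve(
            c2, model.A_eq, model.b_eq, model.bounds,
            A_ub=sparse.vstack(ub_rows), b_ub=np.array(ub_rhs),
        )
        if stage2.status != 0:
            return SimulationResult(status="infeasible")
        butyrate = max(-stage2.fun, 0.0)
        but_row = sparse.csr_matrix(([-1.0], ([0], [model.butyrate_var])), shape=(1, n))
        ub_rows.append(but_row)
        ub_rhs.append(-(butyrate - FIX_SLACK))
    else:
        butyrate = 0.0

    # stage 3: unique reported growth given the butyrate optimum
    stage3 = _solve(
        -model.growth_coeffs, model.A_eq, model.b_eq, model.bounds,
        A_ub=sparse.vstack(ub_rows), b_ub=np.array(ub_rhs),
    )
    if stage3.status != 0:  # pragma: no cover - feasible point exists
        return SimulationResult(status="infeasible")
    g_final = max(-stage3.fun, 0.0)
    ub_rows[0] = growth_row  # growth >= g_final - slack
    ub_rhs[0] = -(g_final - FIX_SLACK)

    # stage 4: parsimonious flux vector; |v_i| <= t_i, minimise sum t
    eye = sparse.identity(n, format="csr")
    A_eq4 = sparse.hstack([model.A_eq, sparse.csr_matrix(model.A_eq.shape)], format="csr")
    pos = sparse.hstack([eye, -eye])
    neg = sparse.hstack([-eye, -eye])
    base_ub = sparse.vstack(ub_rows)
    A_ub4 = sparse.vstack(
        [sparse.hstack([base_ub, sparse.csr_matrix((base_ub.shape[0], n))]), pos, neg],
        format="csr",
    )
    b_ub4 = np.concatenate([np.array(ub_rhs), np.zeros(2 * n)])
    c4 = np.concatenate([np.zeros(n), np.ones(n)])
    bounds4 = list(model.bounds) + [(0.0, None)] * n
    stage4 = _solve(c4, A_eq4, np.zeros(model.A_eq.shape[0]), bounds4,
                    A_ub=A_ub4, b_ub=b_ub4)
    if stage4.status == 0:
        v = stage4.x[:n]
    else:  # pragma: no cover - fall back to the stage-3 vertex
        v = stage3.x

    residual = np.abs(model.A_eq @ v)
    if residual.size and residual.max() > CHECK_TOL:  # pragma: no cover
        raise ArithmeticError(
            f"mass-balance violation {residual.max():.2e} exceeds {CHECK_TOL}"
        )

    member_growth = {
        org: float(v[col]) for org, col in model.biomass_vars.items()
    }
    community_growth = float(model.growth_coeffs @ v)
    # report the stage-2 LP optimum; the flux vector satisfies it up to the
    # fixing slack
    butyrate_flux = max(float(butyrate), 0.0)
    fluxes = {key: float(x) for key, x in zip(model.variables, v)}
    return SimulationResult(
        status="optimal",
        community_growth=community_growth,
        growth_optimum=g_star,
        butyrate_flux=butyrate_flux,
        member_growth=member_growth,
        fluxes=fluxes,
    )


def single_member_growth(network: MetabolicNetwork, medium: Medium) -> float:
    """Stage-1 growth optimum of a one-member community (diagnostic FBA)."""
    spec = ConsortiumSpec.of([network.organism_id])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_community([network], spec, medium)
    stage1 = _solve(-model.growth_coeffs, model.A_eq, model.b_eq, model.bounds)
    if stage1.status != 0:
        return 0.0
    return max(-stage1.fun, 0.0)


def simulate_training_labels(
    pool: Sequence[MetabolicNetwork],
    manifest,
    medium: Medium,
    sizes: Sequence[int],
    tradeoff: float = DEFAULT_TRADEOFF,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate butyrate export for every enumerable consortium.

    Returns a table sorted by (size, members) with columns ``size``,
    ``members`` (semicolon-joined sorted ids), ``butyrate_flux`` and
    ``status``; infeasible rows carry NaN flux and are meant to be excluded
    from training downstream.
    """
    from .encoder import enumerate_consortia  # deferred: avoids cycle

    specs = enumerate_consortia(manifest, sizes)
    if not specs:
        raise ValueError(f"no consortia enumerable for sizes {sorted(sizes)}")
    by_id = {n.organism_id: n for n in pool}
    records = []
    iterator = specs
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(specs, desc="simulating")
        except ImportError:
            pass
    for spec in iterator:
        model = build_community([by_id[m] for m in spec.members], spec, medium)
        result = simulate(model, tradeoff=tradeoff)
        records.append(
            {
                "size": spec.size,
                "members": spec.key(),
                "butyrate_flux": result.butyrate_flux if result.optimal else np.nan,
                "status": result.status,
            }
        )
    table = pd.DataFrame.from_records(records)
    return table.sort_values(["size", "members"], ignore_index=True)
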