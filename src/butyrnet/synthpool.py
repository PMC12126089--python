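"""Synthetic organism pools with a planted butyrate pathway and cross-feeding.

The generator emulates, at toy scale, a gut-bacteria pool in which a minority
of members can ferment to butyrate while every member ferments carbon sources
to a biomass precursor plus acetate.  The planted route mirrors the acetate
cross-feed of real butyrogenic communities:

* catabolism ``CAT_c<i>``:  1 carbon  -> 1 precursor + 1 acetate
* butyrate synthesis ``BUTS``:  2 acetate + 1 precursor -> 1 butyrate

Because butyrate synthesis demands two acetate per precursor, a producer
growing alone is acetate-limited, so acetate secreted by a partner strictly
increases community butyrate export — the cross-feeding signal every
downstream stage (labelling, classification, encoding, regression) is asked
to recover.

All interior conversion reactions are balanced under the toy metabolite
masses in :data:`TOY_MASSES`; biomass and the precursor sink are boundary
pseudo-reactions (drains), as in any constraint-based model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .netmodel import (
    DEFAULT_FLUX_BOUND,
    Medium,
    MetabolicNetwork,
    Reaction,
    load_medium,
    load_network,
    write_medium,
    write_network,
)

__all__ = [
    "UniverseSpec",
    "PoolManifest",
    "TOY_MASSES",
    "make_universe",
    "make_medium",
    "sample_pool",
    "write_pool",
    "load_pool",
    "carbon_exchange_ids",
    "is_mass_consistent",
    "PoolGenerationError",
    "DEFAULT_UPTAKE",
]

#: Default maximum uptake rate opened in generated media (mmol/gDW/h).
DEFAULT_UPTAKE = 10.0

#: Toy metabolite masses used for the balance invariant of interior reactions.
TOY_MASSES = {
    "prec_c": 2.0,
    "ac_e": 2.0,
    "but_e": 6.0,  # 2 acetate + 1 precursor
    "min_e": 1.0,
}

BIOMASS_ID = "BIOMASS"
SINK_ID = "SINK_prec"
BUTYRATE_SYNTH_ID = "BUTS"
BUTYRATE_EXCHANGE_ID = "EX_but_e"
ACETATE_EXCHANGE_ID = "EX_ac_e"
MINERAL_EXCHANGE_ID = "EX_min_e"

#: Reactions exempt from the mass-balance invariant (boundary drains).
BOUNDARY_REACTIONS = frozenset({BIOMASS_ID, SINK_ID})


class PoolGenerationError(RuntimeError):
    """Raised when no feasible pool could be sampled within the retry cap."""


#: Inclusion probabilities used when sampling an organism's reaction subset.
#: Sparse carbon coverage makes community butyrate vary with the carbon
#: repertoires of the members, not just with producer presence.
P_CARBON = 0.45
P_SECRETE_INTERMEDIATE = 0.4
P_USE_INTERMEDIATE = 0.4
P_DECOY = 0.5


@dataclass(frozen=True)
class UniverseSpec:
    """Shape of the toy reaction universe.

    ``n_intermediates`` counts cross-feeding intermediates; the first is
    always acetate (hard-wired into catabolism and butyrate synthesis), so
    values above 1 add generic secreted intermediates ``im<j>_e``.
    """

    n_carbon_sources: int = 2
    n_intermediates: int = 2
    n_decoy_reactions: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carbon_sources < 1 or self.n_intermediates < 1:
            raise ValueError("counts must be >= 1")
        if self.n_decoy_reactions < 0:
            raise ValueError("n_decoy_reactions must be >= 0")


@dataclass(frozen=True)
class PoolManifest:
    """Roster of a generated pool: members, producers, medium, seed."""

    organisms: tuple[str, ...]
    producers: tuple[str, ...]
    medium_path: str
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "organisms", tuple(self.organisms))
        object.__setattr__(self, "producers", tuple(self.producers))
        if len(set(self.organisms)) != len(self.organisms):
            raise ValueError("duplicate organism ids")
        if not self.producers:
            raise ValueError("producers must be non-empty")
        if not set(self.producers) <= set(self.organisms):
            raise ValueError("producers must be a subset of organisms")

    def to_dict(self) -> dict:
        return {
            "organisms": list(self.organisms),
            "producers": list(self.producers),
            "medium_path": self.medium_path,
            "seed": self.seed,
        }


def make_universe(spec: UniverseSpec) -> list[Reaction]:
    """Deterministic toy reaction universe with the planted butyrate route.

    The minimal spec (one carbon source, acetate as the only intermediate, no
    decoys) yields exactly eight reactions: the carbon and mineral uptake
    exchanges, catabolism, butyrate synthesis, the acetate and butyrate
    exchanges, biomass, and the precursor sink.
    """
    masses = dict(TOY_MASSES)
    reactions: list[Reaction] = []

    for i in range(1, spec.n_carbon_sources + 1):
        c = f"c{i}_e"
        masses[c] = 4.0
        reactions.append(Reaction(f"EX_{c}", {c: -1}, is_exchange=True))
        # carbon (4) -> precursor (2) + acetate (2)
        reactions.append(
            Reaction(f"CAT_c{i}", {c: -1, "prec_c": 1, "ac_e": 1}, 0.0)
        )

    reactions.append(Reaction(MINERAL_EXCHANGE_ID, {"min_e": -1}, is_exchange=True))
    reactions.append(Reaction(ACETATE_EXCHANGE_ID, {"ac_e": -1}, is_exchange=True))
    reactions.append(Reaction(BUTYRATE_EXCHANGE_ID, {"but_e": -1}, is_exchange=True))
    # 2 acetate (2+2) + precursor (2) -> butyrate (6)
    reactions.append(
        Reaction(BUTYRATE_SYNTH_ID, {"ac_e": -2, "prec_c": -1, "but_e": 1}, 0.0)
    )
    # boundary drains: growth consumes precursor + mineral; sink vents excess
    reactions.append(Reaction(BIOMASS_ID, {"prec_c": -1, "min_e": -1}, 0.0))
    reactions.append(Reaction(SINK_ID, {"prec_c": -1}, 0.0))

    for j in range(2, spec.n_intermediates + 1):
        im = f"im{j}_e"
        masses[im] = 4.0
        src = f"c{((j - 2) % spec.n_carbon_sources) + 1}_e"
        reactions.append(Reaction(f"EX_{im}", {im: -1}, is_exchange=True))
        reactions.append(Reaction(f"SEC_im{j}", {src: -1, im: 1}, 0.0))
        reactions.append(
            Reaction(f"USE_im{j}", {im: -1, "prec_c": 1, "ac_e": 1}, 0.0)
        )

    # inert decoys: isolated metabolite pairs, forced to zero flux at steady
    # state; named to sort after the functional reactions
    for k in range(1, spec.n_decoy_reactions + 1):
        x, y = f"zdx{k:03d}_c", f"zdy{k:03d}_c"
        masses[x] = masses[y] = 1.0
        reactions.append(Reaction(f"ZDC{k:03d}", {x: -1, y: 1}, 0.0))

    return reactions


def is_mass_consistent(reaction: Reaction, masses: dict[str, float] | None = None) -> bool:
    """Check conservation of toy mass for an interior conversion reaction."""
    if reaction.is_exchange or reaction.id in BOUNDARY_REACTIONS:
        return True
    masses = masses or _universe_masses(reaction)
    total = sum(coef * masses[m] for m, coef in reaction.stoichiometry.items())
    return abs(total) < 1e-9


def _universe_masses(reaction: Reaction) -> dict[str, float]:
    masses = dict(TOY_MASSES)
    for m in reaction.metabolites():
        if m not in masses:
            masses[m] = 4.0 if m.startswith(("c", "im")) else 1.0
    return masses


def carbon_exchange_ids(universe: Sequence[Reaction]) -> list[str]:
    """Exchange reactions of carbon-source metabolites, sorted by id."""
    return sorted(
        r.id
        for r in universe
        if r.is_exchange and r.exchanged_metabolite.startswith("c")
    )


def make_medium(
    universe: Sequence[Reaction], richness: float = 1.0, seed: int = 0
) -> Medium:
    """Medium opening a ``richness`` fraction of carbon sources plus minerals.

    At least one carbon source is always open (floor rule); butyrate is never
    given a positive uptake cap, so all exported butyrate is community-made.
    """
    if not 0 < richness <= 1:
        raise ValueError("richness must be in (0, 1]")
    carbons = [
        r.exchanged_metabolite
        for r in universe
        if r.is_exchange and r.exchanged_metabolite.startswith("c")
    ]
    if not carbons:
        raise ValueError("universe contains no carbon exchange")
    carbons = sorted(carbons)
    n_open = max(1, round(richness * len(carbons)))
    rng = np.random.default_rng(seed)
    open_carbons = sorted(str(c) for c in rng.choice(carbons, size=n_open, replace=False))
    caps = {c: DEFAULT_UPTAKE for c in open_carbons}
    caps["min_e"] = DEFAULT_UPTAKE
    return Medium(uptake_caps=caps)


def _sample_organism(
    universe_by_id: dict[str, Reaction],
    organism_id: str,
    producer: bool,
    open_carbon_idx: list[int],
    carbon_ids: list[str],
    intermediate_js: list[int],
    decoy_ids: list[str],
    rng: np.random.Generator,
) -> MetabolicNetwork:
    chosen: set[str] = {
        BIOMASS_ID,
        SINK_ID,
        MINERAL_EXCHANGE_ID,
        ACETATE_EXCHANGE_ID,
    }
    keep = rng.random(len(carbon_ids)) < P_CARBON
    # guarantee at least one catabolisable carbon that the medium opens
    if not any(keep[i] for i in open_carbon_idx):
        keep[rng.choice(open_carbon_idx)] = True
    for i, cid in enumerate(carbon_ids):
        if keep[i]:
            chosen.add(f"EX_{cid}")
            chosen.add(f"CAT_{cid[:-2]}")
    for j in intermediate_js:
        if rng.random() < P_SECRETE_INTERMEDIATE:
            chosen.update({f"SEC_im{j}", f"EX_im{j}_e"})
        if rng.random() < P_USE_INTERMEDIATE:
            chosen.update({f"USE_im{j}", f"EX_im{j}_e"})
    for did in decoy_ids:
        if rng.random() < P_DECOY:
            chosen.add(did)
    butyrate_exchange = None
    if producer:
        chosen.update({BUTYRATE_SYNTH_ID, BUTYRATE_EXCHANGE_ID})
        butyrate_exchange = BUTYRATE_EXCHANGE_ID
    return MetabolicNetwork(
        organism_id=organism_id,
        reactions=tuple(universe_by_id[rid] for rid in sorted(chosen)),
        biomass_reaction_id=BIOMASS_ID,
        butyrate_exchange_id=butyrate_exchange,
    )


def sample_pool(
    universe: Sequence[Reaction],
    n_organisms: int = 19,
    n_producers: int = 6,
    seed: int = 0,
    medium: Medium | None = None,
    max_retries: int = 50,
) -> tuple[list[MetabolicNetwork], PoolManifest]:
    """Sample organisms as feasible random subsets of the universe.

    Exactly ``n_producers`` members carry the butyrate-synthesis reaction and
    butyrate exchange.  Every sampled organism is verified to grow alone on
    ``medium`` (single-member flux balance); infeasible draws are resampled up
    to ``max_retries`` times.
    """
    from .community import single_member_growth  # deferred: avoids cycle

    if not 1 <= n_producers <= n_organisms:
        raise ValueError("need 1 <= n_producers <= n_organisms")
    universe_by_id = {r.id: r for r in universe}
    if medium is None:
        medium = make_medium(universe, richness=1.0, seed=seed)

    carbon_ids = sorted(
        r.exchanged_metabolite
        for r in universe
        if r.is_exchange and r.exchanged_metabolite.startswith("c")
    )
    open_carbon_idx = [
        i for i, c in enumerate(carbon_ids) if medium.cap(c) > 0
    ]
    if not open_carbon_idx:
        raise PoolGenerationError("medium opens no carbon source")
    intermediate_js = sorted(
        int(r.id[len("SEC_im"):]) for r in universe if r.id.startswith("SEC_im")
    )
    decoy_ids = sorted(r.id for r in universe if r.id.startswith("ZDC"))

    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_organisms)))
    organism_ids = [f"org{i + 1:0{width}d}" for i in range(n_organisms)]
    producer_set = {
        str(o) for o in rng.choice(organism_ids, size=n_producers, replace=False)
    }

    pool: list[MetabolicNetwork] = []
    for oid in organism_ids:
        for attempt in range(max_retries + 1):
            network = _sample_organism(
                universe_by_id,
                oid,
                oid in producer_set,
                open_carbon_idx,
                carbon_ids,
                intermediate_js,
                decoy_ids,
                rng,
            )
            if single_member_growth(network, medium) > 1e-6:
                pool.append(network)
                break
        else:
            raise PoolGenerationError(
                f"no feasible network for {oid} after {max_retries} retries; "
                "consider a larger universe or richer medium"
            )
    manifest = PoolManifest(
        organisms=tuple(organism_ids),
        producers=tuple(sorted(producer_set)),
        medium_path="medium.tsv",
        seed=seed,
    )
    return pool, manifest


def write_pool(
    pool: Sequence[MetabolicNetwork],
    manifest: PoolManifest,
    medium: Medium,
    outdir: str | Path,
) -> Path:
    """Write networks (JSON), medium (TSV) and ``manifest.json`` to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for network in pool:
        write_network(network, outdir / f"{network.organism_id}.json")
    write_medium(medium, outdir / manifest.medium_path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return outdir


def load_pool(
    directory: str | Path,
) -> tuple[list[MetabolicNetwork], PoolManifest, Medium]:
    directory = Path(directory)
    data = json.loads((directory / "manifest.json").read_text())
    manifest = PoolManifest(
        organisms=tuple(data["organisms"]),
        producers=tuple(data["producers"]),
        medium_path=data["medium_path"],
        seed=data["seed"],
    )
    pool = [
        load_network(directory / f"{oid}.json") for oid in manifest.organisms
    ]
    medium = load_medium(directory / manifest.medium_path)
    return pool, manifest, medium
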