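"""Data model and I/O for single-organism metabolic networks and growth media.

A :class:`MetabolicNetwork` is a flat list of reactions with flux bounds, a
designated biomass reaction and (for butyrate producers) a butyrate exchange.
Exchange reactions follow the export convention used throughout the package:
the single exchanged metabolite carries coefficient -1, positive flux is
secretion into the medium and negative flux is uptake from it, so a medium is
fully described by one nonnegative maximum-uptake rate per metabolite.

The canonical on-disk format is a compact JSON schema (see :func:`load_network`
/ :func:`write_network`); SBML Level 3 ingestion is available as a best-effort
reader when python-libsbml is installed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "Medium",
    "PresenceVector",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "load_medium",
    "write_medium",
    "presence_vector",
    "build_universe",
    "DEFAULT_BUTYRATE_ID",
    "DEFAULT_FLUX_BOUND",
]

#: Metabolite id used to auto-detect the butyrate exchange (exact match only).
DEFAULT_BUTYRATE_ID = "but_e"

#: Magnitude used for unconstrained flux bounds (mmol/gDW/h).
DEFAULT_FLUX_BOUND = 1000.0


class NetworkValidationError(ValueError):
    """Raised when a network or medium violates a structural invariant."""


@dataclass(frozen=True)
class Reaction:
    """One reaction: signed stoichiometry plus flux bounds (mmol/gDW/h).

    Exchange reactions reference exactly one metabolite with coefficient -1;
    positive flux secretes that metabolite into the medium.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -DEFAULT_FLUX_BOUND
    upper_bound: float = DEFAULT_FLUX_BOUND
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise NetworkValidationError(
                f"reaction {self.id!r}: stoichiometry must be non-empty"
            )
        for met, coef in self.stoichiometry.items():
            if coef == 0 or not math.isfinite(coef):
                raise NetworkValidationError(
                    f"reaction {self.id!r}: zero/non-finite coefficient for {met!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange:
            if len(self.stoichiometry) != 1:
                raise NetworkValidationError(
                    f"exchange reaction {self.id!r} must reference exactly one "
                    f"metabolite, got {len(self.stoichiometry)}"
                )
            (coef,) = self.stoichiometry.values()
            if coef != -1:
                raise NetworkValidationError(
                    f"exchange reaction {self.id!r} must have coefficient -1 "
                    f"(export convention), got {coef}"
                )

    @property
    def exchanged_metabolite(self) -> str:
        """Metabolite id of an exchange reaction."""
        if not self.is_exchange:
            raise ValueError(f"{self.id!r} is not an exchange reaction")
        return next(iter(self.stoichiometry))

    def metabolites(self) -> Iterable[str]:
        return self.stoichiometry.keys()


@dataclass(frozen=True)
class MetabolicNetwork:
    """One organism's reaction network with a biomass objective.

    ``butyrate_exchange_id`` is set only for organisms structurally able to
    export butyrate; it must name an exchange reaction of the butyrate
    metabolite.
    """

    organism_id: str
    reactions: tuple[Reaction, ...]
    biomass_reaction_id: str
    butyrate_exchange_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(
                f"network {self.organism_id!r}: duplicate reaction ids {dup}"
            )
        by_id = {r.id: r for r in self.reactions}
        if self.biomass_reaction_id not in by_id:
            raise NetworkValidationError(
                f"network {self.organism_id!r}: biomass reaction "
                f"{self.biomass_reaction_id!r} not among reactions"
            )
        if self.butyrate_exchange_id is not None:
            rxn = by_id.get(self.butyrate_exchange_id)
            if rxn is None or not rxn.is_exchange:
                raise NetworkValidationError(
                    f"network {self.organism_id!r}: butyrate_exchange_id "
                    f"{self.butyrate_exchange_id!r} is not an exchange reaction"
                )

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(r.id for r in self.reactions)

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    @property
    def exchanges(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_exchange)

    def to_dict(self) -> dict:
        return {
            "organism_id": self.organism_id,
            "biomass_reaction_id": self.biomass_reaction_id,
            "butyrate_exchange_id": self.butyrate_exchange_id,
            "reactions": [
                {
                    "id": r.id,
                    "stoich": {
                        m: float(r.stoichiometry[m]) for m in sorted(r.stoichiometry)
                    },
                    "lb": float(r.lower_bound),
                    "ub": float(r.upper_bound),
                    "is_exchange": r.is_exchange,
                }
                for r in sorted(self.reactions, key=lambda r: r.id)
            ],
        }


@dataclass(frozen=True)
class Medium:
    """Growth medium: maximum uptake rate (>= 0, mmol/gDW/h) per metabolite.

    Metabolites absent from ``uptake_caps`` cannot be taken up (cap 0) but may
    always be secreted.
    """

    uptake_caps: Mapping[str, float]

    def __post_init__(self) -> None:
        for met, cap in self.uptake_caps.items():
            if cap < 0 or not math.isfinite(cap):
                raise NetworkValidationError(
                    f"medium: uptake cap for {met!r} must be finite and >= 0, "
                    f"got {cap}"
                )

    def cap(self, metabolite_id: str) -> float:
        return float(self.uptake_caps.get(metabolite_id, 0.0))


@dataclass(frozen=True)
class PresenceVector:
    """Fixed-length binary reaction presence encoding over a shared universe."""

    universe: tuple[str, ...]
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "universe", tuple(self.universe))
        if len(self.universe) != bits.shape[0]:
            raise NetworkValidationError("presence vector length mismatch")
        if not np.isin(bits, (0, 1)).all():
            raise NetworkValidationError("presence bits must be 0/1")
        if list(self.universe) != sorted(self.universe):
            raise NetworkValidationError("universe must be sorted lexicographically")


# ---------------------------------------------------------------------------
# I/O


def _reaction_from_json(entry: dict, *, index: int) -> Reaction:
    try:
        return Reaction(
            id=entry["id"],
            stoichiometry={str(m): float(c) for m, c in entry["stoich"].items()},
            lower_bound=float(entry.get("lb", -DEFAULT_FLUX_BOUND)),
            upper_bound=float(entry.get("ub", DEFAULT_FLUX_BOUND)),
            is_exchange=bool(entry.get("is_exchange", False)),
        )
    except (KeyError, TypeError, AttributeError) as exc:
        raise NetworkValidationError(
            f"malformed reaction record #{index} ({entry.get('id', '<no id>')!r}): {exc}"
        ) from exc


def load_network(path: str | Path, format: str = "json") -> MetabolicNetwork:
    """Load and validate a network from JSON (canonical) or SBML Level 3.

    Unknown optional JSON fields are ignored.  Validation errors are raised at
    load time, naming the offending record.
    """
    path = Path(path)
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetworkValidationError(f"{path}: not valid JSON: {exc}") from exc
        try:
            reactions = [
                _reaction_from_json(entry, index=i)
                for i, entry in enumerate(data["reactions"])
            ]
            return MetabolicNetwork(
                organism_id=data["organism_id"],
                reactions=tuple(reactions),
                biomass_reaction_id=data["biomass_reaction_id"],
                butyrate_exchange_id=data.get("butyrate_exchange_id"),
            )
        except KeyError as exc:
            raise NetworkValidationError(f"{path}: missing field {exc}") from exc
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the canonical JSON (sorted keys; byte-stable round trip)."""
    Path(path).write_text(
        json.dumps(network.to_dict(), indent=1, sort_keys=True) + "\n"
    )


def _load_sbml(path: Path, *, butyrate_metabolite: str = DEFAULT_BUTYRATE_ID) -> MetabolicNetwork:
    """Best-effort SBML Level 3 reader (FBC bounds when present, else +/-1000).

    Boundary species are dropped from stoichiometries so that SBML exchange
    reactions collapse to the single-metabolite export convention.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - always present in CI image
        raise ImportError("SBML ingestion requires python-libsbml") from exc

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise NetworkValidationError(
            f"{path}: SBML parse error: {doc.getError(0).getMessage()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkValidationError(f"{path}: SBML file has no model")

    def clip(sid: str, prefix: str) -> str:
        # undo the conventional SBML id mangling (R_/M_ prefixes)
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    boundary = {
        s.getId() for s in model.getListOfSpecies() if s.getBoundaryCondition()
    }
    fbc = model.getPlugin("fbc")
    params = {
        p.getId(): p.getValue() for p in model.getListOfParameters()
    }

    biomass_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = clip(obj.getFluxObjective(0).getReaction(), "R_")

    reactions: list[Reaction] = []
    butyrate_exchange = None
    for rxn in model.getListOfReactions():
        rid = clip(rxn.getId(), "R_")
        stoich: dict[str, float] = {}
        for sr in rxn.getListOfReactants():
            if sr.getSpecies() in boundary:
                continue
            met = clip(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - sr.getStoichiometry()
        for sr in rxn.getListOfProducts():
            if sr.getSpecies() in boundary:
                continue
            met = clip(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + sr.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            continue
        rfbc = rxn.getPlugin("fbc")
        lb, ub = -DEFAULT_FLUX_BOUND, DEFAULT_FLUX_BOUND
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound(), lb)
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound(), ub)
        elif not rxn.getReversible():
            lb = 0.0
        is_exchange = len(stoich) == 1 and next(iter(stoich.values())) == -1
        reactions.append(
            Reaction(rid, stoich, max(lb, -DEFAULT_FLUX_BOUND),
                     min(ub, DEFAULT_FLUX_BOUND), is_exchange)
        )
        if is_exchange and next(iter(stoich)) == butyrate_metabolite:
            butyrate_exchange = rid
        if biomass_id is None and "biomass" in rid.lower():
            biomass_id = rid

    if biomass_id is None:
        raise NetworkValidationError(f"{path}: no biomass reaction identified")
    return MetabolicNetwork(
        organism_id=model.getId() or Path(path).stem,
        reactions=tuple(reactions),
        biomass_reaction_id=biomass_id,
        butyrate_exchange_id=butyrate_exchange,
    )


def load_medium(path: str | Path) -> Medium:
    """Read a two-column TSV ``metabolite_id<TAB>max_uptake`` with a header."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise NetworkValidationError(f"{path}: empty medium file")
    caps: dict[str, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkValidationError(
                f"{path}:{lineno}: expected 2 tab-separated columns"
            )
        met, cap = parts[0].strip(), float(parts[1])
        if met in caps:
            raise NetworkValidationError(f"{path}:{lineno}: duplicate metabolite {met!r}")
        caps[met] = cap
    return Medium(uptake_caps=caps)


def write_medium(medium: Medium, path: str | Path) -> None:
    rows = ["metabolite_id\tmax_uptake"]
    rows += [f"{m}\t{medium.uptake_caps[m]:g}" for m in sorted(medium.uptake_caps)]
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Presence encoding


def presence_vector(
    network: MetabolicNetwork, universe: Sequence[str]
) -> PresenceVector:
    """Binary presence/absence of each universe reaction in ``network``.

    Reactions of the network outside the universe are ignored by contract.
    """
    universe = tuple(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if list(universe) != sorted(set(universe)):
        raise ValueError("universe must be sorted and unique")
    present = network.reaction_ids
    bits = np.fromiter((1 if rid in present else 0 for rid in universe), dtype=np.int8)
    return PresenceVector(universe=universe, bits=bits)


def build_universe(pool: Sequence[MetabolicNetwork]) -> tuple[str, ...]:
    """Sorted union of reaction ids across a pool; order-independent."""
    if not pool:
        raise ValueError("pool must be non-empty")
    org_ids = [n.organism_id for n in pool]
    if len(org_ids) != len(set(org_ids)):
        dup = sorted({o for o in org_ids if org_ids.count(o) > 1})
        raise NetworkValidationError(f"duplicate organism ids in pool: {dup}")
    ids: set[str] = set()
    for network in pool:
        ids.update(network.reaction_ids)
    return tuple(sorted(ids))
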