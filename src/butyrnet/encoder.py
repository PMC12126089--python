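"""Descriptor selection, consortium enumeration and feature-vector assembly.

A consortium of *n* members is encoded as *n* member blocks — each member's
presence bits on one shared set of the k most informative reactions (k = 25
by default) — followed by the C(n, 2) pairwise cross-feeding probabilities in
lexicographic pair order.  The resulting length is

    k * n + n(n-1)/2,

i.e. 51, 78 and 106 features for consortia of two, three and four members at
k = 25.  Reaction importance is taken from a gradient-boosted classifier
trained on labelled pairs; each reaction's importance is summed over its two
positional copies in the pair features, and ties are broken lexicographically
by reaction id so the selection is reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .community import ConsortiumSpec
from .interactions import InteractionClassifier, PairRecord
from .netmodel import MetabolicNetwork, PresenceVector, presence_vector
from .synthpool import PoolManifest

__all__ = [
    "DescriptorSelection",
    "FeatureVector",
    "rank_descriptors",
    "enumerate_consortia",
    "encode_consortium",
    "feature_names",
    "build_dataset",
    "feature_length",
    "DEFAULT_K",
]

DEFAULT_K = 25


def feature_length(n_members: int, k: int = DEFAULT_K) -> int:
    """Encoded vector length: k members blocks plus all pair slots."""
    return k * n_members + n_members * (n_members - 1) // 2


@dataclass(frozen=True)
class DescriptorSelection:
    """Reactions ranked by importance; the first k form the descriptor set."""

    ranked_reactions: tuple[str, ...]
    k: int
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        object.__setattr__(self, "ranked_reactions", tuple(self.ranked_reactions))
        object.__setattr__(self, "universe", tuple(self.universe))

    @property
    def selected(self) -> tuple[str, ...]:
        return self.ranked_reactions[: min(self.k, len(self.ranked_reactions))]


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-layout numeric encoding of one consortium."""

    consortium: ConsortiumSpec
    values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        n = self.consortium.size
        if values.shape[0] != feature_length(n, self.k):
            raise ValueError(
                f"feature vector length {values.shape[0]} != "
                f"{feature_length(n, self.k)} for n={n}, k={self.k}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


def rank_descriptors(
    pair_records: Sequence[PairRecord],
    universe: Sequence[str],
    seed: int = 0,
    k: int = DEFAULT_K,
) -> DescriptorSelection:
    """Rank reactions by summed gradient-boosting importance on pair labels."""
    if k < 1:
        raise ValueError("k must be >= 1")
    labelled = [r for r in pair_records if r.label is not None]
    if len(labelled) < 10:
        raise ValueError(
            f"need at least 10 labelled pair records, got {len(labelled)}"
        )
    universe = tuple(universe)
    u = len(universe)
    X = np.vstack([r.features for r in labelled])
    if X.shape[1] != 2 * u:
        raise ValueError("pair feature length does not match 2 x universe size")
    y = np.array([r.label for r in labelled])
    model = XGBClassifier(
        n_estimators=200,
        max_depth=4,
        learning_rate=0.1,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(X, y)
    importances = model.feature_importances_
    per_reaction = importances[:u] + importances[u:]
    order = sorted(range(u), key=lambda i: (-per_reaction[i], universe[i]))
    ranked = tuple(universe[i] for i in order)
    return DescriptorSelection(ranked_reactions=ranked, k=k, universe=universe)


def enumerate_consortia(
    manifest: PoolManifest, sizes: Sequence[int]
) -> list[ConsortiumSpec]:
    """All size-s member subsets containing at least one butyrate producer.

    The count per size is C(n, s) - C(n - p, s) for a pool of n organisms
    with p producers; sizes larger than the pool yield no entries.  Output is
    sorted by (size, members).
    """
    sizes = sorted(set(sizes))
    if any(s < 2 or s > 13 for s in sizes):
        raise ValueError(f"consortium sizes must lie in 2..13, got {sizes}")
    organisms = sorted(manifest.organisms)
    producers = set(manifest.producers)
    specs: list[ConsortiumSpec] = []
    for size in sizes:
        for combo in itertools.combinations(organisms, size):
            if producers.intersection(combo):
                specs.append(ConsortiumSpec(members=combo))
    return specs


def encode_consortium(
    spec: ConsortiumSpec,
    pool: Sequence[MetabolicNetwork],
    selection: DescriptorSelection,
    classifier: InteractionClassifier,
) -> FeatureVector:
    """Assemble the member blocks and pair-probability tail for one consortium.

    Members are canonically ordered by the spec itself, so the encoding is
    invariant to the order networks are supplied in.
    """
    if selection.universe != classifier.universe:
        raise ValueError("descriptor selection and classifier universes differ")
    by_id = {n.organism_id: n for n in pool}
    missing = [m for m in spec.members if m not in by_id]
    if missing:
        raise KeyError(f"members without a network in the pool: {missing}")
    pv_by_org = {
        m: presence_vector(by_id[m], selection.universe) for m in spec.members
    }
    index = {rid: i for i, rid in enumerate(selection.universe)}
    sel_idx = np.array([index[rid] for rid in selection.selected], dtype=int)

    blocks = [pv_by_org[m].bits[sel_idx].astype(np.float64) for m in spec.members]
    tail = [
        classifier.pair_probability(pv_by_org, a, b)
        for a, b in itertools.combinations(spec.members, 2)
    ]
    values = np.concatenate(blocks + [np.asarray(tail, dtype=np.float64)])
    return FeatureVector(consortium=spec, values=values, k=len(sel_idx))


def feature_names(n_members: int, selection: DescriptorSelection) -> list[str]:
    """Column names: block index + reaction id, then pair-slot names.

    Blocks are indexed positionally (m1, m2, ...), not by organism id, so one
    per-size model applies to any consortium of that size.
    """
    names = [
        f"m{i + 1}_{rid}"
        for i in range(n_members)
        for rid in selection.selected
    ]
    names += [
        f"pair_{a + 1}_{b + 1}"
        for a, b in itertools.combinations(range(n_members), 2)
    ]
    return names


def build_dataset(
    labels: pd.DataFrame,
    encodings: Mapping[str, FeatureVector],
    selection: DescriptorSelection,
) -> dict[int, tuple[pd.DataFrame, pd.Series]]:
    """Per-size feature matrices and targets from labels plus encodings.

    ``labels`` must have columns ``size``, ``members`` (semicolon-joined) and
    ``butyrate_flux``; rows without ``status == "optimal"`` (when a status
    column is present) are excluded.  Raises when a labelled consortium has no
    encoding, listing the orphans.
    """
    table = labels
    if "status" in table.columns:
        table = table[table["status"] == "optimal"]
    orphans = sorted(set(table["members"]) - set(encodings))
    if orphans:
        raise KeyError(
            f"{len(orphans)} labelled consortia lack encodings, e.g. {orphans[:5]}"
        )
    datasets: dict[int, tuple[pd.DataFrame, pd.Series]] = {}
    for size, group in table.groupby("size"):
        group = group.sort_values("members")
        if group.empty:  # pragma: no cover - groupby never yields empty
            continue
        rows = np.vstack([encodings[m].values for m in group["members"]])
        X = pd.DataFrame(
            rows,
            columns=feature_names(int(size), selection),
            index=group["members"].to_numpy(),
        )
        y = pd.Series(
            group["butyrate_flux"].to_numpy(),
            index=X.index,
            name="butyrate_flux",
        )
        datasets[int(size)] = (X, y)
    return datasets
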