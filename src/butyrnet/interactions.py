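"""Pairwise cross-feeding probabilities from reaction-presence features.

Labels come from the package's own community simulator: a pair is labelled
cross-feeding (1) when, at the two-member stage-2 optimum, some medium
metabolite is secreted by one member and taken up by the other, both above a
flux threshold.  Because the staged solver finishes with a parsimonious-flux
pass, exchange fluxes that do not contribute to growth or butyrate export are
zeroed, so the label reflects metabolite transfer the community actually
exploits rather than a degenerate alternative optimum.

A gradient-boosted tree ensemble then maps concatenated presence vectors of
the (lexicographically ordered) pair to a probability in [0, 1].
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from xgboost import XGBClassifier

from .community import (
    DEFAULT_TRADEOFF,
    ConsortiumSpec,
    build_community,
    simulate,
)
from .netmodel import Medium, MetabolicNetwork, PresenceVector, presence_vector

__all__ = [
    "PairRecord",
    "InteractionClassifier",
    "pair_features",
    "label_pair_by_simulation",
    "build_pair_records",
    "train_interaction_classifier",
    "predict_crossfeed_prob",
    "DEFAULT_EPSILON",
]

#: Flux threshold (mmol/gDW/h) above which an exchange counts as transfer.
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class PairRecord:
    """One bacterial pair: canonical order, concatenated features, label."""

    pair: tuple[str, str]
    features: np.ndarray
    label: int | None = None
    probability: float | None = None

    def __post_init__(self) -> None:
        a, b = self.pair
        if not a < b:
            raise ValueError(f"pair must be lexicographically ordered, got {self.pair}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.probability is not None and not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        object.__setattr__(
            self, "features", np.asarray(self.features, dtype=np.float64)
        )


def pair_features(pv_a: PresenceVector, pv_b: PresenceVector) -> np.ndarray:
    """Concatenate presence bits of the canonically ordered pair."""
    if pv_a.universe != pv_b.universe:
        raise ValueError("presence vectors built on different universes")
    return np.concatenate([pv_a.bits, pv_b.bits]).astype(np.float64)


def label_pair_by_simulation(
    pool: Sequence[MetabolicNetwork],
    medium: Medium,
    pair: tuple[str, str],
    tradeoff: float = DEFAULT_TRADEOFF,
    epsilon: float = DEFAULT_EPSILON,
) -> int | None:
    """Simulate the two-member community and detect reciprocal exchange.

    Returns 1 if some medium metabolite is secreted (flux >= epsilon) by one
    member and taken up (flux <= -epsilon) by the other, 0 otherwise, and
    ``None`` when the pair community is infeasible (excluded from training).
    """
    by_id = {n.organism_id: n for n in pool}
    a, b = sorted(pair)
    spec = ConsortiumSpec.of([a, b])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_community([by_id[a], by_id[b]], spec, medium)
        result = simulate(model, tradeoff=tradeoff)
    if not result.optimal:
        return None
    mets = {met for _, met in model.member_exchange_vars}
    for met in sorted(mets):
        flux_a = _exchange_flux(result, model, a, met)
        flux_b = _exchange_flux(result, model, b, met)
        if flux_a is None or flux_b is None:
            continue
        if (flux_a >= epsilon and flux_b <= -epsilon) or (
            flux_b >= epsilon and flux_a <= -epsilon
        ):
            return 1
    return 0


def _exchange_flux(result, model, org: str, met: str) -> float | None:
    col = model.member_exchange_vars.get((org, met))
    if col is None:
        return None
    return result.fluxes[model.variables[col]]


def build_pair_records(
    pool: Sequence[MetabolicNetwork],
    medium: Medium,
    universe: Sequence[str],
    tradeoff: float = DEFAULT_TRADEOFF,
    epsilon: float = DEFAULT_EPSILON,
) -> list[PairRecord]:
    """Label every unordered pair of the pool by simulation.

    Infeasible pairs are dropped.
    """
    vectors = {n.organism_id: presence_vector(n, universe) for n in pool}
    records: list[PairRecord] = []
    for a, b in itertools.combinations(sorted(vectors), 2):
        label = label_pair_by_simulation(pool, medium, (a, b), tradeoff, epsilon)
        if label is None:
            continue
        records.append(
            PairRecord(
                pair=(a, b),
                features=pair_features(vectors[a], vectors[b]),
                label=label,
            )
        )
    return records


@dataclass
class InteractionClassifier:
    """Trained pair classifier bound to a fixed universe ordering."""

    model: XGBClassifier
    universe: tuple[str, ...]
    seed: int

    @property
    def n_features(self) -> int:
        return 2 * len(self.universe)

    def universe_hash(self) -> str:
        return hashlib.sha256("\n".join(self.universe).encode()).hexdigest()[:16]

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature length mismatch: expected {self.n_features}, "
                f"got {features.shape[1]}"
            )
        return self.model.predict_proba(features)[:, 1]

    def pair_probability(
        self, pv_by_org: Mapping[str, PresenceVector], a: str, b: str
    ) -> float:
        """Cross-feeding probability, symmetric in (a, b) by canonical order."""
        a, b = sorted((a, b))
        feats = pair_features(pv_by_org[a], pv_by_org[b])
        return float(self.predict_proba(feats)[0])

    def save(self, directory: str | Path) -> Path:
        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, directory / "interaction_model.joblib")
        (directory / "interaction_meta.json").write_text(
            json.dumps(
                {
                    "universe": list(self.universe),
                    "universe_hash": self.universe_hash(),
                    "seed": self.seed,
                    "format_version": 1,
                },
                indent=1,
            )
        )
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "InteractionClassifier":
        import joblib

        directory = Path(directory)
        meta = json.loads((directory / "interaction_meta.json").read_text())
        model = joblib.load(directory / "interaction_model.joblib")
        return cls(model=model, universe=tuple(meta["universe"]), seed=meta["seed"])


def train_interaction_classifier(
    records: Sequence[PairRecord],
    universe: Sequence[str],
    seed: int = 0,
) -> InteractionClassifier:
    """Fit the gradient-boosted pair classifier on labelled records.

    Deterministic for a fixed seed (single-thread training).  Requires both
    classes among the labels.
    """
    labelled = [r for r in records if r.label is not None]
    if not labelled:
        raise ValueError("no labelled pair records")
    y = np.array([r.label for r in labelled])
    if len(np.unique(y)) < 2:
        raise ValueError(
            "pair labels contain a single class; cannot train a classifier"
        )
    X = np.vstack([r.features for r in labelled])
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
    return InteractionClassifier(model=model, universe=tuple(universe), seed=seed)


def predict_crossfeed_prob(
    classifier: InteractionClassifier, features: np.ndarray
) -> float:
    """Probability in [0, 1] for one feature row (length checked)."""
    return float(classifier.predict_proba(features)[0])
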