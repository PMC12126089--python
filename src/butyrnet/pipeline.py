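"""End-to-end orchestration and evaluation of butyrate predictors.

``evaluate`` computes the comparison metrics used throughout: Pearson and
Spearman correlations with two-sided p-values, an ordinary least-squares fit
(slope, intercept, r-squared — the "linear correlation" reported alongside
the rank statistics), and mean squared error.  ``compare_to_baseline`` lines
learned regressors up against the mechanistic community simulator on one
reference set.  ``run_end_to_end`` chains pool generation, label simulation,
pair labelling, descriptor selection, encoding, per-size training and
evaluation into one reproducible artifact directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import community, encoder, interactions, netmodel, regress, synthpool

__all__ = [
    "EvaluationReport",
    "evaluate",
    "compare_to_baseline",
    "correlation_heatmap",
    "PipelineConfig",
    "run_end_to_end",
]

logger = logging.getLogger("butyrnet")

SIGNIFICANCE = 0.05


@dataclass(frozen=True)
class EvaluationReport:
    """Agreement between one predictor and reference butyrate values."""

    n: int
    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    slope: float | None
    intercept: float | None
    r_squared: float | None
    mse: float
    undefined_reason: str | None = None

    @property
    def significant(self) -> bool:
        return self.pearson_p is not None and self.pearson_p < SIGNIFICANCE

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "mse": self.mse,
            "undefined_reason": self.undefined_reason,
        }


def evaluate(predictions, references) -> EvaluationReport:
    """Correlation and error metrics between predicted and reference values.

    Requires equal-length finite vectors with n >= 3.  With a zero-variance
    input the correlations are undefined and reported as missing (MSE is
    still computed).  Spearman uses average ranks for ties; p-values are
    two-sided.
    """
    pred = np.asarray(predictions, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("predictions and references must be equal-length vectors")
    if pred.size < 3:
        raise ValueError(f"need at least 3 points, got {pred.size}")
    if not (np.isfinite(pred).all() and np.isfinite(ref).all()):
        raise ValueError("inputs must be finite")
    mse = float(np.mean((pred - ref) ** 2))
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        return EvaluationReport(
            n=pred.size,
            pearson_r=None, pearson_p=None,
            spearman_rho=None, spearman_p=None,
            slope=None, intercept=None, r_squared=None,
            mse=mse,
            undefined_reason="zero-variance input: correlation undefined",
        )
    pearson = stats.pearsonr(pred, ref)
    spearman = stats.spearmanr(pred, ref)
    fit = stats.linregress(pred, ref)
    return EvaluationReport(
        n=pred.size,
        pearson_r=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        spearman_rho=float(spearman.statistic),
        spearman_p=float(spearman.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        mse=mse,
    )


def compare_to_baseline(
    predictions: Mapping[str, Sequence[float]],
    references: Sequence[float],
    size: int | None = None,
) -> pd.DataFrame:
    """One evaluation row per predictor on a shared reference set.

    ``predictions`` maps predictor name (regressor family or the mechanistic
    simulator baseline) to its predicted vector.  The best predictor per
    table is flagged by largest absolute Pearson r.
    """
    if not predictions:
        raise ValueError("no predictors supplied")
    ref = np.asarray(references, dtype=np.float64)
    rows = []
    for name in predictions:
        pred = np.asarray(predictions[name], dtype=np.float64)
        if pred.shape != ref.shape:
            raise ValueError(
                f"predictor {name!r} has {pred.size} values, reference has {ref.size}"
            )
        report = evaluate(pred, ref)
        row = {"model": name}
        if size is not None:
            row["size"] = size
        row.update(report.to_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    abs_r = table["pearson_r"].abs()
    table["best"] = False
    if abs_r.notna().any():
        table.loc[abs_r.idxmax(), "best"] = True
    return table


def correlation_heatmap(
    comparison: pd.DataFrame, path: str | Path, metric: str = "pearson_r"
) -> Path:
    """Sizes-by-models heatmap of one correlation metric, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = comparison.pivot(index="size", columns="model", values=metric)
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2, 1 + len(pivot)))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), [f"{s} members" for s in pivot.index])
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            val = pivot.iat[i, j]
            if pd.notna(val):
                ax.text(j, i, f"{val:.2f}", ha="center", va="center", fontsize=8)
    ax.set_title(f"{metric} (predicted vs simulated butyrate)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


@dataclass(frozen=True)
class PipelineConfig:
    """Reproducible configuration of one end-to-end run."""

    out: str
    organisms: int = 19
    producers: int = 6
    carbon_sources: int = 2
    intermediates: int = 2
    decoys: int = 14
    richness: float = 1.0
    sizes: tuple[int, ...] = (2, 3)
    k: int = encoder.DEFAULT_K
    tradeoff: float = community.DEFAULT_TRADEOFF
    seed: int = 0
    cv_folds: int = 5
    split_fraction: float = 0.75
    algorithms: tuple[str, ...] = regress.ALGORITHMS
    grids: Mapping[str, Mapping[str, list]] | None = None

    def __post_init__(self) -> None:
        if not self.out:
            raise ValueError("config requires an output directory")
        object.__setattr__(self, "sizes", tuple(sorted(self.sizes)))
        object.__setattr__(self, "algorithms", tuple(self.algorithms))
        unknown = set(self.algorithms) - set(regress.ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if any(s < 2 or s > community.MAX_CONSORTIUM_SIZE for s in self.sizes):
            raise ValueError("sizes must lie in 2..13")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for key in ("sizes", "algorithms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_end_to_end(config: PipelineConfig) -> Path:
    """Generate, simulate, encode, train and evaluate in one seeded run.

    Writes pool/, labels.csv, pairs.csv, features/size_<n>.csv, models
    metadata, predictions and evaluation CSVs plus a correlation heatmap and
    a run manifest to ``config.out``; reruns with the same config are
    identical up to the PNG byte stream.
    """
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage %-12s elapsed %.1fs", name, time.time() - t0)

    # --- pool -------------------------------------------------------------
    stage("synth-pool")
    uspec = synthpool.UniverseSpec(
        n_carbon_sources=config.carbon_sources,
        n_intermediates=config.intermediates,
        n_decoy_reactions=config.decoys,
        seed=config.seed,
    )
    universe = synthpool.make_universe(uspec)
    medium = synthpool.make_medium(universe, richness=config.richness, seed=config.seed)
    pool, manifest = synthpool.sample_pool(
        universe,
        n_organisms=config.organisms,
        n_producers=config.producers,
        seed=config.seed,
        medium=medium,
    )
    synthpool.write_pool(pool, manifest, medium, out / "pool")
    universe_ids = netmodel.build_universe(pool)

    # --- labels -----------------------------------------------------------
    stage("simulate")
    labels = community.simulate_training_labels(
        pool, manifest, medium, sizes=config.sizes, tradeoff=config.tradeoff
    )
    labels.to_csv(out / "labels.csv", index=False)

    # --- pairs + classifier ----------------------------------------------
    stage("pairs")
    records = interactions.build_pair_records(
        pool, medium, universe_ids, tradeoff=config.tradeoff
    )
    classifier = interactions.train_interaction_classifier(
        records, universe_ids, seed=config.seed
    )
    classifier.save(out / "interaction")
    pv_by_org = {
        n.organism_id: netmodel.presence_vector(n, universe_ids) for n in pool
    }
    pd.DataFrame(
        [
            {
                "org_a": r.pair[0],
                "org_b": r.pair[1],
                "label": r.label,
                "probability": classifier.pair_probability(pv_by_org, *r.pair),
            }
            for r in records
        ]
    ).to_csv(out / "pairs.csv", index=False)

    # --- encoding ---------------------------------------------------------
    stage("encode")
    selection = encoder.rank_descriptors(
        records, universe_ids, seed=config.seed, k=config.k
    )
    (out / "selection.json").write_text(
        json.dumps(
            {"k": selection.k, "selected": list(selection.selected)}, indent=1
        )
    )
    specs = encoder.enumerate_consortia(manifest, config.sizes)
    encodings = {
        spec.key(): encoder.encode_consortium(spec, pool, selection, classifier)
        for spec in specs
    }
    datasets = encoder.build_dataset(labels, encodings, selection)
    features_dir = out / "features"
    features_dir.mkdir(exist_ok=True)
    for size, (X, y) in datasets.items():
        X.assign(butyrate_flux=y).to_csv(
            features_dir / f"size_{size}.csv", index_label="members"
        )

    # --- per-size training and evaluation ---------------------------------
    stage("train")
    comparisons = []
    models_meta = []
    for size, (X, y) in sorted(datasets.items()):
        X_train, X_test, y_train, y_test = regress.split_dataset(
            X, y, fraction=config.split_fraction, seed=config.seed
        )
        models = regress.train_all_families(
            X_train,
            y_train,
            consortium_size=size,
            seed=config.seed,
            algorithms=config.algorithms,
            cv_folds=config.cv_folds,
            grids=config.grids,
        )
        predictions = {
            name: regress.predict(model, X_test) for name, model in models.items()
        }
        # the mechanistic simulator scores perfectly against its own labels;
        # kept as the reference baseline row
        predictions["simulator"] = y_test.to_numpy()
        table = compare_to_baseline(predictions, y_test.to_numpy(), size=size)
        comparisons.append(table)
        pd.DataFrame(predictions, index=X_test.index).assign(
            reference=y_test
        ).to_csv(out / f"predictions_size_{size}.csv", index_label="members")
        for name, model in models.items():
            models_meta.append(
                {
                    "size": size,
                    "algorithm": name,
                    "best_params": model.best_params,
                    "cv_mse": model.cv_mse,
                    "train_mse": model.train_mse,
                    "layout_hash": model.layout_hash,
                    "seed": model.seed,
                }
            )

    comparison = pd.concat(comparisons, ignore_index=True)
    comparison.to_csv(out / "evaluation.csv", index=False)
    correlation_heatmap(comparison, out / "heatmap_pearson.png")
    (out / "models.json").write_text(json.dumps(models_meta, indent=1, default=str))

    stage("manifest")
    run_manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if k != "grids"
        },
        "n_consortia": int(len(labels)),
        "n_pairs": int(len(records)),
        "universe_size": len(universe_ids),
        "universe_hash": classifier.universe_hash(),
        "wall_time_s": round(time.time() - t0, 2),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))
    return out
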