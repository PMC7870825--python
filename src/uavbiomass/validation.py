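"""Threefold cross-validation (temporal / spatial / mixed schemes) and
independent-field validation of the biomass model.

Folds are formed by harvest month (temporal), by replicate (spatial), or by
uniform random assignment repeated for a configured number of iterations
(mixed). For every fold the model is refit on the other two folds and scored
on the held-out rows; accuracy is reported both as the average fold
R-squared (the headline rule) and as the median over month x replicate cell
R-squared values.

By default standardization is refit inside each training fold and applied to
held-out features using training-fold group statistics where the group was
seen in training, else the held-out group's own *feature* statistics;
held-out biomass statistics are never used (cell R-squared is the squared
Pearson correlation, which is affine-invariant per cell, so the observed
biomass can stay on its raw scale). ``standardization="pre"`` accepts a
table standardized once globally before splitting, reproducing the original
workflow in which standardization preceded cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io_formats import MONTH_ORDER
from .modeling import (
    BiomassModel,
    StandardizedTable,
    _row_keys,
    fit_ols,
    metrics,
    predict,
    standardize_by_group,
)


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: temporal, spatial, or mixed (random thirds)."""

    kind: str
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("temporal", "spatial", "mixed"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def make_folds(
    table: pd.DataFrame, scheme: CVScheme, seed: int | None = None
) -> np.ndarray:
    """Fold label per row: by month, by replicate, or seeded random thirds."""
    n = len(table)
    if scheme.kind in ("temporal", "spatial"):
        col = "month" if scheme.kind == "temporal" else "replicate"
        labels = table[col].unique()
        if len(labels) < 3:
            raise ValueError(
                f"{scheme.kind} scheme needs >= 3 distinct {col} labels, "
                f"found {len(labels)}"
            )
        if scheme.kind == "temporal":
            order = {m: i for i, m in enumerate(MONTH_ORDER)}
            labels = sorted(labels, key=lambda m: (order.get(m, len(order)), m))
        else:
            labels = sorted(labels)
        lookup = {lab: i for i, lab in enumerate(labels)}
        return table[col].map(lookup).to_numpy()
    rng = np.random.default_rng(scheme.seed if seed is None else seed)
    folds = np.arange(n) % 3  # sizes differ by at most one
    return folds[rng.permutation(n)]


@dataclass
class CVResult:
    """Per-cell and per-fold accuracies with fitted fold coefficients."""

    scheme: CVScheme
    cells: pd.DataFrame         # iteration, fold, month, replicate, n, r2
    folds: pd.DataFrame         # iteration, fold, n, r2
    coefficients: pd.DataFrame  # iteration, fold, one column per feature
    fold_seeds: list[int] = field(default_factory=list)

    @property
    def median_cell_r2(self) -> float:
        return float(self.cells["r2"].median())

    @property
    def accuracy(self) -> float:
        """Average of fold R-squared values (mean over iterations)."""
        return float(self.folds.groupby("iteration")["r2"].mean().mean())


def _cell_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    if len(obs) < 3 or np.std(obs) == 0 or np.std(pred) == 0:
        return np.nan
    return float(pearsonr(obs, pred).statistic) ** 2


def _standardize_test_features(
    test: pd.DataFrame,
    features: tuple[str, ...],
    train_std: StandardizedTable,
    group_keys: tuple[str, ...],
) -> pd.DataFrame:
    """z-score held-out features: training group stats if the group was seen
    in training, else the held-out group's own feature stats."""
    out = test.copy()
    train_groups = set(
        train_std.group_stats.index.droplevel("column").unique()
    )
    for gkey, sub in test.groupby(list(group_keys), observed=True, sort=False):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        for col in features:
            if gkey in train_groups:
                stats = train_std.group_stats.loc[(*gkey, col)]
                mean, sd = float(stats["mean"]), float(stats["sd"])
            else:
                mean = float(sub[col].mean())
                sd = float(sub[col].std(ddof=1))
            out.loc[sub.index, col] = (sub[col] - mean) / sd
    return out


def cross_validate(
    table: pd.DataFrame,
    scheme: CVScheme,
    features: tuple[str, ...],
    biomass_col: str = "biomass",
    standardization: str = "per_fold",
    group_keys: tuple[str, ...] = ("month", "replicate"),
) -> CVResult:
    """Threefold cross-validation of the linear biomass model.

    ``standardization="per_fold"`` (default, leak-free) refits group
    standardization inside every training fold; ``"pre"`` treats the input
    as already standardized (standardize-once-before-CV mode).
    """
    iterations = scheme.iterations if scheme.kind == "mixed" else 1
    seeds = [
        int(s) for s in
        np.random.SeedSequence(scheme.seed).generate_state(iterations) % (2**31)
    ]
    cell_rows, fold_rows, coef_rows = [], [], []
    for it in range(iterations):
        folds = make_folds(table, scheme, seed=seeds[it])
        for f in sorted(np.unique(folds)):
            test = table[folds == f]
            train = table[folds != f]
            assert len(train.index.intersection(test.index)) == 0  # leakage guard
            if standardization == "per_fold":
                train_std = standardize_by_group(
                    train, value_columns=(*features, biomass_col),
                    group_keys=group_keys,
                )
                model = fit_ols(train_std, features, biomass_col=biomass_col)
                test_feats = _standardize_test_features(
                    test, features, train_std, group_keys
                )
            elif standardization == "pre":
                model = fit_ols(train, features, biomass_col=biomass_col)
                test_feats = test
            else:
                raise ValueError(f"unknown standardization mode {standardization!r}")
            pred = predict(model, test_feats)
            obs = test[biomass_col].to_numpy(dtype=float)
            fold_rows.append((it, int(f), len(test), _cell_r2(obs, pred)))
            coef_rows.append((it, int(f), *model.coefficients))
            for gkey, idx in test.groupby(list(group_keys), observed=True).groups.items():
                gkey = gkey if isinstance(gkey, tuple) else (gkey,)
                pos = test.index.get_indexer(idx)
                cell_rows.append(
                    (it, int(f), *gkey, len(idx), _cell_r2(obs[pos], pred[pos]))
                )
    cells = pd.DataFrame(
        cell_rows, columns=["iteration", "fold", *group_keys, "n", "r2"]
    )
    folds_df = pd.DataFrame(fold_rows, columns=["iteration", "fold", "n", "r2"])
    coefs = pd.DataFrame(coef_rows, columns=["iteration", "fold", *features])
    return CVResult(scheme=scheme, cells=cells, folds=folds_df,
                    coefficients=coefs, fold_seeds=seeds)


def independent_validate(
    model: BiomassModel,
    test_table: pd.DataFrame,
    biomass_col: str = "biomass_kg",
    group_keys: tuple[str, ...] = ("month", "replicate"),
    kg_group_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply a frozen model to an independent field; metrics per replicate.

    Test-field features are standardized within the test field's own
    month x replicate groups (feature statistics only — observed biomass is
    touched solely to compute the final metrics). Predictions stay on the
    standardized scale unless ``kg_group_stats`` (group means/sds of
    biomass, as produced by :func:`standardize_by_group`) is supplied, in
    which case predictions are back-transformed and RMSE is in kg.

    Raises if any test plot key appears among the model's training keys
    (leakage guard).
    """
    overlap = model.training_keys & _row_keys(test_table)
    if overlap:
        raise ValueError(f"training/test overlap on {len(overlap)} plot keys")
    std = standardize_by_group(
        test_table, value_columns=tuple(model.features), group_keys=group_keys
    )
    if kg_group_stats is not None:
        pred = predict(
            model, std.data, group_stats=kg_group_stats,
            groups=std.data[list(group_keys)], biomass_col=biomass_col,
        )
        observed = test_table[biomass_col].to_numpy(dtype=float)
    else:
        # evaluate on the standardized scale: z-score the observed biomass
        # within test groups (evaluation-time scaling only)
        pred = predict(model, std.data)
        obs_std = standardize_by_group(
            test_table, value_columns=(biomass_col,), group_keys=group_keys
        )
        observed = obs_std.data[biomass_col].to_numpy(dtype=float)
    rows = []
    for rep, sub in std.data.groupby("replicate", observed=True):
        pos = std.data.index.get_indexer(sub.index)
        m = metrics(observed[pos], pred[pos])
        rows.append((rep, len(sub), m["r2"], m["pearson"], m["spearman"], m["rmse"]))
    return pd.DataFrame(
        rows, columns=["replicate", "n", "r2", "pearson", "spearman", "rmse"]
    )
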