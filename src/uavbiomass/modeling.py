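"""Biomass modeling: group-wise standardization, feature correlation and
clustering, leave-one-feature-out RSS contributions, the feature-selection
procedure, and the four-feature linear model.

All modeling happens on the standardized scale: every feature and the
observed biomass are z-scored within each month x replicate group (sample
sd, n-1) to remove month and field-position effects before regression.

R-squared is defined as the squared Pearson correlation between observed and
predicted values — cross-field predictions may carry an offset, which this
definition deliberately ignores; ``r2_method="ss"`` gives the 1 - SSE/SST
variant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import pearsonr, spearmanr

KEY_COLUMNS = ("field", "month", "replicate", "row", "col")


@dataclass
class StandardizedTable:
    """Feature matrix + biomass, z-scored within each month x replicate group.

    ``group_stats`` stores the per-group means/sds for back-transforming
    predictions to natural units.
    """

    data: pd.DataFrame
    group_keys: tuple[str, ...]
    value_columns: tuple[str, ...]
    group_stats: pd.DataFrame  # MultiIndex (group..., column) -> mean, sd

    def groups(self):
        return self.data.groupby(list(self.group_keys), observed=True, sort=False)


def standardize_by_group(
    table: pd.DataFrame,
    value_columns: tuple[str, ...] | None = None,
    group_keys: tuple[str, ...] = ("month", "replicate"),
) -> StandardizedTable:
    """z-score every value column within each group (sample sd, n-1).

    Groups must hold at least 3 rows; a zero-variance column in any group is
    an error naming the column and group. NaNs are excluded from the group
    statistics and propagate through unchanged.
    """
    if value_columns is None:
        skip = set(group_keys) | set(KEY_COLUMNS)
        value_columns = tuple(
            c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        )
    out = table.copy()
    stats = []
    for gkey, sub in table.groupby(list(group_keys), observed=True, sort=False):
        if len(sub) < 3:
            raise ValueError(f"group {gkey} has fewer than 3 plots")
        for col in value_columns:
            mean = sub[col].mean()
            sd = sub[col].std(ddof=1)
            if not sd > 0:
                raise ValueError(f"zero variance in column {col!r} of group {gkey}")
            out.loc[sub.index, col] = (sub[col] - mean) / sd
            gtup = gkey if isinstance(gkey, tuple) else (gkey,)
            stats.append((*gtup, col, mean, sd))
    group_stats = pd.DataFrame(
        stats, columns=[*group_keys, "column", "mean", "sd"]
    ).set_index([*group_keys, "column"])
    return StandardizedTable(
        data=out, group_keys=tuple(group_keys),
        value_columns=tuple(value_columns), group_stats=group_stats,
    )


def feature_correlations(
    std: StandardizedTable, columns: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the value columns."""
    cols = list(columns or std.value_columns)
    if len(std.data) < 3:
        raise ValueError("need at least 3 rows for correlations")
    sub = std.data[cols]
    if sub.isna().any().any():
        n_complete = sub.notna().all(axis=1).sum()
        warnings.warn(
            f"missing values present; pairwise-complete correlations "
            f"({n_complete}/{len(sub)} fully complete rows)"
        )
    return sub.corr(method="pearson")


@dataclass
class FeatureClusters:
    """Two-way hierarchical clustering of plots and feature columns."""

    feature_linkage: np.ndarray
    row_linkage: np.ndarray
    feature_order: list[str]
    row_order: np.ndarray
    ordered_matrix: pd.DataFrame


def cluster_features(
    std: StandardizedTable, columns: tuple[str, ...] | None = None
) -> FeatureClusters:
    """Two-way complete-linkage Euclidean clustering (features and plots).

    Leaf orders come from scipy's deterministic dendrogram ordering.
    """
    cols = list(columns or std.value_columns)
    X = std.data[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix must be complete for clustering")
    feat_link = linkage(X.T, method="complete", metric="euclidean")
    row_link = linkage(X, method="complete", metric="euclidean")
    feat_order = [cols[i] for i in leaves_list(feat_link)]
    row_order = leaves_list(row_link)
    ordered = std.data.iloc[row_order][feat_order]
    return FeatureClusters(
        feature_linkage=feat_link, row_linkage=row_link,
        feature_order=feat_order, row_order=row_order, ordered_matrix=ordered,
    )


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    return float(model.fit().ssr)


def rss_contributions(
    std: StandardizedTable,
    features: tuple[str, ...] | None = None,
    biomass_col: str = "biomass",
) -> pd.DataFrame:
    """Leave-one-feature-out RSS increases (the feature-importance measure).

    Fits the full OLS of biomass on all features, then refits dropping each
    feature in turn; the increase in residual sum of squares is that
    feature's contribution. Nested least squares guarantees the increase is
    non-negative. Collinear designs are fit by pseudo-inverse with a warning.
    """
    feats = list(features or [c for c in std.value_columns if c != biomass_col])
    df = std.data.dropna(subset=[*feats, biomass_col])
    if len(df) <= len(feats) + 1:
        raise ValueError("need more rows than features for the full model")
    y = df[biomass_col].to_numpy(dtype=float)
    X = df[feats].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient design: dropping collinear directions (pseudo-inverse fit)")
    rss_full = _ols_rss(y, X)
    rows = []
    for i, f in enumerate(feats):
        rss_red = _ols_rss(y, np.delete(X, i, axis=1))
        delta = rss_red - rss_full
        if -1e-8 < delta < 0:  # float jitter on exactly-nested fits
            delta = 0.0
        rows.append((f, rss_full, rss_red, delta))
    return pd.DataFrame(rows, columns=["feature", "rss_full", "rss_reduced", "delta_rss"])


def select_model_features(
    std: StandardizedTable,
    correlations: pd.DataFrame,
    clusters: FeatureClusters | None = None,
    contributions: pd.DataFrame | None = None,
    biomass_col: str = "biomass",
    area_feature: str = "area",
    height_feature: str = "height",
    volume_feature: str = "volume",
    ndvi_feature: str = "ndvi",
    r_exclude: float = 0.9,
    r_min: float = 0.3,
    n_remaining_clusters: int = 2,
) -> list[str]:
    """Rule-based selection of the prediction features.

    1. The feature with the strongest |R| to biomass is taken first
       (vegetative area, in practice).
    2. If the next-strongest is the composite volume (= area x height),
       height is taken instead; otherwise the next-strongest itself.
    3. The area-defining index (NDVI), features with |R| to NDVI above
       ``r_exclude`` (either sign), and features with |R| to biomass below
       ``r_min`` are excluded.
    4. The remaining candidates are cut into ``n_remaining_clusters``
       clusters; each contributes its member with max |R| to biomass.
    """
    feats = [c for c in correlations.columns if c != biomass_col]
    r_bio = correlations[biomass_col].drop(biomass_col).abs()
    ranked = r_bio.sort_values(ascending=False)
    first = ranked.index[0]
    nxt = ranked.index[1]
    second = height_feature if nxt == volume_feature else nxt
    chosen = [first, second]

    r_ndvi = correlations[ndvi_feature].abs() if ndvi_feature in correlations else None
    candidates = []
    for f in feats:
        if f in chosen or f in (volume_feature, ndvi_feature):
            continue
        if r_ndvi is not None and f in r_ndvi and r_ndvi[f] > r_exclude:
            continue
        if r_bio.get(f, 0.0) < r_min:
            continue
        candidates.append(f)
    if not candidates:
        raise ValueError("no candidate features remain after exclusions")

    k = min(n_remaining_clusters, len(candidates))
    if k == len(candidates):
        groups = {i: [f] for i, f in enumerate(candidates)}
    else:
        X = std.data[candidates].dropna().to_numpy(dtype=float)
        link = linkage(X.T, method="complete", metric="euclidean")
        labels = fcluster(link, t=k, criterion="maxclust")
        groups = {}
        for f, lab in zip(candidates, labels):
            groups.setdefault(lab, []).append(f)
    for members in groups.values():
        chosen.append(max(members, key=lambda f: (r_bio[f], f)))
    return chosen


@dataclass
class BiomassModel:
    """Ordered feature names + regression coefficients on the standardized scale."""

    features: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    training_info: dict = field(default_factory=dict)
    training_keys: frozenset = field(default_factory=frozenset)

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.features, map(float, self.coefficients)))

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.features),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": self.intercept,
            "training_info": self.training_info,
            "training_keys": sorted(map(list, self.training_keys)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BiomassModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            features=tuple(payload["features"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            training_info=payload.get("training_info", {}),
            training_keys=frozenset(tuple(k) for k in payload.get("training_keys", [])),
        )

    @classmethod
    def from_preset(cls, name: str = "final") -> "BiomassModel":
        """Published coefficient presets: ``final`` (outlier group removed)
        or ``full`` (all training data)."""
        from .synthetic_field import BETA_ORDER, EQ1_BETA, FULL_BETA

        beta = {"final": EQ1_BETA, "full": FULL_BETA}[name]
        return cls(features=BETA_ORDER, coefficients=np.asarray(beta, dtype=float),
                   intercept=0.0, training_info={"preset": name})


def _row_keys(df: pd.DataFrame) -> frozenset:
    cols = [c for c in KEY_COLUMNS if c in df.columns]
    if not cols:
        return frozenset()
    return frozenset(map(tuple, df[cols].itertuples(index=False, name=None)))


def fit_ols(
    data: StandardizedTable | pd.DataFrame,
    features: tuple[str, ...],
    biomass_col: str = "biomass",
    exclude_groups: list[tuple] | None = None,
) -> BiomassModel:
    """Least-squares fit of standardized biomass on the named features.

    ``exclude_groups`` drops caller-flagged (month, replicate) outlier
    groups from the fit — the published final model excludes one
    rain-affected harvest group this way.
    """
    df = data.data if isinstance(data, StandardizedTable) else data
    if exclude_groups:
        gk = data.group_keys if isinstance(data, StandardizedTable) else ("month", "replicate")
        keys = df[list(gk)].apply(tuple, axis=1)
        df = df[~keys.isin(set(map(tuple, exclude_groups)))]
    df = df.dropna(subset=[*features, biomass_col])
    if len(df) <= len(features) + 1:
        raise ValueError("not enough rows to fit the model")
    X = df[list(features)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    y = df[biomass_col].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return BiomassModel(
        features=tuple(features),
        coefficients=np.asarray(res.params[1:], dtype=float),
        intercept=float(res.params[0]),
        training_info={"n": int(len(df)), "r2_train": float(res.rsquared)},
        training_keys=_row_keys(df),
    )


def predict(
    model: BiomassModel,
    features: pd.DataFrame,
    group_stats: pd.DataFrame | None = None,
    groups: pd.DataFrame | None = None,
    biomass_col: str = "biomass",
) -> np.ndarray:
    """Standardized biomass predictions; optionally back-transformed to kg.

    Back-transform requires ``group_stats`` (as stored on a
    :class:`StandardizedTable`, containing the biomass column's group
    means/sds) plus the per-row ``groups`` labels.
    """
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise KeyError(f"missing feature columns {missing}")
    X = features[list(model.features)].to_numpy(dtype=float)
    pred = X @ model.coefficients + model.intercept
    if group_stats is None:
        return pred
    if groups is None:
        raise ValueError("groups labels required for back-transform")
    out = np.empty_like(pred)
    for i, (p, grp) in enumerate(zip(pred, groups.itertuples(index=False, name=None))):
        stats = group_stats.loc[(*grp, biomass_col)]
        out[i] = stats["mean"] + stats["sd"] * p
    return out


def metrics(
    observed: np.ndarray, predicted: np.ndarray, r2_method: str = "pearson"
) -> dict[str, float]:
    """Accuracy summary: R-squared, Pearson, Spearman, RMSE.

    R-squared defaults to the squared Pearson correlation of observed vs
    predicted (affine-invariant); RMSE is in the units of the inputs. Zero
    variance in either vector yields NaN correlation markers.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        return {"r2": np.nan, "pearson": np.nan, "spearman": np.nan, "rmse": rmse}
    r = float(pearsonr(obs, pred).statistic)
    rho = float(spearmanr(obs, pred).statistic)
    if r2_method == "pearson":
        r2 = r**2
    elif r2_method == "ss":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / sst
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return {"r2": r2, "pearson": r, "spearman": rho, "rmse": rmse}
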