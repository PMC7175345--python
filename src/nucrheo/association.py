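"""Linking nucleus mechanics to lamin expression and chromatin state.

The analyses here operate on a conditions x features profile matrix
(lamin RNA/protein levels, fitted viscoelastic elements, chromatin
condensation scores) and reproduce the standard association toolkit:
per-feature z-score standardization across conditions, Pearson
correlation between expression and mechanical features, a two-component
PCA whose loading-sign pattern assigns features to co-clusters, and
log2 fold changes for condition contrasts.

All statistics are descriptive (no p-values / multiple-testing
correction): with ~5 conditions per profile the correlations are
exploratory summaries, not hypothesis tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "FoldChangeRecord",
    "zscore",
    "pearson_matrix",
    "pca_cluster",
    "PCAResult",
    "log2_fold_changes",
    "chromatin_scores",
    "combine_protein_levels",
]


@dataclass
class ProfileMatrix:
    """Features x conditions table with per-feature class tags.

    ``values`` is indexed by feature (rows) with conditions as columns;
    ``classes`` tags each feature as rna / protein / mechanics /
    chromatin.  Rows containing missing values are dropped (logged) at
    construction.
    """

    values: pd.DataFrame
    classes: pd.Series = field(default=None)  # type: ignore[assignment]
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.classes is None:
            self.classes = pd.Series("mechanics", index=self.values.index, name="class")
        if not self.classes.index.equals(self.values.index):
            self.classes = self.classes.reindex(self.values.index)
        missing = self.values.isna().any(axis=1)
        if missing.any():
            dropped = list(self.values.index[missing])
            logger.warning("dropping %d feature(s) with missing values: %s",
                           len(dropped), dropped)
            self.values = self.values.loc[~missing]
            self.classes = self.classes.loc[~missing]

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def subset(self, cls: str) -> "ProfileMatrix":
        """Rows belonging to one feature class."""
        mask = self.classes == cls
        return replace(self, values=self.values.loc[mask], classes=self.classes.loc[mask])


def zscore(profile: ProfileMatrix) -> ProfileMatrix:
    """Standardize every feature across conditions (sample sd, ddof=1).

    Zero-variance features cannot be standardized and are dropped with
    a warning.
    """
    v = profile.values
    if v.shape[1] < 3:
        raise ValueError("z-scores need at least 3 conditions per feature")
    sd = v.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping zero-variance feature(s): %s", list(v.index[~keep]))
    v = v.loc[keep]
    z = v.sub(v.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ProfileMatrix(values=z, classes=profile.classes.loc[keep], standardized=True)


def pearson_matrix(a: ProfileMatrix, b: ProfileMatrix) -> pd.DataFrame:
    """Pearson r between every feature of ``a`` and every feature of ``b``.

    Both profiles must share the same condition ordering; the result is
    an ``a``-features x ``b``-features frame with entries in [-1, 1].
    """
    if a.conditions != b.conditions:
        only_a = set(a.conditions) - set(b.conditions)
        only_b = set(b.conditions) - set(a.conditions)
        raise ValueError(
            "condition sets/order differ between profiles"
            + (f"; only in first: {sorted(only_a)}" if only_a else "")
            + (f"; only in second: {sorted(only_b)}" if only_b else "")
        )
    if len(a.conditions) < 3:
        raise ValueError("Pearson correlation needs at least 3 conditions")
    av, bv = a.values.to_numpy(float), b.values.to_numpy(float)
    az = (av - av.mean(1, keepdims=True)) / av.std(1, ddof=1, keepdims=True)
    bz = (bv - bv.mean(1, keepdims=True)) / bv.std(1, ddof=1, keepdims=True)
    r = az @ bz.T / (av.shape[1] - 1)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=a.features, columns=b.features)


@dataclass(frozen=True)
class PCAResult:
    """First two principal components of a standardized profile."""

    loadings: pd.DataFrame              # features x [PC1, PC2]
    scores: pd.DataFrame                # conditions x [PC1, PC2]
    explained_variance_ratio: np.ndarray

    def loading_signs(self) -> dict[str, str]:
        """Sign pattern of each feature's loadings, e.g. ``'+-'``."""
        return {
            feat: "".join("+" if v >= 0 else "-" for v in row)
            for feat, row in self.loadings.iterrows()
        }

    def nearest_features(self, feature: str, candidates: Sequence[str], k: int = 2) -> list[str]:
        """The ``k`` candidates closest to ``feature`` in the loading plane."""
        ref = self.loadings.loc[feature].to_numpy()
        dist = {c: float(np.linalg.norm(self.loadings.loc[c].to_numpy() - ref))
                for c in candidates}
        return sorted(dist, key=dist.get)[:k]


def pca_cluster(profile: ProfileMatrix, n_components: int = 2) -> PCAResult:
    """PCA of a standardized profile; conditions are the observations.

    Returns per-feature loadings on the first two components and the
    explained-variance fractions.  Features whose loadings share a sign
    pattern co-cluster in the loading plane.
    """
    if not profile.standardized:
        raise ValueError("pca_cluster expects a standardized (z-scored) profile")
    n_feat = len(profile.features)
    if n_feat < n_components:
        raise ValueError(f"need at least {n_components} features, got {n_feat}")
    # observations = conditions, variables = features
    X = profile.values.to_numpy(float).T
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(pca.components_.T, index=profile.features, columns=cols)
    return PCAResult(
        loadings=loadings,
        scores=pd.DataFrame(scores, index=profile.conditions, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass(frozen=True)
class FoldChangeRecord:
    """log2 ratio of one feature between two conditions."""

    feature: str
    numerator: str
    denominator: str
    log2_ratio: float


def log2_fold_changes(
    table: pd.DataFrame, contrasts: Sequence[tuple[str, str]]
) -> list[FoldChangeRecord]:
    """log2(numerator/denominator) per feature for each contrast.

    ``table`` is features x conditions with positive entries; a feature
    with a nonpositive value in either condition of a contrast is
    skipped with a warning.
    """
    records = []
    for num, den in contrasts:
        for cond in (num, den):
            if cond not in table.columns:
                raise KeyError(f"condition {cond!r} not present in table")
        for feat in table.index:
            a, b = float(table.at[feat, num]), float(table.at[feat, den])
            if a <= 0 or b <= 0:
                logger.warning("skipping %s (%s vs %s): nonpositive value", feat, num, den)
                continue
            records.append(FoldChangeRecord(feat, num, den, float(np.log2(a / b))))
    return records


def fold_change_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    """Tidy frame view of fold-change records."""
    return pd.DataFrame(
        [(r.feature, r.numerator, r.denominator, r.log2_ratio) for r in records],
        columns=["feature", "numerator", "denominator", "log2_ratio"],
    )


def chromatin_scores(
    scores: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, list[FoldChangeRecord]]:
    """Summarize blinded condensed-chromatin scores and their fold changes.

    ``scores`` is tidy with columns (condition, compartment, nucleus,
    evaluator, score); compartments are peripheral / nucleoplasmic.
    Scores are first averaged over evaluators within each nucleus, then
    over nuclei, giving a mean per condition per compartment; log2 fold
    changes are computed for the requested contrasts on those means.
    """
    required = {"condition", "compartment", "nucleus", "evaluator", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    per_nucleus = (
        scores.groupby(["condition", "compartment", "nucleus"], sort=False)["score"].mean()
    )
    means = per_nucleus.groupby(["condition", "compartment"], sort=False).mean().unstack(
        "compartment"
    )
    empty = means.isna().all(axis=1)
    if empty.any():
        logger.warning("excluding empty condition(s): %s", list(means.index[empty]))
        means = means.loc[~empty]
    records = log2_fold_changes(means.T, contrasts) if contrasts else []
    return means, records


def combine_protein_levels(
    measurements: pd.DataFrame, anchor: str = "WT"
) -> pd.DataFrame:
    """Consensus lamin protein level per condition across methods.

    ``measurements`` is tidy with columns (lamin, condition, method,
    level).  Each method's scale is normalized to its own anchor
    (default WT) value, then methods are averaged unweighted; a lamin
    measured by fewer methods in some condition averages over the
    available ones (logged).  Returns a lamins x conditions frame of
    consensus levels relative to the anchor condition.
    """
    required = {"lamin", "condition", "method", "level"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    pieces = []
    for (lamin, method), grp in measurements.groupby(["lamin", "method"], sort=False):
        ref = grp.loc[grp["condition"] == anchor, "level"]
        if ref.empty or (ref <= 0).any():
            raise ValueError(f"no positive {anchor} anchor for {lamin}/{method}")
        g = grp.copy()
        g["level"] = g["level"] / float(ref.mean())
        pieces.append(g)
    normalized = pd.concat(pieces)
    counts = normalized.groupby(["lamin", "condition"], sort=False)["method"].nunique()
    n_methods = measurements["method"].nunique()
    partial = counts[counts < n_methods]
    if not partial.empty:
        logger.warning("averaging over a subset of methods for: %s",
                       list(partial.index))
    consensus = (
        normalized.groupby(["lamin", "condition"], sort=False)["level"].mean().unstack("condition")
    )
    return consensus
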