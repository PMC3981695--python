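"""Unsupervised dive/bout typing: PCA + k-means + discriminant validation.

The classification engine mirrors the workflow long used for pinniped dive
typing: standardize the shape variables, compress them with a principal
components analysis keeping the leading components that explain at least
80 % of the variance, cluster the factor scores with k-means over a range
of candidate k, validate each solution by training a linear discriminant
on the cluster labels and scoring how many observations it reassigns to
their own cluster, then keep the most parsimonious solution.  The wiggle
count is collapsed to a wiggle-dive indicator and appended to the factor
scores as a categorical passthrough rather than entering the PCA.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut

from .dives import DEEP_THRESHOLD

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSolution",
    "fit_pca",
    "kmeans_scan",
    "validate_dfa",
    "select_parsimonious",
    "name_types",
    "classify_dives",
    "classify_bouts",
    "DIVE_VARIABLES",
    "BOUT_VARIABLES",
]

#: The eight numeric dive-shape variables entering the PCA.
DIVE_VARIABLES = [
    "max_depth",
    "duration",
    "bottom_time",
    "skew1",
    "skew2",
    "btd",
    "btm",
    "mdd",
]

#: The eight bout summary variables (no categorical passthrough).
BOUT_VARIABLES = [
    "n_dives",
    "mean_depth",
    "mean_duration",
    "mean_surface_interval",
    "bout_duration",
    "pct_time_at_depth",
    "pct_square",
    "pct_v",
]


@dataclass
class PCATransform:
    """Standardization plus fitted PCA with the retained component count."""

    variables: list[str]
    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray  # (n_components_total, n_variables)
    explained_variance_ratio_: np.ndarray
    n_components: int

    def transform(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = (
            table[self.variables].to_numpy(dtype=float)
            if isinstance(table, pd.DataFrame)
            else np.asarray(table, dtype=float)
        )
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_[: self.n_components].T

    def standardize(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = (
            table[self.variables].to_numpy(dtype=float)
            if isinstance(table, pd.DataFrame)
            else np.asarray(table, dtype=float)
        )
        return (X - self.mean_) / self.scale_


@dataclass
class ClusterSolution:
    """One fitted k-means solution with its validation accuracy."""

    k: int
    variables: list[str]
    pca: PCATransform
    centroids: np.ndarray  # in clustering space (PC scores + passthrough)
    labels: np.ndarray  # 1..k
    inertia: float
    seed: int
    passthrough: list[str] = field(default_factory=list)
    passthrough_scale: np.ndarray | None = None
    accuracy: float | None = None
    regularized: bool = False
    type_names: dict[int, str] | None = None
    empty_cluster_restarts: int = 0

    def to_json(self) -> str:
        def enc(x):
            return x.tolist() if isinstance(x, np.ndarray) else x

        payload = {
            "k": self.k,
            "variables": self.variables,
            "passthrough": self.passthrough,
            "passthrough_scale": enc(self.passthrough_scale),
            "mean": enc(self.pca.mean_),
            "scale": enc(self.pca.scale_),
            "components": enc(self.pca.components_),
            "explained_variance_ratio": enc(self.pca.explained_variance_ratio_),
            "n_components": self.pca.n_components,
            "centroids": enc(self.centroids),
            "labels": enc(self.labels),
            "inertia": self.inertia,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "regularized": self.regularized,
            "type_names": self.type_names,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClusterSolution":
        d = json.loads(text)
        pca = PCATransform(
            variables=d["variables"],
            mean_=np.array(d["mean"]),
            scale_=np.array(d["scale"]),
            components_=np.array(d["components"]),
            explained_variance_ratio_=np.array(d["explained_variance_ratio"]),
            n_components=d["n_components"],
        )
        return cls(
            k=d["k"],
            variables=d["variables"],
            pca=pca,
            centroids=np.array(d["centroids"]),
            labels=np.array(d["labels"], dtype=int),
            inertia=d["inertia"],
            seed=d["seed"],
            passthrough=d["passthrough"],
            passthrough_scale=(
                None
                if d["passthrough_scale"] is None
                else np.array(d["passthrough_scale"])
            ),
            accuracy=d["accuracy"],
            regularized=d["regularized"],
            type_names=(
                None
                if d["type_names"] is None
                else {int(k): v for k, v in d["type_names"].items()}
            ),
        )


def fit_pca(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    variance_target: float = 0.80,
) -> PCATransform:
    """Standardize and fit a PCA, retaining >= ``variance_target`` variance.

    Constant variables carry no information and are dropped with a logged
    warning.  The retained component count is the smallest m whose
    cumulative explained variance reaches the target.
    """
    if variables is None:
        variables = list(table.columns)
    X = table[variables].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than variables")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        logger.warning("dropping constant variables: %s", dropped)
        variables = [v for v, k in zip(variables, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    pca = PCA(svd_solver="full").fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    # tiny numerical slack so exactly-equal eigenvalue ties resolve as the
    # arithmetic (m/p >= target) dictates
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return PCATransform(
        variables=variables,
        mean_=mean,
        scale_=sd,
        components_=pca.components_,
        explained_variance_ratio_=pca.explained_variance_ratio_,
        n_components=m,
    )


def _clustering_matrix(
    scores: np.ndarray,
    passthrough: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray | None]:
    if passthrough is None:
        return scores, None
    P = np.atleast_2d(np.asarray(passthrough, dtype=float))
    if P.shape[0] != scores.shape[0]:
        P = P.T
    scale = P.std(axis=0)
    scale[scale == 0] = 1.0
    return np.column_stack([scores, P / scale]), scale


def kmeans_scan(
    table: pd.DataFrame,
    pca: PCATransform,
    k_range: tuple[int, int] = (4, 8),
    restarts: int = 25,
    seed: int = 0,
    passthrough: list[str] | None = None,
) -> list[ClusterSolution]:
    """Best-inertia k-means solution for each k in ``k_range`` (inclusive).

    Clustering operates on the retained PC scores; 0/1 categorical
    passthrough columns are scaled to unit variance and appended.  k-means
    uses k-means++ starts with ``restarts`` initializations and a fixed
    seed, so repeated runs are identical.
    """
    scores = pca.transform(table)
    P = (
        table[passthrough].to_numpy(dtype=float)
        if passthrough
        else None
    )
    F, p_scale = _clustering_matrix(scores, P)
    kmin, kmax = k_range
    if kmin < 2 or kmax >= len(table):
        raise ValueError("k_range must lie within [2, n-1]")
    solutions = []
    for k in range(kmin, kmax + 1):
        km = KMeans(
            n_clusters=k,
            n_init=restarts,
            random_state=seed,
            init="k-means++",
        ).fit(F)
        solutions.append(
            ClusterSolution(
                k=k,
                variables=pca.variables,
                pca=pca,
                centroids=km.cluster_centers_,
                labels=km.labels_ + 1,
                inertia=float(km.inertia_),
                seed=seed,
                passthrough=list(passthrough or []),
                passthrough_scale=p_scale,
            )
        )
    return solutions


def validate_dfa(
    solution: ClusterSolution,
    table: pd.DataFrame,
    leave_one_out: bool = False,
) -> float:
    """Discriminant-function validation accuracy (percent) of a solution.

    A linear discriminant classifier is trained on the cluster labels
    using the standardized original variables (plus any scaled categorical
    passthrough) and the accuracy is the share of observations whose
    discriminant reassignment matches their k-means label (resubstitution
    by default; leave-one-out by flag).  A singular pooled within-class
    covariance — e.g. a passthrough constant within every cluster — falls
    back to a ridge-regularized (shrinkage) discriminant, logged and
    flagged on the solution.
    """
    Z = solution.pca.standardize(table)
    if solution.passthrough:
        P = table[solution.passthrough].to_numpy(dtype=float)
        scale = solution.passthrough_scale
        O = np.column_stack([Z, P / scale])
    else:
        O = Z
    y = solution.labels
    # pooled within-class variance per feature; zero anywhere -> singular
    wvar = np.zeros(O.shape[1])
    for c in np.unique(y):
        sub = O[y == c]
        wvar += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    wvar /= len(O)
    singular = wvar.min() < 1e-10
    if singular:
        logger.warning(
            "singular within-class covariance at k=%d; ridge-regularized",
            solution.k,
        )
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        solution.regularized = True
    else:
        clf = LinearDiscriminantAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if leave_one_out:
            correct = 0
            for train, test in LeaveOneOut().split(O):
                pred = clf.fit(O[train], y[train]).predict(O[test])
                correct += int(pred[0] == y[test][0])
            acc = 100.0 * correct / len(O)
        else:
            clf.fit(O, y)
            acc = 100.0 * float((clf.predict(O) == y).mean())
    solution.accuracy = acc
    return acc


def select_parsimonious(
    solutions: list[ClusterSolution],
    tolerance: float = 1.0,
) -> ClusterSolution:
    """Fewest clusters among solutions within ``tolerance`` accuracy points
    of the best-validated solution."""
    if not solutions:
        raise ValueError("no solutions to select from")
    scored = [s for s in solutions if s.accuracy is not None]
    if not scored:
        raise ValueError("run validate_dfa before selection")
    best = max(s.accuracy for s in scored)
    eligible = [s for s in scored if s.accuracy >= best - tolerance]
    return min(eligible, key=lambda s: s.k)


def name_types(
    solution: ClusterSolution,
    table: pd.DataFrame,
    role: str,
) -> pd.DataFrame:
    """Interpretable names for each cluster; returns per-cluster summary.

    Dives: clusters are named by centroid shape (square when the mean BTD
    is at least 0.5, else V), depth class (deep when the mean max depth is
    at least 20 m) and wiggle occurrence.  Bouts: the cluster whose mean
    surface interval exceeds its mean dive duration is the haul-out /
    resting class (Type III); the rest are ordered by mean depth then
    duration — deepest and longest first (Type I), then Type II, ...
    """
    needed = {"dive": {"btd", "max_depth"}, "bout": {"mean_surface_interval"}}
    if role not in needed:
        raise ValueError("role must be 'dive' or 'bout'")
    if not needed[role] <= set(table.columns):
        raise ValueError(f"table lacks the variables of role '{role}'")
    df = table.copy()
    df["_label"] = solution.labels
    cent = df.groupby("_label").mean(numeric_only=True)
    names: dict[int, str] = {}
    if role == "dive":
        for lab, row in cent.iterrows():
            shape = "square" if row["btd"] >= 0.5 else "V"
            depth = "deep" if row["max_depth"] >= DEEP_THRESHOLD else "shallow"
            parts = [depth, shape]
            if "is_wiggle_dive" in cent.columns:
                parts.append(
                    "wiggle" if row["is_wiggle_dive"] >= 0.5 else "no-wiggle"
                )
            names[int(lab)] = " ".join(parts)
    else:
        resting = [
            int(lab)
            for lab, row in cent.iterrows()
            if row["mean_surface_interval"] > row.get("mean_duration", np.inf)
        ]
        foraging = [int(lab) for lab in cent.index if int(lab) not in resting]
        foraging.sort(
            key=lambda lab: (
                -cent.loc[lab, "mean_depth"],
                -cent.loc[lab, "bout_duration"],
            )
        )
        roman = ["I", "II", "IV", "V", "VI", "VII", "VIII"]
        for rank, lab in enumerate(foraging):
            names[lab] = roman[rank]
        resting.sort(key=lambda lab: -cent.loc[lab, "mean_surface_interval"])
        for lab in resting:
            names[lab] = "III"
    solution.type_names = names
    cent = cent.rename(index=names)
    cent.index.name = "type"
    return cent


def _classify(
    table: pd.DataFrame,
    variables: list[str],
    passthrough: list[str] | None,
    k_range: tuple[int, int],
    role: str,
    variance_target: float,
    restarts: int,
    seed: int,
    tolerance: float,
) -> tuple[pd.DataFrame, list[ClusterSolution], ClusterSolution]:
    pca = fit_pca(table, variables, variance_target)
    solutions = kmeans_scan(
        table, pca, k_range=k_range, restarts=restarts, seed=seed,
        passthrough=passthrough,
    )
    for s in solutions:
        validate_dfa(s, table)
    chosen = select_parsimonious(solutions, tolerance)
    name_types(chosen, table, role)
    labeled = table.copy()
    labeled["assigned_cluster"] = chosen.labels
    labeled["assigned_type"] = [chosen.type_names[l] for l in chosen.labels]
    return labeled, solutions, chosen


def classify_dives(
    dive_df: pd.DataFrame,
    k_range: tuple[int, int] = (4, 8),
    variance_target: float = 0.80,
    restarts: int = 25,
    seed: int = 0,
    tolerance: float = 1.0,
):
    """Full dive-typing pipeline; returns (labeled table, solutions, chosen)."""
    df = dive_df.copy()
    df["is_wiggle_dive"] = df["is_wiggle_dive"].astype(float)
    return _classify(
        df, DIVE_VARIABLES, ["is_wiggle_dive"], k_range, "dive",
        variance_target, restarts, seed, tolerance,
    )


def classify_bouts(
    bout_df: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    variance_target: float = 0.80,
    restarts: int = 25,
    seed: int = 0,
    tolerance: float = 1.0,
):
    """Full bout-typing pipeline; returns (labeled table, solutions, chosen)."""
    return _classify(
        bout_df, BOUT_VARIABLES, None, k_range, "bout",
        variance_target, restarts, seed, tolerance,
    )
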