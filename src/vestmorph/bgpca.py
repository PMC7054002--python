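"""Between-group PCA, fossil projection, classification, typicality, HCA.

Between-group PCA (bgPCA) eigendecomposes the covariance of the g group
mean vectors (not of individuals), then projects every specimen — and any
out-of-sample query such as a fossil — onto the resulting axes.  With g
groups there are at most g-1 informative axes; for the 4-clade anthropoid
design that is bgPC1-bgPC3.  Unlike discriminant analysis, bgPCA does not
rescale within-group variation, so it cannot manufacture spurious
separation in the same way when p >> n.

Group affinity of a query is summarised two ways:

* nearest-group-centroid assignment in bgPC space, cross-validated by
  leave-one-out (the classification percentages of a confusion matrix);
* typicality probabilities — the upper tail of chi-square(m) at the
  squared Mahalanobis distance from the query to each group centroid
  under the pooled within-group covariance of scores.  These do not sum
  to one across groups: a query may be atypical of every group (all
  p < 0.05), the expected outcome for a morphology outside the sampled
  variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .shapes import ShapeTable

__all__ = [
    "BetweenGroupPCA",
    "BetweenGroupPCAResults",
    "ClassificationResult",
    "fit_bgpca",
    "loo_classify",
    "typprob",
    "hca_confusion",
]


class BetweenGroupPCA:
    """Between-group PCA model for a labelled ShapeTable.

    Parameters
    ----------
    table:
        Specimen-by-descriptor table with group labels; every group needs
        at least one specimen (two for covariance-based follow-ups).
    n_components:
        Retained axes; defaults to g-1.
    """

    def __init__(self, table: ShapeTable, n_components: int | None = None):
        if table.p < 1:
            raise ValueError("need at least one descriptor")
        counts = table.df.groupby("group").size()
        if len(counts) < 2:
            raise ValueError("need at least two groups")
        if (counts == 0).any():
            raise ValueError("empty group")
        self.table = table
        self.group_labels = sorted(counts.index)
        g = len(self.group_labels)
        self.n_components = min(g - 1, table.p) if n_components is None else n_components
        if not 1 <= self.n_components <= min(g - 1, table.p):
            raise ValueError(f"n_components must lie in [1, {min(g - 1, table.p)}]")

    def fit(self) -> "BetweenGroupPCAResults":
        """Eigendecompose the (unweighted) covariance of group means."""
        X = self.table.X
        groups = self.table.groups.to_numpy()
        means = np.stack(
            [X[groups == gl].mean(axis=0) for gl in self.group_labels]
        )
        grand_mean = means.mean(axis=0)  # mean of group means, unweighted
        Mc = means - grand_mean
        g = len(self.group_labels)
        # economical eigendecomposition via SVD of the g x p centred means
        U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
        eigvals = s**2 / (g - 1)
        m = self.n_components
        eigvals = eigvals[:m]
        eigvecs = Vt[:m].T  # p x m, orthonormal
        # sign convention: the largest-magnitude loading of each axis is positive
        for j in range(m):
            col = eigvecs[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                eigvecs[:, j] = -col
        total = (s**2 / (g - 1)).sum()
        degenerate = total <= 1e-12 * max(1.0, float(np.abs(means).max()) ** 2)
        explained = eigvals / total if not degenerate else np.zeros_like(eigvals)
        scores = (X - grand_mean) @ eigvecs
        return BetweenGroupPCAResults(
            model=self,
            grand_mean=grand_mean,
            group_means=pd.DataFrame(
                means, index=self.group_labels, columns=self.table.descriptor_names
            ),
            eigenvalues=eigvals,
            eigenvectors=eigvecs,
            explained_var=explained,
            scores=self._score_frame(scores),
            degenerate=bool(degenerate),
        )

    def _score_frame(self, scores: np.ndarray) -> pd.DataFrame:
        cols = [f"bgPC{j + 1}" for j in range(scores.shape[1])]
        out = pd.DataFrame(scores, columns=cols)
        out.insert(0, "group", self.table.groups.to_numpy())
        out.insert(0, "species", self.table.species.to_numpy())
        out.insert(0, "specimen", self.table.specimens.to_numpy())
        return out


@dataclass
class BetweenGroupPCAResults:
    """Fitted bgPCA: basis, eigenvalues, per-specimen scores."""

    model: BetweenGroupPCA
    grand_mean: np.ndarray = field(repr=False)
    group_means: pd.DataFrame = field(repr=False)
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)
    explained_var: np.ndarray
    scores: pd.DataFrame = field(repr=False)
    degenerate: bool = False

    # -- projection ----------------------------------------------------

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.scores.columns if c.startswith("bgPC")]

    def project(self, queries: np.ndarray) -> np.ndarray:
        """Project descriptor rows a posteriori onto the fitted axes."""
        Q = np.atleast_2d(np.asarray(queries, dtype=float))
        if Q.shape[1] != self.grand_mean.shape[0]:
            raise ValueError(
                f"query has {Q.shape[1]} descriptors, model expects "
                f"{self.grand_mean.shape[0]}"
            )
        return (Q - self.grand_mean) @ self.eigenvectors

    def backproject(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct a descriptor row from (leading) bgPC scores.

        descriptor = grand mean + sum_j score_j * eigenvector_j.  With a
        landmark-provenance table the result reshapes to (k, 3).
        """
        s = np.asarray(scores, dtype=float).ravel()
        m = self.eigenvectors.shape[1]
        if s.size > m:
            raise ValueError(f"{s.size} scores but only {m} retained components")
        return self.grand_mean + self.eigenvectors[:, : s.size] @ s

    def backproject_landmarks(self, scores: np.ndarray) -> np.ndarray:
        if self.model.table.provenance != "landmark":
            raise ValueError("landmark back-projection needs landmark provenance")
        return self.backproject(scores).reshape(-1, 3)

    # -- group geometry in score space ---------------------------------

    def group_centroids(self) -> pd.DataFrame:
        return self.scores.groupby("group")[self.score_columns].mean()

    def pooled_within_cov(self, ridge: float = 0.0) -> np.ndarray:
        """Pooled within-group covariance of scores: sum of centred
        cross-products over (n - g); optional ridge eps * trace/m."""
        S = self.scores[self.score_columns].to_numpy()
        groups = self.scores["group"].to_numpy()
        n, m = S.shape
        g = len(self.model.group_labels)
        W = np.zeros((m, m))
        for gl in self.model.group_labels:
            sub = S[groups == gl]
            c = sub - sub.mean(axis=0)
            W += c.T @ c
        W /= n - g
        if ridge:
            W = W + ridge * np.trace(W) / m * np.eye(m)
        return W

    # -- classification ------------------------------------------------

    def loo_classify(self) -> "ClassificationResult":
        """Leave-one-out nearest-group-centroid classification in bgPC space.

        The eigenbasis is held fixed; only the left-out specimen's group
        centroid is recomputed without it.
        """
        counts = self.scores.groupby("group").size()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"leave-one-out needs >= 2 specimens per group; too small: "
                f"{sorted(small.index)}"
            )
        S = self.scores[self.score_columns].to_numpy()
        groups = self.scores["group"].to_numpy()
        labels = self.model.group_labels
        sums = {gl: S[groups == gl].sum(axis=0) for gl in labels}
        ns = {gl: int((groups == gl).sum()) for gl in labels}
        predicted = []
        for i in range(len(S)):
            best, best_d = None, np.inf
            for gl in labels:
                if gl == groups[i]:
                    cen = (sums[gl] - S[i]) / (ns[gl] - 1)
                else:
                    cen = sums[gl] / ns[gl]
                d = float(((S[i] - cen) ** 2).sum())
                if d < best_d:
                    best, best_d = gl, d
            predicted.append(best)
        predicted = pd.Series(predicted, name="predicted")
        conf = pd.crosstab(pd.Series(groups, name="true"), predicted)
        conf = conf.reindex(index=labels, columns=labels, fill_value=0).astype(float)
        conf = conf.div(conf.sum(axis=1), axis=0) * 100.0
        accuracy = float((predicted.to_numpy() == groups).mean() * 100.0)
        return ClassificationResult(
            confusion=conf, predicted=predicted, accuracy=accuracy
        )

    def refit_loo_classify(self) -> "ClassificationResult":
        """Leave-one-out with the bgPCA basis refit in every fold (slow path)."""
        table = self.model.table
        labels = self.model.group_labels
        predicted = []
        for i in range(table.n):
            mask = np.ones(table.n, dtype=bool)
            mask[i] = False
            sub = table.subset(mask)
            res = BetweenGroupPCA(sub, self.model.n_components).fit()
            s = res.project(table.X[i])[0]
            cents = res.group_centroids()
            d = ((cents.to_numpy() - s) ** 2).sum(axis=1)
            predicted.append(cents.index[int(np.argmin(d))])
        groups = table.groups.to_numpy()
        predicted = pd.Series(predicted, name="predicted")
        conf = pd.crosstab(pd.Series(groups, name="true"), predicted)
        conf = conf.reindex(index=labels, columns=labels, fill_value=0).astype(float)
        conf = conf.div(conf.sum(axis=1), axis=0) * 100.0
        accuracy = float((predicted.to_numpy() == groups).mean() * 100.0)
        return ClassificationResult(
            confusion=conf, predicted=predicted, accuracy=accuracy
        )

    def typprob(
        self,
        query_scores: np.ndarray,
        method: str = "chisq",
        ridge: float = 0.0,
    ) -> pd.DataFrame:
        """Typicality probability of each query score vector for each group.

        d2 is the squared Mahalanobis distance to the group centroid under
        the pooled within-group covariance; ``method="chisq"`` (default)
        takes the chi-square(m) upper tail at d2, ``method="f"`` the
        small-sample F tail for a new observation.  p < 0.05 reads as the
        query falling outside that group's sampled variability.
        """
        Q = np.atleast_2d(np.asarray(query_scores, dtype=float))
        m = len(self.score_columns)
        if Q.shape[1] != m:
            raise ValueError(f"queries must have {m} score columns")
        W = self.pooled_within_cov(ridge=ridge)
        try:
            Winv = np.linalg.inv(W)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled within-group covariance; pass ridge > 0"
            ) from exc
        cents = self.group_centroids()
        counts = self.scores.groupby("group").size()
        n, g = len(self.scores), len(cents)
        out = {}
        for gl, cen in cents.iterrows():
            diff = Q - cen.to_numpy()
            d2 = np.einsum("ij,jk,ik->i", diff, Winv, diff)
            if method == "chisq":
                p = stats.chi2.sf(d2, df=m)
            elif method == "f":
                nu = n - g
                nk = counts[gl]
                f = d2 * (nu - m + 1) / (nu * m * (1 + 1 / nk))
                p = stats.f.sf(f, m, nu - m + 1)
            else:
                raise ValueError("method must be 'chisq' or 'f'")
            out[gl] = p
        return pd.DataFrame(out, index=[f"query{i}" for i in range(len(Q))])

    def mahalanobis_d2(self, query_scores: np.ndarray, ridge: float = 0.0) -> pd.DataFrame:
        Q = np.atleast_2d(np.asarray(query_scores, dtype=float))
        W = self.pooled_within_cov(ridge=ridge)
        Winv = np.linalg.inv(W)
        out = {}
        for gl, cen in self.group_centroids().iterrows():
            diff = Q - cen.to_numpy()
            out[gl] = np.einsum("ij,jk,ik->i", diff, Winv, diff)
        return pd.DataFrame(out, index=[f"query{i}" for i in range(len(Q))])

    def summary(self) -> str:
        lines = ["Between-group PCA", "=" * 40]
        lines.append(f"groups: {', '.join(self.model.group_labels)}")
        lines.append(f"specimens: {len(self.scores)}  descriptors: {len(self.grand_mean)}")
        if self.degenerate:
            lines.append("WARNING: degenerate model (all group means coincide)")
        for j, (ev, fr) in enumerate(zip(self.eigenvalues, self.explained_var)):
            lines.append(f"bgPC{j + 1}: eigenvalue {ev:.4g}  ({fr * 100:.2f}% of variance)")
        return "\n".join(lines)


@dataclass
class ClassificationResult:
    """Row-normalised confusion matrix (%), per-specimen predictions, accuracy (%)."""

    confusion: pd.DataFrame
    predicted: pd.Series = field(repr=False)
    accuracy: float = 0.0

    def summary(self) -> str:
        lines = ["Cross-validated classification (%)", "=" * 40]
        lines.append(self.confusion.round(1).to_string())
        lines.append(f"overall accuracy: {self.accuracy:.1f}%")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spec-surface convenience wrappers
# ---------------------------------------------------------------------------


def fit_bgpca(table: ShapeTable, n_components: int | None = None) -> BetweenGroupPCAResults:
    return BetweenGroupPCA(table, n_components=n_components).fit()


def loo_classify(
    table: ShapeTable, n_components: int | None = None, refit: bool = False
) -> ClassificationResult:
    res = fit_bgpca(table, n_components=n_components)
    return res.refit_loo_classify() if refit else res.loo_classify()


def typprob(
    results: BetweenGroupPCAResults,
    query_scores: np.ndarray,
    method: str = "chisq",
    ridge: float = 0.0,
) -> pd.DataFrame:
    return results.typprob(query_scores, method=method, ridge=ridge)


def hca_confusion(
    table: ShapeTable,
    g: int | None = None,
    method: str = "ward",
    metric: str = "euclidean",
) -> pd.Series:
    """Group-recovery probabilities from hierarchical clustering.

    Agglomerative clustering (Ward linkage on Euclidean distances by
    default; the linkage is configurable because published analyses often
    leave it unstated) of the specimen descriptors, cut at ``g`` clusters.
    Each cluster is labelled by its majority group; the return value is the
    per-group percentage of members sitting in a cluster of their own label.
    """
    groups = table.groups.to_numpy()
    labels = sorted(set(groups))
    if g is None:
        g = len(labels)
    if table.n < g:
        raise ValueError(f"need at least g={g} specimens, have {table.n}")
    Z = linkage(table.X, method=method, metric=metric)
    clusters = fcluster(Z, t=g, criterion="maxclust")
    cluster_label = {}
    for c in np.unique(clusters):
        members = groups[clusters == c]
        vals, counts = np.unique(members, return_counts=True)
        cluster_label[c] = vals[np.argmax(counts)]
    assigned = np.array([cluster_label[c] for c in clusters])
    out = {}
    for gl in labels:
        mask = groups == gl
        out[gl] = float((assigned[mask] == gl).mean() * 100.0)
    return pd.Series(out, name="correct_percent")
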