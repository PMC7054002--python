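"""Ancestral-state reconstruction under Brownian motion and phylomorphospace.

Under BM the tip values and the internal-node states are jointly
multivariate normal, with covariance given by shared path lengths from
the root.  The maximum-likelihood estimate of every internal state is
therefore the conditional expectation of that joint normal given the
tips, with the (GLS) phylogenetic mean as the unconditional mean.  This
module computes that conditioning exactly (dense linear algebra; the
trees involved have tens of tips), trait by trait.

A phylomorphospace is the tree drawn through an ordination scatter: tips
sit at their (e.g. bgPC1/bgPC2) scores, internal nodes at their ML
reconstructions, and edges mirror the phylogeny, so branch length and
orientation in the plot show the inferred direction of shape change.
Ancestral scores can be pushed back through the ordination basis to a
descriptor vector (and a landmark configuration when the descriptors are
flattened landmarks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bgpca import BetweenGroupPCAResults
from .trees import PhyloTree

__all__ = [
    "AncestralStates",
    "Phylomorphospace",
    "ml_ancestral",
    "build_phylomorphospace",
    "backproject",
]


@dataclass
class AncestralStates:
    """Per-internal-node ML estimates and estimation variances, per trait."""

    estimates: pd.DataFrame  # internal nodes x traits
    variances: pd.DataFrame = field(repr=False)
    sigma2: pd.Series = field(repr=False)  # ML BM rate per trait

    @property
    def node_ids(self) -> list[str]:
        return list(self.estimates.index)

    def write(self, path) -> None:
        long = (
            self.estimates.stack()
            .rename("estimate")
            .to_frame()
            .join(self.variances.stack().rename("variance"))
        )
        long.index.names = ["node", "trait"]
        long.reset_index().to_csv(path, sep="\t", index=False)


def ml_ancestral(tree: PhyloTree, tip_values) -> AncestralStates:
    """ML internal-node states under BM via joint-MVN conditioning.

    ``tip_values`` is a Series (one trait) or DataFrame (tips x traits)
    indexed by tip name.  Traits are processed independently.  The root
    estimate equals the phylogenetic GLS mean of the tips; variances are
    GLS prediction variances (they include the uncertainty of the
    estimated mean, so the root variance is positive).
    """
    if isinstance(tip_values, pd.Series):
        df = tip_values.to_frame(name=tip_values.name or "trait")
    else:
        df = pd.DataFrame(tip_values)
    labels, C, is_tip = tree.full_covariance()
    tip_labels = [l for l, t in zip(labels, is_tip) if t]
    missing = sorted(set(tip_labels) - set(df.index))
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    # zero-length pendant edges duplicate covariance rows -> singular system
    tab = tree.node_table()
    for i, (lab, tip) in enumerate(zip(tab.labels, tab.is_tip)):
        if tip and tab.length[i] == 0:
            raise ValueError(f"zero-length terminal branch above tip {lab!r}")

    Y = df.loc[tip_labels].to_numpy(dtype=float)
    tip_idx = np.where(is_tip)[0]
    node_idx = np.where(~is_tip)[0]
    node_labels = [labels[i] for i in node_idx]
    Cyy = C[np.ix_(tip_idx, tip_idx)]
    Czy = C[np.ix_(node_idx, tip_idx)]
    Czz = C[np.ix_(node_idx, node_idx)]
    n = len(tip_idx)
    ones = np.ones(n)
    Cyy_inv = np.linalg.inv(Cyy)
    s1 = ones @ Cyy_inv @ ones
    A = Czy @ Cyy_inv  # conditioning weights, nodes x tips

    a_hat = (ones @ Cyy_inv @ Y) / s1  # GLS mean per trait
    est = a_hat + A @ (Y - a_hat)  # nodes x traits
    resid = Y - a_hat
    # BM rate with the conventional n-1 denominator (REML-style scaling)
    sigma2 = np.einsum("it,ij,jt->t", resid, Cyy_inv, resid) / (n - 1)

    # GLS prediction variance: conditional variance + mean-estimation term
    cond = np.diag(Czz - A @ Czy.T)
    mean_term = (1.0 - A @ ones) ** 2 / s1
    var_unit = np.clip(cond + mean_term, 0.0, None)
    variances = np.outer(var_unit, sigma2)

    traits = list(df.columns)
    return AncestralStates(
        estimates=pd.DataFrame(est, index=node_labels, columns=traits),
        variances=pd.DataFrame(variances, index=node_labels, columns=traits),
        sigma2=pd.Series(sigma2, index=traits, name="sigma2"),
    )


@dataclass
class Phylomorphospace:
    """Tree projected into a 2D ordination: node coordinates plus edges."""

    coords: pd.DataFrame  # node, axis columns, is_tip
    edges: list[tuple[str, str]]
    axes: tuple[str, str]

    def write(self, path) -> None:
        self.coords.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, tip_labels: bool = True):
        """Draw the phylomorphospace (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        xy = self.coords.set_index("node")[list(self.axes)]
        for parent, child in self.edges:
            seg = xy.loc[[parent, child]]
            ax.plot(seg.iloc[:, 0], seg.iloc[:, 1], color="0.6", lw=1, zorder=1)
        tips = self.coords[self.coords["is_tip"]]
        internals = self.coords[~self.coords["is_tip"]]
        ax.scatter(tips[self.axes[0]], tips[self.axes[1]], s=30, zorder=2)
        ax.scatter(
            internals[self.axes[0]], internals[self.axes[1]],
            s=15, marker="s", color="0.3", zorder=2,
        )
        if tip_labels:
            for _, row in tips.iterrows():
                ax.annotate(
                    row["node"], (row[self.axes[0]], row[self.axes[1]]),
                    fontsize=6, xytext=(2, 2), textcoords="offset points",
                )
        ax.set_xlabel(self.axes[0])
        ax.set_ylabel(self.axes[1])
        return ax


def build_phylomorphospace(tree: PhyloTree, scores: pd.DataFrame) -> Phylomorphospace:
    """Project the tree into an ordination plane.

    ``scores`` is a tips x 2 DataFrame (index = tip names, columns = the
    two ordination axes).  Tip coordinates are taken verbatim; internal
    nodes sit at their ML ancestral estimates per axis.
    """
    if scores.shape[1] != 2:
        raise ValueError("scores must have exactly two axis columns")
    missing = sorted(set(tree.tip_names) - set(scores.index))
    if missing:
        raise ValueError(f"missing tip scores for: {missing}")
    anc = ml_ancestral(tree, scores)
    axes = tuple(scores.columns)
    tab = tree.node_table()
    rows = []
    for lab, tip in zip(tab.labels, tab.is_tip):
        src = scores.loc[lab] if tip else anc.estimates.loc[lab]
        rows.append(
            {"node": lab, axes[0]: float(src[axes[0]]), axes[1]: float(src[axes[1]]),
             "is_tip": bool(tip)}
        )
    edges = [
        (tab.labels[tab.parent[i]], tab.labels[i])
        for i in range(len(tab.labels))
        if tab.parent[i] >= 0
    ]
    return Phylomorphospace(coords=pd.DataFrame(rows), edges=edges, axes=axes)


def backproject(results: BetweenGroupPCAResults, scores) -> np.ndarray:
    """Rotate/translate ordination scores back into descriptor space.

    descriptor = grand mean + Σ score_j · eigenvector_j.  For a
    landmark-provenance model use
    :meth:`BetweenGroupPCAResults.backproject_landmarks` to get (k, 3)
    coordinates.
    """
    return results.backproject(scores)
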