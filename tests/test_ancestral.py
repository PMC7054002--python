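"""Ancestral reconstruction: closed forms, re-rooted GLS oracle, phytools check."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from vestmorph import (
    SimConfig,
    build_phylomorphospace,
    fit_bgpca,
    ml_ancestral,
    parse_newick,
    simulate_bm,
    simulate_shape_sample,
)
from vestmorph.ancestral import backproject
from vestmorph.phylosignal import gls_mean

from conftest import random_tree


def rerooted_gls_oracle(tree, y: pd.Series) -> pd.DataFrame:
    """Independent route: each node's state is the GLS mean of the tips
    under the covariance of the tree re-rooted at that node, computed from
    patristic distances alone."""
    labels, C, is_tip = tree.full_covariance()
    depth = np.diag(C)
    D = depth[:, None] + depth[None, :] - 2 * C  # patristic distances
    tip_idx = np.where(is_tip)[0]
    yv = y.reindex([labels[i] for i in tip_idx]).to_numpy()
    out = {}
    for v in np.where(~is_tip)[0]:
        dv = D[v, tip_idx]
        Cv = 0.5 * (dv[:, None] + dv[None, :] - D[np.ix_(tip_idx, tip_idx)])
        np.fill_diagonal(Cv, dv)
        Ci = np.linalg.inv(Cv)
        ones = np.ones(len(tip_idx))
        out[labels[v]] = float((ones @ Ci @ yv) / (ones @ Ci @ ones))
    return pd.Series(out)


class TestMlAncestral:
    def test_constant_tips_constant_nodes(self, anthropoid_tree):
        y = pd.Series(3.14, index=anthropoid_tree.tip_names)
        # constant traits have zero rate: estimates equal the constant,
        # variances collapse to zero but stay non-negative
        anc = ml_ancestral(anthropoid_tree, y)
        assert np.allclose(anc.estimates.to_numpy(), 3.14)
        assert (anc.variances.to_numpy() >= 0).all()

    def test_two_tip_inverse_variance_weighting(self):
        t = parse_newick("(A:1,B:3);")
        anc = ml_ancestral(t, pd.Series({"A": 1.0, "B": 5.0}))
        expected = (1.0 / 1 + 5.0 / 3) / (1 / 1 + 1 / 3)
        assert anc.estimates.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_matches_rerooted_gls_oracle_on_random_trees(self, rng):
        for _ in range(25):
            t = random_tree(rng, int(rng.integers(4, 11)))
            tips, _ = simulate_bm(t, 1.0, [0.0], seed=int(rng.integers(2**31)))
            y = tips["d0"]
            anc = ml_ancestral(t, y)
            oracle = rerooted_gls_oracle(t, y)
            diff = (anc.estimates["d0"] - oracle.reindex(anc.estimates.index)).abs()
            assert diff.max() < 1e-8

    def test_root_equals_gls_mean(self, anthropoid_tree):
        tips, _ = simulate_bm(anthropoid_tree, 1.0, [0.0], seed=55)
        y = tips["d0"]
        anc = ml_ancestral(anthropoid_tree, y)
        a = gls_mean(
            anthropoid_tree.covariance(list(y.index)), y.to_numpy()
        )
        assert anc.estimates.iloc[0, 0] == pytest.approx(a, abs=1e-8)

    def test_linearity_in_tip_values(self, anthropoid_tree, rng):
        y = pd.Series(rng.standard_normal(27), index=anthropoid_tree.tip_names)
        a1 = ml_ancestral(anthropoid_tree, y).estimates
        a2 = ml_ancestral(anthropoid_tree, 2.5 * y + 7.0).estimates
        assert np.abs(2.5 * a1.to_numpy() + 7.0 - a2.to_numpy()).max() < 1e-8

    def test_zero_length_pendant_rejected(self):
        t = parse_newick("((A:0,B:1):1,C:2);")
        with pytest.raises(ValueError, match="A"):
            ml_ancestral(t, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}))

    def test_missing_tip_value_rejected(self, anthropoid_tree):
        y = pd.Series(1.0, index=anthropoid_tree.tip_names[:-1])
        y.loc["extra"] = 2.0
        with pytest.raises(ValueError, match="missing tip"):
            ml_ancestral(anthropoid_tree, y)

    def test_matches_r_fastanc(self, anthropoid_tree, tmp_path):
        """Independent oracle: phytools::fastAnc estimates and variances."""
        tips, _ = simulate_bm(anthropoid_tree, 1.0, [0.0], seed=99)
        y = tips["d0"]
        (tmp_path / "tree.nwk").write_text(anthropoid_tree.to_newick())
        y.to_csv(tmp_path / "y.csv")
        script = (
            "suppressMessages({library(ape); library(phytools)});"
            f'tree <- read.tree("{tmp_path}/tree.nwk");'
            f'tr <- read.csv("{tmp_path}/y.csv", row.names=1);'
            "y <- setNames(tr[,1], rownames(tr));"
            "fa <- fastAnc(tree, y, vars=TRUE);"
            'write.csv(data.frame(est=fa$ace, var=fa$var), stdout(), row.names=FALSE)'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        lines = [l for l in out.stdout.splitlines() if "," in l]
        ref = pd.DataFrame(
            [list(map(float, l.split(","))) for l in lines[1:]], columns=["est", "var"]
        )
        anc = ml_ancestral(anthropoid_tree, y)
        # ape numbers internal nodes in the same preorder as the written newick
        assert np.abs(anc.estimates["d0"].to_numpy() - ref["est"].to_numpy()).max() < 1e-6
        assert np.abs(anc.variances["d0"].to_numpy() - ref["var"].to_numpy()).max() < 1e-6

    def test_mse_decreases_with_shorter_pendants(self):
        """Shorter terminal branches pin internal states down more tightly."""
        base = "((A:{b},B:{b}):1,(C:{b},D:{b}):1);"
        mses = []
        for b in (2.0, 1.0, 0.25):
            t = parse_newick(base.format(b=b))
            errs = []
            for rep in range(300):
                tips, truth = simulate_bm(t, 1.0, [0.0], seed=60_000 + rep)
                anc = ml_ancestral(t, tips["d0"])
                true_states = truth.internal_states["d0"]
                errs.append(
                    ((anc.estimates["d0"] - true_states.reindex(anc.estimates.index)) ** 2).mean()
                )
            mses.append(np.mean(errs))
        assert mses[0] > mses[1] > mses[2]


class TestPhylomorphospace:
    def test_two_tip_root_weighted_mean(self):
        t = parse_newick("(A:1,B:3);")
        scores = pd.DataFrame(
            {"bgPC1": [0.0, 4.0], "bgPC2": [1.0, 1.0]}, index=["A", "B"]
        )
        pms = build_phylomorphospace(t, scores)
        root = pms.coords[~pms.coords["is_tip"]].iloc[0]
        w = np.array([1 / 1, 1 / 3])
        assert root["bgPC1"] == pytest.approx((w @ [0.0, 4.0]) / w.sum())
        assert root["bgPC2"] == pytest.approx(1.0)

    def test_tips_verbatim_and_edges_mirror_tree(self, anthropoid_tree, rng):
        scores = pd.DataFrame(
            rng.standard_normal((27, 2)), index=anthropoid_tree.tip_names,
            columns=["bgPC1", "bgPC2"],
        )
        pms = build_phylomorphospace(anthropoid_tree, scores)
        tips = pms.coords[pms.coords["is_tip"]].set_index("node")
        assert np.allclose(
            tips.loc[scores.index, ["bgPC1", "bgPC2"]].to_numpy(), scores.to_numpy()
        )
        assert len(pms.edges) == len(pms.coords) - 1

    def test_affine_equivariance(self, anthropoid_tree, rng):
        scores = pd.DataFrame(
            rng.standard_normal((27, 2)), index=anthropoid_tree.tip_names,
            columns=["a1", "a2"],
        )
        p1 = build_phylomorphospace(anthropoid_tree, scores)
        p2 = build_phylomorphospace(anthropoid_tree, scores * 3.0 - 2.0)
        c1 = p1.coords[["a1", "a2"]].to_numpy()
        c2 = p2.coords[["a1", "a2"]].to_numpy()
        assert np.abs(3.0 * c1 - 2.0 - c2).max() < 1e-8

    def test_identical_tips_collapse(self, anthropoid_tree):
        scores = pd.DataFrame(
            np.ones((27, 2)), index=anthropoid_tree.tip_names, columns=["x", "y"]
        )
        pms = build_phylomorphospace(anthropoid_tree, scores)
        assert np.allclose(pms.coords[["x", "y"]].to_numpy(), 1.0)

    def test_plot_runs(self, anthropoid_tree, rng, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        scores = pd.DataFrame(
            rng.standard_normal((27, 2)), index=anthropoid_tree.tip_names,
            columns=["bgPC1", "bgPC2"],
        )
        ax = build_phylomorphospace(anthropoid_tree, scores).plot()
        assert ax is not None


class TestBackprojection:
    def test_zero_scores_give_grand_mean(self):
        table, _ = simulate_shape_sample(SimConfig(seed=21))
        res = fit_bgpca(table)
        assert np.allclose(backproject(res, np.zeros(3)), res.grand_mean)

    def test_project_backproject_consistency(self):
        table, _ = simulate_shape_sample(SimConfig(seed=22))
        res = fit_bgpca(table)
        x = table.X[5]
        s = res.project(x)[0]
        recon = backproject(res, s)
        # reconstruction restores everything within the bgPC span
        resid = x - recon
        assert np.abs(res.eigenvectors.T @ resid).max() < 1e-8

    def test_landmark_backprojection_shape(self):
        table, _ = simulate_shape_sample(SimConfig(seed=23, landmark_mode=True))
        res = fit_bgpca(table)
        lm = res.backproject_landmarks(np.array([0.1, -0.2]))
        assert lm.shape == (45, 3)
        assert np.all(np.isfinite(lm))

    def test_too_many_scores_rejected(self):
        table, _ = simulate_shape_sample(SimConfig(seed=24))
        res = fit_bgpca(table)
        with pytest.raises(ValueError, match="retained"):
            backproject(res, np.zeros(10))
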