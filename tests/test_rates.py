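"""Ancestral states, branch rates, contrasts and joint-increase flags."""

import numpy as np
import pandas as pd
import pytest

import phylolat as pl


def _node_paths(tree):
    parent = {br.child: br.parent for br in tree.branches()}
    paths = {}
    for node in tree.node_ids:
        p, cur = [node], node
        while cur in parent:
            cur = parent[cur]
            p.append(cur)
        paths[node] = p[::-1]
    return paths


def conditional_expectation_oracle(tree, trait):
    """BM ancestral states as the Gaussian conditional expectation from the
    full (all-node) tree covariance, centered at the GLS root estimate."""
    depth = tree.depths()
    paths = _node_paths(tree)
    nodes = tree.node_ids
    tips = tree.tips

    def mrca_depth(u, v):
        shared = None
        for a, b in zip(paths[u], paths[v]):
            if a == b:
                shared = a
            else:
                break
        return depth[shared]

    C = pd.DataFrame(
        [[mrca_depth(u, v) for v in nodes] for u in nodes], index=nodes, columns=nodes
    )
    Ctt = C.loc[tips, tips].to_numpy()
    Cti = np.linalg.inv(Ctt)
    one = np.ones(len(tips))
    x = trait.loc[tips].to_numpy()
    mu = (one @ Cti @ x) / (one @ Cti @ one)
    est = mu + C.loc[nodes, tips].to_numpy() @ Cti @ (x - mu)
    return pd.Series(est, index=nodes)


class TestAncestralBM:
    def test_two_tip_root_is_mean(self):
        t = pl.read_newick("(A:10,B:10);")
        st = pl.ancestral_bm(t, pd.Series({"A": 0.0, "B": 1.0}))
        assert st.states.loc[t.root_id] == pytest.approx(0.5)

    def test_constant_trait_is_conserved(self, tree):
        st = pl.ancestral_bm(tree, pd.Series(2.5, index=tree.tips))
        assert np.allclose(st.states, 2.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_conditional_expectation_oracle(self, random_tree, seed):
        t = random_tree(seed, n_tips=8)
        rng = np.random.default_rng(seed)
        trait = pd.Series(rng.normal(size=8), index=t.tips)
        st = pl.ancestral_bm(t, trait)
        oracle = conditional_expectation_oracle(t, trait)
        assert np.allclose(st.states.loc[oracle.index], oracle, atol=1e-8)

    def test_missing_tip_value_rejected(self, tree):
        with pytest.raises(ValueError, match="missing"):
            pl.ancestral_bm(tree, pd.Series({"Homo_sapiens": 1.0}))


class TestAncestralAP:
    def test_unit_multipliers_reduce_to_bm(self, random_tree):
        t = random_tree(5, n_tips=8)
        rng = np.random.default_rng(5)
        trait = pd.Series(rng.normal(size=8), index=t.tips)
        ones = pd.Series(1.0, index=[br.id for br in t.branches()])
        ap = pl.ancestral_ap(t, trait, pin_multipliers=ones)
        bm = pl.ancestral_bm(t, trait)
        assert np.allclose(ap.states, bm.states.loc[ap.states.index], atol=1e-10)

    def test_displaced_tip_receives_largest_rate_multiplier(self):
        t = pl.read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1.5,F:1.5):1.5);"
        )
        trait = pd.Series(0.0, index=t.tips)
        trait["D"] = 5.0
        ap = pl.ancestral_ap(t, trait)
        assert ap.multipliers.idxmax() == "D"

    def test_constant_trait_gives_unit_multipliers(self, tree):
        ap = pl.ancestral_ap(tree, pd.Series(1.0, index=tree.tips))
        assert np.allclose(ap.states, 1.0)
        assert np.allclose(ap.multipliers, 1.0)

    def test_multipliers_average_one(self, tree, table):
        ap = pl.ancestral_ap(tree, table["log_pch"])
        assert ap.multipliers.mean() == pytest.approx(1.0)
        assert (ap.multipliers > 0).all()


class TestBranchChanges:
    def test_two_tip_rates(self):
        t = pl.read_newick("(A:10,B:10);")
        st = pl.ancestral_bm(t, pd.Series({"A": 0.0, "B": 1.0}))
        bc = pl.branch_changes(st, t)
        assert bc.loc["A", "rate"] == pytest.approx(-0.05)
        assert bc.loc["B", "rate"] == pytest.approx(0.05)

    def test_zero_change_zero_rate(self):
        t = pl.read_newick("(A:10,B:10);")
        st = pl.ancestral_bm(t, pd.Series({"A": 1.0, "B": 1.0}))
        bc = pl.branch_changes(st, t)
        assert (bc["rate"] == 0).all()

    @pytest.mark.parametrize("seed", [3, 4])
    def test_changes_telescope_along_root_to_tip_paths(self, random_tree, seed):
        t = random_tree(seed, n_tips=10)
        rng = np.random.default_rng(seed)
        trait = pd.Series(rng.normal(size=10), index=t.tips)
        st = pl.ancestral_bm(t, trait)
        bc = pl.branch_changes(st, t)
        paths = _node_paths(t)
        for tip in t.tips:
            total = sum(bc.loc[b, "delta"] for b in paths[tip][1:])
            assert total == pytest.approx(
                trait[tip] - st.states.loc[t.root_id], abs=1e-10
            )

    def test_zero_duration_branch_with_change_rejected(self):
        t = pl.read_newick("((A:0.0,B:1):1,C:2);")
        states = pl.AncestralStates(
            states=pd.Series({n: float(i) for i, n in enumerate(t.node_ids)}),
            model="bm",
        )
        with pytest.raises(ValueError, match="zero-duration"):
            pl.branch_changes(states, t)


class TestRobContrast:
    @pytest.fixture
    def tables(self, tree, table):
        rob = pl.branch_changes(pl.ancestral_bm(tree, table["log_rob"]), tree)
        pch = pl.branch_changes(pl.ancestral_bm(tree, table["log_pch"]), tree)
        return pch, rob

    def test_rob_against_itself_is_zero(self, tables):
        _, rob = tables
        out = pl.rob_contrast(rob, rob, beta=1.0)
        assert out["contrast"].abs().max() < 1e-12

    def test_beta_zero_reduces_to_own_rate(self, tables):
        pch, rob = tables
        out = pl.rob_contrast(pch, rob, beta=0.0)
        assert np.allclose(out["contrast"], pch["rate"])

    def test_exact_allometry_gives_zero_contrast(self, tree, table):
        rob = pl.branch_changes(pl.ancestral_bm(tree, table["log_rob"]), tree)
        fake = pl.branch_changes(
            pl.ancestral_bm(tree, 1.7 * table["log_rob"] + 0.4), tree
        )
        out = pl.rob_contrast(fake, rob, beta=1.7)
        assert out["contrast"].abs().max() < 1e-10

    def test_mismatched_trees_rejected(self, tables, random_tree):
        pch, _ = tables
        other = random_tree(0, n_tips=8)
        rng = np.random.default_rng(0)
        rob2 = pl.branch_changes(
            pl.ancestral_bm(other, pd.Series(rng.normal(size=8), index=other.tips)),
            other,
        )
        with pytest.raises(ValueError, match="different trees"):
            pl.rob_contrast(pch, rob2, beta=1.0)


class TestJointIncreaseAndShift:
    def test_all_zero_contrasts_yield_no_flags(self, tree):
        branches = [br.id for br in tree.branches()]
        z = pd.Series(0.0, index=branches)
        assert not pl.classify_joint_increase(z, z).any()

    def test_single_joint_signal_is_the_only_flag(self, tree):
        branches = [br.id for br in tree.branches()]
        rng = np.random.default_rng(1)
        a = pd.Series(rng.normal(0, 0.01, len(branches)), index=branches)
        b = pd.Series(rng.normal(0, 0.01, len(branches)), index=branches)
        a["Hominoidea"] += 1.0
        b["Hominoidea"] += 1.0
        flags = pl.classify_joint_increase(a, b, q=0.75)
        # the spiked branch is always flagged; chance co-exceedances are the
        # combinatorial-null background, so it must also be the extreme branch
        assert flags["Hominoidea"]
        assert a.idxmax() == "Hominoidea" and b.idxmax() == "Hominoidea"

    def test_invariant_to_uniform_duration_rescaling(self, tree, table):
        rob = pl.branch_changes(pl.ancestral_bm(tree, table["log_rob"]), tree)
        pch = pl.branch_changes(pl.ancestral_bm(tree, table["log_pch"]), tree)
        c = pl.rob_contrast(pch, rob, beta=1.2)["contrast"]
        # rescaling every duration by k rescales all contrasts by 1/k
        assert pl.classify_joint_increase(c, c).equals(
            pl.classify_joint_increase(c / 3.0, c / 3.0)
        )

    def test_equal_pf_fm_contrasts_give_zero_shift(self, tree):
        branches = [br.id for br in tree.branches()]
        c = pd.Series(np.linspace(-1, 1, len(branches)), index=branches)
        out = pl.pf_fm_shift(c, c, c)
        assert (out["shift"] == 0).all()

    def test_ranking_restricted_to_positive_pch_branches(self, tree):
        branches = [br.id for br in tree.branches()]
        rng = np.random.default_rng(2)
        pf = pd.Series(rng.normal(size=len(branches)), index=branches)
        fm = pd.Series(rng.normal(size=len(branches)), index=branches)
        pch = pd.Series(rng.normal(size=len(branches)), index=branches)
        out = pl.pf_fm_shift(pf, fm, pch)
        assert out.loc[pch <= 0, "rank"].isna().all()
        ranked = out.loc[pch > 0].sort_values("rank")
        assert ranked["shift"].is_monotonic_decreasing
        assert ranked["rank"].iloc[0] == 1

    def test_joint_null_matches_independent_exceedance_expectation(self, tree):
        """With no lineage effects, the flag count matches the product rule
        for two independent per-trait exceedance sets (Monte Carlo)."""
        diffs = []
        for i in range(120):
            tab = pl.simulate_trait_table(pl.SimulationSpec(tree=tree, seed=20000 + i))
            rob = pl.branch_changes(pl.ancestral_bm(tree, tab["log_rob"]), tree)
            cons = {}
            for trait in ("pf", "pch"):
                bc = pl.branch_changes(pl.ancestral_bm(tree, tab[f"log_{trait}"]), tree)
                cons[trait] = pl.rob_contrast(bc, rob, beta=1.6)["contrast"]
            flags = pl.classify_joint_increase(cons["pf"], cons["pch"], q=0.75)
            n = len(flags)
            na = ((cons["pf"] > 0) & (cons["pf"] > cons["pf"].quantile(0.75))).sum()
            nb = ((cons["pch"] > 0) & (cons["pch"] > cons["pch"].quantile(0.75))).sum()
            diffs.append(flags.sum() - na * nb / n)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < max(3 * se, 0.3)
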