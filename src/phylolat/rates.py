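"""Branch-specific evolutionary rates from ancestral-state reconstruction.

Two reconstructions are provided. ``ancestral_bm`` gives the GLS/ML states
under Brownian motion: each internal node is the solution of the weighted
harmonic system in which a node's value is the mean of its tree-adjacent
nodes weighted by inverse branch length. ``ancestral_ap`` is an
adaptive-peak variant that lets every branch carry its own rate multiplier:
starting from the BM solution it alternates (i) re-solving the internal
states with branch weights inverse to rate-rescaled lengths and (ii) setting
each branch's multiplier proportional to its current absolute change per My,
normalized to mean one, until the states stabilize. With all multipliers
pinned to one it reduces exactly to the BM reconstruction; mean-reverting
(OU-like) behavior is a simulation option, not an estimation mode.

From a reconstruction, per-branch signed changes and rates (per My) follow,
and each branch's change can be contrasted against the change predicted from
rest-of-brain via the clade-general scaling slope: contrast =
(delta_structure - beta * delta_ROB) / duration. Branches where two
structures jointly show disproportionate increases (both contrasts positive
and above their q-th percentile) mark episodes of coordinated expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import PhyloTree

__all__ = [
    "AncestralStates",
    "ancestral_bm",
    "ancestral_ap",
    "branch_changes",
    "rob_contrast",
    "classify_joint_increase",
    "pf_fm_shift",
]


@dataclass(frozen=True)
class AncestralStates:
    """Trait values at every node plus (for the adaptive-peak model)
    per-branch rate multipliers normalized to mean one."""

    states: pd.Series  # node id -> value (tips keep their observed values)
    model: str  # "bm" | "ap"
    multipliers: pd.Series | None = None  # branch id -> positive multiplier


def _check_trait(tree: PhyloTree, trait: pd.Series) -> pd.Series:
    trait = pd.Series(trait, dtype=float)
    missing = set(tree.tips) - set(trait.index)
    if missing:
        raise ValueError(f"trait missing for tips: {sorted(missing)}")
    if trait.loc[list(tree.tips)].isna().any():
        raise ValueError("trait contains missing values")
    return trait.loc[list(tree.tips)]


def _solve_states(tree: PhyloTree, trait: pd.Series,
                  weights: dict[str, float]) -> pd.Series:
    """Solve the weighted-mean fixed point for internal states.

    ``weights[branch_id]`` is the conductance of that branch; each internal
    node's value is the weighted mean of its neighbors, tips held at their
    observed values (the normal equations of minimizing sum w * delta^2).
    """
    internal = [i for i in tree.node_ids if i not in set(tree.tips)]
    idx = {node: k for k, node in enumerate(internal)}
    n = len(internal)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for br in tree.branches():
        w = weights[br.id]
        p, c = br.parent, br.child
        for u, v in ((p, c), (c, p)):
            if u in idx:
                A[idx[u], idx[u]] += w
                if v in idx:
                    A[idx[u], idx[v]] -= w
                else:
                    b[idx[u]] += w * trait.loc[v]
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular reconstruction system: {exc}") from exc
    states = dict(zip(internal, sol))
    states.update(trait.to_dict())
    return pd.Series(states).loc[tree.node_ids]


def _branch_lengths(tree: PhyloTree) -> pd.Series:
    return pd.Series({br.id: br.length for br in tree.branches()})


def ancestral_bm(tree: PhyloTree, trait: pd.Series) -> AncestralStates:
    """ML ancestral states under Brownian motion (inverse-length weights)."""
    trait = _check_trait(tree, trait)
    lens = _branch_lengths(tree)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()
        raise ValueError(f"nonpositive branch lengths make BM states singular: {bad}")
    states = _solve_states(tree, trait, (1.0 / lens).to_dict())
    return AncestralStates(states=states, model="bm")


def ancestral_ap(tree: PhyloTree, trait: pd.Series, tol: float = 1e-8,
                 max_iter: int = 500,
                 pin_multipliers: pd.Series | None = None) -> AncestralStates:
    """Adaptive-peak reconstruction with per-branch rate multipliers.

    Alternates state re-estimation (weights 1 / (multiplier * length)) with
    multiplier updates proportional to each branch's |change| per My
    (normalized to mean one, damped 50/50 with the previous value, floored at
    1e-6) until the largest state change falls below ``tol``. Passing
    ``pin_multipliers`` fixes the multipliers (all-ones reproduces BM).
    """
    trait = _check_trait(tree, trait)
    lens = _branch_lengths(tree)
    if (lens <= 0).any():
        raise ValueError("nonpositive branch lengths")
    parents = {br.id: br.parent for br in tree.branches()}

    if pin_multipliers is not None:
        mult = pd.Series(pin_multipliers, dtype=float).loc[lens.index]
        if (mult <= 0).any():
            raise ValueError("multipliers must be positive")
        states = _solve_states(tree, trait, (1.0 / (mult * lens)).to_dict())
        return AncestralStates(states=states, model="ap", multipliers=mult)

    mult = pd.Series(1.0, index=lens.index)
    states = _solve_states(tree, trait, (1.0 / lens).to_dict())
    last_delta = np.inf
    for _ in range(max_iter):
        abs_rate = pd.Series(
            {b: abs(states.loc[b] - states.loc[parents[b]]) / lens.loc[b]
             for b in lens.index}
        )
        if abs_rate.mean() < 1e-14:
            mult = pd.Series(1.0, index=lens.index)  # constant trait
            break
        target = (abs_rate / abs_rate.mean()).clip(lower=1e-6)
        mult = 0.5 * mult + 0.5 * target
        mult /= mult.mean()
        new_states = _solve_states(tree, trait, (1.0 / (mult * lens)).to_dict())
        last_delta = float((new_states - states).abs().max())
        states = new_states
        if last_delta < tol:
            break
    else:
        raise RuntimeError(
            f"adaptive-peak reconstruction did not converge in {max_iter} "
            f"iterations (last max state change {last_delta:.3g})"
        )
    return AncestralStates(states=states, model="ap", multipliers=mult)


def branch_changes(states: AncestralStates, tree: PhyloTree) -> pd.DataFrame:
    """Per-branch signed change and rate (per My).

    Columns: parent, child, duration, delta, rate; indexed by branch id.
    """
    rows = {}
    for br in tree.branches():
        delta = float(states.states.loc[br.child] - states.states.loc[br.parent])
        if br.length == 0:
            if abs(delta) > 0:
                raise ValueError(
                    f"zero-duration branch {br.id!r} with nonzero change {delta}"
                )
            rate = 0.0
        else:
            rate = delta / br.length
        rows[br.id] = {
            "parent": br.parent,
            "child": br.child,
            "duration": br.length,
            "delta": delta,
            "rate": rate,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rob_contrast(structure_table: pd.DataFrame, rob_table: pd.DataFrame,
                 beta: float) -> pd.DataFrame:
    """Contrast each branch's change against the allometric prediction.

    contrast = (delta_structure - beta * delta_ROB) / duration, with beta the
    clade-general PGLS slope of the structure on rest-of-brain. The returned
    table extends ``structure_table`` with rob_delta, rob_rate and contrast.
    """
    if not structure_table.index.equals(rob_table.index):
        raise ValueError("branch tables come from different trees")
    if not np.allclose(structure_table["duration"], rob_table["duration"]):
        raise ValueError("branch durations disagree between tables")
    out = structure_table.copy()
    out["rob_delta"] = rob_table["delta"]
    out["rob_rate"] = rob_table["rate"]
    out["contrast"] = (out["delta"] - beta * out["rob_delta"]) / out["duration"]
    return out


def classify_joint_increase(contrast_a: pd.Series, contrast_b: pd.Series,
                            q: float = 0.75) -> pd.Series:
    """Flag branches where both contrasts are positive and exceed their own
    q-th percentile across branches (disproportionate joint increase)."""
    if not contrast_a.index.equals(contrast_b.index):
        raise ValueError("contrasts indexed by different branches")
    if not 0.0 <= q < 1.0:
        raise ValueError(f"quantile must lie in [0, 1), got {q}")
    qa = contrast_a.quantile(q)
    qb = contrast_b.quantile(q)
    return (contrast_a > 0) & (contrast_b > 0) & (contrast_a > qa) & (contrast_b > qb)


def pf_fm_shift(pf_contrast: pd.Series, fm_contrast: pd.Series,
                pch_contrast: pd.Series) -> pd.DataFrame:
    """Prefrontal-over-motor shift score per branch.

    shift = PF contrast - FM contrast, reported alongside the branch's PCH
    contrast; branches with positive PCH contrast are ranked by shift
    (1 = largest). Other branches get no rank.
    """
    if not (pf_contrast.index.equals(fm_contrast.index)
            and pf_contrast.index.equals(pch_contrast.index)):
        raise ValueError("contrasts indexed by different branches")
    df = pd.DataFrame(
        {
            "pf_contrast": pf_contrast,
            "fm_contrast": fm_contrast,
            "pch_contrast": pch_contrast,
            "shift": pf_contrast - fm_contrast,
        }
    )
    eligible = df["pch_contrast"] > 0
    df["rank"] = df.loc[eligible, "shift"].rank(ascending=False, method="min")
    return df
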