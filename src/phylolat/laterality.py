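"""Structural laterality: left-vs-right scaling coefficients by CI exclusion.

Hemisphere-specific volumes are each scaled to rest-of-brain by PGLS; the left
and right coefficients are compared by confidence-interval exclusion: a slope
(or intercept) is called asymmetric when either hemisphere's point estimate
lies outside the other hemisphere's 95% interval, which corresponds to
significance at roughly P < 0.05. The rule is evaluated on unrounded values.
A stricter variant requiring exclusion in both directions is available via
``rule="mutual"``. Because CI-exclusion is not an exact alpha = 0.05 test, its
empirical operating characteristics are measured by simulation in the test
suite rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .scaling import ScalingFit, rob_scaling
from .trees import PhyloTree

__all__ = ["LateralityResult", "compare_hemispheres", "laterality_table"]


@dataclass(frozen=True)
class LateralityResult:
    """Left/right comparison of one structure's scaling coefficients."""

    structure: str
    left_fit: ScalingFit
    right_fit: ScalingFit
    slope_asymmetric: bool
    intercept_asymmetric: bool
    slope_direction: str  # "left>right" | "right>left" | "none"
    intercept_direction: str


def _excluded(a: float, ci_b: tuple[float, float], b: float,
              ci_a: tuple[float, float], rule: str) -> bool:
    a_out = not (ci_b[0] <= a <= ci_b[1])
    b_out = not (ci_a[0] <= b <= ci_a[1])
    return (a_out and b_out) if rule == "mutual" else (a_out or b_out)


def compare_hemispheres(left: ScalingFit, right: ScalingFit,
                        structure: str = "", rule: str = "either") -> LateralityResult:
    """Flag slope/intercept asymmetry between two hemisphere fits.

    ``rule="either"`` (default): asymmetric when either coefficient lies
    outside the other fit's 95% CI; ``"mutual"`` requires both exclusions.
    """
    if rule not in ("either", "mutual"):
        raise ValueError(f"rule must be 'either' or 'mutual', got {rule!r}")
    if left.n != right.n:
        raise ValueError(f"fits have different n: {left.n} vs {right.n}")

    slope_flag = _excluded(left.slope, right.slope_ci, right.slope, left.slope_ci, rule)
    int_flag = _excluded(left.intercept, right.intercept_ci,
                         right.intercept, left.intercept_ci, rule)

    def direction(flag: bool, l: float, r: float) -> str:
        if not flag:
            return "none"
        return "left>right" if l > r else "right>left"

    return LateralityResult(
        structure=structure,
        left_fit=left,
        right_fit=right,
        slope_asymmetric=slope_flag,
        intercept_asymmetric=int_flag,
        slope_direction=direction(slope_flag, left.slope, right.slope),
        intercept_direction=direction(int_flag, left.intercept, right.intercept),
    )


def laterality_table(table: pd.DataFrame, tree: PhyloTree, lam="ml",
                     rule: str = "either") -> tuple[pd.DataFrame, list[LateralityResult]]:
    """Hemisphere-specific ROB scaling for PCH, FM and PF plus asymmetry flags.

    Returns a tidy frame (one row per structure x hemisphere, with the
    laterality flags repeated on both rows) and the three LateralityResults.
    """
    fits = rob_scaling(table, tree, lam=lam)
    results = []
    rows = []
    for s in ("pch", "fm", "pf"):
        res = compare_hemispheres(fits[f"{s}_l"], fits[f"{s}_r"], structure=s, rule=rule)
        results.append(res)
        for hemi, fit in (("left", res.left_fit), ("right", res.right_fit)):
            row = fit.row()
            row.update(
                structure=s,
                hemisphere=hemi,
                slope_asymmetric=res.slope_asymmetric,
                slope_direction=res.slope_direction,
                intercept_asymmetric=res.intercept_asymmetric,
                intercept_direction=res.intercept_direction,
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    front = ["structure", "hemisphere"]
    df = df[front + [c for c in df.columns if c not in front]]
    return df, results
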