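"""Synthetic bilateral allometric trait systems on a phylogeny.

The generator emulates the statistical structure the comparative analyses
assume: rest-of-brain (ROB) log volume evolves by Brownian motion (optionally
Ornstein-Uhlenbeck) along the chronogram; each structure x hemisphere log
volume is intercept + slope * ROB plus a phylogenetically structured
deviation. The deviation is one draw from N(0, residual_sd^2 * C_lambda)
where C_lambda is the tree correlation matrix (unit diagonal) with
off-diagonals multiplied by lambda — i.e. a mixture of a Brownian deviation
(weight lambda) and independent Gaussian noise (weight 1 - lambda), so the
simulated residuals carry exactly the phylogenetic signal lambda that the
regression machinery estimates. Left and right deviations are independent by
default (``hemi_corr`` exposes a correlation knob). Branch-specific log
offsets can be injected per trait to create lineage effects with known
location and size. Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CSV_COLUMNS, STRUCTURES, species_means
from .trees import PhyloTree

__all__ = ["SimulationSpec", "simulate_bm", "simulate_ou", "simulate_system",
           "simulate_trait_table"]


@dataclass
class SimulationSpec:
    """Generative parameters for a bilateral allometric trait system.

    Defaults mirror the bundled anthropoid data: log10 ROB centered near 1.9
    (about 80 mL) with a Brownian variance that spreads tips over roughly the
    observed 1.4-log-unit range on a 46-My-deep tree; structure slopes near
    the observed scaling exponents with hemisphere intercepts sized so
    structures are a few percent of ROB; residual scatter of 0.1 log10 units.
    """

    tree: PhyloTree
    root_rob: float = 1.9           # log10 mL at the root
    sigma_rob: float = 0.0044      # BM variance of log10 ROB per My
    slope_l: float = 1.6
    slope_r: float = 1.6
    intercept_l: float = -2.9
    intercept_r: float = -2.9
    lam: float = 1.0               # Pagel's lambda of the residual deviation
    residual_sd: float = 0.1       # SD of each tip's deviation (log10 units)
    ou_alpha: float = 0.0          # mean reversion for ROB; 0 = pure BM
    hemi_corr: float = 0.0         # correlation of left vs right deviations
    shift_branches: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.sigma_rob < 0:
            raise ValueError("sigma_rob must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.ou_alpha < 0:
            raise ValueError("ou_alpha must be >= 0")
        if not -1.0 <= self.hemi_corr <= 1.0:
            raise ValueError("hemi_corr must lie in [-1, 1]")
        branch_ids = {br.id for br in self.tree.branches()}
        valid_traits = set(STRUCTURES) | {
            f"{s}_{h}" for s in STRUCTURES for h in ("l", "r")
        }
        for trait, shifts in self.shift_branches.items():
            if trait not in valid_traits:
                raise ValueError(f"unknown shifted trait {trait!r}")
            unknown = set(shifts) - branch_ids
            if unknown:
                raise ValueError(f"shift branches not in tree: {sorted(unknown)}")


def _mvn(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not np.any(cov):
        return mean.copy()
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    return mean + L @ rng.standard_normal(len(mean))


def simulate_bm(tree: PhyloTree, root: float, sigma: float, seed) -> pd.Series:
    """Tip values of Brownian motion with variance ``sigma`` (units^2/My).

    ``seed`` may be an int or a Generator; a fixed int gives identical output
    across runs.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    V = tree.vcv(1.0).to_numpy() * sigma
    vals = _mvn(np.full(tree.n_tips, float(root)), V, rng)
    return pd.Series(vals, index=tree.tips)


def simulate_ou(tree: PhyloTree, root: float, sigma: float, alpha: float,
                seed) -> pd.Series:
    """Tip values of an Ornstein-Uhlenbeck process with optimum at the root
    value: stationary-start covariance sigma/(2 alpha) * exp(-alpha d_ij) *
    (1 - exp(-2 alpha s_ij)) with s the shared time and d the tree distance."""
    if alpha <= 0:
        return simulate_bm(tree, root, sigma, seed)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    S = tree.vcv(1.0).to_numpy()
    depth = np.diag(S)
    d = depth[:, None] + depth[None, :] - 2 * S  # patristic distances
    cov = sigma / (2 * alpha) * np.exp(-alpha * d) * (1 - np.exp(-2 * alpha * S))
    vals = _mvn(np.full(tree.n_tips, float(root)), cov, rng)
    return pd.Series(vals, index=tree.tips)


def _deviation_cov(tree: PhyloTree, lam: float, sd: float) -> np.ndarray:
    """residual_sd^2 times the lambda-transformed tree correlation matrix."""
    V = tree.vcv(lam).to_numpy()
    scale = np.sqrt(np.diag(V))
    C = V / np.outer(scale, scale)
    return sd**2 * C


def simulate_system(spec: SimulationSpec) -> pd.DataFrame:
    """Simulate one dataset in the volumetric CSV schema (one row per species).

    Volumes are back-transformed to mL (noise is multiplicative on volumes);
    ``brain_size`` is ROB plus the six simulated structure volumes, so the
    dataset module's rest-of-brain recovers the simulated ROB exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    tips = tree.tips
    n = len(tips)

    rob_log = (
        simulate_ou(tree, spec.root_rob, spec.sigma_rob, spec.ou_alpha, rng)
        if spec.ou_alpha > 0
        else simulate_bm(tree, spec.root_rob, spec.sigma_rob, rng)
    )
    cov = _deviation_cov(tree, spec.lam, spec.residual_sd)

    slope = {"l": spec.slope_l, "r": spec.slope_r}
    intercept = {"l": spec.intercept_l, "r": spec.intercept_r}
    zero = np.zeros(n)
    logs: dict[str, pd.Series] = {}
    for s in STRUCTURES:
        common = _mvn(zero, cov, rng)
        for h in ("l", "r"):
            own = _mvn(zero, cov, rng)
            c = spec.hemi_corr
            dev = np.sqrt(abs(c)) * np.sign(c if h == "r" else abs(c)) * common \
                + np.sqrt(1 - abs(c)) * own
            vals = intercept[h] + slope[h] * rob_log.to_numpy() + dev
            logs[f"{s}_{h}"] = pd.Series(vals, index=tips)

    for trait, shifts in spec.shift_branches.items():
        cols = [trait] if "_" in trait else [f"{trait}_l", f"{trait}_r"]
        for branch, offset in shifts.items():
            affected = tree.tip_set(branch) & set(tips)
            for col in cols:
                logs[col].loc[list(affected)] += offset

    vols = {k: 10.0**v for k, v in logs.items()}
    rob_vol = 10.0**rob_log
    brain = rob_vol + sum(vols.values())
    df = pd.DataFrame(
        {
            "species": tips,
            "individual": "sim",
            "brain_size": brain.to_numpy(),
            **{k: vols[k].to_numpy() for k in vols},
        }
    )
    return df[CSV_COLUMNS]


def simulate_trait_table(spec: SimulationSpec, **mean_kwargs) -> pd.DataFrame:
    """Simulate and aggregate to a species-mean trait table in one step."""
    from .data import IndividualRecord

    df = simulate_system(spec)
    records = [
        IndividualRecord(
            species=row["species"], individual=str(row["individual"]),
            brain_size=float(row["brain_size"]),
            **{c: float(row[c]) for c in CSV_COLUMNS[3:]},
        )
        for _, row in df.iterrows()
    ]
    return species_means(records, **mean_kwargs)
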