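"""End-to-end orchestration of the comparative analysis.

``run_all`` loads the volumetric table and chronogram, fits the six
relative-size correlations, the hemisphere-specific rest-of-brain scaling
with laterality flags, and the per-branch rate/contrast tables (bilateral and
both contralateral pairings), writing TSV outputs plus a machine-readable run
manifest with input hashes and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .data import load_volumes, species_means
from .laterality import laterality_table
from .rates import (ancestral_ap, ancestral_bm, branch_changes,
                    classify_joint_increase, pf_fm_shift, rob_contrast)
from .scaling import correlation_battery, pgls_fit
from .trees import PhyloTree

__all__ = ["DEFAULT_CONFIG", "branch_rate_analysis", "run_all"]

log = logging.getLogger("phylolat")

DEFAULT_CONFIG = {
    "log_base": 10.0,
    "bilateral": "sum",       # bilateral size = left + right before logging
    "average": "mean-then-log",
    "lambda": "ml",           # per-regression ML lambda
    "model": "ap",            # branch-rate reconstruction: "ap" or "bm"
    "quantile": 0.75,         # joint-increase threshold
    "laterality_rule": "either",
    "residualize_contrasts": True,
}

_TRAITS = ["pch", "fm", "pf", "pch_l", "pch_r", "fm_l", "fm_r", "pf_l", "pf_r"]
_JOINT_PAIRS = [  # (label, structure contrast A, structure contrast B)
    ("fm_pch", "fm", "pch"),
    ("pf_pch", "pf", "pch"),
    ("fm_l_pch_r", "fm_l", "pch_r"),
    ("fm_r_pch_l", "fm_r", "pch_l"),
    ("pf_l_pch_r", "pf_l", "pch_r"),
    ("pf_r_pch_l", "pf_r", "pch_l"),
]
_SHIFT_VARIANTS = [  # (label, pf trait, fm trait, pch trait)
    ("bilateral", "pf", "fm", "pch"),
    ("l_vs_pch_r", "pf_l", "fm_l", "pch_r"),
    ("r_vs_pch_l", "pf_r", "fm_r", "pch_l"),
]


def branch_rate_analysis(table: pd.DataFrame, tree: PhyloTree,
                         model: str = "ap", q: float = 0.75,
                         lam="ml", residualize: bool = True) -> pd.DataFrame:
    """Per-branch changes, rates and rest-of-brain contrasts for every trait,
    plus joint-increase flags and prefrontal-shift scores.

    Each trait's branch contrast measures its change in excess of the change
    predicted from rest-of-brain via the clade-general PGLS slope beta. With
    ``residualize=True`` (default) the allometry-corrected trait
    ``log y - beta * log ROB`` is reconstructed and its per-branch rate is the
    contrast; with ``residualize=False`` the raw log trait and log ROB are
    reconstructed separately and combined as (delta_y - beta * delta_ROB) /
    duration. The two are algebraically identical under the linear BM
    reconstruction; for the nonlinear adaptive-peak reconstruction the
    corrected-trait route localizes lineage-specific shifts far better.
    """
    if model not in ("ap", "bm"):
        raise ValueError(f"model must be 'ap' or 'bm', got {model!r}")
    reconstruct = ancestral_ap if model == "ap" else ancestral_bm
    taxa = list(table.index)

    rob_states = reconstruct(tree, table["log_rob"])
    rob_tab = branch_changes(rob_states, tree)

    out = rob_tab[["parent", "child", "duration"]].copy()
    out.insert(0, "branch", out.index)
    out["rob_delta"] = rob_tab["delta"]
    out["rob_rate"] = rob_tab["rate"]

    contrasts: dict[str, pd.Series] = {}
    for trait in _TRAITS:
        y = table[f"log_{trait}"]
        states = reconstruct(tree, y)
        tab = branch_changes(states, tree)
        beta = pgls_fit(table["log_rob"], y, tree, lam=lam, taxa=taxa).slope
        if residualize:
            corrected = reconstruct(tree, y - beta * table["log_rob"])
            resid_tab = branch_changes(corrected, tree)
            tab = rob_contrast(resid_tab, rob_tab, 0.0)
            tab[["delta", "rate"]] = branch_changes(states, tree)[["delta", "rate"]]
        else:
            tab = rob_contrast(tab, rob_tab, beta)
        contrasts[trait] = tab["contrast"]
        out[f"{trait}_delta"] = tab["delta"]
        out[f"{trait}_rate"] = tab["rate"]
        out[f"{trait}_contrast"] = tab["contrast"]
        out[f"{trait}_beta"] = beta

    for label, a, b in _JOINT_PAIRS:
        out[f"flag_{label}"] = classify_joint_increase(contrasts[a], contrasts[b], q=q)

    for label, pf, fm, pch in _SHIFT_VARIANTS:
        shift = pf_fm_shift(contrasts[pf], contrasts[fm], contrasts[pch])
        out[f"shift_{label}"] = shift["shift"]
        out[f"shift_rank_{label}"] = shift["rank"]
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(data_path, tree_path, outdir, config: dict | None = None,
            seed: int = 0) -> dict:
    """Run the full analysis and write fits.tsv, scaling.tsv, branches.tsv
    and manifest.json into ``outdir``. Returns the manifest dict."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage=load tree=%s data=%s", tree_path, data_path)
    tree = PhyloTree.from_file(tree_path)
    records = load_volumes(data_path, known_species=tree.tips)
    table = species_means(
        records, log_base=cfg["log_base"], bilateral=cfg["bilateral"],
        average=cfg["average"],
    )
    missing = set(tree.tips) - set(table.index)
    if missing:
        raise ValueError(f"tree tips without data: {sorted(missing)}")
    table = table.loc[list(tree.tips)]

    log.info("stage=correlation_battery n_species=%d", len(table))
    fits = pd.DataFrame([f.row() for f in correlation_battery(table, tree, lam=cfg["lambda"])])

    log.info("stage=laterality")
    scaling_df, _ = laterality_table(table, tree, lam=cfg["lambda"],
                                     rule=cfg["laterality_rule"])

    log.info("stage=branch_rates model=%s q=%.2f", cfg["model"], cfg["quantile"])
    branches = branch_rate_analysis(table, tree, model=cfg["model"],
                                    q=cfg["quantile"], lam=cfg["lambda"],
                                    residualize=cfg["residualize_contrasts"])

    outputs = {}
    for name, df in (("fits.tsv", fits), ("scaling.tsv", scaling_df),
                     ("branches.tsv", branches)):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = str(path)

    manifest = {
        "software": {"name": "phylolat", "version": __version__},
        "inputs": {
            "data": {"path": str(data_path), "sha256": _sha256(data_path)},
            "tree": {"path": str(tree_path), "sha256": _sha256(tree_path)},
        },
        "config": cfg,
        "seed": seed,
        "n_species": int(len(table)),
        "outputs": sorted(outputs),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("stage=done outdir=%s", outdir)
    return manifest
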