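"""Volumetric brain data: loading, validation, species means, rest-of-brain.

The bundled table holds per-individual volumes (mL) of whole brain and of the
posterior cerebellar hemispheres (PCH), frontal motor areas (FM) and
prefrontal cortex (PF), split by hemisphere, for 16 anthropoid species.
Species are the unit of analysis: raw volumes are averaged per species and
then log-transformed (log10 by default). Rest-of-brain (ROB) — the allometric
baseline — is total brain volume minus the six structure volumes, computed per
individual before averaging.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndividualRecord",
    "ValidationError",
    "STRUCTURES",
    "HEMIS",
    "load_volumes",
    "rest_of_brain",
    "species_means",
    "bundled_volumes",
    "bundled_trait_table",
]

STRUCTURES = ("pch", "fm", "pf")
HEMIS = ("l", "r")
_VOL_COLS = [f"{s}_{h}" for s in STRUCTURES for h in HEMIS]
CSV_COLUMNS = ["species", "individual", "brain_size"] + [
    f"{s}_{h}" for h in HEMIS for s in STRUCTURES
]


class ValidationError(ValueError):
    """Raised when a volumetric record violates the schema invariants."""


@dataclass(frozen=True)
class IndividualRecord:
    """One specimen: whole-brain volume plus six structure volumes (mL)."""

    species: str
    individual: str
    brain_size: float
    pch_l: float
    pch_r: float
    fm_l: float
    fm_r: float
    pf_l: float
    pf_r: float

    def structure_volumes(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in _VOL_COLS}

    def validate(self) -> None:
        vols = self.structure_volumes()
        if self.brain_size <= 0:
            raise ValidationError(
                f"{self.species}/{self.individual}: nonpositive brain size"
            )
        for name, v in vols.items():
            if v <= 0:
                raise ValidationError(
                    f"{self.species}/{self.individual}: nonpositive volume {name}={v}"
                )
            if v >= self.brain_size:
                raise ValidationError(
                    f"{self.species}/{self.individual}: structure {name}={v} "
                    f"not smaller than brain size {self.brain_size}"
                )
        if sum(vols.values()) >= self.brain_size:
            raise ValidationError(
                f"{self.species}/{self.individual}: structure volumes sum to "
                f"{sum(vols.values()):.2f} >= brain size {self.brain_size}"
            )


def rest_of_brain(rec: IndividualRecord) -> float:
    """Brain volume minus PCH, FM and PF of both hemispheres (mL)."""
    rob = rec.brain_size - sum(rec.structure_volumes().values())
    if rob <= 0:
        raise ValidationError(
            f"{rec.species}/{rec.individual}: rest-of-brain {rob} is not positive"
        )
    return rob


def load_volumes(path, known_species: Iterable[str] | None = None) -> list[IndividualRecord]:
    """Read and validate the per-individual volumetric CSV.

    Schema: ``species,individual,brain_size,pch_l,fm_l,pf_l,pch_r,fm_r,pf_r``
    with volumes in mL. Every record is validated; ``known_species``, when
    given, restricts the species column to that set.
    """
    df = pd.read_csv(path, dtype={"individual": str})
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    known = set(known_species) if known_species is not None else None
    records = []
    for i, row in df.iterrows():
        if known is not None and row["species"] not in known:
            raise ValidationError(f"row {i}: unknown species {row['species']!r}")
        rec = IndividualRecord(
            species=str(row["species"]),
            individual=str(row["individual"]),
            brain_size=float(row["brain_size"]),
            **{c: float(row[c]) for c in _VOL_COLS},
        )
        try:
            rec.validate()
            rest_of_brain(rec)
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def species_means(
    records: Sequence[IndividualRecord],
    log_base: float = 10.0,
    bilateral: str = "sum",
    average: str = "mean-then-log",
) -> pd.DataFrame:
    """Species-mean trait table with log volumes.

    Raw mL volumes are averaged per species and then log-transformed
    (``average="mean-then-log"``, the default) or log-transformed per
    individual and then averaged (``"log-then-mean"``). Bilateral structure
    size is left + right volume (before logging) by default, or the
    hemispheric mean with ``bilateral="mean"``; log-log slopes are unaffected
    by that choice, intercepts shift by log(2).

    Returns one row per species with columns ``n_individuals``, raw-mean
    volumes, and ``log_*`` columns for each structure x hemisphere, the
    bilateral totals, brain size, and rest-of-brain.
    """
    if not records:
        raise ValidationError("no records")
    if bilateral not in ("sum", "mean"):
        raise ValueError(f"bilateral must be 'sum' or 'mean', got {bilateral!r}")
    if average not in ("mean-then-log", "log-then-mean"):
        raise ValueError(f"unknown averaging mode {average!r}")

    rows = []
    for rec in records:
        d = {"species": rec.species, "brain_size": rec.brain_size, "rob": rest_of_brain(rec)}
        d.update(rec.structure_volumes())
        for s in STRUCTURES:
            pair = getattr(rec, f"{s}_l") + getattr(rec, f"{s}_r")
            d[s] = pair if bilateral == "sum" else pair / 2.0
        rows.append(d)
    per_ind = pd.DataFrame(rows)

    value_cols = ["brain_size", "rob"] + _VOL_COLS + list(STRUCTURES)
    log = lambda v: np.log(v) / np.log(log_base)
    if average == "log-then-mean":
        per_ind[value_cols] = log(per_ind[value_cols])
    grouped = per_ind.groupby("species", sort=False)
    table = grouped[value_cols].mean()
    table.insert(0, "n_individuals", grouped.size())
    logged = table[value_cols] if average == "log-then-mean" else log(table[value_cols])
    for c in value_cols:
        table[f"log_{c}"] = logged[c]
    if average == "log-then-mean":
        # raw-mean columns are still reported on the original scale
        table[value_cols] = log_base ** table[value_cols]
    return table


def bundled_data_path():
    """Filesystem path of the versioned volumetric CSV."""
    return importlib.resources.files("phylolat.resources").joinpath(
        "anthropoid_volumes.csv"
    )


def bundled_volumes() -> list[IndividualRecord]:
    """The versioned 24-specimen, 16-species volumetric table."""
    with importlib.resources.as_file(bundled_data_path()) as p:
        return load_volumes(p)


def bundled_trait_table(**kwargs) -> pd.DataFrame:
    return species_means(bundled_volumes(), **kwargs)
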