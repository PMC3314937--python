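"""Ligand records, target densities, physiological constants and population
binding-class frequencies, plus CSV/YAML I/O.

The packaged table carries the in silico / in vitro characterisation of four
TSPO radioligands (18F-PBR111, 11C-PBR28, 11C-DPA713, 11C-(R)-PK11195):
McGowan volume, lipophilicity, free fractions, per-class target density and
the high/low site affinities that arise from the rs6971 polymorphism.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "Isotope",
    "BindingClass",
    "LigandProperties",
    "TSPOTarget",
    "LigandRecord",
    "PhysiologicalConstants",
    "PopulationFrequencies",
    "LigandValidationError",
    "load_ligand_table",
    "builtin_ligands",
    "write_ligand_table",
    "load_frequencies",
    "load_constants",
    "BUILTIN_FREQUENCIES",
]


class LigandValidationError(ValueError):
    """A ligand table row failed validation; message names field and row."""


class Isotope(enum.Enum):
    """PET radionuclide; value is the half-life in minutes."""

    C11 = 20.4
    F18 = 109.77

    @property
    def half_life(self) -> float:
        return self.value


class BindingClass(enum.Enum):
    """TSPO binding class determined by the rs6971 (Ala147Thr) genotype."""

    HAB = "HAB"
    MAB = "MAB"
    LAB = "LAB"


@dataclass(frozen=True)
class LigandProperties:
    """Physicochemical and affinity parameters of one radioligand.

    ``vx`` is the McGowan characteristic volume (cm^3 mol^-1 / 100), ``clogd``
    the computed logD at pH 7.4, ``f_p``/``f_nd`` the free fractions in plasma
    and tissue, and ``ki_high``/``ki_low`` the affinities (nM) for the high-
    and low-affinity TSPO site (Ki used in place of KD throughout).
    ``ki_high <= ki_low`` is deliberately not required: PK11195 binds both
    sites with an affinity ratio indistinguishable from 1 (~0.8).
    """

    name: str
    isotope: Isotope
    vx: float
    clogd: float
    f_p: float
    f_nd: float
    ki_high: float
    ki_low: float

    def __post_init__(self):
        for fld in ("vx", "clogd", "f_p", "f_nd", "ki_high", "ki_low"):
            v = getattr(self, fld)
            if not v > 0:
                raise LigandValidationError(
                    f"ligand {self.name!r}: field {fld!r} must be > 0, got {v}"
                )
        for fld in ("f_p", "f_nd"):
            v = getattr(self, fld)
            if v > 1:
                raise LigandValidationError(
                    f"ligand {self.name!r}: free fraction {fld!r} must be <= 1, got {v}"
                )


@dataclass(frozen=True)
class TSPOTarget:
    """Target density (nM) per binding class.

    MABs carry both site types; ``mab_high_fraction`` splits Bmax_M between
    them (0.5 by default, i.e. equal numbers of high and low sites).
    """

    bmax_hab: float
    bmax_mab: float
    bmax_lab: float
    mab_high_fraction: float = 0.5

    def __post_init__(self):
        for fld in ("bmax_hab", "bmax_mab", "bmax_lab"):
            if getattr(self, fld) < 0:
                raise LigandValidationError(f"{fld} must be >= 0")
        if not 0 <= self.mab_high_fraction <= 1:
            raise LigandValidationError("mab_high_fraction must be in [0, 1]")


@dataclass(frozen=True)
class LigandRecord:
    """One ligand-table row: properties + target densities (+ stored
    uncertainties, which the computations never use)."""

    properties: LigandProperties
    target: TSPOTarget
    uncertainties: Mapping[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.properties.name


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Fixed physiological parameters of the brain-entry model.

    perfusion_f: cerebral perfusion, mL cm^-3 min^-1.
    surface_s: capillary surface area, cm^2 cm^-3.
    v_aq_p / v_aq_t: apparent aqueous volumes of plasma and tissue.
    k1_scale: empirical in vitro -> in vivo scaling on K1.
    v_b: fractional blood volume in the tissue signal.
    """

    perfusion_f: float = 0.6
    surface_s: float = 150.0
    v_aq_p: float = 0.98
    v_aq_t: float = 0.9
    k1_scale: float = 3.43
    v_b: float = 0.05

    def __post_init__(self):
        for fld in ("perfusion_f", "surface_s", "v_aq_p", "v_aq_t", "k1_scale"):
            if not getattr(self, fld) > 0:
                raise ValueError(f"{fld} must be > 0")
        if not 0 < self.v_b < 1:
            raise ValueError("v_b must be in (0, 1)")


@dataclass(frozen=True)
class PopulationFrequencies:
    """Binding-class proportions of an ethnic group, normalized to sum 1."""

    ethnicity: str
    proportions: Mapping[BindingClass, float]

    def __post_init__(self):
        props = dict(self.proportions)
        for cls_, frac in props.items():
            if frac < 0:
                raise ValueError(
                    f"{self.ethnicity}: negative fraction for {cls_.value}"
                )
        total = sum(props.values())
        if total <= 0:
            raise ValueError(f"{self.ethnicity}: fractions sum to {total}")
        object.__setattr__(
            self,
            "proportions",
            {c: props.get(c, 0.0) / total for c in BindingClass},
        )


# rs6971 binding-class ratios by ethnic group.  The Chinese/Japanese ratio is
# quoted as 94:6:0.001 (LABs vanishingly rare); it is normalized by its own
# sum rather than by 100.
BUILTIN_FREQUENCIES = {
    "Caucasian": (49.0, 42.0, 9.0),
    "AfricanAmerican": (56.0, 38.0, 6.0),
    "ChineseJapanese": (94.0, 6.0, 0.001),
}

_REQUIRED_COLUMNS = [
    "name",
    "isotope",
    "vx",
    "clogd",
    "f_p",
    "f_nd",
    "bmax_hab",
    "bmax_mab",
    "bmax_lab",
    "ki_high",
    "ki_low",
]


def load_ligand_table(source) -> list[LigandRecord]:
    """Read a ligand table (CSV path, file object, or DataFrame).

    Required columns: name, isotope (C11|F18), vx, clogd, f_p, f_nd,
    bmax_hab, bmax_mab, bmax_lab, ki_high, ki_low.  Any additional
    ``*_sd`` / ``*_n`` columns are stored on the record as uncertainties.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LigandValidationError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise LigandValidationError("ligand table contains no ligands")

    extra_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    records = []
    for idx, row in df.iterrows():
        try:
            isotope = Isotope[str(row["isotope"]).strip()]
        except KeyError:
            raise LigandValidationError(
                f"row {idx} ({row['name']!r}): unknown isotope {row['isotope']!r}; "
                f"expected one of {[i.name for i in Isotope]}"
            ) from None
        try:
            props = LigandProperties(
                name=str(row["name"]),
                isotope=isotope,
                vx=float(row["vx"]),
                clogd=float(row["clogd"]),
                f_p=float(row["f_p"]),
                f_nd=float(row["f_nd"]),
                ki_high=float(row["ki_high"]),
                ki_low=float(row["ki_low"]),
            )
            target = TSPOTarget(
                bmax_hab=float(row["bmax_hab"]),
                bmax_mab=float(row["bmax_mab"]),
                bmax_lab=float(row["bmax_lab"]),
            )
        except LigandValidationError as err:
            raise LigandValidationError(f"row {idx}: {err}") from None
        unc = {
            c: float(row[c]) for c in extra_cols if pd.notna(row[c])
        }
        records.append(LigandRecord(props, target, unc))
    return records


def write_ligand_table(records: list[LigandRecord], path) -> None:
    """Write records back to CSV; inverse of :func:`load_ligand_table`."""
    rows = []
    for rec in records:
        p, t = rec.properties, rec.target
        row = {
            "name": p.name,
            "isotope": p.isotope.name,
            "vx": p.vx,
            "clogd": p.clogd,
            "f_p": p.f_p,
            "f_nd": p.f_nd,
            "bmax_hab": t.bmax_hab,
            "bmax_mab": t.bmax_mab,
            "bmax_lab": t.bmax_lab,
            "ki_high": p.ki_high,
            "ki_low": p.ki_low,
        }
        row.update(rec.uncertainties)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def builtin_ligands() -> list[LigandRecord]:
    """The packaged four-ligand characterisation table."""
    with resources.files("tspopet.data").joinpath("ligands.csv").open() as fh:
        return load_ligand_table(fh)


def load_frequencies(ethnicity, proportions=None) -> PopulationFrequencies:
    """Binding-class frequencies for a built-in ethnic group or a user triple.

    ``proportions`` (HAB, MAB, LAB), when given, overrides the built-ins.
    """
    if proportions is None:
        try:
            proportions = BUILTIN_FREQUENCIES[ethnicity]
        except KeyError:
            raise ValueError(
                f"unknown ethnicity {ethnicity!r}; built-ins: "
                f"{sorted(BUILTIN_FREQUENCIES)} (or pass proportions=)"
            ) from None
    hab, mab, lab = proportions
    return PopulationFrequencies(
        ethnicity=ethnicity,
        proportions={
            BindingClass.HAB: hab,
            BindingClass.MAB: mab,
            BindingClass.LAB: lab,
        },
    )


def load_constants(path=None, **overrides) -> PhysiologicalConstants:
    """Physiological constants, optionally overridden from a YAML mapping."""
    consts = PhysiologicalConstants()
    if path is not None:
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        consts = replace(consts, **data)
    if overrides:
        consts = replace(consts, **overrides)
    return consts
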