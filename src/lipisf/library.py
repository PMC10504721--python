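"""Lipid library: species, per-class ion-transform pathways, TSV loaders.

A library couples a list of lipid species (class, carbons:double-bonds
shorthand, molecular formula, neutral monoisotopic mass) with a pathway
table stating which adducts and in-source fragments each lipid class can
form in each polarity. A small library covering the common phospholipid and
sphingomyelin classes is bundled; users drop in their own TSVs to search
any database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .chem import (
    ElementComposition,
    IonTransform,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)


class LibraryError(ValueError):
    """Raised when a library or pathway table fails validation."""


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid at the species level (isomers unresolved at MS1)."""

    name: str
    lipid_class: str
    carbons: int
    double_bonds: int
    formula: ElementComposition
    neutral_mass: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.carbons <= 0:
            raise LibraryError(f"{self.name}: carbons must be > 0")
        if self.double_bonds < 0:
            raise LibraryError(f"{self.name}: double_bonds must be >= 0")
        if self.neutral_mass is None:
            object.__setattr__(self, "neutral_mass", monoisotopic_mass(self.formula))


@dataclass
class LipidLibrary:
    """Species plus the class → transform pathway map, validated on build."""

    species: List[LipidSpecies]
    transforms: Dict[str, IonTransform]
    # (lipid_class, polarity) -> list of transform names
    pathways: Dict[Tuple[str, str], List[str]]
    is_decoy: bool = False
    description: str = ""

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LibraryError(f"duplicate species names: {dupes}")
        missing = sorted(
            {t for ts in self.pathways.values() for t in ts} - set(self.transforms)
        )
        if missing:
            raise LibraryError(f"pathway rows reference undefined transforms: {missing}")

    def transforms_for(self, lipid_class: str, polarity: str) -> List[IonTransform]:
        names = self.pathways.get((lipid_class, polarity), [])
        return [self.transforms[n] for n in names]

    def ion_mz(self, lipid: LipidSpecies, transform: IonTransform) -> float:
        """m/z of ``lipid`` under ``transform``; the transform must be listed
        in the pathway table for the lipid's class and polarity."""
        valid = self.pathways.get((lipid.lipid_class, transform.polarity), [])
        if transform.name not in valid:
            raise LibraryError(
                f"transform {transform.name!r} is not a valid "
                f"{transform.polarity}-mode pathway for class {lipid.lipid_class!r}"
            )
        return ion_mz(lipid.neutral_mass, transform)

    def search_space(self, polarity: str) -> List[Tuple[LipidSpecies, IonTransform, float]]:
        """All (lipid, transform, theoretical m/z) hypotheses for a polarity."""
        out = []
        for sp in self.species:
            for t in self.transforms_for(sp.lipid_class, polarity):
                out.append((sp, t, ion_mz(sp.neutral_mass, t)))
        return out


def _parse_delta(text: str) -> ElementComposition:
    text = (text or "").strip()
    if text in ("", "-"):
        return ElementComposition()
    return parse_formula(text)


def load_transforms(path) -> Dict[str, IonTransform]:
    """Read a transform TSV (name, polarity, kind, delta_gain, delta_loss,
    charge_carrier, plausible)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    out: Dict[str, IonTransform] = {}
    for _, row in df.iterrows():
        name = row["name"].strip()
        if name in out:
            raise LibraryError(f"duplicate transform name {name!r}")
        out[name] = IonTransform(
            name=name,
            polarity=row["polarity"].strip(),
            kind=row["kind"].strip(),
            gain=_parse_delta(row["delta_gain"]),
            loss=_parse_delta(row["delta_loss"]),
            charge_carrier=row["charge_carrier"].strip(),
            plausible=str(row["plausible"]).strip().lower() in ("true", "1", "yes"),
        )
    return out


def load_library(
    species_table,
    pathway_table,
    transform_table,
    mass_check_tol: float = 0.01,
) -> LipidLibrary:
    """Load a library from species / pathway / transform TSVs.

    A species row may carry an optional ``mass`` column; if the mass computed
    from the formula differs by more than ``mass_check_tol`` Da a warning is
    emitted (the computed mass is used regardless).
    """
    transforms = load_transforms(transform_table)

    pw = pd.read_csv(pathway_table, sep="\t", dtype=str)
    pathways: Dict[Tuple[str, str], List[str]] = {}
    for _, row in pw.iterrows():
        key = (row["class"].strip(), row["polarity"].strip())
        pathways.setdefault(key, []).append(row["transform_name"].strip())

    sp = pd.read_csv(species_table, sep="\t", dtype=str)
    species: List[LipidSpecies] = []
    for _, row in sp.iterrows():
        comp = parse_formula(row["formula"])
        s = LipidSpecies(
            name=row["name"].strip(),
            lipid_class=row["class"].strip(),
            carbons=int(row["carbons"]),
            double_bonds=int(row["double_bonds"]),
            formula=comp,
        )
        if "mass" in sp.columns and str(row.get("mass", "")).strip() not in ("", "-", "nan"):
            stated = float(row["mass"])
            if abs(stated - s.neutral_mass) > mass_check_tol:
                warnings.warn(
                    f"{s.name}: stated mass {stated} differs from computed "
                    f"{s.neutral_mass:.5f} by > {mass_check_tol} Da",
                    stacklevel=2,
                )
        species.append(s)

    return LipidLibrary(species=species, transforms=transforms, pathways=pathways)


def load_lipidmaps_species(path) -> pd.DataFrame:
    """Map an LMSD-style export (columns NAME, FORMULA, optionally
    ABBREVIATION) onto the species-TSV schema.

    Shorthand like ``"PC 34:1"`` is parsed out of NAME/ABBREVIATION to fill
    class, carbons and double_bonds; rows without a parseable shorthand are
    dropped.
    """
    import re

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.upper(): c for c in df.columns}
    if "NAME" not in cols or "FORMULA" not in cols:
        raise LibraryError("LIPIDMAPS export must have NAME and FORMULA columns")
    pat = re.compile(r"([A-Za-z]+)\s?(\d+):(\d+)")
    rows = []
    for _, row in df.iterrows():
        label = str(row.get(cols.get("ABBREVIATION", ""), "") or row[cols["NAME"]])
        m = pat.search(label)
        if not m:
            continue
        rows.append(
            dict(
                name=f"{m.group(1)} {m.group(2)}:{m.group(3)}",
                **{"class": m.group(1)},
                carbons=int(m.group(2)),
                double_bonds=int(m.group(3)),
                formula=row[cols["FORMULA"]],
            )
        )
    return pd.DataFrame(rows, columns=["name", "class", "carbons", "double_bonds", "formula"])


def _data_path(fname: str) -> Path:
    return Path(resources.files("lipisf").joinpath("data", fname))  # type: ignore[arg-type]


def bundled_library() -> LipidLibrary:
    """The bundled mini-library: 7 phospholipid/sphingolipid classes,
    ~60 species, and the default adduct / in-source-fragment pathways."""
    lib = load_library(
        _data_path("species.tsv"),
        _data_path("pathways.tsv"),
        _data_path("transforms.tsv"),
    )
    lib.description = "bundled mini-library"
    return lib
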