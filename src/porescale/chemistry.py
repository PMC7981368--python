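"""Per-atom chemistry lookups: van der Waals radii, masses, hydropathic indices.

The hydropathic index table follows the binary atomic hydropathicity
convention (+0.5 hydrophobic, -0.5 hydrophilic) in which every protein atom,
hydrogens included, carries an index determined by its chemical context.
The bundled default is a rule-based table (element defaults plus
residue/atom-name overrides for polar hydrogens and polar carbons); any or
all entries can be replaced from a user YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


class ChemistryError(KeyError):
    """Raised when a lookup is not total over the atoms of a structure."""


@dataclass
class ChemistryTables:
    """Element -> radius/mass tables and the atomic hydropathicity table.

    ``hi_overrides`` maps residue name -> atom name -> index and takes
    precedence over the element-level default; the residue key ``"*"``
    applies to all residues.
    """

    vdw_by_element: dict[str, float]
    mass_by_element: dict[str, float]
    hi_by_element: dict[str, float]
    hi_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ChemistryTables":
        """Load the tables bundled with the package."""
        with resources.files("porescale.data").joinpath("chemistry.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChemistryTables":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "ChemistryTables":
        return cls(
            vdw_by_element={k.upper(): float(v) for k, v in raw["vdw_by_element"].items()},
            mass_by_element={k.upper(): float(v) for k, v in raw["mass_by_element"].items()},
            hi_by_element={k.upper(): float(v) for k, v in raw["hi_by_element"].items()},
            hi_overrides={
                res: {a.upper(): float(v) for a, v in atoms.items()}
                for res, atoms in raw.get("hi_overrides", {}).items()
            },
        )

    def update(self, other: dict) -> None:
        """Merge override entries (same YAML schema) into the tables."""
        for key in ("vdw_by_element", "mass_by_element", "hi_by_element"):
            for k, v in other.get(key, {}).items():
                getattr(self, key)[k.upper()] = float(v)
        for res, atoms in other.get("hi_overrides", {}).items():
            self.hi_overrides.setdefault(res, {}).update(
                {a.upper(): float(v) for a, v in atoms.items()}
            )

    # -- lookups -----------------------------------------------------------

    def vdw(self, element: str, serial: int | None = None) -> float:
        try:
            return self.vdw_by_element[element.upper()]
        except KeyError:
            raise ChemistryError(
                f"no van der Waals radius for element {element!r}"
                + (f" (atom serial {serial})" if serial is not None else "")
            ) from None

    def mass(self, element: str, serial: int | None = None) -> float:
        try:
            return self.mass_by_element[element.upper()]
        except KeyError:
            raise ChemistryError(
                f"no atomic mass for element {element!r}"
                + (f" (atom serial {serial})" if serial is not None else "")
            ) from None

    def hi(self, res_name: str, atom_name: str, element: str,
           serial: int | None = None) -> float:
        atom_name = atom_name.upper()
        for res_key in (res_name.upper(), "*"):
            table = self.hi_overrides.get(res_key)
            if table is not None and atom_name in table:
                return table[atom_name]
        try:
            return self.hi_by_element[element.upper()]
        except KeyError:
            raise ChemistryError(
                f"no hydropathic index for atom {atom_name!r} of {res_name!r} "
                f"(element {element!r}"
                + (f", serial {serial})" if serial is not None else ")")
            ) from None
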