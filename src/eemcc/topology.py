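"""System topology: atoms nested in united atoms, monomers and molecules.

The topology is read from a PDB-dialect file (ATOM/HETATM records for
element, residue numbering and names; CONECT records for bonds) plus a
TSV sidecar that supplies what the PDB dialect cannot express: masses,
partial charges, united-atom membership, monomer class, species role and
molecular formal charge.  Molecules are the connected components of the
bond graph; monomers follow the PDB residue numbering.

Species roles are data, not hard-coded molecule names: the same pipeline
runs with any molecule labelled ``protein``, ``polyanion``, ``buffer``,
``cation``, ``anion`` or ``water``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SPECIES_ROLES = ("protein", "polyanion", "buffer", "cation", "anion", "water")
MONOMER_CLASSES = ("acidic", "basic", "uncharged-polar", "non-polar", "n/a")

SIDECAR_COLUMNS = [
    "atom_index",
    "mass",
    "charge",
    "ua_id",
    "monomer_class",
    "species_role",
    "formal_charge",
]


class TopologyError(ValueError):
    """Raised when a topology file violates the hierarchy contract."""


@dataclass
class Topology:
    """Fully labelled atom hierarchy.

    Arrays are indexed by atom position (0-based, following file order
    after sorting by the PDB atom serial).
    """

    element: np.ndarray  # str per atom
    name: np.ndarray  # PDB atom name per atom
    mass: np.ndarray  # amu
    charge: np.ndarray  # partial charge, e
    ua_id: np.ndarray  # int united-atom id per atom
    monomer_id: np.ndarray  # int monomer id per atom
    molecule_id: np.ndarray  # int molecule id per atom
    bonds: np.ndarray  # (nb, 2) atom-index pairs
    monomer_class: dict[int, str] = field(default_factory=dict)
    species: dict[int, str] = field(default_factory=dict)  # molecule -> role
    formal_charge: dict[int, float] = field(default_factory=dict)
    dihedrals: list[tuple[int, tuple[int, int, int, int]]] = field(
        default_factory=list
    )  # (monomer_id, atom quadruple)
    residue_name: dict[int, str] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.mass)

    def atoms_of(self, key: str, value: int) -> np.ndarray:
        """Atom indices belonging to the given unit.

        ``key`` is one of ``"ua"``, ``"monomer"``, ``"molecule"``.
        """
        arr = {"ua": self.ua_id, "monomer": self.monomer_id,
               "molecule": self.molecule_id}[key]
        return np.flatnonzero(arr == value)

    def units(self, key: str) -> np.ndarray:
        arr = {"ua": self.ua_id, "monomer": self.monomer_id,
               "molecule": self.molecule_id}[key]
        return np.unique(arr)

    def molecules_of_species(self, role: str) -> np.ndarray:
        return np.array(sorted(m for m, r in self.species.items() if r == role))

    def molecule_of_ua(self, ua: int) -> int:
        return int(self.molecule_id[self.atoms_of("ua", ua)[0]])

    def species_of_ua(self, ua: int) -> str:
        return self.species[self.molecule_of_ua(ua)]

    def heavy_atom_of_ua(self, ua: int) -> int:
        """The single non-hydrogen atom of a united atom."""
        idx = self.atoms_of("ua", ua)
        heavy = idx[self.element[idx] != "H"]
        if len(heavy) != 1:
            raise TopologyError(
                f"united atom {ua} has {len(heavy)} heavy atoms; expected 1"
            )
        return int(heavy[0])

    def bonded_to(self, atom: int) -> np.ndarray:
        mask = (self.bonds[:, 0] == atom) | (self.bonds[:, 1] == atom)
        pairs = self.bonds[mask]
        return np.where(pairs[:, 0] == atom, pairs[:, 1], pairs[:, 0])

    def donor_hydrogens(self) -> list[tuple[int, int]]:
        """(hydrogen, bound heteroatom) pairs for H bonded to N or O."""
        out = []
        for h in np.flatnonzero(self.element == "H"):
            for partner in self.bonded_to(int(h)):
                if self.element[partner] in ("N", "O"):
                    out.append((int(h), int(partner)))
        return out

    def levels_of_molecule(self, mol: int) -> tuple[str, ...]:
        """Length scales at which a molecule's entropy is resolved.

        Proteins carry united-atom, monomer and polymer levels; other
        multi-monomer or multi-UA molecules carry UA and monomer levels;
        water and monatomic ions only the UA level.
        """
        role = self.species[mol]
        atoms = self.atoms_of("molecule", mol)
        n_mono = len(np.unique(self.monomer_id[atoms]))
        n_ua = len(np.unique(self.ua_id[atoms]))
        if role == "protein":
            return ("UA", "M", "P")
        if role == "water" or (n_ua == 1 and n_mono == 1):
            return ("UA",)
        return ("UA", "M")

    def validate(self) -> None:
        n = self.n_atoms
        if np.any(self.mass <= 0):
            bad = int(np.flatnonzero(self.mass <= 0)[0])
            raise TopologyError(f"atom {bad} has non-positive mass")
        if self.bonds.size and (self.bonds.max() >= n or self.bonds.min() < 0):
            raise TopologyError("bond references an atom index out of range")
        for label, arr in (("united-atom", self.ua_id),
                           ("monomer", self.monomer_id),
                           ("molecule", self.molecule_id)):
            if np.any(arr < 0):
                bad = int(np.flatnonzero(arr < 0)[0])
                raise TopologyError(f"atom {bad} has no {label} assignment")
        # united atoms: one heavy atom, hydrogens bonded to it
        for ua in self.units("ua"):
            idx = self.atoms_of("ua", int(ua))
            heavy = idx[self.element[idx] != "H"]
            if len(heavy) != 1:
                raise TopologyError(
                    f"united atom {ua} must have exactly one heavy atom, "
                    f"found {len(heavy)}"
                )
            for h in idx[self.element[idx] == "H"]:
                if int(heavy[0]) not in self.bonded_to(int(h)):
                    raise TopologyError(
                        f"hydrogen {h} in united atom {ua} is not bonded to "
                        f"its heavy atom {heavy[0]}"
                    )
        for mol, role in self.species.items():
            atoms = self.atoms_of("molecule", mol)
            if role == "water" and len(atoms) != 3:
                raise TopologyError(
                    f"water molecule {mol} has {len(atoms)} atoms; expected 3"
                )
        # hierarchy partition: each atom in exactly one unit at each level
        for key in ("ua", "monomer", "molecule"):
            total = sum(len(self.atoms_of(key, int(u))) for u in self.units(key))
            if total != n:
                raise TopologyError(f"{key} partition does not cover all atoms")


def _parse_pdb_atoms(lines: list[str]):
    records = []
    conect: list[tuple[int, int]] = []
    for ln in lines:
        rec = ln[:6]
        if rec in ("ATOM  ", "HETATM"):
            serial = int(ln[6:11])
            name = ln[12:16].strip()
            resname = ln[17:20].strip()
            resseq = int(ln[22:26])
            element = ln[76:78].strip() if len(ln) >= 78 else ""
            if not element:
                element = name[:1]
            records.append((serial, name, resname, resseq, element))
        elif rec == "CONECT":
            fields = ln.split()[1:]
            base = int(fields[0])
            for other in fields[1:]:
                conect.append((base, int(other)))
    return records, conect


def read_topology(
    path: str | Path,
    sidecar: str | Path,
    dihedrals: str | Path | None = None,
) -> Topology:
    """Read a PDB-dialect file and its TSV sidecar into a :class:`Topology`.

    The optional ``dihedrals`` file lists one dihedral per line as
    ``monomer_id i j k l`` (0-based atom indices after serial sort).
    Atoms missing from the sidecar, or sidecar rows without mass/charge,
    are hard errors naming the atom.
    """
    lines = Path(path).read_text().splitlines()
    records, conect = _parse_pdb_atoms(lines)
    if not records:
        raise TopologyError(f"no ATOM/HETATM records in {path}")
    records.sort(key=lambda r: r[0])
    serials = [r[0] for r in records]
    serial_to_index = {s: i for i, s in enumerate(serials)}
    n = len(records)

    # "n/a" is a legitimate monomer-class label, not a missing value
    side = pd.read_csv(sidecar, sep="\t", comment="#",
                       keep_default_na=False, na_values=[""])
    missing_cols = [c for c in SIDECAR_COLUMNS if c not in side.columns]
    if missing_cols:
        raise TopologyError(f"sidecar missing columns {missing_cols}")
    side = side.set_index("atom_index")
    for i in range(n):
        if i not in side.index:
            raise TopologyError(f"atom {i} (serial {serials[i]}) has no sidecar row")
        row = side.loc[i]
        if pd.isna(row["mass"]) or pd.isna(row["charge"]):
            raise TopologyError(f"atom {i} is missing mass or charge in sidecar")
        if pd.isna(row["ua_id"]):
            raise TopologyError(f"atom {i} has no united-atom assignment")
    side = side.loc[range(n)]

    bonds = set()
    for a, b in conect:
        if a not in serial_to_index or b not in serial_to_index:
            raise TopologyError(f"CONECT references unknown serial {a}-{b}")
        i, j = serial_to_index[a], serial_to_index[b]
        bonds.add((min(i, j), max(i, j)))
    bond_arr = (np.array(sorted(bonds), dtype=int)
                if bonds else np.empty((0, 2), dtype=int))

    # molecules = connected components of the bond graph
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in bond_arr:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    roots = [find(i) for i in range(n)]
    root_ids = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    molecule_id = np.array([root_ids[r] for r in roots], dtype=int)

    # monomers follow residue numbering, kept distinct across molecules
    reskeys = {}
    monomer_id = np.empty(n, dtype=int)
    for i, (_, _, resname, resseq, _) in enumerate(records):
        key = (molecule_id[i], resseq)
        monomer_id[i] = reskeys.setdefault(key, len(reskeys))

    top = Topology(
        element=np.array([r[4] for r in records], dtype=object),
        name=np.array([r[1] for r in records], dtype=object),
        mass=side["mass"].to_numpy(float),
        charge=side["charge"].to_numpy(float),
        ua_id=side["ua_id"].to_numpy(int),
        monomer_id=monomer_id,
        molecule_id=molecule_id,
        bonds=bond_arr,
    )
    for i in range(n):
        mon = int(monomer_id[i])
        mol = int(molecule_id[i])
        cls = str(side["monomer_class"].iloc[i])
        role = str(side["species_role"].iloc[i])
        if role not in SPECIES_ROLES:
            raise TopologyError(f"atom {i}: unknown species role {role!r}")
        if cls not in MONOMER_CLASSES:
            raise TopologyError(f"atom {i}: unknown monomer class {cls!r}")
        prev = top.monomer_class.setdefault(mon, cls)
        if prev != cls:
            raise TopologyError(f"monomer {mon} has conflicting class labels")
        prev = top.species.setdefault(mol, role)
        if prev != role:
            raise TopologyError(f"molecule {mol} has conflicting species roles")
        top.formal_charge.setdefault(mol, float(side["formal_charge"].iloc[i]))
        top.residue_name.setdefault(mon, records[i][2])

    if dihedrals is not None:
        for ln in Path(dihedrals).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != 5:
                raise TopologyError(f"bad dihedral line: {ln!r}")
            mon = int(parts[0])
            quad = tuple(int(p) for p in parts[1:])
            if any(q < 0 or q >= n for q in quad):
                raise TopologyError(f"dihedral {quad} references unknown atom")
            top.dihedrals.append((mon, quad))  # type: ignore[arg-type]

    top.validate()
    return top


def write_topology(
    top: Topology,
    path: str | Path,
    sidecar: str | Path,
    dihedrals: str | Path | None = None,
) -> None:
    """Write the PDB-dialect + sidecar representation of a topology."""
    with open(path, "w") as fh:
        for i in range(top.n_atoms):
            mon = int(top.monomer_id[i])
            resname = top.residue_name.get(mon, "UNK")[:3]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<3s} A{resseq:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                "{el:>2s}\n".format(
                    serial=i + 1, name=str(top.name[i])[:4], res=resname,
                    resseq=mon % 10000, x=0.0, y=0.0, z=0.0, occ=1.0, b=0.0,
                    el=str(top.element[i]),
                )
            )
        for a, b in top.bonds:
            fh.write(f"CONECT{a + 1:>5d}{b + 1:>5d}\n")
        fh.write("END\n")
    df = pd.DataFrame(
        {
            "atom_index": np.arange(top.n_atoms),
            "mass": top.mass,
            "charge": top.charge,
            "ua_id": top.ua_id,
            "monomer_class": [top.monomer_class[int(m)] for m in top.monomer_id],
            "species_role": [top.species[int(m)] for m in top.molecule_id],
            "formal_charge": [top.formal_charge[int(m)] for m in top.molecule_id],
        }
    )
    df.to_csv(sidecar, sep="\t", index=False)
    if dihedrals is not None:
        with open(dihedrals, "w") as fh:
            fh.write("# monomer_id i j k l\n")
            for mon, quad in top.dihedrals:
                fh.write(f"{mon} {quad[0]} {quad[1]} {quad[2]} {quad[3]}\n")
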