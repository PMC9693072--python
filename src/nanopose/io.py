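"""Structure file readers/writers: XYZ, PDB and a minimal fractional format.

XYZ keeps element + Cartesian coordinates only; labels are regenerated as
``<El><ordinal>`` on read.  PDB (via gemmi) preserves atom labels in the
atom-name field, so labeled molecules round-trip losslessly through PDB.
The fractional format is a small text file with a ``cell`` line followed by
``frac <label> <element> fx fy fz`` records.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .structures import (
    Atom,
    RigidMolecule,
    StructureError,
    UnitCell,
    fractional_to_cartesian,
)

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
    "read_fractional",
    "read_structure",
    "write_structure",
]


def write_xyz(mol: RigidMolecule, path, comment: str = "") -> None:
    lines = [str(len(mol)), comment.replace("\n", " ")]
    for a in mol.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path, **molkw) -> RigidMolecule:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise StructureError(f"empty XYZ file: {path}")
    n = int(lines[0].split()[0])
    atoms = []
    counts: dict[str, int] = {}
    for line in lines[2 : 2 + n]:
        parts = line.split()
        el = parts[0].capitalize()
        counts[el] = counts.get(el, 0) + 1
        atoms.append(Atom(f"{el}{counts[el]}", el, tuple(map(float, parts[1:4]))))
    if len(atoms) != n:
        raise StructureError(f"XYZ header promised {n} atoms, found {len(atoms)}")
    return RigidMolecule(atoms, **molkw)


def write_pdb(mol: RigidMolecule, path, resname: str = "MOL") -> None:
    st = gemmi.Structure()
    st.name = resname
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(1, " ")
    for a in mol.atoms:
        atom = gemmi.Atom()
        atom.name = a.label
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.position)
        res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path, **molkw) -> RigidMolecule:
    st = gemmi.read_structure(str(path))
    atoms = []
    for model in st:
        for chain in model:
            for res in chain:
                for a in res:
                    atoms.append(
                        Atom(a.name, a.element.name, (a.pos.x, a.pos.y, a.pos.z))
                    )
        break  # first model only; the body is rigid, no trajectory semantics
    if not atoms:
        raise StructureError(f"no ATOM records in {path}")
    return RigidMolecule(atoms, **molkw)


def read_fractional(path, **molkw) -> RigidMolecule:
    """Read the minimal cell + fractional-coordinates text format.

    Example::

        cell 10.0 12.0 9.0 90.0 95.5 90.0
        frac C1 C 0.125 0.500 0.250
        frac O1 O 0.300 0.410 0.270
    """
    cell: UnitCell | None = None
    records: list[tuple[str, str, np.ndarray]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "cell":
            cell = UnitCell(*map(float, parts[1:7]))
        elif parts[0] == "frac":
            records.append((parts[1], parts[2], np.array(list(map(float, parts[3:6])))))
        else:
            raise StructureError(f"unrecognized record {parts[0]!r} in {path}")
    if cell is None:
        raise StructureError(f"no cell line in {path}")
    atoms = [
        Atom(label, el, tuple(fractional_to_cartesian(f, cell)))
        for label, el, f in records
    ]
    return RigidMolecule(atoms, **molkw)


_READERS = {".xyz": read_xyz, ".pdb": read_pdb, ".frac": read_fractional}


def read_structure(path, **molkw) -> RigidMolecule:
    """Dispatch on file suffix (.xyz, .pdb, .frac)."""
    suffix = Path(path).suffix.lower()
    try:
        return _READERS[suffix](path, **molkw)
    except KeyError:
        raise StructureError(f"unsupported structure format {suffix!r}") from None


def write_structure(mol: RigidMolecule, path, **kw) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        write_xyz(mol, path, **kw)
    elif suffix == ".pdb":
        write_pdb(mol, path, **kw)
    else:
        raise StructureError(f"unsupported structure format {suffix!r}")
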