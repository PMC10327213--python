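"""Hierarchical protein model with altloc-aware PDB I/O and geometry primitives.

The model is a flat, ordered list of residues; each residue owns one or more
conformers (alternative locations) and each conformer owns its atoms.  Atoms
carry isotropic B, optional anisotropic displacement tensors, and occupancy.
PDB reading/writing is delegated to gemmi; the in-memory hierarchy groups
atoms of one residue by altloc letter, with blank-altloc atoms shared into
every conformer on input and duplicated per conformer on output (the
standard full-duplication altloc convention, readable by any model-building
tool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

# Maximum alternate conformations per residue; altloc letters on output.
MAX_CONFORMERS = 5
ALTLOC_LETTERS = "ABCDE"

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# chi dihedral atom quadruples per residue type; the rotation axis of chi_k
# is the bond between the 2nd and 3rd named atoms.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

AROMATIC_RESIDUES = {"HIS", "TYR", "PHE", "TRP"}

# Idealized rotamer chi-angle means (degrees), compact penultimate-style
# table.  Sampling covers +/-24 deg around each mean, so coarse means
# suffice; per-chi-level unique means are derived on demand.
ROTAMER_LIBRARY: dict[str, list[tuple[float, ...]]] = {
    "SER": [(62.0,), (-65.0,), (180.0,)],
    "CYS": [(62.0,), (-65.0,), (180.0,)],
    "THR": [(62.0,), (-65.0,), (175.0,)],
    "VAL": [(175.0,), (-60.0,), (63.0,)],
    "PRO": [(27.0,), (-27.0,)],  # exo / endo ring flap
    "ILE": [(-65.0, 170.0), (-65.0, -65.0), (62.0, 170.0), (-57.0, 100.0)],
    "LEU": [(-65.0, 175.0), (180.0, 65.0), (-85.0, 65.0), (180.0, 180.0)],
    "ASN": [(-65.0, -20.0), (-65.0, 120.0), (180.0, 30.0), (62.0, -10.0)],
    "ASP": [(-65.0, -15.0), (180.0, 15.0), (62.0, -10.0)],
    "HIS": [(-65.0, -70.0), (-65.0, 165.0), (180.0, -165.0), (62.0, -75.0)],
    "PHE": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0)],
    "TYR": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0)],
    "TRP": [(-65.0, 95.0), (-65.0, -90.0), (180.0, -105.0), (62.0, 90.0)],
    "MET": [(-65.0, -65.0, -70.0), (-65.0, 180.0, 75.0), (180.0, 180.0, 75.0),
            (180.0, 65.0, 75.0), (62.0, 180.0, 75.0)],
    "GLU": [(-65.0, -65.0, -40.0), (-65.0, 180.0, 0.0), (180.0, 180.0, 0.0),
            (62.0, 180.0, 0.0)],
    "GLN": [(-65.0, -65.0, -40.0), (-65.0, 180.0, 0.0), (180.0, 180.0, 0.0),
            (62.0, 180.0, 20.0)],
    "LYS": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-65.0, -65.0, 180.0, 180.0), (62.0, 180.0, 180.0, 180.0)],
    "ARG": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-65.0, -65.0, 180.0, 180.0), (62.0, 180.0, 180.0, 85.0)],
}

STANDARD_AMINO_ACIDS = set(CHI_ATOMS) | {"GLY", "ALA"}


class RotamerLibrary:
    """Map from residue name to idealized chi-angle tuples (degrees)."""

    def __init__(self, table: dict[str, list[tuple[float, ...]]] | None = None):
        self.table = dict(ROTAMER_LIBRARY if table is None else table)

    def rotamers(self, resname: str) -> list[tuple[float, ...]]:
        return self.table.get(resname, [])

    def chi_means(self, resname: str, chi_index: int) -> list[float]:
        """Unique idealized means for one chi level (1-based), in table order."""
        seen: list[float] = []
        for tup in self.table.get(resname, []):
            if chi_index <= len(tup):
                v = tup[chi_index - 1]
                if not any(abs(v - s) < 1.0 for s in seen):
                    seen.append(v)
        return seen

    def n_chi(self, resname: str) -> int:
        return len(CHI_ATOMS.get(resname, []))


@dataclass
class Atom:
    name: str
    pos: np.ndarray
    b: float = 20.0
    occupancy: float = 1.0
    element: str = ""
    aniso: np.ndarray | None = None  # symmetric 3x3, A^2

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not self.element:
            self.element = _guess_element(self.name)

    def copy(self) -> "Atom":
        return Atom(self.name, self.pos.copy(), self.b, self.occupancy,
                    self.element,
                    None if self.aniso is None else self.aniso.copy())


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped[1:]
    if stripped[:2] in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].capitalize()
    return stripped[:1]


@dataclass
class Conformer:
    altloc: str = ""
    atoms: list[Atom] = field(default_factory=list)
    occupancy: float = 1.0

    def copy(self) -> "Conformer":
        return Conformer(self.altloc, [a.copy() for a in self.atoms],
                         self.occupancy)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names: list[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.pos for a in self.atoms])
        return np.array([self.atom(n).pos for n in names])

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def set_occupancy(self, occ: float) -> None:
        self.occupancy = occ
        for a in self.atoms:
            a.occupancy = occ


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str = ""
    name: str = "ALA"
    conformers: list[Conformer] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    def copy(self) -> "Residue":
        return Residue(self.chain, self.seqnum, self.icode, self.name,
                       [c.copy() for c in self.conformers])

    def total_occupancy(self) -> float:
        return sum(c.occupancy for c in self.conformers)

    def is_standard(self) -> bool:
        return self.name in STANDARD_AMINO_ACIDS

    def has_backbone(self) -> bool:
        return all(self.conformers and self.conformers[0].has_atom(n)
                   for n in BACKBONE_ATOMS)


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues])

    def get(self, chain: str, seqnum: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.id == (chain, seqnum, icode):
                return r
        raise KeyError((chain, seqnum, icode))

    def all_atoms(self) -> list[Atom]:
        return [a for r in self.residues for c in r.conformers for a in c.atoms]

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen


class PDBParseError(ValueError):
    pass


def read_pdb(path) -> Structure:
    """Read a PDB file into the altloc-grouped residue hierarchy.

    Atoms with a blank altloc in a residue that also carries lettered
    altlocs are shared into every conformer (partial-duplication input
    convention).  Conformer occupancy is the modal atom occupancy of the
    conformer's own (non-shared) atoms.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"malformed PDB file {path}: {exc}") from exc
    st.setup_entities()
    out = Structure()
    model = st[0]
    for chain in model:
        for res in chain:
            residue = Residue(chain.name, res.seqid.num,
                              (res.seqid.icode or "").strip(), res.name)
            shared: list[Atom] = []
            by_altloc: dict[str, list[Atom]] = {}
            for at in res:
                aniso = None
                if at.aniso.nonzero():
                    u = at.aniso  # U tensor, A^2
                    conv = 8.0 * np.pi ** 2
                    aniso = conv * np.array([
                        [u.u11, u.u12, u.u13],
                        [u.u12, u.u22, u.u23],
                        [u.u13, u.u23, u.u33]])
                # file precision: 3 decimals on coordinates, 2 on occ/B
                atom = Atom(at.name,
                            np.round([at.pos.x, at.pos.y, at.pos.z], 3),
                            round(at.b_iso, 2), round(at.occ, 2),
                            at.element.name, aniso)
                if at.altloc == "\0" or not at.altloc.strip():
                    shared.append(atom)
                else:
                    by_altloc.setdefault(at.altloc, []).append(atom)
            if not by_altloc:
                conf = Conformer("", shared, shared[0].occupancy if shared else 1.0)
                residue.conformers = [conf]
            else:
                for letter in sorted(by_altloc):
                    own = by_altloc[letter]
                    occs = [a.occupancy for a in own]
                    occ = max(set(occs), key=occs.count)
                    atoms = [a.copy() for a in shared] + own
                    residue.conformers.append(Conformer(letter, atoms, occ))
            out.residues.append(residue)
    return out


def write_pdb(structure: Structure, path) -> None:
    """Write the model as standard PDB with full-duplication altlocs."""
    st = gemmi.Structure()
    st.name = "multiconf"
    model = gemmi.Model("1")
    for chain_name in structure.chains():
        chain = gemmi.Chain(chain_name)
        for res in structure.residues:
            if res.chain != chain_name:
                continue
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            multi = len(res.conformers) > 1
            for conf in res.conformers:
                for atom in conf.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.pos = gemmi.Position(*atom.pos)
                    ga.occ = round(conf.occupancy if multi else atom.occupancy, 2)
                    ga.b_iso = atom.b
                    ga.element = gemmi.Element(atom.element)
                    ga.altloc = (conf.altloc or "\0") if multi else "\0"
                    if atom.aniso is not None:
                        conv = 1.0 / (8.0 * np.pi ** 2)
                        a = atom.aniso * conv
                        ga.aniso = gemmi.SMat33f(
                            a[0, 0], a[1, 1], a[2, 2],
                            a[0, 1], a[0, 2], a[1, 2])
                    gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc_opts = gemmi.PdbWriteOptions(seqres_records=False, ter_records=True)
    st.write_pdb(str(path), doc_opts)


def strip_hydrogens(structure: Structure) -> Structure:
    """Return a copy with all hydrogen atoms removed (idempotent)."""
    out = structure.copy()
    for res in out.residues:
        for conf in res.conformers:
            conf.atoms = [a for a in conf.atoms if a.element != "H"]
    return out


class DegenerateGeometryError(ValueError):
    pass


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or norm2 < 1e-10:
        raise DegenerateGeometryError("collinear points in dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def conformer_rmsd(a: Conformer, b: Conformer,
                   atom_subset: list[str] | None = None) -> float:
    """Unsuperposed RMSD over a named atom subset (default: common atoms)."""
    if atom_subset is None:
        names_b = {at.name for at in b.atoms}
        atom_subset = [at.name for at in a.atoms if at.name in names_b]
    if not atom_subset:
        raise ValueError("empty atom subset for RMSD")
    pa = a.coords(atom_subset)
    pb = b.coords(atom_subset)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def sidechain_heavy_names(conf: Conformer) -> list[str]:
    """Heavy-atom names beyond the backbone (CB included)."""
    skip = set(BACKBONE_ATOMS) | {"OXT"}
    return [a.name for a in conf.heavy_atoms() if a.name not in skip]


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


_CCD_BOND_CACHE: dict[str, dict[str, set[str]]] = {}


def _ccd_bond_graph(resname: str) -> dict[str, set[str]] | None:
    """Covalent bonds from the chemical-component dictionary, if known."""
    if resname in _CCD_BOND_CACHE:
        return _CCD_BOND_CACHE[resname]
    try:
        import biotite.structure.info as struc_info

        bonds = struc_info.bonds_in_residue(resname)
    except Exception:
        _CCD_BOND_CACHE[resname] = None
        return None
    graph: dict[str, set[str]] = {}
    for (a, b), _order in bonds.items():
        graph.setdefault(a, set()).add(b)
        graph.setdefault(b, set()).add(a)
    _CCD_BOND_CACHE[resname] = graph
    return graph


def _bonded_graph(conf: Conformer, resname: str | None = None) -> dict[str, set[str]]:
    """Covalent bonds among the conformer's atoms.

    Uses the chemical-component bond table when the residue type is known
    (robust to distorted input geometry); otherwise infers bonds by
    distance.
    """
    atoms = conf.atoms
    if resname is not None:
        table = _ccd_bond_graph(resname)
        if table is not None:
            names = {a.name for a in atoms}
            return {a.name: {n for n in table.get(a.name, ()) if n in names}
                    for a in atoms}
    graph: dict[str, set[str]] = {a.name: set() for a in atoms}
    for i, ai in enumerate(atoms):
        for aj in atoms[i + 1:]:
            cutoff = 1.95
            if "S" in (ai.element, aj.element):
                cutoff = 2.2
            if "H" in (ai.element, aj.element):
                cutoff = 1.3
            if np.linalg.norm(ai.pos - aj.pos) < cutoff:
                graph[ai.name].add(aj.name)
                graph[aj.name].add(ai.name)
    return graph


def rotate_about_bond(conf: Conformer, fixed: str, pivot: str,
                      angle_deg: float, resname: str | None = None) -> Conformer:
    """Rigidly rotate all atoms distal to bond fixed->pivot by angle_deg."""
    out = conf.copy()
    graph = _bonded_graph(out, resname)
    graph[fixed].discard(pivot)
    graph[pivot].discard(fixed)
    moving: set[str] = set()
    stack = [pivot]
    while stack:
        cur = stack.pop()
        if cur in moving:
            continue
        moving.add(cur)
        stack.extend(graph[cur] - moving)
    p0 = out.atom(fixed).pos
    axis = out.atom(pivot).pos - p0
    R = _rotation_matrix(axis, angle_deg)
    for atom in out.atoms:
        if atom.name in moving and atom.name != pivot:
            atom.pos = p0 + R @ (atom.pos - p0)
    return out


def get_chi(conf: Conformer, resname: str, chi_index: int) -> float:
    quads = CHI_ATOMS.get(resname)
    if not quads or chi_index < 1 or chi_index > len(quads):
        raise ValueError(f"{resname} has no chi{chi_index}")
    names = quads[chi_index - 1]
    return dihedral(*(conf.atom(n).pos for n in names))


def set_chi(conf: Conformer, resname: str, chi_index: int,
            angle_deg: float) -> Conformer:
    """Return a conformer whose chi(chi_index) equals angle_deg.

    Rotation is rigid about the chi bond: bond lengths, bond angles and all
    distances on each side of the bond are preserved.  Proline is excluded
    (its ring is sampled by a dedicated flap move in the sampler).
    """
    if resname == "PRO":
        raise ValueError("proline chi is sampled via ring flap, not set_chi")
    current = get_chi(conf, resname, chi_index)
    delta = angle_deg - current
    names = CHI_ATOMS[resname][chi_index - 1]
    return rotate_about_bond(conf, names[1], names[2], delta, resname)
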