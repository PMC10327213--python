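"""Peptide construction with standard geometry.

Backbones are built atom-by-atom from internal coordinates (the NeRF
construction); side chains are grafted from idealized chemical-component
templates (biotite's bundled CCD) by superposing the template backbone
frame, which guarantees correct L-stereochemistry and ideal bond lengths.
Used by the synthetic benchmark and the test suite; not part of the
map-fitting pipeline itself.
"""

from __future__ import annotations

import numpy as np
import biotite.structure.info as struc_info

from multiconf.structure import Atom, Conformer, Residue, Structure

# backbone internal coordinates (A, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position d with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (NeRF construction)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(chi),
                        bond * np.sin(theta) * np.sin(chi)])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    M = np.stack([bc, m, n], axis=1)
    return c + M @ d_local


def _frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame anchored on the N-CA-C triad."""
    e1 = c - n
    e1 /= np.linalg.norm(e1)
    v = ca - n
    e2 = v - e1 * (v @ e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


_TEMPLATE_CACHE: dict[str, tuple] = {}


def _sidechain_template(resname: str):
    """Heavy side-chain atoms of the CCD ideal residue, in its N-CA-C frame."""
    if resname in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[resname]
    tpl = struc_info.residue(resname)
    coord = {n: tpl.coord[i] for i, n in enumerate(tpl.atom_name)}
    elem = {n: tpl.element[i] for i, n in enumerate(tpl.atom_name)}
    F = _frame(coord["N"], coord["CA"], coord["C"])
    ca = coord["CA"]
    backbone = {"N", "CA", "C", "O", "OXT"}
    entries = []
    for name in tpl.atom_name:
        if name in backbone or elem[name] == "H":
            continue
        entries.append((str(name), str(elem[name]), F.T @ (coord[name] - ca)))
    _TEMPLATE_CACHE[resname] = tuple(entries)
    return _TEMPLATE_CACHE[resname]


def idealize_sidechain(conf, resname: str):
    """Rebuild the side chain with ideal template geometry at the input's
    chi angles.

    Backbone atoms keep their positions; side-chain atoms are regrafted
    from the ideal chemical-component template in the local N-CA-C frame
    and rotated back to the conformer's current chi angles.  B-factors and
    occupancies are preserved by atom name.  Standard model preparation
    before internal-coordinate sampling: rotation about chi bonds assumes
    undistorted side-chain geometry.
    """
    from multiconf.structure import CHI_ATOMS, get_chi, set_chi, Atom, Conformer

    n_chi = len(CHI_ATOMS.get(resname, []))
    if resname == "PRO" or not conf.has_atom("CB"):
        return conf.copy()
    try:
        template = _sidechain_template(resname)
    except KeyError:
        return conf.copy()
    old_chis = []
    try:
        for k in range(1, n_chi + 1):
            old_chis.append(get_chi(conf, resname, k))
    except (KeyError, ValueError):
        return conf.copy()
    F = _frame(conf.atom("N").pos, conf.atom("CA").pos, conf.atom("C").pos)
    ca = conf.atom("CA").pos
    old = {a.name: a for a in conf.atoms}
    backbone = {"N", "CA", "C", "O", "OXT"}
    atoms = [a.copy() for a in conf.atoms if a.name in backbone]
    for name, element, local in template:
        src = old.get(name)
        atoms.append(Atom(name, ca + F @ local,
                          src.b if src else conf.atoms[0].b,
                          src.occupancy if src else conf.occupancy, element))
    out = Conformer(conf.altloc, atoms, conf.occupancy)
    for k, chi in enumerate(old_chis, start=1):
        out = set_chi(out, resname, k, chi)
    return out


def build_peptide(sequence: list[str], phi: float = -140.0, psi: float = 135.0,
                  chain: str = "A", bfactor: float = 10.0,
                  start_seqnum: int = 1) -> Structure:
    """Extended-chain peptide with standard geometry and ideal side chains.

    Default torsions are beta-strand-like so side chains of consecutive
    residues stay out of each other's way.  Side chains keep the template's
    ideal chi angles; callers rotate them to rotamer targets afterwards.
    """
    structure = Structure()
    prev_c = prev_n = prev_ca = None
    for i, resname in enumerate(sequence):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            dummy = np.array([0.0, 1.0, 0.0])
            c = place_atom(dummy, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi + 60.0)
        else:
            n = place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi)
            ca = place_atom(prev_ca, prev_c, n, BOND_N_CA, ANGLE_C_N_CA, 180.0)
            c = place_atom(prev_c, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        # next-residue N fixes psi; O sits trans to it
        n_next = place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms = [Atom("N", n, bfactor, 1.0, "N"),
                 Atom("CA", ca, bfactor, 1.0, "C"),
                 Atom("C", c, bfactor, 1.0, "C"),
                 Atom("O", o, bfactor, 1.0, "O")]
        F = _frame(n, ca, c)
        for name, element, local in _sidechain_template(resname):
            atoms.append(Atom(name, ca + F @ local, bfactor, 1.0, element))
        conf = Conformer("", atoms, 1.0)
        structure.residues.append(
            Residue(chain, start_seqnum + i, "", resname, [conf]))
        prev_n, prev_ca, prev_c = n, ca, c
    return structure
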