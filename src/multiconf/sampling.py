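"""Candidate conformation enumeration and pruning.

Stages mirror the per-residue build order: rigid backbone translations
(9 isotropic / 81 anisotropic candidates), aromatic Ca-Cb-Cg angle
perturbations (x5), chi-angle grids around idealized rotamer means
(9 offsets per mean), proline ring flaps, and B-factor multipliers (x6).
Everything here is deterministic: identical inputs give identical candidate
lists in identical order, and no RNG is used anywhere in the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from multiconf.structure import (
    AROMATIC_RESIDUES,
    BACKBONE_ATOMS,
    CHI_ATOMS,
    Conformer,
    Residue,
    RotamerLibrary,
    _bonded_graph,
    _rotation_matrix,
    get_chi,
    set_chi,
)

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "Se": 1.90}
CLASH_SCALE = 0.75  # permissiveness factor on hard-sphere radii


class MissingBackboneError(ValueError):
    """Signals the driver to skip this residue."""


@dataclass
class SamplingParams:
    backbone_step: float = 0.1         # A
    backbone_extent: float = 0.3       # A
    aromatic_step: float = 3.75        # deg
    aromatic_extent: float = 7.5       # deg
    chi_step: float = 6.0              # deg
    chi_extent: float = 24.0           # deg
    redundancy_rmsd: float = 0.01      # A
    bfactor_multipliers: tuple = (0.5, 0.7, 0.9, 1.1, 1.3, 1.5)
    clash_scale: float = CLASH_SCALE

    def __post_init__(self):
        for step, extent in ((self.backbone_step, self.backbone_extent),
                             (self.aromatic_step, self.aromatic_extent),
                             (self.chi_step, self.chi_extent)):
            if abs(extent / step - round(extent / step)) > 1e-9:
                raise ValueError("sampling step must divide its extent")

    def chi_offsets(self) -> np.ndarray:
        n = int(round(self.chi_extent / self.chi_step))
        return np.arange(-n, n + 1) * self.chi_step

    def aromatic_offsets(self) -> np.ndarray:
        n = int(round(self.aromatic_extent / self.aromatic_step))
        return np.arange(-n, n + 1) * self.aromatic_step


@dataclass
class CandidateSet:
    residue_id: tuple
    resname: str
    stage: str
    conformers: list[Conformer]
    reference: Conformer                 # unperturbed input (topology source)
    densities: np.ndarray | None = None  # (n_candidates, n_voxels)
    footprint: object = None

    def __len__(self) -> int:
        return len(self.conformers)

    def replaced(self, conformers: list[Conformer], stage: str) -> "CandidateSet":
        return CandidateSet(self.residue_id, self.resname, stage,
                            conformers, self.reference)


def _pseudo_cb_direction(conf: Conformer) -> np.ndarray:
    """Tetrahedral Cb direction built from backbone geometry (Gly)."""
    n = conf.atom("N").pos
    ca = conf.atom("CA").pos
    c = conf.atom("C").pos
    v1 = (ca - n) / np.linalg.norm(ca - n)
    v2 = (ca - c) / np.linalg.norm(ca - c)
    bis = v1 + v2
    bis /= np.linalg.norm(bis)
    perp = np.cross(v2, v1)
    perp /= np.linalg.norm(perp)
    ang = np.radians(54.75)
    d = bis * np.cos(ang) + perp * np.sin(ang)
    return d / np.linalg.norm(d)


def _isotropic_directions(conf: Conformer) -> np.ndarray:
    ca = conf.atom("CA").pos
    if conf.has_atom("CB"):
        d1 = conf.atom("CB").pos - ca
    else:
        d1 = _pseudo_cb_direction(conf)
    d2 = conf.atom("N").pos - conf.atom("C").pos    # C->N direction
    d3 = np.cross(d1, d2)
    dirs = np.stack([d1, d2, d3])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _principal_axes(aniso: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(aniso)
    order = np.argsort(vals)[::-1]
    axes = vecs[:, order].T
    # deterministic sign: largest-magnitude component positive
    for ax in axes:
        k = int(np.argmax(np.abs(ax)))
        if ax[k] < 0:
            ax *= -1.0
    return axes


def _isotropic_offsets(dirs: np.ndarray, params: SamplingParams) -> list[np.ndarray]:
    """9 translations: the null move, both signs of a mid-extent step along
    each of the three directions, and both signs of the full extent along
    the Ca-Cb direction (the dominant side-chain degree of freedom).

    The enumeration count (9, including the unperturbed input) is the
    contract; the composition is a policy.  A sign-symmetric grid is used so
    the sampler can track backbone displacements of either sense.
    """
    mid = 2.0 * params.backbone_step
    offsets = [np.zeros(3)]
    for d in dirs:
        offsets.append(mid * d)
        offsets.append(-mid * d)
    offsets.append(params.backbone_extent * dirs[0])
    offsets.append(-params.backbone_extent * dirs[0])
    return offsets


def _anisotropic_offsets(axes: np.ndarray, params: SamplingParams) -> list[np.ndarray]:
    """81 translations along the displacement-tensor principal axes.

    The enumeration count (81) is the contract; the composition is a policy:
    null + 3 magnitudes x 26 sign patterns (78) + the mixed-magnitude
    diagonal and its negative.
    """
    mags = np.arange(params.backbone_step,
                     params.backbone_extent + 1e-9, params.backbone_step)
    offsets = [np.zeros(3)]
    signs = [-1, 0, 1]
    for m in mags:
        for s0 in signs:
            for s1 in signs:
                for s2 in signs:
                    if s0 == s1 == s2 == 0:
                        continue
                    offsets.append(m * (s0 * axes[0] + s1 * axes[1]
                                        + s2 * axes[2]))
    diag = (mags[0] * axes[0] + mags[min(1, len(mags) - 1)] * axes[1]
            + mags[-1] * axes[2])
    offsets.append(diag)
    offsets.append(-diag)
    return offsets


def sample_backbone(residue: Residue, params: SamplingParams | None = None,
                    base: Conformer | None = None) -> CandidateSet:
    """Collective rigid translation of the residue (N, Ca, C, O backbone with
    the side chain riding along).

    Isotropic B-factors give 9 candidates along the Ca-Cb, C-N and
    (Cb-Ca x C-N) directions; an anisotropic Cb tensor gives 81 along its
    principal axes.  The unperturbed conformer is always candidate 0.
    """
    params = params or SamplingParams()
    conf = base if base is not None else residue.conformers[0]
    for name in BACKBONE_ATOMS:
        if not conf.has_atom(name):
            raise MissingBackboneError(f"{residue.id} missing {name}")
    cb_aniso = None
    if conf.has_atom("CB") and conf.atom("CB").aniso is not None:
        cb_aniso = conf.atom("CB").aniso
    if cb_aniso is not None:
        offsets = _anisotropic_offsets(_principal_axes(cb_aniso), params)
    else:
        offsets = _isotropic_offsets(_isotropic_directions(conf), params)
    out: list[Conformer] = []
    for off in offsets:
        c = conf.copy()
        for atom in c.atoms:
            atom.pos = atom.pos + off
        out.append(c)
    return CandidateSet(residue.id, residue.name, "backbone", out, conf.copy())


def sample_aromatic_angle(candidates: CandidateSet,
                          params: SamplingParams | None = None) -> CandidateSet:
    """Perturb the Ca-Cb-Cg ('aromatic') angle for His/Tyr/Phe/Trp.

    Each input conformer yields 5 outputs at angle offsets
    {-7.5, -3.75, 0, +3.75, +7.5} degrees; other residue types pass through
    unchanged.  The rotation moves the side chain beyond Cb rigidly about an
    axis through Cb normal to the Ca-Cb-Cg plane.
    """
    params = params or SamplingParams()
    if candidates.resname not in AROMATIC_RESIDUES:
        return candidates
    out: list[Conformer] = []
    for conf in candidates.conformers:
        ca = conf.atom("CA").pos
        cb = conf.atom("CB").pos
        cg = conf.atom("CG").pos
        axis = np.cross(ca - cb, cg - cb)
        axis /= np.linalg.norm(axis)
        graph = _bonded_graph(candidates.reference, candidates.resname)
        graph["CB"].discard("CG")
        graph["CG"].discard("CB")
        moving: set[str] = set()
        stack = ["CG"]
        while stack:
            cur = stack.pop()
            if cur in moving:
                continue
            moving.add(cur)
            stack.extend(graph[cur] - moving)
        for off in params.aromatic_offsets():
            c = conf.copy()
            R = _rotation_matrix(axis, off)
            for atom in c.atoms:
                if atom.name in moving:
                    atom.pos = cb + R @ (atom.pos - cb)
            out.append(c)
    return candidates.replaced(out, "aromatic")


def _proline_flap_candidates(conf: Conformer, params: SamplingParams) -> list[Conformer]:
    """Exo/endo pyrrolidine pucker via Cg rotation about the Cb-Cd chord.

    The flap preserves both Cb-Cg and Cg-Cd bond lengths exactly.  The
    mirrored pucker is the rotation carrying Cg to the reflected side of the
    ring plane; each pucker is sampled at the chi grid offsets.
    """
    cb = conf.atom("CB").pos
    cd = conf.atom("CD").pos
    ca = conf.atom("CA").pos
    cg = conf.atom("CG").pos
    axis = cd - cb
    axis /= np.linalg.norm(axis)
    # out-of-plane angle of CG about the CB-CD axis relative to CA
    rel_g = cg - cb
    rel_a = ca - cb
    g_perp = rel_g - axis * (rel_g @ axis)
    a_perp = rel_a - axis * (rel_a @ axis)
    cosang = (g_perp @ a_perp) / (np.linalg.norm(g_perp) * np.linalg.norm(a_perp))
    sinang = (np.cross(a_perp, g_perp) @ axis) / (
        np.linalg.norm(g_perp) * np.linalg.norm(a_perp))
    alpha = np.degrees(np.arctan2(sinang, cosang))
    out: list[Conformer] = []
    for base in (0.0, -2.0 * alpha):     # current pucker and its mirror
        for off in params.chi_offsets():
            c = conf.copy()
            R = _rotation_matrix(axis, base + off)
            at = c.atom("CG")
            at.pos = cb + R @ (at.pos - cb)
            out.append(c)
    return out


def sample_chi(candidates: CandidateSet, chi_index: int,
               library: RotamerLibrary | None = None,
               params: SamplingParams | None = None) -> CandidateSet:
    """Enumerate chi(chi_index) around every idealized rotamer mean.

    Per input conformer: (#means at this chi level) x 9 offsets of
    -24..+24 deg in 6 deg steps.  Proline instead gets 2 ring puckers x 9
    flap offsets.
    """
    params = params or SamplingParams()
    library = library or RotamerLibrary()
    resname = candidates.resname
    n_chi = len(CHI_ATOMS.get(resname, []))
    if chi_index < 1 or chi_index > n_chi:
        raise ValueError(f"{resname} has no chi{chi_index}")
    out: list[Conformer] = []
    if resname == "PRO":
        for conf in candidates.conformers:
            out.extend(_proline_flap_candidates(conf, params))
        return candidates.replaced(out, f"chi_{chi_index}")
    lib_means = library.chi_means(resname, chi_index)
    offsets = params.chi_offsets()

    def circ(a: float, b: float) -> float:
        return (a - b + 180.0) % 360.0 - 180.0

    for conf in candidates.conformers:
        # The input conformation counts as an additional rotamer, so sampling
        # never does worse than the input even when its chi sits between
        # idealized wells.  Its deviation from the nearest idealized mean is
        # largely a property of the local frame (strained or distorted
        # geometry rotates the nominal chi of every well), so the deviation
        # is also carried over to the other rotamer means.
        current = get_chi(conf, resname, chi_index)
        means = list(lib_means)
        if means:
            delta = min((circ(current, m) for m in means), key=abs)
            for m in lib_means:
                means.append(m + delta)
        else:
            means.append(current)
        unique: list[float] = []
        for m in means:
            if not any(abs(circ(m, u)) < params.chi_step / 2 for u in unique):
                unique.append(m)
        for mean in unique:
            for off in offsets:
                out.append(set_chi(conf, resname, chi_index, mean + off))
    return candidates.replaced(out, f"chi_{chi_index}")


def _excluded_pairs(reference: Conformer,
                    resname: str | None = None) -> set[frozenset]:
    """1-2 and 1-3 bonded heavy-atom pairs from the reference topology."""
    graph = _bonded_graph(reference, resname)
    excluded: set[frozenset] = set()
    for a, nbrs in graph.items():
        for b in nbrs:
            excluded.add(frozenset((a, b)))
            for c in graph[b]:
                if c != a:
                    excluded.add(frozenset((a, c)))
    return excluded


def has_internal_clash(conf: Conformer, excluded: set[frozenset],
                       clash_scale: float = CLASH_SCALE) -> bool:
    atoms = conf.heavy_atoms()
    for i, ai in enumerate(atoms):
        ri = VDW_RADII.get(ai.element, 1.7)
        for aj in atoms[i + 1:]:
            if frozenset((ai.name, aj.name)) in excluded:
                continue
            limit = clash_scale * (ri + VDW_RADII.get(aj.element, 1.7))
            if np.linalg.norm(ai.pos - aj.pos) < limit:
                return True
    return False


def prune(candidates: CandidateSet,
          params: SamplingParams | None = None) -> CandidateSet:
    """Drop internally clashing conformers and near-duplicates.

    Greedy first-seen-wins filtering: a candidate is kept iff it has no
    internal hard-sphere overlap (scaled vdW radii, 1-2/1-3 pairs excluded)
    and its all-atom RMSD to every previously kept candidate is at least
    the redundancy threshold (0.01 A).  Idempotent.
    """
    params = params or SamplingParams()
    excluded = _excluded_pairs(candidates.reference, candidates.resname)
    confs = candidates.conformers
    if not confs:
        return candidates.replaced([], candidates.stage)
    coords = np.array([[a.pos for a in c.atoms] for c in confs])
    n_atoms = coords.shape[1]
    kept_idx: list[int] = []
    for i, conf in enumerate(confs):
        if has_internal_clash(conf, excluded, params.clash_scale):
            continue
        if kept_idx:
            diff = coords[kept_idx] - coords[i]
            d2 = np.einsum("kax,kax->k", diff, diff) / n_atoms
            if np.any(d2 < params.redundancy_rmsd ** 2):
                continue
        kept_idx.append(i)
    return candidates.replaced([confs[i] for i in kept_idx], candidates.stage)


def sample_bfactors(candidates: CandidateSet,
                    params: SamplingParams | None = None) -> CandidateSet:
    """Cross every conformer with the B-factor multiplier set.

    Coordinates are unchanged; every atom's B is scaled by the conformer's
    multiplier.  Densities must be recomputed by the caller.
    """
    params = params or SamplingParams()
    out: list[Conformer] = []
    for conf in candidates.conformers:
        for mult in params.bfactor_multipliers:
            c = conf.copy()
            for atom in c.atoms:
                atom.b = atom.b * mult
            out.append(c)
    return candidates.replaced(out, "bfactor")
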