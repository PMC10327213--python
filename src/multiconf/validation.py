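"""Model assessment metrics.

Occupancy-weighted B-factor, the >0.5 A side-chain RMSD multiconformer
criterion, ground-truth match classification, per-atom Q-scores, and
rotamer-agreement categories between two models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from multiconf.density import DensityGrid, sigma2_from_b
from multiconf.structure import (
    Atom,
    CHI_ATOMS,
    Conformer,
    Residue,
    RotamerLibrary,
    Structure,
    conformer_rmsd,
    get_chi,
    sidechain_heavy_names,
)

logger = logging.getLogger(__name__)

MATCH_CUTOFF = 0.5  # A, side-chain heavy-atom RMSD

MATCH_CATEGORIES = ("multiconformer_match", "multiconformer_no_match",
                    "single_match", "single_no_match")
ROTAMER_CATEGORIES = ("consistent", "additional_in_model2",
                      "additional_in_model1", "consistent_and_different",
                      "different")


@dataclass
class MatchReport:
    cutoff: float = MATCH_CUTOFF
    categories: dict[tuple, str] = field(default_factory=dict)

    def fraction(self, category: str) -> float:
        if not self.categories:
            return 0.0
        hits = sum(1 for v in self.categories.values() if v == category)
        return hits / len(self.categories)


def weighted_bfactor(residue: Residue) -> float:
    """Occupancy-weighted B-factor: residue mean of occ * (4*pi/B)^1.5."""
    vals = []
    for conf in residue.conformers:
        for atom in conf.heavy_atoms():
            if atom.b <= 0:
                raise ValueError(f"non-positive B on {atom.name}")
            vals.append(atom.occupancy * (4.0 * np.pi / atom.b) ** 1.5)
    if not vals:
        raise ValueError("residue has no heavy atoms")
    return float(np.mean(vals))


def _comparison_names(residue: Residue) -> list[str]:
    names = sidechain_heavy_names(residue.conformers[0])
    if not names:  # Gly/Ala: no side chain beyond Cb -> all heavy atoms
        names = [a.name for a in residue.conformers[0].heavy_atoms()]
    return names


def is_multiconformer(residue: Residue, cutoff: float = MATCH_CUTOFF) -> bool:
    """True iff some conformer pair differs by more than the side-chain
    heavy-atom RMSD cutoff (nearly-overlapping altlocs do not count)."""
    confs = residue.conformers
    if len(confs) < 2:
        return False
    names = _comparison_names(residue)
    for i in range(len(confs)):
        for j in range(i + 1, len(confs)):
            common = [n for n in names
                      if confs[i].has_atom(n) and confs[j].has_atom(n)]
            if common and conformer_rmsd(confs[i], confs[j], common) > cutoff:
                return True
    return False


def _pair_rmsd(a: Conformer, b: Conformer, names: list[str]) -> float:
    common = [n for n in names if a.has_atom(n) and b.has_atom(n)]
    if not common:
        return np.inf
    return conformer_rmsd(a, b, common)


def classify_match(truth: Residue, test: Residue,
                   cutoff: float = MATCH_CUTOFF) -> str:
    """Match category of a built residue against ground truth.

    The test residue's multiconformer status (under the >cutoff RMSD
    distinctness rule) picks the multiconformer/single axis.  A
    multiconformer match requires the truth to be multiconformer too, every
    test conformer to lie within the cutoff of some truth conformer, and
    every truth conformer to be covered by some test conformer — i.e. the
    distinct conformational states agree; several test conformers
    representing heterogeneity within one state do not break the match,
    because they are not distinct states under the same rule.
    """
    names = _comparison_names(truth)
    test_multi = is_multiconformer(test, cutoff)
    truth_multi = is_multiconformer(truth, cutoff)
    if test_multi:
        if not truth_multi:
            return "multiconformer_no_match"
        test_covered = all(
            min(_pair_rmsd(tc, gc, names) for gc in truth.conformers) <= cutoff
            for tc in test.conformers)
        truth_covered = all(
            min(_pair_rmsd(tc, gc, names) for tc in test.conformers) <= cutoff
            for gc in truth.conformers)
        return ("multiconformer_match" if test_covered and truth_covered
                else "multiconformer_no_match")
    primary = max(test.conformers, key=lambda c: c.occupancy)
    if truth_multi:
        return "single_no_match"
    best = min(_pair_rmsd(primary, gc, names) for gc in truth.conformers)
    return "single_match" if best <= cutoff else "single_no_match"


def classify_model(truth: Structure, test: Structure,
                   cutoff: float = MATCH_CUTOFF) -> MatchReport:
    report = MatchReport(cutoff=cutoff)
    for t_res in truth.residues:
        try:
            q_res = test.get(*t_res.id)
        except KeyError:
            continue
        report.categories[t_res.id] = classify_match(t_res, q_res, cutoff)
    return report


# --- Q-score -----------------------------------------------------------

QSCORE_SHELL_RADII = np.linspace(0.1, 2.0, 8)
QSCORE_POINTS_PER_SHELL = 8


def _shell_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (spherical Fibonacci)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def qscore(atom: Atom, grid: DensityGrid, resolution: float,
           shell_radii: np.ndarray = QSCORE_SHELL_RADII,
           points_per_shell: int = QSCORE_POINTS_PER_SHELL) -> float:
    """Resolvability of one atom: correlation of the radially sampled map
    profile around the atom with the ideal Gaussian profile implied by its
    B-factor and the map resolution.  1 means a perfect fit; a flat local
    map returns 0.
    """
    dirs = _shell_directions(points_per_shell)
    points = [atom.pos]
    ref = [1.0]
    s2 = sigma2_from_b(atom.b, resolution)
    for r in shell_radii:
        g = float(np.exp(-r ** 2 / (2 * s2)))
        for d in dirs:
            points.append(atom.pos + r * d)
            ref.append(g)
    pts = np.array(points)
    idx = grid.xyz_to_index(pts).T
    sampled = map_coordinates(grid.values.astype(float), idx, order=1,
                              mode="nearest")
    ref = np.array(ref)
    if np.std(sampled) < 1e-12 or np.std(ref) < 1e-12:
        logger.info("flat map profile at %s: Q-score 0", atom.name)
        return 0.0
    return float(np.corrcoef(sampled, ref)[0, 1])


def residue_qscore(residue: Residue, grid: DensityGrid,
                   resolution: float) -> float:
    scores = [qscore(a, grid, resolution)
              for c in residue.conformers for a in c.heavy_atoms()]
    return float(np.mean(scores))


def conformer_qscore(conf: Conformer, grid: DensityGrid,
                     resolution: float) -> float:
    return float(np.mean([qscore(a, grid, resolution)
                          for a in conf.heavy_atoms()]))


# --- rotamer agreement -------------------------------------------------


def _circular_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def rotamer_name(conf: Conformer, resname: str,
                 library: RotamerLibrary) -> int | None:
    """Index of the nearest library rotamer over the first two chi angles."""
    rots = library.rotamers(resname)
    n_chi = min(2, len(CHI_ATOMS.get(resname, [])))
    if not rots or n_chi == 0 or resname == "PRO":
        return None
    chis = [get_chi(conf, resname, k + 1) for k in range(n_chi)]
    # collapse to the first-two-chi bins of the library
    bins: list[tuple[float, ...]] = []
    for tup in rots:
        key = tuple(round(v) for v in tup[:n_chi])
        if key not in [tuple(round(v) for v in b) for b in bins]:
            bins.append(tup[:n_chi])
    dists = [max(_circular_diff(c, m) for c, m in zip(chis, b))
             for b in bins]
    return int(np.argmin(dists))


def rotamer_agreement(model1: Structure, model2: Structure,
                      library: RotamerLibrary | None = None) -> dict[tuple, str]:
    """Per-residue rotamer comparison over the first two chi angles.

    Categories: consistent (same rotamer sets), additional_in_model2 /
    additional_in_model1 (one model's set strictly contains the other's),
    consistent_and_different (overlapping but distinct), different
    (disjoint sets).
    """
    library = library or RotamerLibrary()
    out: dict[tuple, str] = {}
    for r1 in model1.residues:
        try:
            r2 = model2.get(*r1.id)
        except KeyError:
            continue
        set1 = {rotamer_name(c, r1.name, library) for c in r1.conformers}
        set2 = {rotamer_name(c, r2.name, library) for c in r2.conformers}
        set1.discard(None)
        set2.discard(None)
        if set1 == set2:
            cat = "consistent"
        elif set1 < set2:
            cat = "additional_in_model2"
        elif set2 < set1:
            cat = "additional_in_model1"
        elif set1 & set2:
            cat = "consistent_and_different"
        else:
            cat = "different"
        out[r1.id] = cat
    return out


def report_csv(report: MatchReport, path) -> None:
    import pandas as pd

    rows = [{"chain": k[0], "seqnum": k[1], "icode": k[2], "category": v}
            for k, v in report.categories.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
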