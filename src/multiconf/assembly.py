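"""Segment assembly: reconnecting independently built residues.

After per-residue building, contiguous runs of multiconformer residues
("segments") need occupancies that are consistent along the backbone and
altloc labels that do not produce steric clashes between spatially adjacent
conformers.  This module identifies segments, re-optimizes occupancies over
sliding three-residue fragment windows with a segment-mode BIC, relabels
altlocs by Monte Carlo annealing of a soft steric overlap energy, repairs
hand-edited models (segment-only mode), and culls/renormalizes low
occupancies for final output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from multiconf.density import (
    DensityGrid,
    OutOfMapError,
    ScatteringMode,
    default_rmask,
    density_from_conformer,
    extract_footprint,
    target_vector,
)
from multiconf.occupancy import BICParams, MIQPConfig, select_by_bic
from multiconf.sampling import VDW_RADII
from multiconf.structure import ALTLOC_LETTERS, Conformer, Residue, Structure

logger = logging.getLogger(__name__)

CULL_CUTOFF = 0.10
CONTACT_RADIUS = 4.0


@dataclass
class Segment:
    """Contiguous run of residues with multiple conformations, delimited on
    both ends by single-conformation residues (or chain breaks)."""

    residue_indices: list[int]   # indices into Structure.residues


def _contiguous(prev: Residue, cur: Residue) -> bool:
    return (prev.chain == cur.chain
            and (cur.seqnum - prev.seqnum) in (0, 1))


def identify_segments(model: Structure) -> list[Segment]:
    """Maximal contiguous runs of multiconformer residues."""
    segments: list[Segment] = []
    current: list[int] = []
    prev: Residue | None = None
    for i, res in enumerate(model.residues):
        multi = len(res.conformers) > 1
        broken = prev is not None and not _contiguous(prev, res)
        if current and (not multi or broken):
            segments.append(Segment(current))
            current = []
        if multi:
            current.append(i)
        prev = res
    if current:
        segments.append(Segment(current))
    return segments


def _fragment_conformer(residues: list[Residue], choice: tuple[int, ...]) -> Conformer:
    atoms = []
    for res, ci in zip(residues, choice):
        atoms.extend(a.copy() for a in res.conformers[ci].atoms)
    frag = Conformer("", atoms, 1.0)
    for a in frag.atoms:
        a.occupancy = 1.0
    return frag


def optimize_segment(model: Structure, segment: Segment, grid: DensityGrid,
                     mode: ScatteringMode, resolution: float,
                     config: MIQPConfig | None = None,
                     bic_params: BICParams | None = None,
                     rmask: float | None = None) -> None:
    """Harmonize occupancies along a segment (in place).

    A window of up to three residues slides N-to-C; within each window every
    cross-product of member conformations is a fragment candidate scored by
    the density fit, and the BIC (segment mode: k = number of conformations)
    selects the fragment set.  Conformers not used by any selected fragment
    are culled; a conformer's occupancy becomes the summed weight of the
    selected fragments containing it, so paired neighbors end up sharing
    occupancies.
    """
    import itertools

    config = config or MIQPConfig()
    bic_params = bic_params or BICParams(k_mode="segment")
    if bic_params.k_mode != "segment":
        bic_params = BICParams(bic_params.scaling_factor, "segment")
    rmask = rmask if rmask is not None else default_rmask(resolution)
    idxs = segment.residue_indices
    if len(idxs) < 2:
        return
    width = min(3, len(idxs))
    for start in range(0, len(idxs) - width + 1):
        window = idxs[start:start + width]
        residues = [model.residues[i] for i in window]
        choices = list(itertools.product(
            *[range(len(r.conformers)) for r in residues]))
        if len(choices) < 2:
            continue
        frags = [_fragment_conformer(residues, ch) for ch in choices]
        try:
            fp = extract_footprint(frags, grid, rmask)
        except OutOfMapError:
            logger.info("segment window %s outside map", window)
            continue
        densities = np.stack([
            density_from_conformer(f, fp, mode, resolution) for f in frags])
        target = target_vector(grid, fp, mode)
        sol = select_by_bic(densities, target, config, bic_params,
                            n_atoms=1, conformers=frags)
        if not sol.selected:
            continue
        keep_weights: list[dict[int, float]] = [dict() for _ in residues]
        for sel, w in zip(sol.selected, sol.weights):
            for pos, ci in enumerate(choices[sel]):
                keep_weights[pos][ci] = keep_weights[pos].get(ci, 0.0) + float(w)
        for pos, res in enumerate(residues):
            kept = sorted(keep_weights[pos])
            if not kept:
                continue
            new_confs = []
            for rank, ci in enumerate(kept):
                conf = res.conformers[ci]
                conf.set_occupancy(round(keep_weights[pos][ci], 4))
                new_confs.append(conf)
            for rank, conf in enumerate(new_confs):
                conf.altloc = "" if len(new_confs) == 1 else ALTLOC_LETTERS[rank]
            res.conformers = new_confs


def _clash_energy_pairs(model: Structure) -> list[tuple]:
    """Inter-residue heavy-atom pairs within the contact radius.

    Precomputed over all conformer pairs of different residues; the energy
    of a labeling counts only pairs whose altlocs interact (equal letters,
    or either blank).
    """
    entries = []   # (res_i, conf_i, res_j, conf_j, overlap^2)
    residues = model.residues
    coords = []
    for ri, res in enumerate(residues):
        for ci, conf in enumerate(res.conformers):
            for atom in conf.heavy_atoms():
                coords.append((ri, ci, atom))
    for a in range(len(coords)):
        ri, ci, ai = coords[a]
        ra = VDW_RADII.get(ai.element, 1.7)
        for b in range(a + 1, len(coords)):
            rj, cj, aj = coords[b]
            if ri == rj:
                continue
            d = float(np.linalg.norm(ai.pos - aj.pos))
            if d > CONTACT_RADIUS:
                continue
            overlap = ra + VDW_RADII.get(aj.element, 1.7) - d
            if overlap > 0:
                entries.append((ri, ci, rj, cj, overlap ** 2))
    return entries


def _labeling_energy(entries, labels: dict[int, list[int]]) -> float:
    """Soft steric energy of a labeling: sum of squared overlaps over
    same-altloc (or blank) atom pairs of different residues."""
    e = 0.0
    for ri, ci, rj, cj, pen in entries:
        li = labels[ri][ci]
        lj = labels[rj][cj]
        if li == -1 or lj == -1 or li == lj:
            e += pen
    return e


def relabel(model: Structure, seed: int = 0) -> Structure:
    """Assign altloc letters to minimize same-altloc steric clashes.

    Monte Carlo with label-swap proposals within one residue, linearly
    annealed temperature, best-seen state returned, so the final energy
    never exceeds the initial one.  Reproducible for a fixed seed.
    """
    out = model.copy()
    entries = _clash_energy_pairs(out)
    multi = [i for i, r in enumerate(out.residues) if len(r.conformers) > 1]
    # label index per conformer: -1 for blank (single-conformer residues)
    labels = {i: ([-1] if len(r.conformers) == 1
                  else list(range(len(r.conformers))))
              for i, r in enumerate(out.residues)}
    if not multi or not entries:
        return out
    rng = np.random.default_rng(seed)
    energy = _labeling_energy(entries, labels)
    best_energy = energy
    best_labels = {i: list(v) for i, v in labels.items()}
    n_steps = 10 * len(multi) ** 2
    t0 = max(best_energy, 1.0)
    for step in range(n_steps):
        temp = t0 * (1.0 - step / n_steps) + 1e-9
        ri = multi[int(rng.integers(len(multi)))]
        k = len(labels[ri])
        a, b = rng.choice(k, size=2, replace=False)
        labels[ri][a], labels[ri][b] = labels[ri][b], labels[ri][a]
        new_energy = _labeling_energy(entries, labels)
        if (new_energy <= energy
                or rng.random() < np.exp(-(new_energy - energy) / temp)):
            energy = new_energy
            if energy < best_energy:
                best_energy = energy
                best_labels = {i: list(v) for i, v in labels.items()}
        else:
            labels[ri][a], labels[ri][b] = labels[ri][b], labels[ri][a]
    for i, res in enumerate(out.residues):
        if len(res.conformers) > 1:
            for conf, lab in zip(res.conformers, best_labels[i]):
                conf.altloc = ALTLOC_LETTERS[lab]
            res.conformers.sort(key=lambda c: c.altloc)
    return out


def clash_energy(model: Structure) -> float:
    """Current same-altloc steric energy of a model (diagnostic)."""
    entries = _clash_energy_pairs(model)
    labels = {}
    for i, r in enumerate(model.residues):
        labels[i] = [(-1 if not c.altloc else ALTLOC_LETTERS.index(c.altloc))
                     for c in r.conformers]
    return _labeling_energy(entries, labels)


def equalize_segment_conformers(model: Structure, segment: Segment) -> None:
    """Duplicate conformers so all segment residues have equal counts.

    Duplicates split their parent's occupancy equally; per-residue occupancy
    totals are preserved exactly.
    """
    idxs = segment.residue_indices
    target = max(len(model.residues[i].conformers) for i in idxs)
    for i in idxs:
        res = model.residues[i]
        confs = res.conformers
        n = len(confs)
        if n == target:
            continue
        total_needed = target - n
        copies_per = [total_needed // n + (1 if k < total_needed % n else 0)
                      for k in range(n)]
        new_confs = []
        for conf, extra in zip(confs, copies_per):
            share = conf.occupancy / (extra + 1)
            conf.set_occupancy(share)
            new_confs.append(conf)
            for _ in range(extra):
                dup = conf.copy()
                dup.set_occupancy(share)
                new_confs.append(dup)
        for rank, conf in enumerate(new_confs):
            conf.altloc = ALTLOC_LETTERS[rank]
        res.conformers = new_confs


def segment_only(model: Structure, grid: DensityGrid | None = None,
                 mode: ScatteringMode | None = None,
                 resolution: float | None = None,
                 seed: int = 0) -> Structure:
    """Repair a (possibly hand-edited) multiconformer model.

    Within each segment conformer counts are equalized by duplication, then
    occupancies are re-optimized against the map (when one is supplied) and
    altlocs relabeled; finally per-residue occupancies are normalized to 1.
    """
    out = model.copy()
    segments = identify_segments(out)
    for seg in segments:
        equalize_segment_conformers(out, seg)
        if grid is not None and mode is not None and resolution is not None:
            optimize_segment(out, seg, grid, mode, resolution)
    out = relabel(out, seed)
    for res in out.residues:
        total = res.total_occupancy()
        if total > 0:
            for conf in res.conformers:
                conf.set_occupancy(conf.occupancy / total)
    return out


def cull_low_occupancy(model: Structure, cutoff: float = CULL_CUTOFF) -> Structure:
    """Remove conformers below the occupancy cutoff and renormalize to 1.

    If every conformer is below the cutoff the highest-occupancy one is kept
    at occupancy 1.  Single-conformer residues get a blank altloc.
    Idempotent.
    """
    out = model.copy()
    for res in out.residues:
        kept = [c for c in res.conformers if c.occupancy >= cutoff]
        if not kept:
            kept = [max(res.conformers, key=lambda c: c.occupancy)]
        total = sum(c.occupancy for c in kept)
        for c in kept:
            c.set_occupancy(c.occupancy / total if total > 0 else 1.0 / len(kept))
        if len(kept) == 1:
            kept[0].altloc = ""
            kept[0].set_occupancy(1.0)
        else:
            for rank, c in enumerate(kept):
                c.altloc = ALTLOC_LETTERS[rank]
        res.conformers = kept
    return out


def write_occupancy_restraints(model: Structure, path) -> None:
    """Write per-segment group occupancy restraints.

    One group per (segment, altloc): a Phenix-style selection naming the
    chain, the residue range and the altloc letter, so refinement can
    constrain all members of a segment's alternative conformation to one
    occupancy.
    """
    segments = identify_segments(model)
    with open(path, "w") as fh:
        fh.write("# group occupancy restraints: one group per segment altloc\n")
        for seg in segments:
            residues = [model.residues[i] for i in seg.residue_indices]
            chain = residues[0].chain
            lo = min(r.seqnum for r in residues)
            hi = max(r.seqnum for r in residues)
            altlocs = sorted({c.altloc for r in residues for c in r.conformers
                              if c.altloc})
            for alt in altlocs:
                fh.write("group {\n")
                fh.write(f"  selection = (chain {chain} and resseq {lo}:{hi} "
                         f"and altloc {alt})\n")
                fh.write("}\n")
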