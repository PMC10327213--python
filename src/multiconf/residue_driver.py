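"""Per-residue multiconformer building and the Q-score gate.

Residues are independent units of work: the driver never mutates shared
state, candidate ordering is fixed, and no RNG is used, so building residues
in any order (or concurrently) yields identical models.  Each residue can be
scored against a sub-grid covering its footprint instead of the whole map;
results are identical as long as the sub-grid covers the candidates plus
the footprint margin.
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
    extract_footprint,
    target_vector,
)
from multiconf.occupancy import (
    BICParams,
    MIQPConfig,
    MIQPInfeasibleError,
    miqp_solve,
    nonconvex_fallback,
    qp_solve,
    select_by_bic,
)
from multiconf.sampling import (
    CandidateSet,
    MissingBackboneError,
    SamplingParams,
    prune,
    sample_aromatic_angle,
    sample_backbone,
    sample_bfactors,
    sample_chi,
)
from multiconf.structure import (
    ALTLOC_LETTERS,
    CHI_ATOMS,
    Conformer,
    Residue,
    RotamerLibrary,
    Structure,
    conformer_rmsd,
    strip_hydrogens,
)

logger = logging.getLogger(__name__)

# weight floor and cap for conformers carried from the QP reduction stage
QP_KEEP_MIN_WEIGHT = 0.002
QP_KEEP_MAX = 15


def _score_candidates(cset: CandidateSet, grid: DensityGrid,
                      mode: ScatteringMode, resolution: float,
                      rmask: float):
    """Shared footprint, per-candidate unit-occupancy densities, target."""
    from multiconf.density import sigma2_from_b

    fp = extract_footprint(cset.conformers, grid, rmask)
    amps = mode.amplitudes
    n_cand = len(cset.conformers)
    densities = np.zeros((n_cand, fp.n))
    # vectorized Gaussian synthesis over (candidates x atoms x voxels)
    pos = np.array([[a.pos for a in c.atoms] for c in cset.conformers])
    s2 = np.array([[sigma2_from_b(a.b, resolution) for a in c.atoms]
                   for c in cset.conformers])
    amp = np.array([[amps.get(a.element, 6.0) for a in c.atoms]
                    for c in cset.conformers])
    chunk = max(1, int(2e7 // (pos.shape[1] * fp.n + 1)))
    for lo in range(0, n_cand, chunk):
        hi = min(lo + chunk, n_cand)
        diff = pos[lo:hi, :, None, :] - fp.xyz[None, None, :, :]
        r2 = np.einsum("canx,canx->can", diff, diff)
        densities[lo:hi] = np.sum(
            amp[lo:hi, :, None] * (2 * np.pi * s2[lo:hi, :, None]) ** -1.5
            * np.exp(-r2 / (2 * s2[lo:hi, :, None])), axis=1)
    target = target_vector(grid, fp, mode)
    cset.densities = densities
    cset.footprint = fp
    return densities, target, fp


def _qp_reduce(cset: CandidateSet, densities, target) -> CandidateSet:
    """One QP pass keeping the best-supported conformers (paper: 5-15)."""
    sol = qp_solve(densities, target)
    pairs = [(i, w) for i, w in zip(sol.selected, sol.weights)
             if w >= QP_KEEP_MIN_WEIGHT]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    keep = sorted(i for i, _ in pairs[:QP_KEEP_MAX])
    if not keep:
        keep = [0]
    return cset.replaced([cset.conformers[i] for i in keep], cset.stage)


def _miqp_select(cset: CandidateSet, densities, target,
                 config: MIQPConfig) -> CandidateSet:
    try:
        sol = miqp_solve(densities, target, config)
    except MIQPInfeasibleError:
        sol = nonconvex_fallback(densities, target, config,
                                 conformers=cset.conformers)
    kept = [cset.conformers[i] for i in sol.selected]
    return cset.replaced(kept if kept else [cset.conformers[0]], cset.stage)


def _merge_duplicates(conformers: list[Conformer], weights: list[float],
                      rmsd_tol: float = 0.01):
    """Sum weights of coordinate-identical conformers (B-variants)."""
    out_confs: list[Conformer] = []
    out_w: list[float] = []
    for conf, w in zip(conformers, weights):
        for j, kept in enumerate(out_confs):
            if conformer_rmsd(conf, kept) < rmsd_tol:
                out_w[j] += w
                break
        else:
            out_confs.append(conf)
            out_w.append(w)
    return out_confs, out_w


def build_residue(residue: Residue, grid: DensityGrid, mode: ScatteringMode,
                  resolution: float,
                  params: SamplingParams | None = None,
                  config: MIQPConfig | None = None,
                  bic_params: BICParams | None = None,
                  library: RotamerLibrary | None = None,
                  rmask: float | None = None,
                  idealize: bool = True) -> Residue:
    """Build a parsimonious multiconformer for one residue.

    Pipeline: strip hydrogens, backbone translations, aromatic-angle
    perturbation where applicable, then per chi level: rotamer-grid
    sampling, pruning, a QP reduction, B-factor expansion and an MIQP
    selection capped at five conformers; at the terminal chi the MIQP is
    replaced by BIC selection over cardinalities 1..5.  Gly/Ala stop after
    backbone scoring.  Residues that cannot be built (missing backbone,
    outside the map, non-standard) are returned unchanged.
    """
    params = params or SamplingParams()
    config = config or MIQPConfig()
    bic_params = bic_params or BICParams(k_mode="residue")
    library = library or RotamerLibrary()
    rmask = rmask if rmask is not None else default_rmask(resolution)

    if not residue.is_standard():
        logger.info("skip %s %s: non-standard", residue.id, residue.name)
        return residue
    work = Residue(residue.chain, residue.seqnum, residue.icode, residue.name,
                   [residue.conformers[0].copy()])
    work = _strip_residue_h(work)
    bases = [work.conformers[0]]
    if idealize:
        # also sample from an ideal-geometry copy of the side chain: the
        # input template may carry geometry distortion, the ideal template
        # may sit off the density — candidates from both let the fit decide
        from multiconf.peptide import idealize_sidechain

        ideal = idealize_sidechain(work.conformers[0], residue.name)
        if conformer_rmsd(ideal, work.conformers[0]) > 1e-3:
            bases.append(ideal)

    try:
        csets = [sample_backbone(work, params, base=b) for b in bases]
        cset = csets[0]
        for extra in csets[1:]:
            cset = cset.replaced(cset.conformers + extra.conformers,
                                 cset.stage)
    except MissingBackboneError:
        logger.info("skip %s: incomplete backbone", residue.id)
        return residue

    n_chi = len(CHI_ATOMS.get(residue.name, []))
    try:
        if residue.name in ("GLY", "ALA") or n_chi == 0:
            cset = prune(cset, params)
            densities, target, fp = _score_candidates(
                cset, grid, mode, resolution, rmask)
            cset = _qp_reduce(cset, densities, target)
            return _final_select(cset, grid, mode, resolution, rmask,
                                 params, config, bic_params, residue)
        cset = sample_aromatic_angle(cset, params)
        chi_levels = 1 if residue.name == "PRO" else n_chi
        for chi_index in range(1, chi_levels + 1):
            terminal = chi_index == chi_levels
            cset = sample_chi(cset, chi_index, library, params)
            cset = prune(cset, params)
            if not cset.conformers:
                cset = cset.replaced([cset.reference.copy()], cset.stage)
            densities, target, fp = _score_candidates(
                cset, grid, mode, resolution, rmask)
            cset = _qp_reduce(cset, densities, target)
            if terminal:
                return _final_select(cset, grid, mode, resolution, rmask,
                                     params, config, bic_params, residue)
            cset = sample_bfactors(cset, params)
            densities, target, fp = _score_candidates(
                cset, grid, mode, resolution, rmask)
            cset = _miqp_select(cset, densities, target, config)
    except OutOfMapError:
        logger.info("skip %s: outside map", residue.id)
        return residue
    raise AssertionError("unreachable")  # pragma: no cover


def _final_select(cset: CandidateSet, grid, mode, resolution, rmask,
                  params, config, bic_params, residue: Residue) -> Residue:
    """Terminal scoring: B-factor expansion then BIC over cardinalities."""
    cset = sample_bfactors(cset, params)
    densities, target, fp = _score_candidates(cset, grid, mode, resolution,
                                              rmask)
    n_atoms = len(cset.reference.heavy_atoms())
    sol = select_by_bic(densities, target, config, bic_params,
                        n_atoms=n_atoms, conformers=cset.conformers)
    confs = [cset.conformers[i] for i in sol.selected]
    weights = [float(w) for w in sol.weights]
    if not confs:
        confs, weights = [cset.reference.copy()], [1.0]
    confs, weights = _merge_duplicates(confs, weights)
    order = sorted(range(len(confs)), key=lambda i: (-weights[i], i))
    out = Residue(residue.chain, residue.seqnum, residue.icode, residue.name,
                  [])
    for rank, i in enumerate(order):
        conf = confs[i]
        conf.altloc = "" if len(order) == 1 else ALTLOC_LETTERS[rank]
        conf.set_occupancy(round(weights[i], 4))
        out.conformers.append(conf)
    return out


def _strip_residue_h(residue: Residue) -> Residue:
    for conf in residue.conformers:
        conf.atoms = [a for a in conf.atoms if a.element != "H"]
    return residue


def subgrid_around(grid: DensityGrid, conformers: list[Conformer],
                   margin: float) -> DensityGrid:
    """Extract the sub-grid covering the conformers plus a margin.

    Building a residue against its sub-grid gives results identical to the
    full map as long as the margin covers the footprint radius.
    """
    coords = np.concatenate([c.coords() for c in conformers])
    lo_xyz = coords.min(axis=0) - margin
    hi_xyz = coords.max(axis=0) + margin
    lo = np.maximum(np.floor(grid.xyz_to_index(lo_xyz)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.xyz_to_index(hi_xyz)).astype(int) + 1,
                    np.array(grid.shape))
    values = grid.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
    return DensityGrid(values, grid.spacing.copy(),
                       grid.origin + lo * grid.spacing)


def read_qscores(path) -> dict[tuple[str, int], float]:
    """Whitespace-delimited ``chain resnum qscore`` lines."""
    out: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 3 or parts[0].startswith("#"):
                continue
            out[(parts[0], int(parts[1]))] = float(parts[2])
    return out


def qscore_gate(residue: Residue,
                qscores: dict[tuple[str, int], float] | None,
                cutoff: float = 0.7) -> bool:
    """True if the residue should get multiconformer building.

    Residues scoring below the cutoff are left single-conformer (they still
    participate in segment assembly).  With no Q-score table the feature is
    off and everything passes; residues missing from the table pass with a
    log note.
    """
    if qscores is None:
        return True
    key = (residue.chain, residue.seqnum)
    if key not in qscores:
        logger.info("no Q-score for %s; passing", residue.id)
        return True
    return qscores[key] >= cutoff


def build_model(structure: Structure, grid: DensityGrid,
                mode: ScatteringMode, resolution: float,
                params: SamplingParams | None = None,
                config: MIQPConfig | None = None,
                bic_params: BICParams | None = None,
                library: RotamerLibrary | None = None,
                rmask: float | None = None,
                qscores: dict | None = None,
                qscore_cutoff: float = 0.7,
                use_subgrids: bool = True) -> Structure:
    """Run the per-residue builder over a whole structure."""
    rmask_eff = rmask if rmask is not None else default_rmask(resolution)
    out = Structure()
    source = strip_hydrogens(structure)
    for residue in source.residues:
        if not qscore_gate(residue, qscores, qscore_cutoff):
            out.residues.append(residue.copy())
            continue
        g = grid
        if use_subgrids:
            try:
                # margin: farthest chi-swing of a long side chain + footprint
                g = subgrid_around(grid, residue.conformers,
                                   8.0 + 2.0 * rmask_eff)
            except (ValueError, IndexError):
                g = grid
        built = build_residue(residue, g, mode, resolution, params, config,
                              bic_params, library, rmask)
        out.residues.append(built)
    return out
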