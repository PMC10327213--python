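"""Occupancy fitting: QP, cardinality/threshold-constrained MIQP, and BIC.

The occupancy problem is a constrained least-squares fit: find weights w
minimizing ``|| target - sum_i w_i rho_i ||^2`` subject to ``w >= 0`` and
``sum w <= 1`` (the deficit absorbs unmodeled disorder).  The MIQP variant
additionally caps the number of selected conformers (cardinality <= 5) and
forces every selected weight above an occupancy threshold (0.2 X-ray /
0.3 EM).

Both problems are solved deterministically without an external MIQP
backend: the QP via non-negative least squares on an augmented system (a
slack variable turns the sum constraint into an equality enforced by a
large penalty row), and the MIQP via exhaustive enumeration of candidate
subsets in Gram-matrix space, preceded by a QP prescreen that keeps the
top-weighted candidates when the pool is large.  Subset solves work on the
Cholesky factor of the subset Gram matrix, so their cost is independent of
footprint size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

WEIGHT_PRUNE = 1e-4       # weights below this are dropped from `selected`
FEASIBILITY_TOL = 1e-6
PRESCREEN_POOL = 12       # max subset-enumeration pool size


class SolverError(RuntimeError):
    def __init__(self, status: str):
        super().__init__(f"occupancy solver failed: {status}")
        self.status = status


class MIQPInfeasibleError(SolverError):
    """No subset satisfied the cardinality/threshold constraints."""


@dataclass
class OccupancySolution:
    selected: list[int]
    weights: np.ndarray
    rss: float
    cardinality_used: int
    bic: float | None = None

    def weight_of(self, index: int) -> float:
        return float(self.weights[self.selected.index(index)])


@dataclass
class BICParams:
    scaling_factor: float = 0.95
    k_mode: str = "residue"

    def __post_init__(self):
        if not 0 < self.scaling_factor <= 1:
            raise ValueError("scaling factor must be in (0, 1]")
        if self.k_mode not in ("residue", "segment"):
            raise ValueError(f"unknown k_mode {self.k_mode!r}")


@dataclass
class MIQPConfig:
    cardinality: int = 5
    threshold: float = 0.2

    def __post_init__(self):
        if not 1 <= self.cardinality <= 5:
            raise ValueError("cardinality must be in 1..5")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def for_mode(cls, mode: str, cardinality: int = 5) -> "MIQPConfig":
        return cls(cardinality=cardinality,
                   threshold=0.3 if mode == "em" else 0.2)


def _as_matrix(densities) -> np.ndarray:
    A = np.asarray(densities, dtype=float)
    if A.ndim != 2:
        raise ValueError("densities must be a 2-D (candidates x voxels) array")
    return A


def qp_solve(densities, target) -> OccupancySolution:
    """Least-squares occupancies with w >= 0 and sum(w) <= 1.

    Solved as NNLS on an augmented system: a non-negative slack s with the
    equality ``sum w + s = 1`` enforced by a penalty row much larger than
    the data scale.
    """
    A = _as_matrix(densities)          # (m, nvox)
    b = np.asarray(target, dtype=float)
    m = A.shape[0]
    if m == 0:
        raise ValueError("need at least one candidate")
    scale = max(1.0, float(np.abs(A).max()), float(np.abs(b).max()))
    mu = 1e5 * scale
    design = np.zeros((A.shape[1] + 1, m + 1))
    design[:-1, :-1] = A.T
    design[-1, :] = mu
    rhs = np.concatenate([b, [mu]])
    try:
        sol, _ = nnls(design, rhs)
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise SolverError(str(exc)) from exc
    w = sol[:-1]
    resid = b - A.T @ w
    rss = float(resid @ resid)
    selected = [i for i in range(m) if w[i] >= WEIGHT_PRUNE]
    return OccupancySolution(selected, w[selected], rss, len(selected))


def _gram(A: np.ndarray, b: np.ndarray):
    return A @ A.T, A @ b, float(b @ b)


def _subset_qp(G: np.ndarray, c: np.ndarray, bb: float, subset: tuple[int, ...],
               threshold: float) -> tuple[float, np.ndarray] | None:
    """Constrained LS on one subset: w_i >= threshold, sum w <= 1.

    Works on the Cholesky factor of the subset Gram matrix; returns
    (rss, weights) or None if infeasible.
    """
    k = len(subset)
    cap = 1.0 - k * threshold
    if cap < -FEASIBILITY_TOL:
        return None
    cap = max(cap, 0.0)
    idx = list(subset)
    Gs = G[np.ix_(idx, idx)]
    cs = c[idx]
    jitter = 1e-10 * max(np.trace(Gs), 1.0)
    try:
        L = np.linalg.cholesky(Gs + jitter * np.eye(k))
    except np.linalg.LinAlgError:
        return None
    # substitute w = threshold + u, u >= 0, sum u <= cap
    shift = threshold * Gs.sum(axis=1)
    y = np.linalg.solve(L, cs - shift)
    mu = 1e5 * max(1.0, float(np.abs(L).max()))
    design = np.zeros((k + 1, k + 1))
    design[:k, :k] = L.T
    design[k, :] = mu
    rhs = np.concatenate([y, [mu * cap]])
    u, _ = nnls(design, rhs)
    w = threshold + u[:k]
    rss = bb - 2.0 * float(cs @ w) + float(w @ Gs @ w)
    return max(rss, 0.0), w


def _prescreen(A: np.ndarray, b: np.ndarray, pool_size: int) -> list[int]:
    """Indices of the candidates kept for subset enumeration."""
    m = A.shape[0]
    if m <= pool_size:
        return list(range(m))
    qp = qp_solve(A, b)
    full = np.zeros(m)
    full[qp.selected] = qp.weights
    # stable sort: descending weight, ascending index on ties
    order = np.argsort(-full, kind="stable")
    return sorted(int(i) for i in order[:pool_size])


def _best_per_cardinality(A: np.ndarray, b: np.ndarray, config: MIQPConfig,
                          pool: list[int] | None = None
                          ) -> dict[int, OccupancySolution]:
    """One enumeration pass; best subset solution for each cardinality."""
    if pool is None:
        pool = _prescreen(A, b, PRESCREEN_POOL)
    G, c, bb = _gram(A, b)
    best: dict[int, OccupancySolution] = {}
    for k in range(1, config.cardinality + 1):
        if k > len(pool):
            break
        best_rss = np.inf
        best_sub: tuple[int, ...] | None = None
        best_w: np.ndarray | None = None
        for subset in itertools.combinations(pool, k):
            res = _subset_qp(G, c, bb, subset, config.threshold)
            if res is None:
                continue
            rss, w = res
            if rss < best_rss - 1e-12:
                best_rss, best_sub, best_w = rss, subset, w
        if best_sub is not None:
            best[k] = OccupancySolution(list(best_sub), best_w, best_rss, k)
    return best


def miqp_solve(densities, target, config: MIQPConfig) -> OccupancySolution:
    """QP objective plus cardinality and minimum-weight constraints."""
    A = _as_matrix(densities)
    b = np.asarray(target, dtype=float)
    per_card = _best_per_cardinality(A, b, config)
    if not per_card:
        raise MIQPInfeasibleError("no feasible subset")
    # lowest rss; ties broken toward fewer conformers
    best_k = min(per_card, key=lambda k: (per_card[k].rss, k))
    return per_card[best_k]


def nonconvex_fallback(densities, target, config: MIQPConfig,
                       conformers=None) -> OccupancySolution:
    """Iteratively drop one of the two closest candidates until MIQP succeeds.

    Proximity is conformer all-atom RMSD when conformers are supplied,
    otherwise the RMS difference of the candidate density vectors.  The
    later-indexed member of the closest pair is removed each round, so the
    procedure terminates in at most n-1 iterations.
    """
    from multiconf.structure import conformer_rmsd

    A = _as_matrix(densities)
    b = np.asarray(target, dtype=float)
    alive = list(range(A.shape[0]))
    while True:
        try:
            sol = miqp_solve(A[alive], b, config)
            return OccupancySolution([alive[i] for i in sol.selected],
                                     sol.weights, sol.rss,
                                     sol.cardinality_used)
        except MIQPInfeasibleError:
            if len(alive) == 1:
                sub = qp_solve(A[alive], b)
                return OccupancySolution([alive[i] for i in sub.selected],
                                         sub.weights, sub.rss,
                                         sub.cardinality_used)
        best = None
        for ii in range(len(alive)):
            for jj in range(ii + 1, len(alive)):
                i, j = alive[ii], alive[jj]
                if conformers is not None:
                    d = conformer_rmsd(conformers[i], conformers[j])
                else:
                    d = float(np.sqrt(np.mean((A[i] - A[j]) ** 2)))
                if best is None or d < best[0]:
                    best = (d, j)
        alive.remove(best[1])


def compute_bic(rss: float, n: int, k: int,
                params: BICParams | None = None) -> float:
    """Bayesian information criterion: n*ln(rss/n) + k*ln(n)*scaling_factor."""
    params = params or BICParams()
    if n <= 1:
        raise ValueError("need n > 1 voxels for BIC")
    if k < 1:
        raise ValueError("need k >= 1 parameters")
    if rss <= 0:
        logger.warning("BIC rss clamp: rss=%g <= 0", rss)
        rss = np.finfo(float).eps * n
    return float(n * np.log(rss / n) + k * np.log(n) * params.scaling_factor)


def parameter_count(n_conformers: int, n_atoms: int,
                    mode: str = "residue") -> int:
    """k for the BIC: 4 per atom per conformer (x,y,z,B), or the conformer
    count in segment mode."""
    if n_conformers < 1 or n_atoms < 1:
        raise ValueError("counts must be positive")
    if mode == "segment":
        return n_conformers
    return 4 * n_conformers * n_atoms


def select_by_bic(densities, target, config: MIQPConfig,
                  bic_params: BICParams | None = None,
                  n_atoms: int = 1,
                  conformers=None) -> OccupancySolution:
    """Run MIQP at every cardinality 1..max and return the lowest-BIC fit.

    Ties go to the smaller cardinality (parsimony).  If every cardinality is
    infeasible even after the fallback, the best single-candidate QP fit is
    returned.
    """
    bic_params = bic_params or BICParams()
    A = _as_matrix(densities)
    b = np.asarray(target, dtype=float)
    n = len(b)
    per_card = _best_per_cardinality(A, b, config)
    if not per_card:
        # all cardinalities infeasible: best single-candidate QP fit
        best = None
        for i in range(A.shape[0]):
            sub = qp_solve(A[i:i + 1], b)
            if best is None or sub.rss < best.rss:
                best = OccupancySolution([i] if sub.selected else [],
                                         sub.weights, sub.rss,
                                         sub.cardinality_used)
        return best
    best_sol = None
    for k in sorted(per_card):
        sol = per_card[k]
        kparams = parameter_count(k, n_atoms, bic_params.k_mode)
        sol.bic = compute_bic(sol.rss, n, kparams, bic_params)
        if best_sol is None or sol.bic < best_sol.bic - 1e-12:
            best_sol = sol
    return best_sol
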