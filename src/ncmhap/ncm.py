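"""Phase 2: neutrosophic c-means (NCM) clustering of partially observed
binary fragment vectors.

NCM extends fuzzy c-means with two extra memberships per data point: an
*indeterminacy* degree I_i tied to the boundary between the point's two
closest clusters, and an *outlier* (falsity) degree F_i tied to a constant
regularization distance delta. For every point the determinate memberships
T_ij, I_i and F_i sum to one, so a noisy fragment that fits neither
haplotype sheds determinate weight into I and F instead of dragging a
cluster center toward itself — this is the mechanism by which the method
tolerates high sequencing-error rates.

The objective minimized by alternating updates is

    J(T, I, F, C) = sum_ij w1 T_ij^m d2(x_i, c_j)
                  + sum_i  w2 I_i^m  d2(x_i, cbar_i)
                  + sum_i  delta^2 w3 F_i^m

where d2 is the squared distance *averaged over the fragment's observed
sites* (so fragments of different coverage are comparable and delta has a
consistent scale) and cbar_i is the midpoint of the point's two strongest
centers — with two clusters, always (c1 + c2) / 2. The membership weights
enter linearly: this is the objective whose exact per-point minimizers are
the classic NCM membership updates T_ij ~ (1/w1) d^(-1/(m-1)),
I_i ~ (1/w2) dbar^(-1/(m-1)), F_i ~ (1/w3) (delta^2)^(-1/(m-1)); writing
the weights inside the power, as parts of the NCM literature typeset it,
is inconsistent with those same updates and would break the descent
property of the alternation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fragments import SNPMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NCMParams:
    """NCM hyperparameters.

    Defaults follow the tuned operating point for diploid fragment
    clustering: fuzzifier m=2 and tolerance 1e-5 as in standard fuzzy
    c-means, outlier regularizer delta=25, membership weights
    (w1, w2, w3) = (0.7, 0.2, 0.1).
    """

    m_fuzz: float = 2.0
    epsilon: float = 1e-5
    delta: float = 25.0
    w1: float = 0.7
    w2: float = 0.2
    w3: float = 0.1
    max_iter: int = 100
    n_clusters: int = 2

    def __post_init__(self) -> None:
        if self.m_fuzz <= 1:
            raise ValueError("m_fuzz must be > 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if min(self.w1, self.w2, self.w3) <= 0:
            raise ValueError("membership weights must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_clusters != 2:
            raise ValueError("only two clusters are supported (diploid phasing)")


@dataclass
class NCMState:
    """Clustering state returned by :func:`ncm_cluster`."""

    T: np.ndarray
    I: np.ndarray
    F: np.ndarray
    centers: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def masked_distance2(x_row, center) -> float:
    """Mean squared distance over the fragment's observed sites.

    ``x_row`` may be a string over {0,1,-} or an (alleles, observed) pair;
    the center is a real vector in [0,1]^n defined at every site.
    """
    from .graph_init import _coerce_row

    alleles, observed = _coerce_row(x_row)
    center = np.asarray(center, dtype=np.float64).reshape(-1)
    if alleles.size != center.size:
        raise ValueError("fragment and center lengths differ")
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError("fragment observes no site")
    diff = (alleles.astype(np.float64) - center)[observed]
    return float(np.mean(diff * diff))


def indeterminacy_center(t_row: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Midpoint of the two centers with the largest memberships for a point.

    With two clusters this is always (c1 + c2) / 2; for more clusters the
    two largest T entries select the pair (ties: lower cluster index).
    """
    centers = np.asarray(centers, dtype=np.float64)
    t_row = np.asarray(t_row, dtype=np.float64)
    if centers.shape[0] < 2:
        raise ValueError("need at least two clusters")
    order = np.argsort(-t_row, kind="stable")
    p, q = int(order[0]), int(order[1])
    return (centers[p] + centers[q]) / 2.0


def _point_center_dist2(
    alleles: np.ndarray, observed: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """N x C matrix of masked mean squared distances."""
    a = alleles.astype(np.float64)
    n_obs = observed.sum(axis=1).astype(np.float64)
    diff2 = (a[:, None, :] - centers[None, :, :]) ** 2
    return np.einsum("ijk,ik->ij", diff2, observed.astype(np.float64)) / n_obs[:, None]


def _point_row_dist2(
    alleles: np.ndarray, observed: np.ndarray, row: np.ndarray
) -> np.ndarray:
    """Masked mean squared distance of every fragment to one real row."""
    a = alleles.astype(np.float64)
    n_obs = observed.sum(axis=1).astype(np.float64)
    diff2 = (a - row[None, :]) ** 2
    return (diff2 * observed).sum(axis=1) / n_obs


def update_memberships(
    x: SNPMatrix, centers: np.ndarray, p: NCMParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (T, I, F) minimizing the objective for fixed centers.

    T_ij ~ (1/w1) d_ij^(-1/(m-1)),  I_i ~ (1/w2) dbar_i^(-1/(m-1)),
    F_i ~ (1/w3) (delta^2)^(-1/(m-1)), normalized per point so that
    sum_j T_ij + I_i + F_i = 1. A point at distance zero from a center
    takes hard membership there (limit convention); likewise a point
    sitting exactly on the midpoint center takes I = 1.
    """
    centers = np.asarray(centers, dtype=np.float64)
    if centers.shape != (p.n_clusters, x.n_sites):
        raise ValueError("centers have the wrong shape")
    d = _point_center_dist2(x.alleles, x.observed, centers)
    cbar = centers.mean(axis=0)  # two clusters: midpoint, independent of T
    dbar = _point_row_dist2(x.alleles, x.observed, cbar)

    ex = 1.0 / (p.m_fuzz - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        raw_t = (1.0 / p.w1) * np.power(d, -ex)
        raw_i = (1.0 / p.w2) * np.power(dbar, -ex)
    raw_f = np.full(x.n_fragments, (1.0 / p.w3) * (p.delta**2) ** (-ex))

    t = np.empty_like(d)
    i_mem = np.empty_like(dbar)
    f_mem = np.empty_like(dbar)

    singular_c = (d == 0).any(axis=1)
    singular_b = (dbar == 0) & ~singular_c
    regular = ~singular_c & ~singular_b

    k = 1.0 / (raw_t[regular].sum(axis=1) + raw_i[regular] + raw_f[regular])
    t[regular] = k[:, None] * raw_t[regular]
    i_mem[regular] = k * raw_i[regular]
    f_mem[regular] = k * raw_f[regular]
    # rows hitting a zero distance are overwritten below with the
    # hard-membership limit, so any inf/nan above never leaks out

    if singular_c.any():
        t[singular_c] = 0.0
        rows = np.flatnonzero(singular_c)
        cols = np.argmax(d[rows] == 0, axis=1)  # first zero-distance center
        t[rows, cols] = 1.0
        i_mem[singular_c] = 0.0
        f_mem[singular_c] = 0.0
    if singular_b.any():
        t[singular_b] = 0.0
        i_mem[singular_b] = 1.0
        f_mem[singular_b] = 0.0
    return t, i_mem, f_mem


def update_centers(
    x: SNPMatrix,
    t: np.ndarray,
    p: NCMParams,
    prev_centers: np.ndarray,
    i_mem: np.ndarray | None = None,
) -> np.ndarray:
    """Per-column weighted mean of observed alleles, one row per cluster.

    The weight of fragment i in cluster j is w1 T_ij^m / |obs_i|; the
    coverage factor matches the averaged distances in the objective, so the
    plain form (``i_mem=None``) exactly minimizes the objective's
    determinate term. When the indeterminacy memberships are supplied, the
    boundary term — whose midpoint center (c1+c2)/2 also moves with the
    centers — is included and the two centers solve the coupled per-column
    2x2 normal equations jointly, making the center step the exact
    coordinate minimizer of the full objective (this is what guarantees a
    non-increasing objective trace). Columns with zero total weight
    (unobserved in both clusters) keep their previous value; all entries
    are clamped to [0, 1].
    """
    n_obs = x.observed.sum(axis=1, keepdims=True)
    w = p.w1 * np.asarray(t, dtype=np.float64) ** p.m_fuzz / n_obs
    obs = x.observed.astype(np.float64)
    a = (x.alleles * x.observed).astype(np.float64)
    num = w.T @ a          # C x n
    den = w.T @ obs
    centers = np.array(prev_centers, dtype=np.float64, copy=True)

    if i_mem is None:
        ok = den > 0
        centers[ok] = num[ok] / den[ok]
        uncovered = ~ok.any(axis=0)
    else:
        v = p.w2 * np.asarray(i_mem, dtype=np.float64) ** p.m_fuzz / n_obs[:, 0]
        v_col = obs.T @ v                      # per-column boundary weight
        b_col = a.T @ v
        # per column minimize W1(c1-.)^2 + W2(c2-.)^2 + V(mid(c)-.)^2 over
        # [0,1]^2 by coordinate descent; each scalar step is the exact
        # box-constrained minimizer, so the objective can only decrease
        m11 = den[0] + v_col / 4.0
        m22 = den[1] + v_col / 4.0
        m12 = v_col / 4.0
        r1 = num[0] + b_col / 2.0
        r2 = num[1] + b_col / 2.0
        c1 = np.clip(centers[0], 0.0, 1.0)
        c2 = np.clip(centers[1], 0.0, 1.0)
        upd1 = m11 > 0
        upd2 = m22 > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            for _ in range(200):
                new1 = np.where(upd1, np.clip((r1 - m12 * c2) / m11, 0.0, 1.0), c1)
                new2 = np.where(upd2, np.clip((r2 - m12 * new1) / m22, 0.0, 1.0), c2)
                delta = max(
                    np.abs(new1 - c1).max(initial=0.0),
                    np.abs(new2 - c2).max(initial=0.0),
                )
                c1, c2 = new1, new2
                if delta < 1e-14:
                    break
        centers[0] = c1
        centers[1] = c2
        uncovered = ~upd1 & ~upd2
    if uncovered.any():
        logger.warning(
            "%d column(s) carry zero weight in both clusters; keeping previous centers",
            int(uncovered.sum()),
        )
    return np.clip(centers, 0.0, 1.0)


def ncm_objective(
    x: SNPMatrix,
    t: np.ndarray,
    i_mem: np.ndarray,
    f_mem: np.ndarray,
    centers: np.ndarray,
    p: NCMParams,
) -> float:
    """The three-term NCM objective with masked mean squared distances.

    Weights multiply the fuzzified memberships linearly (w1 T^m, not
    (w1 T)^m): this is the functional whose exact constrained minimizers
    are the closed-form membership updates, so the alternating iteration
    is a true block-coordinate descent on it.
    """
    centers = np.asarray(centers, dtype=np.float64)
    d = _point_center_dist2(x.alleles, x.observed, centers)
    dbar = _point_row_dist2(x.alleles, x.observed, centers.mean(axis=0))
    term1 = float((p.w1 * t**p.m_fuzz * d).sum())
    term2 = float((p.w2 * i_mem**p.m_fuzz * dbar).sum())
    term3 = float((p.delta**2 * p.w3 * f_mem**p.m_fuzz).sum())
    return term1 + term2 + term3


def ncm_cluster(
    x: SNPMatrix,
    init_centers,
    p: NCMParams | None = None,
    seed: int = 0,
) -> NCMState:
    """Alternate membership and center updates until the centers settle.

    ``init_centers`` is a (2, n) real array in [0,1] or the string
    ``"random"`` (uniform draws from ``seed``). Iteration stops when the
    largest entrywise center change is <= epsilon or after max_iter
    iterations (the state is then flagged unconverged, not raised).
    """
    p = p or NCMParams()
    if isinstance(init_centers, str):
        if init_centers != "random":
            raise ValueError("init_centers must be an array or 'random'")
        rng = np.random.default_rng(seed)
        centers = rng.uniform(size=(p.n_clusters, x.n_sites))
    else:
        centers = np.asarray(init_centers, dtype=np.float64)
        if centers.shape != (p.n_clusters, x.n_sites):
            raise ValueError(
                f"init_centers must have shape ({p.n_clusters}, {x.n_sites})"
            )
        centers = np.clip(centers, 0.0, 1.0)

    state = NCMState(
        T=np.zeros((x.n_fragments, p.n_clusters)),
        I=np.zeros(x.n_fragments),
        F=np.zeros(x.n_fragments),
        centers=centers,
    )
    for it in range(1, p.max_iter + 1):
        t, i_mem, f_mem = update_memberships(x, centers, p)
        new_centers = update_centers(x, t, p, centers, i_mem=i_mem)
        delta_c = float(np.abs(new_centers - centers).max())
        j = ncm_objective(x, t, i_mem, f_mem, new_centers, p)
        state.T, state.I, state.F = t, i_mem, f_mem
        state.centers = new_centers
        state.objective_trace.append(j)
        state.n_iter = it
        logger.debug("ncm iter %d: J=%.8g max|dC|=%.3g", it, j, delta_c)
        centers = new_centers
        if delta_c <= p.epsilon:
            state.converged = True
            break
    return state
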