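"""Phase 1: fragment distances, the fuzzy conflict graph, greedy bipartition.

Fragments drawn from the same chromosome copy agree wherever they overlap
(up to sequencing error), fragments from opposite copies disagree at every
jointly observed heterozygous site. The normalized Hamming distance (NHD)
between two fragments — mismatches divided by the number of jointly observed
sites — therefore sits near 0 for same-copy pairs and near 1 for
opposite-copy pairs, with noise pushing it toward the uninformative middle.

The *fuzzy conflict graph* has one node per fragment and one NHD-weighted
edge per overlapping pair; edges of weight exactly 0.5 carry no clustering
information and are dropped. A greedy bipartition seeded at the
maximum-weight edge produces the initial two-cluster assignment whose
per-column allele means seed the NCM refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fragments import GAP, SNPMatrix

#: tolerance for "weight equals 0.5" — exact float comparison is meaningless
HALF_EDGE_TOL = 1e-9


class NoOverlapError(ValueError):
    """Two fragments share no jointly observed site; NHD is undefined."""


def _coerce_row(row) -> tuple[np.ndarray, np.ndarray]:
    """Accept a string over {0,1,-} or an (alleles, observed) pair."""
    if isinstance(row, str):
        arr = np.frombuffer(row.encode(), dtype="S1")
        observed = arr != b"-"
        alleles = np.where(arr == b"1", 1, 0).astype(np.uint8)
        return alleles, observed
    alleles, observed = row
    return np.asarray(alleles, dtype=np.uint8), np.asarray(observed, dtype=bool)


def site_mismatch(a, b) -> int:
    """Binary mismatch indicator for two allele-or-gap symbols.

    Returns 1 iff both symbols are observed alleles and they differ; a gap
    on either side contributes 0.
    """
    if a in (GAP, None) or b in (GAP, None):
        return 0
    return int(str(a) != str(b))


def hamming_distance(f_i, f_j) -> int:
    """Number of jointly observed sites at which two fragments disagree.

    Zero means the fragments are compatible (consistent with a common
    chromosome copy on their overlap).
    """
    a_i, o_i = _coerce_row(f_i)
    a_j, o_j = _coerce_row(f_j)
    if a_i.shape != a_j.shape:
        raise ValueError(f"fragment lengths differ: {a_i.size} vs {a_j.size}")
    joint = o_i & o_j
    return int(np.count_nonzero((a_i != a_j) & joint))


def nhd(f_i, f_j) -> float:
    """Normalized Hamming distance: mismatches / jointly observed sites.

    Raises
    ------
    NoOverlapError
        If the fragments observe no common site (graph construction treats
        this as "no edge" rather than a distance).
    """
    a_i, o_i = _coerce_row(f_i)
    a_j, o_j = _coerce_row(f_j)
    if a_i.shape != a_j.shape:
        raise ValueError(f"fragment lengths differ: {a_i.size} vs {a_j.size}")
    joint = o_i & o_j
    s_ij = int(np.count_nonzero(joint))
    if s_ij == 0:
        raise NoOverlapError("fragments share no observed site")
    return int(np.count_nonzero((a_i != a_j) & joint)) / s_ij


@dataclass
class ConflictGraph:
    """Weighted conflict graph over fragments, stored as edge arrays.

    Edges are (i, j, weight) with i < j, weight = NHD in [0, 1]; pairs with
    no overlap and pairs with weight 0.5 have no edge.
    """

    n_nodes: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    weight: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.edge_i.size

    def edges(self) -> list[tuple[int, int, float]]:
        return [
            (int(i), int(j), float(w))
            for i, j, w in zip(self.edge_i, self.edge_j, self.weight)
        ]

    def write_edgelist(self, path) -> None:
        """Dump edges as 'i j weight' lines (debugging aid)."""
        with open(path, "w") as fh:
            for i, j, w in self.edges():
                fh.write(f"{i} {j} {w:.10g}\n")


def pairwise_nhd(x: SNPMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs NHD and overlap counts.

    Returns (nhd_matrix, overlap_counts); entries with zero overlap hold NaN.
    """
    obs = x.observed.astype(np.float64)
    a1 = (x.alleles * x.observed).astype(np.float64)   # observed '1' indicator
    a0 = ((1 - x.alleles) * x.observed).astype(np.float64)
    mism = a1 @ a0.T + a0 @ a1.T
    overlap = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(overlap > 0, mism / np.maximum(overlap, 1), np.nan)
    return d, overlap.astype(np.int64)


def build_conflict_graph(x: SNPMatrix) -> ConflictGraph:
    """Construct the fuzzy conflict graph over all overlapping pairs."""
    d, overlap = pairwise_nhd(x)
    m = x.n_fragments
    iu, ju = np.triu_indices(m, k=1)
    w = d[iu, ju]
    keep = (overlap[iu, ju] > 0) & (np.abs(w - 0.5) > HALF_EDGE_TOL)
    return ConflictGraph(m, iu[keep], ju[keep], w[keep])


@dataclass
class Bipartition:
    """Initial two-cluster assignment of fragments with per-cluster centers.

    ``centers[j]`` holds the per-column mean of observed alleles among
    cluster j+1's members; columns no member observes carry the maximally
    indeterminate value 0.5. ``mec`` is the error-correction cost of the
    rounded centers.
    """

    assignment: np.ndarray
    centers: np.ndarray
    mec: int
    seed_edge: tuple[int, int] | None = field(default=None)


def _cluster_centers(x: SNPMatrix, assignment: np.ndarray) -> np.ndarray:
    """Per-cluster per-column mean of observed alleles; uncovered -> 0.5."""
    centers = np.full((2, x.n_sites), 0.5)
    for j in (1, 2):
        rows = assignment == j
        if not rows.any():
            continue
        cov = x.observed[rows].sum(axis=0)
        ones = (x.alleles[rows] * x.observed[rows]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            centers[j - 1] = np.where(cov > 0, ones / np.maximum(cov, 1), 0.5)
    return centers


def _consensus(x: SNPMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rounded per-column majority allele over ``rows``; ties -> 0.

    Returns (alleles, defined); a column observed by no member is undefined.
    """
    cov = x.observed[rows].sum(axis=0)
    ones = (x.alleles[rows] * x.observed[rows]).sum(axis=0)
    alleles = (2 * ones > cov).astype(np.uint8)
    return alleles, cov > 0


def _row_to_consensus_nhd(
    x: SNPMatrix, rows_idx: np.ndarray, cons: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """NHD of each listed fragment to a rounded consensus; NaN if no overlap."""
    c_alleles, c_defined = cons
    obs = x.observed[rows_idx] & c_defined
    mism = ((x.alleles[rows_idx] != c_alleles) & obs).sum(axis=1)
    s = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(s > 0, mism / np.maximum(s, 1), np.nan)


def initial_bipartition(x: SNPMatrix, g: ConflictGraph) -> Bipartition:
    """Greedy bipartition of the conflict graph.

    The endpoints of the maximum-weight edge (ties: lexicographically
    smallest (i, j)) seed the two clusters. Remaining fragments are assigned
    one at a time, alternating between the clusters: the unassigned fragment
    with the highest NHD to the reference cluster's rounded consensus is
    selected and joins the cluster whose consensus it is closer to — the
    *opposite* cluster when it genuinely conflicts with the reference (the
    common case, and the tie-break), but the reference itself once only
    same-copy fragments remain, so that a noise-free instance is always
    split exactly by chromosome of origin. The joining cluster's consensus
    is recomputed after every assignment. Fragments with no overlap against
    either consensus are deferred and finally placed in the cluster with
    the lower defined NHD (default 1).
    """
    from .pipeline import mec_score, round_centers_to_haplotypes

    m = x.n_fragments
    if m < 2:
        raise ValueError("bipartition needs at least two fragments")

    assignment = np.zeros(m, dtype=np.int64)
    seed_edge: tuple[int, int] | None = None

    if g.n_edges == 0:
        warnings.warn(
            "conflict graph has no edges; assigning all fragments to cluster 1",
            stacklevel=2,
        )
        assignment[:] = 1
    else:
        # max-weight seed edge; ties broken by smallest (i, j)
        order = np.lexsort((g.edge_j, g.edge_i, -g.weight))
        best = order[0]
        i0, j0 = int(g.edge_i[best]), int(g.edge_j[best])
        seed_edge = (i0, j0)
        assignment[i0] = 1
        assignment[j0] = 2

        consensus = {j: _consensus(x, assignment == j) for j in (1, 2)}
        turn = 0  # even: reference C1, odd: reference C2
        while True:
            unassigned = np.flatnonzero(assignment == 0)
            if unassigned.size == 0:
                break
            placed = False
            for attempt in range(2):
                ref = 1 if (turn + attempt) % 2 == 0 else 2
                dist = _row_to_consensus_nhd(x, unassigned, consensus[ref])
                defined = ~np.isnan(dist)
                if not defined.any():
                    continue
                # highest distance; ties -> smallest fragment index
                cand = unassigned[defined]
                cdist = dist[defined]
                pos = int(np.argmax(cdist))  # argmax returns first maximum
                pick = int(cand[pos])
                d_ref = float(cdist[pos])
                opp = 2 if ref == 1 else 1
                d_opp = _row_to_consensus_nhd(
                    x, np.array([pick]), consensus[opp]
                )[0]
                if np.isnan(d_opp):
                    target = opp if d_ref >= 0.5 else ref
                elif d_opp > d_ref:
                    target = ref  # conflicts more with the opposite side
                else:
                    target = opp
                assignment[pick] = target
                consensus[target] = _consensus(x, assignment == target)
                placed = True
                break
            turn += 1
            if not placed:
                break  # remaining fragments overlap neither consensus: defer

        # deferred pass: isolated / non-overlapping fragments
        for idx in np.flatnonzero(assignment == 0):
            d1 = _row_to_consensus_nhd(x, np.array([idx]), consensus[1])[0]
            d2 = _row_to_consensus_nhd(x, np.array([idx]), consensus[2])[0]
            if np.isnan(d1) and np.isnan(d2):
                target = 1
            elif np.isnan(d2) or (not np.isnan(d1) and d1 <= d2):
                target = 1
            else:
                target = 2
            assignment[idx] = target
            consensus[target] = _consensus(x, assignment == target)

    centers = _cluster_centers(x, assignment)
    coverage = x.observed.any(axis=0)
    mec = mec_score(x, round_centers_to_haplotypes(centers, coverage))
    return Bipartition(assignment, centers, mec, seed_edge)
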