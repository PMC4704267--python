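"""Linkage-group construction, marker ordering and Kosambi map distances.

Two-point estimation for selfed RILs: over lines where both markers are
homozygous, the recombinant-line fraction R is the fraction of A/B vs B/A
patterns; the meiotic recombination fraction follows the selfing-series
inversion r = R / (2(1 - R)) (Haldane & Waddington fixation formula — the
residual bias for F5-derived lines is below estimation noise at these
population sizes, and is recorded in map metadata). The two-point LOD is

    LOD = k*log10(R/0.5) + (n-k)*log10((1-R)/0.5),   0*log10(0) = 0,

with k recombinants of n informative lines. Markers are clustered into
linkage groups as connected components of the LOD >= threshold graph,
ordered within a group by a minimum-spanning-tree backbone plus windowed
2-opt refinement, and placed on the cM scale by accumulating Kosambi
distances over adjacent pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.stats import spearmanr

from .model import A, B, GenotypeMatrix, LinkageGroup, LinkageMap, MapforgeError, PhysicalPlacement

_EPS = 1e-9


class UninformativePair(MapforgeError):
    """No line has homozygous calls at both markers."""


def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 * ln((1+2r)/(1-2r)).

    ``r`` is clamped to 0.5 - 1e-6 before evaluation; negative r is rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise MapforgeError("recombination fraction must be >= 0")
    r = np.minimum(r, 0.5 - 1e-6)
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


@dataclass
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    R_hat: float  # recombinant-line fraction, clamped to [0, 0.5]
    r_hat: float  # meiotic recombination fraction, in [0, 0.5]
    lod: float
    n_informative: int


def _indicator(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    va = (g.calls == A).astype(np.float64)
    vb = (g.calls == B).astype(np.float64)
    return va, vb


def pairwise_tables(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Dense all-pairs tables (R_hat, r_hat, lod, n_informative) via BLAS
    products over A/B indicator matrices; identical to the per-pair
    definition."""
    va, vb = _indicator(g)
    k = va @ vb.T + vb @ va.T  # recombinant counts
    m = va + vb
    n = m @ m.T  # informative counts
    with np.errstate(divide="ignore", invalid="ignore"):
        big_r = np.where(n > 0, k / np.maximum(n, 1.0), np.nan)
    big_r = np.minimum(big_r, 0.5)
    r_hat = np.clip(big_r / (2.0 * (1.0 - big_r)), 0.0, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(k > 0, k * np.log10(np.maximum(2.0 * big_r, _EPS)), 0.0)
        term2 = np.where(n - k > 0, (n - k) * np.log10(2.0 * (1.0 - big_r)), 0.0)
    lod = np.maximum(term1 + term2, 0.0)
    np.fill_diagonal(lod, 0.0)
    return big_r, r_hat, lod, n.astype(np.int64)


def pairwise_linkage(g: GenotypeMatrix, i: str, j: str) -> PairwiseLinkage:
    """Two-point linkage between markers ``i`` and ``j``."""
    idx = g.marker_index()
    ci, cj = g.calls[idx[i]], g.calls[idx[j]]
    hom = np.isin(ci, (A, B)) & np.isin(cj, (A, B))
    n = int(hom.sum())
    if n == 0:
        raise UninformativePair(f"no informative lines for pair ({i!r}, {j!r})")
    k = int((ci[hom] != cj[hom]).sum())
    big_r = min(k / n, 0.5)
    r_hat = min(max(big_r / (2.0 * (1.0 - big_r)), 0.0), 0.5)
    lod = 0.0
    if k > 0:
        lod += k * np.log10(2.0 * big_r)
    if n - k > 0:
        lod += (n - k) * np.log10(2.0 * (1.0 - big_r))
    return PairwiseLinkage(i, j, big_r, r_hat, max(lod, 0.0), n)


def group_markers(
    lod: np.ndarray, marker_ids: Sequence[str], lod_threshold: float = 11.0
) -> list[list[str]]:
    """Partition markers into connected components of the graph with an edge
    wherever pairwise LOD >= threshold. Groups are returned largest first
    (ties by first member's input position)."""
    adj = sparse.csr_matrix((lod >= lod_threshold).astype(np.int8))
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    first: dict[int, int] = {}
    for i, (lab, mid) in enumerate(zip(labels, marker_ids)):
        groups.setdefault(lab, []).append(mid)
        first.setdefault(lab, i)
    order = sorted(groups, key=lambda lab: (-len(groups[lab]), first[lab]))
    return [groups[lab] for lab in order]


def _mst_backbone(r: np.ndarray) -> list[int]:
    """Diameter path of the MST of the r-weighted complete graph, as the
    initial marker order."""
    k = r.shape[0]
    mst = csgraph.minimum_spanning_tree(r + _EPS)  # +eps: keep r=0 edges present
    mst = mst + mst.T

    def farthest(src: int) -> tuple[int, np.ndarray]:
        dist, pred = csgraph.dijkstra(mst, indices=src, return_predecessors=True)
        return int(np.argmax(dist)), pred

    u, _ = farthest(0)
    v, pred = farthest(u)
    path = [v]
    while path[-1] != u:
        path.append(int(pred[path[-1]]))
    on_path = set(path)
    # insert off-backbone markers where they least lengthen the order
    for node in range(k):
        if node in on_path:
            continue
        best_cost, best_pos = np.inf, 0
        for pos in range(len(path) + 1):
            left = r[path[pos - 1], node] if pos > 0 else 0.0
            right = r[node, path[pos]] if pos < len(path) else 0.0
            removed = r[path[pos - 1], path[pos]] if 0 < pos < len(path) else 0.0
            cost = left + right - removed
            if cost < best_cost - 1e-12:
                best_cost, best_pos = cost, pos
        path.insert(best_pos, node)
        on_path.add(node)
    return path


def _two_opt(order: list[int], r: np.ndarray, window: int = 8) -> list[int]:
    """Windowed 2-opt: reverse any segment of length <= window that lowers the
    sum of adjacent r; repeat until no improving swap."""
    order = list(order)
    k = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, min(i + window, k)):
                a = r[order[i - 1], order[j]] if i > 0 else 0.0
                b = r[order[i], order[j + 1]] if j < k - 1 else 0.0
                c = r[order[i - 1], order[i]] if i > 0 else 0.0
                d = r[order[j], order[j + 1]] if j < k - 1 else 0.0
                if a + b < c + d - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    return order


def order_group(
    g: GenotypeMatrix,
    members: Sequence[str],
    placement: Optional[PhysicalPlacement] = None,
    window: int = 8,
) -> list[tuple[str, float]]:
    """Order the markers of one linkage group and assign cM positions.

    The order minimizes the sum of adjacent r_hat (MST backbone + windowed
    2-opt); cM positions accumulate Kosambi distances, anchored at 0.
    Orientation: positive rank correlation with physical position when a
    placement is supplied, else the lexicographically smaller end marker
    comes first.
    """
    members = list(members)
    if len(members) == 1:
        return [(members[0], 0.0)]
    sub = g.subset(marker_mask=[m in set(members) for m in g.marker_ids])
    # keep genotype-matrix input order for determinism
    ids = sub.marker_ids
    _, r_hat, _, _ = pairwise_tables(sub)
    r = np.nan_to_num(r_hat, nan=0.5)
    order = _two_opt(_mst_backbone(r), r, window=window)

    oriented = _orient(order, ids, placement)
    cms = np.concatenate([[0.0], np.cumsum(kosambi(r[oriented[:-1], oriented[1:]]))])
    return [(ids[i], float(c)) for i, c in zip(oriented, cms)]


def _orient(order: list[int], ids: list[str], placement: Optional[PhysicalPlacement]) -> list[int]:
    if placement is not None:
        pos = {m: p for m, _, p in placement.records.itertuples(index=False, name=None)}
        shared = [(rank, pos[ids[i]]) for rank, i in enumerate(order) if ids[i] in pos]
        if len(shared) >= 2:
            rho = spearmanr([s[0] for s in shared], [s[1] for s in shared]).statistic
            if rho is not None and rho < 0:
                return order[::-1]
            return order
    if ids[order[0]] > ids[order[-1]]:
        return order[::-1]
    return order


def build_map(
    g: GenotypeMatrix,
    lod_threshold: float = 11.0,
    placement: Optional[PhysicalPlacement] = None,
    window: int = 8,
    population_id: Optional[str] = None,
) -> LinkageMap:
    """Group, order and scale a (QC-filtered, binned) genotype matrix."""
    _, _, lod, _ = pairwise_tables(g)
    groups = group_markers(lod, g.marker_ids, lod_threshold)
    lgs = []
    for gi, members in enumerate(groups, start=1):
        loci = order_group(g, members, placement=placement, window=window)
        lgs.append(LinkageGroup(f"LG{gi:02d}", loci))
    return LinkageMap(
        population_id or g.population_id,
        lgs,
        metadata={
            "lod_threshold": lod_threshold,
            "ril_inversion": "R = 2r/(1+2r) at selfing fixation",
            "mapping_function": "kosambi",
            "two_opt_window": window,
        },
    )
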