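"""Broad-phase neighbor search and overlap classification.

Only particles with the same parent (siblings) exert contact forces on each
other, and a contained particle interacts with its own parent's shell from
the inside.  Cross-compartment contact is always mediated by the shell in
between.  Ignore relations (installed during compartment division) suppress
individual pairs.

Candidate generation is fully vectorized: small sibling groups use an
all-pairs distance matrix, large ones a uniform cell grid sized to the
typical radius (outsized particles are paired against everyone, so the
candidate set is always a superset of the true contacts).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core_model import MEDIUM, ModelError, SystemState

FREE_FREE = "free_free"
INNER_SHELL = "inner_shell"
CROSSING_SHELL = "crossing_shell"

#: sibling-group size above which the uniform grid replaces all-pairs
_BRUTE_MAX = 600


@dataclass
class OverlapPair:
    """A positive-depth geometric overlap.

    ``normal`` is the unit direction of the repulsive force on particle
    ``id_a``: along the center line away from ``id_b`` for sibling contacts,
    and pointing inward (toward the shell center) when ``id_a`` sits inside
    its parent shell ``id_b``.
    """

    id_a: int
    id_b: int
    relation: str
    depth: float
    normal: np.ndarray
    center_distance: float


def overlap_depth(pa, pb, relation: str) -> float:
    """Overlap depth between two particle handles under a given relation.

    free_free: d = r_a + r_b - |x_a - x_b|  (siblings)
    inner_shell / crossing_shell: d = (|x_a - x_b| + r_a) - r_b
    with ``pb`` the shell being crossed.  Negative results are clipped to 0.
    """
    dist = float(np.linalg.norm(pa.position - pb.position))
    if relation == FREE_FREE:
        if pa.parent != pb.parent:
            raise ModelError("free_free overlap requires sibling particles")
        d = pa.radius + pb.radius - dist
    elif relation in (INNER_SHELL, CROSSING_SHELL):
        if relation == INNER_SHELL and pa.parent != pb.id:
            raise ModelError("inner_shell overlap requires pb to be pa's parent")
        d = (dist + pa.radius) - pb.radius
    else:
        raise ModelError(f"unknown overlap relation {relation!r}")
    return max(d, 0.0)


def _grid_candidates(pos: np.ndarray, rad: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Candidate index pairs (i < j) from a uniform grid.

    Particles larger than the grid scale are paired against everyone, which
    keeps the output a superset of the true contact set for any radius mix.
    """
    n = pos.shape[0]
    scale = 3.0 * float(np.median(rad))
    big = np.flatnonzero(rad > scale)
    small = np.flatnonzero(rad <= scale)
    out_i: list[np.ndarray] = []
    out_j: list[np.ndarray] = []
    if big.size:
        # big x everything (dedup: big x big counted once via index order)
        for b in big:
            others = np.concatenate([small, big[big > b]])
            out_i.append(np.full(others.size, b))
            out_j.append(others)
    if small.size > 1:
        cell = 2.0 * float(rad[small].max())
        keys = np.floor(pos[small] / cell).astype(np.int64)
        cells: dict[tuple, np.ndarray] = {}
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        for ci in range(uniq.shape[0]):
            cells[tuple(uniq[ci])] = small[np.flatnonzero(inverse == ci)]
        offsets = _neighbor_offsets(pos.shape[1])
        for key, members in cells.items():
            m = members.size
            if m > 1:
                ii, jj = np.triu_indices(m, 1)
                out_i.append(members[ii])
                out_j.append(members[jj])
            for off in offsets:
                other = cells.get(tuple(k + o for k, o in zip(key, off)))
                if other is not None:
                    gi, gj = np.meshgrid(members, other, indexing="ij")
                    out_i.append(gi.ravel())
                    out_j.append(gj.ravel())
    if not out_i:
        return (np.empty(0, dtype=np.intp),) * 2
    i = np.concatenate(out_i)
    j = np.concatenate(out_j)
    swap = i > j
    i[swap], j[swap] = j[swap], i[swap]
    return i, j


def _neighbor_offsets(dim: int) -> list[tuple[int, ...]]:
    """Half of the neighbor-cell offsets (lexicographically positive)."""
    from itertools import product

    return [off for off in product((-1, 0, 1), repeat=dim) if off > (0,) * dim]


class BroadPhase:
    """Spatial index over sibling groups; queries return contact supersets."""

    def __init__(self, state: SystemState):
        self.state = state

    def candidate_arrays(self, group: list[int]
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(slots, i, j): candidate local index pairs within one group."""
        state = self.state
        n = len(group)
        slots = np.fromiter((state.meta[g].slot for g in group),
                            dtype=np.intp, count=n)
        if n < 2:
            return slots, np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        if n <= _BRUTE_MAX:
            i, j = np.triu_indices(n, 1)
            return slots, i, j
        i, j = _grid_candidates(state.pos[slots], state.rad[slots])
        return slots, i, j

    def candidates(self, group: list[int]) -> list[tuple[int, int]]:
        """Candidate id pairs (a < b) within one sibling group."""
        _, i, j = self.candidate_arrays(group)
        out = {(group[a], group[b]) if group[a] < group[b]
               else (group[b], group[a]) for a, b in zip(i, j)}
        return sorted(out)


def build_broadphase(state: SystemState) -> BroadPhase:
    """Construct the spatial index for the current particle configuration."""
    return BroadPhase(state)


def _ignored(state: SystemState, a: int, b: int) -> bool:
    return b in state.meta[a].ignore or a in state.meta[b].ignore


def detect_overlaps(state: SystemState) -> list[OverlapPair]:
    """All positive-depth overlaps among siblings and child-vs-parent shells.

    Deterministic order: sorted by (id_a, id_b); each unordered pair appears
    exactly once.  Pairs related through an ignore set are suppressed.
    """
    pairs: list[OverlapPair] = []
    if not state.meta:
        return pairs
    domain = state.physics.domain
    periodic = domain.boundary == "periodic"
    lengths = domain.lengths
    broad = build_broadphase(state)

    groups = [(MEDIUM, state.children_of(MEDIUM))] + \
        [(pid, state.children_of(pid)) for pid in state.particle_ids()
         if state.children[pid]]
    for parent, group in groups:
        n = len(group)
        if n < 2:
            continue
        use_mi = periodic and parent == MEDIUM  # minimum image at top level
        slots = np.fromiter((state.meta[g].slot for g in group),
                            dtype=np.intp, count=n)
        if n <= _BRUTE_MAX and not use_mi:
            # dense all-pairs narrow phase (C-speed distance matrix)
            pos = state.pos[slots]
            rad = state.rad[slots]
            dmat = cdist(pos, pos)
            depth_mat = rad[:, None] + rad[None, :] - dmat
            hi, hj = np.nonzero(np.triu(depth_mat > 0.0, k=1))
            for a, b in zip(hi, hj):
                id_a, id_b = group[a], group[b]
                if _ignored(state, id_a, id_b):
                    continue
                d = float(dmat[a, b])
                normal = (pos[a] - pos[b]) / d if d > 0 \
                    else _fallback_normal(state)
                pairs.append(OverlapPair(id_a, id_b, FREE_FREE,
                                         float(depth_mat[a, b]), normal, d))
        else:
            _, ci, cj = broad.candidate_arrays(group)
            if ci.size == 0:
                continue
            delta = state.pos[slots[ci]] - state.pos[slots[cj]]
            if use_mi:
                delta -= lengths * np.round(delta / lengths)
            dist = np.sqrt((delta**2).sum(axis=1))
            depth = state.rad[slots[ci]] + state.rad[slots[cj]] - dist
            hits = np.flatnonzero(depth > 0.0)
            for h in hits:
                id_a, id_b = group[ci[h]], group[cj[h]]
                if _ignored(state, id_a, id_b):
                    continue
                d = float(dist[h])
                normal = delta[h] / d if d > 0 else _fallback_normal(state)
                pairs.append(OverlapPair(id_a, id_b, FREE_FREE,
                                         float(depth[h]), normal, d))

    # child against its own parent's shell, from the inside
    for parent, group in groups:
        if parent == MEDIUM:
            continue
        pslot = state.meta[parent].slot
        slots = np.fromiter((state.meta[g].slot for g in group),
                            dtype=np.intp, count=len(group))
        delta = state.pos[slots] - state.pos[pslot]
        dist = np.sqrt((delta**2).sum(axis=1))
        depth = dist + state.rad[slots] - state.rad[pslot]
        hits = np.flatnonzero(depth > 0.0)
        for h in hits:
            pid = group[h]
            if _ignored(state, pid, parent):
                continue
            d = float(dist[h])
            # repulsion on the inner particle points back toward the center
            normal = -delta[h] / d if d > 0 else _fallback_normal(state)
            pairs.append(OverlapPair(pid, parent, INNER_SHELL,
                                     float(depth[h]), normal, d))

    pairs.sort(key=lambda p: (p.id_a, p.id_b))
    return pairs


def _fallback_normal(state: SystemState) -> np.ndarray:
    n = np.zeros(state.physics.dimension)
    n[0] = 1.0
    return n


def detect_overlaps_bruteforce(state: SystemState) -> list[OverlapPair]:
    """All-pairs O(n²) scalar oracle with identical semantics."""
    pairs: list[OverlapPair] = []
    domain = state.physics.domain
    periodic = domain.boundary == "periodic"
    lengths = domain.lengths
    ids = state.particle_ids()
    for i, id_a in enumerate(ids):
        ma = state.meta[id_a]
        for id_b in ids[i + 1:]:
            mb = state.meta[id_b]
            if ma.parent != mb.parent:
                continue
            if _ignored(state, id_a, id_b):
                continue
            delta = state.pos[ma.slot] - state.pos[mb.slot]
            if periodic and ma.parent == MEDIUM:
                delta -= lengths * np.round(delta / lengths)
            dist = float(np.linalg.norm(delta))
            depth = float(state.rad[ma.slot] + state.rad[mb.slot]) - dist
            if depth <= 0.0:
                continue
            normal = delta / dist if dist > 0 else _fallback_normal(state)
            pairs.append(OverlapPair(id_a, id_b, FREE_FREE, depth, normal, dist))
    for pid in ids:
        meta = state.meta[pid]
        if meta.parent == MEDIUM or _ignored(state, pid, meta.parent):
            continue
        pmeta = state.meta[meta.parent]
        delta = state.pos[meta.slot] - state.pos[pmeta.slot]
        dist = float(np.linalg.norm(delta))
        depth = (dist + float(state.rad[meta.slot])) - float(state.rad[pmeta.slot])
        if depth <= 0.0:
            continue
        normal = -delta / dist if dist > 0 else _fallback_normal(state)
        pairs.append(OverlapPair(pid, meta.parent, INNER_SHELL, depth, normal, dist))
    pairs.sort(key=lambda p: (p.id_a, p.id_b))
    return pairs
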