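"""Competing multi-source first-arrival propagation on a grid (numba kernel).

Each colony expands from its seed cell through cells that are empty or its
own, one stencil step at a time; the arrival time of a step is the
accumulated Euclidean step length divided by the colony's rate. A cell is
finalised the first time it is popped from the priority queue and is never
relabelled afterwards (contact inhibition). Ties in arrival time are broken
toward the lowest colony label via a composite heap key.

The stencil of order ``r`` contains every coprime integer offset with
max-norm <= r; higher orders reduce the anisotropy of the induced path
metric (worst-case overestimate of Euclidean distance: ~8.2% at order 1 in
2D, ~2.8% at order 2, ~1.3% at order 3).
"""

from __future__ import annotations

from math import gcd
from itertools import product

import numpy as np
from numba import njit

__all__ = ["stencil_offsets", "propagate"]


def stencil_offsets(dim: int, order: int):
    """Return (offsets, costs): coprime offsets with max-norm <= order.

    ``offsets`` is (m, dim) int64; ``costs`` (m,) float64 Euclidean lengths
    in cell units.
    """
    if order < 1:
        raise ValueError("stencil order must be >= 1")
    offs = []
    for v in product(range(-order, order + 1), repeat=dim):
        if all(c == 0 for c in v):
            continue
        g = 0
        for c in v:
            g = gcd(g, abs(c))
        if g == 1:
            offs.append(v)
    offsets = np.array(offs, dtype=np.int64)
    costs = np.sqrt((offsets.astype(float) ** 2).sum(axis=1))
    order_key = np.lexsort((offsets.T[::-1]).tolist() + [costs])
    return offsets[order_key], costs[order_key]


@njit(cache=True)
def _heap_push(heap_t, heap_l, heap_c, size, t, lab, cell):
    i = size
    heap_t[i] = t
    heap_l[i] = lab
    heap_c[i] = cell
    while i > 0:
        parent = (i - 1) >> 1
        if heap_t[i] < heap_t[parent] or (
            heap_t[i] == heap_t[parent] and heap_l[i] < heap_l[parent]
        ):
            heap_t[i], heap_t[parent] = heap_t[parent], heap_t[i]
            heap_l[i], heap_l[parent] = heap_l[parent], heap_l[i]
            heap_c[i], heap_c[parent] = heap_c[parent], heap_c[i]
            i = parent
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(heap_t, heap_l, heap_c, size):
    t0 = heap_t[0]
    l0 = heap_l[0]
    c0 = heap_c[0]
    size -= 1
    heap_t[0] = heap_t[size]
    heap_l[0] = heap_l[size]
    heap_c[0] = heap_c[size]
    i = 0
    while True:
        left = 2 * i + 1
        right = left + 1
        smallest = i
        if left < size and (
            heap_t[left] < heap_t[smallest]
            or (heap_t[left] == heap_t[smallest] and heap_l[left] < heap_l[smallest])
        ):
            smallest = left
        if right < size and (
            heap_t[right] < heap_t[smallest]
            or (heap_t[right] == heap_t[smallest] and heap_l[right] < heap_l[smallest])
        ):
            smallest = right
        if smallest == i:
            break
        heap_t[i], heap_t[smallest] = heap_t[smallest], heap_t[i]
        heap_l[i], heap_l[smallest] = heap_l[smallest], heap_l[i]
        heap_c[i], heap_c[smallest] = heap_c[smallest], heap_c[i]
        i = smallest
    return t0, l0, c0, size


@njit(cache=True)
def _propagate_kernel(
    inside, coords, shape, offsets, flat_offsets, step_times, seed_cells, t_stop
):
    # step_times: (n_labels, n_offsets) time per stencil step for each colony
    n = inside.size
    n_seeds = seed_cells.size
    best_t = np.full(n, np.inf)
    best_l = np.zeros(n, np.int32)
    final = np.zeros(n, np.uint8)
    arrival = np.full(n, np.inf)
    label = np.zeros(n, np.int32)

    cap = 4 * n + 16
    heap_t = np.empty(cap, np.float64)
    heap_l = np.empty(cap, np.int32)
    heap_c = np.empty(cap, np.int64)
    size = 0

    for s in range(n_seeds):
        cell = seed_cells[s]
        lab = s + 1
        if best_t[cell] > 0.0 or (best_t[cell] == 0.0 and lab < best_l[cell]):
            best_t[cell] = 0.0
            best_l[cell] = lab
            size = _heap_push(heap_t, heap_l, heap_c, size, 0.0, lab, cell)

    dim = shape.size
    n_off = offsets.shape[0]

    while size > 0:
        t, lab, cell, size = _heap_pop(heap_t, heap_l, heap_c, size)
        if final[cell]:
            continue
        final[cell] = 1
        arrival[cell] = t
        label[cell] = lab
        li = lab - 1
        for j in range(n_off):
            ok = True
            for a in range(dim):
                c = coords[cell, a] + offsets[j, a]
                if c < 0 or c >= shape[a]:
                    ok = False
                    break
            if not ok:
                continue
            nb = cell + flat_offsets[j]
            if final[nb] or not inside[nb]:
                continue
            t2 = t + step_times[li, j]
            if t2 > t_stop:
                continue
            if t2 < best_t[nb] or (t2 == best_t[nb] and lab < best_l[nb]):
                best_t[nb] = t2
                best_l[nb] = lab
                if size >= heap_t.size:
                    new_cap = heap_t.size * 2
                    nt = np.empty(new_cap, np.float64)
                    nl = np.empty(new_cap, np.int32)
                    nc = np.empty(new_cap, np.int64)
                    nt[:size] = heap_t[:size]
                    nl[:size] = heap_l[:size]
                    nc[:size] = heap_c[:size]
                    heap_t, heap_l, heap_c = nt, nl, nc
                size = _heap_push(heap_t, heap_l, heap_c, size, t2, lab, nb)

    return label, arrival


def propagate(
    inside_mask: np.ndarray,
    seed_indices: np.ndarray,
    rates: np.ndarray,
    resolution: float,
    order: int,
    t_stop: float,
):
    """Run competing first-arrival propagation.

    Parameters
    ----------
    inside_mask : bool ndarray (grid shape)
        Cells inside the arena wall.
    seed_indices : (K, dim) int
        Grid indices of the seed cells; colony labels are 1..K in order.
    rates : (K,) float
        Expansion rates, mm/h.
    resolution : float
        Cell edge, mm.
    order : int
        Stencil order.
    t_stop : float
        Horizon: cells with arrival time beyond this are left unreached.

    Returns
    -------
    label : int32 ndarray (grid shape), 0 where unreached
    arrival : float64 ndarray (grid shape), +inf where unreached
    """
    shape = np.asarray(inside_mask.shape, dtype=np.int64)
    dim = shape.size
    offsets, costs = stencil_offsets(dim, order)
    strides = np.ones(dim, dtype=np.int64)
    for a in range(dim - 2, -1, -1):
        strides[a] = strides[a + 1] * shape[a + 1]
    flat_offsets = offsets @ strides

    idx = np.indices(inside_mask.shape).reshape(dim, -1).T
    coords = np.ascontiguousarray(idx, dtype=np.int64)

    seed_cells = np.asarray(seed_indices, dtype=np.int64) @ strides
    step_times = (
        costs[None, :] * float(resolution) / np.asarray(rates, dtype=float)[:, None]
    )
    label, arrival = _propagate_kernel(
        inside_mask.reshape(-1),
        coords,
        shape,
        offsets,
        flat_offsets,
        np.ascontiguousarray(step_times),
        seed_cells,
        float(t_stop),
    )
    return label.reshape(inside_mask.shape), arrival.reshape(inside_mask.shape)
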