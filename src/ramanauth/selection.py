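"""Duplex representative subset selection.

Classic duplex: seed each of two sets with the mutually farthest pair of
remaining points, then alternately hand each set the remaining point
farthest (by minimum distance) from that set's members.  Deterministic:
distance ties resolve to the lowest row index.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DuplexSplit", "duplex_split", "pc_scores"]


@dataclass(frozen=True)
class DuplexSplit:
    set_a: tuple[int, ...]
    set_b: tuple[int, ...]
    selection_order: tuple[tuple[str, int], ...]


def pc_scores(x: np.ndarray, n_pc: int = 5) -> np.ndarray:
    """First ``n_pc`` principal-component scores of the centered matrix."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_pc = min(n_pc, s.size)
    return xc @ vt[:n_pc].T


def _farthest_pair(d: np.ndarray, remaining: list[int]) -> tuple[int, int]:
    best = (-1.0, remaining[0], remaining[0])
    for ii, i in enumerate(remaining):
        for j in remaining[ii + 1:]:
            if d[i, j] > best[0]:
                best = (d[i, j], i, j)
    return best[1], best[2]


def duplex_split(x: np.ndarray, k: int) -> DuplexSplit:
    """Split rows of ``x`` by the duplex algorithm; ``set_a`` holds the
    first ``k`` selections for set A, everything else lands in ``set_b``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not 1 <= k <= (n + 1) // 2:
        raise ValueError(f"k must be in [1, ceil(n/2)] = [1, {(n + 1) // 2}]")

    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=2))

    remaining = list(range(n))
    set_a: list[int] = []
    set_b: list[int] = []
    order: list[tuple[str, int]] = []

    def take_pair(target: list[int], label: str) -> None:
        i, j = _farthest_pair(d, remaining)
        for idx in sorted((i, j)):
            target.append(idx)
            order.append((label, idx))
            remaining.remove(idx)

    def take_farthest(target: list[int], label: str) -> None:
        dist = [min(d[i, j] for j in target) for i in remaining]
        best = int(np.argmax(dist))
        idx = remaining[best]
        target.append(idx)
        order.append((label, idx))
        remaining.remove(idx)

    take_pair(set_a, "a")
    if remaining:
        if len(remaining) >= 2:
            take_pair(set_b, "b")
        else:  # n == 3: the lone leftover seeds set B
            idx = remaining.pop(0)
            set_b.append(idx)
            order.append(("b", idx))
    while remaining and len(set_a) < k:
        take_farthest(set_a, "a")
        if remaining:
            take_farthest(set_b, "b")
    # set_a reached k (or pool exhausted): everything left goes to B
    while remaining:
        take_farthest(set_b, "b")

    set_a = set_a[:k]
    in_a = set(set_a)
    set_b = [i for i in range(n) if i not in in_a]
    return DuplexSplit(
        set_a=tuple(set_a),
        set_b=tuple(set_b),
        selection_order=tuple(order),
    )
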