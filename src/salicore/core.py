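"""Mini-core subset selection by Gower distance and nearest-entry objectives.

The core set should both spread its entries apart (maximize E-NE, the mean
distance from each selected entry to its nearest other selected entry) and
cover the whole collection (minimize A-NE, the mean distance from every
accession to its nearest selected entry). With all traits numeric, Gower
distance reduces to the range-normalized Manhattan distance averaged over
traits, so every pairwise distance lives in [0, 1].

Selection maximizes combined = w_E * E-NE - w_A * A-NE (equal weights by
default) with a seeded parallel-tempering swap search; a tiny exhaustive
enumerator serves as an independent optimum oracle on small instances.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    CombinatorialBudgetError,
    CoreSizeError,
    DegenerateTraitWarning,
    UndefinedStatisticError,
)
from .traits import TraitTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric genotype-by-genotype distance matrix with zero diagonal."""

    genotype_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def gower_matrix(table: TraitTable) -> DistanceMatrix:
    """Gower distances between genotypes over all-numeric traits.

    d(i,k) = mean_j |x_ij - x_kj| / range_j. Traits with zero range carry no
    information and are dropped with a warning; non-finite cells raise with
    the genotype and trait named.
    """
    data = table.data
    if len(data) < 2:
        raise UndefinedStatisticError("Gower distance requires at least 2 genotypes")
    bad = np.argwhere(~np.isfinite(data.to_numpy(dtype=float)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-finite trait value at genotype {data.index[i]!r}, trait {data.columns[j]!r}")
    ranges = data.max(axis=0) - data.min(axis=0)
    keep = [t for t in data.columns if ranges[t] > 0]
    dropped = [t for t in data.columns if ranges[t] == 0]
    if dropped:
        msg = f"zero-range trait(s) dropped from Gower distance: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, DegenerateTraitWarning, stacklevel=2)
    if not keep:
        raise UndefinedStatisticError("all traits have zero range")
    scaled = (data[keep] / ranges[keep]).to_numpy(dtype=float)
    dist = squareform(pdist(scaled, metric="cityblock")) / len(keep)
    return DistanceMatrix(list(data.index.astype(str)), dist)


def core_objectives(dist: DistanceMatrix, subset: Sequence[int],
                    weights: tuple[float, float] = (0.5, 0.5)) -> dict[str, float]:
    """E-NE, A-NE and the combined objective for an index subset.

    combined = w_E * E_NE - w_A * A_NE; selected accessions contribute zero
    to A-NE because they are their own nearest entry.
    """
    idx = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
    if idx.size < 2:
        raise UndefinedStatisticError("E-NE undefined for fewer than 2 entries")
    if idx.size > dist.n:
        raise CoreSizeError("subset larger than the collection")
    sub = dist.matrix[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    e_ne = float(sub.min(axis=1).mean())
    a_ne = float(dist.matrix[:, idx].min(axis=1).mean())
    w_e, w_a = weights
    return {"E_NE": e_ne, "A_NE": a_ne, "combined": w_e * e_ne - w_a * a_ne}


def core_size(fraction: float, n: int) -> int:
    """Round-half-up core size (0.20 of 318 -> 64)."""
    return int(math.floor(fraction * n + 0.5))


@dataclass
class CoreSelection:
    """Result of a core-subset search."""

    selected: tuple[int, ...]
    genotype_ids: list[str]
    fraction: float
    e_ne: float
    a_ne: float
    combined: float
    weights: tuple[float, float]
    seed: int | None
    trace: list[tuple[int, float]] = field(default_factory=list)
    n_moves: int = 0


def _objective(matrix: np.ndarray, idx: np.ndarray, w_e: float, w_a: float) -> float:
    sub = matrix[np.ix_(idx, idx)]
    n = idx.size
    sub = sub + np.diag(np.full(n, np.inf))
    return w_e * sub.min(axis=1).mean() - w_a * matrix[:, idx].min(axis=1).mean()


def select_core(dist: DistanceMatrix, fraction: float = 0.20,
                weights: tuple[float, float] = (0.5, 0.5),
                seed: int | None = None,
                replicas: int = 4,
                temperatures: tuple[float, float] = (1e-4, 5e-2),
                patience: int = 5000,
                exchange_every: int = 50) -> CoreSelection:
    """Seeded parallel-tempering search for the core subset.

    ``replicas`` chains run at a geometric temperature ladder between
    ``temperatures``; each move swaps one selected with one unselected
    genotype under Metropolis acceptance on the combined objective, and
    adjacent replicas periodically exchange states. The search stops after
    ``patience`` consecutive proposed moves without improving the best
    combined objective seen, which makes the run a pure function of the seed.
    """
    n = dist.n
    k = core_size(fraction, n)
    if k < 2 or k > n:
        raise CoreSizeError(f"core size {k} infeasible for collection of {n}")
    w_e, w_a = weights
    rng = np.random.default_rng(seed)
    matrix = dist.matrix

    if k == n:
        idx = np.arange(n)
        obj = _objective(matrix, idx, w_e, w_a)
        e = core_objectives(dist, idx, weights)
        return CoreSelection(tuple(idx), [dist.genotype_ids[i] for i in idx], fraction,
                             e["E_NE"], e["A_NE"], obj, weights, seed)

    t_lo, t_hi = temperatures
    temps = np.geomspace(t_lo, t_hi, max(1, replicas))
    states = []
    for _ in range(max(1, replicas)):
        sel = rng.choice(n, size=k, replace=False)
        states.append([np.sort(sel), _objective(matrix, np.sort(sel), w_e, w_a)])

    best_idx, best_obj = min(states, key=lambda s: -s[1])
    best_idx = best_idx.copy()
    trace: list[tuple[int, float]] = [(0, best_obj)]
    moves = 0
    since_improve = 0
    while since_improve < patience:
        for r, (sel, obj) in enumerate(states):
            moves += 1
            since_improve += 1
            out_pos = rng.integers(sel.size)
            candidates = np.setdiff1d(np.arange(n), sel, assume_unique=False)
            new_member = candidates[rng.integers(candidates.size)]
            proposal = sel.copy()
            proposal[out_pos] = new_member
            proposal.sort()
            new_obj = _objective(matrix, proposal, w_e, w_a)
            delta = new_obj - obj
            if delta > 0 or rng.random() < math.exp(delta / temps[r]):
                states[r][0], states[r][1] = proposal, new_obj
                if new_obj > best_obj + 1e-15:
                    best_obj, best_idx = new_obj, proposal.copy()
                    since_improve = 0
                    trace.append((moves, best_obj))
            if since_improve >= patience:
                break
        # adjacent-replica exchange on the tempered objective
        if moves // max(1, len(states)) % exchange_every == 0:
            for r in range(len(states) - 1):
                d = (states[r + 1][1] - states[r][1]) * (1 / temps[r] - 1 / temps[r + 1])
                if d > 0 or rng.random() < math.exp(d):
                    states[r], states[r + 1] = states[r + 1], states[r]

    e = core_objectives(dist, best_idx, weights)
    return CoreSelection(tuple(int(i) for i in best_idx),
                         [dist.genotype_ids[i] for i in best_idx],
                         fraction, e["E_NE"], e["A_NE"], best_obj, weights, seed,
                         trace, moves)


def exhaustive_core(dist: DistanceMatrix, k: int,
                    weights: tuple[float, float] = (0.5, 0.5),
                    budget: int = 10**6) -> tuple[tuple[int, ...], float]:
    """Optimal k-subset by full enumeration (test oracle for small instances).

    Ties break to the lexicographically smallest index set. Refuses when
    C(N, k) exceeds ``budget``.
    """
    n = dist.n
    if k < 2 or k > n:
        raise CoreSizeError(f"k={k} infeasible for collection of {n}")
    count = math.comb(n, k)
    if count > budget:
        raise CombinatorialBudgetError(f"C({n},{k}) = {count} exceeds budget {budget}")
    w_e, w_a = weights
    best: tuple[int, ...] | None = None
    best_obj = -np.inf
    for combo in combinations(range(n), k):
        obj = _objective(dist.matrix, np.asarray(combo), w_e, w_a)
        if obj > best_obj:
            best_obj, best = obj, combo
    assert best is not None
    return best, float(best_obj)
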