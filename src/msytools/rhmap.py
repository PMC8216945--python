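"""Radiation-hybrid two-point analysis, linkage grouping, ordering, error flags.

Model: each hybrid clone retains donor fragments independently with
probability r; radiation breaks fall between two markers with probability
theta.  Under equal retention the joint presence/absence probabilities of a
marker pair are

    P(H,H) = (1 - theta) r + theta r^2
    P(H,A) = P(A,H) = theta r (1 - r)
    P(A,A) = (1 - theta)(1 - r) + theta (1 - r)^2

and the two-point LOD is the log10 likelihood ratio of the joint MLE over
the unlinked submodel theta = 1.  Distances are in centiRays,
100 x (-ln(1 - theta)), additive under the Poisson breakage process.

Marker ordering minimizes the sum of adjacent distances — an open-path
travelling-salesman problem, solved exactly for small groups and by a
multi-start nearest-neighbour + 2-opt/Or-opt heuristic otherwise.  A fitted
order supports obligate-break counting and single-flip likelihood-gain
flagging of probable laboratory errors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import xlogy

__all__ = [
    "RHVector",
    "TwoPointResult",
    "two_point",
    "pair_counts",
    "pairwise_table",
    "linkage_groups",
    "MarkerOrder",
    "order_markers",
    "obligate_breaks",
    "flag_errors",
    "read_panel_tsv",
]

LN10 = math.log(10.0)
DEFAULT_DISTANCE_CAP = 500.0  # cR ceiling for theta-hat = 1 pairs fed to the TSP


@dataclass(frozen=True)
class RHVector:
    """One marker's calls (H present / A absent / ? ambiguous) across a panel."""

    marker_id: str
    calls: str

    def __post_init__(self) -> None:
        bad = set(self.calls) - set("HA?")
        if bad:
            raise ValueError(f"illegal call symbols {sorted(bad)}")
        if all(c == "?" for c in self.calls):
            raise ValueError(f"{self.marker_id}: no informative calls")

    def __len__(self) -> int:
        return len(self.calls)


def read_panel_tsv(path: str | Path) -> list[RHVector]:
    vectors = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            marker_id, calls = line.split("\t")
            vectors.append(RHVector(marker_id, calls))
    return vectors


@dataclass(frozen=True)
class TwoPointResult:
    marker_i: str
    marker_j: str
    theta_hat: float
    r_hat: float
    lod: float
    n_informative: int

    @property
    def distance(self) -> float:
        """centiRays; capped for unlinked (theta = 1) pairs."""
        if self.theta_hat >= 1.0:
            return DEFAULT_DISTANCE_CAP
        return min(100.0 * -math.log1p(-self.theta_hat), DEFAULT_DISTANCE_CAP)


def pair_counts(vi: RHVector, vj: RHVector) -> tuple[int, int, int, int]:
    """(n_HH, n_HA, n_AH, n_AA) over hybrids informative in both markers."""
    if len(vi) != len(vj):
        raise ValueError("vectors come from panels of different size")
    nhh = nha = nah = naa = 0
    for a, b in zip(vi.calls, vj.calls):
        if a == "?" or b == "?":
            continue
        if a == "H":
            if b == "H":
                nhh += 1
            else:
                nha += 1
        else:
            if b == "H":
                nah += 1
            else:
                naa += 1
    return nhh, nha, nah, naa


def _loglik(theta, r, nhh, nd, naa):
    """Natural-log likelihood of the 2x2 counts under (theta, r); vectorized."""
    d = theta * r * (1.0 - r)
    phh = r - d
    paa = (1.0 - r) - d
    with np.errstate(divide="ignore", invalid="ignore"):
        return xlogy(nhh, phh) + xlogy(nd, d) + xlogy(naa, paa)


def two_point_from_counts(
    nhh: int, nha: int, nah: int, naa: int, marker_i: str = "i", marker_j: str = "j"
) -> TwoPointResult:
    """Joint (theta, r) MLE and LOD from a 2x2 co-retention table.

    The model maps (theta, r) one-to-one onto trinomial probabilities
    (P(H,H), P(discordant), P(A,A)) = (r - d, 2d, (1-r) - d) with
    d = theta r (1 - r), so the MLE is closed-form: the unconstrained
    trinomial MLE gives r_hat = (2 n_HH + n_disc) / 2n (the marginal
    retention frequency) and theta_hat = [n_disc / 2n] / (r_hat (1 - r_hat)),
    clipped to the model boundary [0, 1].  A clip to theta = 1 lands exactly
    on the unlinked submodel, hence LOD = 0 there; n_disc = 0 gives
    theta_hat = 0 (perfect co-segregation).
    """
    n = nhh + nha + nah + naa
    if n == 0:
        raise ValueError("no informative hybrids shared by the two markers")
    nd = nha + nah

    r0 = (2 * nhh + nd) / (2 * n)  # marginal retention; also the joint MLE of r
    if r0 <= 0.0 or r0 >= 1.0:
        # a constant marker pair carries no linkage information
        return TwoPointResult(marker_i, marker_j, 1.0, r0, 0.0, n)

    # unlinked submodel theta = 1: independent retention at r0
    ll0 = float(_loglik(1.0, r0, nhh, nd, naa))

    d_hat = nd / (2.0 * n)
    theta_hat = min(d_hat / (r0 * (1.0 - r0)), 1.0)
    if theta_hat >= 1.0:
        return TwoPointResult(marker_i, marker_j, 1.0, r0, 0.0, n)
    ll_hat = float(_loglik(theta_hat, r0, nhh, nd, naa))
    lod = max((ll_hat - ll0) / LN10, 0.0)
    return TwoPointResult(marker_i, marker_j, theta_hat, r0, lod, n)


def two_point(vi: RHVector, vj: RHVector) -> TwoPointResult:
    nhh, nha, nah, naa = pair_counts(vi, vj)
    return two_point_from_counts(nhh, nha, nah, naa, vi.marker_id, vj.marker_id)


def pairwise_table(vectors: Sequence[RHVector]) -> dict[tuple[str, str], TwoPointResult]:
    """All-pairs two-point results keyed by sorted (marker_i, marker_j)."""
    out: dict[tuple[str, str], TwoPointResult] = {}
    for vi, vj in itertools.combinations(vectors, 2):
        key = tuple(sorted((vi.marker_id, vj.marker_id)))
        out[key] = two_point(vi, vj)
    return out


def linkage_groups(
    vectors: Sequence[RHVector],
    lod_threshold: float = 10.0,
    pairwise: Mapping[tuple[str, str], TwoPointResult] | None = None,
) -> list[set[str]]:
    """Single-linkage connected components of the LOD >= threshold graph.

    Singleton components are markers without enough evidence of linkage to
    anything.  Groups are returned largest-first (ties by marker id).
    """
    if len(vectors) < 2:
        raise ValueError("need at least two markers")
    if pairwise is None:
        pairwise = pairwise_table(vectors)
    g = nx.Graph()
    g.add_nodes_from(v.marker_id for v in vectors)
    for (a, b), tp in pairwise.items():
        if tp.lod >= lod_threshold:
            g.add_edge(a, b)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# marker ordering (open-path TSP)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerOrder:
    order: tuple[str, ...]
    objective: float  # sum of adjacent two-point distances (cR)
    optimal: bool  # True when found by exhaustive search

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("order must be a permutation without repeats")


def _distance_matrix(
    markers: Sequence[str], pairwise: Mapping[tuple[str, str], TwoPointResult]
) -> np.ndarray:
    m = len(markers)
    d = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        key = tuple(sorted((markers[i], markers[j])))
        if key not in pairwise:
            raise ValueError(f"missing two-point result for pair {key}")
        d[i, j] = d[j, i] = pairwise[key].distance
    return d


def _path_cost(d: np.ndarray, perm: Sequence[int]) -> float:
    return float(sum(d[a, b] for a, b in zip(perm, perm[1:])))


def _nearest_neighbour(d: np.ndarray, start: int) -> list[int]:
    m = d.shape[0]
    left = set(range(m)) - {start}
    path = [start]
    while left:
        cur = path[-1]
        nxt = min(left, key=lambda j: (d[cur, j], j))
        path.append(nxt)
        left.remove(nxt)
    return path


def _two_opt(d: np.ndarray, path: list[int]) -> tuple[list[int], float]:
    """Best-improvement 2-opt (segment reversal) + Or-opt (segment relocation)."""
    m = len(path)
    best = path[:]
    best_cost = _path_cost(d, best)
    improved = True
    while improved:
        improved = False
        # 2-opt: reverse best[i:j]
        for i in range(m - 1):
            for j in range(i + 2, m + 1):
                if i == 0 and j == m:
                    continue  # full reversal changes nothing
                cand = best[:i] + best[i:j][::-1] + best[j:]
                c = _path_cost(d, cand)
                if c < best_cost - 1e-12:
                    best, best_cost = cand, c
                    improved = True
        # Or-opt: move a run of 1..3 markers elsewhere
        for seg in (1, 2, 3):
            for i in range(m - seg + 1):
                chunk = best[i : i + seg]
                rest = best[:i] + best[i + seg :]
                for k in range(len(rest) + 1):
                    if k == i:
                        continue
                    cand = rest[:k] + chunk + rest[k:]
                    c = _path_cost(d, cand)
                    if c < best_cost - 1e-12:
                        best, best_cost = cand, c
                        improved = True
    return best, best_cost


def order_markers(
    markers: Sequence[str],
    pairwise: Mapping[tuple[str, str], TwoPointResult],
    strategy: str = "auto",
    exhaustive_max: int = 8,
    n_starts: int = 16,
    seed: int = 0,
) -> MarkerOrder:
    """Minimum-adjacent-distance open path over the group's markers.

    ``strategy``: "auto" (exhaustive up to ``exhaustive_max`` markers, else
    heuristic), "exhaustive", or "heuristic".  The heuristic runs
    nearest-neighbour from up to ``n_starts`` start markers and polishes each
    with 2-opt and Or-opt; it is deterministic given ``seed``.  An order and
    its reverse are equivalent; the returned orientation puts the
    lexicographically smaller endpoint first.
    """
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("need at least two markers to order")
    if strategy not in {"auto", "exhaustive", "heuristic"}:
        raise ValueError("strategy must be auto/exhaustive/heuristic")
    d = _distance_matrix(markers, pairwise)
    m = len(markers)

    exhaustive = strategy == "exhaustive" or (strategy == "auto" and m <= exhaustive_max)
    if exhaustive:
        best, best_cost = None, math.inf
        for perm in itertools.permutations(range(m)):
            if perm[0] > perm[-1]:
                continue  # skip mirror images
            c = _path_cost(d, perm)
            if c < best_cost:
                best, best_cost = list(perm), c
    else:
        rng = np.random.default_rng(seed)
        if m <= n_starts:
            starts = list(range(m))
        else:
            starts = sorted(rng.choice(m, size=n_starts, replace=False).tolist())
        best, best_cost = None, math.inf
        for s in starts:
            path = _nearest_neighbour(d, s)
            path, c = _two_opt(d, path)
            if c < best_cost - 1e-12:
                best, best_cost = path, c

    order = [markers[i] for i in best]
    if order[0] > order[-1]:
        order.reverse()
    return MarkerOrder(tuple(order), best_cost, exhaustive)


def obligate_breaks(
    order: Sequence[str], vectors: Mapping[str, RHVector] | Sequence[RHVector]
) -> tuple[list[int], int]:
    """Adjacent H<->A transitions per hybrid along ``order``, skipping '?'.

    Returns (per-hybrid counts, total).
    """
    by_id = (
        {v.marker_id: v for v in vectors} if not isinstance(vectors, Mapping) else dict(vectors)
    )
    missing = [mid for mid in order if mid not in by_id]
    if missing:
        raise ValueError(f"order references unknown markers {missing}")
    n_hybrids = len(next(iter(by_id.values())))
    per_hybrid = []
    for h in range(n_hybrids):
        calls = [by_id[mid].calls[h] for mid in order]
        informative = [c for c in calls if c != "?"]
        per_hybrid.append(sum(a != b for a, b in zip(informative, informative[1:])))
    return per_hybrid, sum(per_hybrid)


# ---------------------------------------------------------------------------
# laboratory-error flagging
# ---------------------------------------------------------------------------

_THETA_FLOOR = 1e-6


def _chain_loglik10(
    calls: Sequence[str], thetas: Sequence[float], r: float
) -> float:
    """log10 likelihood of one hybrid's calls chained along a fixed order.

    '?' calls are skipped; the effective breakage probability across a gap is
    1 - prod(1 - theta_i) by independence of Poisson breaks.
    """
    idx = [i for i, c in enumerate(calls) if c != "?"]
    if not idx:
        return 0.0
    ll = math.log10(r if calls[idx[0]] == "H" else 1.0 - r)
    for a, b in zip(idx, idx[1:]):
        keep = 1.0
        for t in thetas[a:b]:
            keep *= 1.0 - t
        theta_eff = max(1.0 - keep, _THETA_FLOOR)
        d = theta_eff * r * (1.0 - r)
        ca, cb = calls[a], calls[b]
        if ca == "H":
            p = (r - d) / r if cb == "H" else d / r
        else:
            p = d / (1.0 - r) if cb == "H" else ((1.0 - r) - d) / (1.0 - r)
        ll += math.log10(max(p, 1e-300))
    return ll


def flag_errors(
    order: Sequence[str],
    vectors: Mapping[str, RHVector] | Sequence[RHVector],
    log10_threshold: float = 3.0,
    mode: str = "likelihood",
    pairwise: Mapping[tuple[str, str], TwoPointResult] | None = None,
) -> list[tuple[str, int]]:
    """Probable lab errors as (marker_id, hybrid_index) pairs.

    ``mode="likelihood"`` (default): flag a call when flipping it alone raises
    the chained map log10-likelihood by >= ``log10_threshold``.
    ``mode="singleton"``: flag isolated discordances (both informative
    neighbours agree with each other and disagree with the call) — the
    double-break counting interpretation.  '?' calls are never flagged.
    """
    by_id = (
        {v.marker_id: v for v in vectors} if not isinstance(vectors, Mapping) else dict(vectors)
    )
    order = list(order)
    vecs = [by_id[mid] for mid in order]
    n_hybrids = len(vecs[0])

    if mode == "singleton":
        flags = []
        for h in range(n_hybrids):
            calls = [v.calls[h] for v in vecs]
            idx = [i for i, c in enumerate(calls) if c != "?"]
            for a, b, c in zip(idx, idx[1:], idx[2:]):
                if calls[a] == calls[c] != calls[b]:
                    flags.append((order[b], h))
        return flags
    if mode != "likelihood":
        raise ValueError("mode must be 'likelihood' or 'singleton'")

    # interval breakage probabilities from adjacent two-point fits, global r
    if pairwise is None:
        pairwise = {}
        for a, b in zip(order, order[1:]):
            key = tuple(sorted((a, b)))
            pairwise = {**pairwise, key: two_point(by_id[a], by_id[b])}
    thetas = []
    for a, b in zip(order, order[1:]):
        key = tuple(sorted((a, b)))
        tp = pairwise[key] if key in pairwise else two_point(by_id[a], by_id[b])
        thetas.append(max(tp.theta_hat, _THETA_FLOOR))
    all_calls = "".join(v.calls for v in vecs)
    n_h = all_calls.count("H")
    n_a = all_calls.count("A")
    r = min(max(n_h / (n_h + n_a), 1e-6), 1.0 - 1e-6)

    flags = []
    for h in range(n_hybrids):
        calls = [v.calls[h] for v in vecs]
        base = _chain_loglik10(calls, thetas, r)
        for i, c in enumerate(calls):
            if c == "?":
                continue
            flipped = calls.copy()
            flipped[i] = "A" if c == "H" else "H"
            gain = _chain_loglik10(flipped, thetas, r) - base
            if gain >= log10_threshold:
                flags.append((order[i], h))
    return flags
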