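"""Two-point RH statistics, grouping, TSP ordering and error flagging."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import xlogy

from msytools import rhmap, simdata
from msytools.rhmap import RHVector
from msytools.scenarios import rh_panel_geometry, small_group_ordering


def grid_oracle(nhh, nha, nah, naa, step=1e-3):
    """Brute-force likelihood grid over (theta, r) plus the unlinked model."""
    n = nhh + nha + nah + naa
    nd = nha + nah
    thetas = np.arange(0.0, 1.0 + step / 2, step)
    rs = np.arange(step, 1.0, step)
    tg, rg = np.meshgrid(thetas, rs, indexing="ij")
    d = tg * rg * (1 - rg)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(nhh, rg - d) + xlogy(nd, d) + xlogy(naa, (1 - rg) - d)
    k = int(np.nanargmax(ll))
    r0 = (2 * nhh + nd) / (2 * n)
    ll0 = xlogy(nhh, r0 * r0) + xlogy(nd, r0 * (1 - r0)) + xlogy(naa, (1 - r0) * (1 - r0))
    return (
        float(tg.flat[k]),
        float(rg.flat[k]),
        max(float((ll.flat[k] - ll0) / np.log(10)), 0.0),
    )


# ---------------------------------------------------------------------------
# vectors and counts
# ---------------------------------------------------------------------------


def test_vector_validation():
    with pytest.raises(ValueError):
        RHVector("m", "HAX")
    with pytest.raises(ValueError):
        RHVector("m", "???")


def test_pair_counts_drop_ambiguous():
    vi = RHVector("a", "HHA?A")
    vj = RHVector("b", "HAH?A")
    assert rhmap.pair_counts(vi, vj) == (1, 1, 1, 1)
    with pytest.raises(ValueError):
        rhmap.pair_counts(vi, RHVector("c", "HH"))


def test_no_shared_informative_hybrids_is_an_error():
    with pytest.raises(ValueError):
        rhmap.two_point(RHVector("a", "H?"), RHVector("b", "?H"))


# ---------------------------------------------------------------------------
# two-point MLE
# ---------------------------------------------------------------------------


def test_identical_vectors_cosegregate_perfectly():
    calls = "H" * 28 + "A" * 65
    tp = rhmap.two_point(RHVector("a", calls), RHVector("b", calls))
    assert tp.theta_hat == 0.0
    assert tp.distance == 0.0
    assert tp.lod > 0
    assert tp.n_informative == 93


def test_exact_independence_table_gives_lod_zero():
    tp = rhmap.two_point_from_counts(9, 21, 21, 49)
    assert tp.theta_hat == 1.0
    assert tp.lod == 0.0
    assert tp.r_hat == pytest.approx(0.3)
    assert tp.distance == rhmap.DEFAULT_DISTANCE_CAP


def test_linked_table_matches_grid_oracle():
    tp = rhmap.two_point_from_counts(25, 5, 5, 65)
    oth, orr, olod = grid_oracle(25, 5, 5, 65)
    assert tp.theta_hat == pytest.approx(oth, abs=2e-3)
    assert tp.r_hat == pytest.approx(orr, abs=2e-3)
    assert tp.lod == pytest.approx(olod, abs=0.01)
    assert tp.lod > 10


@given(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=60),
)
def test_lod_is_never_negative(nhh, nha, nah, naa):
    if nhh + nha + nah + naa == 0:
        return
    tp = rhmap.two_point_from_counts(nhh, nha, nah, naa)
    assert tp.lod >= 0.0
    assert 0.0 <= tp.theta_hat <= 1.0
    if tp.theta_hat == 1.0:
        assert tp.lod == 0.0


def test_two_point_is_symmetric(rng):
    for _ in range(20):
        a = "".join(rng.choice(list("HA?"), size=60, p=[0.3, 0.6, 0.1]))
        b = "".join(rng.choice(list("HA?"), size=60, p=[0.3, 0.6, 0.1]))
        if all(c == "?" for c in a) or all(c == "?" for c in b):
            continue
        va, vb = RHVector("a", a), RHVector("b", b)
        try:
            ij = rhmap.two_point(va, vb)
            ji = rhmap.two_point(vb, va)
        except ValueError:
            continue
        assert ij.theta_hat == ji.theta_hat
        assert ij.r_hat == ji.r_hat
        assert ij.lod == ji.lod


def test_distance_is_monotone_in_theta():
    tps = [
        rhmap.TwoPointResult("a", "b", t, 0.3, 1.0, 93)
        for t in (0.0, 0.1, 0.3, 0.6, 0.9, 0.99)
    ]
    distances = [tp.distance for tp in tps]
    assert distances == sorted(distances)
    assert distances[0] == 0.0


def test_theta_recovery_over_simulated_panels():
    """Median adjacent |theta_hat - theta_true| <= 0.03 over 200 panels.

    At the panel-geometry spacing (theta 0.05) the per-pair estimator's
    sampling sd at 93 hybrids is ~0.035, so the median error sits near 0.024.
    """
    theta_true = 0.05
    spacing = -math.log1p(-theta_true)
    errs = []
    for seed in range(200):
        spec = simdata.RHPanelSpec(
            groups=(tuple(i * spacing for i in range(6)),),
            n_hybrids=93,
            retention_prob=0.3,
            seed=seed,
        )
        panel = simdata.simulate_rh_panel(spec)
        vecs = {v.marker_id: v for v in panel.vectors()}
        for a, b in zip(panel.true_order[0], panel.true_order[0][1:]):
            tp = rhmap.two_point(vecs[a], vecs[b])
            errs.append(abs(tp.theta_hat - theta_true))
    assert float(np.median(errs)) <= 0.03


# ---------------------------------------------------------------------------
# linkage groups
# ---------------------------------------------------------------------------


def test_threshold_zero_joins_everything():
    spec = simdata.RHPanelSpec(groups=((0.0, 0.1), (5.0, 5.1)), n_hybrids=50, seed=3)
    panel = simdata.simulate_rh_panel(spec)
    groups = rhmap.linkage_groups(panel.vectors(), lod_threshold=0.0)
    assert len(groups) == 1


def test_two_blocks_resolve_into_two_groups():
    spacing = -math.log(0.9)
    spec = simdata.RHPanelSpec(
        groups=(tuple(i * spacing for i in range(5)), tuple(i * spacing for i in range(4))),
        n_hybrids=93,
        retention_prob=0.3,
        seed=4,
    )
    panel = simdata.simulate_rh_panel(spec)
    groups = rhmap.linkage_groups(panel.vectors(), lod_threshold=10.0)
    assert {frozenset(g) for g in groups} == {
        frozenset(panel.true_order[0]),
        frozenset(panel.true_order[1]),
    }


def test_panel_geometry_29_markers_two_groups_two_singletons():
    geo = rh_panel_geometry(seed=1)
    multi = [g for g in geo["groups"] if len(g) > 1]
    singletons = {next(iter(g)) for g in geo["groups"] if len(g) == 1}
    assert {frozenset(g) for g in multi} == {frozenset(t) for t in geo["true_groups"]}
    assert singletons == geo["singleton_ids"]


def test_linkage_requires_two_markers():
    with pytest.raises(ValueError):
        rhmap.linkage_groups([RHVector("a", "HA")])


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------


def _tp(a, b, theta):
    return rhmap.TwoPointResult(a, b, theta, 0.3, 20.0, 93)


def test_metric_line_is_ordered():
    pw = {
        ("A", "B"): _tp("A", "B", 1 - math.exp(-0.10)),
        ("B", "C"): _tp("B", "C", 1 - math.exp(-0.10)),
        ("A", "C"): _tp("A", "C", 1 - math.exp(-0.20)),
    }
    mo = rhmap.order_markers(["A", "B", "C"], pw)
    assert mo.order in (("A", "B", "C"), ("C", "B", "A"))
    assert mo.optimal
    assert mo.objective == pytest.approx(20.0)


def test_missing_pairwise_entry_is_reported():
    pw = {("A", "B"): _tp("A", "B", 0.1)}
    with pytest.raises(ValueError, match="missing two-point"):
        rhmap.order_markers(["A", "B", "C"], pw)


def test_small_groups_heuristic_matches_exhaustive_and_truth():
    for case in small_group_ordering(seed=1):
        assert case["heuristic"].objective == pytest.approx(case["exhaustive"].objective)
        assert case["heuristic_matches_truth"], case["size"]
        assert case["exhaustive"].optimal and not case["heuristic"].optimal


def test_objective_is_reversal_invariant_and_beats_greedy(rng):
    m = 12
    pos = np.cumsum(rng.uniform(0.05, 0.3, size=m))
    markers = [f"m{i}" for i in range(m)]
    pw = {}
    for i, j in itertools.combinations(range(m), 2):
        theta = 1 - math.exp(-abs(pos[i] - pos[j]))
        pw[tuple(sorted((markers[i], markers[j])))] = _tp(markers[i], markers[j], theta)
    mo = rhmap.order_markers(markers, pw, strategy="heuristic", seed=0)
    d = rhmap._distance_matrix(markers, pw)
    # reversal invariance of the objective
    rev_cost = rhmap._path_cost(d, [markers.index(x) for x in mo.order[::-1]])
    assert rev_cost == pytest.approx(mo.objective)
    # never worse than plain greedy nearest-neighbour from any start
    greedy_best = min(
        rhmap._path_cost(d, rhmap._nearest_neighbour(d, s)) for s in range(m)
    )
    assert mo.objective <= greedy_best + 1e-9


def test_noisy_panel_order_recovery_within_two_swaps():
    """2% call errors leave each group within 2 adjacent swaps of the truth."""
    spacing = -math.log(0.85)
    for seed in (1, 2):
        spec = simdata.RHPanelSpec(
            groups=(
                tuple(i * spacing for i in range(14)),
                tuple(i * spacing for i in range(13)),
            ),
            n_hybrids=93,
            retention_prob=0.3,
            error_rate=0.02,
            seed=seed,
        )
        panel = simdata.simulate_rh_panel(spec)
        pw = rhmap.pairwise_table(panel.vectors())
        for truth in panel.true_order:
            mo = rhmap.order_markers(truth, pw, seed=seed)
            pos = {m: i for i, m in enumerate(mo.order)}
            swaps = sum(
                1 for a, b in itertools.combinations(truth, 2) if pos[a] > pos[b]
            )
            swaps = min(swaps, len(truth) * (len(truth) - 1) // 2 - swaps)
            assert swaps <= 2, (seed, truth[0], swaps)


# ---------------------------------------------------------------------------
# obligate breaks
# ---------------------------------------------------------------------------


def test_obligate_breaks_basics():
    vecs = [RHVector("a", "HH"), RHVector("b", "AH"), RHVector("c", "HH")]
    per_hybrid, total = rhmap.obligate_breaks(["a", "b", "c"], vecs)
    assert per_hybrid == [2, 0]
    assert total == 2


def test_all_present_hybrid_has_no_breaks():
    vecs = [RHVector(m, "H") for m in "abc"]
    assert rhmap.obligate_breaks(["a", "b", "c"], vecs) == ([0], 0)


def test_ambiguous_calls_are_skipped_in_break_counting():
    vecs = [RHVector("a", "HH"), RHVector("b", "?A"), RHVector("c", "HH")]
    # hybrid 0: H,(skip),H -> 0 breaks; hybrid 1: H,A,H -> 2 breaks
    assert rhmap.obligate_breaks(["a", "b", "c"], vecs) == ([0, 2], 2)


def test_obligate_breaks_match_direct_scan(rng):
    m, n = 10, 40
    vecs = [
        RHVector(f"m{i}", "".join(rng.choice(list("HA?"), size=n, p=[0.3, 0.6, 0.1])))
        for i in range(m)
    ]
    order = [f"m{i}" for i in range(m)]
    per_hybrid, total = rhmap.obligate_breaks(order, vecs)
    by_id = {v.marker_id: v for v in vecs}
    expected_total = 0
    for h in range(n):
        seq = [by_id[x].calls[h] for x in order if by_id[x].calls[h] != "?"]
        expected_total += sum(a != b for a, b in zip(seq, seq[1:]))
    assert total == expected_total
    assert sum(per_hybrid) == total


# ---------------------------------------------------------------------------
# error flagging
# ---------------------------------------------------------------------------


def _tight_panel(seed=11, theta=0.02, m=10):
    spacing = -math.log1p(-theta)
    spec = simdata.RHPanelSpec(
        groups=(tuple(i * spacing for i in range(m)),),
        n_hybrids=93,
        retention_prob=0.3,
        seed=seed,
    )
    return simdata.simulate_rh_panel(spec)


def test_noiseless_panel_has_no_flags():
    panel = _tight_panel()
    vecs = {v.marker_id: v for v in panel.vectors()}
    assert rhmap.flag_errors(panel.true_order[0], vecs) == []


def test_seeded_flip_is_flagged_by_both_modes():
    panel = _tight_panel()
    order = panel.true_order[0]
    vecs = {v.marker_id: v for v in panel.vectors()}
    mid = order[4]
    calls = list(vecs[mid].calls)
    calls[5] = "A" if calls[5] == "H" else "H"
    vecs[mid] = RHVector(mid, "".join(calls))
    assert (mid, 5) in rhmap.flag_errors(order, vecs, log10_threshold=3.0)
    assert (mid, 5) in rhmap.flag_errors(order, vecs, mode="singleton")


def test_flip_gain_matches_direct_chain_likelihood():
    """The reported flags are exactly the calls whose single-flip gain >= 3."""
    panel = _tight_panel(seed=12)
    order = panel.true_order[0]
    vecs = {v.marker_id: v for v in panel.vectors()}
    mid = order[5]
    calls = list(vecs[mid].calls)
    calls[7] = "A" if calls[7] == "H" else "H"
    vecs[mid] = RHVector(mid, "".join(calls))
    flags = set(rhmap.flag_errors(order, vecs, log10_threshold=3.0))

    # independent oracle: recompute every flip gain from the chain likelihood
    pw = {tuple(sorted((a, b))): rhmap.two_point(vecs[a], vecs[b])
          for a, b in zip(order, order[1:])}
    thetas = [max(pw[tuple(sorted((a, b)))].theta_hat, 1e-6)
              for a, b in zip(order, order[1:])]
    allcalls = "".join(vecs[m].calls for m in order)
    r = allcalls.count("H") / (allcalls.count("H") + allcalls.count("A"))
    expected = set()
    n_hyb = len(next(iter(vecs.values())))
    for h in range(n_hyb):
        row = [vecs[m].calls[h] for m in order]
        base = rhmap._chain_loglik10(row, thetas, r)
        for i, c in enumerate(row):
            if c == "?":
                continue
            alt = row.copy()
            alt[i] = "A" if c == "H" else "H"
            if rhmap._chain_loglik10(alt, thetas, r) - base >= 3.0:
                expected.add((order[i], h))
    assert flags == expected
    assert (mid, 7) in flags


def test_ambiguous_calls_are_never_flagged():
    panel = _tight_panel(seed=13)
    order = panel.true_order[0]
    vecs = {v.marker_id: v for v in panel.vectors()}
    mid = order[3]
    calls = list(vecs[mid].calls)
    calls[9] = "?"
    vecs[mid] = RHVector(mid, "".join(calls))
    for marker, hybrid in rhmap.flag_errors(order, vecs):
        assert vecs[marker].calls[hybrid] != "?"
    for marker, hybrid in rhmap.flag_errors(order, vecs, mode="singleton"):
        assert vecs[marker].calls[hybrid] != "?"
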