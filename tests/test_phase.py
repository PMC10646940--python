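"""Phase-space bookkeeping: classification, selectivity curves, maps.

These tests run on synthetic phase-point results (no optimisation), except
for one tiny end-to-end scan.
"""

import numpy as np
import pandas as pd
import pytest

from cgcage import AngleGrid, accessible_map, classify, percent_selected, scan
from cgcage.phase import (
    DEFAULT_THRESHOLD,
    PhasePointResult,
    proportion_accessible,
    results_table,
)


def point(topology, combo, e_b, torsion="on", n_bbs=None):
    sizes = {"Tri2Di3": 5, "Tri4Di6": 10, "Tri8Di12": 20, "Tet6Di12": 18}
    return PhasePointResult(
        topology=topology,
        combo=combo,
        torsion_state=torsion,
        e_b=e_b,
        stable=e_b <= DEFAULT_THRESHOLD,
        n_building_blocks=n_bbs or sizes.get(topology, 10),
        seed=0,
    )


COMBO = {"ditopic": 120.0, "tritopic": 110.0}


def test_classify_unstable_selective_mixed():
    results = [
        point("Tri2Di3", COMBO, 5.0),
        point("Tri4Di6", COMBO, 0.1),
        point("Tri8Di12", COMBO, 0.2),
    ]
    (out,) = classify(results)
    assert out.outcome == "mixed"
    assert out.stable_topologies == ("Tri4Di6", "Tri8Di12")
    assert out.smallest_stable == "Tri4Di6"

    (sel,) = classify(results[:2])
    assert sel.outcome == "selective"
    (uns,) = classify([results[0]])
    assert uns.outcome == "unstable"
    assert uns.smallest_stable is None


def test_threshold_monotonicity_of_stable_sets():
    rng = np.random.default_rng(5)
    results = [
        point("Tri4Di6", {"ditopic": d, "tritopic": t}, float(rng.exponential(0.5)))
        for d in (110.0, 120.0)
        for t in (100.0, 110.0)
    ]
    for t1, t2 in [(0.1, 0.3), (0.3, 1.0)]:
        s1 = {(r.topology, r.combo_key()) for r in results if r.e_b <= t1}
        s2 = {(r.topology, r.combo_key()) for r in results if r.e_b <= t2}
        assert s1 <= s2


def test_percent_selected_limits_and_peak():
    """Zero threshold selects nothing; infinite threshold makes all mixed;
    an interior threshold can select everything (curve has a maximum)."""
    results = []
    for i, d in enumerate((100.0, 110.0, 120.0)):
        combo = {"ditopic": d, "tritopic": 110.0}
        results.append(point("Tri4Di6", combo, 0.2))  # stable at 0.3
        results.append(point("Tri8Di12", combo, 1.0 + i))  # stable only late
    curve = percent_selected(results, [0.0, 0.3, 100.0], "3C")
    assert curve.percent_selected.tolist() == [0.0, 100.0, 0.0]


def test_percent_selected_requires_family():
    with pytest.raises(ValueError):
        percent_selected([], [0.3], "5C")


def test_accessible_map_table_and_unknown_fill():
    results = [
        point("Tri4Di6", {"ditopic": d, "tritopic": t}, 0.1 if d == 110.0 else 5.0)
        for d in (110.0, 120.0)
        for t in (100.0, 110.0)
    ]
    outcomes = classify(results)
    grid = AngleGrid(ditopic=(110.0, 120.0, 130.0), tritopic=(100.0, 110.0))
    df = accessible_map(outcomes, grid=grid)
    assert isinstance(df, pd.DataFrame)
    assert len(df) == 6  # 3 x 2 grid
    unknown = df[df.outcome == "unknown"]
    assert set(unknown.angle_ditopic) == {130.0}
    stable_rows = df[df.outcome == "selective"]
    assert set(stable_rows.angle_ditopic) == {110.0}
    assert set(stable_rows.smallest_stable) == {"Tri4Di6"}


def test_proportion_accessible_bounds():
    results = [
        point("Tri4Di6", {"ditopic": d, "tritopic": 110.0}, e)
        for d, e in [(100.0, 0.1), (110.0, 0.2), (120.0, 5.0), (130.0, 9.0)]
    ]
    assert proportion_accessible(results, "Tri4Di6") == pytest.approx(0.5)
    all_stable = [point("Tri4Di6", {"ditopic": d, "tritopic": 1.0}, 0.0) for d in range(4)]
    assert proportion_accessible(all_stable, "Tri4Di6") == 1.0
    assert proportion_accessible([], "Tri4Di6") == 0.0


def test_empty_grid_returns_no_results():
    grid = AngleGrid(ditopic=(), tritopic=(), tetratopic=())
    assert scan(["Tri4Di6"], grid=grid) == []


def test_scan_order_invariance_via_content_seeds():
    """Point seeds derive from content, so topology order cannot matter."""
    from cgcage.optimiser import SearchConfig

    fast = SearchConfig(md_steps=100, md_frames=2, shift_factors=(1.5,))
    grid = AngleGrid(ditopic=(120.0,), tritopic=(110.0,), tetratopic=(80.0,))
    a = scan(["Tri2Di3", "Tet2Di4"], grid=grid, search=fast, seed=9)
    b = scan(["Tet2Di4", "Tri2Di3"], grid=grid, search=fast, seed=9)
    ka = {(r.topology, r.combo_key()): r.e_b for r in a}
    kb = {(r.topology, r.combo_key()): r.e_b for r in b}
    assert ka == kb


def test_scan_cache_resumes():
    from cgcage.optimiser import SearchConfig

    fast = SearchConfig(md_steps=100, md_frames=2, shift_factors=(1.5,))
    grid = AngleGrid(ditopic=(120.0,), tritopic=(110.0,))
    cache = {}
    a = scan(["Tri2Di3"], grid=grid, search=fast, seed=9, cache=cache)
    assert len(cache) == 1
    b = scan(["Tri2Di3"], grid=grid, search=fast, seed=9, cache=cache)
    assert b[0] is a[0]


def test_results_table_schema():
    df = results_table([point("Tri4Di6", COMBO, 0.1)])
    assert list(df.columns) == [
        "topology",
        "family",
        "torsion_state",
        "ditopic_angle",
        "polytopic_angle",
        "E_b",
        "stable",
        "outcome",
        "smallest_stable",
        "seed",
    ]
    assert df.family[0] == "3C"
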