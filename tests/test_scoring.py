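"""Scoring-module tests: classification, break counting, tabulation, and the
exact/nonparametric tests, each checked against an independent oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cytodose.scoring import (
    AberrationCategory,
    AberrationEvent,
    AberrationSubtype,
    CellRecord,
    ScoringTable,
    classify_event,
    count_breaks,
    fisher_exact,
    mann_whitney_u,
    read_cell_records,
    tabulate,
    write_cell_records,
)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "code,category,subtype",
    [
        ("dic", AberrationCategory.UNSTABLE_EXCHANGE, AberrationSubtype.DICENTRIC),
        ("r", AberrationCategory.UNSTABLE_EXCHANGE, AberrationSubtype.CENTRIC_RING),
        ("t(unbal)", AberrationCategory.UNSTABLE_EXCHANGE,
         AberrationSubtype.UNBALANCED_TRANSLOCATION),
        ("t(bal)", AberrationCategory.STABLE_EXCHANGE,
         AberrationSubtype.BALANCED_TRANSLOCATION),
        ("ace", AberrationCategory.EXCESS_FRAGMENT,
         AberrationSubtype.TERMINAL_FRAGMENT),
        ("DIC", AberrationCategory.UNSTABLE_EXCHANGE, AberrationSubtype.DICENTRIC),
        (" T(Bal) ", AberrationCategory.STABLE_EXCHANGE,
         AberrationSubtype.BALANCED_TRANSLOCATION),
    ],
)
def test_classify_event_codes(code, category, subtype):
    ev = classify_event(code)
    assert ev.category is category
    assert ev.subtype is subtype


def test_classify_event_rejects_unknown_code():
    with pytest.raises(ValueError, match="xyz"):
        classify_event("xyz")
    # the error must list the accepted codes
    with pytest.raises(ValueError, match="dic"):
        classify_event("frag")


def test_event_invariants():
    with pytest.raises(ValueError):
        AberrationEvent(
            category=AberrationCategory.STABLE_EXCHANGE,
            subtype=AberrationSubtype.DICENTRIC,
        )
    with pytest.raises(ValueError):  # exchanges involve >= 2 chromosomes
        AberrationEvent(
            category=AberrationCategory.UNSTABLE_EXCHANGE,
            subtype=AberrationSubtype.DICENTRIC,
            chromosomes_involved=("1",),
        )
    ev = AberrationEvent(
        category=AberrationCategory.STABLE_EXCHANGE,
        subtype=AberrationSubtype.BALANCED_TRANSLOCATION,
        chromosomes_involved=("1", "15"),
    )
    assert ev.chromosomes_involved == ("1", "15")
    with pytest.raises(ValueError):
        AberrationEvent(
            category=AberrationCategory.EXCESS_FRAGMENT,
            chromosomes_involved=("27",),
        )


def test_cell_record_aberrant_iff_any_event():
    empty = CellRecord("c1", 0.0)
    assert not empty.is_aberrant
    rec = CellRecord("c2", 0.5, (classify_event("ace"),))
    assert rec.is_aberrant
    with pytest.raises(ValueError):
        CellRecord("c3", -0.1)


# ---------------------------------------------------------------------------
# break counting
# ---------------------------------------------------------------------------

def _records_from_composition(n_stable, n_unstable, n_fragments, dose=0.0):
    """One event per cell, the simplest composition realisation."""
    events = (
        [classify_event("t(bal)")] * n_stable
        + [classify_event("dic")] * n_unstable
        + [classify_event("ace")] * n_fragments
    )
    return [
        CellRecord(f"c{i}", dose, (ev,)) for i, ev in enumerate(events)
    ]


def test_count_breaks_simple_rules():
    assert count_breaks(CellRecord("c", 0.0)) == 0
    assert count_breaks(CellRecord("c", 0.0, (classify_event("t(bal)"),))) == 2
    assert count_breaks(CellRecord("c", 0.0, (classify_event("ace"),))) == 1
    # a complex aberration may need more breaks than the simple rule assigns
    complex_ev = AberrationEvent(
        category=AberrationCategory.UNSTABLE_EXCHANGE,
        subtype=AberrationSubtype.UNBALANCED_TRANSLOCATION,
        breaks_override=4,
    )
    assert count_breaks(CellRecord("c", 1.0, (complex_ev,))) == 4


@pytest.mark.parametrize(
    "n_stable,n_unstable,n_fragments,expected",
    [
        (2, 2, 18, 26),  # control composition
        (2, 2, 23, 31),  # 0.25 Gy composition
        (3, 2, 30, 40),  # 0.5 Gy composition
    ],
)
def test_minimal_break_identity_on_compositions(
    n_stable, n_unstable, n_fragments, expected
):
    """2 breaks per exchange + 1 per fragment over a dose group's events."""
    records = _records_from_composition(n_stable, n_unstable, n_fragments)
    assert sum(count_breaks(r) for r in records) == expected


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def test_tabulate_all_clear_records():
    records = [CellRecord(f"c{i}", 0.1) for i in range(200)]
    table = tabulate(records)
    row = table.counts.loc[0.1]
    assert row["cells_scored"] == 200
    assert row[["breaks", "aberrant_cells", "total_aberrations"]].sum() == 0
    assert (table.frequencies.loc[0.1] == 0).all()


def test_tabulate_control_composition():
    """18 fragment-only + 4 single-exchange aberrations over 22 of 500 cells."""
    records = _records_from_composition(2, 2, 18)
    records += [CellRecord(f"n{i}", 0.0) for i in range(500 - 22)]
    table = tabulate(records)
    row = table.counts.loc[0.0]
    assert row["breaks"] == 26
    assert row["aberrant_cells"] == 22
    assert row["total_aberrations"] == 22
    freq = table.frequencies.loc[0.0]
    assert freq["breaks"] == pytest.approx(5.2)
    assert freq["aberrant_cells"] == pytest.approx(4.4)


def test_tabulate_order_invariant_and_multi_event_cells():
    rng = np.random.default_rng(7)
    records = _records_from_composition(1, 2, 5, dose=0.5)
    # one cell carrying several events counts once as aberrant
    multi = CellRecord(
        "multi", 0.5, (classify_event("dic"), classify_event("ace"))
    )
    records.append(multi)
    shuffled = list(records)
    rng.shuffle(shuffled)
    t1, t2 = tabulate(records), tabulate(shuffled)
    assert t1 == t2
    row = t1.counts.loc[0.5]
    assert row["aberrant_cells"] == 9
    assert row["total_aberrations"] == 10
    assert row["breaks"] == 2 * 4 + 6


def test_tabulate_rejects_empty():
    with pytest.raises(ValueError):
        tabulate([])


def test_scoring_table_invariant_violations():
    import pandas as pd

    base = dict(
        dose_gy=[0.0], cells_scored=[100], breaks=[5], aberrant_cells=[4],
        stable_exchanges=[1], unstable_exchanges=[1], total_aberrations=[4],
        excess_fragments=[2],
    )
    ScoringTable(pd.DataFrame(base))
    bad = dict(base, total_aberrations=[5])  # breaks the sum identity
    with pytest.raises(ValueError):
        ScoringTable(pd.DataFrame(bad))
    bad = dict(base, aberrant_cells=[5], total_aberrations=[4])
    with pytest.raises(ValueError):
        ScoringTable(pd.DataFrame(bad))


def test_cell_record_tsv_round_trip(tmp_path):
    records = _records_from_composition(2, 3, 4, dose=0.25)
    records.append(CellRecord("clean", 0.25))
    path = tmp_path / "cells.tsv"
    write_cell_records(records, path)
    back = read_cell_records(path)
    assert len(back) == len(records)
    assert tabulate(back) == tabulate(records)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_identical_proportions_is_one():
    assert fisher_exact(10, 90, 10, 90) == pytest.approx(1.0)


def test_fisher_matches_scipy_spot_checks():
    rng = np.random.default_rng(11)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 40, size=4)
        if (a + b == 0) or (c + d == 0):
            continue
        ours = fisher_exact(a, b, c, d, "two")
        _, ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)
        ours_g = fisher_exact(a, b, c, d, "greater")
        _, ref_g = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        assert ours_g == pytest.approx(ref_g, rel=1e-9, abs=1e-12)


def test_fisher_dose_group_significance(fixture_table):
    """Aberrant-cell excesses at 0.1 Gy and exchange excesses at 1 Gy are
    flagged as the calibration study's footnotes report."""
    t = fixture_table
    c, nc = t.control_row("aberrant_cells")
    p = fisher_exact(19, 200 - 19, c, nc - c, "greater")
    assert p < 0.05
    c, nc = t.control_row("stable_exchanges")
    p = fisher_exact(15, 200 - 15, c, nc - c, "greater")
    assert p < 0.01


def test_fisher_rejects_invalid_counts():
    with pytest.raises(ValueError):
        fisher_exact(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        fisher_exact(1.5, 2, 3, 4)
    with pytest.raises(ValueError):
        fisher_exact(1, 2, 3, 4, sided="both")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_permutation_oracle(x, y, sided="two"):
    """Exact p by enumerating every split of the pooled sample."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2
    hits = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        if sided == "two":
            hits += abs(u - mu) >= abs(obs - mu) - 1e-9
        else:
            hits += u >= obs - 1e-9
        total += 1
    return hits / total


def test_mwu_identical_samples():
    u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert u == pytest.approx(4.5)  # n*m/2 under full ties
    assert p == pytest.approx(1.0)


def test_mwu_separated_samples_exact():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(2 / 20)  # 2 of the 20 rank splits are as extreme


@pytest.mark.parametrize(
    "x,y",
    [
        ([1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 5.0]),
        ([0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 2.0]),
        ([5, 1, 3, 3, 2], [4, 4, 2, 6]),
    ],
)
def test_mwu_matches_permutation_oracle_with_ties(x, y):
    _, p = mann_whitney_u(x, y)
    assert p == pytest.approx(_mwu_permutation_oracle(x, y), abs=1e-12)
    _, p_g = mann_whitney_u(x, y, sided="greater")
    assert p_g == pytest.approx(_mwu_permutation_oracle(x, y, "greater"), abs=1e-12)


def test_mwu_large_sample_matches_scipy_asymptotic():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = rng.normal(0.3, size=35)
    u, p = mann_whitney_u(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_mwu_null_rejection_rate_near_alpha():
    """Drawing both samples from one distribution rejects at ~ the alpha level."""
    rng = np.random.default_rng(19)
    reps, alpha = 1000, 0.05
    rejections = 0
    for _ in range(reps):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        _, p = mann_whitney_u(x, y)
        rejections += p <= alpha
    # binomial(1000, 0.05) three-sigma band
    assert 0.03 <= rejections / reps <= 0.075


def test_mwu_rejects_empty_sample():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 5), min_size=2, max_size=5),
    st.lists(st.integers(0, 5), min_size=2, max_size=5),
)
def test_mwu_exact_path_is_symmetric(x, y):
    """Swapping the samples mirrors U and preserves the two-sided p."""
    u_xy, p_xy = mann_whitney_u(x, y)
    u_yx, p_yx = mann_whitney_u(y, x)
    assert u_xy + u_yx == pytest.approx(len(x) * len(y))
    assert p_xy == pytest.approx(p_yx, abs=1e-12)
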