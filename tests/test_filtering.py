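import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dietsweep as ds
from dietsweep.table import ValidationError
from conftest import random_tables


def make_table(columns, sample_ids=None):
    counts = np.column_stack(columns)
    return ds.ReadCountTable(
        taxon_ids=[f"t{i}" for i in range(counts.shape[0])],
        sample_ids=sample_ids or [f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
    )


count_columns = st.lists(
    st.lists(st.integers(0, 500), min_size=6, max_size=6),
    min_size=2, max_size=5,
)


class TestToRRA:
    def test_exact_divisions(self):
        t = make_table([[25_000, 0], [75, 25]])
        rra = ds.to_rra(t)
        np.testing.assert_allclose(rra[:, 0], [1.0, 0.0])
        np.testing.assert_allclose(rra[:, 1], [0.75, 0.25])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = make_table([rng.integers(1, 1000, size=12) for _ in range(3)])
        assert np.allclose(ds.to_rra(t).sum(axis=0), 1.0, atol=1e-12)

    def test_empty_sample_warns_and_stays_zero(self):
        t = make_table([[5, 3], [0, 0]])
        with pytest.warns(UserWarning, match="zero reads"):
            rra = ds.to_rra(t)
        assert rra[:, 1].tolist() == [0.0, 0.0]


class TestApplyThreshold:
    def test_zero_threshold_is_identity(self):
        t = make_table([[90, 6, 4, 0]])
        out = ds.apply_threshold(t, 0.0)
        np.testing.assert_array_equal(out.counts, t.counts)

    def test_strict_retention_at_five_percent(self):
        # RRAs 0.90, 0.06, 0.04 -> the 0.04 taxon does not exceed 0.05
        t = make_table([[90, 6, 4]])
        out = ds.apply_threshold(t, 0.05)
        assert out.counts[:, 0].tolist() == [90, 6, 0]
        assert out.richness().tolist() == [2]

    def test_threshold_one_removes_even_monocultures(self):
        t = make_table([[123]])
        assert ds.apply_threshold(t, 1.0).richness().tolist() == [0]

    def test_counts_not_renormalised(self):
        t = make_table([[900, 60, 40]])
        out = ds.apply_threshold(t, 0.05)
        assert out.counts[0, 0] == 900 and out.counts[1, 0] == 60

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_threshold_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            ds.apply_threshold(make_table([[1]]), bad)

    @given(cols=count_columns, threshold=st.floats(0, 0.2))
    def test_idempotence(self, cols, threshold):
        t = make_table([np.array(c) for c in cols])
        once = ds.apply_threshold(t, threshold)
        twice = ds.apply_threshold(once, threshold)
        np.testing.assert_array_equal(once.counts, twice.counts)

    @given(cols=count_columns,
           t1=st.floats(0, 0.1), t2=st.floats(0, 0.1))
    def test_nesting(self, cols, t1, t2):
        """Retained set at the higher threshold is a subset of the lower's."""
        lo, hi = sorted([t1, t2])
        t = make_table([np.array(c) for c in cols])
        kept_lo = ds.apply_threshold(t, lo).counts > 0
        kept_hi = ds.apply_threshold(t, hi).counts > 0
        assert not (kept_hi & ~kept_lo).any()


class TestThresholdSweep:
    def test_brute_force_oracle(self):
        """Retained sets match an independent per-cell comparison loop."""
        grid = [0.0, 0.01, 0.05, 0.2]
        for table in random_tables(5, seed=11):
            sweep = ds.threshold_sweep(table, grid)
            for j, sid in enumerate(table.sample_ids):
                total = table.counts[:, j].sum()
                for k, thr in enumerate(grid):
                    expected = {
                        table.taxon_ids[i]
                        for i in range(table.n_taxa)
                        if table.counts[i, j] > 0
                        and total > 0
                        and table.counts[i, j] / total > thr
                    }
                    assert sweep.retained[sid][k] == frozenset(expected)
                    assert sweep.richness.loc[sid].iloc[k] == len(expected)

    def test_monotone_richness_and_loss(self):
        for table in random_tables(3, seed=4):
            sweep = ds.threshold_sweep(table)
            assert (sweep.richness.diff(axis=1).iloc[:, 1:] <= 0).all().all()
            assert (sweep.pct_loss.diff(axis=1).iloc[:, 1:] >= -1e-9).all().all()
            assert (sweep.pct_loss.iloc[:, 0] == 0).all()
            assert sweep.pct_loss.to_numpy().min() >= 0
            assert sweep.pct_loss.to_numpy().max() <= 100

    def test_richness_bounded_by_reciprocal_threshold(self):
        for table in random_tables(3, seed=9, n_taxa=40):
            sweep = ds.threshold_sweep(table, [0.002, 0.01, 0.05])
            for thr in sweep.thresholds:
                assert (sweep.richness[thr] < 1 / thr).all()

    def test_single_taxon_sample(self):
        t = make_table([[77]])
        sweep = ds.threshold_sweep(t, [0.0, 0.3, 0.9])
        assert (sweep.richness.iloc[0] == 1).all()
        assert (sweep.pct_loss.iloc[0] == 0).all()

    def test_bad_grids(self):
        t = make_table([[1]])
        with pytest.raises(ValidationError):
            ds.threshold_sweep(t, [])
        with pytest.raises(ValidationError):
            ds.threshold_sweep(t, [0.05, 0.01])

    def test_default_grid_is_26_points(self):
        grid = ds.default_threshold_grid()
        assert len(grid) == 26 and grid[0] == 0 and grid[-1] == 0.05


class TestConvergence:
    def test_identical_samples_converge_at_zero(self):
        t = make_table([[10, 5], [10, 5]], sample_ids=["a", "b"])
        sweep = ds.threshold_sweep(t, [0.0, 0.01])
        assert ds.convergence_threshold(sweep, 0) == 0.0

    def test_disjoint_monocultures(self):
        t = make_table([[50, 0], [0, 70]], sample_ids=["a", "b"])
        sweep = ds.threshold_sweep(t, [0.0, 0.01])
        assert ds.convergence_threshold(sweep, 0) == 0.0

    def test_never_converges_returns_none(self):
        t = make_table([[100, 100], [0, 100]], sample_ids=["a", "b"])
        sweep = ds.threshold_sweep(t, [0.0, 0.1])
        assert ds.convergence_threshold(sweep, 0) is None

    def test_minimal_tolerance_mode(self):
        table = ds.simulate_consumers(seed=1)
        sweep = ds.threshold_sweep(table)
        thr, tol = ds.convergence_threshold(sweep, tolerance=None)
        assert thr in sweep.thresholds
        spread = sweep.richness.max(axis=0) - sweep.richness.min(axis=0)
        assert spread[thr] == tol == spread.min()

    def test_requires_two_samples(self):
        sweep = ds.threshold_sweep(make_table([[5]]), [0.0])
        with pytest.raises(ValidationError):
            ds.convergence_threshold(sweep)


class TestRankOrder:
    def test_stable_order_has_no_inversions(self):
        t = make_table([[60, 25, 15], [95, 5, 0]],
                       sample_ids=["rich", "poor"])
        # rich sample keeps 3 taxa everywhere; poor keeps fewer -- no flips
        sweep = ds.threshold_sweep(t, [0.0, 0.05])
        ranks, inversions = ds.rank_order_trajectory(sweep)
        assert inversions == []
        assert ranks.loc["rich"].tolist() == [1.0, 1.0]

    def test_even_vs_skewed_inversion(self):
        # A: 10 taxa at 10% each; B: one taxon at 91%, nine at 1% each
        a = [100] * 10
        b = [910] + [10] * 9
        t = ds.ReadCountTable(
            taxon_ids=[f"t{i}" for i in range(10)],
            sample_ids=["A", "B"],
            counts=np.column_stack([a, b]),
        )
        sweep = ds.threshold_sweep(t, [0.0, 0.05])
        ranks, inversions = ds.rank_order_trajectory(sweep)
        # tie at threshold 0 (10 vs 10) then A keeps 10, B keeps 1: no strict
        # reversal of a strict base ordering, so no inversion is recorded
        assert sweep.richness.loc["A"].tolist() == [10, 10]
        assert sweep.richness.loc["B"].tolist() == [10, 1]
        assert inversions == []
        # but starting from a strict ordering the reversal is an inversion:
        # B is richer unfiltered (10 vs 5) yet collapses to 1 at 5%
        a2 = [200] * 5 + [0] * 5
        b2 = [910] + [10] * 9
        t2 = ds.ReadCountTable(
            taxon_ids=[f"t{i}" for i in range(10)],
            sample_ids=["A", "B"],
            counts=np.column_stack([a2, b2]),
        )
        sweep2 = ds.threshold_sweep(t2, [0.0, 0.05])
        _, inv2 = ds.rank_order_trajectory(sweep2)
        assert inv2 == [0.05]

    def test_single_sample_empty_inversions(self):
        sweep = ds.threshold_sweep(make_table([[5]]), [0.0, 0.1])
        ranks, inversions = ds.rank_order_trajectory(sweep)
        assert inversions == []


class TestDropoutLedger:
    def test_dominant_taxon_never_drops(self, small_table):
        ledger = ds.dropout_ledger(small_table, [0.0, 0.002, 0.05],
                                   group_by="species", taxon_level=None)
        listed = set()
        for taxa in ledger["taxa"]:
            listed.update(taxa.split(";"))
        assert "t1" not in listed  # 90% RRA in s1

    def test_fixture_ledger_brute_force(self, wildlife):
        table = wildlife.table
        thr = 0.002
        ledger = ds.dropout_ledger(table, [0.0, thr], ("species", "season"),
                                   taxon_level="family")
        assert len(ledger) > 0
        # brute-force recomputation for one group
        groups = table.groups(("species", "season"))
        gname, sids = sorted(groups.items())[0]
        cols = [table.sample_index(s) for s in sids]
        rra = table.counts[:, cols] / table.counts[:, cols].sum(axis=0)
        base = (table.counts[:, cols] > 0).any(axis=1)
        kept = (rra > thr).any(axis=1)
        lost = {table.taxon_ids[i] for i in np.flatnonzero(base & ~kept)}
        sub = ledger[(ledger["group"] == gname) & (ledger["threshold"] == thr)]
        listed = set()
        for taxa in sub["taxa"]:
            listed.update(taxa.split(";"))
        assert listed == lost
        # grass-like families (many low-RRA members) dominate the losses
        fam_losses = sub.set_index("rank_label")["n_taxa_lost"]
        assert fam_losses.sum() == len(lost)

    def test_empty_grid_beyond_zero(self, small_table):
        ledger = ds.dropout_ledger(small_table, [0.0], "species", None)
        assert ledger.empty

    def test_unknown_group_key(self, small_table):
        with pytest.raises(ValidationError):
            ds.dropout_ledger(small_table, [0.0, 0.01], "habitat", None)

    def test_unannotated_taxa_reported_unknown(self, small_table):
        ledger = ds.dropout_ledger(small_table, [0.0, 0.5], "species", "family")
        assert "unknown" in set(ledger["rank_label"])
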