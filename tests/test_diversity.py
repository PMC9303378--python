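import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dietsweep as ds
from dietsweep.table import ValidationError

compositions = st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30)


class TestHillNumber:
    @pytest.mark.parametrize("q", [0, 0.5, 1, 2])
    def test_uniform_composition(self, q):
        p = np.full(7, 1 / 7)
        assert ds.hill_number(p, q) == pytest.approx(7.0, abs=1e-10)

    def test_inverse_simpson_hand_value(self):
        assert ds.hill_number([0.8, 0.2], 2) == pytest.approx(1 / 0.68, abs=1e-12)

    def test_exp_shannon_hand_value(self):
        expected = np.exp(-(0.8 * np.log(0.8) + 0.2 * np.log(0.2)))
        assert ds.hill_number([0.8, 0.2], 1) == pytest.approx(expected, rel=1e-12)
        assert ds.hill_number([0.8, 0.2], 1) == pytest.approx(1.649385, abs=1e-6)

    def test_richness_counts_positive_entries_only(self):
        assert ds.hill_number([0.5, 0.5, 0.0], 0) == 2

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValidationError):
            ds.hill_number([0.0, 0.0], 1)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            ds.hill_number([0.9, -0.1], 1)

    @given(comp=compositions)
    def test_continuity_at_q1(self, comp):
        p = np.array(comp) / np.sum(comp)
        d1 = ds.hill_number(p, 1.0)
        assert abs(ds.hill_number(p, 1 + 1e-6) - d1) < 1e-4
        assert abs(ds.hill_number(p, 1 - 1e-6) - d1) < 1e-4

    @given(comp=compositions)
    def test_monotone_nonincreasing_in_q(self, comp):
        p = np.array(comp) / np.sum(comp)
        qs = [0, 0.5, 1.0, 1.5, 2.0, 3.0]
        d = [ds.hill_number(p, q) for q in qs]
        assert all(d[i] >= d[i + 1] - 1e-9 for i in range(len(d) - 1))
        assert d[-1] >= 1.0 - 1e-12

    @given(comp=compositions, q=st.floats(0, 3))
    def test_doubling_property(self, comp, q):
        """Splitting every taxon into two equal halves doubles D(q)."""
        p = np.array(comp) / np.sum(comp)
        doubled = np.concatenate([p / 2, p / 2])
        assert ds.hill_number(doubled, q) == pytest.approx(
            2 * ds.hill_number(p, q), rel=1e-9)

    def test_agreement_with_scikit_bio(self):
        """D(0), D(1), D(2) match sobs / exp(Shannon) / ENS-PIE within 1e-9."""
        from skbio.diversity.alpha import enspie, shannon, sobs
        rng = np.random.default_rng(12)
        for _ in range(30):
            counts = rng.integers(0, 50, size=rng.integers(2, 25))
            if counts.sum() == 0:
                counts[0] = 1
            p = counts / counts.sum()
            assert ds.hill_number(p, 0) == pytest.approx(
                sobs(counts), abs=1e-9)
            assert ds.hill_number(p, 1) == pytest.approx(
                np.exp(shannon(counts, base=np.e)), rel=1e-9)
            assert ds.hill_number(p, 2) == pytest.approx(
                enspie(counts), rel=1e-9)


class TestDiversityProfile:
    def test_consumer_rank_order_preserved(self):
        table = ds.simulate_consumers(seed=3)
        profiles = {p.unit_id: p for p in ds.diversity_profile(table)}
        spec, inter, gen = (profiles[s] for s in table.sample_ids)
        assert (gen.d_values >= inter.d_values - 1e-9).all()
        assert (inter.d_values >= spec.d_values - 1e-9).all()

    def test_monoculture_flat_at_one(self):
        t = ds.ReadCountTable(["a"], ["s1"], np.array([[500]]))
        (profile,) = ds.diversity_profile(t)
        assert np.allclose(profile.d_values, 1.0)

    def test_q0_matches_sweep_richness(self, small_table):
        profiles = ds.diversity_profile(small_table, q_grid=[0.0])
        sweep = ds.threshold_sweep(small_table, [0.0])
        for p in profiles:
            assert p.at(0.0) == sweep.richness.loc[p.unit_id, 0.0]

    def test_pooled_profiles(self, small_table):
        profiles = ds.diversity_profile(small_table, q_grid=[0.0, 1.0],
                                        pool_by="species")
        ids = {p.unit_id for p in profiles}
        assert ids == {"bison", "bighorn"}

    def test_empty_unit_skipped_with_warning(self):
        t = ds.ReadCountTable(["a"], ["s1", "s2"], np.array([[5, 0]]))
        with pytest.warns(UserWarning):
            profiles = ds.diversity_profile(t, q_grid=[0.0])
        assert [p.unit_id for p in profiles] == ["s1"]


class TestGroupSummary:
    @staticmethod
    def _profiles(values, q=0.0):
        return [
            ds.DiversityProfile(unit_id=f"u{i}", q_grid=np.array([q]),
                                d_values=np.array([v]))
            for i, v in enumerate(values)
        ]

    def test_identical_members_sd_zero(self):
        out = ds.group_summary(self._profiles([4.0, 4.0]),
                               {"u0": "g", "u1": "g"}, q_values=[0.0])
        assert out.loc[0, "sd"] == 0.0

    def test_log_transform_hand_values(self):
        out = ds.group_summary(self._profiles([2.0, 8.0]),
                               {"u0": "g", "u1": "g"}, q_values=[0.0],
                               transform="log")
        # per-sample logs ln2, ln8: mean = ln4, sample SD = |ln8-ln2|/sqrt(2)
        assert out.loc[0, "mean"] == pytest.approx(np.log(4.0), rel=1e-12)
        assert out.loc[0, "sd"] == pytest.approx(
            (np.log(8) - np.log(2)) / np.sqrt(2), rel=1e-12)
        assert out.loc[0, "sd"] == pytest.approx(0.980258, abs=1e-6)

    def test_raw_mean_without_transform(self):
        out = ds.group_summary(self._profiles([2.0, 8.0]),
                               {"u0": "g", "u1": "g"}, q_values=[0.0])
        assert out.loc[0, "mean"] == 5.0

    def test_single_member_flagged(self):
        out = ds.group_summary(self._profiles([3.0]), {"u0": "g"},
                               q_values=[0.0])
        assert bool(out.loc[0, "single_member"]) and out.loc[0, "sd"] == 0.0

    def test_unmapped_unit_rejected(self):
        with pytest.raises(ValidationError):
            ds.group_summary(self._profiles([1.0]), {}, q_values=[0.0])


class TestCompareMethods:
    def test_single_category_composite(self, small_table):
        micro = pd.DataFrame(
            {"bison_summer": [100.0], "bison_winter": [100.0],
             "bighorn_summer": [100.0]}, index=["grass"])
        out = ds.compare_methods(small_table, micro)
        micro_rows = out[out["method"] == "microhistology"]
        assert (micro_rows["mean"] == 1.0).all()

    def test_identical_compositions_agree(self):
        counts = np.array([[50], [30], [20]])
        t = ds.ReadCountTable(
            ["a", "b", "c"], ["s1"], counts,
            sample_meta=pd.DataFrame({"species": ["bison"],
                                      "season": ["summer"]},
                                     index=pd.Index(["s1"], name="sample_id")))
        micro = pd.DataFrame({"bison_summer": [50.0, 30.0, 20.0]},
                             index=["a", "b", "c"])
        out = ds.compare_methods(t, micro)
        for q in (0.0, 1.0, 2.0):
            sub = out[out["q"] == q]
            dna = sub[sub["method"] == "dna"]["mean"].iloc[0]
            mic = sub[sub["method"] == "microhistology"]["mean"].iloc[0]
            assert dna == pytest.approx(mic, rel=1e-12)

    def test_lumping_reduces_richness(self, wildlife):
        micro = ds.generate_microhistology(wildlife)
        identity = ds.generate_microhistology(wildlife, "identity")
        for col in micro.columns:
            assert (micro[col] > 0).sum() < (identity[col] > 0).sum()

    def test_unmatched_groups_listed(self, small_table):
        micro = pd.DataFrame({"moose_fall": [100.0]}, index=["x"])
        with pytest.raises(ValidationError, match="moose_fall"):
            ds.compare_methods(small_table, micro)

    def test_bad_percent_sums_rejected(self, small_table):
        micro = pd.DataFrame(
            {"bison_summer": [50.0], "bison_winter": [100.0],
             "bighorn_summer": [100.0]}, index=["grass"])
        with pytest.raises(ValidationError, match="100"):
            ds.compare_methods(small_table, micro)
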