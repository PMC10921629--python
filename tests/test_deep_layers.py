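"""Band elimination, self-weighting, interval selection and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemorisk import deep_layers, panel_io
from hemorisk.deep_layers import (
    EliminationConfig,
    SelectionConfig,
    assign_record_label,
    elimination_sweep,
    eliminate_normal_records,
    select_by_interval,
    self_weight,
    split_train_test,
)
from hemorisk.panel_io import DegenerateInputError, PanelMatrix, analyte_stats
from hemorisk.synthetic import GeneratorConfig, generate_panels


def _norm_matrix(values):
    return PanelMatrix(values=np.asarray(values, dtype=float), normalized=True)


@pytest.fixture(scope="module")
def toy():
    """A hand-built normalized panel with known mean/std per column."""
    rng = np.random.default_rng(9)
    values = rng.uniform(0, 1, size=(200, 5))
    values[0] = 0.0  # pin the extremes so min=0, max=1 in every column
    values[1] = 1.0
    m = _norm_matrix(values)
    return m, analyte_stats(m)


class TestElimination:
    def test_record_at_means_is_eliminated(self, toy):
        m, s = toy
        values = np.vstack([m.values, s.mean])
        m2 = _norm_matrix(values)
        res = eliminate_normal_records(m2, analyte_stats(m2), EliminationConfig(1.0))
        assert not res.keep_mask[-1]

    def test_one_out_of_band_analyte_keeps_whole_record(self, toy):
        m, s = toy
        row = s.mean.copy()
        row[2] = s.mean[2] + 2.0 * s.std[2]
        m2 = _norm_matrix(np.vstack([m.values, row]))
        s2 = analyte_stats(m2)
        res = eliminate_normal_records(m2, s2, EliminationConfig(1.0))
        assert (np.abs(row - s2.mean) > s2.std).any()  # still out of band
        assert res.keep_mask[-1]

    def test_huge_band_eliminates_everything(self, toy):
        m, s = toy
        res = eliminate_normal_records(m, s, EliminationConfig(a_fe=100.0))
        assert res.n_eliminated == m.n and res.n_retained == 0

    def test_partition_invariant(self, toy):
        m, s = toy
        for a in (0.0, 0.3, 1.0, 2.5):
            res = eliminate_normal_records(m, s, EliminationConfig(a))
            assert res.n_eliminated + res.n_retained == m.n

    def test_stats_mismatch_rejected(self, toy):
        m, s = toy
        bad = panel_io.AnalyteStats(
            min=s.min[:4], max=s.max[:4], mean=s.mean[:4], std=s.std[:4], n=s.n
        )
        with pytest.raises(Exception):
            eliminate_normal_records(m, bad)

    @settings(derandomize=True, max_examples=25)
    @given(
        seed=st.integers(min_value=0, max_value=2**16),
        a_lo=st.floats(min_value=0.0, max_value=2.0),
        delta=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_monotonicity_eliminated_sets_nest(self, seed, a_lo, delta):
        rng = np.random.default_rng(seed)
        m = _norm_matrix(rng.uniform(0, 1, size=(60, 5)))
        s = analyte_stats(m)
        lo = eliminate_normal_records(m, s, EliminationConfig(a_lo))
        hi = eliminate_normal_records(m, s, EliminationConfig(a_lo + delta))
        # eliminated at the narrower band is a subset of eliminated at the wider
        assert np.all(hi.keep_mask <= lo.keep_mask)


class TestEliminationSweep:
    def test_zero_band_eliminates_only_exact_means(self, toy):
        m, s = toy
        table = elimination_sweep(m, s, [0.0])
        expected = int(np.all(m.values == s.mean, axis=1).sum())
        assert table.loc[0, "n_eliminated"] == expected

    def test_counts_weakly_increasing_in_a_fe(self, toy):
        m, s = toy
        table = elimination_sweep(m, s, [0.1, 0.5, 1.0, 2.0, 3.0])
        counts = table["n_eliminated"].to_numpy()
        assert np.all(np.diff(counts) >= 0)

    def test_sweep_matches_per_value_calls(self, toy):
        m, s = toy
        grid = [0.2, 0.7, 1.3]
        table = elimination_sweep(m, s, grid)
        for a, n in zip(table["a_fe"], table["n_eliminated"]):
            direct = eliminate_normal_records(m, s, EliminationConfig(a))
            assert n == direct.n_eliminated

    def test_negative_a_fe_rejected(self, toy):
        m, s = toy
        with pytest.raises(ValueError):
            elimination_sweep(m, s, [-0.5])

    def test_empty_grid_rejected(self, toy):
        m, s = toy
        with pytest.raises(ValueError):
            elimination_sweep(m, s, [])


class TestSelfWeighting:
    def test_extremes_map_to_plus_minus_100_and_band_edge_to_zero(self, toy):
        m, s = toy
        keep = eliminate_normal_records(m, s, EliminationConfig(1.0))
        wp = self_weight(m, s, keep)
        kept_vals = m.values[keep.keep_mask]
        for j in range(5):
            at_max = kept_vals[:, j] == s.max[j]
            at_min = kept_vals[:, j] == s.min[j]
            assert np.allclose(wp.analyte_weights[at_max, j], 100.0)
            assert np.allclose(wp.analyte_weights[at_min, j], -100.0)

    def test_band_boundary_weight_is_zero(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 1, size=(100, 5))
        values[0], values[1] = 0.0, 1.0
        m = _norm_matrix(values)
        s = analyte_stats(m)
        row = s.mean + s.std  # exactly on the band edge everywhere
        row[0] = 0.0  # force retention via one worst-case analyte
        m2 = _norm_matrix(np.vstack([values, row]))
        s2 = analyte_stats(m2)
        keep = eliminate_normal_records(m2, s2, EliminationConfig(1.0))
        wp = self_weight(m2, s2, keep)
        last = wp.analyte_weights[-1]
        edge = np.isclose(np.abs(m2.values[-1] - s2.mean), s2.std)
        assert np.all(last[edge] == 0.0)

    def test_weights_and_labels_bounded(self, weighted_1k):
        assert np.all(np.abs(weighted_1k.analyte_weights) <= 100.0 + 1e-12)
        assert np.all(np.abs(weighted_1k.record_label) <= 100.0 + 1e-12)

    def test_zero_weight_iff_inside_band(self, normalized_1k, stats_1k, weighted_1k):
        norm, _ = normalized_1k
        kept = norm.values[weighted_1k.source_rows]
        inside = np.abs(kept - stats_1k.mean) <= stats_1k.std
        assert np.array_equal(weighted_1k.analyte_weights == 0.0, inside)

    def test_every_retained_record_has_a_nonzero_weight(self, weighted_1k):
        assert np.all(np.any(weighted_1k.analyte_weights != 0.0, axis=1))

    def test_weight_sign_and_monotonicity_beyond_band(self, weighted_1k,
                                                      normalized_1k, stats_1k):
        norm, _ = normalized_1k
        dev = norm.values[weighted_1k.source_rows] - stats_1k.mean
        w = weighted_1k.analyte_weights
        out = w != 0.0
        assert np.all(np.sign(w[out]) == np.sign(dev[out]))
        # strictly increasing |weight| in |dev| beyond the band, per column/side
        for j in range(5):
            for sign in (1, -1):
                mask = out[:, j] & (np.sign(dev[:, j]) == sign)
                order = np.argsort(np.abs(dev[mask, j]))
                assert np.all(np.diff(np.abs(w[mask, j])[order]) >= 0)

    def test_degenerate_side_scale_raises(self):
        # with stats computed from the scored data itself an out-of-band value
        # always pushes the extreme past the band, so D_side > beta holds ...
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 1, size=(50, 5))
        m = _norm_matrix(values)
        s = analyte_stats(m)
        keep = eliminate_normal_records(m, s, EliminationConfig(1.0))
        self_weight(m, s, keep)  # never degenerate
        # ... but externally supplied stats (training stats applied to new
        # data) can place the observed extreme inside the band: degenerate.
        ext = panel_io.AnalyteStats(
            min=np.zeros(5), max=np.full(5, 0.6),
            mean=np.full(5, 0.5), std=np.full(5, 0.3), n=50,
        )
        m2 = _norm_matrix(np.vstack([values, np.full(5, 0.9)]))
        keep2 = eliminate_normal_records(m2, ext, EliminationConfig(1.0))
        with pytest.raises(DegenerateInputError):
            self_weight(m2, ext, keep2)


class TestRecordLabel:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            ((0, 0, -40, 0, 0), -40.0),  # single nonzero analyte
            ((30, -50, 0, 0, 0), -50.0),  # max-magnitude rule
            ((50, -50, 0, 0, 0), 50.0),  # tie broken by analyte priority
        ],
    )
    def test_label_rules(self, weights, expected):
        assert assign_record_label(weights) == expected

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            assign_record_label((0.0,) * 5)


class TestIntervalSelection:
    def test_cap_at_i_t(self, weighted_1k):
        ts, summary = select_by_interval(weighted_1k, SelectionConfig(i_t=5))
        t = summary.table
        assert (t["selected_pos"] == np.minimum(t["existing_pos"], 5)).all()
        assert (t["selected_neg"] == np.minimum(t["existing_neg"], 5)).all()
        assert ts.m == summary.total_selected

    def test_underfull_bins_select_everything(self, weighted_1k):
        ts, summary = select_by_interval(weighted_1k, SelectionConfig(i_t=10**6))
        assert summary.total_selected == summary.total_existing == ts.m
        assert ts.m == weighted_1k.record_label.size

    def test_existing_counts_cover_all_retained(self, weighted_1k):
        _, summary = select_by_interval(weighted_1k, SelectionConfig(i_t=50))
        assert summary.total_existing == weighted_1k.record_label.size

    def test_empty_bins_report_zero_without_error(self):
        wp = deep_layers.WeightedPanel(
            analyte_weights=np.array([[95.0, 0, 0, 0, 0]]),
            record_label=np.array([95.0]),
            source_rows=np.array([0]),
            values=np.array([[1.0, 0.5, 0.5, 0.5, 0.5]]),
        )
        _, summary = select_by_interval(wp)
        t = summary.table.set_index("interval")
        assert t.loc[100, "existing_pos"] == 1
        assert t.drop(index=100)["existing_pos"].sum() == 0
        assert t["existing_neg"].sum() == 0

    def test_ranking_prefers_extreme_labels(self):
        labels = np.array([11.0, 15.0, 19.0, 13.0])  # all in the (10, 20] bin
        wp = deep_layers.WeightedPanel(
            analyte_weights=np.column_stack([labels] + [np.zeros(4)] * 4),
            record_label=labels,
            source_rows=np.arange(4),
            values=np.full((4, 5), 0.5),
        )
        ts, _ = select_by_interval(wp, SelectionConfig(i_t=2))
        assert sorted(ts.d_tr.tolist()) == [15.0, 19.0]

    def test_bin_edges_are_half_open(self):
        # +10 belongs to (0, 10]; 10.5 to (10, 20]; -10 to [-10, 0); -10.5 to [-20, -10)
        ids = deep_layers._bin_ids_for_labels(
            np.array([10.0, 10.5, -10.0, -10.5, 100.0, -100.0]), 10
        )
        assert ids.tolist() == [10, 20, -10, -20, 100, -100]


class TestSplit:
    def test_per_bin_rounding(self):
        labels = np.array([12.0, 14.0, 16.0, 18.0])
        ts = deep_layers.TrainingSet(
            d_e=np.full((4, 5), 0.5),
            d_tr=labels,
            bin_id=np.full(4, 20),
            source_rows=np.arange(4),
        )
        out = split_train_test(ts, fraction=0.75, seed=1)
        assert (out.split_tag == "train").sum() == 3
        assert (out.split_tag == "test").sum() == 1

    def test_same_seed_same_tags(self, training_set_1k, weighted_1k):
        ts, _ = select_by_interval(weighted_1k, SelectionConfig(i_t=50))
        a = split_train_test(ts, fraction=0.75, seed=42)
        b = split_train_test(ts, fraction=0.75, seed=42)
        assert np.array_equal(a.split_tag, b.split_tag)

    def test_partition_is_exact(self, training_set_1k):
        tags = training_set_1k.split_tag
        assert set(tags) <= {"train", "test"}
        train = training_set_1k.partition("train")
        test = training_set_1k.partition("test")
        assert train.m + test.m == training_set_1k.m
        assert set(train.source_rows) & set(test.source_rows) == set()

    def test_bad_fraction_rejected(self, training_set_1k):
        with pytest.raises(ValueError):
            split_train_test(training_set_1k, fraction=1.5, seed=0)

    def test_csv_round_trip(self, tmp_path, training_set_1k):
        path = tmp_path / "ts.csv"
        training_set_1k.to_csv(path)
        back = deep_layers.TrainingSet.from_csv(path)
        np.testing.assert_allclose(back.d_e, training_set_1k.d_e, atol=1e-9)
        np.testing.assert_allclose(back.d_tr, training_set_1k.d_tr, atol=1e-9)
        assert np.array_equal(back.split_tag, training_set_1k.split_tag)


class TestEndToEndDeterminism:
    def test_identical_inputs_and_seed_give_identical_training_sets(self, tmp_path):
        def run(out):
            recs = generate_panels(GeneratorConfig(n=800, seed=55))
            raw = panel_io.records_to_matrix(recs)
            norm, _ = panel_io.min_max_normalize(raw)
            s = analyte_stats(norm)
            keep = eliminate_normal_records(norm, s)
            wp = self_weight(norm, s, keep)
            ts, _ = select_by_interval(wp, SelectionConfig(i_t=100))
            ts = split_train_test(ts, seed=55)
            ts.to_csv(out)
            return out.read_bytes()

        assert run(tmp_path / "a.csv") == run(tmp_path / "b.csv")
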