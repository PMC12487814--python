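"""Time-lagged cross-correlation: oracle agreement, neighbours, filtering."""

import numpy as np
import pandas as pd
import pytest

import chronovae as cv
from chronovae.tlcc import (TLCCConfig, TLCCMatrix, assign_proximal_peaks,
                            build_tlcc_matrix, default_shifts,
                            filter_and_categorize, select_neighbors,
                            tlcc_vector)

GRID = TLCCConfig().time_grid()
SHIFTS = default_shifts()
CORE = (8.0, 8.5)


def brute_force_tlcc(expr, acc, shifts, core, grid):
    """Independent oracle: slice and correlate explicitly for every shift."""
    dt = grid[1] - grid[0]
    core_idx = [i for i, t in enumerate(grid) if core[0] - 1e-9 <= t <= core[1] + 1e-9]
    out = []
    for s in shifts:
        k = int(round(s / dt))
        e = [expr[i] for i in core_idx]
        a = [acc[i + k] for i in core_idx]
        if np.std(e) == 0 or np.std(a) == 0:
            out.append(np.nan)
        else:
            out.append(np.corrcoef(e, a)[0, 1])
    return np.array(out)


class TestTLCCVector:
    def test_has_exactly_101_entries_for_default_shifts(self):
        v = tlcc_vector(np.sin(GRID), np.sin(GRID), SHIFTS, CORE, GRID)
        assert len(v) == 101
        assert len(SHIFTS) == 101

    def test_identical_trajectories_peak_at_zero_shift_with_value_one(self):
        x = np.sin(2 * np.pi * GRID / 1.3)
        v = tlcc_vector(x, x, SHIFTS, CORE, GRID)
        assert SHIFTS[np.nanargmax(v)] == 0.0
        assert np.nanmax(v) == pytest.approx(1.0)

    def test_known_offset_recovered_at_negative_shift(self):
        # accessibility pattern occurs 0.1 day earlier than expression
        expr = np.sin(2 * np.pi * GRID / 1.4)
        acc = np.sin(2 * np.pi * (GRID + 0.1) / 1.4)
        v = tlcc_vector(expr, acc, SHIFTS, CORE, GRID)
        assert SHIFTS[np.nanargmax(v)] == pytest.approx(-0.1, abs=0.011)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            expr = rng.normal(size=len(GRID)).cumsum()
            acc = rng.normal(size=len(GRID)).cumsum()
            got = tlcc_vector(expr, acc, SHIFTS, CORE, GRID)
            want = brute_force_tlcc(expr, acc, SHIFTS, CORE, GRID)
            assert np.allclose(got, want, equal_nan=True, atol=1e-12)

    def test_time_reversal_reverses_the_vector(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=len(GRID)).cumsum()
        acc = rng.normal(size=len(GRID)).cumsum()
        fwd = tlcc_vector(expr, acc, SHIFTS, CORE, GRID)
        # reversing both trajectories maps the core window onto [8, 8.5]
        # again (the grid is symmetric about 8.25), with shifts negated
        rev = tlcc_vector(expr[::-1], acc[::-1], SHIFTS, CORE, GRID)
        assert np.allclose(rev, fwd[::-1], equal_nan=True, atol=1e-12)

    def test_constant_window_recorded_as_missing(self):
        v = tlcc_vector(np.ones(len(GRID)), np.sin(GRID), SHIFTS, CORE, GRID)
        assert np.all(np.isnan(v))

    def test_shift_must_align_with_grid_step(self):
        with pytest.raises(ValueError, match="multiple"):
            tlcc_vector(np.sin(GRID), np.sin(GRID), np.array([0.005]),
                        CORE, GRID)


class TestConfig:
    def test_interval_must_pad_core_by_max_shift(self):
        with pytest.raises(ValueError, match="pad"):
            TLCCConfig(interval=(7.8, 9.0), core_window=(8.0, 8.5))

    def test_default_grid_covers_interval_uniformly(self):
        assert GRID[0] == 7.5 and GRID[-1] == 9.0
        assert len(GRID) == 151
        assert np.allclose(np.diff(GRID), 0.01)


class TestSelectNeighbors:
    def test_single_model_reduces_to_plain_top_k(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(30, 4))
        ids = [f"c{i}" for i in range(30)]
        got = select_neighbors([emb], ids, "c0")
        d = np.linalg.norm(emb - emb[0], axis=1)
        d[0] = np.inf
        assert got == ["c0"] + [ids[i] for i in np.argsort(d)[:4]]
        assert len(got) == 5  # query plus four neighbours

    def test_duplicates_of_the_query_selected_first(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(20, 3))
        emb[7] = emb[0]
        emb[13] = emb[0]
        got = select_neighbors([emb], [f"c{i}" for i in range(20)], "c0")
        assert set(got[1:3]) == {"c7", "c13"}

    def test_consistent_rankings_across_models_match_single_model(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(40, 5))
        ids = [f"c{i}" for i in range(40)]
        single = select_neighbors([emb], ids, "c3")
        # isometries preserve all distances, so rankings agree per model
        rot, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        ensemble = [emb, emb @ rot, (emb @ rot) @ rot]
        assert select_neighbors(ensemble, ids, "c3") == single

    def test_absent_from_all_top_lists_excluded(self):
        emb = np.array([[0.0], [1.0], [2.0], [50.0]])
        with pytest.warns(UserWarning, match="eligible"):
            got = select_neighbors([emb], ["a", "b", "c", "far"], "a",
                                   k_top=2, n_keep=3)
        assert "far" not in got


class TestProximalPeaks:
    TSS = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "position": [500_000, 500_000, 100_000],
        "strand": ["+", "-", "+"],
        "gene_id": ["gPlus", "gMinus", "gChr2"],
    })

    def test_upstream_window_is_strand_aware(self):
        peaks = pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [400_000, 290_000, 600_000],
            "end": [400_500, 299_000, 600_500],
            "peak_id": ["p100kbLeft", "p210kbLeft", "p100kbRight"],
        })
        pairs = set(assign_proximal_peaks(self.TSS, peaks))
        assert ("p100kbLeft", "gPlus") in pairs      # 100 kb upstream of +
        assert ("p210kbLeft", "gPlus") not in pairs  # beyond 200 kb
        assert ("p100kbRight", "gMinus") in pairs    # right of a - TSS
        assert ("p100kbRight", "gPlus") not in pairs

    def test_unknown_chromosome_warned_and_skipped(self):
        peaks = pd.DataFrame({"chrom": ["chrX"], "start": [0],
                              "end": [100], "peak_id": ["p"]})
        with pytest.warns(UserWarning, match="chrX"):
            assert assign_proximal_peaks(self.TSS, peaks) == []


class TestFilterAndCategorize:
    @staticmethod
    def matrix(cols, index):
        return TLCCMatrix(SHIFTS, np.column_stack(cols), index)

    @staticmethod
    def col(best_shift, height=0.8):
        v = np.zeros(101)
        v[np.argmin(np.abs(SHIFTS - best_shift))] = height
        return v

    def test_pair_in_two_cells_with_good_correlation_retained(self):
        m = self.matrix([self.col(-0.1), self.col(-0.12)],
                        [("p", "g", "c1"), ("p", "g", "c2")])
        out = filter_and_categorize(m)
        assert list(out.category) == ["before"]

    def test_low_correlation_columns_removed(self):
        m = self.matrix([self.col(-0.1, height=0.4),
                         self.col(-0.1, height=0.4)],
                        [("p", "g", "c1"), ("p", "g", "c2")])
        assert filter_and_categorize(m).empty

    def test_single_cell_pairs_removed(self):
        m = self.matrix([self.col(0.2)], [("p", "g", "c1")])
        assert filter_and_categorize(m).empty

    def test_discordant_signs_flagged(self):
        m = self.matrix([self.col(-0.1), self.col(0.1)],
                        [("p", "g", "c1"), ("p", "g", "c2")])
        assert list(filter_and_categorize(m).category) == ["discordant"]

    def test_zero_shift_maximum_is_uncategorised(self):
        m = self.matrix([self.col(0.0), self.col(0.0)],
                        [("p", "g", "c1"), ("p", "g", "c2")])
        assert list(filter_and_categorize(m).category) == ["uncategorized"]

    def test_argmax_tie_breaks_toward_smallest_absolute_shift(self):
        v = np.zeros(101)
        v[np.argmin(np.abs(SHIFTS - 0.1))] = 0.8
        v[np.argmin(np.abs(SHIFTS - 0.4))] = 0.8
        m = self.matrix([v, v], [("p", "g", "c1"), ("p", "g", "c2")])
        out = filter_and_categorize(m)
        assert out.median_best_shift.iloc[0] == pytest.approx(0.1)


class TestBuildMatrix:
    def test_shape_is_101_by_pairs_times_cells(self, mm_ensemble, mm_sim):
        rna, _, _, truth = mm_sim
        qidx = int(np.flatnonzero(np.isclose(rna.time, 8.25))[0])
        pairs = [(f"peak{p}", f"gene{truth.peak_gene[p]}")
                 for p in range(3) if truth.peak_gene[p] >= 0]
        out = build_tlcc_matrix(mm_ensemble[:2], rna.cell_ids[qidx], pairs,
                                TLCCConfig())
        assert out.matrix.shape == (101, len(pairs) * 5)

    def test_empty_pairs_give_empty_matrix_with_warning(self, mm_ensemble):
        with pytest.warns(UserWarning, match="no .peak, gene. pairs"):
            out = build_tlcc_matrix(mm_ensemble[:1], "rna0", [], TLCCConfig())
        assert out.matrix.shape == (101, 0)

    def test_deterministic_given_trained_ensemble(self, mm_ensemble, mm_sim):
        rna, _, _, truth = mm_sim
        qidx = int(np.flatnonzero(np.isclose(rna.time, 8.25))[0])
        pairs = [(f"peak{p}", f"gene{truth.peak_gene[p]}")
                 for p in range(2) if truth.peak_gene[p] >= 0]
        a = build_tlcc_matrix(mm_ensemble[:2], rna.cell_ids[qidx], pairs,
                              TLCCConfig())
        b = build_tlcc_matrix(mm_ensemble[:2], rna.cell_ids[qidx], pairs,
                              TLCCConfig())
        assert np.array_equal(a.matrix, b.matrix, equal_nan=True)


class TestLagRecovery:
    def test_statistic_recovers_programmed_lags_on_ideal_trajectories(self):
        """Narrow contained pulses: the windowed cross-correlation argmax
        equals the programmed lag to +/-0.02 day for >=80% of linked pairs."""
        cfg = cv.preset("multimodal", seed=5, n_cell_types=2, n_genes=60,
                        cells_per_type_per_time=5,
                        multimodal=cv.MultimodalDesign(
                            n_peaks=30, n_linked=20,
                            link_width=(0.05, 0.09)))
        _, _, _, truth = cv.simulate_multimodal(cfg)
        ok = tot = 0
        for p in range(30):
            g = truth.peak_gene[p]
            if g < 0:
                continue
            expr = truth.true_fraction(0, GRID)[g]
            acc = truth.peak_probability(0, GRID)[p]
            v = tlcc_vector(expr, acc, SHIFTS, CORE, GRID)
            if np.all(np.isnan(v)) or np.nanmax(v) < 0.5:
                continue
            tot += 1
            ok += abs(SHIFTS[np.nanargmax(v)] - truth.peak_lag[p]) <= 0.021
        assert tot >= 10
        assert ok / tot >= 0.8

    def test_trained_ensemble_recovers_before_after_classes(self, mm_sim,
                                                            mm_ensemble):
        """Headline property: the sign of the recovered lag matches the
        programmed before/after class for >=80% of retained pairs."""
        rna, _, _, truth = mm_sim
        qidx = int(np.flatnonzero(np.isclose(rna.time, 8.25))[0])
        pairs = [(f"peak{p}", f"gene{truth.peak_gene[p]}")
                 for p in range(30) if truth.peak_gene[p] >= 0]
        cats = filter_and_categorize(build_tlcc_matrix(
            mm_ensemble, rna.cell_ids[qidx], pairs, TLCCConfig()))
        lag_of = {f"peak{p}": truth.peak_lag[p] for p in range(30)}
        ok = sum(row.category == ("before" if lag_of[row.peak_id] < 0
                                  else "after")
                 for row in cats.itertuples())
        assert len(cats) >= 10
        assert ok / len(cats) >= 0.8
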