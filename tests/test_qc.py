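"""QC metrics: FRiP, cell filtering, Cramér's V, kNN label agreement."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splitmark.qc import (
    contingency_2x2,
    cramers_v,
    cramers_v_table,
    filter_cells,
    frip,
    knn_label_agreement,
    summarize,
)


def frag_df(rows):
    return pd.DataFrame(rows, columns=["cell", "target", "contig", "start", "end", "dup_count"])


PEAKS = pd.DataFrame({"contig": ["chr1"], "start": [1000], "end": [2000]})


class TestFrip:
    def test_all_fragments_inside_peaks(self):
        frags = frag_df([(0, "m", "chr1", 1100, 1200, 1), (0, "m", "chr1", 1500, 1900, 1)])
        table, agg = frip(frags, PEAKS)
        assert agg["m"] == 1.0

    def test_whole_genome_peak(self):
        frags = frag_df([(0, "m", "chr1", 0, 100, 1), (0, "m", "chr1", 90_000, 90_100, 1)])
        peaks = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [10**6]})
        _, agg = frip(frags, peaks)
        assert agg["m"] == 1.0

    def test_three_of_four(self):
        frags = frag_df(
            [
                (0, "m", "chr1", 1100, 1200, 1),
                (0, "m", "chr1", 1990, 2100, 1),  # 10 bp overlap counts
                (0, "m", "chr1", 500, 999, 1),
                (0, "m", "chr1", 1500, 1600, 1),
            ]
        )
        _, agg = frip(frags, PEAKS)
        assert agg["m"] == 0.75

    def test_single_shared_base_counts(self):
        frags = frag_df([(0, "m", "chr1", 1999, 2100, 1), (0, "m", "chr1", 2000, 2100, 1)])
        _, agg = frip(frags, PEAKS)
        assert agg["m"] == 0.5  # half-open: start 2000 does not overlap [1000,2000)

    def test_invariant_to_peak_order_and_splitting(self, rng):
        frags = frag_df(
            [(0, "m", "chr1", int(s), int(s) + 80, 1) for s in rng.integers(0, 5000, 200)]
        )
        peaks = pd.DataFrame(
            {"contig": ["chr1"] * 2, "start": [1000, 3000], "end": [2000, 3500]}
        )
        shuffled = peaks.sample(frac=1.0, random_state=1)
        split = pd.DataFrame(
            {
                "contig": ["chr1"] * 3,
                "start": [1000, 1500, 3000],
                "end": [1500, 2000, 3500],  # touching halves of the first peak
            }
        )
        res = [frip(frags, p)[1]["m"] for p in (peaks, shuffled, split)]
        assert res[0] == res[1] == res[2]

    def test_cell_with_no_fragments_is_missing_not_zero(self):
        frags = frag_df([(0, "m", "chr1", 1100, 1200, 1)])
        table, _ = frip(frags, PEAKS)
        assert set(table["cell"]) == {0}  # cell 1 absent, not reported as 0


class TestFilterCells:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["dna_unique", "rna_unique"])

    def test_boundary_is_strict(self):
        cells = self.make([(2500, 3000), (2501, 2001)])
        passing, _ = filter_cells(cells)
        assert list(passing) == [1]

    def test_hand_enumerated_table(self):
        cells = self.make([(2400, 5000), (9000, 1999), (2501, 2001), (0, 0), (10_000, 10_000)])
        passing, recovery = filter_cells(cells, n_input=10)
        assert list(passing) == [2, 4]
        assert recovery == 0.2

    def test_monotone_in_thresholds(self, rng):
        cells = self.make(
            np.column_stack([rng.integers(0, 5000, 200), rng.integers(0, 5000, 200)])
        )
        base, _ = filter_cells(cells, dna_min=1000, rna_min=1000)
        stricter, _ = filter_cells(cells, dna_min=2000, rna_min=1500)
        assert set(stricter) <= set(base)


class TestCramersV:
    def test_identical_binary_matrices(self, rng):
        m = (rng.random((50, 40)) < 0.3).astype(int)
        assert cramers_v(m, m) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(11)
        a = (rng.random((100, 100)) < 0.5).astype(int)
        b = (rng.random((100, 100)) < 0.5).astype(int)
        assert cramers_v(a, b) <= 0.05

    @pytest.mark.parametrize(
        "table",
        [
            [[8, 2], [3, 7]],
            [[10, 0], [0, 10]],
            [[5, 5], [5, 5]],
            [[1, 9], [9, 1]],
            [[12, 3], [4, 1]],
        ],
    )
    def test_matches_bruteforce_chi_square(self, table):
        """Oracle: V = sqrt(N (ad-bc)^2 / (r1 r2 c1 c2) / N) for 2x2 tables."""
        (a, b), (c, d) = table
        n = a + b + c + d
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        assert cramers_v_table(np.array(table)) == pytest.approx(np.sqrt(chi2 / n))

    def test_symmetry(self, rng):
        a = (rng.random((30, 30)) < 0.4).astype(int)
        b = (rng.random((30, 30)) < 0.6).astype(int)
        assert cramers_v(a, b) == pytest.approx(cramers_v(b, a))

    def test_degenerate_margin_is_zero_with_warning(self):
        a = np.ones((10, 10), dtype=int)
        b = (np.arange(100).reshape(10, 10) % 2).astype(int)
        with pytest.warns(UserWarning):
            assert cramers_v(a, b) == 0.0

    def test_contingency_table_construction(self):
        a = np.array([[1, 0], [1, 1]])
        b = np.array([[1, 1], [0, 1]])
        table = contingency_2x2(a > 0, b > 0)
        assert table.tolist() == [[2, 1], [1, 0]]


class TestKnnLabelAgreement:
    def test_separable_clusters_score_one(self, rng):
        a = rng.normal(0, 0.1, size=(40, 3))
        b = rng.normal(10, 0.1, size=(40, 3)) + 10
        x = np.vstack([a, b])
        labels = np.array(["a"] * 40 + ["b"] * 40)
        assert knn_label_agreement(x, labels, k=20) == 1.0

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(400, 5))
        labels = np.array(["a", "b"] * 200)
        rng.shuffle(labels)
        k = 50
        got = knn_label_agreement(x, labels, k=k)
        se = np.sqrt(0.25 / (400 * k))  # neighbours overlap; bound is generous
        assert abs(got - 0.5) <= 10 * se

    def test_k_equals_n_minus_one_is_forced(self):
        rng = np.random.default_rng(4)
        n = 60
        x = rng.normal(size=(n, 2))
        labels = np.array(["a"] * 20 + ["b"] * 40)
        got = knn_label_agreement(x, labels, k=n - 1)
        expected = (20 * 19 + 40 * 39) / (n * (n - 1))
        assert got == pytest.approx(expected)

    def test_domain_errors(self):
        x = np.zeros((10, 2))
        labels = np.zeros(10)
        with pytest.raises(ValueError):
            knn_label_agreement(x, labels, k=0)
        with pytest.raises(ValueError):
            knn_label_agreement(x, labels, k=10)

    def test_deterministic_under_exact_ties(self):
        x = np.zeros((6, 2))  # all points identical: pure tie-break by index
        labels = np.array([1, 0, 1, 0, 1, 0])
        a = knn_label_agreement(x, labels, k=2)
        b = knn_label_agreement(x, labels, k=2)
        assert a == b


class TestSummarize:
    def test_report_regeneration_is_byte_identical(self, small_result, small_run, tmp_path):
        peaks = dict(small_run.merged_peaks)
        peaks["IgG"] = pd.concat(peaks.values(), ignore_index=True)
        paths = []
        for tag in ("a", "b"):
            rep = summarize(
                small_result.demux_stats,
                small_result.fragments,
                small_result.molecules,
                peaks,
                small_run.design,
                n_cells_loaded=small_run.scenario.n_cells,
            )
            p = tmp_path / f"qc_{tag}.json"
            rep.to_json(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_duplication_rate_matches_factor(self, small_result):
        # duplication factor 2 -> rate ~0.5 (position collisions add a whisker)
        rate = small_result.report.dataset["duplication_rate"]
        assert abs(rate - 0.5) < 0.01

    def test_no_duplicates_gives_zero_rate(self, design):
        from splitmark.pipeline import run_pipeline

        from conftest import small_scenario

        sc = small_scenario(
            n_cells=10,
            duplication_factor=1,
            fragments_per_cell={"H3K27me3": (30, 10), "H3K27ac": (30, 10), "IgG": (10, 10)},
            umis_per_cell=(30, 10),
            seed=21,
        )
        res = run_pipeline(sc, design, batch_size=10_000)
        # distinct molecules can still coincide in position; allow that whisker
        assert res.report.dataset["duplication_rate"] <= 0.005

    def test_report_fields(self, small_result):
        rep = small_result.report
        assert {"dna_unique", "rna_unique", "pass"} <= set(rep.per_cell.columns)
        assert (rep.per_cell_target["duplication_rate"].between(0, 1)).all()
        valid_json = json.dumps(rep.dataset)
        assert valid_json
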