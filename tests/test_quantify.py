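"""Deduplication rules, gene counting and bin matrices against brute-force oracles."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from splitmark.quantify import (
    CountMatrix,
    count_genes,
    dedup_dna,
    dedup_rna,
    make_bin_matrix,
    read_fragments,
    write_fragments,
)


def rec(cell, target, contig, start, end, strand="+", umi="AAAAAAAA"):
    return dict(cell=cell, target=target, contig=contig, start=start, end=end,
                strand=strand, umi=umi)


class TestDedupDna:
    def test_position_only_ignores_umi(self):
        records = pd.DataFrame(
            [rec(0, "m", "chr1", 100, 150, umi=u) for u in ("AAAAAAAA", "CCCCCCCC", "GGGGGGGG")]
        )
        frags = dedup_dna(records)
        assert len(frags) == 1
        assert frags.iloc[0]["dup_count"] == 3

    def test_same_position_different_cells_kept(self):
        records = pd.DataFrame([rec(0, "m", "chr1", 100, 150), rec(1, "m", "chr1", 100, 150)])
        assert len(dedup_dna(records)) == 2

    def test_conservation_on_random_input(self, rng):
        n = 10_000
        records = pd.DataFrame(
            {
                "cell": rng.integers(0, 20, n),
                "target": rng.choice(["a", "b"], n),
                "contig": rng.choice(["chr1", "chr2"], n),
                "start": rng.integers(0, 500, n),
                "end": rng.integers(0, 500, n) + 600,
                "strand": rng.choice(["+", "-"], n),
            }
        )
        frags = dedup_dna(records)
        assert int(frags["dup_count"].sum()) == n

    def test_matches_bruteforce_grouping(self, rng):
        """Oracle: exhaustive Counter over tuple keys on 10k random records."""
        n = 10_000
        records = pd.DataFrame(
            {
                "cell": rng.integers(0, 15, n),
                "target": rng.choice(["x", "y"], n),
                "contig": rng.choice(["c1", "c2"], n),
                "start": rng.integers(0, 60, n),
                "end": rng.integers(60, 120, n),
                "strand": rng.choice(["+", "-"], n),
            }
        )
        oracle = Counter(
            tuple(t) for t in records[["cell", "target", "contig", "start", "end", "strand"]]
            .itertuples(index=False)
        )
        frags = dedup_dna(records)
        got = {
            tuple(t): c
            for *t, c in frags[
                ["cell", "target", "contig", "start", "end", "strand", "dup_count"]
            ].itertuples(index=False)
        }
        assert got == dict(oracle)


class TestDedupRna:
    def test_distinct_umis_kept(self):
        records = pd.DataFrame(
            [rec(0, None, "chr1", 100, 150, umi="AAAAAAAA"),
             rec(0, None, "chr1", 100, 150, umi="CCCCCCCC")]
        )
        assert len(dedup_rna(records)) == 2

    def test_identical_umi_collapsed(self):
        records = pd.DataFrame([rec(0, None, "chr1", 100, 150)] * 5)
        mols = dedup_rna(records)
        assert len(mols) == 1 and mols.iloc[0]["dup_count"] == 5

    def test_five_prime_anchor_is_strand_aware(self):
        # a '-' read at (100,150) anchors at 149, not 100
        records = pd.DataFrame(
            [rec(0, None, "chr1", 100, 150, strand="+"),
             rec(0, None, "chr1", 100, 150, strand="-")]
        )
        mols = dedup_rna(records)
        assert sorted(mols["pos"]) == [100, 149]

    def test_idempotent(self, rng):
        n = 2_000
        records = pd.DataFrame(
            {
                "cell": rng.integers(0, 10, n),
                "contig": rng.choice(["c1"], n),
                "start": rng.integers(0, 50, n),
                "end": rng.integers(50, 100, n),
                "strand": rng.choice(["+", "-"], n),
                "umi": rng.integers(0, 16, n),
            }
        )
        once = dedup_rna(records)
        again = dedup_rna(
            once.rename(columns={"pos": "start"}).assign(end=lambda d: d["start"] + 1)
        )
        assert len(once) == len(again)

    def test_matches_bruteforce_grouping(self, rng):
        n = 10_000
        records = pd.DataFrame(
            {
                "cell": rng.integers(0, 15, n),
                "contig": rng.choice(["c1", "c2"], n),
                "start": rng.integers(0, 40, n),
                "end": rng.integers(40, 80, n),
                "strand": rng.choice(["+", "-"], n),
                "umi": rng.integers(0, 8, n),
            }
        )
        pos = np.where(records["strand"] == "-", records["end"] - 1, records["start"])
        oracle = Counter(zip(records["cell"], records["contig"], pos, records["umi"]))
        mols = dedup_rna(records)
        got = {
            (c, ct, p, u): n_
            for c, ct, p, u, n_ in mols[["cell", "contig", "pos", "umi", "dup_count"]]
            .itertuples(index=False)
        }
        assert got == dict(oracle)
        assert int(mols["dup_count"].sum()) == n


class TestCountGenes:
    annotation = pd.DataFrame(
        {
            "contig": ["chr1", "chr1", "chr1", "chr2"],
            "start": [100, 500, 550, 0],
            "end": [200, 600, 650, 100],
            "name": ["gA", "gB", "gC", "gD"],
        }
    )

    def mols(self, rows):
        return pd.DataFrame(rows, columns=["cell", "contig", "pos", "umi", "dup_count"])

    def test_unique_overlap_assigned(self):
        cm, stats = count_genes(self.mols([(0, "chr1", 150, 1, 1)]), self.annotation)
        assert stats == {"assigned": 1, "unassigned": 0, "ambiguous": 0}
        assert cm.matrix[0, 0] == 1

    def test_intergenic_dropped(self):
        cm, stats = count_genes(self.mols([(0, "chr1", 300, 1, 1)]), self.annotation)
        assert stats["unassigned"] == 1 and cm.total == 0

    def test_overlapping_genes_ambiguous(self):
        cm, stats = count_genes(self.mols([(0, "chr1", 575, 1, 1)]), self.annotation)
        assert stats["ambiguous"] == 1 and cm.total == 0

    def test_long_early_gene_still_found(self):
        # gene spanning a later short gene's end: count==1 resolves to the long gene
        ann = pd.DataFrame(
            {"contig": ["chr1", "chr1"], "start": [0, 50], "end": [500, 60], "name": ["L", "S"]}
        )
        cm, stats = count_genes(self.mols([(0, "chr1", 70, 1, 1)]), ann)
        assert stats["assigned"] == 1
        assert cm.matrix[0, 0] == 1  # row 0 is L

    def test_simulated_totals_match_expected_expression(self, small_run, small_result):
        """Per-gene totals agree with the scenario's expression weights: at
        least 95% of well-expressed genes fall within 4 SE of the multinomial
        expectation (all-genes-within-3-SE would itself be a rare event)."""
        sc = small_run.scenario
        cm = small_result.count_matrix
        # expected molecules per gene before dedup ~ after dedup (umi space huge)
        type_of_cell = small_run.cells["type_idx"].to_numpy()
        per_type_umis = np.bincount(type_of_cell, weights=np.bincount(
            small_run._rna["cell"], minlength=sc.n_cells))
        expected = sum(
            per_type_umis[t] * small_run.gene_weights[t] for t in range(len(sc.cell_types))
        )
        observed = np.asarray(cm.matrix.sum(axis=1)).ravel()
        # order: annotation order equals gene index order
        se = np.sqrt(expected)
        big = expected > 50
        assert (np.abs(observed[big] - expected[big]) <= 4 * se[big]).mean() > 0.95

    def test_mtx_round_trip(self, tmp_path):
        cm, _ = count_genes(
            self.mols([(0, "chr1", 150, 1, 1), (1, "chr2", 50, 2, 1)]), self.annotation
        )
        cm.write_mtx(tmp_path / "mtx")
        back = CountMatrix.read_mtx(tmp_path / "mtx")
        assert (back.matrix != cm.matrix).nnz == 0
        assert back.gene_ids == cm.gene_ids
        assert back.cell_ids == cm.cell_ids


class TestBinMatrix:
    lengths = {"chr1": 12_000}

    def frags(self, rows):
        return pd.DataFrame(rows, columns=["cell", "contig", "start", "end", "dup_count"])

    def test_fragment_within_first_bin(self):
        m, labels, cells = make_bin_matrix(
            self.frags([(0, "chr1", 0, 100, 1)]), 5000, self.lengths
        )
        assert m.shape == (3, 1)
        assert m[0, 0] == 1 and m.sum() == 1

    def test_boundary_fragment_hits_both_bins(self):
        m, _, _ = make_bin_matrix(self.frags([(0, "chr1", 4900, 5100, 1)]), 5000, self.lengths)
        assert m[0, 0] == 1 and m[1, 0] == 1 and m.sum() == 2

    def test_empty_input_gives_zero_matrix(self):
        m, labels, cells = make_bin_matrix(self.frags([]), 5000, self.lengths, cell_ids=[0, 1])
        assert m.shape == (3, 2) and m.nnz == 0

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            make_bin_matrix(self.frags([]), 0, self.lengths)


def test_fragment_file_round_trip(tmp_path, small_result):
    frags = small_result.fragments.head(500).copy()
    for suffix in ("tsv", "tsv.gz"):
        p = tmp_path / f"frags.{suffix}"
        write_fragments(frags, p)
        back = read_fragments(p)
        assert len(back) == len(frags)
        assert int(back["dup_count"].sum()) == int(frags["dup_count"].sum())
        assert (back.groupby("contig").size().sort_index()
                == frags.groupby("contig", observed=True).size().sort_index()).all()
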