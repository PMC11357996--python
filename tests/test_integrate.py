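"""Expression I/O, QC, normalization, downsampling, DE and on-target QC."""

import numpy as np
import pytest
import scipy.sparse as sp

import _oracles
from mutlink.align import AlignmentRecord, parse_cigar
from mutlink.integrate import (
    ExpressionMatrix,
    benjamini_hochberg,
    differential_expression,
    downsample_groups,
    filter_cells,
    log_normalize,
    on_target_report,
    read_expression,
    write_expression,
)
from mutlink.simulate import simulate_expression


def make_expr(counts, barcodes=None, features=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return ExpressionMatrix(
        sp.csr_matrix(counts),
        barcodes or [f"b{i}" for i in range(n_cells)],
        features or [(f"G{i}", f"GENE{i}") for i in range(n_genes)],
    )


class TestExpressionIO:
    def test_load_shape_and_entries(self, tmp_path):
        expr = make_expr([[1, 0, 2], [0, 3, 0]])
        write_expression(expr, tmp_path)
        back = read_expression(
            tmp_path / "matrix.mtx", tmp_path / "barcodes.tsv", tmp_path / "features.tsv"
        )
        assert back.counts.shape == (2, 3)
        assert back.counts.nnz == 3

    def test_all_zero_column_retained(self, tmp_path):
        expr = make_expr([[1, 0], [2, 0]])
        write_expression(expr, tmp_path)
        back = read_expression(
            tmp_path / "matrix.mtx", tmp_path / "barcodes.tsv", tmp_path / "features.tsv"
        )
        assert back.n_cells == 2
        assert back.counts[:, 1].nnz == 0

    def test_round_trip_identity(self, tmp_path, rng):
        counts = rng.poisson(1.0, size=(30, 20))
        expr = make_expr(counts)
        write_expression(expr, tmp_path)
        back = read_expression(
            tmp_path / "matrix.mtx", tmp_path / "barcodes.tsv", tmp_path / "features.tsv"
        )
        assert (back.counts.toarray() == counts).all()
        assert back.barcodes == expr.barcodes and back.features == expr.features


class TestFilterCells:
    def _expr(self, genes_per_cell):
        n_genes = 250
        cols = []
        for g in genes_per_cell:
            col = np.zeros(n_genes, dtype=int)
            col[:g] = 1
            cols.append(col)
        return make_expr(np.column_stack(cols))

    def test_below_threshold_removed_boundary_kept(self):
        expr = self._expr([150, 200, 250])
        kept = filter_cells(expr, min_genes=200)
        assert kept.barcodes == ["b1", "b2"]  # 150 dropped, exactly 200 kept

    def test_zero_threshold_is_identity(self):
        expr = self._expr([3, 5])
        assert filter_cells(expr, min_genes=0).barcodes == expr.barcodes

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError):
            filter_cells(self._expr([10, 20]), min_genes=200)


class TestLogNormalize:
    def test_hand_computed_value(self):
        # count 10 in a cell of total 100 at scale 10,000 -> ln(1 + 1000)
        expr = make_expr([[10], [90]])
        norm = log_normalize(expr)
        assert norm.dense()[0, 0] == pytest.approx(np.log(1 + 1000.0))

    def test_zero_count_stays_zero(self):
        norm = log_normalize(make_expr([[0], [5]]))
        assert norm.dense()[0, 0] == 0.0

    def test_depth_invariance(self):
        a = log_normalize(make_expr([[10], [90]])).dense()
        b = log_normalize(make_expr([[20], [180]])).dense()
        assert np.allclose(a, b)

    def test_round_trip_recovers_proportions(self, rng):
        counts = rng.poisson(2.0, size=(50, 10)) + 1
        expr = make_expr(counts)
        norm = log_normalize(expr).dense()
        recovered = np.expm1(norm)
        recovered /= recovered.sum(axis=0, keepdims=True)
        assert np.allclose(recovered, counts / counts.sum(axis=0, keepdims=True))


class TestDownsample:
    def test_min_target_equalizes_groups(self, rng):
        groups = {
            "CM": [f"cm{i}" for i in range(4435)],
            "IM": [f"im{i}" for i in range(1600)],
            "NCM": [f"ncm{i}" for i in range(1006)],
        }
        sampled = downsample_groups(groups, "min", seed=1)
        assert {g: len(v) for g, v in sampled.items()} == {
            "CM": 1006, "IM": 1006, "NCM": 1006,
        }
        for g, members in sampled.items():
            assert len(set(members)) == len(members)  # no duplicates
            assert set(members) <= set(groups[g])  # labels preserved

    def test_group_at_target_unchanged(self):
        groups = {"a": ["x", "y", "z"], "b": ["p", "q", "r", "s"]}
        sampled = downsample_groups(groups, 3, seed=0)
        assert sampled["a"] == ["x", "y", "z"]

    def test_seed_reproducible(self):
        groups = {"a": [f"a{i}" for i in range(100)], "b": [f"b{i}" for i in range(50)]}
        assert downsample_groups(groups, "min", seed=7) == downsample_groups(
            groups, "min", seed=7
        )

    def test_target_above_group_size_rejected(self):
        with pytest.raises(ValueError):
            downsample_groups({"a": ["x"], "b": ["y", "z"]}, 2)


class TestBenjaminiHochberg:
    def test_hand_applied_stepup(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(benjamini_hochberg(p), [0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_coded_oracle_on_random_vectors(self, rng):
        for _ in range(500):
            p = rng.random(int(rng.integers(1, 60)))
            assert np.allclose(benjamini_hochberg(p), _oracles.bh_stepup(p))

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(200)
        assert (benjamini_hochberg(p) >= p - 1e-12).all()


class TestDifferentialExpression:
    def test_identical_groups_p_one(self):
        values = np.tile(np.arange(1, 7, dtype=float), (5, 1))
        expr = make_expr(values.astype(int))
        norm = log_normalize(expr)
        res = differential_expression(norm, ["b0", "b1", "b2"], ["b3", "b4", "b5"])
        # same per-cell totals and counts -> identical normalized values
        assert np.allclose(res["p_value"], 1.0)
        assert not res["significant"].any()

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(0)
        barcodes = [f"c{i}" for i in range(400)]
        group_a, group_b = barcodes[:200], barcodes[200:]
        shifted = list(range(50))
        expr = simulate_expression(
            400, 1000, seed=42, barcodes=barcodes,
            boosted_barcodes=group_a, boosted_genes=shifted, fold=np.e,
        )
        norm = log_normalize(filter_cells(expr, min_genes=0))
        res = differential_expression(norm, group_a, group_b)
        hits = set(res.index[res["significant"] & (res["direction"] == "up")])
        recovered = len(hits & set(shifted)) / len(shifted)
        assert recovered >= 0.95

    def test_groups_must_be_disjoint_and_large_enough(self):
        norm = log_normalize(make_expr(np.ones((5, 6), dtype=int)))
        with pytest.raises(ValueError, match="disjoint"):
            differential_expression(norm, ["b0", "b1", "b2"], ["b2", "b3", "b4"])
        with pytest.raises(ValueError, match=">= 3"):
            differential_expression(norm, ["b0", "b1"], ["b2", "b3", "b4"])

    def test_paired_mode_uses_patient_averages(self):
        rng = np.random.default_rng(3)
        n_per = 10
        barcodes = [f"c{i}" for i in range(4 * n_per * 2)]
        counts = rng.poisson(5.0, size=(40, len(barcodes)))
        expr = make_expr(counts, barcodes=barcodes)
        norm = log_normalize(expr)
        half = len(barcodes) // 2
        group_a, group_b = barcodes[:half], barcodes[half:]
        paired_by = {}
        for i, bc in enumerate(group_a):
            paired_by[bc] = f"P{i // n_per}"
        for i, bc in enumerate(group_b):
            paired_by[bc] = f"P{i // n_per}"
        res = differential_expression(norm, group_a, group_b, paired_by=paired_by)
        assert len(res) == 40 and res["p_value"].between(0, 1).all()

    def test_paired_mode_enforces_min_cells(self):
        norm = log_normalize(make_expr(np.ones((4, 8), dtype=int)))
        paired_by = {f"b{i}": "P0" for i in range(8)}
        with pytest.raises(ValueError, match="patients"):
            differential_expression(
                norm, [f"b{i}" for i in range(4)], [f"b{i}" for i in range(4, 8)],
                paired_by=paired_by, min_cells_per_patient=5,
            )


class TestOnTarget:
    def _aln(self, read_id, contig, start, length=50):
        return AlignmentRecord(read_id, contig, start, parse_cigar(f"{length}M"))

    def test_fraction_from_counts(self):
        alns = [self._aln(f"r{i}", "g", 100) for i in range(80)]
        alns += [self._aln(f"x{i}", "g", 5000) for i in range(20)]
        rep = on_target_report(alns, [("g", 0, 1000)])
        assert rep.on_target_fraction == pytest.approx(0.80)
        assert rep.n_aligned == 100

    def test_empty_target_set_zero(self):
        rep = on_target_report([self._aln("r", "g", 100)], [])
        assert rep.on_target_fraction == 0.0

    def test_single_base_overlap_counts(self):
        # read spans ref positions 100..149 (1-based) = [99, 149) 0-based
        rep = on_target_report([self._aln("r", "g", 100)], [("g", 148, 200)])
        assert rep.n_on_target == 1
        rep = on_target_report([self._aln("r", "g", 100)], [("g", 149, 200)])
        assert rep.n_on_target == 0

    def test_matches_brute_force_overlap_scan(self, rng):
        intervals = [
            ("g", int(s), int(s) + int(rng.integers(1, 300)))
            for s in rng.integers(0, 5000, size=30)
        ]
        alns = [
            self._aln(f"r{i}", "g", int(rng.integers(1, 5000)), length=int(rng.integers(1, 200)))
            for i in range(300)
        ]
        rep = on_target_report(alns, intervals)
        plain = [(s, e) for _, s, e in intervals]
        expected = sum(
            _oracles.overlaps_any(a.ref_start - 1, a.ref_end, plain) for a in alns
        )
        assert rep.n_on_target == expected
        assert sum(rep.per_gene_counts.values()) == rep.n_aligned


def test_null_simulation_type_one_error(rng):
    """Null 1,000 genes x 200+200 cells: raw p<0.05 fraction within 3 SE of 5%."""
    barcodes = [f"c{i}" for i in range(400)]
    expr = simulate_expression(400, 1000, seed=77, barcodes=barcodes, mean_depth=3000)
    norm = log_normalize(filter_cells(expr, min_genes=0))
    perm = rng.permutation(400)
    group_a = [barcodes[i] for i in perm[:200]]
    group_b = [barcodes[i] for i in perm[200:]]
    res = differential_expression(norm, group_a, group_b)
    tested = res[~res["zero_variance"]]
    rate = (tested["p_value"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(tested))
    assert abs(rate - 0.05) < 3 * se
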