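import numpy as np
import pandas as pd
import pytest

from demeta.preprocess import (
    FilterReport,
    collapse_probes_iqr,
    intersect_genes,
    rank_sum_filter,
)

from conftest import make_dataset


def probe_map(pairs):
    return pd.DataFrame(pairs, columns=["probe_id", "gene_symbol"])


def brute_iqr(values):
    """Quartiles by explicit linear interpolation between order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def quant(q):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return quant(0.75) - quant(0.25)


class TestCollapseProbesIQR:
    def test_largest_iqr_probe_wins(self):
        ds = make_dataset([[1, 2, 3, 4], [0, 10, 0, 10]], ["c1", "c2"], ["n1", "n2"],
                          genes=["P1", "P2"])
        out = collapse_probes_iqr(ds, probe_map([("P1", "G"), ("P2", "G")]))
        # IQR(P1)=1.5 < IQR(P2)=10 under linear-interpolation quartiles
        assert out.features == ["G"]
        assert list(out.values.loc["G"]) == [0, 10, 0, 10]

    def test_single_probe_passthrough(self):
        ds = make_dataset([[5, 6, 7, 8]], ["c1", "c2"], ["n1", "n2"], genes=["P1"])
        out = collapse_probes_iqr(ds, probe_map([("P1", "G")]))
        assert list(out.values.loc["G"]) == [5, 6, 7, 8]

    def test_tie_keeps_first_in_file_order(self):
        ds = make_dataset([[1, 2, 3, 4], [11, 12, 13, 14]], ["c1", "c2"], ["n1", "n2"],
                          genes=["PA", "PB"])
        out = collapse_probes_iqr(ds, probe_map([("PA", "G"), ("PB", "G")]))
        assert list(out.values.loc["G"]) == [1, 2, 3, 4]

    def test_unannotated_probes_dropped(self):
        ds = make_dataset([[1, 2, 3, 4], [4, 3, 2, 1]], ["c1", "c2"], ["n1", "n2"],
                          genes=["P1", "PX"])
        out = collapse_probes_iqr(ds, probe_map([("P1", "G1"), ("PX", "")]))
        assert out.features == ["G1"]

    def test_no_annotated_probes_is_error(self):
        ds = make_dataset([[1, 2, 3, 4]], ["c1", "c2"], ["n1", "n2"], genes=["P1"])
        with pytest.raises(ValueError, match="no annotated"):
            collapse_probes_iqr(ds, probe_map([("P1", "")]))

    def test_matches_brute_force_quantile_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((12, 7))
        genes = [f"P{i}" for i in range(12)]
        ds = make_dataset(values, ["c1", "c2", "c3"], ["n1", "n2", "n3", "n4"], genes=genes)
        pm = probe_map([(f"P{i}", f"G{i % 4}") for i in range(12)])
        out = collapse_probes_iqr(ds, pm)
        for gene in out.features:
            probes = [i for i in range(12) if f"G{i % 4}" == gene]
            best = max(probes, key=lambda i: (brute_iqr(values[i]), -i))
            assert np.array_equal(out.values.loc[gene].to_numpy(), values[best])

    def test_each_output_row_is_an_input_row(self, small_collection):
        ds = small_collection.datasets["AS"]
        out = collapse_probes_iqr(ds, small_collection.probe_map_for("AS"))
        input_rows = {tuple(r) for r in ds.values.to_numpy()}
        sample = out.values.to_numpy()[:25]
        assert all(tuple(r) in input_rows for r in sample)


class TestIntersectGenes:
    def test_set_intersection(self):
        d1 = make_dataset([[1] * 4, [2] * 4, [3] * 4], ["c1", "c2"], ["n1", "n2"],
                          genes=["A", "B", "C"])
        d2 = make_dataset([[1] * 4, [2] * 4, [3] * 4], ["c1", "c2"], ["n1", "n2"],
                          genes=["B", "C", "D"])
        d3 = make_dataset([[1] * 4, [2] * 4], ["c1", "c2"], ["n1", "n2"], genes=["C", "B"])
        out = intersect_genes([d1, d2, d3])
        assert all(ds.features == ["B", "C"] for ds in out)

    def test_identical_panels_canonical_order(self):
        d1 = make_dataset([[1] * 4, [2] * 4], ["c1", "c2"], ["n1", "n2"], genes=["Z", "A"])
        d2 = make_dataset([[3] * 4, [4] * 4], ["c1", "c2"], ["n1", "n2"], genes=["Z", "A"])
        out = intersect_genes([d1, d2])
        assert out[0].features == ["A", "Z"]
        assert list(out[0].values.loc["Z"]) == [1, 1, 1, 1]

    def test_disjoint_panels_error(self):
        d1 = make_dataset([[1] * 4], ["c1", "c2"], ["n1", "n2"], genes=["A"])
        d2 = make_dataset([[1] * 4], ["c1", "c2"], ["n1", "n2"], genes=["B"])
        with pytest.raises(ValueError, match="empty intersection"):
            intersect_genes([d1, d2])


class TestRankSumFilter:
    def _collection(self, rng, n_genes, n_datasets=2, n_samples=6):
        genes = [f"G{i:03d}" for i in range(n_genes)]
        return [
            make_dataset(
                rng.standard_normal((n_genes, n_samples)) + np.arange(n_genes)[:, None],
                [f"c{j}" for j in range(3)],
                [f"n{j}" for j in range(n_samples - 3)],
                genes=genes,
            )
            for _ in range(n_datasets)
        ]

    def test_floor_based_counts(self):
        rng = np.random.default_rng(0)
        out, rep = rank_sum_filter(self._collection(rng, 10), 0.30, 0.30)
        assert rep.n_removed_unexpressed == 3  # floor(0.3 * 10)
        assert rep.n_removed_uninformative == 2  # floor(0.3 * 7)
        assert rep.n_retained == 5
        assert all(len(ds.features) == 5 for ds in out)

    def test_zero_fractions_identity(self):
        rng = np.random.default_rng(1)
        data = self._collection(rng, 8)
        out, rep = rank_sum_filter(data, 0.0, 0.0)
        assert rep.n_removed_unexpressed == rep.n_removed_uninformative == 0
        assert out[0].features == data[0].features
        assert np.array_equal(out[0].values.to_numpy(), data[0].values.to_numpy())

    def test_hand_set_rank_sums(self):
        """2 datasets x 4 genes with means giving rank sums (2,4,6,8): only the
        rank-sum-2 gene is removed at frac_mean=0.25."""
        genes = ["g1", "g2", "g3", "g4"]
        base = np.array([[1.0], [2.0], [3.0], [4.0]])  # per-gene means, both datasets
        values = np.repeat(base, 4, axis=1)
        noise = np.array([[0.0, 0.0, 0.1, -0.1]])  # equal means, small SD
        data = [
            make_dataset(values + noise, ["c1", "c2"], ["n1", "n2"], genes=genes)
            for _ in range(2)
        ]
        out, rep = rank_sum_filter(data, 0.25, 0.0)
        assert rep.n_removed_unexpressed == 1
        assert out[0].features == ["g2", "g3", "g4"]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        data = self._collection(rng, 12)
        out, _ = rank_sum_filter(data, 0.25, 0.25)
        perm = rng.permutation(12)
        permuted = [ds.subset_features([ds.features[i] for i in perm]) for ds in data]
        out_p, _ = rank_sum_filter(permuted, 0.25, 0.25)
        assert set(out[0].features) == set(out_p[0].features)
        for sid in range(2):
            a = out[sid].values.sort_index()
            b = out_p[sid].values.sort_index()
            assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_mismatched_gene_lists_rejected(self):
        d1 = make_dataset([[1] * 4, [2] * 4], ["c1", "c2"], ["n1", "n2"], genes=["A", "B"])
        d2 = make_dataset([[1] * 4, [2] * 4], ["c1", "c2"], ["n1", "n2"], genes=["A", "C"])
        with pytest.raises(ValueError, match="gene list differs"):
            rank_sum_filter([d1, d2])


def test_dead_genes_all_removed(small_collection):
    """Planted dead genes (lowest mean and SD everywhere) never survive filtering."""
    coll = small_collection
    gene_level = [
        collapse_probes_iqr(ds, coll.probe_map_for(sid))
        for sid, ds in coll.datasets.items()
    ]
    merged = intersect_genes(gene_level)
    filtered, report = rank_sum_filter(merged)
    retained = set(filtered[0].features)
    assert not (retained & coll.truth.dead_genes())
    assert report.n_retained == len(retained)


def test_filter_report_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        FilterReport(10, 10, 3, 2, 6)
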