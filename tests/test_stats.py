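import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

import ribowave as rw
from ribowave.errors import ParameterError
from ribowave.genetic_code import SENSE_CODONS
from ribowave.stats import decoding_anticodons, unit_profile

from conftest import brute_force_offset_profile


def _enrichment_from_counts(vectors, trim=0):
    counts = rw.PositionCounts(
        {g: np.asarray(v, dtype=np.int64) for g, v in vectors.items()}
    )
    return rw.relative_enrichment(counts, trim)


class TestOffsetProfile:
    def test_single_codon_identity_gene_is_flat(self):
        cds = rw.CodingSequenceSet([rw.CodingSequence("g", ("GCT",) * 20, "TAA")])
        rng = np.random.default_rng(1)
        enr = _enrichment_from_counts({"g": rng.integers(1, 30, 20)})
        prof = rw.offset_profile(enr, cds, range(-3, 4))
        row = prof.E.loc["GCT"]
        # normalization forces the all-positions mean to 1 at offset 0; with a
        # single identity every stratum is the full (shift-trimmed) gene
        assert row[0] == pytest.approx(1.0, abs=1e-12)
        assert np.isfinite(row).all()

    def test_matches_brute_force_on_toy_genes(self, toy_cds):
        rng = np.random.default_rng(7)
        enr = _enrichment_from_counts(
            {"gene1": rng.integers(0, 9, 12), "gene2": rng.integers(0, 9, 8)},
            trim=1,
        )
        offsets = list(range(-4, 8))
        prof = rw.offset_profile(enr, toy_cds, offsets)
        E_ref, N_ref = brute_force_offset_profile(enr, toy_cds, offsets)
        pd.testing.assert_frame_equal(prof.E, E_ref, check_dtype=False)
        pd.testing.assert_frame_equal(prof.n, N_ref, check_dtype=False)

    def test_empty_strata_have_nan_mean_and_zero_count(self, toy_cds):
        enr = _enrichment_from_counts({"gene1": [1] * 12, "gene2": [1] * 8})
        prof = rw.offset_profile(enr, toy_cds, range(0, 2))
        # TTT never occurs in the toy genes
        assert np.isnan(prof.E.loc["TTT", 0])
        assert prof.n.loc["TTT", 0] == 0

    def test_site_occupancy_extraction(self, toy_cds):
        rng = np.random.default_rng(3)
        enr = _enrichment_from_counts(
            {"gene1": rng.integers(1, 9, 12), "gene2": rng.integers(1, 9, 8)}
        )
        prof = rw.offset_profile(enr, toy_cds, range(0, 3))
        occ = rw.site_occupancies(prof)
        assert list(occ.columns) == ["A", "P", "E"]
        pd.testing.assert_series_equal(
            occ["A"], prof.E[0], check_names=False
        )
        with pytest.raises(ParameterError):
            rw.site_occupancies(rw.offset_profile(enr, toy_cds, range(5, 9)))


class TestTAI:
    def test_single_anticodon_codon_normalizes_to_one(self):
        # GCT is decoded by AGC (cognate, I:U); give it all the copies
        table = rw.compute_tai({"AGC": 10.0}, codons=["GCT"])
        assert table.tai["GCT"] == 1.0

    def test_relative_weights(self):
        # GCT: cognate AGC (penalty 0) 8 copies -> W=8
        # GCC: cognate GGC 4 copies -> W=4
        table = rw.compute_tai(
            {"AGC": 8.0, "GGC": 4.0},
            s_weights={"WC": 0.0, "I:U": 0.0, "I:C": 1.0, "I:A": 1.0,
                       "G:U": 1.0, "U:G": 1.0},
            codons=["GCT", "GCC"],
        )
        assert table.tai["GCT"] == 1.0
        assert table.tai["GCC"] == 0.5

    def test_wobble_weighted_sums_match_hand_computation(self):
        # toy 4-codon code over GCN with penalties s(G:U)=0.4, s(I:C)=0.3,
        # s(I:A)=0.9, s(U:G)=0.6 and copies AGC=4, GGC=2, TGC=1, CGC=3
        tgcn = {"AGC": 4.0, "GGC": 2.0, "TGC": 1.0, "CGC": 3.0}
        s = {"WC": 0.0, "I:U": 0.0, "G:U": 0.4, "I:C": 0.3, "I:A": 0.9, "U:G": 0.6}
        table = rw.compute_tai(tgcn, s, codons=["GCT", "GCC", "GCA", "GCG"])
        W = {
            "GCT": 1.0 * 4 + (1 - 0.4) * 2,   # I:U cognate + G:U wobble = 5.2
            "GCC": 1.0 * 2 + (1 - 0.3) * 4,   # WC + I:C wobble = 4.8
            "GCA": 1.0 * 1 + (1 - 0.9) * 4,   # WC + I:A wobble = 1.4
            "GCG": 1.0 * 3 + (1 - 0.6) * 1,   # WC + U:G wobble = 3.4
        }
        top = max(W.values())
        for codon, w in W.items():
            assert table.weights[codon] == pytest.approx(w)
            assert table.tai[codon] == pytest.approx(w / top)

    def test_anticodon_pairing_geometry(self):
        # codon GCT: anticodon stem = revcomp(GC) = GC; cognate AGC
        assert decoding_anticodons("GCT") == [("AGC", "I:U"), ("GGC", "G:U")]
        assert decoding_anticodons("AAA") == [("TTT", "WC"), ("ATT", "I:A")]

    def test_undecodable_codon_is_an_error(self):
        with pytest.raises(ParameterError, match="no decoding anticodon"):
            rw.compute_tai({"AGC": 5.0}, codons=["GCT", "TTT"])

    def test_penalty_range_validated(self):
        with pytest.raises(ParameterError):
            rw.compute_tai({"AGC": 5.0}, s_weights={"WC": -0.1}, codons=["GCT"])


class TestSpearman:
    def _table(self, seed=0):
        return rw.synthetic_tai_table(seed=seed)

    def test_perfect_positive(self):
        tai = self._table()
        rho, p = rw.spearman_vs_inverse_tai(tai.inverse(), tai)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        tai = self._table()
        rho, p = rw.spearman_vs_inverse_tai(tai.tai, tai)
        assert rho == pytest.approx(-1.0)
        assert p > 0.999

    def test_two_swapped_ranks_match_exact_formula(self):
        # rank-formula oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        tai = rw.TAITable(
            tai=pd.Series(
                np.linspace(0.1, 1.0, 10), index=list(SENSE_CODONS)[:10]
            ),
            weights=pd.Series(dtype=float),
        )
        values = (1.0 / tai.tai).copy()
        # swap the values at adjacent ranks 4 and 5 -> two d=1 displacements
        values.iloc[[4, 5]] = values.iloc[[5, 4]].to_numpy()
        rho, _ = rw.spearman_vs_inverse_tai(values, tai)
        assert rho == pytest.approx(1 - 6 * 2 / (10 * 99))

    def test_constant_input_rejected(self):
        tai = self._table()
        with pytest.raises(ParameterError):
            rw.spearman_vs_inverse_tai(
                pd.Series(1.0, index=list(SENSE_CODONS)), tai
            )


class TestCorrelationMatrix:
    def _occ(self, values):
        df = pd.DataFrame(
            {"A": values, "P": values, "E": values},
            index=list(SENSE_CODONS)[: len(values)],
        )
        return df

    def test_identical_tables_correlate_perfectly(self):
        v = np.linspace(0.5, 2.0, 10)
        mat = rw.experiment_correlation_matrix(
            {"x": self._occ(v), "y": self._occ(v)}, "A"
        )
        np.testing.assert_allclose(mat.to_numpy(), 1.0)

    def test_negated_about_mean_gives_minus_one(self):
        v = np.linspace(0.5, 2.0, 10)
        flipped = 2 * v.mean() - v
        mat = rw.experiment_correlation_matrix(
            {"x": self._occ(v), "y": self._occ(flipped)}, "A"
        )
        assert mat.loc["x", "y"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a, b, c = rng.normal(1, 0.3, (3, 12))
        mat = rw.experiment_correlation_matrix(
            {"a": self._occ(a), "b": self._occ(b), "c": self._occ(c)}, "A"
        )
        def pearson(x, y):
            xm, ym = x - x.mean(), y - y.mean()
            return (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert mat.loc["a", "b"] == pytest.approx(pearson(a, b))
        assert mat.loc["b", "c"] == pytest.approx(pearson(b, c))
        np.testing.assert_allclose(np.diag(mat), 1.0)


class TestUPGMA:
    def test_identical_rows_merge_first_at_zero_distance(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        res = rw.upgma_cluster(m)
        assert res.linkage[0, 2] == 0.0  # first merge distance
        left, right = res.top_split()
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"a", "b"}), frozenset({"c"})
        }

    def test_planted_two_block_structure_recovered(self):
        rng = np.random.default_rng(11)
        labels = [f"chx{i}" for i in range(4)] + [f"none{i}" for i in range(4)]
        base = np.ones((8, 8)) * 0.1
        base[:4, :4] = 0.9
        base[4:, 4:] = 0.9
        np.fill_diagonal(base, 1.0)
        noise = rng.normal(0, 0.02, (8, 8))
        m = pd.DataFrame(base + (noise + noise.T) / 2, index=labels, columns=labels)
        res = rw.upgma_cluster(m)
        left, right = res.top_split()
        assert {frozenset(left), frozenset(right)} == {
            frozenset(labels[:4]), frozenset(labels[4:])
        }

    def test_newick_is_parseable_with_matching_leaves(self):
        rng = np.random.default_rng(2)
        labels = list("abcde")
        x = rng.normal(0, 1, (5, 5))
        m = pd.DataFrame((x + x.T) / 2, index=labels, columns=labels)
        res = rw.upgma_cluster(m)
        tree = Phylo.read(io.StringIO(res.newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == labels
        # ultrametric: all leaves at the same depth from the root
        depths = tree.depths()
        leaf_depths = {d for t, d in depths.items() if t.name in labels}
        assert max(leaf_depths) - min(leaf_depths) < 1e-6

    def test_non_square_rejected(self):
        with pytest.raises(ParameterError):
            rw.upgma_cluster(pd.DataFrame(np.ones((2, 3))))


class TestWaveAnalysis:
    def _profile(self, fill=1.0, offsets=range(0, 31)):
        return unit_profile(offsets) if fill == 1.0 else None

    def test_equal_profiles_give_zero_deltas_and_flagged_regression(self):
        prof = unit_profile(range(0, 31))
        res = rw.wave_analysis(prof, prof, window=(6, 30))
        assert not res.regression_defined
        assert np.isnan(res.slope)
        np.testing.assert_allclose(res.per_codon["delta_binding"], 0.0)
        np.testing.assert_allclose(res.per_codon["wave_area"], 0.0)

    def test_constructed_conservation_gives_slope_minus_one(self):
        # per codon, place a binding-site change delta at the A-site and put
        # exactly -delta into the downstream window: slope -1, r^2 = 1
        offsets = list(range(0, 31))
        ref = unit_profile(offsets)
        E = ref.E.copy()
        rng = np.random.default_rng(13)
        deltas = rng.normal(0, 0.5, len(SENSE_CODONS))
        for i, codon in enumerate(SENSE_CODONS):
            E.loc[codon, 0] += deltas[i]
            E.loc[codon, 10] -= 0.6 * deltas[i]
            E.loc[codon, 11] -= 0.4 * deltas[i]
        test = rw.OffsetProfile(E, ref.n.copy())
        res = rw.wave_analysis(test, ref, window=(6, 30))
        assert res.regression_defined
        assert res.slope == pytest.approx(-1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            res.per_codon["corrected_aggregate"],
            3.0 + deltas - deltas,
            atol=1e-9,
        )

    def test_window_must_clear_binding_sites(self):
        prof = unit_profile(range(0, 31))
        with pytest.raises(ParameterError):
            rw.wave_analysis(prof, prof, window=(2, 30))

    def test_unit_baseline_equals_explicit_reference(self):
        offsets = list(range(0, 31))
        ref = unit_profile(offsets)
        E = ref.E.copy()
        E.loc["CGA", 12] = 1.7
        test = rw.OffsetProfile(E, ref.n.copy())
        res_none = rw.wave_analysis(test, None, window=(6, 30))
        res_unit = rw.wave_analysis(test, ref, window=(6, 30))
        pd.testing.assert_frame_equal(res_none.per_codon, res_unit.per_codon)


class TestPeakCenter:
    def _triangular_profile(self, center=20, half=5, height=0.6):
        offsets = list(range(0, 41))
        prof = unit_profile(offsets)
        E = prof.E.copy()
        for d in offsets:
            h = max(0.0, 1 - abs(d - center) / half) * height
            E.loc["CGA", d] = 1.0 + h
        return rw.OffsetProfile(E, prof.n.copy())

    def test_symmetric_peak_centroid(self):
        prof = self._triangular_profile(center=20)
        center, height, width = rw.peak_center(prof, "CGA", (6, 40), 1.0)
        assert center == pytest.approx(20.0, abs=0.5)
        assert height == pytest.approx(0.6, abs=1e-9)
        assert width > 0

    def test_flat_profile_is_flagged(self):
        prof = unit_profile(range(0, 41))
        center, height, width = rw.peak_center(prof, "CGA", (6, 40), 1.0)
        assert np.isnan(center) and np.isnan(height) and np.isnan(width)

    def test_window_outside_profile_rejected(self):
        prof = unit_profile(range(0, 10))
        with pytest.raises(ParameterError):
            rw.peak_center(prof, "CGA", (6, 40), 1.0)
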