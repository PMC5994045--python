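"""Population statistics: Weir-Cockerham F_ST, GWH, windowed pi, PCA, p-distance."""

import numpy as np
import pytest

from conftest import make_table
from declinomics import popstats, synthio


def wc84_scalar(genotype_rows, group_labels):
    """Independent spreadsheet-style evaluation of the 1984 variance
    components, written with plain scalar arithmetic."""
    groups = sorted(set(group_labels))
    A = B = C = 0.0
    for row in genotype_rows:
        n_i, p_i, h_i = [], [], []
        for g in groups:
            calls = [x for x, l in zip(row, group_labels) if l == g and x >= 0]
            if not calls:
                continue
            n_i.append(len(calls))
            p_i.append(sum(calls) / (2 * len(calls)))
            h_i.append(sum(1 for x in calls if x == 1) / len(calls))
        r = len(n_i)
        if r < 2:
            continue
        N = sum(n_i)
        n_bar = N / r
        n_c = (N - sum(n**2 for n in n_i) / N) / (r - 1)
        p_bar = sum(n * p for n, p in zip(n_i, p_i)) / N
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(n_i, h_i)) / N
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


class TestWeirCockerhamFst:
    def test_complete_fixation_gives_one(self):
        t = make_table([[0, 0, 2, 2], [0, 0, 2, 2]], samples=list("abcd"))
        fst, _ = popstats.weir_cockerham_fst(t, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert fst == pytest.approx(1.0)

    def test_identical_group_multisets_give_non_positive_estimate(self):
        t = make_table([[0, 1, 2, 0, 1, 2]], samples=list("abcdef"))
        grouping = dict(zip("abcdef", ["g1"] * 3 + ["g2"] * 3))
        fst, _ = popstats.weir_cockerham_fst(t, grouping)
        assert fst <= 0.0

    def test_toy_matches_scalar_oracle(self):
        rows = [[0, 1, 2, 2, 2, 1], [0, 0, 1, 1, 2, 2], [1, 0, 0, 2, 1, 2]]
        labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
        t = make_table(rows, samples=list("abcdef"))
        fst, frame = popstats.weir_cockerham_fst(t, dict(zip("abcdef", labels)))
        assert fst == pytest.approx(wc84_scalar(rows, labels), rel=1e-12)
        assert len(frame) == 3

    def test_missing_data_matches_scalar_oracle(self):
        rows = [[0, -1, 2, 2, 2, 1], [-1, -1, 1, 1, 2, 0]]
        labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
        t = make_table(rows, samples=list("abcdef"))
        fst, _ = popstats.weir_cockerham_fst(t, dict(zip("abcdef", labels)))
        assert fst == pytest.approx(wc84_scalar(rows, labels), rel=1e-12)

    def test_invariant_to_group_relabeling_and_allele_swap(self, structured_small):
        table, truth = structured_small
        fst, _ = popstats.weir_cockerham_fst(table, truth.grouping)
        relabeled = {s: "X" if g == "deme0" else "Y" for s, g in truth.grouping.items()}
        fst2, _ = popstats.weir_cockerham_fst(table, relabeled)
        assert fst2 == pytest.approx(fst, rel=1e-12)
        swapped = table.take(np.arange(table.n_sites))
        swapped.genotypes = (2 - table.genotypes).astype(np.int8)
        fst3, _ = popstats.weir_cockerham_fst(swapped, truth.grouping)
        assert fst3 == pytest.approx(fst, rel=1e-9)

    def test_monomorphic_data_raises(self):
        t = make_table([[0, 0, 0, 0]], samples=list("abcd"))
        with pytest.raises(popstats.FstUndefinedError):
            popstats.weir_cockerham_fst(t, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})

    def test_recovers_generating_f_loosely(self):
        # tighter 20-replicate recovery lives in the acceptance suite
        vals = []
        for seed in range(3):
            spec = synthio.StructuredGenotypeSpec(
                n_per_deme=50, n_sites=2_000, fst_target=0.15, seed=seed
            )
            t, truth = synthio.gen_structured_genotypes(spec)
            fst, _ = popstats.weir_cockerham_fst(t, truth.grouping)
            vals.append(fst)
        assert np.mean(vals) == pytest.approx(0.15, abs=0.03)


class TestGenomeWideHet:
    def test_study_scale_arithmetic(self):
        # mean per-individual variant count over a 1.8 Gb genome
        h = popstats.genome_wide_het(33_331_199 // 5, 1_800_000_000)
        assert float(f"{h.gwh:.2g}") == 0.0037

    @pytest.mark.parametrize("n, L, expected", [(0, 100, 0.0), (100, 100, 1.0)])
    def test_bounds(self, n, L, expected):
        assert popstats.genome_wide_het(n, L).gwh == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            popstats.genome_wide_het(1, 0)


class TestWindowedPi:
    def test_single_site_allele_pair_enumeration(self):
        # 2 diploids, dosages 1 and 1 -> alleles {A,C,A,C}: 4 of the 6
        # unordered allele pairs differ, so site pi = 2/3
        t = make_table([[1, 1]], positions=[50])
        frame = popstats.windowed_pi(t, window=100)
        assert len(frame) == 1
        assert frame.pi[0] == pytest.approx((2 / 3) / 100)

    def test_empty_window_reports_zero(self):
        t = make_table([[0, 1]], positions=[250_000])
        frame = popstats.windowed_pi(t, window=100_000)
        assert list(frame.pi[:2]) == [0.0, 0.0]
        assert frame.start.tolist() == [1, 100_001, 200_001]

    def test_multi_site_brute_force_pair_oracle(self):
        rng = np.random.default_rng(5)
        gt = rng.integers(0, 3, size=(20, 4)).astype(np.int8)
        t = make_table(gt, positions=rng.choice(np.arange(1, 1_000), 20, replace=False))
        idx = np.argsort(t.pos)
        t = t.take(idx)
        frame = popstats.windowed_pi(t, window=1_000)
        total = 0.0
        for row in gt:
            alleles = []
            for g in row:
                alleles += [0] * (2 - g) + [1] * g
            diffs = sum(
                1
                for i in range(len(alleles))
                for j in range(i + 1, len(alleles))
                if alleles[i] != alleles[j]
            )
            total += diffs / (len(alleles) * (len(alleles) - 1) / 2)
        assert frame.pi.sum() * 1_000 == pytest.approx(total, rel=1e-12)

    def test_sum_invariant_to_window_size(self, structured_small):
        table, _ = structured_small
        a = popstats.windowed_pi(table, window=1_000)
        b = popstats.windowed_pi(table, window=50_000)
        assert (a.pi * 1_000).sum() == pytest.approx((b.pi * 50_000).sum(), rel=1e-9)


class TestGenotypePca:
    def test_duplicated_row_clusters_separate_on_pc1(self):
        gt = np.array(
            [[0, 0, 0, 2, 2, 2], [0, 0, 0, 2, 2, 2], [2, 2, 2, 0, 0, 0]], dtype=np.int8
        )
        t = make_table(gt, samples=list("abcdef"))
        coords, fracs = popstats.genotype_pca(t)
        pc1 = coords[:, 0]
        assert np.std(pc1[:3]) == pytest.approx(0.0, abs=1e-9)
        assert np.std(pc1[3:]) == pytest.approx(0.0, abs=1e-9)
        assert abs(pc1[0] - pc1[3]) > 1.0
        assert fracs[0] == pytest.approx(1.0)

    def test_small_matrix_matches_eigendecomposition(self):
        gt = np.array([[0, 1, 2], [0, 2, 0]], dtype=np.int8)  # 2 sites x 3 samples
        t = make_table(gt)
        coords, fracs = popstats.genotype_pca(t)
        d = gt.T.astype(float)
        d = d - d.mean(axis=0)
        evals, evecs = np.linalg.eigh(d.T @ d)  # 2x2 feature scatter matrix
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        assert fracs[:2] == pytest.approx(evals / evals.sum(), rel=1e-9)
        proj = np.abs(d @ evecs[:, order])  # sign of axes is arbitrary
        assert np.abs(coords[:, :2]) == pytest.approx(proj, abs=1e-9)

    def test_identical_rows_have_zero_variance_fractions(self):
        t = make_table([[1, 1, 1], [2, 2, 2]])
        _, fracs = popstats.genotype_pca(t)
        assert np.all(fracs == 0.0)

    def test_fractions_ordered_and_bounded(self, structured_small):
        table, _ = structured_small
        _, fracs = popstats.genotype_pca(table)
        assert np.all(fracs >= 0)
        assert np.all(np.diff(fracs) <= 1e-12)
        assert fracs.sum() <= 1 + 1e-9

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            popstats.genotype_pca(make_table([[1]]))


class TestPairwisePDistance:
    def test_identical_sequences(self):
        d = popstats.pairwise_p_distance("ACGTACGT", "ACGTACGT")
        assert (d.n_substitutions, d.distance) == (0, 0.0)

    def test_two_substitutions_over_mitogenome_scale(self):
        a = "A" * 16_000
        b = "A" * 7_999 + "C" + "A" * 7_999 + "G"
        d = popstats.pairwise_p_distance(a, b)
        assert d.n_substitutions == 2
        assert d.distance == pytest.approx(1.25e-4)

    def test_gaps_and_ambiguity_excluded_from_denominator(self):
        d = popstats.pairwise_p_distance("AC-GNT", "ACCGAT")
        assert d.n_compared == 4  # positions 3 and 5 skipped
        assert d.n_substitutions == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            popstats.pairwise_p_distance("ACGT", "ACG")
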