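"""Genotype I/O and pairwise distance metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from landgen.genetics import (
    DistanceMatrix,
    GeneticsError,
    GenotypeTable,
    dps_matrix,
    euclidean_matrix,
    read_genotypes,
    rousset_a_matrix,
    write_genotypes,
)

from conftest import toy_genotypes  # noqa: F401


def rousset_a_oracle(calls, i, j):
    """Independent enumeration of Rousset's a for one pair.

    Counts allelic identities gene-by-gene with explicit loops; missing calls
    are (0, 0) and excluded pairwise.
    """
    n, L, _ = calls.shape
    num = den = 0.0
    for l in range(L):
        if 0 in calls[i, l] or 0 in calls[j, l]:
            continue
        typed = [k for k in range(n) if 0 not in calls[k, l]]
        qw = sum(calls[k, l, 0] == calls[k, l, 1] for k in typed) / len(typed)
        qb = sum(
            calls[i, l, x] == calls[j, l, y] for x in (0, 1) for y in (0, 1)
        ) / 4.0
        num += qw - qb
        den += 1.0 - qw
    return num / den


def dps_oracle(calls, i, j):
    num = den = 0
    for l in range(calls.shape[1]):
        a, b = calls[i, l], calls[j, l]
        if 0 in a or 0 in b:
            continue
        shared = 0
        remaining = list(b)
        for x in a:
            if x in remaining:
                shared += 1
                remaining.remove(x)
        num += shared
        den += 2
    return 1.0 - num / den


class TestGenotypeTable:
    def test_half_missing_call_rejected(self):
        calls = np.array([[[1, 0]], [[2, 2]]])
        with pytest.raises(GeneticsError, match="half-missing"):
            GenotypeTable(["a", "b"], ["L1"], calls, np.zeros((2, 2)))

    def test_duplicate_labels_rejected(self):
        calls = np.ones((2, 1, 2), int)
        with pytest.raises(GeneticsError, match="duplicate"):
            GenotypeTable(["a", "a"], ["L1"], calls, np.zeros((2, 2)))


class TestGenePopIO:
    def write_minimal(self, tmp_path):
        gp = tmp_path / "toy.gen"
        gp.write_text(
            "toy data\nL1\nL2\nPOP\nind1, 001002 003003\nind2, 000000 003004\n"
        )
        coords = tmp_path / "coords.csv"
        coords.write_text("individual,x,y\nind1,0,0\nind2,30,40\n")
        return gp, coords

    def test_minimal_file(self, tmp_path):
        gp, coords = self.write_minimal(tmp_path)
        g = read_genotypes(gp, coords)
        assert g.n == 2 and g.n_loci == 2
        assert tuple(g.calls[0, 0]) == (1, 2)
        # 000000 is a missing call
        assert g.missing_mask()[1, 0]
        assert not g.missing_mask()[1, 1]

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        n, L = 137, 11
        calls = rng.integers(1, 30, size=(n, L, 2))
        missing = rng.random((n, L)) < 0.05
        calls[missing] = 0
        g = GenotypeTable(
            [f"ind{k}" for k in range(n)],
            [f"L{k}" for k in range(L)],
            calls,
            rng.uniform(0, 1e4, (n, 2)).round(3),
            ["north"] * 70 + ["south"] * 67,
        )
        gp, cs = tmp_path / "rt.gen", tmp_path / "rt.csv"
        write_genotypes(g, gp, cs)
        back = read_genotypes(gp, cs)
        assert back.individuals == g.individuals
        assert back.loci == g.loci
        assert np.array_equal(back.calls, g.calls)
        assert np.allclose(back.coords, g.coords)
        assert back.area_tag == g.area_tag

    def test_missing_coordinates_named_error(self, tmp_path):
        gp, _ = self.write_minimal(tmp_path)
        coords = pd.DataFrame({"individual": ["ind1"], "x": [0.0], "y": [0.0]})
        with pytest.raises(GeneticsError, match="ind2"):
            read_genotypes(gp, coords=coords)

    def test_bad_allele_code_length(self, tmp_path):
        gp = tmp_path / "bad.gen"
        gp.write_text("t\nL1\nPOP\nind1, 00102\n")
        coords = pd.DataFrame({"individual": ["ind1"], "x": [0.0], "y": [0.0]})
        with pytest.raises(GeneticsError, match="length"):
            read_genotypes(gp, coords=coords)


class TestDps:
    def test_identical_genotypes_zero(self):
        calls = np.array([[[1, 2], [3, 4]], [[1, 2], [3, 4]]])
        g = GenotypeTable(["a", "b"], ["L1", "L2"], calls, np.zeros((2, 2)))
        assert dps_matrix(g).values[0, 1] == 0.0

    def test_one_shared_allele_per_locus_is_half(self):
        calls = np.array([[[1, 2], [3, 4]], [[1, 5], [3, 6]]])
        g = GenotypeTable(["a", "b"], ["L1", "L2"], calls, np.zeros((2, 2)))
        assert dps_matrix(g).values[0, 1] == 0.5

    def test_fully_disjoint_alleles_one(self):
        calls = np.array([[[1, 2], [3, 4]], [[5, 6], [7, 8]]])
        g = GenotypeTable(["a", "b"], ["L1", "L2"], calls, np.zeros((2, 2)))
        assert dps_matrix(g).values[0, 1] == 1.0

    def test_no_cotyped_locus_error(self):
        calls = np.array([[[1, 1], [0, 0]], [[0, 0], [2, 2]]])
        g = GenotypeTable(["a", "b"], ["L1", "L2"], calls, np.zeros((2, 2)))
        with pytest.raises(GeneticsError, match="co-typed"):
            dps_matrix(g)

    def test_multiplicity_counting(self):
        # homozygote vs heterozygote sharing: (1,1) vs (1,2) shares 1 allele
        calls = np.array([[[1, 1]], [[1, 2]]])
        g = GenotypeTable(["a", "b"], ["L1"], calls, np.zeros((2, 2)))
        assert dps_matrix(g).values[0, 1] == 0.5


class TestRoussetA:
    def test_matches_enumeration_oracle(self, toy_genotypes):
        dm = rousset_a_matrix(toy_genotypes)
        calls = toy_genotypes.calls
        for i, j in itertools.combinations(range(4), 2):
            assert dm.values[i, j] == pytest.approx(rousset_a_oracle(calls, i, j))

    def test_fuzzed_tables_match_oracle_with_missing(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 7))
            calls = rng.integers(1, 5, size=(n, 3, 2))
            drop = rng.random((n, 3)) < 0.2
            calls[drop] = 0
            try:
                g = GenotypeTable(
                    [f"i{k}" for k in range(n)], ["A", "B", "C"], calls, np.zeros((n, 2))
                )
                dm = rousset_a_matrix(g)
            except GeneticsError:
                continue
            for i, j in itertools.combinations(range(n), 2):
                assert dm.values[i, j] == pytest.approx(rousset_a_oracle(calls, i, j))

    def test_monomorphic_dataset_error(self):
        calls = np.full((3, 2, 2), 7)
        g = GenotypeTable(["a", "b", "c"], ["L1", "L2"], calls, np.zeros((3, 2)))
        with pytest.raises(GeneticsError, match="polymorphism"):
            rousset_a_matrix(g)

    def test_increasing_sharing_never_increases_a(self):
        # focal pair (0,1): raise allele sharing stepwise, all else fixed
        base = np.array(
            [
                [[1, 2], [5, 6]],
                [[3, 4], [7, 8]],
                [[1, 3], [5, 7]],
                [[2, 4], [6, 8]],
            ]
        )
        variants = [base.copy() for _ in range(3)]
        variants[1][1, 0] = [1, 4]  # share one allele at locus 1
        variants[2][1] = [[1, 2], [7, 8]]  # share both at locus 1
        values = []
        for calls in variants:
            g = GenotypeTable(list("abcd"), ["L1", "L2"], calls, np.zeros((4, 2)))
            values.append(rousset_a_matrix(g).values[0, 1])
        assert values[0] >= values[1] >= values[2]


class TestInvariants:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(1, 6, size=(6, 4, 2))
        g1 = GenotypeTable([f"i{k}" for k in range(6)], list("ABCD"), calls, np.zeros((6, 2)))
        # bijective recoding of allele codes per locus
        recoded = calls.copy()
        for l in range(4):
            perm = rng.permutation(np.arange(1, 10))
            recoded[:, l] = perm[calls[:, l] - 1]
        g2 = GenotypeTable([f"i{k}" for k in range(6)], list("ABCD"), recoded, np.zeros((6, 2)))
        assert np.allclose(dps_matrix(g1).values, dps_matrix(g2).values)
        assert np.allclose(rousset_a_matrix(g1).values, rousset_a_matrix(g2).values)

    def test_dps_bounds_and_symmetry_fuzzed(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(1, 4, size=(8, 5, 2))
        g = GenotypeTable([f"i{k}" for k in range(8)], list("ABCDE"), calls, np.zeros((8, 2)))
        dm = dps_matrix(g)
        assert np.all(dm.values >= 0) and np.all(dm.values <= 1)
        assert np.allclose(dm.values, dm.values.T)

    def test_pairwise_missing_equals_reduced_table(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(1, 5, size=(4, 3, 2))
        full = calls.copy()
        full[0, 2] = 0  # locus C missing for individual 0
        g_full = GenotypeTable(list("abcd"), list("ABC"), full, np.zeros((4, 2)))
        g_red = GenotypeTable(list("abcd"), list("AB"), calls[:, :2], np.zeros((4, 2)))
        d_full = dps_matrix(g_full)
        d_red = dps_matrix(g_red)
        for j in range(1, 4):
            assert d_full.values[0, j] == pytest.approx(d_red.values[0, j])


class TestEuclidean:
    def test_known_distances(self, toy_genotypes):
        dm = euclidean_matrix(toy_genotypes)
        assert dm.values[0, 1] == pytest.approx(5.0)  # 3-4-5 triangle
        assert dm.values[0, 0] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 1000, (10, 2))
        calls = np.ones((10, 1, 2), int)
        calls[:, 0, 0] = np.arange(1, 11)  # avoid monomorphism constraints
        g = GenotypeTable([f"i{k}" for k in range(10)], ["L1"], calls, coords)
        dm = euclidean_matrix(g)
        for i in range(10):
            for j in range(10):
                expected = np.hypot(*(coords[i] - coords[j]))
                assert dm.values[i, j] == pytest.approx(expected)


class TestDistanceMatrixType:
    def test_asymmetry_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(GeneticsError, match="symmetric"):
            DistanceMatrix(["a", "b"], m, "geographic")

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        m = rng.random((4, 4)); m = (m + m.T) / 2; np.fill_diagonal(m, 0)
        dm = DistanceMatrix(list("abcd"), m, "effective")
        p = tmp_path / "m.csv"
        dm.write_csv(p)
        back = DistanceMatrix.read_csv(p, "effective")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)
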