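"""G matrix, top-k relationships, Mendelian inconsistency, MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockimpute.core import MISSING, DataError, GenotypeMatrix, ParameterError
from flockimpute.relatedness import (
    AlleleFrequencies,
    GMatrix,
    allele_frequencies,
    avtop10_mi,
    compute_G,
    mds_cluster,
    mendelian_inconsistency,
    mi_counts,
    top_k_relationships,
)


def make_geno(data, prefix="a"):
    data = np.asarray(data, dtype=np.int8)
    animals = np.array([f"{prefix}{i}" for i in range(data.shape[0])], dtype=object)
    snps = np.array([f"s{j}" for j in range(data.shape[1])], dtype=object)
    return GenotypeMatrix(animals, snps, data)


def brute_force_G(data, p):
    """Independent double-loop evaluation of G = XX'/(2*sum p(1-p))."""
    n, m = data.shape
    scale = 2.0 * sum(pi * (1 - pi) for pi in p)
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(m):
                xj = 0.0 if data[j, i] == MISSING else data[j, i] - 2 * p[i]
                xk = 0.0 if data[k, i] == MISSING else data[k, i] - 2 * p[i]
                acc += xj * xk
            G[j, k] = acc / scale
    return G


class TestAlleleFrequencies:
    @pytest.mark.parametrize("dosages, expected", [
        ([0, 1, 2], 0.5),
        ([2, 2, 2], 1.0),
        ([2, MISSING, 1], 0.75),
    ])
    def test_hand_computed_frequencies(self, dosages, expected):
        geno = make_geno(np.array(dosages, dtype=np.int8)[:, None])
        freqs = allele_frequencies(geno)
        assert freqs.p[0] == pytest.approx(expected)

    def test_all_missing_snp_flagged(self):
        geno = make_geno([[MISSING, 0], [MISSING, 1]])
        freqs = allele_frequencies(geno)
        assert not freqs.defined[0] and freqs.defined[1]

    def test_empty_animal_set_rejected(self):
        geno = make_geno([[0, 1], [1, 2]])
        with pytest.raises(DataError):
            allele_frequencies(geno, animal_set=[])


class TestComputeG:
    def test_single_snp_hand_example(self):
        """One SNP, p = 0.5, dosages (0, 2): X = (-1, 1), G = [[2,-2],[-2,2]]."""
        geno = make_geno([[0], [2]])
        freqs = AlleleFrequencies(geno.snps, np.array([0.5]), np.array([True]))
        gmat = compute_G(geno, freqs)
        assert np.allclose(gmat.G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_animal_rows_identical(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        data[4] = data[0]
        geno = make_geno(data)
        gmat = compute_G(geno, allele_frequencies(geno))
        assert np.allclose(gmat.G[0], gmat.G[4])
        assert np.allclose(gmat.G[:, 0], gmat.G[:, 4])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            data = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
            data[rng.random(data.shape) < 0.1] = MISSING
            geno = make_geno(data)
            freqs = allele_frequencies(geno)
            gmat = compute_G(geno, freqs)
            assert np.allclose(gmat.G, brute_force_G(data, freqs.p), atol=1e-10)

    def test_monomorphic_matrix_rejected(self):
        geno = make_geno(np.zeros((3, 10)))
        with pytest.raises(DataError):
            compute_G(geno, allele_frequencies(geno))

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        geno = make_geno(rng.integers(0, 3, size=(8, 60)))
        gmat = compute_G(geno, allele_frequencies(geno))
        assert np.allclose(gmat.G, gmat.G.T)


class TestTopK:
    def test_exact_copy_gives_diagonal_value(self):
        rng = np.random.default_rng(4)
        data = rng.integers(0, 3, size=(3, 80)).astype(np.int8)
        data[1] = data[0]
        geno = make_geno(data)
        gmat = compute_G(geno, allele_frequencies(geno))
        stats = top_k_relationships(gmat, reference=["a1"], targets=["a0"], k=1)
        assert stats.per_target.iloc[0]["relationship"] == pytest.approx(gmat.G[0, 0])

    def test_shortfall_recorded(self):
        rng = np.random.default_rng(5)
        geno = make_geno(rng.integers(0, 3, size=(8, 60)))
        ref = [f"a{i}" for i in range(5)]
        stats = top_k_relationships(compute_G(geno, allele_frequencies(geno)),
                                    ref, ["a6", "a7"], k=10)
        assert (stats.summary["k_used"] == 5).all()
        assert (stats.summary["shortfall"] == 5).all()

    def test_scenario_mean_is_mean_of_target_means(self):
        rng = np.random.default_rng(6)
        geno = make_geno(rng.integers(0, 3, size=(10, 60)))
        stats = top_k_relationships(compute_G(geno, allele_frequencies(geno)),
                                    [f"a{i}" for i in range(6)],
                                    ["a7", "a8", "a9"], k=3)
        assert stats.scenario_mean == pytest.approx(stats.summary["mean"].mean())

    def test_overlapping_sets_rejected(self):
        rng = np.random.default_rng(7)
        geno = make_geno(rng.integers(0, 3, size=(4, 30)))
        gmat = compute_G(geno, allele_frequencies(geno))
        with pytest.raises(ParameterError):
            top_k_relationships(gmat, ["a0", "a1"], ["a1", "a2"])

    def test_empty_reference_rejected(self):
        rng = np.random.default_rng(7)
        geno = make_geno(rng.integers(0, 3, size=(4, 30)))
        gmat = compute_G(geno, allele_frequencies(geno))
        with pytest.raises(DataError):
            top_k_relationships(gmat, [], ["a1"])


class TestMendelianInconsistency:
    @pytest.mark.parametrize("a, b, expected", [
        ([0, 2, 1], [0, 2, 1], (0, 3)),
        ([0, 2, 1], [2, 2, 1], (1, 3)),
        ([0, MISSING], [2, 2], (1, 1)),
    ])
    def test_hand_counted(self, a, b, expected):
        assert mendelian_inconsistency(np.array(a), np.array(b)) == expected

    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=30),
           st.data())
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_label_flip_invariant(self, a, data):
        b = data.draw(st.lists(st.sampled_from([0, 1, 2, MISSING]),
                               min_size=len(a), max_size=len(a)))
        a, b = np.array(a), np.array(b)
        assert mendelian_inconsistency(a, b) == mendelian_inconsistency(b, a)
        # consistent A/B relabeling at every SNP: dosage d -> 2 - d
        fa = np.where(a == MISSING, MISSING, 2 - a)
        fb = np.where(b == MISSING, MISSING, 2 - b)
        assert mendelian_inconsistency(fa, fb) == mendelian_inconsistency(a, b)

    def test_matrix_form_matches_pairwise(self):
        rng = np.random.default_rng(8)
        data = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        data[rng.random(data.shape) < 0.15] = MISSING
        geno = make_geno(data)
        rows, cols = ["a0", "a1", "a2"], ["a3", "a4", "a5"]
        counts, co = mi_counts(geno, rows, cols)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                ri = list(geno.animals).index(r)
                ci = list(geno.animals).index(c)
                mi, cc = mendelian_inconsistency(data[ri], data[ci])
                assert counts[i, j] == mi and co[i, j] == cc


class TestAvtop10:
    def test_k_exact_copies_give_zero(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=40).astype(np.int8)
        data = np.vstack([base] * 4 + [rng.integers(0, 3, size=40)])
        geno = make_geno(data)
        profile = avtop10_mi(["a0"], ["a1", "a2", "a3", "a4"], geno, k=3)
        assert profile.table.iloc[0]["avtop10"] == 0.0

    def test_mean_of_lowest_k(self):
        # target homozygous 0 everywhere; references built to give MI 1,2,3,4
        m = 10
        target = np.zeros(m, dtype=np.int8)
        rows = [target]
        for mi in (4, 1, 2, 3):  # order scrambled on purpose
            r = np.zeros(m, dtype=np.int8)
            r[:mi] = 2
            rows.append(r)
        geno = make_geno(np.vstack(rows))
        profile = avtop10_mi(["a0"], ["a1", "a2", "a3", "a4"], geno, k=2)
        assert profile.table.iloc[0]["avtop10"] == pytest.approx(1.5)

    def test_offspring_has_lower_avtop10_than_unrelated(self, multibreed,
                                                        multibreed_groups):
        pop, panels = multibreed
        low = panels[0]
        from flockimpute.panels import mask_to_panel

        romney = multibreed_groups["romney"]
        primera = multibreed_groups["primera"]
        reference = romney[:120]
        offspring = [a for a in romney[120:]
                     if pop.pedigree.table.set_index("animal").loc[a, "sire"] in set(reference)][:5]
        lowg = mask_to_panel(pop.genotypes, low)
        prof = avtop10_mi(offspring + primera[-5:], reference, lowg)
        tab = prof.table.set_index("target")
        assert tab.loc[offspring, "avtop10"].mean() < tab.loc[primera[-5:], "avtop10"].mean()


class TestMDS:
    def test_identical_animals_identical_coordinates(self):
        rng = np.random.default_rng(10)
        data = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        data[1] = data[0]
        geno = make_geno(data)
        gmat = compute_G(geno, allele_frequencies(geno))
        coords = mds_cluster(gmat, {a: "g" for a in geno.animals}, dims=2, seed=0)
        c = coords.set_index("animal")
        assert np.allclose(c.loc["a0", ["axis1", "axis2"]].to_numpy(dtype=float),
                           c.loc["a1", ["axis1", "axis2"]].to_numpy(dtype=float),
                           atol=1e-8)

    def test_recovers_planar_distances_exactly(self):
        """Points with pairwise distances (3, 4, 5) embed exactly in 2D."""
        # Gram matrix of points (0,0), (3,0), (0,4)
        G = np.array([[0.0, 0.0, 0.0], [0.0, 9.0, 0.0], [0.0, 0.0, 16.0]])
        gmat = GMatrix(np.array(["p0", "p1", "p2"], dtype=object), G,
                       np.zeros((3, 1)), 1.0)
        coords = mds_cluster(gmat, {"p0": "g", "p1": "g", "p2": "g"}, dims=2, seed=0)
        xy = coords[["axis1", "axis2"]].to_numpy(dtype=float)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
        expected = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        assert np.allclose(d, expected, atol=1e-8)

    def test_diverged_breeds_separate(self, multibreed, multibreed_groups):
        pop, _ = multibreed
        geno = pop.genotypes
        dom = pop.pedigree.dominant_breed()
        groups = {a: dom[a] for a in geno.animals if dom[a] in ("romney", "primera")}
        gmat = compute_G(geno, allele_frequencies(geno))
        coords = mds_cluster(gmat, groups, sample_per_group=60, dims=2, seed=1)
        xy = coords[["axis1", "axis2"]].to_numpy(dtype=float)
        lab = coords["group"].to_numpy()
        cents = {g: xy[lab == g].mean(axis=0) for g in ("romney", "primera")}
        between = np.linalg.norm(cents["romney"] - cents["primera"])
        within = np.mean([np.linalg.norm(xy[lab == g] - cents[g], axis=1).mean()
                          for g in ("romney", "primera")])
        assert between > within

    def test_seeded_sampling_reproducible(self, multibreed):
        pop, _ = multibreed
        geno = pop.genotypes
        dom = pop.pedigree.dominant_breed()
        groups = {a: dom[a] for a in geno.animals}
        gmat = compute_G(geno, allele_frequencies(geno))
        a = mds_cluster(gmat, groups, sample_per_group=30, dims=2, seed=5)
        b = mds_cluster(gmat, groups, sample_per_group=30, dims=2, seed=5)
        pd.testing.assert_frame_equal(a, b)
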