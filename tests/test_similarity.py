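"""Tanimoto and city-block primitives against naive loop oracles,
metric axioms, and the intra-/inter-set library summaries."""

import numpy as np
import pytest

from dfp import (
    InputError,
    MACCS166,
    LibrarySpec,
    ValidationError,
    bit_probabilities,
    build_dfp,
    build_dfp_for_database,
    city_block,
    generate_library,
    generate_random_reference,
    inter_set_matrix,
    intra_set_pairwise,
    intra_set_vs_dfp,
    tanimoto,
)
from dfp.core import DatabaseFingerprint
from dfp.similarity import _pairwise_tanimoto_values

from .conftest import make_matrix


def naive_tanimoto(a, b):
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return inter / union if union else 0.0


def naive_city_block(a, b):
    return sum(abs(int(x) - int(y)) for x, y in zip(a, b))


def _dfp_from_bits(bits, label="d"):
    bits = np.asarray(bits, dtype=np.uint8)
    from dfp import scheme_for_length

    return DatabaseFingerprint(bits=bits, threshold=0.5, strategy="fixed",
                               n_source=1, scheme=scheme_for_length(len(bits)),
                               source_label=label)


class TestPrimitives:
    def test_tanimoto_examples(self):
        assert tanimoto([1, 0, 1], [1, 0, 1]) == 1.0
        assert tanimoto([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0
        assert tanimoto([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_tanimoto_zero_zero_convention(self):
        assert tanimoto([0, 0], [0, 0]) == 0.0

    def test_city_block_examples(self):
        assert city_block([1, 0, 1], [1, 0, 1]) == 0
        ones = np.ones(166, dtype=np.uint8)
        assert city_block(ones, 1 - ones) == 166

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tanimoto([1, 0], [1, 0, 1])
        with pytest.raises(ValidationError):
            city_block([1, 0], [1])

    def test_oracle_equivalence_on_1000_seeded_pairs(self, rng):
        # popcount-accelerated paths must match the naive per-bit loops
        a = (rng.random((1000, 64)) < 0.4).astype(np.uint8)
        b = (rng.random((1000, 64)) < 0.6).astype(np.uint8)
        for i in range(1000):
            assert tanimoto(a[i], b[i]) == pytest.approx(
                naive_tanimoto(a[i], b[i]), abs=1e-12)
            assert city_block(a[i], b[i]) == naive_city_block(a[i], b[i])

    def test_metric_axioms_city_block(self, rng):
        vectors = (rng.random((30, 40)) < 0.5).astype(np.uint8)
        for a in vectors[:10]:
            assert city_block(a, a) == 0
        for a, b, c in zip(vectors[:10], vectors[10:20], vectors[20:30]):
            assert city_block(a, b) == city_block(b, a)
            assert city_block(a, c) <= city_block(a, b) + city_block(b, c)

    def test_tanimoto_range_and_identity(self, rng):
        vectors = (rng.random((20, 50)) < 0.5).astype(np.uint8)
        for a, b in zip(vectors[:10], vectors[10:]):
            value = tanimoto(a, b)
            assert 0.0 <= value <= 1.0
            assert value == tanimoto(b, a)
            if value == 1.0:
                assert np.array_equal(a, b)


class TestIntraSetPairwise:
    def test_identical_pair(self):
        matrix = make_matrix([[1, 0, 1], [1, 0, 1]])
        summary = intra_set_pairwise(matrix)
        assert (summary.mean, summary.sd) == (1.0, 0.0)
        assert summary.n_pairs_or_mols == 1
        assert not summary.sampled

    def test_random_reference_near_one_third(self, random_reference):
        summary = intra_set_pairwise(random_reference)
        assert summary.n_pairs_or_mols == 1500 * 1499 // 2
        assert round(summary.mean, 2) == 0.33

    def test_sampled_agrees_with_exact(self):
        spec = LibrarySpec(n=500, scheme=MACCS166,
                           profile=np.full(166, 0.4), seed=77, label="s")
        matrix = generate_library(spec)
        exact = intra_set_pairwise(matrix)
        sampled = intra_set_pairwise(matrix, max_exact_n=100,
                                     sample_pairs=20000, seed=5)
        assert sampled.sampled and sampled.seed == 5
        se = sampled.sd / np.sqrt(sampled.n_pairs_or_mols)
        assert abs(sampled.mean - exact.mean) < 3 * se

    def test_exact_matches_naive_loop_on_small_set(self, rng):
        bits = (rng.random((12, 30)) < 0.5).astype(np.uint8)
        values = _pairwise_tanimoto_values(bits)
        oracle = [naive_tanimoto(bits[i], bits[j])
                  for i in range(12) for j in range(i + 1, 12)]
        assert np.allclose(sorted(values), sorted(oracle))

    def test_single_molecule_rejected(self):
        with pytest.raises(InputError):
            intra_set_pairwise(make_matrix([[1, 0]]))


class TestIntraSetVsDfp:
    def test_single_molecule_library_own_dfp(self, rng):
        row = (rng.random(166) < 0.3).astype(np.uint8)
        matrix = make_matrix(row[None, :])
        dfp = build_dfp_for_database(matrix, threshold=0.5)
        assert intra_set_vs_dfp(matrix, dfp).mean == 1.0

    def test_all_zero_dfp_gives_zero(self, rng):
        matrix = make_matrix((rng.random((10, 20)) < 0.5).astype(np.uint8))
        dfp = _dfp_from_bits(np.zeros(20))
        assert intra_set_vs_dfp(matrix, dfp).mean == 0.0

    def test_matches_direct_loop_oracle(self):
        profile = np.where(np.arange(166) % 2 == 0, 0.95, 0.05)
        matrix = generate_library(LibrarySpec(
            n=200, scheme=MACCS166, profile=profile, seed=13, label="bimodal"))
        dfp = build_dfp_for_database(matrix, threshold=0.5)
        summary = intra_set_vs_dfp(matrix, dfp)
        oracle = np.mean([naive_tanimoto(row, dfp.bits)
                          for row in matrix.bits])
        assert summary.mean == pytest.approx(oracle, abs=1e-12)
        assert summary.n_pairs_or_mols == 200

    def test_scheme_mismatch_rejected(self, rng):
        matrix = make_matrix((rng.random((5, 20)) < 0.5).astype(np.uint8))
        with pytest.raises(ValidationError):
            intra_set_vs_dfp(matrix, _dfp_from_bits(np.zeros(21)))


class TestInterSetMatrix:
    def test_duplicate_dfp_gives_zero_matrix(self):
        x = _dfp_from_bits([1, 0, 1, 1], label="x")
        matrix = inter_set_matrix([x, x])
        assert matrix.values.tolist() == [[0, 0], [0, 0]]

    def test_symmetry_triangle_and_integrality(self, rng):
        dfps = [_dfp_from_bits((rng.random(40) < 0.5).astype(np.uint8),
                               label=f"d{i}") for i in range(5)]
        matrix = inter_set_matrix(dfps, metric="city_block")
        values = matrix.values
        assert np.allclose(values, values.T)
        assert np.allclose(np.diag(values), 0.0)
        assert np.allclose(values, np.round(values))
        assert (values >= 0).all() and (values <= 40).all()
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert values[i, j] <= values[i, k] + values[k, j] + 1e-9

    def test_random_dfp_is_most_distant_from_correlated_family(self):
        # libraries jittered around a shared profile stay mutually close;
        # the random reference should be the clear outlier
        rng = np.random.default_rng(42)
        base = rng.uniform(0.05, 0.95, 166)
        dfps = []
        for i in range(3):
            profile = np.clip(base + rng.normal(0, 0.03, 166), 0, 1)
            lib = generate_library(LibrarySpec(
                n=400, scheme=MACCS166, profile=profile,
                seed=100 + i, label=f"fam{i}"))
            dfps.append(build_dfp_for_database(lib, threshold=0.5))
        random_dfp = build_dfp_for_database(
            generate_random_reference(n=400, seed=999), threshold=0.5)
        matrix = inter_set_matrix([*dfps, random_dfp], metric="city_block")
        for i in range(3):
            to_random = matrix.values[i, 3]
            within = [matrix.values[i, j] for j in range(3) if j != i]
            assert to_random > max(within)

    def test_one_minus_tanimoto_metric(self):
        a = _dfp_from_bits([1, 1, 0, 0], label="a")
        b = _dfp_from_bits([1, 0, 1, 0], label="b")
        matrix = inter_set_matrix([a, b], metric="one_minus_tanimoto")
        assert matrix.values[0, 1] == pytest.approx(1 - 1 / 3)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValidationError):
            inter_set_matrix([_dfp_from_bits([1, 0]),
                              _dfp_from_bits([1, 0, 1])])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(InputError):
            inter_set_matrix([_dfp_from_bits([1, 0])])

    def test_tsv_round_trip_labels(self, tmp_path):
        a = _dfp_from_bits([1, 1, 0, 0], label="liba")
        b = _dfp_from_bits([1, 0, 1, 0], label="libb")
        path = tmp_path / "m.tsv"
        inter_set_matrix([a, b]).to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["label", "liba", "libb"]
        assert lines[1].split("\t") == ["liba", "0", "2"]
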