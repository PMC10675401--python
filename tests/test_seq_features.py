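import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from _oracles import brute_dp_pssm, brute_pc_correlation

from locfuse import (
    AA_ORDER,
    ProteinRecord,
    Pssm,
    aac_pssm,
    dp_pssm,
    greedy_cluster,
    length_filter,
    load_property_table,
    pc_correlation,
    pseaac_dipeptide,
    pssm_composition,
)
from locfuse.properties import PropertyTable
from locfuse.seq_features import InputTooShortError, alignment_identity

sequences = st.text(alphabet=AA_ORDER, min_size=2, max_size=60)


def _random_sequence(rng, n):
    return "".join(rng.choice(list(AA_ORDER), size=n))


# ---------------------------------------------------------------- clustering


def test_identical_sequences_collapse_to_first():
    records = [ProteinRecord("a", "ACDEFGHIKL" * 3), ProteinRecord("b", "ACDEFGHIKL" * 3)]
    reps = greedy_cluster(records, 0.9)
    assert [r.id for r in reps] == ["a"]


def test_disjoint_sequences_all_retained():
    records = [
        ProteinRecord("a", "AAAAAAAAAA"),
        ProteinRecord("b", "CCCCCCCCCC"),
        ProteinRecord("c", "DDDDDDDDDD"),
    ]
    assert [r.id for r in greedy_cluster(records, 0.9)] == ["a", "b", "c"]


def test_near_duplicate_removed_against_hamming_oracle(rng):
    # B equals A with 5 substitutions and no indels, so the optimal global
    # alignment is the identity mapping and the oracle identity is Hamming
    base = _random_sequence(rng, 100)
    pos = rng.choice(100, size=5, replace=False)
    mutated = list(base)
    for p in pos:
        mutated[p] = AA_ORDER[(AA_ORDER.index(base[p]) + 1) % 20]
    mutated = "".join(mutated)
    oracle_identity = sum(a == b for a, b in zip(base, mutated)) / 100
    assert oracle_identity == 0.95
    assert abs(alignment_identity(base, mutated) - oracle_identity) < 1e-12

    records = [ProteinRecord("A", base), ProteinRecord("B", mutated)]
    assert [r.id for r in greedy_cluster(records, 0.9)] == ["A"]
    assert [r.id for r in greedy_cluster(records, 0.96)] == ["A", "B"]


def test_cluster_output_subset_and_order_stable(rng):
    records = [ProteinRecord(f"p{i}", _random_sequence(rng, 30 + i)) for i in range(6)]
    reps = greedy_cluster(records, 0.9)
    assert {r.id for r in reps} <= {r.id for r in records}
    shuffled = [records[i] for i in rng.permutation(len(records))]
    reps_shuffled = greedy_cluster(shuffled, 0.9)
    assert {r.id for r in reps_shuffled} == {r.id for r in reps}


def test_cutoff_one_merges_only_exact_duplicates():
    records = [
        ProteinRecord("a", "ACDEFGHIKLMNPQRS"),
        ProteinRecord("b", "ACDEFGHIKLMNPQRS"),
        ProteinRecord("c", "ACDEFGHIKLMNPQRT"),
    ]
    assert [r.id for r in greedy_cluster(records, 1.0)] == ["a", "c"]


def test_length_filter_inclusive_bounds():
    make = lambda n: ProteinRecord(f"L{n}", "A" * n)
    kept = length_filter([make(49), make(50), make(5000), make(5001)])
    assert [len(r) for r in kept] == [50, 5000]
    assert length_filter([]) == []


# ------------------------------------------------------------------- PseAAC


def test_pseaac_homopolymer():
    fv = pseaac_dipeptide(ProteinRecord("p", "AAA"))
    assert fv.values[0] == 1.0 and fv.values[1:20].sum() == 0
    assert fv.values[20] == 1.0 and fv.values[21:].sum() == 0


def test_pseaac_acac_hand_enumeration():
    fv = pseaac_dipeptide(ProteinRecord("p", "ACAC"))
    comp = fv.values[:20]
    assert comp[AA_ORDER.index("A")] == 0.5 and comp[AA_ORDER.index("C")] == 0.5
    dipep = fv.values[20:].reshape(20, 20)
    assert dipep[AA_ORDER.index("A"), AA_ORDER.index("C")] == pytest.approx(2 / 3)
    assert dipep[AA_ORDER.index("C"), AA_ORDER.index("A")] == pytest.approx(1 / 3)


@settings(deadline=None, max_examples=40)
@given(sequences)
def test_pseaac_blocks_each_sum_to_one(seq):
    fv = pseaac_dipeptide(ProteinRecord("p", seq))
    assert fv.dimension == 420
    assert fv.values[:20].sum() == pytest.approx(1.0)
    assert fv.values[20:].sum() == pytest.approx(1.0)


def test_pseaac_too_short():
    with pytest.raises(InputTooShortError):
        pseaac_dipeptide(ProteinRecord("p", "A"))


# ------------------------------------------------------- property correlation


def test_pc_homopolymer_all_zero():
    fv = pc_correlation(ProteinRecord("p", "A" * 30))
    assert fv.dimension == 3675
    assert np.all(fv.values == 0)


def test_pc_range_and_dimension(rng):
    fv = pc_correlation(ProteinRecord("p", _random_sequence(rng, 40)))
    assert fv.dimension == 3675
    assert fv.values.min() >= -1 - 1e-12 and fv.values.max() <= 1 + 1e-12


def _toy_table(raw):
    """A reduced table padded to the required 50 scales."""
    rng = np.random.default_rng(99)
    full = np.vstack([raw, rng.normal(size=(50 - raw.shape[0], 20))])
    names = tuple(f"prop{i}" for i in range(50))
    sd = full.std(axis=1, keepdims=True)
    znorm = (full - full.mean(axis=1, keepdims=True)) / sd
    return PropertyTable(names, full, znorm)


def test_pc_matches_textbook_pearson_loop(rng):
    seq = _random_sequence(rng, 10)
    table = _toy_table(rng.normal(size=(3, 20)))
    fv = pc_correlation(ProteinRecord("p", seq), table)
    profiles = table.profile(seq)  # (L, 50)
    L = len(seq)
    # brute-force: unordered property pairs in lexicographic order, lags 1..3
    pos = 0
    for p in range(50):
        for q in range(p + 1, 50):
            for d in (1, 2, 3):
                x, y = profiles[: L - d, p], profiles[d:, q]
                expected = 0.0 if (x.std() == 0 or y.std() == 0) else stats.pearsonr(x, y)[0]
                assert fv.values[pos] == pytest.approx(expected, abs=1e-9), (p, q, d)
                pos += 1
    assert pos == 3675


def test_pc_invariant_to_affine_rescaling_of_a_scale(rng):
    seq = _random_sequence(rng, 25)
    raw = rng.normal(size=(50, 20))
    table = _toy_table(raw[:3])
    rescaled_raw = table.raw.copy()
    rescaled_raw[0] = 7.5 * rescaled_raw[0] - 2.0
    sd = rescaled_raw.std(axis=1, keepdims=True)
    table2 = PropertyTable(
        table.names, rescaled_raw,
        (rescaled_raw - rescaled_raw.mean(axis=1, keepdims=True)) / sd,
    )
    a = pc_correlation(ProteinRecord("p", seq), table)
    b = pc_correlation(ProteinRecord("p", seq), table2)
    assert np.allclose(a.values, b.values)


def test_packaged_property_table_shape():
    table = load_property_table()
    assert table.raw.shape == (50, 20)
    assert np.allclose(table.znorm.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(table.znorm.std(axis=1), 1, atol=1e-12)


# ------------------------------------------------------------ PSSM features


def test_dp_pssm_zero_and_constant_matrices():
    zero = Pssm("z", np.zeros((8, 20)))
    assert np.all(dp_pssm(zero).values == 0)
    const = Pssm("c", np.full((8, 20), 3.0))
    v = dp_pssm(const).values
    assert np.all(v[:20] == 3.0) and np.all(v[20:] == 0.0)


def test_dp_pssm_matches_brute_force_oracle(rng):
    for _ in range(20):
        E = rng.integers(-7, 8, size=(8, 20)).astype(float)
        got = dp_pssm(Pssm("r", E)).values
        np.testing.assert_allclose(got, brute_dp_pssm(E), rtol=1e-9, atol=1e-12)


def test_dp_pssm_too_short():
    with pytest.raises(InputTooShortError):
        dp_pssm(Pssm("s", np.zeros((5, 20))), alpha=5)


def test_aac_pssm_row_mean():
    rows = np.arange(60, dtype=float).reshape(3, 20)
    assert np.allclose(aac_pssm(Pssm("m", rows)).values, rows.mean(axis=0))


def test_pssm_composition_constant_matrix():
    seq = "ACDACD"
    fv = pssm_composition(Pssm("c", np.full((6, 20), 2.0), residues=seq))
    grid = fv.values.reshape(20, 20)
    present = {AA_ORDER.index(c) for c in seq}
    for a in range(20):
        assert np.all(grid[a] == (2.0 if a in present else 0.0))


def test_pssm_descriptors_match_double_loop_oracle(rng):
    for _ in range(20):
        L = int(rng.integers(6, 12))
        seq = _random_sequence(rng, L)
        E = rng.normal(size=(L, 20))
        pssm = Pssm("r", E, residues=seq)
        comp = pssm_composition(pssm).values.reshape(20, 20)
        expected = np.zeros((20, 20))
        for a, letter in enumerate(AA_ORDER):
            rows = [i for i, c in enumerate(seq) if c == letter]
            if rows:
                for j in range(20):
                    expected[a, j] = sum(E[i, j] for i in rows) / len(rows)
        np.testing.assert_allclose(comp, expected, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(
            aac_pssm(pssm).values,
            [sum(E[i, j] for i in range(L)) / L for j in range(20)],
            rtol=1e-9,
        )
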