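"""Reactivity computation, normalization, restrained folding and ensemble
interpretation, all checked against closed forms or enumeration."""

import math

import numpy as np
import pandas as pd
import pytest

from draictools.structure import (
    EnergyModel,
    PairProbMatrix,
    PseudoEnergyParams,
    call_well_determined_regions,
    classify_pairing_level,
    classify_pairing_levels,
    extract_fused_construct,
    normalize_reactivity,
    partition_pair_probabilities,
    predict_structure,
    raw_reactivity,
    shape_pseudo_energy,
)
from draictools.synthetic import SimConfig, simulate_map_counts


def _counts(rows):
    return pd.DataFrame(
        rows,
        columns=["position", "base", "mod_mutations", "mod_reads",
                 "untr_mutations", "untr_reads"],
    )


class TestRawReactivity:
    def test_rate_difference(self):
        prof = raw_reactivity(
            _counts([[1, "A", 500, 10_000, 100, 10_000]]), min_depth=1000
        )
        assert prof.raw[0] == pytest.approx(0.05 - 0.01)

    def test_negative_difference_retained(self):
        prof = raw_reactivity(
            _counts([[1, "G", 100, 10_000, 500, 10_000]]), min_depth=1000
        )
        assert prof.raw[0] == pytest.approx(-0.04)

    def test_low_depth_becomes_no_data(self):
        prof = raw_reactivity(
            _counts([[1, "C", 10, 500, 5, 10_000]]), min_depth=1000
        )
        assert math.isnan(prof.raw[0])

    def test_malformed_table_raises(self):
        with pytest.raises(ValueError, match="missing columns"):
            raw_reactivity(pd.DataFrame({"position": [1]}))

    def test_mutations_exceeding_reads_raise(self):
        with pytest.raises(ValueError, match="mutations > reads"):
            raw_reactivity(_counts([[1, "A", 20, 10, 0, 10]]))


class TestNormalization:
    def test_identical_values_normalize_to_one(self):
        prof = raw_reactivity(
            _counts([[i, "A", 500, 10_000, 100, 10_000]
                     for i in range(1, 101)])
        )
        norm = normalize_reactivity(prof)
        assert norm.norm_factor == pytest.approx(0.04)
        assert np.allclose(norm.normalized, 1.0)

    def test_factor_matches_percentile_oracle(self):
        rng = np.random.default_rng(3)
        raw_vals = rng.random(50) * 0.1 + 0.001
        rows = [
            [i + 1, "A", int(v * 10_000), 10_000, 0, 10_000]
            for i, v in enumerate(raw_vals)
        ]
        norm = normalize_reactivity(raw_reactivity(_counts(rows)))
        vals = np.sort(np.asarray(norm.raw))[::-1]
        n = len(vals)
        expected = vals[int(n * 0.02):int(n * 0.10)].mean()
        assert norm.norm_factor == pytest.approx(expected)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        base = rng.integers(100, 5000, size=80)
        def normalized(scale):
            rows = [
                [i + 1, "A", int(c) * scale, 100_000, 0, 100_000]
                for i, c in enumerate(base)
            ]
            return normalize_reactivity(raw_reactivity(_counts(rows)))
        n1 = np.asarray(normalized(1).normalized)
        n3 = np.asarray(normalized(3).normalized)
        assert np.allclose(n1, n3)

    def test_too_few_positions_raises(self):
        prof = raw_reactivity(
            _counts([[i, "A", 10, 10_000, 0, 10_000] for i in range(1, 30)])
        )
        with pytest.raises(ValueError, match="50"):
            normalize_reactivity(prof)


class TestPseudoEnergy:
    def test_zero_reactivity_gives_intercept(self):
        assert shape_pseudo_energy(0.0) == pytest.approx(-0.6)

    def test_log_unit_point(self):
        assert shape_pseudo_energy(math.e - 1) == pytest.approx(1.8 - 0.6)

    def test_unit_reactivity(self):
        assert shape_pseudo_energy(1.0) == pytest.approx(
            1.8 * math.log(2) - 0.6
        )

    def test_negative_clamped_and_nodata_zero(self):
        assert shape_pseudo_energy(-0.5) == pytest.approx(-0.6)
        assert shape_pseudo_energy(float("nan")) == 0.0

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="m must be"):
            PseudoEnergyParams(m=0.0)


class TestPartitionFunction:
    def test_poly_a_has_no_pairs(self):
        pp = partition_pair_probabilities("A" * 20)
        assert pp.matrix.max() == 0.0

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_enumeration_oracle(self, enum_pair_probs, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 21))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        react = None
        if trial % 2:
            react = rng.random(n) * 2
            react[rng.random(n) < 0.2] = np.nan
        expected = enum_pair_probs(seq, react)
        pp = partition_pair_probabilities(seq, reactivity=react)
        denom = np.maximum(expected, 1e-12)
        assert np.max(np.abs(pp.matrix - expected) / denom) < 1e-9

    def test_probability_conservation_and_symmetry(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGU"), size=120))
        pp = partition_pair_probabilities(seq)
        assert np.allclose(pp.matrix, pp.matrix.T)
        assert pp.matrix.sum(axis=1).max() <= 1.0 + 1e-9
        assert pp.matrix.min() >= 0.0

    def test_min_hairpin_loop_respected(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGU"), size=60))
        pp = partition_pair_probabilities(seq)
        n = len(seq)
        for i in range(n):
            for j in range(i + 1, min(i + 4, n)):
                assert pp.matrix[i, j] == 0.0

    def test_raising_reactivity_never_increases_pairing(self):
        # m > 0: a more reactive nucleotide is penalized when paired
        rng = np.random.default_rng(10)
        seq = "GGGAGCUCAAAAGAGCUCCC"
        react = rng.random(len(seq)) * 0.5
        target = 4
        low = partition_pair_probabilities(seq, reactivity=react)
        react_hi = react.copy()
        react_hi[target] += 2.0
        high = partition_pair_probabilities(seq, reactivity=react_hi)
        assert (
            high.matrix[target].sum() <= low.matrix[target].sum() + 1e-12
        )

    def test_invalid_alphabet_raises(self):
        with pytest.raises(ValueError, match="invalid characters"):
            partition_pair_probabilities("ACGUX")

    def test_oversized_sequence_advises_windowing(self):
        with pytest.raises(ValueError, match="windows"):
            partition_pair_probabilities("ACGU" * 30, max_length=100)

    def test_restraints_sharpen_true_helix(self, locus):
        rna = locus.transcript_with_middle.replace("T", "U")
        react = np.asarray(locus.true_reactivity)
        plain = partition_pair_probabilities(rna)
        restrained = partition_pair_probabilities(rna, reactivity=react)
        mean_plain = np.mean([plain.prob(i, j) for i, j in locus.true_structure])
        mean_restr = np.mean(
            [restrained.prob(i, j) for i, j in locus.true_structure]
        )
        assert mean_restr > mean_plain


class TestClassification:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.96, ">0.95"), (0.95, ">0.8"), (0.81, ">0.8"), (0.8, ">0.75"),
         (0.76, ">0.75"), (0.6, ">0.50"), (0.5, "<=0.5"), (0.1, "<=0.5")],
    )
    def test_strict_thresholds(self, p, expected):
        assert classify_pairing_level(p) == expected

    def test_table_output(self):
        m = np.zeros((6, 6))
        m[0, 5] = m[5, 0] = 0.97
        m[1, 4] = m[4, 1] = 0.6
        pp = PairProbMatrix(matrix=m, sequence="GGGCCC",
                            energy_model_id="test")
        df = classify_pairing_levels(pp)
        levels = dict(zip(zip(df["i"], df["j"]), df["level"]))
        assert levels[(1, 6)] == ">0.95"
        assert levels[(2, 5)] == ">0.50"


def _helix_matrix(n, helices):
    m = np.zeros((n, n))
    for (i0, j0, length, p) in helices:
        for k in range(length):
            a, b = i0 + k - 1, j0 - k - 1
            m[a, b] = m[b, a] = p
    return m


class TestWellDeterminedRegions:
    def test_single_strong_helix(self):
        m = _helix_matrix(20, [(2, 19, 5, 0.99)])
        pp = PairProbMatrix(matrix=m, sequence="A" * 20,
                            energy_model_id="test")
        regions = call_well_determined_regions(pp)
        assert len(regions) == 1
        assert regions[0].span == (2, 19)
        assert len(regions[0].pairs) == 5
        assert regions[0].min_probability == pytest.approx(0.99)

    def test_weak_interior_pair_splits_run(self):
        m = _helix_matrix(30, [(2, 29, 7, 0.99)])
        # depress the middle pair below threshold
        m[4, 25] = m[25, 4] = 0.90
        pp = PairProbMatrix(matrix=m, sequence="A" * 30,
                            energy_model_id="test")
        # the weak pair splits the 7-pair helix into two 3-pair runs
        regions = call_well_determined_regions(pp, min_helix=3)
        assert [len(r.pairs) for r in regions] == [3, 3]
        # runs shorter than min_helix are dropped entirely
        assert call_well_determined_regions(pp, min_helix=4) == []

    def test_two_disjoint_helices_ordered_by_coordinate(self):
        m = _helix_matrix(40, [(21, 38, 4, 0.97), (2, 18, 4, 0.97)])
        pp = PairProbMatrix(matrix=m, sequence="A" * 40,
                            energy_model_id="test")
        regions = call_well_determined_regions(pp, min_helix=3)
        assert [r.span[0] for r in regions] == [2, 21]
        assert all(len(r.pairs) == 4 for r in regions)


class TestFusedConstruct:
    def test_published_interval_pair_yields_36_nt(self):
        rng = np.random.default_rng(11)
        tx = "".join(rng.choice(list("ACGU"), size=800))
        fused = extract_fused_construct(tx, [(705, 722), (741, 758)])
        assert len(fused.sequence) == 36
        assert fused.sequence == tx[704:722] + tx[740:758]

    def test_single_interval_is_identity_subsequence(self):
        tx = "ACGUACGUAC"
        fused = extract_fused_construct(tx, [(3, 7)])
        assert fused.sequence == tx[2:7]

    def test_overlapping_intervals_raise(self):
        tx = "A" * 800
        with pytest.raises(ValueError, match="overlap"):
            extract_fused_construct(tx, [(705, 745), (741, 758)])

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="outside"):
            extract_fused_construct("ACGU", [(1, 10)])

    def test_linker_inserted_between_intervals(self):
        fused = extract_fused_construct("AAACCCGGGUUU", [(1, 3), (10, 12)],
                                        linker="GAAA")
        assert fused.sequence == "AAA" + "GAAA" + "UUU"


class TestPredictStructure:
    def test_zero_matrix_gives_all_dots(self):
        pp = PairProbMatrix(matrix=np.zeros((8, 8)), sequence="A" * 8,
                            energy_model_id="test")
        assert predict_structure(pp) == "." * 8

    def test_hairpin_matches_map_structure(self, enum_pair_probs):
        seq = "GGGGAAAACCCC"
        pp = partition_pair_probabilities(seq)
        db = predict_structure(pp)
        # the dominant structure pairs the G-run with the C-run
        expected = enum_pair_probs(seq)
        for i, j in [(0, 11), (1, 10), (2, 9), (3, 8)]:
            if expected[i, j] > 0.5:
                assert db[i] == "(" and db[j] == ")"

    def test_output_is_balanced(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGU"), size=50))
        db = predict_structure(partition_pair_probabilities(seq))
        assert db.count("(") == db.count(")")
        assert len(db) == len(seq)


def test_reactivity_window_interval_arithmetic():
    """A profile over transcript positions 677-1107 has exactly 431 rows."""
    cfg = SimConfig(seed=20, exon_upstream_len=700, exon_downstream_len=400)
    from draictools.synthetic import build_synthetic_locus

    locus = build_synthetic_locus(cfg)
    counts = simulate_map_counts(locus, cfg, window=(677, 1107))
    prof = raw_reactivity(counts, min_depth=1000)
    assert len(prof) == 431
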