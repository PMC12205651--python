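"""Generator tests: locus geometry, read mixtures, expression effects,
mutation counts and sensorgram noise all match their stated models."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from draictools.synthetic import (
    ConfigurationError,
    SimConfig,
    SprParams,
    build_synthetic_locus,
    simulate_expression_matrix,
    simulate_map_counts,
    simulate_reads,
    simulate_sensorgram,
)


class TestLocus:
    def test_middle_exon_defaults_to_30_nt(self, locus):
        assert len(locus.exon_middle) == 30

    def test_transcripts_are_exact_exon_concatenations(self, locus):
        assert locus.transcript_with_middle == (
            locus.exon_upstream + locus.exon_middle + locus.exon_downstream
        )
        assert locus.transcript_without_middle == (
            locus.exon_upstream + locus.exon_downstream
        )

    def test_same_seed_gives_identical_locus(self, default_config):
        assert build_synthetic_locus(default_config) == build_synthetic_locus(
            default_config
        )

    def test_structure_is_nested_hairpin_with_loop_at_least_3(self, locus):
        pairs = sorted(locus.true_structure)
        # consecutive pairs close inward: (i, j), (i+1, j-1), ...
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            assert (i2, j2) == (i1 + 1, j1 - 1)
        innermost = pairs[-1]
        assert innermost[1] - innermost[0] - 1 >= 3

    def test_helix_pairs_are_complementary(self, locus):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        tx = locus.transcript_with_middle
        for i, j in locus.true_structure:
            assert tx[j - 1] == comp[tx[i - 1]]

    def test_true_reactivity_low_on_paired_high_on_loops(self, locus):
        paired = {p for ij in locus.true_structure for p in ij}
        react = locus.true_reactivity
        for pos in paired:
            assert react[pos - 1] < 0.5
        unpaired = set(range(1, len(react) + 1)) - paired
        assert all(react[p - 1] > 0.5 for p in unpaired)

    def test_gc_content_concentrates_at_target(self):
        # 10,030 bases at GC 0.5: binomial sd ~ 0.005, so [0.49, 0.51]
        cfg = SimConfig(seed=1, exon_upstream_len=5000,
                        exon_downstream_len=5000)
        locus = build_synthetic_locus(cfg)
        tx = locus.transcript_with_middle
        gc = (tx.count("G") + tx.count("C")) / len(tx)
        assert 0.49 <= gc <= 0.51

    def test_short_exon_raises_naming_the_exon(self):
        with pytest.raises(ConfigurationError, match="exon_upstream"):
            build_synthetic_locus(SimConfig(exon_upstream_len=10))


class TestReads:
    def test_read_count_equals_depth_exactly(self, locus, default_config):
        cfg = dataclasses.replace(default_config, depth=517)
        assert len(simulate_reads(locus, cfg, "s1")) == 517

    def test_pure_inclusion_sample_has_no_skipping_junction(self, locus):
        from draictools.junctions import design_junction_probes, reverse_complement

        cfg = SimConfig(seed=2, mixture=1.0, error_rate=0.0, depth=3000)
        _, skip = design_junction_probes(
            locus.exon_upstream, locus.exon_middle, locus.exon_downstream
        )
        rc = reverse_complement(skip.sequence)
        for rec in simulate_reads(locus, cfg, "s1"):
            s = str(rec.seq)
            assert skip.sequence not in s and rc not in s

    def test_error_free_reads_are_exact_substrings(self, locus):
        from draictools.junctions import reverse_complement

        cfg = SimConfig(seed=3, error_rate=0.0, depth=500)
        w, wo = locus.transcript_with_middle, locus.transcript_without_middle
        for rec in simulate_reads(locus, cfg, "s1"):
            s = str(rec.seq)
            assert any(
                s in t or reverse_complement(s) in t for t in (w, wo)
            )

    def test_junction_read_count_matches_closed_form_expectation(self, locus):
        from draictools.junctions import design_junction_probes

        cfg = SimConfig(seed=4, mixture=1.0, error_rate=0.0, depth=40_000)
        incl, _ = design_junction_probes(
            locus.exon_upstream, locus.exon_middle, locus.exon_downstream
        )
        tx = locus.transcript_with_middle
        probe_start = tx.index(incl.sequence)          # 0-based
        L, n = cfg.read_length, len(tx)
        starts_total = n - L + 1
        lo = max(0, probe_start + 40 - L)
        hi = min(probe_start, n - L)
        covering = max(0, hi - lo + 1)
        expected = cfg.depth * covering / starts_total
        observed = sum(
            incl.sequence in str(r.seq)
            or incl.sequence in str(r.seq.reverse_complement())
            for r in simulate_reads(locus, cfg, "s1")
        )
        assert abs(observed - expected) <= 3 * np.sqrt(expected)

    def test_mixture_mapping_and_missing_sample_error(self, locus):
        cfg = SimConfig(seed=5, mixture={"a": 0.5}, depth=10)
        assert len(simulate_reads(locus, cfg, "a")) == 10
        with pytest.raises(ConfigurationError, match="sample"):
            simulate_reads(locus, cfg, "unknown")

    def test_read_longer_than_transcript_raises(self, locus):
        cfg = SimConfig(seed=6, read_length=1000)
        with pytest.raises(ConfigurationError, match="read_length"):
            simulate_reads(locus, cfg, "s1")

    def test_same_seed_same_reads(self, locus, default_config):
        r1 = simulate_reads(locus, default_config, "s1")
        r2 = simulate_reads(locus, default_config, "s1")
        assert [str(a.seq) for a in r1] == [str(b.seq) for b in r2]


class TestExpression:
    def test_null_effect_centers_mean_difference_at_zero(self):
        cfg = SimConfig(seed=7, delta=0.0, n_genes=2000,
                        n_samples_per_group=10)
        X, labels, _ = simulate_expression_matrix(cfg)
        logx = np.log2(X)
        diff = (
            logx.loc[:, labels == "exon4a"].mean(axis=1)
            - logx.loc[:, labels == "no4a"].mean(axis=1)
        )
        # per-gene SE ~ sigma*sqrt(2/10) <= 0.36; mean over 2000 genes ~ 0.008
        assert abs(diff.mean()) < 0.025

    def test_delta_minus_one_halves_target_geometric_mean(self):
        cfg = SimConfig(seed=8, delta=-1.0, n_genes=1000,
                        n_samples_per_group=30, target_set_size=100)
        X, labels, target = simulate_expression_matrix(cfg)
        logx = np.log2(X.loc[target])
        ratio = 2 ** (
            logx.loc[:, labels == "exon4a"].mean(axis=1)
            - logx.loc[:, labels == "no4a"].mean(axis=1)
        )
        assert np.allclose(ratio.mean(), 0.5, atol=0.05)

    def test_non_target_genes_unaffected_by_delta(self):
        base = SimConfig(seed=9, delta=0.0)
        shifted = dataclasses.replace(base, delta=-2.0)
        X0, _, target = simulate_expression_matrix(base)
        X1, _, _ = simulate_expression_matrix(shifted)
        others = X0.index.difference(target)
        pd.testing.assert_frame_equal(X0.loc[others], X1.loc[others])

    def test_target_larger_than_genome_raises(self):
        with pytest.raises(ConfigurationError, match="target_set_size"):
            SimConfig(n_genes=10, target_set_size=11)


class TestMapCounts:
    def test_zero_paired_rate_centers_paired_reactivity_at_zero(self, locus):
        from draictools.structure import raw_reactivity

        cfg = SimConfig(seed=10, rate_paired=0.0, shape_depth=50_000)
        prof = raw_reactivity(simulate_map_counts(locus, cfg), min_depth=1000)
        paired = {p for ij in locus.true_structure for p in ij}
        vals = [prof.raw[p - 1] for p in paired]
        se = np.sqrt(2 * 0.01 / 50_000)         # two binomial channels
        assert abs(np.mean(vals)) < 3 * se

    def test_loop_rate_recovered_within_3_sigma(self, locus):
        from draictools.structure import raw_reactivity

        cfg = SimConfig(seed=11, rate_loop=0.04, shape_depth=50_000)
        prof = raw_reactivity(simulate_map_counts(locus, cfg), min_depth=1000)
        paired = {p for ij in locus.true_structure for p in ij}
        loops = [
            prof.raw[p - 1]
            for p in range(1, len(prof) + 1)
            if p not in paired
        ]
        n_loops = len(loops)
        se = np.sqrt(0.05 * 0.95 / 50_000 + 0.01 * 0.99 / 50_000) / np.sqrt(n_loops)
        assert abs(np.mean(loops) - 0.04) < 3 * se

    def test_zero_depth_flags_everything_no_data(self, locus):
        from draictools.structure import raw_reactivity

        cfg = SimConfig(seed=12, shape_depth=0)
        prof = raw_reactivity(simulate_map_counts(locus, cfg))
        assert all(np.isnan(v) for v in prof.raw)

    def test_window_restricts_positions(self, locus):
        cfg = SimConfig(seed=13)
        df = simulate_map_counts(locus, cfg, window=(10, 20))
        assert list(df["position"]) == list(range(10, 21))


class TestSensorgram:
    def test_noiseless_plateau_reaches_langmuir_isotherm(self):
        spr = SprParams(noise_sd=0.0, t_assoc_end=5e5, t_dissoc_end=6e5,
                        dt=1e4)
        cfg = SimConfig(seed=14, spr=spr)
        df = simulate_sensorgram(cfg)
        kD = spr.kd / spr.ka
        for conc, grp in df[df["phase"] == "assoc"].groupby("conc_M"):
            req = spr.rmax * conc / (conc + kD)
            assert grp["response_RU"].iloc[-1] == pytest.approx(req, rel=1e-3)

    def test_dissociation_half_life_identity(self):
        kd = np.log(2) / 150.0          # half-life 150 s; dt 37.5 divides 600
        spr = SprParams(kd=kd, noise_sd=0.0, t_assoc_end=600.0,
                        t_dissoc_end=1200.0, dt=np.log(2) / kd / 4)
        cfg = SimConfig(seed=15, spr=spr)
        df = simulate_sensorgram(cfg)
        one = df[(df["conc_M"] == spr.concentrations[-1])
                 & (df["replicate"] == 1)]
        assoc_end = one[one["phase"] == "assoc"]["response_RU"].iloc[-1]
        t_half = 600.0 + np.log(2) / spr.kd
        dissoc = one[one["phase"] == "dissoc"]
        idx = (dissoc["time_s"] - t_half).abs().idxmin()
        assert dissoc.loc[idx, "response_RU"] == pytest.approx(
            assoc_end / 2, rel=0.01
        )

    def test_noise_sd_recovered_from_residuals(self):
        noisy = SimConfig(seed=16, spr=SprParams(noise_sd=2.0))
        clean = SimConfig(seed=16, spr=SprParams(noise_sd=0.0))
        resid = (
            simulate_sensorgram(noisy)["response_RU"]
            - simulate_sensorgram(clean)["response_RU"]
        )
        assert np.std(resid) == pytest.approx(2.0, rel=0.05)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ConfigurationError, match="positive"):
            SprParams(concentrations=(1e-9, -1e-9))

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ConfigurationError, match="distinct"):
            SprParams(concentrations=(1e-9, 1e-9))
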