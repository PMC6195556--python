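"""Synthetic-data generator: reference structure, read simulation,
contamination injection, spectral counts, determinism."""

import numpy as np
import pandas as pd
import pytest

from venomgland import simulate as sim
from venomgland.metadata import DEFAULT_FAMILY_SIZES


def small_config(**kw):
    base = dict(
        seed=11, n_individuals=3, n_toxins=6, n_nontoxins=3,
        family_sizes={"SVMP": 3, "CTL": 2, "PLA2": 1},
        depth_per_transcript=40, error_rate=0.0, fragment_mean=250,
        fragment_sd=50, absence_rate=0.0, toxin_length_range=(300, 600),
        nontoxin_length_range=(300, 600),
    )
    base.update(kw)
    return sim.SimulationConfig(**base)


class TestGenerateReference:
    def test_all_nontoxin_when_no_toxins_requested(self):
        cfg = small_config(n_toxins=0, n_nontoxins=5, family_sizes={})
        truth = sim.generate_reference(cfg)
        assert len(truth.transcripts) == 5
        assert all(t.family == "nontoxin" for t in truth.transcripts)

    def test_family_sizes_respected_for_default_composition(self):
        cfg = sim.SimulationConfig(seed=1, n_individuals=2, n_toxins=62,
                                   n_nontoxins=0, depth_per_transcript=1)
        truth = sim.generate_reference(cfg)
        fams = pd.Series([t.family for t in truth.transcripts])
        assert (fams == "SVMP").sum() == DEFAULT_FAMILY_SIZES["SVMP"] == 16
        assert len(truth.transcripts) == 62
        assert fams.nunique() == 19

    def test_cds_in_frame_and_within_sequence(self):
        truth = sim.generate_reference(small_config())
        for t in truth.transcripts:
            s, e = t.cds
            assert 0 <= s < e <= len(t.sequence)
            assert (e - s) % 3 == 0
            assert t.sequence[s : s + 3] == "ATG"

    def test_zero_transcripts_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            small_config(n_toxins=0, n_nontoxins=0).validate()

    def test_same_seed_reproduces_reference_bytes(self):
        a = sim.generate_reference(small_config())
        b = sim.generate_reference(small_config())
        assert [(t.id, t.sequence) for t in a.transcripts] == [
            (t.id, t.sequence) for t in b.transcripts
        ]
        assert a.haplotypes == b.haplotypes

    def test_absence_never_removes_transcript_everywhere(self):
        cfg = small_config(absence_rate=0.95)
        truth = sim.generate_reference(cfg)
        assert not truth.planted_absences.all(axis=1).any()


class TestSimulateReads:
    def test_planted_absence_produces_zero_reads(self):
        cfg = small_config(absence_rate=0.4)
        truth = sim.generate_reference(cfg)
        simr = sim.simulate_reads(truth, cfg)
        for ind in cfg.individuals():
            for t in truth.transcripts:
                if truth.planted_absences.loc[t.id, ind]:
                    assert truth.fragment_counts.loc[t.id, ind] == 0
                    hap = truth.haplotypes[ind][t.id]
                    for frag in simr.fragments[ind]:
                        assert frag.sequence not in hap

    def test_error_free_reads_are_exact_substrings(self):
        cfg = small_config(error_rate=0.0)
        truth = sim.generate_reference(cfg)
        simr = sim.simulate_reads(truth, cfg)
        ind = cfg.individuals()[0]
        haps = list(truth.haplotypes[ind].values())
        for frag in simr.fragments[ind][:100]:
            assert any(frag.sequence in h for h in haps)

    def test_fragment_count_ratio_matches_abundance_binomial(self):
        # two equal-length transcripts at 1:3 abundance; the fraction of
        # fragments from the abundant one is Binomial(n, 0.75)
        cfg = small_config(n_toxins=2, n_nontoxins=0,
                          family_sizes={"SVMP": 2},
                          toxin_length_range=(600, 601),
                          depth_per_transcript=2500, expression_sigma=0.0,
                          individual_expression_sigma=0.0,
                          toxin_abundance_multiplier=1.0, n_individuals=1)
        truth = sim.generate_reference(cfg)
        tids = [t.id for t in truth.transcripts]
        truth.true_expression.loc[tids[0]] = 2.5e5
        truth.true_expression.loc[tids[1]] = 7.5e5
        simr = sim.simulate_reads(truth, cfg)
        counts = truth.fragment_counts[cfg.individuals()[0]]
        n = counts.sum()
        p = 0.75
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[tids[1]] - n * p) < 3 * sigma

    def test_total_fragments_match_requested_effort(self):
        cfg = small_config(depth_per_transcript=100)
        truth = sim.generate_reference(cfg)
        simr = sim.simulate_reads(truth, cfg)
        lengths = sum(len(t) for t in truth.transcripts)
        effort = cfg.depth_per_transcript * lengths / 1000.0
        for ind in cfg.individuals():
            total = truth.fragment_counts[ind].sum()
            assert abs(total - effort) < 4 * np.sqrt(effort)  # Poisson

    def test_fragment_shorter_than_read_is_an_error(self):
        with pytest.raises(ValueError):
            small_config(fragment_mean=100.0, read_length=150).validate()

    def test_same_seed_gives_identical_fastq(self):
        cfg = small_config()
        a = sim.simulate_reads(sim.generate_reference(cfg), cfg)
        b = sim.simulate_reads(sim.generate_reference(cfg), cfg)
        ind = cfg.individuals()[0]
        ra = [(r1.id, r1.sequence, r1.quality, r2.sequence, r2.quality)
              for r1, r2 in a.pairs[ind]]
        rb = [(r1.id, r1.sequence, r1.quality, r2.sequence, r2.quality)
              for r1, r2 in b.pairs[ind]]
        assert ra == rb


class TestInjectContamination:
    def _reads(self, cfg):
        truth = sim.generate_reference(cfg)
        simr = sim.simulate_reads(truth, cfg)
        return {i: [r for p in simr.pairs[i] for r in p] for i in cfg.individuals()}

    def test_rate_zero_is_identity(self):
        raw = self._reads(small_config())
        out, ids = sim.inject_contamination(raw, 0.0, seed=1)
        assert all(len(ids[s]) == 0 for s in raw)
        assert all(out[s] == list(raw[s]) for s in raw)

    def test_injected_count_within_binomial_bounds(self):
        raw = self._reads(small_config(depth_per_transcript=200))
        out, ids = sim.inject_contamination(raw, 0.05, seed=1)
        for s, reads in raw.items():
            n = len(reads)
            sigma = np.sqrt(n * 0.05 * 0.95)
            assert abs(len(ids[s]) - 0.05 * n) < 3 * sigma

    def test_contaminant_ids_recorded_and_disjoint_from_native(self):
        raw = self._reads(small_config())
        out, ids = sim.inject_contamination(raw, 0.05, seed=1)
        for s in raw:
            native = {r.id for r in raw[s]}
            injected = {r.id for r in out[s]} - native
            assert injected == ids[s]
            assert not (ids[s] & native)

    def test_single_sample_lane_with_positive_rate_errors(self):
        raw = self._reads(small_config())
        lanes = {s: f"L{i}" for i, s in enumerate(raw)}
        with pytest.raises(ValueError):
            sim.inject_contamination(raw, 0.05, seed=1, lane_of=lanes)

    def test_pair_aware_injection_moves_both_mates(self):
        raw = self._reads(small_config())
        out, ids = sim.inject_contamination(raw, 0.05, seed=1, pair_aware=True)
        for s in raw:
            bases = {i[:-2] for i in ids[s]}
            for b in bases:
                assert {b + "/1", b + "/2"} <= ids[s]


class TestSpectralCounts:
    def test_zero_noise_unit_slope_counts_equal_concentrations(self):
        conc = pd.DataFrame({"I1": [10.0, 20.0, 30.0]}, index=["a", "b", "c"])
        slopes = pd.DataFrame(1.0, index=["I1"], columns=["rep1", "rep2", "rep3"])
        table, _ = sim.simulate_spectral_counts(conc, noise_cv=0.0, seed=0,
                                                true_slopes=slopes)
        for rep in ("rep1", "rep2", "rep3"):
            assert np.allclose(table.loc[["a", "b", "c"], ("I1", rep)],
                               conc["I1"])

    def test_standard_rows_carry_known_amounts(self):
        conc = pd.DataFrame({"I1": [10.0]}, index=["a"])
        slopes = pd.DataFrame(1.0, index=["I1"], columns=["rep1", "rep2", "rep3"])
        table, _ = sim.simulate_spectral_counts(conc, noise_cv=0.0, seed=0,
                                                true_slopes=slopes)
        assert list(table.index[:3]) == ["P00811", "P31658", "P31697"]
        assert np.allclose(table.iloc[:3][("I1", "rep1")], [25.0, 250.0, 2500.0])

    def test_negative_concentration_rejected(self):
        conc = pd.DataFrame({"I1": [-1.0]}, index=["a"])
        with pytest.raises(ValueError):
            sim.simulate_spectral_counts(conc, seed=0)

    def test_downstream_fit_recovers_slope_under_noise(self):
        # regression-through-origin oracle at cv = 0.05: a three-point fit
        # dominated by the largest standard has slope error on the cv
        # scale; the mean absolute relative error over replicates should
        # sit near 2*cv/sqrt(3) and each replicate within a few cv.
        from venomgland.proteomics import StandardSet, fit_all_conversion_factors

        rng = np.random.default_rng(0)
        cv = 0.05
        inds = [f"I{j}" for j in range(8)]
        conc = pd.DataFrame(
            {i: rng.uniform(5, 2000, 100) for i in inds},
            index=[f"p{k}" for k in range(100)],
        )
        slopes = pd.DataFrame(2.0, index=inds, columns=["rep1", "rep2", "rep3"])
        table, _ = sim.simulate_spectral_counts(conc, noise_cv=cv, seed=1,
                                                true_slopes=slopes)
        fitted = fit_all_conversion_factors(table, StandardSet())
        rel = np.abs(fitted.to_numpy() - 2.0) / 2.0
        assert rel.max() < 4 * cv
        assert rel.mean() < 1.5 * 2 * cv / np.sqrt(3)


def test_lineage_tree_contains_every_individual():
    cfg = small_config()
    nwk = sim.lineage_tree(cfg.resolved_factor_table())
    for ind in cfg.individuals():
        assert ind in nwk
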