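import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from deepsoma.calling import (
    GERMLINE, HET, HOM, LOH, LOW_COVERAGE, REF, SOMATIC, UNKNOWN,
    CallerParams, DegenerateTableWarning, Genotype, call_genotype,
    call_sample_set, call_unpaired, classify_paired, fisher_somatic_p,
)
from deepsoma.pileups import SiteKey, SitePileup
from deepsoma.simulate import PlantedVariant, SimConfig, simulate_aliquot_pair, simulate_pileups
from tests.conftest import exact_fisher_tail


def pile(ref="A", alt="T", depth=1000, alt_n=0, alt_fwd=None, sample="s"):
    if alt_fwd is None:
        alt_fwd = alt_n // 2
    counts = {ref: (depth - alt_n - (depth - alt_n) // 2, (depth - alt_n) // 2),
              alt: (alt_fwd, alt_n - alt_fwd)}
    return SitePileup(SiteKey("chr1", 100, ref), sample, counts)


class TestGenotype:
    @pytest.mark.parametrize("depth,alt_n,expected", [
        (1000, 8, REF),        # vaf 0.008 below the 1% floor
        (1000, 800, HOM),      # vaf 0.8 above the 75% hom cut
        (40, 20, LOW_COVERAGE),
        (1000, 300, HET),
        (1000, 1, REF),        # below min_reads2
    ])
    def test_threshold_semantics(self, depth, alt_n, expected):
        gt = call_genotype(pile(depth=depth, alt_n=alt_n), "T", CallerParams())
        assert gt.call == expected

    def test_strand_gate(self):
        params = CallerParams(min_strands2=2)
        gt = call_genotype(pile(alt_n=20, alt_fwd=20), "T", params)
        assert gt.call == REF
        gt = call_genotype(pile(alt_n=20, alt_fwd=10), "T", params)
        assert gt.call == HET

    def test_alt_equal_ref_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(pile(), "A", CallerParams())

    def test_role_selects_coverage_threshold(self):
        params = CallerParams(min_coverage_case=50, min_coverage_normal=200)
        p = pile(depth=100, alt_n=10)
        assert call_genotype(p, "T", params, role="case").call == HET
        assert call_genotype(p, "T", params, role="normal").call == LOW_COVERAGE


class TestFisher:
    def test_no_contrast_is_insignificant(self):
        assert fisher_somatic_p(990, 10, 990, 10) > 0.5

    def test_maximal_contrast_vanishes(self):
        assert fisher_somatic_p(0, 1000, 1000, 0) < 1e-100

    def test_matches_enumeration_oracle_on_spec_table(self):
        p = fisher_somatic_p(980, 20, 995, 5)
        assert abs(p - exact_fisher_tail(980, 20, 995, 5)) < 1e-12

    @given(st.integers(0, 60), st.integers(0, 60),
           st.integers(0, 60), st.integers(0, 60))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert abs(fisher_somatic_p(a, b, c, d) - exact_fisher_tail(a, b, c, d)) < 1e-12

    def test_all_zero_table_degenerate(self):
        with pytest.warns(DegenerateTableWarning):
            assert fisher_somatic_p(0, 0, 0, 0) == 1.0

    def test_p_decreases_with_depth_at_fixed_contrast(self):
        """At a fixed VAF contrast (3% vs 0%), deeper sequencing gives
        stronger evidence: p is monotone non-increasing on a depth grid."""
        ps = []
        for depth in (100, 200, 500, 1000, 2000):
            alt = int(round(depth * 0.03))
            ps.append(fisher_somatic_p(depth - alt, alt, depth, 0))
        assert all(p2 <= p1 * (1 + 1e-12) for p1, p2 in zip(ps, ps[1:]))


class TestClassifyPaired:
    def test_case_only_significant_is_somatic(self):
        assert classify_paired(Genotype(HET, 0.02), Genotype(REF, 0.0),
                               0.001, CallerParams()) == SOMATIC

    def test_both_tissues_is_germline(self):
        assert classify_paired(Genotype(HET, 0.5), Genotype(HET, 0.48),
                               0.9, CallerParams()) == GERMLINE

    def test_control_only_significant_is_loh(self):
        assert classify_paired(Genotype(REF, 0.0), Genotype(HET, 0.5),
                               0.01, CallerParams()) == LOH

    def test_insignificant_contrast_is_unknown(self):
        assert classify_paired(Genotype(HET, 0.02), Genotype(REF, 0.0),
                               0.2, CallerParams()) == UNKNOWN

    def test_low_coverage_cannot_classify(self):
        with pytest.raises(ValueError):
            classify_paired(Genotype(LOW_COVERAGE, 0.0), Genotype(HET, 0.5),
                            0.01, CallerParams())


class TestCallUnpaired:
    def test_no_alt_reads_no_call(self):
        assert call_unpaired(pile(alt_n=0), CallerParams()) == []

    def test_three_percent_variant_significant_at_low_error(self):
        calls = call_unpaired(pile(alt_n=30), CallerParams(error_rate=0.001))
        assert len(calls) == 1
        assert calls[0].p_somatic < 0.05
        assert calls[0].status == UNKNOWN

    def test_variant_at_error_rate_not_significant(self):
        calls = call_unpaired(pile(alt_n=30), CallerParams(error_rate=0.03))
        assert len(calls) == 1
        assert calls[0].p_somatic >= 0.05


class TestCallSampleSet:
    def _planted(self, seed=101, vaf=0.05, n_sites=100):
        probe, _ = simulate_pileups(
            SimConfig(n_sites=n_sites, samples=("case", "ctrl"), seed=seed))
        alt = "C" if probe.site_key(30).ref != "C" else "G"
        cfg = SimConfig(
            n_sites=n_sites, samples=("case", "ctrl"), error_rate=0.0,
            germline_het_rate=0.05, germline_hom_rate=0.02, seed=seed,
            somatic_plants=[PlantedVariant(30, alt, vaf, ("case",))])
        return simulate_pileups(cfg), alt

    def test_planted_somatic_called_somatic(self):
        (pileup, truth), alt = self._planted()
        calls = call_sample_set(pileup, "case", ("ctrl",), CallerParams())
        som = [c for c in calls if c.status == SOMATIC]
        assert len(som) == 1
        assert som[0].key.pos == int(pileup.sites["pos"][30]) and som[0].alt == alt

    def test_germline_never_somatic(self):
        (pileup, truth), _ = self._planted()
        calls = call_sample_set(pileup, "case", ("ctrl",), CallerParams())
        het_pos = set(truth[truth["klass"].str.startswith("germline")]["pos"])
        for c in calls:
            if c.key.pos in het_pos:
                assert c.status == GERMLINE

    def test_aliquot_null_has_no_somatic_calls(self):
        cfg = SimConfig(n_sites=2000, germline_het_rate=0.02, error_rate=0.0,
                        seed=77)
        pileup, _ = simulate_aliquot_pair(cfg)
        a, b = pileup.samples
        calls = call_sample_set(pileup, a, (b,), CallerParams())
        assert all(c.status not in (SOMATIC, LOH) for c in calls)

    def test_case_control_swap_maps_somatic_to_loh(self):
        (pileup, _), alt = self._planted()
        fwd = call_sample_set(pileup, "case", ("ctrl",), CallerParams())
        rev = call_sample_set(pileup, "ctrl", ("case",), CallerParams())
        som_sites = {(c.key.pos, c.alt) for c in fwd if c.status == SOMATIC}
        loh_sites = {(c.key.pos, c.alt) for c in rev if c.status == LOH}
        assert som_sites and som_sites == loh_sites

    def test_three_way_design(self):
        probe, _ = simulate_pileups(
            SimConfig(n_sites=60, samples=("case", "c1", "c2"), seed=5))
        alt = "C" if probe.site_key(10).ref != "C" else "G"
        cfg = SimConfig(n_sites=60, samples=("case", "c1", "c2"),
                        error_rate=0.0, germline_het_rate=0.1, seed=5,
                        somatic_plants=[PlantedVariant(10, alt, 0.05, ("case",))])
        pileup, _ = simulate_pileups(cfg)
        calls = call_sample_set(pileup, "case", ("c1", "c2"), CallerParams())
        som = [c for c in calls if c.status == SOMATIC]
        assert [c.key.pos for c in som] == [int(pileup.sites["pos"][10])]
        # plant shared with one control reads as germline
        cfg2 = dataclasses.replace(
            cfg, somatic_plants=[PlantedVariant(10, alt, 0.3, ("case", "c1"))])
        pileup2, _ = simulate_pileups(cfg2)
        calls2 = call_sample_set(pileup2, "case", ("c1", "c2"), CallerParams())
        at_site = [c for c in calls2 if c.key.pos == int(pileup2.sites["pos"][10])]
        assert at_site and all(c.status == GERMLINE for c in at_site)

    def test_missing_design_sample_rejected(self):
        (pileup, _), _ = self._planted()
        with pytest.raises(KeyError):
            call_sample_set(pileup, "case", ("nope",), CallerParams())

    def test_type_one_error_controlled_before_cascade(self):
        """On null data (no somatic truth), the pre-cascade SOMATIC rate per
        examined site stays within the nominal significance level + 3 sigma."""
        n_sites, n_rep = 5000, 4
        total_som, total_sites = 0, 0
        for seed in range(n_rep):
            cfg = SimConfig(n_sites=n_sites, error_rate=0.001,
                            germline_het_rate=0.0, germline_hom_rate=0.0,
                            seed=300 + seed)
            pileup, _ = simulate_aliquot_pair(cfg)
            a, b = pileup.samples
            calls = call_sample_set(pileup, a, (b,), CallerParams())
            total_som += sum(1 for c in calls if c.status in (SOMATIC, LOH))
            total_sites += n_sites
        alpha = CallerParams().somatic_p_value
        bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / total_sites)
        assert total_som / total_sites <= bound
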