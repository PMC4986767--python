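import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from deepsoma.calling import LOH, SOMATIC, UNKNOWN, CallerParams, call_sample_set
from deepsoma.filters import (
    FilterConfig, call_id, control_absence_filter, depth_filter,
    frequency_window_filter, read_evidence_filter, recurrence_artifact_filter,
    run_cascade, strand_filter,
)
from deepsoma.pileups import ReadEvidence, SiteKey, SitePileup
from deepsoma.simulate import PlantedVariant, SimConfig, simulate_aliquot_pair, simulate_pileups
from tests.conftest import make_call


def ctrl_pileup(alt="T", alt_n=0, depth=1000):
    counts = {"A": (depth - alt_n, 0), alt: (alt_n, 0)}
    return SitePileup(SiteKey("chr1", 100, "A"), "ctrl", counts)


class TestDepthFilter:
    @pytest.mark.parametrize("case_d,ctrl_d,n_ctrl,ok", [
        (300, (300,), 1, True),    # inclusive two-way minimum
        (299, (300,), 1, False),
        (300, (299,), 1, False),
        (250, (300, 300), 2, True),  # three-way case minimum drops to 250
        (249, (300, 300), 2, False),
        (250, (300, 299), 2, False),
    ])
    def test_paired_thresholds(self, case_d, ctrl_d, n_ctrl, ok):
        c = make_call(depth_case=case_d, depth_controls=ctrl_d,
                      controls=("c",) * n_ctrl, alt_controls=((0, 0),) * n_ctrl)
        got, obs, thr = depth_filter(c, FilterConfig(), n_controls=n_ctrl)
        assert got is ok

    def test_failure_audit_names_limiting_depth(self):
        c = make_call(depth_case=299, depth_controls=(400,))
        ok, obs, thr = depth_filter(c, FilterConfig(), 1)
        assert (ok, obs, thr) == (False, 299.0, 300.0)

    @pytest.mark.parametrize("depth,ok", [(301, True), (300, False)])
    def test_unpaired_depth_is_strict(self, depth, ok):
        c = make_call(depth_case=depth, controls=(), depth_controls=(),
                      alt_controls=())
        assert depth_filter(c, FilterConfig(), 0, unpaired=True)[0] is ok


class TestStrandFilter:
    @pytest.mark.parametrize("fwd,rev,ok", [
        (4, 4, True), (10, 3, False), (3, 10, False), (0, 0, False), (5, 9, True),
    ])
    def test_four_reads_per_strand_inclusive(self, fwd, rev, ok):
        c = make_call(alt_fwd=fwd, alt_rev=rev)
        assert strand_filter(c, FilterConfig())[0] is ok


class TestControlAbsence:
    def test_clean_controls_pass(self):
        c = make_call()
        ok, obs, _ = control_absence_filter(c, [ctrl_pileup(alt_n=0)], FilterConfig())
        assert ok and obs == 0

    def test_single_alt_read_fails_by_default(self):
        c = make_call()
        ok, obs, _ = control_absence_filter(c, [ctrl_pileup(alt_n=1)], FilterConfig())
        assert not ok and obs == 1

    def test_relaxed_threshold_tolerates_error_reads(self):
        cfg = FilterConfig(control_absence_max_alt_reads=2)
        c = make_call()
        assert control_absence_filter(c, [ctrl_pileup(alt_n=1)], cfg)[0]
        assert not control_absence_filter(c, [ctrl_pileup(alt_n=3)], cfg)[0]

    def test_missing_control_fails(self):
        ok, obs, _ = control_absence_filter(make_call(), [None], FilterConfig())
        assert not ok and math.isinf(obs)


class TestFrequencyWindow:
    @pytest.mark.parametrize("vaf,ok", [(0.39, True), (0.40, False), (0.03, True)])
    def test_strictly_below_screening_window(self, vaf, ok):
        c = make_call(vaf_case=vaf)
        assert frequency_window_filter(c, FilterConfig())[0] is ok

    def test_reporting_window_knob(self):
        c = make_call(vaf_case=0.30)
        cfg = FilterConfig()
        assert frequency_window_filter(c, cfg)[0]
        assert not frequency_window_filter(c, cfg, window=cfg.report_unpaired_freq)[0]


class TestRecurrence:
    def test_variant_in_most_samples_flagged_everywhere(self):
        calls = [make_call(sample=f"s{i}", pos=41354661, vaf_case=0.03)
                 for i in range(35)]
        calls += [make_call(sample=f"u{i}", pos=999, vaf_case=0.03)
                  for i in range(1)]
        flagged = recurrence_artifact_filter(calls, FilterConfig())
        assert ("chr1", 41354661, "A", "T") in flagged
        assert ("chr1", 999, "A", "T") not in flagged

    def test_boundary_below_min_samples_not_flagged(self):
        cfg = FilterConfig()
        calls = [make_call(sample=f"s{i}", vaf_case=0.03)
                 for i in range(cfg.recurrence_min_samples - 1)]
        assert recurrence_artifact_filter(calls, cfg) == set()
        calls.append(make_call(sample="one_more", vaf_case=0.03))
        assert len(recurrence_artifact_filter(calls, cfg)) == 1

    def test_high_vaf_recurrence_is_not_an_artifact(self):
        # a germline SNP present at 50% in every sample is not flagged
        calls = [make_call(sample=f"s{i}", vaf_case=0.5) for i in range(30)]
        assert recurrence_artifact_filter(calls, FilterConfig()) == set()


def clean_read(strand="+"):
    return ReadEvidence(0, 30, math.inf, 35, 60, strand)


def dirty_read(strand="+", mismatches=4, dist_end=30, dist_indel=math.inf):
    return ReadEvidence(mismatches, dist_end, dist_indel, 35, 60, strand)


class TestReadEvidence:
    def test_clean_support_passes(self):
        ev = [clean_read("+")] * 5 + [clean_read("-")] * 5
        ok, obs, thr, flags = read_evidence_filter(make_call(), ev, FilterConfig())
        assert ok and flags == []

    def test_all_reads_with_many_mismatches_fail(self):
        ev = [dirty_read("+")] * 6 + [dirty_read("-")] * 6
        ok, *_ = read_evidence_filter(make_call(), ev, FilterConfig())
        assert not ok

    def test_mixed_support_survives_removal(self):
        ev = ([clean_read("+")] * 4 + [clean_read("-")] * 4
              + [dirty_read("+"), dirty_read("-", dist_end=2),
                 dirty_read("+", mismatches=0, dist_indel=5)])
        ok, obs, *_ = read_evidence_filter(make_call(), ev, FilterConfig())
        assert ok and obs == 4

    @pytest.mark.parametrize("kw", [
        dict(mismatches=4), dict(dist_end=5), dict(dist_indel=10)])
    def test_each_discard_rule_inclusive_boundary(self, kw):
        ev = [dirty_read(s, **{**dict(mismatches=0), **kw})
              for s in ("+",) * 4 + ("-",) * 4]
        ok, obs, *_ = read_evidence_filter(make_call(), ev, FilterConfig())
        assert not ok and obs == 0

    def test_no_evidence_passes_flagged(self):
        ok, _, _, flags = read_evidence_filter(make_call(), None, FilterConfig())
        assert ok and flags == ["NO_EVIDENCE"]


class TestRunCascade:
    def test_empty_input(self):
        surv, audit = run_cascade([], None, FilterConfig())
        assert surv == [] and audit.to_frame().empty

    def test_planted_variant_survives_paired_criteria(self):
        probe, _ = simulate_pileups(SimConfig(n_sites=80, samples=("case", "ctrl"), seed=55))
        alt = "C" if probe.site_key(20).ref != "C" else "G"
        cfg = SimConfig(n_sites=80, samples=("case", "ctrl"), error_rate=0.0,
                        germline_het_rate=0.05, seed=55, attach_evidence=True,
                        somatic_plants=[PlantedVariant(20, alt, 0.03, ("case",))])
        pileup, _ = simulate_pileups(cfg)
        calls = call_sample_set(pileup, "case", ("ctrl",), CallerParams())
        surv, audit = run_cascade(calls, pileup, FilterConfig(), mode="paired")
        assert [(c.key.pos, c.alt) for c in surv] == [(int(pileup.sites["pos"][20]), alt)]
        # audit is complete: every call audited on every applicable filter
        df = audit.to_frame()
        assert set(df["call_id"]) == {call_id(c) for c in calls}

    def test_aliquot_null_yields_zero_survivors(self):
        cfg = SimConfig(n_sites=5000, error_rate=0.001, germline_het_rate=0.02,
                        seed=303)
        pileup, _ = simulate_aliquot_pair(cfg)
        a, b = pileup.samples
        calls = call_sample_set(pileup, a, (b,), CallerParams())
        surv, _ = run_cascade(calls, pileup, FilterConfig(), mode="paired")
        assert surv == []

    def test_unpaired_mode_gates_on_p_and_window(self):
        keep = make_call(controls=(), depth_controls=(), alt_controls=(),
                         depth_case=1000, alt_fwd=15, alt_rev=15, p=0.001,
                         status=UNKNOWN)
        too_frequent = make_call(pos=200, controls=(), depth_controls=(),
                                 alt_controls=(), depth_case=1000,
                                 alt_fwd=225, alt_rev=225, p=1e-30,
                                 status=UNKNOWN)
        insignificant = make_call(pos=300, controls=(), depth_controls=(),
                                  alt_controls=(), depth_case=1000,
                                  alt_fwd=15, alt_rev=15, p=0.2,
                                  status=UNKNOWN)
        surv, _ = run_cascade([keep, too_frequent, insignificant], None,
                              FilterConfig(), mode="unpaired")
        assert surv == [keep]
        assert too_frequent.filters_failed == ["frequency_window"]
        assert insignificant.filters_failed == ["status_gate"]

    @given(st.lists(
        st.tuples(st.integers(0, 3),          # sample index
                  st.integers(0, 5),          # site index
                  st.integers(200, 1200),     # case depth
                  st.integers(200, 1200),     # control depth
                  st.integers(0, 30),         # alt fwd
                  st.integers(0, 30),         # alt rev
                  st.integers(0, 2),          # control alt reads
                  st.sampled_from([SOMATIC, LOH, "GERMLINE", UNKNOWN]),
                  st.floats(1e-6, 1.0)),      # p
        max_size=25))
    def test_monotone_and_idempotent_on_random_call_sets(self, rows):
        calls = [make_call(sample=f"s{si}", pos=100 + 50 * pi, depth_case=dc,
                           depth_controls=(dn,), alt_fwd=af, alt_rev=ar,
                           alt_controls=((ca, 0),), p=p, status=stat)
                 for si, pi, dc, dn, af, ar, ca, stat, p in rows]
        surv, audit = run_cascade(calls, None, FilterConfig(), mode="paired")
        assert set(map(id, surv)) <= set(map(id, calls))
        surv2, _ = run_cascade(list(surv), None, FilterConfig(), mode="paired")
        assert [call_id(c) for c in surv2] == [call_id(c) for c in surv]

    def test_pass_set_insensitive_to_call_order(self):
        calls = [make_call(sample=f"s{i}", pos=100 + 10 * i,
                           alt_fwd=3 + i, alt_rev=9 - i,
                           depth_case=280 + 10 * i, p=0.01)
                 for i in range(6)]
        surv_a, _ = run_cascade(list(calls), None, FilterConfig())
        surv_b, _ = run_cascade(list(reversed(calls)), None, FilterConfig())
        assert {call_id(c) for c in surv_a} == {call_id(c) for c in surv_b}

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            run_cascade([], None, FilterConfig(), mode="sideways")
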