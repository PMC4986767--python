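import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deepsoma.calling import VariantCall
from deepsoma.pileups import SiteKey

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_call(pos=100, ref="A", alt="T", sample="case", controls=("ctrl",),
              depth_case=1000, depth_controls=(1000,), alt_fwd=10, alt_rev=10,
              alt_controls=((0, 0),), vaf_case=None, vaf_control=0.0,
              p=0.001, status="SOMATIC", chrom="chr1"):
    """Factory for hand-built variant calls in filter tests."""
    if vaf_case is None:
        vaf_case = (alt_fwd + alt_rev) / depth_case
    return VariantCall(
        key=SiteKey(chrom, pos, ref), alt=alt, sample_case=sample,
        samples_control=tuple(controls), depth_case=depth_case,
        depth_controls=tuple(depth_controls), alt_fwd_case=alt_fwd,
        alt_rev_case=alt_rev, alt_controls=tuple(alt_controls),
        vaf_case=vaf_case, vaf_control=vaf_control, p_somatic=p, status=status,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def exact_fisher_tail(case_ref, case_alt, ctrl_ref, ctrl_alt):
    """Independent oracle: one-sided Fisher p by brute-force enumeration of
    the hypergeometric tail in exact integer arithmetic (correctly rounded
    float on the final division)."""
    import math
    N = case_ref + case_alt + ctrl_ref + ctrl_alt
    if N == 0:
        return 1.0
    K = case_alt + ctrl_alt
    n = case_ref + case_alt
    num = 0
    for k in range(case_alt, min(K, n) + 1):
        if n - k > N - K:
            continue
        num += math.comb(K, k) * math.comb(N - K, n - k)
    return num / math.comb(N, n)
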