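import re

import pytest
from hypothesis import HealthCheck, settings

import lirscan

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Independent re-scan mechanism: overlapping regex over the raw sequence,
# used to cross-check the scanner's per-core iteration.
CORE_RE = re.compile(r"(?=([WFY])..([ILV]))")


def naive_scan(seq: str):
    """Every core occurrence found by regex lookahead; (start, end, window,
    pattern_class, truncated) with 1-based inclusive coordinates."""
    hits = []
    for m in CORE_RE.finditer(seq):
        i = m.start()
        w_start = max(0, i - 2)
        window = seq[w_start : i + 4]
        if not set(window) <= set(lirscan.AMINO_ACIDS):
            continue
        truncated = i < 2
        if truncated:
            pclass = "WxxL"
        else:
            pclass = "xLIR" if lirscan.matches_xlir(window) else "WxxL"
        hits.append((w_start + 1, i + 4, window, pclass, truncated))
    return hits


@pytest.fixture(scope="session")
def pattern():
    return lirscan.default_pattern()


@pytest.fixture(scope="session")
def default_pssm():
    return lirscan.build_pssm(lirscan.load_training_set())
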