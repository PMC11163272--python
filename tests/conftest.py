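import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def lcs_bruteforce(a: str, b: str) -> int:
    """Independent longest-common-contiguous-substring oracle (classic DP)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def acg_paircount(spike_bins, max_lag=50):
    """Ordered-pair counting oracle for the autocorrelogram."""
    import numpy as np

    bins = sorted(set(int(b) for b in spike_bins))
    counts = np.zeros(max_lag, dtype=int)
    for i, a in enumerate(bins):
        for b in bins[i + 1 :]:
            lag = b - a
            if lag > max_lag:
                break
            counts[lag - 1] += 1
    return counts
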