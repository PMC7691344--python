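import math

import numpy as np
import pytest

from ripwob.core import AnalysisWindow

# ---------------------------------------------------------------------------
# Independent brute-force oracles. These deliberately use plain Python loops
# and math, not the package's vectorised paths, so agreement with the
# implementation is meaningful.
# ---------------------------------------------------------------------------


def phase_oracle_deg(x, y) -> float:
    """Normalized-inner-product phase angle via explicit sums."""
    x = list(map(float, x))
    y = list(map(float, y))
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    c = sxy / math.sqrt(sxx * syy)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def excursion_oracle(x) -> float:
    """Peak-to-peak after removing the line through the window endpoints."""
    x = list(map(float, x))
    n = len(x)
    resid = [x[i] - (x[0] + (x[-1] - x[0]) * i / (n - 1)) for i in range(n)]
    return max(resid) - min(resid)


def lbi_oracle(x, y) -> float:
    a_rc = excursion_oracle(x)
    a_ab = excursion_oracle(y)
    a_sum = excursion_oracle([xi + yi for xi, yi in zip(x, y)])
    return (a_rc + a_ab) / a_sum


def rc_percent_oracle(x, y) -> float:
    a_rc = excursion_oracle(x)
    a_ab = excursion_oracle(y)
    return 100.0 * a_rc / (a_rc + a_ab)


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def sine_window(n=20, periods=1.0, phase_deg=0.0, amp=1.0, offset=0.0):
    """Sinusoid sampled over ``periods`` full cycles at n points."""
    t = np.arange(n) / n
    return amp * np.sin(2 * np.pi * periods * t - math.radians(phase_deg)) + offset


def lagged_pair(n=20, periods=1.0, lag_deg=0.0, amp_x=1.0, amp_y=1.0):
    """Equal-frequency sinusoid pair with y lagging x by lag_deg."""
    x = sine_window(n, periods, 0.0, amp_x)
    y = sine_window(n, periods, lag_deg, amp_y)
    return AnalysisWindow(x, y)
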