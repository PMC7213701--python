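"""Independent brute-force re-implementations used as test oracles.

Pure-Python loops with no code shared with the package: grid construction,
exponential evaluation, trapezoidal mean, band selection and median are all
written from first principles so agreement with the package is meaningful.
"""

import math


def brute_force_t_end(rr_ms: float, interpretation: str, dt_ms: float = 1.0) -> float:
    """Full curve -> band constant -> open-band median chain, by exhaustive scan.

    Raises ValueError when the band selects no sample or collapses onto the
    R peak (median time <= 0), mirroring the estimator's no-estimate cases.
    """
    n = math.ceil(rr_ms / dt_ms)
    ts = [i * dt_ms for i in range(n) if i * dt_ms < rr_ms]
    vals = [100.0 * math.exp(-2.0 * math.pi * t / rr_ms) for t in ts]
    # trapezoidal mean over [0, RR], closing the last interval with the
    # analytic endpoint value 100*e^(-2*pi)
    integral = 0.0
    for i in range(len(ts) - 1):
        integral += 0.5 * (vals[i] + vals[i + 1]) * (ts[i + 1] - ts[i])
    end_value = 100.0 * math.exp(-2.0 * math.pi)
    integral += 0.5 * (vals[-1] + end_value) * (rr_ms - ts[-1])
    mean = integral / rr_ms

    x = 1000.0 / rr_ms
    if interpretation == "quotient":
        k = abs(mean / x - 6.0 * math.pi * x * x)
    elif interpretation == "product":
        k = abs(mean * x - 6.0 * math.pi * x * x)
    else:
        raise ValueError(f"unknown interpretation {interpretation!r}")

    selected = [t for t, v in zip(ts, vals) if k - 0.5 < v < k + 1.0]
    if not selected:
        raise ValueError("empty band")
    m = len(selected)
    if m % 2:
        med = selected[m // 2]
    else:
        med = 0.5 * (selected[m // 2 - 1] + selected[m // 2])
    if med <= 0:
        raise ValueError("band at R peak")
    return med
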