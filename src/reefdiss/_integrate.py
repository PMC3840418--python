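"""Fixed-step classical 4th-order Runge–Kutta shared by the sea-level and reef models."""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["rk4_path"]


def rk4_path(
    rhs: Callable[[float, float], float],
    y0: float,
    report_times: np.ndarray,
    step: float,
) -> np.ndarray:
    """Integrate ``dy/dt = rhs(t, y)`` from ``report_times[0]`` with fixed step ``step``.

    Returns ``y`` sampled at ``report_times``.  Each reporting interval is cut
    into an integer number of sub-steps no longer than ``step``, so the grid
    always lands exactly on the reporting times.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    times = np.asarray(report_times, dtype=float)
    out = np.empty_like(times)
    out[0] = y = float(y0)
    t = times[0]
    for i in range(1, times.size):
        span = times[i] - t
        n_sub = max(1, int(np.ceil(span / step - 1e-12)))
        h = span / n_sub
        for _ in range(n_sub):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        t = times[i]
        out[i] = y
    return out
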