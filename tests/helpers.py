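"""Independent oracles shared between the unit and acceptance suites."""

import numpy as np

from erstress import sensing as sn


def brute_force_equilibrium(sys: sn.SensorSystem, iters: int = 200):
    """Nested interval bisection on the conservation residuals, which are
    monotone in the free concentrations.  Independent of the package's
    damped fixed-point/Newton solver."""

    def free_b_given_c(C):
        lo, hi = 0.0, sys.B_tot
        for _ in range(iters):
            mid = (lo + hi) / 2
            T = sys.T_tot / (1 + mid / sys.K_TB + C / sys.K_TC)
            if mid * (1 + T / sys.K_TB + C / sys.K_BC) - sys.B_tot > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    lo, hi = 0.0, sys.C_tot
    for _ in range(iters):
        mid = (lo + hi) / 2
        B = free_b_given_c(mid)
        T = sys.T_tot / (1 + B / sys.K_TB + mid / sys.K_TC)
        if mid * (1 + T / sys.K_TC + B / sys.K_BC) - sys.C_tot > 0:
            hi = mid
        else:
            lo = mid
    C = (lo + hi) / 2
    return free_b_given_c(C), C


def robust_z_oracle(values: np.ndarray) -> np.ndarray:
    """Asymmetric percentile z-scores of one intensity bin, assembled from
    first principles (sorting and linear interpolation by hand)."""
    values = np.asarray(values, float)
    srt = np.sort(values)
    n = srt.size

    def interp_percentile(q):
        pos = q / 100.0 * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

    med = interp_percentile(50.0)
    up_w = interp_percentile(84.13) - med
    dn_w = med - interp_percentile(15.87)
    out = np.empty(n)
    for i, v in enumerate(values):
        dev = v - med
        out[i] = dev / up_w if dev >= 0 else dev / dn_w
    return out
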