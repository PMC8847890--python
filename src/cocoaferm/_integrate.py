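"""Numba-compiled ODE core: full-model right-hand side and integrators.

The fermentation posterior requires on the order of 1e5 trajectory solves
per fit, so the right-hand side and the adaptive Dormand–Prince 5(4)
stepper are compiled with numba.  The parameter vector ``p`` is always the
full 43-entry vector in canonical table order; variants are expressed by
zeroing the entries of inactive mechanisms, which removes their rates
identically.

Index layout of ``p`` (kept in sync with ``model_core.PARAMETER_TABLE``;
a unit test asserts agreement between this kernel and the pure-python
reference right-hand side):

    0-7   mu:    Y_Glc, Y_Fru, Y_LA, LAB_Glc, LAB_Fru, AAB_EtOH, AAB_LA, AAB_Ac
    8-15  K:     same order as mu
    16-18 k:     Y, LAB, AAB
    19-39 yields (table order)
    40-42 b:     EtOH, LA, Ac
"""

import numpy as np
from numba import njit

STATUS_MESSAGES = {
    0: "ok",
    1: "maximum number of steps exceeded",
    2: "non-finite state encountered",
    3: "state became negative beyond tolerance",
    4: "step size underflow",
}


@njit(cache=True)
def rhs_full(y, p):
    Glc, Fru, EtOH, LA, Ac, Y, LAB, AAB = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7],
    )

    # Monod / Contois growth rates; a depleted (or undershot) substrate
    # contributes no growth.
    v1 = p[0] * Glc / (Glc + p[8]) * Y if Glc > 0.0 else 0.0
    v2 = p[1] * Fru / (Fru + p[9]) * Y if Fru > 0.0 else 0.0
    v3 = p[3] * Glc / (Glc + p[11]) * LAB if Glc > 0.0 else 0.0
    v4 = p[5] * EtOH / (EtOH + p[13]) * AAB if EtOH > 0.0 else 0.0
    v5 = p[6] * LA / (LA + p[14] * AAB) * AAB if LA > 0.0 and AAB > 0.0 else 0.0
    v9 = p[4] * Fru / (Fru + p[12]) * LAB if Fru > 0.0 else 0.0
    v10 = p[2] * LA / (LA + p[10]) * Y if LA > 0.0 else 0.0
    v11 = p[7] * Ac / (Ac + p[15]) * AAB if Ac > 0.0 else 0.0

    # Chick-Watson mortality (second/third order overall).
    v6 = p[16] * Y * EtOH if EtOH > 0.0 else 0.0
    v7 = p[17] * LAB * LA if LA > 0.0 else 0.0
    v8 = p[18] * AAB * Ac * Ac

    # First-order decay.
    d1 = p[40] * EtOH
    d2 = p[41] * LA
    d3 = p[42] * Ac

    out = np.empty(8)
    out[0] = -p[19] * v1 - p[20] * v3
    out[1] = -p[21] * v2 - p[22] * v9
    out[2] = (
        p[23] * v1 + p[24] * v2 + p[25] * v10 + p[26] * v3 + p[27] * v9
        - p[28] * v4 - d1
    )
    out[3] = p[29] * v3 + p[30] * v9 - p[31] * v5 - p[32] * v10 - d2
    out[4] = (
        p[33] * v3 + p[34] * v9 + p[35] * v4 + p[36] * v5
        + p[37] * v1 + p[38] * v2 - p[39] * v11 - d3
    )
    out[5] = v1 + v2 + v10 - v6
    out[6] = v3 + v9 - v7
    out[7] = v4 + v5 + v11 - v8
    return out


@njit(cache=True)
def dp45_integrate(p, y0, t_eval, rtol, atol, max_steps, neg_slack):
    """Adaptive Dormand–Prince 5(4) integration with dense hits at t_eval.

    Returns (trajectory, status, t_fail).  The stepper lands exactly on
    each requested output time by capping the step; after every accepted
    step, components in [-neg_slack*atol, 0) are projected to 0 and larger
    negatives abort with status 3.
    """
    n_out = t_eval.shape[0]
    out = np.zeros((n_out, 8))
    out[0] = y0

    t = t_eval[0]
    y = y0.copy()
    k1 = rhs_full(y, p)
    h = (t_eval[n_out - 1] - t) / 100.0
    if h <= 0.0:
        h = 1e-3
    n_steps = 0
    idx = 1

    while idx < n_out:
        t_target = t_eval[idx]
        while t < t_target:
            if n_steps >= max_steps:
                return out, 1, t
            hit = False
            if t + h >= t_target:
                h_step = t_target - t
                hit = True
            else:
                h_step = h

            # Dormand-Prince stages (FSAL: k1 carried over).
            k2 = rhs_full(y + h_step * (0.2 * k1), p)
            k3 = rhs_full(y + h_step * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2), p)
            k4 = rhs_full(
                y + h_step * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2 + 32.0 / 9.0 * k3), p
            )
            k5 = rhs_full(
                y
                + h_step
                * (
                    19372.0 / 6561.0 * k1
                    - 25360.0 / 2187.0 * k2
                    + 64448.0 / 6561.0 * k3
                    - 212.0 / 729.0 * k4
                ),
                p,
            )
            k6 = rhs_full(
                y
                + h_step
                * (
                    9017.0 / 3168.0 * k1
                    - 355.0 / 33.0 * k2
                    + 46732.0 / 5247.0 * k3
                    + 49.0 / 176.0 * k4
                    - 5103.0 / 18656.0 * k5
                ),
                p,
            )
            y_new = y + h_step * (
                35.0 / 384.0 * k1
                + 500.0 / 1113.0 * k3
                + 125.0 / 192.0 * k4
                - 2187.0 / 6784.0 * k5
                + 11.0 / 84.0 * k6
            )
            k7 = rhs_full(y_new, p)

            # embedded 4th-order error estimate
            err_norm = 0.0
            for i in range(8):
                e = h_step * (
                    71.0 / 57600.0 * k1[i]
                    - 71.0 / 16695.0 * k3[i]
                    + 71.0 / 1920.0 * k4[i]
                    - 17253.0 / 339200.0 * k5[i]
                    + 22.0 / 525.0 * k6[i]
                    - 1.0 / 40.0 * k7[i]
                )
                ymax = max(abs(y[i]), abs(y_new[i]))
                sc = atol + rtol * ymax
                err_norm += (e / sc) ** 2
            err_norm = np.sqrt(err_norm / 8.0)
            n_steps += 1

            if not np.isfinite(err_norm):
                return out, 2, t

            if err_norm <= 1.0:
                # accept
                t = t + h_step
                y = y_new
                k1 = k7
                for i in range(8):
                    if y[i] < 0.0:
                        if y[i] >= -neg_slack * atol:
                            y[i] = 0.0
                        else:
                            return out, 3, t
                if err_norm == 0.0:
                    factor = 5.0
                else:
                    factor = min(5.0, max(0.2, 0.9 * err_norm ** -0.2))
                if not hit:
                    h = h_step * factor
                else:
                    h = max(h, h_step) * factor
            else:
                h = h_step * max(0.2, 0.9 * err_norm ** -0.2)
                if h < 1e-14 * max(1.0, abs(t)):
                    return out, 4, t

        out[idx] = y
        idx += 1

    return out, 0, t



@njit(cache=True)
def rk4_fixed(p, y0, t_eval, h):
    """Classic fixed-step RK4 at step h, hitting every output time exactly.

    Independent of the adaptive stepper; used as a brute-force oracle.
    """
    n_out = t_eval.shape[0]
    out = np.zeros((n_out, 8))
    out[0] = y0
    y = y0.copy()
    t = t_eval[0]
    for idx in range(1, n_out):
        t_target = t_eval[idx]
        while t < t_target - 1e-12:
            h_step = min(h, t_target - t)
            k1 = rhs_full(y, p)
            k2 = rhs_full(y + 0.5 * h_step * k1, p)
            k3 = rhs_full(y + 0.5 * h_step * k2, p)
            k4 = rhs_full(y + h_step * k3, p)
            y = y + h_step / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h_step
        out[idx] = y
        t = t_target
    return out
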