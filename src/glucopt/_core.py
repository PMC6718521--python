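"""Compiled numerical kernels for the 8-state glucose-insulin-incretin ODE.

State vector layout (fixed, shared by every routine here):

    0 IntestG [g]    glucose in the intestinal lumen
    1 GIP     [pM]   intact GIP
    2 GLP1    [pM]   intact GLP-1 (held at 0 for GLP-1-free structures)
    3 AGutG   [g]    glucose absorbed from the gut, pre-appearance
    4 G       [mg/dL] blood glucose
    5 I       [pM]   insulin
    6 CP      [pM]   C-peptide
    7 X       [-]    effective insulin at target organs (dimensionless)

Parameter vector layout (24 entries): the 18 estimated kinetic parameters
followed by the 6 closure-derived quantities::

    0 k2   1 k3   2 k4   3 k5   4 k6   5 k7   6 k8   7 k10
    8 L2   9 L4  10 L6  11 L8  12 L11 13 V
   14 a   15 b  16 c   17 d
   18 k9  19 k11 20 k12 21 k13 22 GIP_B 23 GLP1_B

GLP-1-free model variants are integrated on the same padded vector with
k4 = k5 = 0, GLP1(0) = 0 and c = d = 0, which makes the GLP-1 row
identically zero; the public API strips that column.
"""

import numpy as np
from numba import njit

N_STATES = 8
N_PARAMS = 24

# state indices
IDX_INTESTG, IDX_GIP, IDX_GLP1, IDX_AGUTG, IDX_G, IDX_I, IDX_CP, IDX_X = range(8)

EULER = 0
RK4 = 1


@njit(cache=True, error_model="numpy")
def flux_at(t, starts, ends, rates):
    """Piecewise-constant ingestion flux [g/min]; windows are half-open."""
    for j in range(starts.shape[0]):
        if starts[j] <= t < ends[j]:
            return rates[j]
    return 0.0


@njit(cache=True, error_model="numpy")
def fluxes(y, p, gflux, out):
    """Evaluate the 13 model fluxes v1..v13 into out (length 13)."""
    ig = y[IDX_INTESTG]
    gip = y[IDX_GIP]
    glp1 = y[IDX_GLP1]
    ag = y[IDX_AGUTG]
    g = y[IDX_G]
    i = y[IDX_I]
    cp = y[IDX_CP]
    x = y[IDX_X]

    out[0] = gflux                                   # v1: ingestion
    out[1] = p[0] * ig / (p[8] + ig)                 # v2: GIP secretion
    out[2] = p[1] * (p[22] - gip)                    # v3: GIP relaxation to basal
    out[3] = p[2] * ig / (p[9] + ig)                 # v4: GLP-1 secretion
    out[4] = p[3] * (p[23] - glp1)                   # v5: GLP-1 relaxation to basal
    out[5] = p[4] * ig / (p[10] + ig)                # v6: gut absorption
    out[6] = p[5] * ag                               # v7: appearance in blood
    out[7] = p[6] / (p[11] + x)                      # v8: hepatic production (inhibited by X)
    out[8] = p[18] * g * x                           # v9: insulin-dependent uptake
    # v10: secretion, glucose plus independent/cooperative incretin terms
    out[9] = p[7] * (g + p[14] * gip + p[15] * g * gip + p[16] * glp1 + p[17] * g * glp1)
    out[10] = p[19] * i / (p[12] + i)                # v11: insulin flow to target organs
    out[11] = p[20] * cp                             # v12: C-peptide clearance
    out[12] = p[21] * x                              # v13: effective-insulin turnover


@njit(cache=True, error_model="numpy", inline="always")
def _deriv(y, p, gflux, dy):
    """Allocation-free state derivative (hot path of the integrators)."""
    ig = y[IDX_INTESTG]
    gip = y[IDX_GIP]
    glp1 = y[IDX_GLP1]
    g = y[IDX_G]
    i = y[IDX_I]
    x = y[IDX_X]
    v2 = p[0] * ig / (p[8] + ig)
    v3 = p[1] * (p[22] - gip)
    v4 = p[2] * ig / (p[9] + ig)
    v5 = p[3] * (p[23] - glp1)
    v6 = p[4] * ig / (p[10] + ig)
    v7 = p[5] * y[IDX_AGUTG]
    v8 = p[6] / (p[11] + x)
    v9 = p[18] * g * x
    v10 = p[7] * (g + p[14] * gip + p[15] * g * gip + p[16] * glp1 + p[17] * g * glp1)
    v11 = p[19] * i / (p[12] + i)
    v12 = p[20] * y[IDX_CP]
    v13 = p[21] * x
    dy[IDX_INTESTG] = gflux - v6
    dy[IDX_GIP] = v2 + v3
    dy[IDX_GLP1] = v4 + v5
    dy[IDX_AGUTG] = v6 - v7
    dy[IDX_G] = v7 / p[13] + v8 - v9
    dy[IDX_I] = v10 - v11
    dy[IDX_CP] = v10 - v12
    dy[IDX_X] = v11 / p[19] - v13


@njit(cache=True, error_model="numpy")
def rhs(y, p, gflux, dy):
    """State derivative; v7 is scaled by 1/V and v11 by 1/k11 as in the model."""
    _deriv(y, p, gflux, dy)


@njit(cache=True, error_model="numpy")
def integrate_fixed(y0, p, starts, ends, rates, dt, out_steps, n_steps, method, floor_zero):
    """Fixed-step integration on the grid t_i = i*dt, i = 0..n_steps.

    The ingestion flux is evaluated at the midpoint of each step and held
    constant across the step, which is exact when dt divides every event
    boundary (events sit on the 5-min/0.5-min grid by construction).

    Returns (out, fail_time): out has one row per entry of out_steps (step
    indices at which to record the state, sorted ascending); fail_time is
    -1.0 on success or the time at which a non-finite state appeared.
    """
    y = y0.copy()
    dy = np.empty(N_STATES)
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    ytmp = np.empty(N_STATES)
    out = np.empty((out_steps.shape[0], N_STATES))
    ptr = 0
    for i in range(n_steps + 1):
        while ptr < out_steps.shape[0] and out_steps[ptr] == i:
            for s in range(N_STATES):
                out[ptr, s] = y[s]
                if not np.isfinite(y[s]):
                    return out, i * dt
            ptr += 1
        if i == n_steps:
            break
        t = i * dt
        gf = flux_at(t + 0.5 * dt, starts, ends, rates)
        if method == EULER:
            _deriv(y, p, gf, dy)
            for s in range(N_STATES):
                y[s] += dt * dy[s]
        else:  # RK4 with the input held constant over the step
            _deriv(y, p, gf, k1)
            for s in range(N_STATES):
                ytmp[s] = y[s] + 0.5 * dt * k1[s]
            _deriv(ytmp, p, gf, k2)
            for s in range(N_STATES):
                ytmp[s] = y[s] + 0.5 * dt * k2[s]
            _deriv(ytmp, p, gf, k3)
            for s in range(N_STATES):
                ytmp[s] = y[s] + dt * k3[s]
            _deriv(ytmp, p, gf, k4)
            for s in range(N_STATES):
                y[s] += dt / 6.0 * (k1[s] + 2.0 * k2[s] + 2.0 * k3[s] + k4[s])
        if floor_zero:
            for s in range(N_STATES):
                if y[s] < 0.0:
                    y[s] = 0.0
    return out, -1.0
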