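"""Numba step kernel for the two-layer LIF/WTA simulation.

The kernel mirrors `salif.lif.euler_step` term by term (same expression,
same operation order) so the jitted path and the numpy reference path
produce bit-identical trajectories.  Before the first WTA spike there
are no lateral interactions: the saliency layer sees only its constant
input current and leak, the WTA layer only leak plus the one-step
excitatory pulse from its own saliency neuron.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_runs(I, dt, C, Gleak, Eleak, Gexc_pulse, Eexc, Einh,
                  Vthresh, Cw, Gleakw, max_steps):
    """Integrate R independent runs until the first WTA spike.

    Parameters
    ----------
    I : (R, N) float64
        Input current per run and location (noise already applied).

    Returns
    -------
    steps : (R,) int64 — step index of the first WTA spike, -1 censored
    winners : (R,) int64 — flat location index of the winner, -1 censored
    err : (R,) uint8 — 1 if the integration became non-finite
    """
    R, N = I.shape
    steps = np.full(R, -1, dtype=np.int64)
    winners = np.full(R, -1, dtype=np.int64)
    err = np.zeros(R, dtype=np.uint8)
    a = dt / C
    aw = dt / Cw
    for r in range(R):
        Vs = np.full(N, Eleak)
        Vw = np.full(N, Eleak)
        for n in range(1, max_steps + 1):
            best = -1
            best_v = 0.0
            for j in range(N):
                v = Vs[j] + a * (
                    I[r, j]
                    - Gleak * (Vs[j] - Eleak)
                    - 0.0 * (Vs[j] - Eexc)
                    - 0.0 * (Vs[j] - Einh)
                )
                if not np.isfinite(v):
                    err[r] = 1
                    break
                sal_fired = v > Vthresh
                if sal_fired:
                    Vs[j] = Eleak
                    ge = Gexc_pulse
                else:
                    Vs[j] = v
                    ge = 0.0
                w = Vw[j] + aw * (
                    0.0
                    - Gleakw * (Vw[j] - Eleak)
                    - ge * (Vw[j] - Eexc)
                    - 0.0 * (Vw[j] - Einh)
                )
                Vw[j] = w
                if w > Vthresh and (best < 0 or w > best_v):
                    best = j
                    best_v = w
            if err[r] == 1:
                break
            if best >= 0:
                steps[r] = n
                winners[r] = best
                break
    return steps, winners, err
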