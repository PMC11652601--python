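"""Independent oracles used by the tests.

The ODE oracle integrates the two-state absorption system (gut -> central)
with a high-accuracy adaptive solver and never touches the closed-form
code path it checks.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentration(cl, v, ka, dose_times, dose_amounts, t_eval):
    """Concentration (ng/mL) at ``t_eval`` by direct ODE integration.

    States: a (mg in gut), c (mg/L in central).
    da/dt = -ka a;  dc/dt = ka a / v - (cl/v) c.
    Doses are instantaneous additions to the gut compartment.
    """
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    events = sorted(zip(dose_times, dose_amounts))
    out = np.zeros_like(t_eval)
    state = np.array([0.0, 0.0])
    t_now = 0.0
    checkpoints = sorted(set([t for t, _ in events] + list(t_eval)))

    def rhs(_t, yv):
        a, c = yv
        return [-ka * a, ka * a / v - (cl / v) * c]

    ev = list(events)
    for t_next in checkpoints:
        if t_next > t_now:
            sol = solve_ivp(
                rhs, (t_now, t_next), state, rtol=1e-11, atol=1e-13, method="DOP853"
            )
            state = sol.y[:, -1]
            t_now = t_next
        while ev and abs(ev[0][0] - t_now) < 1e-12:
            state[0] += ev.pop(0)[1]
        sel = np.abs(t_eval - t_now) < 1e-12
        out[sel] = state[1] * 1000.0  # mg/L -> ng/mL
    return out if out.size > 1 else float(out[0])


def ode_steady_state_trough(cl, v, ka, amount, interval, n_half_lives=40):
    """Steady-state trough by running the ODE over many half-lives."""
    ke = cl / v
    t_half = np.log(2.0) / ke
    n_doses = int(np.ceil(n_half_lives * t_half / interval)) + 1
    times = [interval * k for k in range(n_doses)]
    amounts = [amount] * n_doses
    return ode_concentration(cl, v, ka, times, amounts, interval * n_doses)
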