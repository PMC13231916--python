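import numpy as np
import pytest
from scipy.integrate import solve_ivp

from voripk import StudyDesign, default_population, simulate_study
from voripk.model_core import total_clearance


@pytest.fixture(scope="session")
def pop():
    """Published final-model population parameters (packaged defaults)."""
    return default_population()


@pytest.fixture(scope="session")
def study(pop):
    """A default 31-subject synthetic study under the published model."""
    return simulate_study(StudyDesign(), pop, "smpc", seed=42)


def ode_concentrations(times, doses, p, rtol=1e-10, atol=1e-12):
    """Independent oracle: stiff adaptive ODE integration of
    dA/dt = R(t) - CL_total(t)/V * A, split at every rate discontinuity
    and observation time."""
    ts = np.asarray(times, dtype=float)
    tend = float(ts.max())

    def rhs(t, y):
        r = sum(d.rate for d in doses if d.start_time <= t < d.end_time)
        return [r - float(total_clearance(t, p)) / p.V * y[0]]

    edges = np.unique(np.concatenate(
        [[0.0, tend], [d.start_time for d in doses],
         [d.end_time for d in doses], ts]))
    edges = edges[edges <= tend]
    y = 0.0
    vals = {0.0: 0.0}
    for a, b in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(rhs, (a, b), [y], method="Radau", rtol=rtol, atol=atol)
        y = float(sol.y[0, -1])
        vals[b] = y
    return np.array([vals[t] for t in ts]) / p.V
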