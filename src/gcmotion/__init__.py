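"""gcmotion: chemokine-driven B-cell migration models.

Deterministic and stochastic models of germinal-center B cells migrating
between the dark and light zones under two opposing chemokine fields
(CXCL12/CXCR4 and CXCL13/CXCR5), with chemokine-induced receptor
down-regulation as the oscillation-generating feedback.  Includes
bifurcation analysis (Hopf/fold detection and two-parameter boundary
tracing), trajectory phenotyping, and a 3D stochastic individual-based
simulator on voxelized chemokine fields.
"""

from __future__ import annotations

import numpy as np

from .fields import ChemokineEnvironment, GaussianField1D, VoxelGrid3D, discretize
from .integrate import Trajectory, integrate_ode, integrate_sde
from .models import (ChemotaxisParams, FullModel, MassActionParams,
                     ReceptorParams, SingleReceptorModel, ToyModel, ToyParams)
from .scenarios import (Scenario, SCENARIOS, list_scenarios, load_scenario,
                        make_model, scenario_model)

__version__ = "0.1.0"

#: reference initial condition of the 1D simulations: x=0, v=1, r1=1, r2=1
DEFAULT_STATE0 = (0.0, 1.0, 1.0, 1.0)


def simulate(scenario, t_final: float = 2000.0, state0=DEFAULT_STATE0,
             n_samples: int = 4000, seed: int = 0, dt: float = 0.01,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Simulate a named scenario (or Scenario object) from ``state0``.

    Deterministic scenarios (sigma = 0) use the adaptive ODE integrator;
    scenarios with sigma > 0 use fixed-step Euler-Maruyama with velocity
    noise and the given seed.
    """
    sc = scenario if isinstance(scenario, Scenario) else load_scenario(scenario)
    model = make_model(sc.model, sc.parameters)
    sigma = float(sc.parameters.get("sigma", 0.0))
    t_eval = np.linspace(0.0, t_final, n_samples)
    meta = {"scenario": sc.name, "model": sc.model,
            "parameters": dict(sc.parameters)}
    if sigma > 0:
        return integrate_sde(model.rhs, state0, (0.0, t_final), dt=dt,
                             sigma=sigma, seed=seed, t_eval=t_eval, meta=meta)
    return integrate_ode(model.rhs, state0, (0.0, t_final), t_eval=t_eval,
                         rtol=rtol, atol=atol, meta=meta)
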