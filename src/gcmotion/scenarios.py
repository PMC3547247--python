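"""Named parameter scenarios and model construction.

Every figure-caption parameter set from the source study is registered here
under a stable name, with its provenance string.  Parameter keys are ASCII
transliterations of the model symbols:

    c, w        chemokine peak height and width (both fields)
    k           half-separation of the zone centres (um)
    pi1, pi2    receptor synthesis rates
    delta1, delta2      constitutive receptor degradation rates
    tau1, tau2          bound-receptor removal rates (full model)
    kappa1, kappa2      receptor-regulation association constants
    epsilon1, epsilon2  chemotactic-signal association constants
    chi         chemotactic responsiveness
    zeta        chemotactic signal scale (default 1)
    gamma       velocity drag
    sigma       Langevin noise intensity (default 0)

Scenario files (YAML or JSON) with the keys ``model`` and ``parameters``
round-trip through :func:`load_scenario` / :func:`Scenario.dump`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fields import ChemokineEnvironment
from .models import (ChemotaxisParams, FullModel, ReceptorParams,
                     SingleReceptorModel, ToyModel, ToyParams)

__all__ = ["Scenario", "load_scenario", "make_model", "make_environment",
           "list_scenarios", "SCENARIOS", "FIG7_PAIRS"]

_TOY_KEYS = {"c", "w", "k", "pi1", "pi2", "delta1", "delta2", "gamma"}
_FULL_KEYS = {"c", "w", "k", "pi1", "pi2", "delta1", "delta2", "tau1",
              "tau2", "kappa1", "kappa2", "epsilon1", "epsilon2", "chi",
              "gamma"}
_OPTIONAL_KEYS = {"zeta", "sigma", "c2", "w2"}

_REQUIRED = {
    "toy": _TOY_KEYS,
    "full": _FULL_KEYS,
    "single_receptor": _FULL_KEYS,
}


@dataclass(frozen=True)
class Scenario:
    """A named, validated parameter set for one model variant."""

    name: str
    model: str
    parameters: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if self.model not in _REQUIRED:
            raise ValueError(
                f"unknown model '{self.model}'; expected one of "
                f"{sorted(_REQUIRED)}")
        required = _REQUIRED[self.model]
        keys = set(self.parameters)
        missing = sorted(required - keys)
        unknown = sorted(keys - required - _OPTIONAL_KEYS)
        errors = []
        if missing:
            errors.append(f"missing keys: {missing}")
        if unknown:
            errors.append(f"unknown keys: {unknown}")
        bad = [k for k, v in self.parameters.items()
               if not isinstance(v, (int, float))]
        if bad:
            errors.append(f"non-numeric values for: {sorted(bad)}")
        if errors:
            raise ValueError(
                f"scenario '{self.name}' ({self.model}): " + "; ".join(errors))

    def with_updates(self, **updates) -> "Scenario":
        params = dict(self.parameters)
        params.update(updates)
        return Scenario(name=self.name, model=self.model, parameters=params,
                        provenance=self.provenance)

    def dump(self, path) -> None:
        path = Path(path)
        payload = {"name": self.name, "model": self.model,
                   "parameters": dict(self.parameters),
                   "provenance": self.provenance}
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_FIG2_FIXED = dict(c=20.0, w=15.7, pi2=1.0, delta1=0.001, delta2=0.001,
                   gamma=1.0)
_FIG4_FIXED = dict(c=10.0, w=25.0, pi2=0.1, tau1=0.06, tau2=0.06,
                   delta1=0.006, delta2=0.006, kappa1=1.0, kappa2=0.1,
                   epsilon1=0.3, epsilon2=0.3, chi=28.0, zeta=1.0, gamma=5.0)

#: the six colour-coded (k, pi1) pairs of the phenomenological model's
#: two-parameter diagram; 'oscillatory' means sustained oscillation from the
#: reference initial condition, 'steady_state' convergence to a fixed point.
FIG7_PAIRS = {
    "cyan": (43.0, 0.9, "oscillatory"),
    "black": (44.0, 0.75, "oscillatory"),
    "green": (50.0, 0.15, "oscillatory"),
    "magenta": (44.0, 0.9, "steady_state"),
    "blue": (50.0, 0.25, "steady_state"),
    "red": (50.0, 0.05, "steady_state"),
}

_FIG5 = {
    "fig5_topleft": (dict(c=10.0, w=25.0, pi1=0.15, pi2=0.15, tau1=0.06,
                          tau2=0.06, delta1=0.006, delta2=0.006, kappa1=0.5,
                          kappa2=0.5, epsilon1=0.3, epsilon2=0.3, chi=28.0,
                          gamma=5.0, k=50.0),
                     "symmetric inter-zone oscillations"),
    "fig5_topcenter": (dict(c=10.0, w=25.0, pi1=0.23, pi2=0.15, tau1=0.06,
                            tau2=0.06, delta1=0.006, delta2=0.006,
                            kappa1=0.5, kappa2=0.5, epsilon1=0.3,
                            epsilon2=0.3, chi=28.0, gamma=5.0, k=50.0),
                       "asymmetric oscillations"),
    "fig5_topright": (dict(c=10.0, w=25.0, pi1=0.15, pi2=0.15, tau1=0.06,
                           tau2=0.06, delta1=0.006, delta2=0.006, kappa1=3.6,
                           kappa2=0.5, epsilon1=0.3, epsilon2=0.3, chi=28.0,
                           gamma=5.0, k=50.0),
                      "oscillations confined to one zone"),
    "fig5_bottomleft": (dict(c=5.0, w=22.0, pi1=0.02, pi2=0.004, tau1=0.005,
                             tau2=0.01, delta1=0.001, delta2=0.001,
                             kappa1=10.0, kappa2=10.0, epsilon1=3.0,
                             epsilon2=0.2, chi=26.67, gamma=0.03, k=45.0),
                        "nested large and small oscillations in both zones"),
    "fig5_bottomcenter": (dict(c=5.0, w=22.0, pi1=0.05, pi2=0.006, tau1=0.04,
                               tau2=0.015, delta1=0.001, delta2=0.001,
                               kappa1=10.0, kappa2=10.0, epsilon1=6.0,
                               epsilon2=0.1, chi=3.33, gamma=0.03, k=45.0),
                          "nested small oscillations in one zone"),
    "fig5_bottomright": (dict(c=5.0, w=22.0, pi1=0.05, pi2=0.0056,
                              tau1=0.005, tau2=0.018, delta1=0.001,
                              delta2=0.001, kappa1=5.5, kappa2=10.0,
                              epsilon1=6.0, epsilon2=0.1, chi=16.17,
                              gamma=0.03, k=45.0),
                         "irregular ('apparently chaotic') oscillations"),
}


def _build_registry() -> dict[str, Scenario]:
    reg: dict[str, Scenario] = {}
    reg["fig2_default"] = Scenario(
        name="fig2_default", model="toy",
        parameters={**_FIG2_FIXED, "pi1": 0.3, "k": 30.0},
        provenance="toy-model bifurcation diagram, fixed parameters with "
                   "pi1=0.3")
    reg["fig4_default"] = Scenario(
        name="fig4_default", model="full",
        parameters={**_FIG4_FIXED, "pi1": 0.15, "k": 50.0},
        provenance="phenomenological-model bifurcation diagram, fixed "
                   "parameters with pi1=0.15")
    for name, (params, desc) in _FIG5.items():
        reg[name] = Scenario(name=name, model="full", parameters=dict(params),
                             provenance=f"oscillation-diversity panel: {desc}")
    for colour, (k, pi1, behaviour) in FIG7_PAIRS.items():
        nm = f"fig7_{colour}"
        reg[nm] = Scenario(
            name=nm, model="full",
            parameters={**_FIG4_FIXED, "pi1": pi1, "k": k},
            provenance=f"(k, pi1) pair '{colour}': expected {behaviour}")
    return reg


SCENARIOS: dict[str, Scenario] = _build_registry()


def list_scenarios() -> list[str]:
    return sorted(SCENARIOS)


def load_scenario(name_or_path) -> Scenario:
    """Fetch a registered scenario by name, or parse a YAML/JSON file.

    Validation reports all problems (missing keys, unknown keys,
    non-numeric values) in a single error message.
    """
    key = str(name_or_path)
    if key in SCENARIOS:
        return SCENARIOS[key]
    path = Path(key)
    if not path.exists():
        raise KeyError(
            f"'{key}' is neither a registered scenario "
            f"({', '.join(list_scenarios())}) nor an existing file")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "parameters" not in data:
        raise ValueError(f"scenario file {path} must map 'model' and "
                         f"'parameters'")
    return Scenario(name=data.get("name", path.stem),
                    model=data.get("model", "full"),
                    parameters=dict(data["parameters"]),
                    provenance=data.get("provenance", f"file:{path}"))


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def make_environment(params: dict) -> ChemokineEnvironment:
    return ChemokineEnvironment.symmetric(
        c=params["c"], w=params["w"], k=params["k"],
        c2=params.get("c2"), w2=params.get("w2"))


def make_model(model: str, params: dict):
    """Build a model instance from a flat parameter mapping."""
    env = make_environment(params)
    if model == "toy":
        tp = ToyParams(pi1=params["pi1"], pi2=params["pi2"],
                       delta1=params["delta1"], delta2=params["delta2"],
                       gamma=params["gamma"])
        return ToyModel(env, tp)
    if model in ("full", "single_receptor"):
        rp1 = ReceptorParams(pi=params["pi1"], tau=params["tau1"],
                             kappa=params["kappa1"], delta=params["delta1"])
        rp2 = ReceptorParams(pi=params["pi2"], tau=params["tau2"],
                             kappa=params["kappa2"], delta=params["delta2"])
        cp = ChemotaxisParams(chi=params["chi"],
                              epsilon1=params["epsilon1"],
                              epsilon2=params["epsilon2"],
                              gamma=params["gamma"],
                              zeta=params.get("zeta", 1.0),
                              sigma=params.get("sigma", 0.0))
        cls = FullModel if model == "full" else SingleReceptorModel
        return cls(env, rp1, rp2, cp)
    raise ValueError(f"unknown model '{model}'")


def scenario_model(scenario: Scenario | str):
    sc = scenario if isinstance(scenario, Scenario) else load_scenario(scenario)
    return make_model(sc.model, sc.parameters)
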