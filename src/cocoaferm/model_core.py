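"""Kinetic model variants for cocoa bean fermentation.

The baseline model couples eight states — glucose (Glc), fructose (Fru),
ethanol (EtOH), lactic acid (LA), acetic acid (Ac) and the biomasses of
yeast (Y), lactic acid bacteria (LAB) and acetic acid bacteria (AAB) —
through Monod/Contois growth rates, Chick–Watson mortality rates and, in
extended variants, first-order metabolite decay.  Five optional mechanisms
can be toggled on top of the baseline:

* M1 — abiotic decay of EtOH, LA and Ac (evaporation, diffusion into beans);
* M2 — fructose consumption by LAB, with EtOH/LA/Ac side products;
* M3 — acetate production by yeast during sugar growth;
* M4 — lactate consumption by yeast, producing EtOH;
* M5 — over-oxidation of acetate by AAB.

All 2^5 = 32 mechanism subsets define the family of model variants,
labelled ``MI(0)``, ``MI(2,3)``, …, ``MI(1,2,3,4,5)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._integrate import STATUS_MESSAGES, dp45_integrate

__all__ = [
    "STATE_NAMES",
    "MECHANISMS",
    "ParamSpec",
    "PARAMETER_TABLE",
    "PARAM_INDEX",
    "MechanismSet",
    "ModelVariant",
    "SolverConfig",
    "SimulationError",
    "monod_rate",
    "contois_rate",
    "mortality_rate",
    "decay_rate",
    "enumerate_variants",
    "build_variant",
    "rhs",
    "simulate",
]

#: Fixed state ordering used by every trajectory/observation matrix.
STATE_NAMES = ("Glc", "Fru", "EtOH", "LA", "Ac", "Y", "LAB", "AAB")

MECHANISMS = ("M1", "M2", "M3", "M4", "M5")


@dataclass(frozen=True)
class ParamSpec:
    """One row of the kinetic-parameter table.

    ``kind`` is one of ``mu`` (maximum specific growth rate), ``K``
    (saturation constant), ``k`` (mortality constant), ``yield`` or ``b``
    (decay rate).  ``group`` names the microbial group the parameter is
    associated with (None for pure decay rates).  ``scale_num`` and
    ``scale_den`` encode the unit-restoration map: a parameter estimated on
    max-scaled series is converted back to original units by multiplying
    with the product of the named series' maxima over ``scale_num`` divided
    by the product over ``scale_den``.
    """

    name: str
    tag: str  # "B" or "M1".."M5"
    kind: str
    group: str | None
    scale_num: tuple[str, ...] = ()
    scale_den: tuple[str, ...] = ()


def _mu(name, tag, group):
    return ParamSpec(name, tag, "mu", group)


def _K(name, tag, group, substrate, contois=False):
    den = (group,) if contois else ()
    return ParamSpec(name, tag, "K", group, (substrate,), den)


def _k(name, tag, group, product, order=1):
    return ParamSpec(name, tag, "k", group, (), (product,) * order)


def _Y(name, tag, group, metabolite):
    return ParamSpec(name, tag, "yield", group, (metabolite,), (group,))


def _b(name, tag):
    return ParamSpec(name, tag, "b", None)


#: The 43 kinetic parameters in canonical (table-row) order.  The first
#: 19 rows are growth/saturation/mortality constants, rows 20–40 the 21
#: yield coefficients, rows 41–43 the decay rates.
PARAMETER_TABLE: tuple[ParamSpec, ...] = (
    _mu("mu_Y_Glc", "B", "Y"),
    _mu("mu_Y_Fru", "B", "Y"),
    _mu("mu_Y_LA", "M4", "Y"),
    _mu("mu_LAB_Glc", "B", "LAB"),
    _mu("mu_LAB_Fru", "M2", "LAB"),
    _mu("mu_AAB_EtOH", "B", "AAB"),
    _mu("mu_AAB_LA", "B", "AAB"),
    _mu("mu_AAB_Ac", "M5", "AAB"),
    _K("K_Y_Glc", "B", "Y", "Glc"),
    _K("K_Y_Fru", "B", "Y", "Fru"),
    _K("K_Y_LA", "M4", "Y", "LA"),
    _K("K_LAB_Glc", "B", "LAB", "Glc"),
    _K("K_LAB_Fru", "M2", "LAB", "Fru"),
    _K("K_AAB_EtOH", "B", "AAB", "EtOH"),
    _K("K_AAB_LA", "B", "AAB", "LA", contois=True),
    _K("K_AAB_Ac", "M5", "AAB", "Ac"),
    _k("k_Y", "B", "Y", "EtOH"),
    _k("k_LAB", "B", "LAB", "LA"),
    _k("k_AAB", "B", "AAB", "Ac", order=2),
    _Y("Y_Glc_Y", "B", "Y", "Glc"),
    _Y("Y_Glc_LAB", "B", "LAB", "Glc"),
    _Y("Y_Fru_Y", "B", "Y", "Fru"),
    _Y("Y_Fru_LAB", "M2", "LAB", "Fru"),
    _Y("Y_EtOH_Y_Glc", "B", "Y", "EtOH"),
    _Y("Y_EtOH_Y_Fru", "B", "Y", "EtOH"),
    _Y("Y_EtOH_Y_LA", "M4", "Y", "EtOH"),
    _Y("Y_EtOH_LAB_Glc", "M2", "LAB", "EtOH"),
    _Y("Y_EtOH_LAB_Fru", "M2", "LAB", "EtOH"),
    _Y("Y_EtOH_AAB", "B", "AAB", "EtOH"),
    _Y("Y_LA_LAB_Glc", "B", "LAB", "LA"),
    _Y("Y_LA_LAB_Fru", "M2", "LAB", "LA"),
    _Y("Y_LA_AAB", "B", "AAB", "LA"),
    _Y("Y_LA_Y", "M4", "Y", "LA"),
    _Y("Y_Ac_LAB_Glc", "B", "LAB", "Ac"),
    _Y("Y_Ac_LAB_Fru", "M2", "LAB", "Ac"),
    _Y("Y_Ac_AAB_EtOH", "B", "AAB", "Ac"),
    _Y("Y_Ac_AAB_LA", "B", "AAB", "Ac"),
    _Y("Y_Ac_Y_Glc", "M3", "Y", "Ac"),
    _Y("Y_Ac_Y_Fru", "M3", "Y", "Ac"),
    _Y("Y_Ac_AAB", "M5", "AAB", "Ac"),
    _b("b_EtOH", "M1"),
    _b("b_LA", "M1"),
    _b("b_Ac", "M1"),
)

PARAM_INDEX = {spec.name: i for i, spec in enumerate(PARAMETER_TABLE)}

N_PARAMS_FULL = len(PARAMETER_TABLE)  # 43
N_PARAMS_BASELINE = sum(1 for s in PARAMETER_TABLE if s.tag == "B")  # 24


class SimulationError(RuntimeError):
    """Raised when the ODE integration fails; carries the failing time."""

    def __init__(self, message: str, time: float):
        super().__init__(f"{message} (t = {time:g} h)")
        self.time = time


# ---------------------------------------------------------------------------
# mechanism sets and variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class MechanismSet:
    """A subset of the five optional mechanisms, identifying a variant."""

    m1: bool = False
    m2: bool = False
    m3: bool = False
    m4: bool = False
    m5: bool = False

    @classmethod
    def from_indices(cls, indices) -> "MechanismSet":
        indices = set(indices)
        bad = indices - {1, 2, 3, 4, 5}
        if bad:
            raise ValueError(f"unknown mechanism indices: {sorted(bad)}")
        return cls(*(i in indices for i in range(1, 6)))

    @classmethod
    def from_label(cls, label: str) -> "MechanismSet":
        text = label.strip()
        if not (text.startswith("MI(") and text.endswith(")")):
            raise ValueError(f"not a variant label: {label!r}")
        inner = text[3:-1]
        if inner == "0":
            return cls()
        return cls.from_indices(int(tok) for tok in inner.split(","))

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, on in enumerate((self.m1, self.m2, self.m3, self.m4, self.m5), 1) if on
        )

    @property
    def label(self) -> str:
        if not self.indices:
            return "MI(0)"
        return "MI(" + ",".join(str(i) for i in self.indices) + ")"

    @property
    def tags(self) -> frozenset:
        return frozenset({"B"} | {f"M{i}" for i in self.indices})

    def __contains__(self, mechanism: str) -> bool:
        return mechanism in self.tags

    def __iter__(self):
        return iter(self.indices)

    def __len__(self):
        return len(self.indices)


@dataclass(frozen=True)
class ModelVariant:
    """A concrete model: mechanism set plus its ordered free-parameter manifest."""

    mechanisms: MechanismSet
    parameter_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def label(self) -> str:
        return self.mechanisms.label


def build_variant(mechanisms: MechanismSet | str) -> ModelVariant:
    """Assemble the variant for a mechanism set.

    The free parameters are exactly the table rows tagged ``B`` plus the
    rows tagged with each active mechanism, in table-row order.
    """
    if isinstance(mechanisms, str):
        mechanisms = MechanismSet.from_label(mechanisms)
    tags = mechanisms.tags
    names = tuple(spec.name for spec in PARAMETER_TABLE if spec.tag in tags)
    return ModelVariant(mechanisms=mechanisms, parameter_names=names)


def enumerate_variants() -> list[MechanismSet]:
    """All 32 mechanism subsets: baseline first, then by size, then lexicographic."""
    out = []
    for size in range(6):
        for combo in itertools.combinations(range(1, 6), size):
            out.append(MechanismSet.from_indices(combo))
    return out


# ---------------------------------------------------------------------------
# rate laws (scalar reference forms)
# ---------------------------------------------------------------------------


def _check_nonneg(**kwargs):
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def monod_rate(mu_max: float, K: float, S: float, X: float) -> float:
    """Monod growth rate mu_max * S/(S+K) * X; zero whenever S is zero."""
    _check_nonneg(mu_max=mu_max, K=K, S=S, X=X)
    if S == 0.0:
        return 0.0
    return mu_max * S / (S + K) * X


def contois_rate(mu_max: float, K: float, S: float, X: float) -> float:
    """Contois growth rate mu_max * S/(S + K*X) * X (saturation scales with biomass)."""
    _check_nonneg(mu_max=mu_max, K=K, S=S, X=X)
    if S == 0.0 or X == 0.0:
        return 0.0
    return mu_max * S / (S + K * X) * X


def mortality_rate(k: float, X: float, P: float, order: int = 1) -> float:
    """Chick–Watson mortality k * X * P**order; order 1 (Y, LAB) or 2 (AAB)."""
    if order not in (1, 2):
        raise ValueError(f"unsupported mortality order {order}; expected 1 or 2")
    _check_nonneg(k=k, X=X, P=P)
    return k * X * P**order


def decay_rate(b: float, M: float) -> float:
    """First-order abiotic decay b * M."""
    _check_nonneg(b=b, M=M)
    return b * M


# ---------------------------------------------------------------------------
# full right-hand side and simulation
# ---------------------------------------------------------------------------


def full_param_vector(params, mechanisms: MechanismSet) -> np.ndarray:
    """Embed a parameter mapping/sequence into the full 43-vector.

    Entries belonging to inactive mechanisms are set to 0, which removes
    their rates identically (every extended term is proportional to one of
    its mechanism's parameters).  ``params`` may be a mapping from names to
    values or a sequence ordered like the variant manifest.
    """
    variant = build_variant(mechanisms)
    vec = np.zeros(N_PARAMS_FULL)
    if isinstance(params, dict):
        missing = [n for n in variant.parameter_names if n not in params]
        if missing:
            raise KeyError(
                f"{variant.label} requires parameters missing from input: {missing}"
            )
        for name in variant.parameter_names:
            vec[PARAM_INDEX[name]] = params[name]
    else:
        values = np.asarray(params, dtype=float)
        if values.shape != (variant.n_params,):
            raise ValueError(
                f"{variant.label} takes {variant.n_params} parameters, got {values.shape}"
            )
        for name, value in zip(variant.parameter_names, values):
            vec[PARAM_INDEX[name]] = value
    if np.any(vec < 0):
        raise ValueError("kinetic parameters must be non-negative")
    return vec


def _rhs_reference(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Pure-python right-hand side of the full model (oracle for the jitted one)."""
    Glc, Fru, EtOH, LA, Ac, Y, LAB, AAB = y
    g = PARAM_INDEX.__getitem__

    v1 = monod_rate(p[g("mu_Y_Glc")], p[g("K_Y_Glc")], Glc, Y)
    v2 = monod_rate(p[g("mu_Y_Fru")], p[g("K_Y_Fru")], Fru, Y)
    v3 = monod_rate(p[g("mu_LAB_Glc")], p[g("K_LAB_Glc")], Glc, LAB)
    v4 = monod_rate(p[g("mu_AAB_EtOH")], p[g("K_AAB_EtOH")], EtOH, AAB)
    v5 = contois_rate(p[g("mu_AAB_LA")], p[g("K_AAB_LA")], LA, AAB)
    v6 = mortality_rate(p[g("k_Y")], Y, EtOH, 1)
    v7 = mortality_rate(p[g("k_LAB")], LAB, LA, 1)
    v8 = mortality_rate(p[g("k_AAB")], AAB, Ac, 2)
    v9 = monod_rate(p[g("mu_LAB_Fru")], p[g("K_LAB_Fru")], Fru, LAB)
    v10 = monod_rate(p[g("mu_Y_LA")], p[g("K_Y_LA")], LA, Y)
    v11 = monod_rate(p[g("mu_AAB_Ac")], p[g("K_AAB_Ac")], Ac, AAB)
    d1 = decay_rate(p[g("b_EtOH")], EtOH)
    d2 = decay_rate(p[g("b_LA")], LA)
    d3 = decay_rate(p[g("b_Ac")], Ac)

    dGlc = -p[g("Y_Glc_Y")] * v1 - p[g("Y_Glc_LAB")] * v3
    dFru = -p[g("Y_Fru_Y")] * v2 - p[g("Y_Fru_LAB")] * v9
    dEtOH = (
        p[g("Y_EtOH_Y_Glc")] * v1
        + p[g("Y_EtOH_Y_Fru")] * v2
        + p[g("Y_EtOH_Y_LA")] * v10
        + p[g("Y_EtOH_LAB_Glc")] * v3
        + p[g("Y_EtOH_LAB_Fru")] * v9
        - p[g("Y_EtOH_AAB")] * v4
        - d1
    )
    dLA = (
        p[g("Y_LA_LAB_Glc")] * v3
        + p[g("Y_LA_LAB_Fru")] * v9
        - p[g("Y_LA_AAB")] * v5
        - p[g("Y_LA_Y")] * v10
        - d2
    )
    dAc = (
        p[g("Y_Ac_LAB_Glc")] * v3
        + p[g("Y_Ac_LAB_Fru")] * v9
        + p[g("Y_Ac_AAB_EtOH")] * v4
        + p[g("Y_Ac_AAB_LA")] * v5
        + p[g("Y_Ac_Y_Glc")] * v1
        + p[g("Y_Ac_Y_Fru")] * v2
        - p[g("Y_Ac_AAB")] * v11
        - d3
    )
    dY = v1 + v2 + v10 - v6
    dLAB = v3 + v9 - v7
    dAAB = v4 + v5 + v11 - v8
    return np.array([dGlc, dFru, dEtOH, dLA, dAc, dY, dLAB, dAAB])


def rhs(state, params, mechanisms: MechanismSet | str | None = None) -> np.ndarray:
    """Time derivative of the 8-state vector for a given variant.

    ``params`` may be a name→value mapping (entries for inactive mechanisms
    are ignored), an ordered sequence matching the variant manifest, or —
    when ``mechanisms`` is None — a full 43-vector applied as-is.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (8,):
        raise ValueError(f"state must have 8 components, got shape {y.shape}")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    if mechanisms is None:
        p = np.asarray(params, dtype=float)
        if p.shape != (N_PARAMS_FULL,):
            raise ValueError("without a mechanism set, params must be the full 43-vector")
    else:
        if isinstance(mechanisms, str):
            mechanisms = MechanismSet.from_label(mechanisms)
        p = full_param_vector(params, mechanisms)
    return _rhs_reference(y, p)


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive Runge–Kutta 4(5) settings (Dormand–Prince pair)."""

    rtol: float = 1e-6
    atol: float = 1e-6
    max_steps: int = 10_000
    method: str = "rk45"
    #: integrator outputs in [-neg_slack*atol, 0) are clamped to 0;
    #: anything below raises SimulationError.
    neg_slack: float = 100.0


DEFAULT_SOLVER = SolverConfig()


def simulate(
    variant: ModelVariant | MechanismSet | str,
    params,
    init,
    times,
    solver: SolverConfig = DEFAULT_SOLVER,
) -> np.ndarray:
    """Integrate a variant and return the state at each requested time.

    ``times`` must be strictly increasing with ``times[0]`` the initial
    time; ``init`` is the (non-negative) state at ``times[0]``.  Returns a
    ``(len(times), 8)`` array.
    """
    if isinstance(variant, str):
        variant = build_variant(variant)
    elif isinstance(variant, MechanismSet):
        variant = build_variant(variant)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a 1-D array of at least one time")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (8,):
        raise ValueError("initial state must have 8 components")
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    p = full_param_vector(params, variant.mechanisms)
    out, status, t_fail = dp45_integrate(
        p, y0, t, solver.rtol, solver.atol, solver.max_steps, solver.neg_slack
    )
    if status != 0:
        raise SimulationError(STATUS_MESSAGES[status], t_fail)
    return out


def trajectory_frame(times, trajectory):
    """Trajectory as a DataFrame with the canonical CSV header."""
    import pandas as pd

    frame = pd.DataFrame(trajectory, columns=list(STATE_NAMES))
    frame.insert(0, "time", np.asarray(times, dtype=float))
    return frame
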