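"""Synthetic fermentation trials with the structure the analysis assumes.

Real cocoa fermentation time series are short (6–17 observation times over
roughly 0–160 h), exhibit a three-phase microbial succession (a yeast
bloom, then lactic acid bacteria, then acetic acid bacteria) and carry
roughly Gaussian observation noise once max-scaled.  The generator
simulates a chosen model variant at a preset "true" parameter vector,
adds independent Normal noise on the scaled space (where the likelihood
operates), and converts back to raw units — metabolites in mg/g pulp,
microbes in log10 CFU/g — so that the full preprocessing→fit→assessment
pipeline can be exercised end to end with known ground truth.

The default parameter preset was chosen to reproduce the canonical
succession (yeast peaking first, LAB second, AAB third, sugars depleted,
ethanol then acetate accumulating before oxidation) and is documented as a
fixture, verified by inspecting simulated trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .model_core import (
    MechanismSet,
    STATE_NAMES,
    build_variant,
    simulate,
)
from .preprocessing import (
    DEFAULT_CELL_MASS_MG,
    FermentationDataset,
    MICROBE_NAMES,
    ScaledDataset,
    mass_to_cfu,
    rescale_params,
    scale_params,
)

__all__ = [
    "DEFAULT_TRUE_PARAMS",
    "DEFAULT_INITIAL_STATE",
    "DEFAULT_SCALE_FACTORS",
    "GeneratorConfig",
    "TrialTruth",
    "Cohort",
    "GenerationError",
    "generate_trial",
    "generate_cohort",
    "true_params_in_fit_space",
]


class GenerationError(RuntimeError):
    pass


#: "True" kinetic parameters on the scaled space, one value for all 43
#: table rows.  Baseline entries produce the three-phase succession; the
#: mechanism entries are modest effects that perturb, not overturn, the
#: baseline dynamics.
DEFAULT_TRUE_PARAMS = {
    # baseline growth: yeasts are glucophilic (fast, low-K glucose uptake;
    # slower, high-K fructose uptake), so glucose depletes first
    "mu_Y_Glc": 0.13, "mu_Y_Fru": 0.055, "K_Y_Glc": 0.25, "K_Y_Fru": 0.70,
    "mu_LAB_Glc": 0.11, "K_LAB_Glc": 0.45,
    "mu_AAB_EtOH": 0.10, "K_AAB_EtOH": 0.60,
    "mu_AAB_LA": 0.035, "K_AAB_LA": 0.50,
    # baseline mortality
    "k_Y": 0.085, "k_LAB": 0.05, "k_AAB": 0.30,
    # baseline yields (per unit biomass grown, scaled space)
    "Y_Glc_Y": 0.45, "Y_Glc_LAB": 0.35, "Y_Fru_Y": 0.85,
    "Y_EtOH_Y_Glc": 0.60, "Y_EtOH_Y_Fru": 0.35, "Y_EtOH_AAB": 0.90,
    "Y_LA_LAB_Glc": 1.10, "Y_LA_AAB": 0.50,
    "Y_Ac_LAB_Glc": 0.35, "Y_Ac_AAB_EtOH": 0.65, "Y_Ac_AAB_LA": 0.45,
    # M1: abiotic decay
    "b_EtOH": 0.006, "b_LA": 0.005, "b_Ac": 0.004,
    # M2: LAB on fructose
    "mu_LAB_Fru": 0.07, "K_LAB_Fru": 0.50, "Y_Fru_LAB": 0.45,
    "Y_EtOH_LAB_Glc": 0.15, "Y_EtOH_LAB_Fru": 0.15,
    "Y_LA_LAB_Fru": 0.80, "Y_Ac_LAB_Fru": 0.30,
    # M3: acetate from yeast
    "Y_Ac_Y_Glc": 0.12, "Y_Ac_Y_Fru": 0.10,
    # M4: yeast on lactate
    "mu_Y_LA": 0.03, "K_Y_LA": 0.50, "Y_EtOH_Y_LA": 0.30, "Y_LA_Y": 0.50,
    # M5: acetate over-oxidation
    "mu_AAB_Ac": 0.04, "K_AAB_Ac": 0.60, "Y_Ac_AAB": 0.60,
}

#: Scaled initial state: sugars at their maximum, products near zero,
#: microbial biomass 1–2% of its eventual maximum (counts start around
#: 10^6 CFU/g and peak near 10^8).
DEFAULT_INITIAL_STATE = np.array([1.0, 1.0, 0.01, 0.01, 0.01, 0.02, 0.02, 0.01])

#: Nominal raw-unit series maxima: pulp sugars ~50 mg/g, ethanol ~18,
#: lactic ~7 and acetic acid ~10 mg/g; microbial biomass maxima consistent
#: with peak counts of roughly 10^8 (Y), 10^9 (LAB) and 10^8.7 (AAB) CFU/g
#: at the default cell masses.
DEFAULT_SCALE_FACTORS = np.array([55.0, 48.0, 18.0, 7.0, 10.0, 5.0, 1.2, 0.5])

_MICROBE_IDX = [STATE_NAMES.index(n) for n in MICROBE_NAMES]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic trial."""

    variant: MechanismSet = MechanismSet()
    true_params: dict | None = None  # None: DEFAULT_TRUE_PARAMS subset
    initial_state: np.ndarray = field(default_factory=lambda: DEFAULT_INITIAL_STATE.copy())
    n_timepoints: int = 12
    horizon: float = 160.0
    noise_sd: float = 0.03
    seed: int = 0
    grid: str = "jitter"  # "jitter" or "uniform"
    #: The fitting convention anchors the ODE initial state at the first
    #: observation row; leaving that row noise-free keeps the generated
    #: trial consistent with its own ground truth.  Set True to emulate
    #: noise on the anchor as well (recovery is then confounded by the
    #: perturbed initial condition).
    noise_at_t0: bool = False
    scale_factors: np.ndarray = field(default_factory=lambda: DEFAULT_SCALE_FACTORS.copy())
    cell_masses: dict = field(default_factory=lambda: dict(DEFAULT_CELL_MASS_MG))
    features: dict = field(default_factory=dict)
    code: str = "synth"

    def __post_init__(self):
        if not 6 <= self.n_timepoints <= 17:
            raise ValueError("n_timepoints must lie in [6, 17]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.grid not in ("uniform", "jitter"):
            raise ValueError(f"unknown grid {self.grid!r}")

    def resolved_params(self) -> dict:
        variant = build_variant(self.variant)
        source = self.true_params or DEFAULT_TRUE_PARAMS
        params = {n: source[n] for n in variant.parameter_names}
        if any(v <= 0 for v in params.values()):
            raise ValueError("true parameters must be positive")
        return params


@dataclass(frozen=True)
class TrialTruth:
    """Everything needed to score a fit against the generating process."""

    variant_label: str
    params_scaled: dict
    sigma: float
    initial_state: np.ndarray
    times: np.ndarray
    trajectory_scaled: np.ndarray
    scale_factors: np.ndarray
    seed: int


@dataclass(frozen=True)
class Cohort:
    datasets: list
    truths: list
    labels: list

    def __len__(self):
        return len(self.datasets)


def _sample_times(config: GeneratorConfig, rng) -> np.ndarray:
    times = np.linspace(0.0, config.horizon, config.n_timepoints)
    if config.grid == "jitter":
        spacing = config.horizon / (config.n_timepoints - 1)
        jitter = rng.uniform(-0.3, 0.3, size=config.n_timepoints - 2) * spacing
        times[1:-1] = times[1:-1] + jitter
        times.sort()
    return times


def generate_trial(config: GeneratorConfig):
    """Simulate, perturb and package one trial.

    Returns ``(dataset, truth)``: a raw-unit FermentationDataset (microbes
    in log10 CFU/g) and the TrialTruth record.  Noise is Normal(0,
    noise_sd) on the scaled space, independent across all entries;
    negative noisy values are clipped to zero (to a small positive floor
    for microbial series, which must survive the log transform).
    """
    rng = np.random.default_rng(config.seed)
    params = config.resolved_params()
    times = _sample_times(config, rng)
    try:
        traj = simulate(config.variant, params, config.initial_state, times)
    except Exception as exc:  # noqa: BLE001 - repackage with context
        raise GenerationError(f"trajectory simulation failed: {exc}") from exc

    # Noise is Gaussian on the max-scaled space the likelihood operates on:
    # each series gets sd = noise_sd times its own trajectory maximum, so
    # that after the fitting pipeline's max-scaling the shared-sigma noise
    # model holds with sigma ~= noise_sd on every series.
    series_max = np.maximum(traj.max(axis=0), 1e-12)
    noise = rng.normal(0.0, config.noise_sd, size=traj.shape) * series_max
    if not config.noise_at_t0:
        noise[0] = 0.0
    noisy = np.clip(traj + noise, 0.0, None)
    noisy[:, _MICROBE_IDX] = np.clip(noisy[:, _MICROBE_IDX], 1e-6, None)

    raw = noisy * config.scale_factors
    obs = raw.copy()
    for name, j in zip(MICROBE_NAMES, _MICROBE_IDX):
        obs[:, j] = mass_to_cfu(raw[:, j], config.cell_masses[name])

    dataset = FermentationDataset(
        code=config.code,
        times=times,
        observations=obs,
        features=dict(config.features),
        units="raw",
    )
    truth = TrialTruth(
        variant_label=build_variant(config.variant).label,
        params_scaled=params,
        sigma=config.noise_sd,
        initial_state=np.asarray(config.initial_state, dtype=float).copy(),
        times=times.copy(),
        trajectory_scaled=traj,
        scale_factors=np.asarray(config.scale_factors, dtype=float).copy(),
        seed=config.seed,
    )
    return dataset, truth


def true_params_in_fit_space(truth: TrialTruth, scaled: ScaledDataset) -> dict:
    """Express the generating parameters in a fitted dataset's scaled units.

    The generator works on its own nominal scale; a refit max-scales by the
    observed (noisy) maxima, which differ slightly.  Converting the truth
    through raw units into the fit's scale makes the two comparable
    exactly.
    """
    variant = build_variant(truth.variant_label)
    raw = rescale_params(truth.params_scaled, truth.scale_factors, variant)
    return scale_params(raw, scaled.scale_factors, variant)


def generate_cohort(
    base: GeneratorConfig,
    classes: dict,
    n_per_class: int,
    feature: str = "cultivar",
) -> Cohort:
    """Generate a labelled multi-class cohort for classification tests.

    ``classes`` maps a class label to an additive offset dict applied to
    the base true parameters; offsets must keep every parameter positive.
    Each trial gets a fresh seed derived from the base seed.
    """
    if not classes:
        raise ValueError("at least one class is required")
    variant = build_variant(base.variant)
    base_params = base.resolved_params()

    n_trials = len(classes) * n_per_class
    child_seeds = np.random.SeedSequence(base.seed).generate_state(n_trials) % (2**31)

    datasets, truths, labels = [], [], []
    k = 0
    for label, offsets in classes.items():
        unknown = set(offsets) - set(variant.parameter_names)
        if unknown:
            raise ValueError(f"offsets for unknown/inactive parameters: {sorted(unknown)}")
        params = dict(base_params)
        for name, delta in offsets.items():
            params[name] = params[name] + delta
            if params[name] <= 0:
                raise ValueError(
                    f"offset for {name} drives the parameter non-positive"
                )
        for r in range(n_per_class):
            config = _dc_replace(
                base,
                true_params=params,
                seed=int(child_seeds[k]),
                code=f"{base.code}-{label}-{r + 1}",
                features={**base.features, feature: label},
            )
            ds, truth = generate_trial(config)
            datasets.append(ds)
            truths.append(truth)
            labels.append(label)
            k += 1
    return Cohort(datasets=datasets, truths=truths, labels=labels)
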