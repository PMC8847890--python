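"""Dataset containers, unit conversion, max-scaling and parameter rescaling.

A fermentation trial is a table of observation times (hours) and eight
series: Glc, Fru, EtOH, LA, Ac in mg per g pulp and Y/LAB/AAB counts in
log10 CFU per g pulp.  Before fitting, microbial counts are converted to
biomass (mg per g pulp) and every series is divided by its own maximum, so
that all fitted quantities live in roughly [0, 1].  Parameter estimates
obtained on scaled series are mapped back to original units by the
dimensional transformations encoded in the parameter table; the map is
pinned by the requirement that integrating in raw units and then scaling
gives the same trajectories as integrating the transformed parameters from
scaled initial conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import PARAMETER_TABLE, PARAM_INDEX, STATE_NAMES, ModelVariant

__all__ = [
    "MICROBE_NAMES",
    "DEFAULT_CELL_MASS_MG",
    "FEATURE_KEYS",
    "FermentationDataset",
    "ScaledDataset",
    "DataError",
    "cfu_to_mass",
    "mass_to_cfu",
    "to_model_units",
    "max_scale",
    "unscale",
    "rescale_params",
    "scale_params",
    "read_dataset_csv",
    "write_dataset_csv",
]

MICROBE_NAMES = ("Y", "LAB", "AAB")

#: Assumed dry mass of one colony-forming unit, mg per CFU.  These are
#: package defaults of the right order of magnitude for yeasts and
#: bacteria; they cancel exactly under max-scaling, so fitting never
#: depends on them — only reporting in original units does.
DEFAULT_CELL_MASS_MG = {"Y": 5e-8, "LAB": 1e-9, "AAB": 1e-9}

#: Trial metadata vocabulary (cohort schema).
FEATURE_KEYS = ("country", "cultivar", "method", "turning", "controlled_temperature")

MIN_OBSERVATIONS = 5


class DataError(ValueError):
    """Raised for malformed or unusable observation data."""


@dataclass(frozen=True)
class FermentationDataset:
    """A single fermentation trial.

    ``observations`` is a (T, 8) matrix in STATE_NAMES order; NaN marks a
    missing observation.  ``units`` is ``"raw"`` (microbes in log10 CFU/g)
    or ``"mass"`` (all series in mg/g pulp).
    """

    code: str
    times: np.ndarray
    observations: np.ndarray
    features: dict = field(default_factory=dict)
    units: str = "raw"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        obs = np.asarray(self.observations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "observations", obs)
        if times.ndim != 1:
            raise DataError("times must be 1-D")
        if np.any(np.diff(times) <= 0):
            raise DataError("times must be strictly increasing")
        if obs.shape != (times.size, len(STATE_NAMES)):
            raise DataError(
                f"observations must be (T, 8); got {obs.shape} for T={times.size}"
            )
        if times.size < MIN_OBSERVATIONS:
            raise DataError(
                f"dataset {self.code!r} has {times.size} observations; "
                f"at least {MIN_OBSERVATIONS} are required"
            )
        if self.units not in ("raw", "mass"):
            raise DataError(f"unknown units tag {self.units!r}")

    @property
    def n_times(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.observations, columns=list(STATE_NAMES))
        frame.insert(0, "time", self.times)
        return frame


@dataclass(frozen=True)
class ScaledDataset:
    """Max-scaled view of a trial: each series divided by its own maximum."""

    scaled: np.ndarray
    scale_factors: np.ndarray
    source: FermentationDataset

    @property
    def times(self) -> np.ndarray:
        return self.source.times

    @property
    def code(self) -> str:
        return self.source.code

    @property
    def features(self) -> dict:
        return self.source.features

    @property
    def initial_state(self) -> np.ndarray:
        """First scaled observation row, used as the ODE initial state."""
        row = self.scaled[0]
        if np.any(~np.isfinite(row)):
            raise DataError(
                f"dataset {self.code!r}: first observation row has missing values"
            )
        return row.copy()


def cfu_to_mass(log10_cfu, cell_mass: float):
    """Convert log10 colony counts per g pulp to biomass in mg per g pulp."""
    if cell_mass <= 0:
        raise DataError("cell_mass must be positive")
    value = np.asarray(log10_cfu, dtype=float)
    if np.any(~np.isfinite(value)):
        raise DataError("log10 CFU values must be finite")
    result = cell_mass * 10.0**value
    return float(result) if result.ndim == 0 else result


def mass_to_cfu(mass_mg, cell_mass: float):
    """Inverse of :func:`cfu_to_mass`; requires strictly positive biomass."""
    if cell_mass <= 0:
        raise DataError("cell_mass must be positive")
    value = np.asarray(mass_mg, dtype=float)
    if np.any(value <= 0):
        raise DataError("biomass must be positive to convert to log10 CFU")
    result = np.log10(value / cell_mass)
    return float(result) if result.ndim == 0 else result


def to_model_units(
    dataset: FermentationDataset, cell_masses: dict | None = None
) -> FermentationDataset:
    """Convert the three microbial series from log10 CFU/g to mg/g pulp."""
    if dataset.units == "mass":
        return dataset
    cell_masses = dict(DEFAULT_CELL_MASS_MG, **(cell_masses or {}))
    obs = dataset.observations.copy()
    for name in MICROBE_NAMES:
        j = STATE_NAMES.index(name)
        col = obs[:, j]
        finite = np.isfinite(col)
        converted = np.full_like(col, np.nan)
        converted[finite] = cfu_to_mass(col[finite], cell_masses[name])
        obs[:, j] = converted
    return replace(dataset, observations=obs, units="mass")


def max_scale(
    dataset: FermentationDataset, cell_masses: dict | None = None
) -> ScaledDataset:
    """Divide each series by its own maximum (ignoring missing values).

    Raw-unit datasets are first converted to model (mass) units.
    """
    dataset = to_model_units(dataset, cell_masses)
    obs = dataset.observations
    factors = np.full(len(STATE_NAMES), np.nan)
    for j, name in enumerate(STATE_NAMES):
        col = obs[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            raise DataError(f"series {name} is entirely missing")
        m = np.nanmax(col)
        if m <= 0:
            raise DataError(f"series {name} has non-positive maximum {m}")
        factors[j] = m
    return ScaledDataset(scaled=obs / factors, scale_factors=factors, source=dataset)


def unscale(scaled: ScaledDataset) -> np.ndarray:
    """Recover the mass-unit observation matrix from a scaled dataset."""
    return scaled.scaled * scaled.scale_factors


def _scale_ratio(spec, factors: dict) -> float:
    ratio = 1.0
    for name in spec.scale_num:
        ratio *= factors[name]
    for name in spec.scale_den:
        ratio /= factors[name]
    return ratio


def _factor_map(scale_factors) -> dict:
    factors = np.asarray(scale_factors, dtype=float)
    if factors.shape != (len(STATE_NAMES),):
        raise DataError("scale_factors must have one entry per state")
    if np.any(factors <= 0) or np.any(~np.isfinite(factors)):
        raise DataError("scale factors must be positive and finite")
    return dict(zip(STATE_NAMES, factors))


def rescale_params(
    scaled_params: dict, scale_factors, variant: ModelVariant | None = None
) -> dict:
    """Map parameter estimates from scaled units back to original units.

    Growth and decay rates are time-only (h^-1) and pass through; Monod
    saturation constants pick up their substrate's maximum (Contois: the
    LA/AAB maximum ratio); yields pick up metabolite-over-biomass maxima;
    mortality constants divide by the relevant product maximum (squared for
    AAB).  This is the unique map under which scaled-space and raw-space
    integrations are dynamically equivalent.
    """
    factors = _factor_map(scale_factors)
    names = variant.parameter_names if variant is not None else scaled_params.keys()
    out = {}
    for name in names:
        spec = PARAMETER_TABLE[PARAM_INDEX[name]]
        out[name] = scaled_params[name] * _scale_ratio(spec, factors)
    return out


def scale_params(
    raw_params: dict, scale_factors, variant: ModelVariant | None = None
) -> dict:
    """Inverse of :func:`rescale_params`: original units to scaled units."""
    factors = _factor_map(scale_factors)
    names = variant.parameter_names if variant is not None else raw_params.keys()
    out = {}
    for name in names:
        spec = PARAMETER_TABLE[PARAM_INDEX[name]]
        out[name] = raw_params[name] / _scale_ratio(spec, factors)
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_dataset_csv(
    path, code: str | None = None, features_path=None, units: str = "raw"
) -> FermentationDataset:
    """Read a trial from CSV with columns ``time,Glc,...,AAB``.

    An optional JSON sidecar supplies metadata features (country, cultivar,
    method, turning, controlled_temperature).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    expected = ["time", *STATE_NAMES]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    features = {}
    if features_path is not None:
        features = json.loads(Path(features_path).read_text())
    else:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            features = json.loads(sidecar.read_text())
    return FermentationDataset(
        code=code or path.stem,
        times=frame["time"].to_numpy(),
        observations=frame[list(STATE_NAMES)].to_numpy(),
        features=features,
        units=units,
    )


def write_dataset_csv(dataset: FermentationDataset, path, write_features: bool = True):
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    if write_features and dataset.features:
        path.with_suffix(".json").write_text(json.dumps(dataset.features, indent=2))
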