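"""Classifying fermentation features from posterior parameter draws.

Posterior draws (rescaled to original units) from fits of one variant over
many trials are pooled, filtered to their per-chain 95% credible boxes,
optionally restricted to a biologically meaningful parameter subgroup, and
projected by PCA (mean-centred, unscaled).  Separation between feature
classes (cultivar, country, method, turning, temperature control) is
quantified by pairwise squared Mahalanobis distances between class
centroids on the first two principal components, summarized by their
median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .model_core import PARAMETER_TABLE, PARAM_INDEX
from .preprocessing import rescale_params

__all__ = [
    "SUBGROUPS",
    "DrawTable",
    "PcaResult",
    "SeparationResult",
    "filter_ci_draws",
    "build_draw_table",
    "subset_params",
    "param_subgroup",
    "run_pca",
    "pairwise_mahalanobis",
]

SUBGROUPS = (
    "all",
    "max_growth_rates",
    "mortality_rates",
    "yield_coefficients",
    "Y_related",
    "LAB_related",
    "AAB_related",
)

_METADATA_COLUMNS = ("dataset", "chain", "class_label")


@dataclass(frozen=True)
class DrawTable:
    """Pooled retained posterior draws with per-row provenance.

    ``data`` holds one column per (rescaled) model parameter plus the
    metadata columns dataset, chain and class_label.
    """

    data: pd.DataFrame
    variant_label: str

    @property
    def param_names(self) -> tuple:
        return tuple(c for c in self.data.columns if c not in _METADATA_COLUMNS)

    @property
    def values(self) -> np.ndarray:
        return self.data[list(self.param_names)].to_numpy(dtype=float)

    @property
    def classes(self) -> np.ndarray:
        return self.data["class_label"].to_numpy()


def filter_ci_draws(fit, level: float = 0.95):
    """Retain draws lying inside every parameter's per-chain central CI.

    For each chain, the central ``level`` interval of each kinetic
    parameter is computed; a draw (row) is retained only if all of its
    coordinates fall inside their own intervals, keeping draw vectors
    joint.  Returns ``(draws, chain_ids)`` over the kinetic parameters
    (sigma excluded).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    q_lo, q_hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    theta = fit.draws[:, :-1]  # drop sigma
    kept_rows, kept_chains = [], []
    for chain in np.unique(fit.chain_ids):
        block = theta[fit.chain_ids == chain]
        lo, hi = np.percentile(block, [q_lo, q_hi], axis=0)
        inside = np.all((block >= lo) & (block <= hi), axis=1)
        kept_rows.append(block[inside])
        kept_chains.append(np.full(int(inside.sum()), chain))
    draws = np.vstack(kept_rows)
    if draws.shape[0] == 0:
        raise ValueError("credible-interval filtering retained no draws")
    return draws, np.concatenate(kept_chains)


def build_draw_table(
    fits,
    class_labels: dict | None = None,
    feature: str | None = None,
    level: float = 0.95,
    rescale: bool = False,
) -> DrawTable:
    """Pool CI-filtered draws from fits of one variant over several trials.

    ``fits`` maps dataset code to a PosteriorFit.  Class labels come
    either from ``class_labels`` (code → label) or from each fit's stored
    features via ``feature``.  By default draws stay on each trial's
    max-scaled space, where all parameters are of order one — the reason
    the downstream PCA can use mean-centring without variance scaling.
    With ``rescale`` they are instead transformed to original units using
    each fit's scale factors (useful for reporting, but then columns such
    as saturation constants in mg/g dominate an unscaled PCA).
    """
    if not fits:
        raise ValueError("no fits supplied")
    labels = None
    frames = []
    for code, fit in fits.items():
        names = fit.param_names[:-1]
        if labels is None:
            labels = names
            variant_label = fit.variant_label
        elif names != labels or fit.variant_label != variant_label:
            raise ValueError("all fits must come from the same model variant")
        draws, chains = filter_ci_draws(fit, level)
        if rescale:
            if fit.scale_factors is None:
                raise ValueError(f"fit {code!r} carries no scale factors")
            unit = dict.fromkeys(names, 1.0)
            ratios_map = rescale_params(unit, fit.scale_factors)
            draws = draws * np.array([ratios_map[n] for n in names])
        frame = pd.DataFrame(draws, columns=list(labels))
        frame["dataset"] = code
        frame["chain"] = chains
        if class_labels is not None:
            frame["class_label"] = class_labels[code]
        elif feature is not None:
            frame["class_label"] = fit.features.get(feature)
        else:
            frame["class_label"] = code
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    data = data[data["class_label"].notna()]
    return DrawTable(data=data, variant_label=variant_label)


def param_subgroup(parameter_names, subgroup: str) -> list:
    """Subset of parameter names belonging to a subgroup.

    Kind-based subgroups: maximum specific growth rates, mortality rates,
    yield coefficients.  Group-based subgroups (Y/LAB/AAB-related) collect
    every parameter whose definition names that microbial group, including
    its saturation constants.  Saturation constants and decay rates never
    form their own subgroup; both appear in "all", and saturation
    constants additionally in the related-group subsets.
    """
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")
    if subgroup == "all":
        return list(parameter_names)
    kind_map = {
        "max_growth_rates": "mu",
        "mortality_rates": "k",
        "yield_coefficients": "yield",
    }
    out = []
    for name in parameter_names:
        spec = PARAMETER_TABLE[PARAM_INDEX[name]]
        if subgroup in kind_map:
            if spec.kind == kind_map[subgroup]:
                out.append(name)
        else:  # {Y,LAB,AAB}_related
            group = subgroup.split("_")[0]
            if spec.group == group:
                out.append(name)
    return out


def subset_params(table: DrawTable, subgroup: str) -> DrawTable:
    """Column-restrict a draw table to one parameter subgroup."""
    names = param_subgroup(table.param_names, subgroup)
    if not names:
        raise ValueError(
            f"subgroup {subgroup!r} is empty for variant {table.variant_label}"
        )
    data = table.data[names + list(_METADATA_COLUMNS)].copy()
    return DrawTable(data=data, variant_label=table.variant_label)


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # (rows, components)
    loadings: np.ndarray  # (parameters, components)
    explained_variance_ratio: np.ndarray
    param_names: tuple


def run_pca(table: DrawTable | np.ndarray, n_components: int | None = None) -> PcaResult:
    """PCA on mean-centred (never variance-scaled) parameter draws.

    Deterministic up to component sign; the sign is fixed so that each
    component's largest-magnitude loading is positive.
    """
    if isinstance(table, DrawTable):
        X = table.values
        names = table.param_names
    else:
        X = np.asarray(table, dtype=float)
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    k = n_components or min(X.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # (params, components)
    for j in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        param_names=names,
    )


@dataclass(frozen=True)
class SeparationResult:
    """Pairwise squared Mahalanobis distances between class centroids."""

    distances: pd.DataFrame  # symmetric, zero diagonal
    median: float
    centroids: pd.DataFrame
    pooled_cov: np.ndarray

    @property
    def pairs(self) -> list:
        labels = list(self.distances.index)
        return [
            (a, b, self.distances.loc[a, b])
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
        ]


def pairwise_mahalanobis(scores: np.ndarray, classes) -> SeparationResult:
    """Squared Mahalanobis separation of class centroids on (PC1, PC2).

    The metric is the pooled within-class covariance of the scores; the
    median over class pairs summarizes a feature's overall separation.
    """
    X = np.asarray(scores, dtype=float)[:, :2]
    classes = np.asarray(classes)
    labels = [lab for lab in pd.unique(classes)]
    if len(labels) < 2:
        raise ValueError("at least 2 classes are required")
    groups = {lab: X[classes == lab] for lab in labels}
    for lab, g in groups.items():
        if g.shape[0] < 3:
            raise ValueError(f"class {lab!r} has fewer than 3 rows")

    n_total = X.shape[0]
    pooled = np.zeros((2, 2))
    cents = {}
    for lab, g in groups.items():
        c = g.mean(axis=0)
        cents[lab] = c
        dev = g - c
        pooled += dev.T @ dev
    pooled /= n_total - len(labels)

    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"pooled within-class covariance is singular (condition number {cond:.3g})"
        )
    inv = np.linalg.inv(pooled)

    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = cents[a] - cents[b]
            val = float(d @ inv @ d)
            dist.loc[a, b] = val
            dist.loc[b, a] = val
    offdiag = [dist.loc[a, b] for i, a in enumerate(labels) for b in labels[i + 1 :]]
    return SeparationResult(
        distances=dist,
        median=float(np.median(offdiag)),
        centroids=pd.DataFrame(cents, index=["PC1", "PC2"]).T,
        pooled_cov=pooled,
    )
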