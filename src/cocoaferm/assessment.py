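"""Scoring model variants across a collection of fermentation datasets.

Two complementary views of variant quality:

* predictive accuracy per dataset, via PSIS-LOO (Pareto-smoothed
  importance-sampling leave-one-out cross-validation) and pseudo-BMA
  weights (a softmax over LOO elpd values), averaged into a per-variant
  ``BMA_w`` with failed fits contributing zero;
* robustness across datasets, via the observed success rate (OSR — the
  fraction of usable datasets a variant fits successfully) and, for
  multi-mechanism variants, the expected success rate (ESR — the product
  of the stand-alone OSRs of its constituent mechanisms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .model_core import MechanismSet, build_variant, enumerate_variants

__all__ = [
    "LooResult",
    "SuccessMatrix",
    "psis_loo",
    "pseudo_bma_weights",
    "mean_bma",
    "compute_osr",
    "compute_esr",
    "assessment_table",
]


@dataclass(frozen=True)
class LooResult:
    """Expected log pointwise predictive density estimated by PSIS-LOO."""

    elpd: float
    se: float
    pareto_k: np.ndarray
    pointwise: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.pointwise.size


def psis_loo(pointwise_loglik: np.ndarray, chain_ids=None) -> LooResult:
    """PSIS-LOO from a (draws, observations) pointwise log-likelihood matrix.

    With ``chain_ids`` the draws are split into their chains so that the
    relative efficiency entering the importance-sampling diagnostics is
    estimated from the actual autocorrelation; otherwise a single chain is
    assumed.  Degenerate input (identical draws) reduces to the in-sample
    log predictive density with undefined (NaN) Pareto shapes.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log likelihood must be (draws, observations)")
    n_draws, n_obs = ll.shape
    if n_draws < 100:
        raise ValueError("at least 100 draws are required for PSIS-LOO")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log likelihood contains non-finite values")

    if np.allclose(ll, ll[0], rtol=0, atol=1e-12):
        pointwise = ll[0]
        se = float(np.sqrt(n_obs * np.var(pointwise)))
        return LooResult(
            elpd=float(pointwise.sum()),
            se=se,
            pareto_k=np.full(n_obs, np.nan),
            pointwise=pointwise,
        )

    if chain_ids is not None:
        chain_ids = np.asarray(chain_ids)
        chains = np.unique(chain_ids)
        per = [ll[chain_ids == c] for c in chains]
        depth = min(len(x) for x in per)
        cube = np.stack([x[:depth] for x in per])  # (chain, draw, obs)
    else:
        cube = ll[None, :, :]

    if cube.shape[0] > 1:
        # relative efficiency from the log-likelihood's own autocorrelation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = az.ess(az.from_dict(posterior={"ll": cube}), method="mean")
        reff = float(np.nanmean(ess["ll"].values) / (cube.shape[0] * cube.shape[1]))
        reff = min(max(reff, 1e-3), 1.0)
    else:
        reff = 1.0

    idata = az.from_dict(log_likelihood={"y": cube})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True, reff=reff)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
        pointwise=np.asarray(res.loo_i.values, dtype=float),
    )


def pseudo_bma_weights(loos) -> np.ndarray:
    """Pseudo-BMA weights: softmax of elpd values over competing models.

    Accepts LooResult objects or plain elpd floats; invariant under a
    common shift of all elpds.  This is the basic exp(elpd) normalization
    without the Bayesian-bootstrap correction.
    """
    if len(loos) == 0:
        raise ValueError("at least one model is required")
    elpds = np.array(
        [loo.elpd if isinstance(loo, LooResult) else float(loo) for loo in loos]
    )
    shifted = elpds - elpds.max()
    w = np.exp(shifted)
    return w / w.sum()


class SuccessMatrix:
    """Success/failure/not-run bookkeeping for (variant, dataset) pairs.

    Backed by a DataFrame with variant labels as rows and dataset codes as
    columns; entries are 1.0 (success), 0.0 (failure) or NaN (not run).
    """

    def __init__(self, variants=None, datasets=None, table: pd.DataFrame | None = None):
        if table is not None:
            self.table = table.astype(float)
        else:
            variants = [
                v.label if isinstance(v, MechanismSet) else str(v)
                for v in (variants if variants is not None else enumerate_variants())
            ]
            self.table = pd.DataFrame(
                np.nan, index=list(variants), columns=list(datasets or [])
            )

    def record(self, variant_label: str, dataset_code: str, success: bool):
        self.table.loc[variant_label, dataset_code] = float(success)

    @property
    def qualifying_datasets(self) -> list:
        """Datasets fitted successfully by at least one variant."""
        col_ok = (self.table == 1.0).any(axis=0)
        return list(self.table.columns[col_ok])

    def successes(self, variant_label: str) -> int:
        return int((self.table.loc[variant_label] == 1.0).sum())

    def __repr__(self):
        return f"SuccessMatrix({self.table.shape[0]} variants x {self.table.shape[1]} datasets)"


def compute_osr(success: SuccessMatrix) -> pd.Series:
    """Observed success rate per variant.

    The denominator is the number of datasets fitted by at least one
    variant; datasets no variant could describe are excluded.
    """
    qualifying = success.qualifying_datasets
    if not qualifying:
        raise ValueError("no dataset was fitted by any variant; OSR undefined")
    d = len(qualifying)
    sub = success.table[qualifying]
    return (sub == 1.0).sum(axis=1) / d


def compute_esr(osr_singles, mechanisms: MechanismSet | str) -> float:
    """Expected success rate: product of the stand-alone mechanism OSRs.

    ``osr_singles`` maps mechanism index (1..5) to the OSR of the
    corresponding single-mechanism variant.  Defined only for variants
    with at least two mechanisms.
    """
    if isinstance(mechanisms, str):
        mechanisms = MechanismSet.from_label(mechanisms)
    if len(mechanisms) < 2:
        raise ValueError("ESR is defined only for multi-mechanism variants")
    esr = 1.0
    for i in mechanisms.indices:
        esr *= float(osr_singles[i])
    return esr


def mean_bma(weights_by_dataset: dict, success: SuccessMatrix) -> pd.Series:
    """Average pseudo-BMA weight per variant over qualifying datasets.

    ``weights_by_dataset`` maps dataset code to a {variant label: weight}
    dict over the variants that succeeded on that dataset.  A variant
    contributes zero on datasets where it failed or was not run; the
    denominator is the number of datasets fitted by at least one variant.
    """
    qualifying = success.qualifying_datasets
    if not qualifying:
        raise ValueError("no qualifying datasets")
    d = len(qualifying)
    out = pd.Series(0.0, index=success.table.index)
    for code in qualifying:
        for label, w in weights_by_dataset.get(code, {}).items():
            out[label] += w
    return out / d


def assessment_table(
    success: SuccessMatrix, weights_by_dataset: dict, round_to: int | None = None
) -> pd.DataFrame:
    """Per-variant summary: label, parameter count, BMA_w, OSR, ESR.

    ESR is reported only for variants with >= 2 mechanisms (NaN
    otherwise).  ``round_to`` applies display rounding; internals keep
    full precision.
    """
    osr = compute_osr(success)
    bma = mean_bma(weights_by_dataset, success)
    osr_singles = {}
    for i in range(1, 6):
        label = MechanismSet.from_indices([i]).label
        if label in osr.index:
            osr_singles[i] = osr[label]

    rows = []
    for label in success.table.index:
        ms = MechanismSet.from_label(label)
        esr = np.nan
        if len(ms) >= 2 and all(i in osr_singles for i in ms.indices):
            esr = compute_esr(osr_singles, ms)
        rows.append(
            {
                "variant": label,
                "n_params": build_variant(ms).n_params,
                "BMA_w": bma[label],
                "OSR": osr[label],
                "ESR": esr,
            }
        )
    frame = pd.DataFrame(rows).set_index("variant")
    if round_to is not None:
        for col in ("BMA_w", "OSR", "ESR"):
            frame[col] = frame[col].round(round_to)
    return frame
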