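"""Synthetic multivariate longitudinal data with a known generating truth.

Two study designs are built in.  Both have three markers, each with a fixed
and random intercept and slope on a scaled visit-time covariate, and a joint
6x6 random-effects covariance shared across markers:

* scenario 1 — three Gaussian markers,
* scenario 2 — the same coefficients and covariance, but marker 2 is Poisson
  (log link) and marker 3 is Bernoulli (logit link).

Each subject receives a number of visits drawn uniformly from {5, ..., 10};
the covariate is visit time scaled to [0, 1] and shared across markers at a
visit (one schedule per subject).  An optional per-marker missingness rate
drops individual observations, mimicking studies where not every marker is
collected at every visit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    MARKER_COL,
    RESPONSE_COL,
    SUBJECT_COL,
    ConfigurationError,
    LongitudinalDataset,
    MarkerSpec,
    read_long_table,
)
from .families import BERNOULLI, GAUSSIAN, POISSON

__all__ = ["TrueModel", "scenario_truth", "simulate_dataset", "TIME_COL"]

TIME_COL = "time"

_SCENARIO_BETA = {
    0: (0.68, -0.95),
    1: (-2.50, 0.12),
    2: (0.45, 1.21),
}

_SCENARIO_SIGMA2_EPS = (0.10, 0.25, 0.15)

_SCENARIO_SIGMA_R = np.array(
    [
        [2.58, 0.46, 0.22, 0.42, 0.78, 0.23],
        [0.46, 1.21, 0.37, 0.69, 0.14, 0.19],
        [0.22, 0.37, 1.04, 0.73, 0.61, 0.38],
        [0.42, 0.69, 0.73, 1.36, 0.87, 0.14],
        [0.78, 0.14, 0.61, 0.87, 1.73, 0.92],
        [0.23, 0.19, 0.38, 0.14, 0.92, 1.47],
    ]
)


@dataclass(frozen=True)
class TrueModel:
    """A generating MGLMM: marker specs, coefficients and covariance."""

    marker_specs: tuple[MarkerSpec, ...]
    beta: tuple[np.ndarray, ...]  # per-marker fixed-effect vectors
    sigma2_eps: dict  # marker index -> residual variance (gaussian only)
    Sigma_R: np.ndarray
    visit_range: tuple[int, int] = (5, 10)
    missing_rate: float = 0.0

    def __post_init__(self):
        q = sum(sp.q_r for sp in self.marker_specs)
        SR = np.asarray(self.Sigma_R, dtype=float)
        if SR.shape != (q, q):
            raise ConfigurationError(
                f"Sigma_R must be {q}x{q} for these marker specs, got {SR.shape}"
            )
        np.linalg.cholesky(SR)  # SPD required
        for r, sp in enumerate(self.marker_specs):
            if len(self.beta[r]) != sp.p_r:
                raise ConfigurationError(f"beta[{r}] has wrong length")

    def beta_stacked(self) -> np.ndarray:
        return np.concatenate([np.asarray(b, dtype=float) for b in self.beta])


def _scenario_specs(families) -> tuple[MarkerSpec, ...]:
    return tuple(
        MarkerSpec(
            name=f"marker{r + 1}",
            family=fam,
            fixed=("intercept", TIME_COL),
            random=("intercept", TIME_COL),
        )
        for r, fam in enumerate(families)
    )


def scenario_truth(scenario_id: int) -> TrueModel:
    """The built-in generating models (see module docstring)."""
    if scenario_id == 1:
        families = (GAUSSIAN, GAUSSIAN, GAUSSIAN)
        sigma2 = {0: 0.10, 1: 0.25, 2: 0.15}
    elif scenario_id == 2:
        families = (GAUSSIAN, POISSON, BERNOULLI)
        sigma2 = {0: 0.10}
    else:
        raise ConfigurationError(f"unknown scenario id {scenario_id!r}; expected 1 or 2")
    return TrueModel(
        marker_specs=_scenario_specs(families),
        beta=tuple(np.array(_SCENARIO_BETA[r]) for r in range(3)),
        sigma2_eps=sigma2,
        Sigma_R=_SCENARIO_SIGMA_R.copy(),
    )


def simulate_dataset(
    truth: TrueModel, m: int, seed: int
) -> tuple[LongitudinalDataset, np.ndarray]:
    """Draw ``m`` subjects from the generating model; returns the validated
    dataset and the latent random effects (``m x q``) for recovery testing.

    Draw order is fixed (visit counts, random effects, responses per marker)
    so datasets are bit-identical given ``(truth, m, seed)``.
    """
    if m < 1:
        raise ConfigurationError("m must be at least 1")
    rng = np.random.default_rng(seed)
    lo, hi = truth.visit_range
    n_visits = rng.integers(lo, hi + 1, size=m)
    q = truth.Sigma_R.shape[0]
    u = rng.multivariate_normal(np.zeros(q), truth.Sigma_R, size=m, method="cholesky")

    q_off = np.concatenate([[0], np.cumsum([sp.q_r for sp in truth.marker_specs])])

    # one shared visit schedule per subject: time scaled to [0, 1]
    subj = np.repeat(np.arange(m), n_visits)
    starts = np.concatenate([[0], np.cumsum(n_visits)[:-1]])
    j = np.arange(len(subj)) - starts[subj]
    denom = np.maximum(n_visits[subj] - 1, 1)
    x = j / denom

    def resolve(name: str) -> np.ndarray:
        if name == "intercept":
            return np.ones_like(x)
        if name == TIME_COL:
            return x
        raise ConfigurationError(
            f"the simulator only generates 'intercept' and '{TIME_COL}' covariates, "
            f"got {name!r}"
        )

    frames = []
    for r, sp in enumerate(truth.marker_specs):
        Xr = np.column_stack([resolve(c) for c in sp.fixed])
        Zr = np.column_stack([resolve(c) for c in sp.random])
        eta = Xr @ np.asarray(truth.beta[r], dtype=float)
        eta += np.einsum("nk,nk->n", Zr, u[subj, q_off[r] : q_off[r + 1]])
        tag = sp.family.family_tag
        if tag == "gaussian":
            y = eta + rng.normal(0.0, np.sqrt(truth.sigma2_eps[r]), size=len(eta))
        elif tag == "poisson":
            y = rng.poisson(np.exp(eta)).astype(float)
        else:
            y = (rng.random(len(eta)) < expit(eta)).astype(float)
        frames.append(
            pd.DataFrame(
                {SUBJECT_COL: subj, MARKER_COL: sp.name, TIME_COL: x, RESPONSE_COL: y}
            )
        )
    table = pd.concat(frames, ignore_index=True)

    if truth.missing_rate > 0.0:
        keep = rng.random(len(table)) >= truth.missing_rate
        table = table.loc[keep].reset_index(drop=True)

    dataset = read_long_table(table, truth.marker_specs)
    return dataset, u


def write_truth_sidecar(truth: TrueModel, m: int, seed: int, path) -> None:
    """Write the generating parameters next to a simulated CSV (JSON)."""
    import json

    payload = {
        "m": m,
        "seed": seed,
        "markers": [
            {
                "name": sp.name,
                "family": sp.family.family_tag,
                "beta": list(map(float, truth.beta[r])),
                "sigma2_eps": truth.sigma2_eps.get(r),
            }
            for r, sp in enumerate(truth.marker_specs)
        ],
        "Sigma_R": np.asarray(truth.Sigma_R).tolist(),
        "visit_range": list(truth.visit_range),
        "missing_rate": truth.missing_rate,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
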