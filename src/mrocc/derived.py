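"""Reported quantities derived from posterior draws.

Turns a :class:`~mrocc.mcmc.PosteriorSamples` into the study's deliverables:
per-region richness estimates next to observed counts, coefficient tables
with credible-interval significance classes, covariate prediction curves for
expected richness M*Omega and community occupancy, and the marginal
human-density effect (how many extra persons/km2 produce a given fractional
richness decline at the reference landscape).

Significance convention: an effect is *significant* when its 90% equal-tailed
credible interval excludes zero, *weak* when only the 50% interval does, and
*none* otherwise. Prediction curves hold the other covariates at the
reference profile — standardized mean (0), Afrotropics, fast-trigger camera —
with species random effects set to zero (the community-median species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data_model import StandardizationRecord
from .mcmc import PosteriorSamples, summarize
from .model_core import OCCUPANCY_TERMS, RICHNESS_TERMS

__all__ = [
    "SIGNIFICANT_90",
    "WEAK_50",
    "NONE",
    "EffectSummary",
    "classify_significance",
    "effects_table",
    "richness_table",
    "expected_richness",
    "predict_richness_curve",
    "predict_occupancy_curve",
    "marginal_density_effect",
]

SIGNIFICANT_90 = "significant_90"
WEAK_50 = "weak_50"
NONE = "none"


@dataclass(frozen=True)
class EffectSummary:
    block: str  # richness | occupancy | detection
    parameter: str
    median: float
    lo50: float
    hi50: float
    lo90: float
    hi90: float
    significance: str


def classify_significance(
    ci50: tuple[float, float], ci90: tuple[float, float]
) -> str:
    """Classify an effect from its nested 50% and 90% credible intervals."""
    lo50, hi50 = ci50
    lo90, hi90 = ci90
    if lo50 > hi50 or lo90 > hi90:
        raise ValueError("malformed interval (lo > hi)")
    if lo50 < lo90 - 1e-12 or hi50 > hi90 + 1e-12:
        raise ValueError("50% interval must lie within the 90% interval")
    if lo90 > 0 or hi90 < 0:
        return SIGNIFICANT_90
    if lo50 > 0 or hi50 < 0:
        return WEAK_50
    return NONE


_BLOCKS = (
    ("richness", "beta", RICHNESS_TERMS),
    ("occupancy", "theta", OCCUPANCY_TERMS),
    ("detection", "alpha", ("intercept", "cam_type", "settl_site")),
)


def effects_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Slope effects of all three blocks with significance classes."""
    rows = []
    for block, prefix, terms in _BLOCKS:
        for term in terms:
            if term == "intercept":
                continue
            x = samples.scalar(f"{prefix}_{term}").ravel()
            lo50, hi50 = np.quantile(x, [0.25, 0.75])
            lo90, hi90 = np.quantile(x, [0.05, 0.95])
            rows.append(
                EffectSummary(
                    block=block,
                    parameter=term,
                    median=float(np.median(x)),
                    lo50=float(lo50),
                    hi50=float(hi50),
                    lo90=float(lo90),
                    hi90=float(hi90),
                    significance=classify_significance(
                        (float(lo50), float(hi50)), (float(lo90), float(hi90))
                    ),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def richness_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-region observed n_r and estimated richness (median, 90% CI).

    The reported median is rounded to the nearest whole species.
    """
    rows = []
    N = samples.draws["N"]  # (C, S, R)
    for r, rid in enumerate(samples.region_ids):
        x = N[:, :, r].ravel()
        lo, hi = np.quantile(x, [0.05, 0.95])
        rows.append(
            {
                "region_id": rid,
                "n_observed": int(samples.n_obs[r]),
                "N_median": int(round(float(np.median(x)))),
                "N_mean": float(x.mean()),
                "lo90": float(lo),
                "hi90": float(hi),
            }
        )
    return pd.DataFrame(rows)


def expected_richness(Omega, M: int):
    """E[N_r] = M * Omega_r, the data-augmentation identity."""
    return M * np.asarray(Omega, dtype=float)


def _beta_draws(samples: PosteriorSamples) -> np.ndarray:
    b = samples.draws["beta"]
    return b.reshape(-1, b.shape[-1])


def _reference_eta(
    draws: np.ndarray, terms: tuple, reference: dict[str, float] | None
) -> np.ndarray:
    """Linear predictor of each draw at a reference covariate profile."""
    x = np.zeros(len(terms))
    x[0] = 1.0
    for name, val in (reference or {}).items():
        if name not in terms:
            raise KeyError(f"unknown covariate {name!r}")
        x[terms.index(name)] = val
    return draws @ x


def predict_richness_curve(
    samples: PosteriorSamples,
    covariate: str,
    grid,
    reference: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Median and 90% band of expected richness M*Omega along one covariate.

    ``grid`` is in standardized units; other covariates sit at the reference
    profile (0 = their mean; Afrotropics).
    """
    if covariate not in RICHNESS_TERMS or covariate == "intercept":
        raise KeyError(f"unknown richness covariate {covariate!r}")
    draws = _beta_draws(samples)
    k = RICHNESS_TERMS.index(covariate)
    eta0 = _reference_eta(draws, RICHNESS_TERMS, reference)
    rows = []
    for g in np.atleast_1d(np.asarray(grid, dtype=float)):
        vals = samples.M * expit(eta0 + draws[:, k] * g)
        lo, hi = np.quantile(vals, [0.05, 0.95])
        rows.append(
            {
                "covariate": covariate,
                "x": float(g),
                "median": float(np.median(vals)),
                "lo90": float(lo),
                "hi90": float(hi),
            }
        )
    return pd.DataFrame(rows)


def predict_occupancy_curve(
    samples: PosteriorSamples,
    covariate: str,
    grid,
    reference: dict[str, float] | None = None,
    integrate_random_effects: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Median and 90% band of community occupancy along one covariate.

    By default the species random effect is set to zero (the community-median
    species). ``integrate_random_effects=True`` instead averages the inverse
    logit over eps ~ Normal(0, sigma_psi) per draw (sigma averaged over
    regions), giving the community-mean species.
    """
    if covariate not in OCCUPANCY_TERMS or covariate == "intercept":
        raise KeyError(f"unknown occupancy covariate {covariate!r}")
    t = samples.draws["theta"]
    draws = t.reshape(-1, t.shape[-1])
    k = OCCUPANCY_TERMS.index(covariate)
    eta0 = _reference_eta(draws, OCCUPANCY_TERMS, reference)
    if integrate_random_effects:
        sig = samples.draws["sigma_psi"].reshape(draws.shape[0], -1).mean(axis=1)
        eps = np.random.default_rng(seed).standard_normal((16, 1))
    rows = []
    for g in np.atleast_1d(np.asarray(grid, dtype=float)):
        eta = eta0 + draws[:, k] * g
        if integrate_random_effects:
            vals = expit(eta[None, :] + eps * sig[None, :]).mean(axis=0)
        else:
            vals = expit(eta)
        lo, hi = np.quantile(vals, [0.05, 0.95])
        rows.append(
            {
                "covariate": covariate,
                "x": float(g),
                "median": float(np.median(vals)),
                "lo90": float(lo),
                "hi90": float(hi),
            }
        )
    return pd.DataFrame(rows)


def marginal_density_effect(
    samples: PosteriorSamples,
    hden_record: StandardizationRecord,
    decline_fraction: float = 0.01,
    reference: dict[str, float] | None = None,
) -> float:
    """Raw-scale human-density increase producing a given richness decline.

    At the posterior-median richness coefficients, solves for the increase
    Delta (persons/km2) such that expected richness at the reference profile
    shifted by Delta equals (1 - decline_fraction) times its reference value.
    Returns NaN when the human-density effect is zero or the wrong sign
    (no finite increase produces a decline).
    """
    if not (0.0 < decline_fraction < 1.0):
        raise ValueError("decline_fraction must be in (0, 1)")
    beta_med = np.median(_beta_draws(samples), axis=0)
    k = RICHNESS_TERMS.index("hden")
    x = np.zeros(len(RICHNESS_TERMS))
    x[0] = 1.0
    for name, val in (reference or {}).items():
        x[RICHNESS_TERMS.index(name)] = val
    eta0 = float(beta_med @ x)
    slope = float(beta_med[k])
    ref_std = float(x[k])
    target = (1.0 - decline_fraction) * expit(eta0)
    if slope >= 0 or target <= 0 or target >= 1:
        return float("nan")
    # logit(target) = eta0 + slope * delta_std  (all else fixed)
    delta_std = (float(logit(target)) - eta0) / slope
    return float(delta_std * hden_record.sd)


def solve_density_effect_bisection(
    beta_median: np.ndarray,
    hden_record: StandardizationRecord,
    M: int,
    decline_fraction: float = 0.01,
    hi: float = 1e3,
) -> float:
    """Root-finding variant of the marginal density effect (standardized
    shift solved by bisection, then mapped to persons/km2). Used as an
    internal cross-check of the closed-form solution."""
    k = RICHNESS_TERMS.index("hden")
    eta0 = float(beta_median[0])
    slope = float(beta_median[k])
    ref_val = M * expit(eta0)

    def f(d):
        return M * expit(eta0 + slope * d) - (1 - decline_fraction) * ref_val

    if slope >= 0:
        return float("nan")
    d = brentq(f, 0.0, hi, xtol=1e-12)
    return float(d * hden_record.sd)
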