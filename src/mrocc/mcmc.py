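"""Metropolis-within-Gibbs sampler for the multi-region community model.

Sweep order per iteration:

1. membership indicators ``omega`` from their full conditional with the
   occupancy states ``z`` marginalized site-by-site (partially collapsed:
   avoids the absorbing state where z = 0 everywhere locks omega at 0);
2. ``z`` from its full conditional given the fresh omega;
3. each continuous block — beta, theta, alpha, the species random effects
   eps (element-wise), and the region random-effect SDs (on the log scale
   with a Jacobian correction) — by adaptive random-walk Metropolis.

Proposal scales adapt by Robbins–Monro toward a 0.44 univariate acceptance
rate during burn-in and are frozen afterwards, so retained draws come from a
fixed kernel. Richness N_r = n_r + (augmented omega sum) is recorded every
retained iteration. Runs are deterministic given the config seed.

Diagnostics are the classic ones an S1-style summary table reports: the
Gelman–Rubin potential scale reduction factor (split-chain by default, with
the unsplit two-chain variant available) and autocorrelation-sum effective
sample size.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, log_expit

from .data_model import (
    AugmentedDetectionArray,
    CovariateTable,
    StudyDataset,
    augment,
    standardize_covariates,
    standardize_site_settlement,
)
from .model_core import (
    DETECTION_TERMS,
    Design,
    ModelParams,
    OCCUPANCY_TERMS,
    PriorSpec,
    RICHNESS_TERMS,
    occupancy_design_matrix,
    richness_design_matrix,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "build_design",
    "run",
    "fit",
    "rhat",
    "ess",
    "summarize",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    Presets: :meth:`desk` (3 x 15,000 with 5,000 burn-in; minutes on a
    laptop-scale problem), :meth:`recovery` (single short chain for replicate
    simulation studies), and :meth:`paper` (3 chains, 100,000 burn-in,
    400,000 retained post-burn-in draws, thin 1 — the full-study setting).
    """

    n_chains: int = 3
    n_iter: int = 15_000
    n_burnin: int = 5_000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44
    adapt_power: float = 0.6
    record_lp: bool = True

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin >= 1 and n_chains >= 1 required")

    @property
    def n_retained(self) -> int:
        return -(-(self.n_iter - self.n_burnin) // self.thin)

    @classmethod
    def desk(cls, seed: int = 0) -> "SamplerConfig":
        return cls(n_chains=3, n_iter=15_000, n_burnin=5_000, seed=seed)

    @classmethod
    def recovery(cls, seed: int = 0) -> "SamplerConfig":
        return cls(n_chains=1, n_iter=4_000, n_burnin=1_500, seed=seed,
                   record_lp=False)

    @classmethod
    def paper(cls, seed: int = 0) -> "SamplerConfig":
        return cls(n_chains=3, n_iter=500_000, n_burnin=100_000, seed=seed)


@dataclass
class PosteriorSamples:
    """Retained draws of all monitored parameters plus derived richness.

    ``draws`` maps block names to arrays of shape (chains, retained) or
    (chains, retained, dim): beta, theta, alpha, sigma_psi, sigma_p, N, lp.
    """

    draws: dict[str, np.ndarray]
    region_ids: list[str]
    n_obs: np.ndarray  # n_r per region
    M: int
    config: SamplerConfig
    acceptance: dict[str, float] = field(default_factory=dict)
    runtime_s: float = 0.0
    standardization: dict | None = None

    def scalar_names(self) -> list[str]:
        names = [f"beta_{t}" for t in RICHNESS_TERMS]
        names += [f"theta_{t}" for t in OCCUPANCY_TERMS]
        names += [f"alpha_{t}" for t in DETECTION_TERMS]
        names += [f"sigma_psi_{r}" for r in self.region_ids]
        names += [f"sigma_p_{r}" for r in self.region_ids]
        names += [f"N_{r}" for r in self.region_ids]
        if "lp" in self.draws:
            names.append("lp")
        return names

    def scalar(self, name: str) -> np.ndarray:
        """Per-chain draws (chains, retained) of one scalar parameter."""
        if name == "lp":
            return self.draws["lp"]
        for block, terms in (
            ("beta", RICHNESS_TERMS),
            ("theta", OCCUPANCY_TERMS),
            ("alpha", DETECTION_TERMS),
        ):
            prefix = block + "_"
            if name.startswith(prefix) and name[len(prefix):] in terms:
                k = terms.index(name[len(prefix):])
                return self.draws[block][:, :, k]
        for block in ("sigma_psi", "sigma_p", "N"):
            prefix = block + "_"
            if name.startswith(prefix) and name[len(prefix):] in self.region_ids:
                r = self.region_ids.index(name[len(prefix):])
                return self.draws[block][:, :, r]
        raise KeyError(name)

    def summary(self, levels: Sequence[float] = (0.5, 0.9, 0.95)) -> pd.DataFrame:
        return summarize(self, levels=levels)

    def to_csv(self, path: str | Path) -> None:
        """Flat long-format export: chain, iter, parameter, value."""
        rows = []
        for name in self.scalar_names():
            x = self.scalar(name)
            for c in range(x.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iter": np.arange(x.shape[1]),
                            "parameter": name,
                            "value": x[c],
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# design / padding


def build_design(
    data: StudyDataset,
    std_covariates: pd.DataFrame,
    site_settl_std: dict[str, np.ndarray],
) -> Design:
    """Assemble padded standardized design arrays in dataset region order."""
    df = std_covariates.set_index("region_id").loc[data.region_ids].reset_index()
    X_rich = richness_design_matrix(df)
    X_occ = occupancy_design_matrix(df)
    J_max = max(r.n_sites for r in data.regions)
    R = data.n_regions
    cam = np.zeros((R, J_max))
    ssl = np.zeros((R, J_max))
    mask = np.zeros((R, J_max), dtype=bool)
    K = np.zeros((R, J_max))
    for r_i, reg in enumerate(data.regions):
        J = reg.n_sites
        cam[r_i, :J] = [1.0 if s.cam_trigger == "moderate" else 0.0 for s in reg.sites]
        ssl[r_i, :J] = site_settl_std[reg.region_id]
        mask[r_i, :J] = True
        K[r_i, :J] = reg.effort
    return Design(
        X_rich=X_rich, X_occ=X_occ, cam=cam, settl_site=ssl,
        site_mask=mask, K=K, region_ids=list(data.region_ids),
    )


def _pad_augmented(aug: AugmentedDetectionArray) -> tuple[np.ndarray, np.ndarray]:
    """(R, M, J_max) padded counts and (R, M) detected-row mask."""
    J_max = max(r.y.shape[1] for r in aug.regions)
    R = len(aug.regions)
    y = np.zeros((R, aug.M, J_max))
    det = np.zeros((R, aug.M), dtype=bool)
    for r_i, reg in enumerate(aug.regions):
        y[r_i, :, : reg.y.shape[1]] = reg.y
        det[r_i, : reg.n_detected] = True
    return y, det


# fast closed-form log prior densities for the supported families
def _prior_lp(entry: tuple, x):
    fam = entry[0]
    x = np.asarray(x, dtype=float)
    if fam == "normal":
        _, loc, sd = entry
        return -0.5 * ((x - loc) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
    if fam == "logistic":
        _, loc, scale = entry
        u = np.abs((x - loc) / scale)
        return -u - 2.0 * np.log1p(np.exp(-u)) - math.log(scale)
    if fam == "uniform":
        _, lo, hi = entry
        return np.where((x > lo) & (x < hi), -math.log(hi - lo), -np.inf)
    raise ValueError(f"unknown prior family {fam!r}")


def _zmul(indicator: np.ndarray, values: np.ndarray) -> np.ndarray:
    """indicator * values with the 0 * (-inf) = 0 convention."""
    return np.where(indicator == 0, 0.0, indicator * values)


# ---------------------------------------------------------------------------
# single chain


def _run_chain(
    y: np.ndarray,
    det: np.ndarray,
    design: Design,
    priors: PriorSpec,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    fixed: ModelParams | None,
) -> dict[str, np.ndarray]:
    R, M, J = y.shape
    mask = design.site_mask
    mask3 = mask[:, None, :]
    Kb = design.K[:, None, :]
    K_site = design.K  # (R, J)
    Xr, Xo = design.X_rich, design.X_occ
    cam, ssl = design.cam, design.settl_site
    n_act = design.n_active_sites.astype(float)
    ydet = y > 0

    # constant part of the binomial coefficients (nonzero only where y > 0,
    # and y > 0 forces z = 1, so the z-weighted sum never varies)
    logc_const = float(
        np.sum((gammaln(Kb + 1) - gammaln(y + 1) - gammaln(Kb - y + 1))[ydet])
    )

    if fixed is not None:
        beta = fixed.beta.copy()
        theta = fixed.theta.copy()
        alpha = fixed.alpha.copy()
        sigma_psi = np.broadcast_to(fixed.sigma_psi, (R,)).astype(float).copy()
        sigma_p = np.broadcast_to(fixed.sigma_p, (R,)).astype(float).copy()
        eps_psi = (
            fixed.eps_psi.copy() if fixed.eps_psi is not None else np.zeros((R, M))
        )
        eps_p = fixed.eps_p.copy() if fixed.eps_p is not None else np.zeros((R, M))
    else:
        beta = np.zeros(len(RICHNESS_TERMS))
        theta = np.zeros(len(OCCUPANCY_TERMS))
        alpha = np.zeros(len(DETECTION_TERMS))
        sigma_psi = np.ones(R)
        sigma_p = np.ones(R)
        eps_psi = np.zeros((R, M))
        eps_p = np.zeros((R, M))

    omega = det | (rng.random((R, M)) < 0.5)
    z = ((ydet | (rng.random((R, M, J)) < 0.5)) & mask3 & omega[:, :, None])

    # linear predictor caches (always finite: parameters are finite reals)
    eta_rich = Xr @ beta
    lpsi = (theta[0] + Xo @ theta[1:])[:, None] + eps_psi
    lgp = (alpha[0] + alpha[1] * cam + alpha[2] * ssl)[:, None, :] + eps_p[:, :, None]

    def llz_total(lpsi_arr, omega_f, sz):
        lsp = log_expit(lpsi_arr)
        rows = sz * lsp + (n_act[:, None] - sz) * (lsp - lpsi_arr)
        return float(np.sum(omega_f * rows))

    def ll_omega_total(eta, n_mem):
        ls = log_expit(eta)
        return float(np.sum(n_mem * ls + (M - n_mem) * (ls - eta)))

    def lly_dense(lgp_arr):
        lsp = log_expit(lgp_arr)
        inner = y * lsp + (Kb - y) * (lsp - lgp_arr)
        return float(inner[z].sum())

    # fallback if the random z initialization is impossible (e.g. psi or p
    # pinned numerically at a boundary by fixed parameters)
    omega_f = omega.astype(float)
    sz = (z.sum(axis=2)).astype(float)
    ll0 = (
        ll_omega_total(eta_rich, omega_f.sum(1))
        + llz_total(lpsi, omega_f, sz)
        + lly_dense(lgp)
    )
    if not np.isfinite(ll0):
        omega = det.copy()
        z = ydet & mask3
        omega_f = omega.astype(float)
        sz = z.sum(axis=2).astype(float)
        ll0 = (
            ll_omega_total(eta_rich, omega_f.sum(1))
            + llz_total(lpsi, omega_f, sz)
            + lly_dense(lgp)
        )
        if not np.isfinite(ll0):
            raise RuntimeError(
                "initialization has -inf posterior even at the "
                "detection-implied latent state"
            )

    # adaptive proposal scales (log scale for Robbins-Monro updates)
    ls_beta = np.full(len(beta), math.log(0.2))
    ls_theta = np.full(len(theta), math.log(0.2))
    ls_alpha = np.full(len(alpha), math.log(0.1))
    ls_eps_psi = np.full((R, M), math.log(0.5))
    ls_eps_p = np.full((R, M), math.log(0.5))
    ls_sig_psi = np.full(R, math.log(0.3))
    ls_sig_p = np.full(R, math.log(0.3))
    ls_scl_psi = np.full(R, math.log(0.1))
    ls_scl_p = np.full(R, math.log(0.1))

    n_keep = cfg.n_retained
    out = {
        "beta": np.empty((n_keep, len(beta))),
        "theta": np.empty((n_keep, len(theta))),
        "alpha": np.empty((n_keep, len(alpha))),
        "sigma_psi": np.empty((n_keep, R)),
        "sigma_p": np.empty((n_keep, R)),
        "N": np.empty((n_keep, R), dtype=int),
    }
    if cfg.record_lp:
        out["lp"] = np.empty(n_keep)
    acc_sums: dict[str, float] = {
        k: 0.0 for k in ("beta", "theta", "alpha", "eps_psi", "eps_p", "sigma")
    }
    n_post = 0

    occ_cols = [np.ones(R)] + [Xo[:, k] for k in range(Xo.shape[1])]
    tgt = cfg.target_accept

    keep_idx = 0
    for it in range(cfg.n_iter):
        adapting = it < cfg.n_burnin
        gamma = (it + 1) ** (-cfg.adapt_power) if adapting else 0.0

        # ---- 1. omega | params (z marginalized), then 2. z | omega --------
        lspsi = log_expit(lpsi)  # log psi, (R, M)
        psi = np.exp(lspsi)
        one_m_psi = np.exp(lspsi - lpsi)
        lsp_full = log_expit(lgp)  # log p
        lognm = Kb * (lsp_full - lgp)  # log (1-p)^K; K = 0 padding -> 0
        qK = np.exp(lognm)
        num = psi[:, :, None] * qK
        m = num + one_m_psi[:, :, None]
        with np.errstate(divide="ignore"):
            lm = np.where(mask3, np.log(m), 0.0).sum(axis=2)
        pr_omega = expit(eta_rich[:, None] + lm)
        omega = det | (rng.random((R, M)) < pr_omega)
        omega_f = omega.astype(float)

        pz = np.where(ydet, 1.0, num / np.maximum(m, 1e-300))
        z = (rng.random((R, M, J)) < pz) & mask3 & omega[:, :, None]
        n_mem = omega_f.sum(axis=1)

        # sparse view of occupied cells for the detection likelihood
        r_i, m_i, j_i = np.nonzero(z)
        row_id = r_i * M + m_i
        sz = np.bincount(row_id, minlength=R * M).reshape(R, M).astype(float)
        yz = y[r_i, m_i, j_i]
        Kz = K_site[r_i, j_i]

        if fixed is None:
            # ---- 3a. richness coefficients --------------------------------
            ll_om = ll_omega_total(eta_rich, n_mem)
            a_acc = np.empty(len(beta))
            for k in range(len(beta)):
                step = math.exp(ls_beta[k]) * rng.standard_normal()
                eta_new = eta_rich + step * Xr[:, k]
                ll_new = ll_omega_total(eta_new, n_mem)
                block = "intercepts" if k == 0 else "slopes"
                d = ll_new - ll_om + float(
                    _prior_lp(getattr(priors, block), beta[k] + step)
                    - _prior_lp(getattr(priors, block), beta[k])
                )
                a = 1.0 if d >= 0 else math.exp(d)
                a_acc[k] = a
                if rng.random() < a:
                    beta[k] += step
                    eta_rich = eta_new
                    ll_om = ll_new
            if adapting:
                ls_beta += gamma * (a_acc - tgt)
            acc_beta = float(a_acc.mean())

            # ---- 3b. community occupancy coefficients ---------------------
            ll_z = llz_total(lpsi, omega_f, sz)
            a_acc = np.empty(len(theta))
            for k in range(len(theta)):
                step = math.exp(ls_theta[k]) * rng.standard_normal()
                lpsi_new = lpsi + step * occ_cols[k][:, None]
                ll_new = llz_total(lpsi_new, omega_f, sz)
                block = "intercepts" if k == 0 else "slopes"
                d = ll_new - ll_z + float(
                    _prior_lp(getattr(priors, block), theta[k] + step)
                    - _prior_lp(getattr(priors, block), theta[k])
                )
                a = 1.0 if d >= 0 else math.exp(d)
                a_acc[k] = a
                if rng.random() < a:
                    theta[k] += step
                    lpsi = lpsi_new
                    ll_z = ll_new
            if adapting:
                ls_theta += gamma * (a_acc - tgt)
            acc_theta = float(a_acc.mean())

            # ---- 3c. species occupancy random effects (element-wise) ------
            prop = np.exp(ls_eps_psi) * rng.standard_normal((R, M))
            lpsi_new = lpsi + prop
            ls_old = log_expit(lpsi)
            ls_new = log_expit(lpsi_new)
            d = omega_f * (
                sz * (ls_new - ls_old)
                + (n_act[:, None] - sz) * ((ls_new - lpsi_new) - (ls_old - lpsi))
            )
            d -= ((eps_psi + prop) ** 2 - eps_psi**2) / (
                2.0 * sigma_psi[:, None] ** 2
            )
            a = np.exp(np.minimum(d, 0.0))
            acc = rng.random((R, M)) < a
            eps_psi = np.where(acc, eps_psi + prop, eps_psi)
            lpsi = np.where(acc, lpsi_new, lpsi)
            if adapting:
                ls_eps_psi += gamma * (a - tgt)
            acc_eps_psi = float(a.mean())

            # ---- 3d. detection coefficients (sparse over z = 1 cells) -----
            lgp_z = lgp[r_i, m_i, j_i]

            def lly_z(vals):
                lsp = log_expit(vals)
                return float(np.sum(yz * lsp + (Kz - yz) * (lsp - vals)))

            ll_y = lly_z(lgp_z)
            det_cols_z = (None, cam[r_i, j_i], ssl[r_i, j_i])
            a_acc = np.empty(len(alpha))
            alpha_shift = 0.0  # scalar part of accepted shifts (intercept)
            for k in range(len(alpha)):
                step = math.exp(ls_alpha[k]) * rng.standard_normal()
                vals_new = lgp_z + (step if k == 0 else step * det_cols_z[k])
                ll_new = lly_z(vals_new)
                block = "intercepts" if k == 0 else "slopes"
                d = ll_new - ll_y + float(
                    _prior_lp(getattr(priors, block), alpha[k] + step)
                    - _prior_lp(getattr(priors, block), alpha[k])
                )
                a = 1.0 if d >= 0 else math.exp(d)
                a_acc[k] = a
                if rng.random() < a:
                    alpha[k] += step
                    lgp_z = vals_new
                    ll_y = ll_new
                    if k == 0:
                        lgp += step
                    else:
                        lgp += step * (cam if k == 1 else ssl)[:, None, :]
            if adapting:
                ls_alpha += gamma * (a_acc - tgt)
            acc_alpha = float(a_acc.mean())

            # ---- 3e. species detection random effects (element-wise) ------
            prop = np.exp(ls_eps_p) * rng.standard_normal((R, M))
            vals_new = lgp_z + prop[r_i, m_i]
            lsp_o = log_expit(lgp_z)
            lsp_n = log_expit(vals_new)
            cell_d = (yz * (lsp_n - lsp_o)
                      + (Kz - yz) * ((lsp_n - vals_new) - (lsp_o - lgp_z)))
            d = np.bincount(row_id, weights=cell_d, minlength=R * M).reshape(R, M)
            d -= ((eps_p + prop) ** 2 - eps_p**2) / (2.0 * sigma_p[:, None] ** 2)
            a = np.exp(np.minimum(d, 0.0))
            acc = rng.random((R, M)) < a
            eps_p = np.where(acc, eps_p + prop, eps_p)
            lgp += np.where(acc, prop, 0.0)[:, :, None]
            if adapting:
                ls_eps_p += gamma * (a - tgt)
            acc_eps_p = float(a.mean())

            # ---- 3f. random-effect SDs on the log scale -------------------
            acc_sig_parts = []
            for eps, sig, ls in (
                (eps_psi, sigma_psi, ls_sig_psi),
                (eps_p, sigma_p, ls_sig_p),
            ):
                lstep = np.exp(ls) * rng.standard_normal(R)
                prop_sig = sig * np.exp(lstep)
                ss = (eps**2).sum(axis=1)
                d = (
                    -M * lstep
                    - 0.5 * ss * (prop_sig**-2 - sig**-2)
                    + lstep  # Jacobian of the log-scale walk
                    + _prior_lp(priors.sigmas, prop_sig)
                    - _prior_lp(priors.sigmas, sig)
                )
                with np.errstate(invalid="ignore"):
                    a = np.exp(np.minimum(d, 0.0))
                a = np.where(np.isfinite(d), a, 0.0)
                acc = rng.random(R) < a
                sig[acc] = prop_sig[acc]
                if adapting:
                    ls += gamma * (a - tgt)
                acc_sig_parts.append(float(a.mean()))

            # ---- 3g. joint (sigma, eps) rescaling per region --------------
            # moves along the funnel direction the univariate walks cross
            # slowly: sigma' = c sigma, eps' = c eps; log target changes by
            # Delta(loglik) + log c (prior-vs-Jacobian residual)
            lc = np.exp(ls_scl_psi) * rng.standard_normal(R)
            c = np.exp(lc)
            sig_new = sigma_psi * c
            lpsi_new = lpsi + (c - 1.0)[:, None] * eps_psi
            ls_old = log_expit(lpsi)
            ls_new = log_expit(lpsi_new)
            d_rows = omega_f * (
                sz * (ls_new - ls_old)
                + (n_act[:, None] - sz) * ((ls_new - lpsi_new) - (ls_old - lpsi))
            )
            d = d_rows.sum(axis=1) + lc
            d += _prior_lp(priors.sigmas, sig_new) - _prior_lp(priors.sigmas, sigma_psi)
            with np.errstate(invalid="ignore"):
                a = np.exp(np.minimum(d, 0.0))
            a = np.where(np.isfinite(d), a, 0.0)
            acc = rng.random(R) < a
            sigma_psi = np.where(acc, sig_new, sigma_psi)
            eps_psi = np.where(acc[:, None], eps_psi * c[:, None], eps_psi)
            lpsi = np.where(acc[:, None], lpsi_new, lpsi)
            if adapting:
                ls_scl_psi += gamma * (a - tgt)
            acc_sig_parts.append(float(a.mean()))

            lc = np.exp(ls_scl_p) * rng.standard_normal(R)
            c = np.exp(lc)
            sig_new = sigma_p * c
            shift = (c - 1.0)[:, None] * eps_p  # (R, M)
            vals_new = lgp_z + shift[r_i, m_i]
            lsp_o = log_expit(lgp_z)
            lsp_n = log_expit(vals_new)
            cell_d = (yz * (lsp_n - lsp_o)
                      + (Kz - yz) * ((lsp_n - vals_new) - (lsp_o - lgp_z)))
            d = (
                np.bincount(r_i, weights=cell_d, minlength=R)
                + lc
                + _prior_lp(priors.sigmas, sig_new)
                - _prior_lp(priors.sigmas, sigma_p)
            )
            with np.errstate(invalid="ignore"):
                a = np.exp(np.minimum(d, 0.0))
            a = np.where(np.isfinite(d), a, 0.0)
            acc = rng.random(R) < a
            sigma_p = np.where(acc, sig_new, sigma_p)
            eps_p = np.where(acc[:, None], eps_p * c[:, None], eps_p)
            lgp += np.where(acc[:, None], shift, 0.0)[:, :, None]
            lgp_z = np.where(acc[r_i], vals_new, lgp_z)
            if adapting:
                ls_scl_p += gamma * (a - tgt)
            acc_sig_parts.append(float(a.mean()))

            acc_sigma = float(np.mean(acc_sig_parts))

            if not adapting:
                acc_sums["beta"] += acc_beta
                acc_sums["theta"] += acc_theta
                acc_sums["alpha"] += acc_alpha
                acc_sums["eps_psi"] += acc_eps_psi
                acc_sums["eps_p"] += acc_eps_p
                acc_sums["sigma"] += acc_sigma
                n_post += 1

        # ---- record -------------------------------------------------------
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            out["beta"][keep_idx] = beta
            out["theta"][keep_idx] = theta
            out["alpha"][keep_idx] = alpha
            out["sigma_psi"][keep_idx] = sigma_psi
            out["sigma_p"][keep_idx] = sigma_p
            out["N"][keep_idx] = n_mem.astype(int)
            if cfg.record_lp:
                ll_om_now = ll_omega_total(eta_rich, n_mem)
                ll_z_now = llz_total(lpsi, omega_f, sz)
                lsp = log_expit(lgp[r_i, m_i, j_i])
                lgp_v = lgp[r_i, m_i, j_i]
                ll_y_now = float(
                    np.sum(yz * lsp + (Kz - yz) * (lsp - lgp_v))
                ) + logc_const
                lp_eps = float(
                    np.sum(
                        -0.5 * (eps_psi / sigma_psi[:, None]) ** 2
                        - np.log(sigma_psi[:, None])
                    )
                    + np.sum(
                        -0.5 * (eps_p / sigma_p[:, None]) ** 2
                        - np.log(sigma_p[:, None])
                    )
                    - R * M * math.log(2 * math.pi)
                )
                lp_par = float(
                    _prior_lp(priors.intercepts, beta[0])
                    + _prior_lp(priors.intercepts, theta[0])
                    + _prior_lp(priors.intercepts, alpha[0])
                    + np.sum(_prior_lp(priors.slopes, beta[1:]))
                    + np.sum(_prior_lp(priors.slopes, theta[1:]))
                    + np.sum(_prior_lp(priors.slopes, alpha[1:]))
                    + np.sum(_prior_lp(priors.sigmas, sigma_psi))
                    + np.sum(_prior_lp(priors.sigmas, sigma_p))
                )
                out["lp"][keep_idx] = (
                    ll_om_now + ll_z_now + ll_y_now + lp_eps + lp_par
                )
            keep_idx += 1

    out["_acceptance"] = {
        k: (v / n_post if n_post else float("nan")) for k, v in acc_sums.items()
    }
    return out


# ---------------------------------------------------------------------------
# public entry points


def run(
    data: AugmentedDetectionArray,
    design: Design,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    fixed_params: ModelParams | None = None,
) -> PosteriorSamples:
    """Run the sampler on augmented data with a prepared design.

    ``fixed_params`` pins every continuous parameter (useful for exact
    small-instance validation: only omega and z are then updated, from their
    exact full conditionals).
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    y, det = _pad_augmented(data)
    t0 = time.perf_counter()
    chains = []
    for child in np.random.SeedSequence(config.seed).spawn(config.n_chains):
        chains.append(
            _run_chain(
                y, det, design, priors, config,
                np.random.default_rng(child), fixed_params,
            )
        )
    draws: dict[str, np.ndarray] = {}
    for key in chains[0]:
        if key.startswith("_"):
            continue
        draws[key] = np.stack([c[key] for c in chains])
    acc = {
        k: float(np.mean([c["_acceptance"][k] for c in chains]))
        for k in chains[0]["_acceptance"]
    }
    return PosteriorSamples(
        draws=draws,
        region_ids=list(design.region_ids),
        n_obs=np.array([r.n_detected for r in data.regions]),
        M=data.M,
        config=config,
        acceptance=acc,
        runtime_s=time.perf_counter() - t0,
    )


def fit(
    data: StudyDataset,
    covariates: CovariateTable,
    M: int = 55,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    fixed_params: ModelParams | None = None,
    log_skewed: bool = False,
) -> PosteriorSamples:
    """Standardize covariates, augment to M rows, and sample the posterior."""
    covariates = covariates.reindex(data.region_ids)
    std, records = standardize_covariates(covariates, log_skewed=log_skewed)
    site_std, site_rec = standardize_site_settlement(data)
    aug = augment(data, M)
    design = build_design(data, std, site_std)
    samples = run(aug, design, priors=priors, config=config,
                  fixed_params=fixed_params)
    samples.standardization = {**records, "settl_site": site_rec}
    return samples


# ---------------------------------------------------------------------------
# diagnostics


def rhat(chains: np.ndarray, split: bool = True) -> float:
    """Gelman–Rubin potential scale reduction factor for one scalar.

    ``chains`` is (n_chains, n_draws). ``split=True`` (default) halves each
    chain first; ``split=False`` is the classic multi-chain formula. Returns
    NaN when the within-chain variance vanishes (undefined, not an error).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    C, S = x.shape
    if C < 2 or S < 2:
        raise ValueError("need >= 2 chains of >= 2 draws")
    W = float(x.var(axis=1, ddof=1).mean())
    B = S * float(x.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return float("nan")
    var_plus = (S - 1) / S * W + B / S
    return math.sqrt(var_plus / W)


def ess(chains: np.ndarray) -> float:
    """Effective sample size by the classic autocorrelation-sum estimator.

    Averages per-chain autocovariances, forms rho_t against the pooled
    variance estimate, and truncates at the first negative paired sum
    (Geyer's initial positive sequence).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    C, S = x.shape
    if S < 4:
        return float("nan")
    W = float(x.var(axis=1, ddof=1).mean())
    if W == 0.0:
        return float("nan")
    if C >= 2:
        B = S * float(x.mean(axis=1).var(ddof=1))
        var_plus = (S - 1) / S * W + B / S
    else:
        var_plus = W
    xc = x - x.mean(axis=1, keepdims=True)
    n_fft = int(2 ** math.ceil(math.log2(2 * S)))
    f = np.fft.rfft(xc, n=n_fft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=n_fft, axis=1)[:, :S].real / S
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    tau = 1.0
    t = 1
    while t + 1 < S:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(C * S / tau)


def summarize(
    samples: PosteriorSamples, levels: Sequence[float] = (0.5, 0.9, 0.95)
) -> pd.DataFrame:
    """Posterior summary table: mean, SD, median, equal-tailed intervals at
    the requested levels, split R-hat, and autocorrelation-sum ESS.

    Quantiles use numpy's linear-interpolation rule. Richness rows (N_*) keep
    the raw median; round for reporting.
    """
    for lev in levels:
        if not (0.0 < lev < 1.0):
            raise ValueError(f"credible level {lev} outside (0, 1)")
    rows = []
    for name in samples.scalar_names():
        x = samples.scalar(name)
        flat = x.ravel()
        row = {
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
            "median": float(np.median(flat)),
        }
        for lev in levels:
            lo, hi = np.quantile(flat, [(1 - lev) / 2, (1 + lev) / 2])
            tag = f"{lev * 100:g}".replace(".", "_")
            row[f"lo{tag}"] = float(lo)
            row[f"hi{tag}"] = float(hi)
        can_rhat = x.shape[0] >= 2 or x.shape[1] >= 4
        row["rhat"] = rhat(x) if can_rhat else float("nan")
        row["ess"] = ess(x)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
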