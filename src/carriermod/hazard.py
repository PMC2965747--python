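"""Retrospective-likelihood hazard-ratio estimation with robust clustered variance.

Carriers enter cancer-genetics studies because of their phenotype, so a
prospective Cox fit of genotype effects is biased.  The estimator here
maximises the likelihood of the observed genotypes conditional on the
observed phenotypes,

    L_i(beta, q) = P(t_i, delta_i | g_i) p_s(g_i) / sum_g P(t_i, delta_i | g) p_s(g),

where P(t, delta | g) is the proportional-hazards survival kernel on a known
carrier baseline hazard (the baseline terms lambda0(t)^delta cancel in the
conditional) and p_s(g) are HWE genotype priors with a per-stratum allele
frequency q_s profiled jointly with beta.  Familial dependence is handled by
a Huber/Lin-Wei sandwich variance with families as clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize as opt
import scipy.stats as st
from scipy.special import logsumexp

from .assoc import ScanInputs, prepare_scan_inputs
from .cohort import Carrier, IncidenceModel, StratumScheme, ValidationError
from .genotypes import MISSING

__all__ = [
    "HRFit",
    "retro_loglik",
    "fit_hr",
    "fit_age_interaction",
    "combined_stage_fit",
    "meta_fixed_effect",
]

Z975 = 1.959964
BETA_BOUND = 5.0

_CODINGS = {
    # genotype value -> covariate vector x(g)
    "per_allele": np.array([[0.0], [1.0], [2.0]]),
    "genotype_2df": np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
}


@dataclass
class HRFit:
    model: str
    beta: np.ndarray
    se_robust: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    freqs: dict[str, float]
    loglik: float
    loglik_null: float
    n: int
    n_families: int
    converged: bool
    extra: dict = field(default_factory=dict)


def _genotype_log_priors(q: np.ndarray) -> np.ndarray:
    """(S, 3) log HWE genotype probabilities from per-stratum allele freq q."""
    q = np.clip(q, 1e-12, 1 - 1e-12)
    return np.log(np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=1))


def _loglik_terms(
    beta: np.ndarray,
    q: np.ndarray,
    g: np.ndarray,
    delta: np.ndarray,
    lam0: np.ndarray,
    stratum: np.ndarray,
    coding: np.ndarray,
) -> np.ndarray:
    """Per-carrier retrospective log-likelihood contributions."""
    eta = coding @ beta  # (3,) linear predictor per genotype value
    logp = _genotype_log_priors(q)  # (S, 3)
    # kernel(g') = delta*eta(g') - lam0*exp(eta(g')) for each carrier x genotype value
    kern = delta[:, None] * eta[None, :] - lam0[:, None] * np.exp(eta)[None, :]
    own = kern[np.arange(g.size), g] + logp[stratum, g]
    denom = logsumexp(kern + logp[stratum], axis=1)
    return own - denom


def retro_loglik(
    beta: np.ndarray | float,
    freqs: np.ndarray,
    g: np.ndarray,
    delta: np.ndarray,
    lam0: np.ndarray,
    stratum: np.ndarray,
    model: str = "per_allele",
) -> float:
    """Total retrospective log-likelihood (see module docstring).

    ``freqs`` holds one allele frequency per stratum code appearing in
    ``stratum``; carriers with missing genotype must already be dropped.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if not np.all(np.isfinite(beta)):
        raise ValidationError("beta must be finite")
    if np.asarray(lam0).size != np.asarray(g).size:
        raise ValidationError("Lambda0 missing for some carriers")
    coding = _CODINGS[model]
    return float(
        _loglik_terms(
            beta,
            np.asarray(freqs, dtype=float),
            np.asarray(g, dtype=int),
            np.asarray(delta, dtype=float),
            np.asarray(lam0, dtype=float),
            np.asarray(stratum, dtype=int),
            coding,
        ).sum()
    )


def _complete_case(g: np.ndarray, inputs: ScanInputs):
    g = np.asarray(g)
    obs = g != MISSING
    idx = np.flatnonzero(obs)
    sub_strat = inputs.stratum[idx]
    # re-code strata compactly over the observed carriers
    labels, codes = np.unique(sub_strat, return_inverse=True)
    return (
        g[idx].astype(int),
        inputs.delta[idx],
        inputs.lam0[idx],
        codes,
        [inputs.stratum_labels[k] for k in labels],
        inputs.family[idx],
    )


def _sandwich_se(
    theta: np.ndarray,
    per_ind,
    family: np.ndarray,
    n_beta: int,
    eps: float = 1e-5,
) -> np.ndarray:
    """Robust A^-1 B A^-1 with family-cluster score outer products.

    ``per_ind(theta)`` returns the vector of per-carrier log-likelihood
    contributions; gradient and Hessian are central finite differences.
    """
    p = theta.size
    n = family.size
    grad_i = np.zeros((n, p))
    for k in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        grad_i[:, k] = (per_ind(tp) - per_ind(tm)) / (2 * eps)
    # cluster scores
    fams, codes = np.unique(family, return_inverse=True)
    s_f = np.zeros((fams.size, p))
    np.add.at(s_f, codes, grad_i)
    b = s_f.T @ s_f
    # observed information (negative Hessian of the total loglik)
    a = np.zeros((p, p))
    f0 = per_ind(theta).sum()
    for k in range(p):
        for l in range(k, p):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[[k, l]] += eps
            tmm[[k, l]] -= eps
            tpm[k] += eps
            tpm[l] -= eps
            tmp[k] -= eps
            tmp[l] += eps
            if k == l:
                tp, tm = theta.copy(), theta.copy()
                tp[k] += eps
                tm[k] -= eps
                h = (per_ind(tp).sum() - 2 * f0 + per_ind(tm).sum()) / eps**2
            else:
                h = (
                    per_ind(tpp).sum() - per_ind(tpm).sum() - per_ind(tmp).sum() + per_ind(tmm).sum()
                ) / (4 * eps**2)
            a[k, l] = a[l, k] = -h
    try:
        a_inv = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        a_inv = np.linalg.pinv(a)
    cov = a_inv @ b @ a_inv
    return np.sqrt(np.maximum(np.diag(cov)[:n_beta], 0.0))


def _null_loglik(g: np.ndarray, stratum: np.ndarray, n_strata: int) -> tuple[float, np.ndarray]:
    """Closed-form beta=0 fit: q_s = stratum allele frequency; multinomial loglik."""
    counts = np.bincount(stratum, minlength=n_strata).astype(float)
    gsum = np.bincount(stratum, weights=g.astype(float), minlength=n_strata)
    with np.errstate(invalid="ignore"):
        q = np.where(counts > 0, gsum / (2 * counts), 0.5)
    logp = _genotype_log_priors(q)
    return float(logp[stratum, g].sum()), q


def fit_hr(
    g: np.ndarray,
    inputs: ScanInputs,
    model: str = "per_allele",
    compute_se: bool = True,
    tol: float = 1e-8,
) -> HRFit:
    """Maximise the retrospective likelihood jointly over beta and frequencies.

    Bounded quasi-Newton (L-BFGS-B, |beta| <= 5, frequencies on the logit
    scale) with finite-difference gradients; robust family-clustered
    sandwich standard errors; HR and 95% CI on the exp scale.
    """
    if model not in _CODINGS:
        raise ValidationError(f"unknown model: {model}")
    gg, delta, lam0, stratum, labels, family = _complete_case(g, inputs)
    if np.unique(gg).size < 2:
        raise ValidationError("fewer than 2 genotype classes present")
    n_strata = len(labels)
    coding = _CODINGS[model]
    n_beta = coding.shape[1]
    ll0, q0 = _null_loglik(gg, stratum, n_strata)

    def unpack(theta):
        return theta[:n_beta], 1.0 / (1.0 + np.exp(-theta[n_beta:]))

    def per_ind(theta):
        b, q = unpack(theta)
        return _loglik_terms(b, q, gg, delta, lam0, stratum, coding)

    def nll(theta):
        return -per_ind(theta).sum()

    theta0 = np.concatenate([np.zeros(n_beta), np.log(q0 / (1 - np.clip(q0, 1e-9, 1 - 1e-9)))])
    bounds = [(-BETA_BOUND, BETA_BOUND)] * n_beta + [(-12.0, 12.0)] * n_strata
    res = opt.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol, "maxiter": 500}
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise ValidationError(f"optimizer failed: {res.message}")
    beta_hat, q_hat = unpack(res.x)
    at_bound = np.any(np.abs(beta_hat) >= BETA_BOUND - 1e-6)
    if at_bound:
        import warnings

        warnings.warn("beta bounded at |beta| = 5 (possible separation)", stacklevel=2)
    se = (
        _sandwich_se(res.x, per_ind, family, n_beta)
        if compute_se
        else np.full(n_beta, np.nan)
    )
    fams = np.unique(family).size
    return HRFit(
        model=model,
        beta=beta_hat,
        se_robust=se,
        hr=np.exp(beta_hat),
        ci_low=np.exp(beta_hat - Z975 * se),
        ci_high=np.exp(beta_hat + Z975 * se),
        freqs={lab: float(qv) for lab, qv in zip(labels, q_hat)},
        loglik=-res.fun,
        loglik_null=ll0,
        n=int(gg.size),
        n_families=int(fams),
        converged=bool(res.success and not at_bound),
    )


def _cumhaz_age_varying(
    t: np.ndarray, x: np.ndarray, b0: float, b1: float, t_ref: float, m: IncidenceModel
) -> np.ndarray:
    """H(t | x) = int_0^t lambda0(u) exp((b0 + b1 (u - t_ref)) x) du, piecewise exact.

    ``t`` (n,) and ``x`` (k,) broadcast to an (n, k) matrix of cumulative
    hazards under the age-varying per-allele effect.
    """
    edges = np.asarray(m.age_band_edges, dtype=float)
    rates = np.asarray(m.rates, dtype=float)
    lo_e, hi_e = edges[:-1], edges[1:]
    a = np.clip(t[:, None], None, hi_e)[..., None]  # (n, bands, 1)
    lo = lo_e[None, :, None]
    valid = a > lo
    bx = b1 * x[None, None, :]
    scale = np.exp((b0 - b1 * t_ref) * x)[None, None, :]
    with np.errstate(over="ignore", invalid="ignore"):
        small = np.abs(bx) < 1e-9
        upper = np.exp(bx * a)
        lower = np.exp(bx * np.broadcast_to(lo, a.shape))
        seg = np.where(small, np.maximum(a - lo, 0.0), (upper - lower) / np.where(small, 1.0, bx))
    seg = np.where(valid, seg, 0.0)
    return (rates[None, :, None] * scale * seg).sum(axis=1)


def fit_age_interaction(
    g: np.ndarray,
    inputs: ScanInputs,
    incidence: IncidenceModel,
    t_ref: float = 50.0,
    compute_se: bool = True,
    tol: float = 1e-8,
) -> HRFit:
    """Age-varying per-allele effect exp((b0 + b1 (t - t_ref)) g) with a 1-df LR test of b1 = 0.

    The cumulative-hazard integral is evaluated exactly per incidence band.
    Returns an :class:`HRFit` for (b0, b1); ``extra["lr_p"]`` holds the
    interaction p-value against the age-constant fit.
    """
    gg, delta, lam0, stratum, labels, family = _complete_case(g, inputs)
    if np.unique(gg).size < 2:
        raise ValidationError("fewer than 2 genotype classes present")
    n_strata = len(labels)
    t_i = inputs.censor_age[np.flatnonzero(np.asarray(g) != MISSING)]
    gvals = np.array([0.0, 1.0, 2.0])

    def per_ind(theta):
        b0, b1 = theta[0], theta[1]
        q = 1.0 / (1.0 + np.exp(-theta[2:]))
        logp = _genotype_log_priors(q)
        h = _cumhaz_age_varying(t_i, gvals, b0, b1, t_ref, incidence)  # (n, 3)
        eta_t = (b0 + b1 * (t_i[:, None] - t_ref)) * gvals[None, :]
        kern = delta[:, None] * eta_t - h
        own = kern[np.arange(gg.size), gg] + logp[stratum, gg]
        denom = logsumexp(kern + logp[stratum], axis=1)
        return own - denom

    def nll(theta):
        return -per_ind(theta).sum()

    _, q0 = _null_loglik(gg, stratum, n_strata)
    theta0 = np.concatenate([[0.0, 0.0], np.log(q0 / (1 - np.clip(q0, 1e-9, 1 - 1e-9)))])
    bounds = [(-BETA_BOUND, BETA_BOUND), (-1.0, 1.0)] + [(-12.0, 12.0)] * n_strata
    res = opt.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol, "maxiter": 500}
    )
    base = fit_hr(g, inputs, model="per_allele", compute_se=False, tol=tol)
    lr = max(0.0, 2.0 * (-res.fun - base.loglik))
    lr_p = float(st.chi2.sf(lr, df=1))
    beta_hat = res.x[:2]
    se = _sandwich_se(res.x, per_ind, family, 2) if compute_se else np.full(2, np.nan)
    q_hat = 1.0 / (1.0 + np.exp(-res.x[2:]))
    return HRFit(
        model="age_interaction",
        beta=beta_hat,
        se_robust=se,
        hr=np.exp(beta_hat),
        ci_low=np.exp(beta_hat - Z975 * se),
        ci_high=np.exp(beta_hat + Z975 * se),
        freqs={lab: float(qv) for lab, qv in zip(labels, q_hat)},
        loglik=-res.fun,
        loglik_null=base.loglik,
        n=int(gg.size),
        n_families=int(np.unique(family).size),
        converged=bool(res.success),
        extra={"lr_stat": lr, "lr_p": lr_p, "beta_age_constant": base.beta},
    )


def combined_stage_fit(
    carriers1: Sequence[Carrier],
    g1: np.ndarray,
    carriers2: Sequence[Carrier],
    g2: np.ndarray,
    incidence: IncidenceModel,
    model: str = "per_allele",
    scheme: StratumScheme | None = None,
) -> HRFit:
    """Pooled retrospective fit with stage appended to the stratum key.

    Carriers must be disjoint across stages (cross-stage duplicates are a QC
    responsibility); per-stage-stratum allele frequencies are profiled.
    """
    ids1 = {c.individual_id for c in carriers1}
    overlap = ids1 & {c.individual_id for c in carriers2}
    if overlap:
        raise ValidationError(f"carriers appear in both stages: {sorted(overlap)[:5]}")
    pooled = [*carriers1, *carriers2]
    scheme = scheme or StratumScheme(include_stage=True)
    if not scheme.include_stage:
        raise ValidationError("combined fit requires a stage-including stratum scheme")
    inputs = prepare_scan_inputs(pooled, incidence, scheme=scheme)
    keep = {c.individual_id: i for i, c in enumerate(pooled)}
    g = np.concatenate([np.asarray(g1), np.asarray(g2)])
    g = np.asarray([g[keep[i]] for i in inputs.ids])
    return fit_hr(g, inputs, model=model)


def meta_fixed_effect(
    hr1: float,
    ci1: tuple[float, float],
    hr2: float,
    ci2: tuple[float, float],
) -> tuple[float, tuple[float, float]]:
    """Inverse-variance fixed-effect combination of two (HR, 95% CI) pairs.

    Log-scale SEs are recovered from the CI widths, SE_k = (log U_k - log
    L_k) / (2 * 1.959964); the combined estimate is the precision-weighted
    mean of the log HRs.
    """
    betas, ses = [], []
    for hr, (lo, hi) in ((hr1, ci1), (hr2, ci2)):
        if hi <= lo:
            raise ValidationError("degenerate CI (upper <= lower)")
        if not 0 < lo <= hr <= hi:
            raise ValidationError(f"CI ({lo}, {hi}) does not bracket HR {hr}")
        betas.append(np.log(hr))
        ses.append((np.log(hi) - np.log(lo)) / (2 * Z975))
    w = 1.0 / np.asarray(ses) ** 2
    beta = float(np.sum(w * betas) / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return float(np.exp(beta)), (float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se)))
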