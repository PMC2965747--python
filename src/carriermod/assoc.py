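"""Kinship-adjusted 1-df score test from the retrospective likelihood.

Model.  For carrier i with censoring age t_i, case status delta_i and
genotype g_i, the retrospective likelihood of the genotypes given the
phenotypes, with a per-allele log-hazard-ratio beta on a known baseline
cumulative hazard Lambda0, has per-carrier log-likelihood

    l_i(beta) = delta_i beta g_i - Lambda0(t_i) e^{beta g_i} + log p_s(g_i)
                - log sum_g p_s(g) exp(delta_i beta g - Lambda0(t_i) e^{beta g}).

Differentiating at beta = 0 with the stratum genotype frequencies profiled
at their null MLE (the stratum sample mean) gives the score

    U = sum_i c_i (g_i - gbar_s(i)),   c_i = delta_i - Lambda0(t_i),

i.e. a covariance between the martingale-type residual c_i and the
stratum-centred genotype.  Writing U = sum_i a_i g_i with centred weights
a_i = c_i - (sum_{j in s(i)} c_j) / n_s(i) — an identity, since the centring
constant multiplies sum_i (g_i - gbar) = 0 — the null variance over the
genotype distribution is

    V = sum_{i,j in same family} a_i a_j 2 phi_ij sigma_s(i) sigma_s(j),

with sigma^2_s = 2 p_s (1 - p_s) the HWE genotype variance and phi the
pedigree kinship (2 phi_ii = 1 for non-inbred carriers).  Unrelated
carriers contribute a_i^2 sigma^2_s.  The centred weights matter: under
phenotype-based ascertainment the residuals c_i do not sum to zero within a
stratum, and omitting the centring overstates V.  chi^2 = U^2 / V on 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .cohort import (
    Carrier,
    IncidenceModel,
    KinshipMatrix,
    StratumScheme,
    ValidationError,
    assign_strata,
)
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "ScoreResult",
    "ScanSummary",
    "ScanInputs",
    "prepare_scan_inputs",
    "score_test",
    "genome_scan",
    "genomic_inflation",
    "qq_points",
    "CHI2_1_MEDIAN",
]

CHI2_1_MEDIAN = 0.4549364


@dataclass
class ScoreResult:
    snp_id: str
    u: float
    v: float
    chisq: float | None
    p: float | None
    n_used: int
    freq_by_stratum: dict[str, float] = field(default_factory=dict)
    flag: str = ""


@dataclass
class ScanSummary:
    results: pd.DataFrame
    lambda_gc: float
    qq: pd.DataFrame


@dataclass
class ScanInputs:
    """Aligned per-carrier arrays plus the within-family kinship pair list."""

    ids: list[str]
    delta: np.ndarray  # case indicator
    lam0: np.ndarray  # Lambda0(t_i), cohort-adjusted
    censor_age: np.ndarray  # t_i in years (needed by age-varying models)
    stratum: np.ndarray  # integer stratum codes
    stratum_labels: list[str]
    family: np.ndarray  # integer family codes
    pair_i: np.ndarray  # within-family pair indices (includes i==j diagonal)
    pair_j: np.ndarray
    pair_coef: np.ndarray  # 2*phi_ij, doubled for off-diagonal pairs


def prepare_scan_inputs(
    carriers: Sequence[Carrier],
    incidence: IncidenceModel,
    kinship: KinshipMatrix | None = None,
    scheme: StratumScheme = StratumScheme(),
) -> ScanInputs:
    """Assign strata, evaluate Lambda0 per carrier, and list kinship pairs.

    Without an explicit kinship matrix, members of the same family are
    given the default relatedness 2*phi = 0.5 (first-degree relatives, the
    structure the synthetic generator produces); with one, the pedigree
    coefficients are used.  Carriers excluded by stratum assignment are
    dropped.
    """
    key_by_id, _summary, excluded = assign_strata(carriers, scheme)
    dropped = {iid for iid, _ in excluded}
    kept = [c for c in carriers if c.individual_id not in dropped]
    ids = [c.individual_id for c in kept]
    labels = sorted({key_by_id[i] for i in ids})
    lab_code = {s: k for k, s in enumerate(labels)}
    stratum = np.asarray([lab_code[key_by_id[i]] for i in ids])
    delta = np.asarray([c.affected for c in kept], dtype=float)
    lam0 = np.asarray(
        [incidence.cumulative(c.censor_age, c.birth_year)[0] for c in kept]
    )
    fam_labels = {f: k for k, f in enumerate(dict.fromkeys(c.family_id for c in kept))}
    family = np.asarray([fam_labels[c.family_id] for c in kept])

    pair_i, pair_j, pair_coef = [], [], []
    members: dict[int, list[int]] = {}
    for idx, f in enumerate(family):
        members.setdefault(int(f), []).append(idx)
    for f, idxs in members.items():
        for a_pos, i in enumerate(idxs):
            two_phi_ii = 2 * kinship.get(ids[i], ids[i]) if kinship is not None else 1.0
            pair_i.append(i)
            pair_j.append(i)
            pair_coef.append(two_phi_ii)
            for j in idxs[a_pos + 1 :]:
                two_phi = 2 * kinship.get(ids[i], ids[j]) if kinship is not None else 0.5
                pair_i.append(i)
                pair_j.append(j)
                pair_coef.append(2 * two_phi)  # counts (i,j) and (j,i)
    return ScanInputs(
        ids=ids,
        delta=delta,
        lam0=lam0,
        censor_age=np.asarray([c.censor_age for c in kept], dtype=float),
        stratum=stratum,
        stratum_labels=labels,
        family=family,
        pair_i=np.asarray(pair_i),
        pair_j=np.asarray(pair_j),
        pair_coef=np.asarray(pair_coef, dtype=float),
    )


def _centered_weights(c: np.ndarray, stratum: np.ndarray, n_strata: int) -> np.ndarray:
    sums = np.bincount(stratum, weights=c, minlength=n_strata)
    counts = np.bincount(stratum, minlength=n_strata).astype(float)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / counts, 0.0)
    return c - means[stratum]


def score_test(
    g: np.ndarray,
    inputs: ScanInputs,
    snp_id: str = "snp",
    adjusted: bool = True,
    variance: str = "hwe",
) -> ScoreResult:
    """Single-SNP kinship-adjusted score test; missing genotypes are dropped.

    ``variance`` selects the per-stratum genotype variance: ``"hwe"``
    (default) uses 2 p(1-p) from the stratum allele frequency with an exact
    finite-sample unbiasedness correction for the plugin bias
    E[2 phat (1-phat)] = sigma^2 (1 - K_s / (2 n_s^2)) — without it the
    score test is slightly anti-conservative in small strata;
    ``"hwe_plugin"`` omits the correction; ``"empirical"`` uses the sample
    genotype variance.  ``adjusted=False`` zeroes the off-diagonal kinship
    terms (the naive independence variance, for diagnostics only).
    """
    g = np.asarray(g, dtype=float)
    obs = g != MISSING
    n_used = int(obs.sum())
    if n_used == 0:
        return ScoreResult(snp_id, 0.0, 0.0, None, None, 0, flag="all_missing")
    s = inputs.stratum
    n_strata = len(inputs.stratum_labels)
    c = inputs.delta - inputs.lam0

    sub_s = s[obs]
    counts = np.bincount(sub_s, minlength=n_strata).astype(float)
    gsums = np.bincount(sub_s, weights=g[obs], minlength=n_strata)
    with np.errstate(invalid="ignore"):
        gbar = np.where(counts > 0, gsums / counts, 0.0)
    phat = gbar / 2.0
    freqs = {
        inputs.stratum_labels[k]: float(phat[k]) for k in range(n_strata) if counts[k] > 0
    }
    if variance in ("hwe", "hwe_plugin"):
        sig2 = 2.0 * phat * (1.0 - phat)
        if variance == "hwe":
            # unbiasedness correction: E[2 phat (1-phat)] = sigma^2 (1 - K_s / (2 n_s^2))
            # with K_s the within-stratum sum of 2*phi over observed pairs
            pi, pj, coef = inputs.pair_i, inputs.pair_j, inputs.pair_coef
            both = obs[pi] & obs[pj]
            k_rel = np.bincount(s[pi[both]], weights=coef[both], minlength=n_strata)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = 1.0 / np.maximum(1.0 - k_rel / (2.0 * counts**2), 1.0 / 3.0)
            sig2 = sig2 * np.where(counts > 0, corr, 1.0)
    elif variance == "empirical":
        g2sums = np.bincount(sub_s, weights=g[obs] ** 2, minlength=n_strata)
        with np.errstate(invalid="ignore"):
            sig2 = np.where(counts > 0, g2sums / counts - gbar**2, 0.0)
    else:
        raise ValidationError(f"unknown variance estimator: {variance}")

    # centred weights over observed carriers only
    c_obs = np.where(obs, c, 0.0)
    csums = np.bincount(sub_s, weights=c[obs], minlength=n_strata)
    with np.errstate(invalid="ignore"):
        cmeans = np.where(counts > 0, csums / counts, 0.0)
    a = np.where(obs, c_obs - cmeans[s], 0.0)

    u = float(np.sum(a[obs] * (g[obs] - gbar[sub_s])))
    if np.all(sig2[counts > 0] == 0):
        return ScoreResult(snp_id, 0.0, 0.0, None, 1.0, n_used, freqs, flag="monomorphic")

    w = a * np.sqrt(np.maximum(sig2, 0.0))[s]
    pi, pj, coef = inputs.pair_i, inputs.pair_j, inputs.pair_coef
    if not adjusted:
        keep = pi == pj
        pi, pj, coef = pi[keep], pj[keep], coef[keep]
    v = float(np.sum(coef * w[pi] * w[pj]))
    if v <= 0:
        return ScoreResult(snp_id, u, v, None, None, n_used, freqs, flag="nonpositive_variance")
    chisq = u * u / v
    p = float(st.chi2.sf(chisq, df=1))
    return ScoreResult(snp_id, u, v, chisq, max(p, np.finfo(float).tiny), n_used, freqs)


def genome_scan(
    gm: GenotypeMatrix,
    inputs: ScanInputs,
    adjusted: bool = True,
    variance: str = "hwe",
    chunk: int = 4096,
) -> ScanSummary:
    """Score test per SNP over a genotype matrix aligned with ``inputs.ids``.

    Complete matrices (no missing calls) take a vectorised path that
    requires each family to lie within a single stratum (true for the
    synthetic cohorts); otherwise SNPs are tested one at a time.
    """
    if gm.sample_ids != inputs.ids:
        raise ValidationError("genotype matrix and scan inputs are not aligned")
    no_missing = not (gm.calls == MISSING).any()
    fam_in_stratum = all(
        np.unique(inputs.stratum[inputs.family == f]).size == 1
        for f in np.unique(inputs.family)
    )
    if no_missing and fam_in_stratum:
        res = _scan_fast(gm, inputs, adjusted, variance, chunk)
    else:
        rows = []
        for j in range(gm.n_snps):
            r = score_test(gm.calls[:, j], inputs, gm.snps["snp_id"].iloc[j], adjusted, variance)
            rows.append((r.snp_id, r.n_used, r.u, r.v, r.chisq, r.p))
        res = pd.DataFrame(rows, columns=["snp", "n", "U", "V", "chisq", "p"])
    res.insert(1, "chr", gm.snps["chrom"].to_numpy())
    res.insert(2, "pos", gm.snps["pos"].to_numpy())
    ok = res["chisq"].notna()
    lam = genomic_inflation(res.loc[ok, "chisq"].to_numpy()) if ok.any() else float("nan")
    qq = qq_points(res.loc[ok & res["p"].notna(), "p"].to_numpy()) if ok.any() else pd.DataFrame()
    return ScanSummary(results=res, lambda_gc=lam, qq=qq)


def _scan_fast(
    gm: GenotypeMatrix, inputs: ScanInputs, adjusted: bool, variance: str, chunk: int
) -> pd.DataFrame:
    n, m = gm.n_samples, gm.n_snps
    s = inputs.stratum
    n_strata = len(inputs.stratum_labels)
    counts = np.bincount(s, minlength=n_strata).astype(float)
    c = inputs.delta - inputs.lam0
    a = _centered_weights(c, s, n_strata)
    # per-stratum quadratic form of the centred weights against 2*phi
    pi, pj, coef = inputs.pair_i, inputs.pair_j, inputs.pair_coef
    if not adjusted:
        keep = pi == pj
        pi, pj, coef = pi[keep], pj[keep], coef[keep]
    q_terms = coef * a[pi] * a[pj]
    q_strat = np.bincount(s[pi], weights=q_terms, minlength=n_strata)
    # finite-sample unbiasedness correction for the HWE variance (see score_test)
    k_rel = np.bincount(s[inputs.pair_i], weights=inputs.pair_coef, minlength=n_strata)
    with np.errstate(invalid="ignore", divide="ignore"):
        sig2_corr = 1.0 / np.maximum(1.0 - k_rel / (2.0 * counts**2), 1.0 / 3.0)
    sig2_corr = np.where(counts > 0, sig2_corr, 1.0)

    u_all = np.empty(m)
    v_all = np.empty(m)
    phat_all = np.empty((n_strata, m))
    onehot = np.zeros((n_strata, n), dtype=np.float32)
    onehot[s, np.arange(n)] = 1.0
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        g = gm.calls[:, lo:hi].astype(np.float32)
        gsum = onehot @ g  # (S, chunk)
        gbar = gsum / counts[:, None]
        phat = gbar / 2.0
        phat_all[:, lo:hi] = phat
        if variance in ("hwe", "hwe_plugin"):
            sig2 = 2.0 * phat * (1.0 - phat)
            if variance == "hwe":
                sig2 = sig2 * sig2_corr[:, None]
        elif variance == "empirical":
            g2 = onehot @ (g * g)
            sig2 = g2 / counts[:, None] - gbar**2
        else:
            raise ValidationError(f"unknown variance estimator: {variance}")
        u_all[lo:hi] = a @ g  # centring constant drops out: sum_s a over stratum = 0
        v_all[lo:hi] = q_strat @ sig2

    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = np.where(v_all > 0, u_all**2 / v_all, np.nan)
    p = np.where(np.isfinite(chisq), st.chi2.sf(np.nan_to_num(chisq), df=1), np.nan)
    mono = np.all((phat_all <= 0) | (phat_all >= 1) | (counts[:, None] == 0), axis=0)
    p = np.where(mono, 1.0, p)
    return pd.DataFrame(
        {
            "snp": gm.snps["snp_id"].to_numpy(),
            "n": n,
            "U": u_all,
            "V": v_all,
            "chisq": chisq,
            "p": p,
        }
    )


def genomic_inflation(chisq: np.ndarray) -> float:
    """lambda = median(chi^2) / median of the 1-df chi-square distribution."""
    chisq = np.asarray(chisq, dtype=float)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValidationError("no chi-square values")
    if chisq.size < 100:
        warnings.warn("fewer than 100 chi-square values; lambda is noisy", stacklevel=2)
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def qq_points(p: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot, sorted most significant first."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    obs = -np.log10(np.sort(p))
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected": exp, "observed": obs})
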