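"""Synthetic carrier cohorts with the statistical structure the analyses assume.

The generator produces two-generation families of mutation carriers assigned
to country x founder-mutation strata, draws founder genotypes under
Hardy-Weinberg equilibrium with per-stratum allele frequencies, transmits
alleles Mendelianly (which induces the within-family genotype correlation
the kinship-adjusted score test must absorb), samples breast cancer onset
ages from a proportional-hazards model on a piecewise-constant carrier
baseline hazard with a multiplicative per-allele SNP effect, applies
phenotype-based two-stage ascertainment, and optionally corrupts the
genotype matrix with the defect classes the QC cascade is designed to catch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Carrier,
    EventHistory,
    IncidenceModel,
    Pedigree,
    ValidationError,
    derive_time_at_risk,
)
from .genotypes import MISSING, GenotypeMatrix, snp_table

__all__ = [
    "SimConfig",
    "AscertainmentScheme",
    "ArtifactConfig",
    "FamilySet",
    "CohortData",
    "default_incidence",
    "default_country_weights",
    "simulate_families",
    "simulate_genotypes",
    "simulate_phenotypes",
    "build_carriers",
    "apply_ascertainment",
    "inject_artifacts",
    "simulate_cohort",
    "simulate_null_scan_cohort",
]

# Stage-1-like country composition (fractions of carriers per country of
# study; 14 countries, one of them rare).
_COUNTRIES = {
    "Australia": 0.087,
    "Canada": 0.123,
    "Denmark": 0.005,
    "France": 0.035,
    "Finland": 0.025,
    "Germany": 0.045,
    "Iceland": 0.015,
    "Israel": 0.062,
    "Italy": 0.070,
    "Spain": 0.081,
    "Sweden": 0.012,
    "Netherlands": 0.019,
    "UK": 0.160,
    "USA": 0.261,
}


def default_country_weights() -> dict[str, float]:
    w = dict(_COUNTRIES)
    tot = sum(w.values())
    return {k: v / tot for k, v in w.items()}


def default_incidence() -> IncidenceModel:
    """Synthetic carrier baseline hazard, rising by age decade.

    Cumulative risk is ~50% by age 70.  These are NOT published carrier
    incidence rates; they are a plausible synthetic default, and users supply
    their own rate tables for real analyses.
    """
    return IncidenceModel(
        age_band_edges=[0, 20, 30, 40, 50, 60, 70, 80],
        rates=[0.0, 0.004, 0.012, 0.022, 0.018, 0.015, 0.015],
    )


@dataclass(frozen=True)
class AscertainmentScheme:
    """Phenotype-based selection; never looks at genotype.

    Stage-1 default: affected carriers with diagnosis at or below
    ``case_max_dx`` (sampling weighted toward diagnoses under
    ``case_young_age``) and unaffected carriers censored after
    ``control_min_censor``.
    """

    case_max_dx: float = 50.0
    case_young_age: float = 40.0
    case_young_weight: float = 3.0
    control_min_censor: float = 40.0
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass(frozen=True)
class ArtifactConfig:
    """Rates and counts of planted genotyping defects."""

    background_missing: float = 0.0
    pheno_diff_snps: int = 0
    pheno_missing_delta: float = 0.05
    batch_diff_snps: int = 0
    batch_missing_delta: float = 0.05
    n_batches: int = 2
    n_duplicates: int = 0
    n_het_outliers: int = 0
    het_boost: float = 0.5
    n_hwe_snps: int = 0
    hwe_het_deficit: float = 0.8
    n_ancestry: int = 0
    ancestry_fst: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "background_missing",
            "pheno_missing_delta",
            "batch_missing_delta",
            "het_boost",
            "hwe_het_deficit",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]: {v}")
        if not 0.0 < self.ancestry_fst < 1.0:
            raise ValidationError("ancestry_fst must be in (0,1)")


@dataclass
class SimConfig:
    n_families: int = 500
    family_size_probs: Sequence[float] = (0.45, 0.35, 0.20)  # sizes 1, 2, 3, ...
    country_weights: Mapping[str, float] = field(default_factory=default_country_weights)
    delt_prob: float = 0.2
    causal_maf: float | Mapping[str, float] = 0.3
    beta: float = 0.0
    n_null_snps: int = 100
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    incidence: IncidenceModel = field(default_factory=default_incidence)
    ovarian_rate: float = 0.002  # events/person-year from age 30
    bpm_rate: float = 0.002  # events/person-year from age 30
    min_obs_age: float = 25.0
    max_obs_age: float = 80.0
    ascertainment: AscertainmentScheme = field(default_factory=AscertainmentScheme)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValidationError("beta must be finite")
        lo, hi = self.null_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("null MAF range must lie in (0, 0.5]")
        mafs = (
            self.causal_maf.values()
            if isinstance(self.causal_maf, Mapping)
            else [self.causal_maf]
        )
        for p in mafs:
            if not 0.0 < p < 1.0:
                raise ValidationError(f"causal allele frequency must be in (0,1): {p}")
        probs = np.asarray(self.family_size_probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0 or np.any(probs < 0) or probs.sum() <= 0:
            raise ValidationError("family_size_probs must be non-negative, non-empty")


@dataclass
class FamilySet:
    """Pedigrees plus the typed (cohort) members and stratum per family.

    Pedigrees include latent, untyped founder parents so that kinship is
    defined for sibships; ``typed_ids`` lists the cohort members, and
    ``mother_of``/``father_of`` give each typed member's parents (either may
    be a latent id or None for founders).
    """

    pedigrees: list[Pedigree]
    strata: dict[str, tuple[str, bool]]  # family_id -> (country, delT)
    typed_ids: dict[str, list[str]]

    def all_typed(self) -> list[str]:
        return [i for fam in self.pedigrees for i in self.typed_ids[fam.family_id]]


def simulate_families(cfg: SimConfig, rng: np.random.Generator | None = None) -> FamilySet:
    """Draw family sizes, structures and stratum assignments.

    A size-1 family is a lone founder; larger families are a typed mother, a
    latent (untyped) father and typed children, so typed members are related
    with kinship 0.25 (parent-offspring and full sibs).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    probs = np.asarray(cfg.family_size_probs, dtype=float)
    probs = probs / probs.sum()
    sizes = rng.choice(np.arange(1, probs.size + 1), size=cfg.n_families, p=probs)
    countries = list(cfg.country_weights)
    cw = np.asarray([cfg.country_weights[c] for c in countries], dtype=float)
    cw = cw / cw.sum()
    fam_country = rng.choice(countries, size=cfg.n_families, p=cw)
    fam_delt = rng.random(cfg.n_families) < cfg.delt_prob

    pedigrees: list[Pedigree] = []
    strata: dict[str, tuple[str, bool]] = {}
    typed: dict[str, list[str]] = {}
    for k, size in enumerate(sizes):
        fid = f"fam{k}"
        members: list[tuple[str, str | None, str | None, int]] = []
        if size == 1:
            members.append((f"{fid}_i0", None, None, 2))
            typed[fid] = [f"{fid}_i0"]
        else:
            mother, father = f"{fid}_m", f"{fid}_f"
            members.append((mother, None, None, 2))
            members.append((father, None, None, 1))  # latent, untyped
            kids = [f"{fid}_i{j}" for j in range(size - 1)]
            for kid in kids:
                members.append((kid, father, mother, 2))
            typed[fid] = [mother] + kids
        pedigrees.append(Pedigree(family_id=fid, members=members))
        strata[fid] = (str(fam_country[k]), bool(fam_delt[k]))
    return FamilySet(pedigrees=pedigrees, strata=strata, typed_ids=typed)


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry from parent dosages (Mendelian segregation)."""
    het = parent == 1
    allele = (parent == 2).astype(np.int8)
    allele[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    return allele


def simulate_genotypes(
    fams: FamilySet, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Founders ~ Binomial(2, p_stratum) under HWE; children by transmission.

    The causal SNP is the first column (snp_id ``causal``); null SNPs follow
    with frequencies drawn uniformly from ``cfg.null_maf_range`` (shared
    across strata).  The causal frequency may vary by stratum country when
    ``cfg.causal_maf`` is a mapping.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    m = cfg.n_null_snps + 1
    null_p = rng.uniform(*cfg.null_maf_range, size=cfg.n_null_snps)

    sample_ids: list[str] = []
    family_ids: list[str] = []
    rows: list[np.ndarray] = []
    for ped in fams.pedigrees:
        fid = ped.family_id
        country, _delt = fams.strata[fid]
        if isinstance(cfg.causal_maf, Mapping):
            p_c = cfg.causal_maf.get(country)
            if p_c is None:
                raise ValidationError(f"no causal frequency for stratum {country}")
        else:
            p_c = cfg.causal_maf
        p = np.concatenate([[p_c], null_p])
        typed = fams.typed_ids[fid]
        if len(typed) == 1:
            g = rng.binomial(2, p).astype(np.int8)
            rows.append(g[None, :])
        else:
            mother = rng.binomial(2, p).astype(np.int8)
            father = rng.binomial(2, p).astype(np.int8)
            fam_rows = [mother]
            for _ in range(len(typed) - 1):
                kid = _transmit(mother, rng) + _transmit(father, rng)
                fam_rows.append(kid.astype(np.int8))
            rows.append(np.stack(fam_rows))
        sample_ids.extend(typed)
        family_ids.extend([fid] * len(typed))

    calls = np.concatenate(rows, axis=0)
    snps = snp_table(m)
    snps.loc[0, "snp_id"] = "causal"
    return GenotypeMatrix(sample_ids, snps, calls, family_ids)


def _fast_null_genotypes(
    fams: FamilySet, n_snps: int, maf_range: tuple[float, float], rng: np.random.Generator
) -> GenotypeMatrix:
    """Vectorised null-SNP-only generation for large genome scans.

    Equivalent in law to :func:`simulate_genotypes` without the causal column
    but drawing all families' founders in one pass (null frequencies shared
    across strata make this possible).
    """
    p = rng.uniform(*maf_range, size=n_snps)
    sample_ids: list[str] = []
    family_ids: list[str] = []
    mother_idx: list[int] = []  # per child, row index of mother / father
    father_idx: list[int] = []
    child_slots: list[int] = []
    founder_slots: list[int] = []
    n_rows = 0
    n_founder_draws = 0
    founder_draw_of_row: list[tuple[int, int]] = []  # (row, founder draw index)
    latent_father_draw: dict[str, int] = {}
    for ped in fams.pedigrees:
        fid = ped.family_id
        typed = fams.typed_ids[fid]
        if len(typed) == 1:
            founder_draw_of_row.append((n_rows, n_founder_draws))
            founder_slots.append(n_rows)
            n_founder_draws += 1
            n_rows += 1
        else:
            mother_row = n_rows
            founder_draw_of_row.append((mother_row, n_founder_draws))
            n_founder_draws += 1
            father_draw = n_founder_draws
            latent_father_draw[fid] = father_draw
            n_founder_draws += 1
            n_rows += 1
            for _ in typed[1:]:
                mother_idx.append(mother_row)
                father_idx.append(father_draw)
                child_slots.append(n_rows)
                n_rows += 1
        sample_ids.extend(typed)
        family_ids.extend([fid] * len(typed))

    founders = rng.binomial(2, p[None, :], size=(n_founder_draws, n_snps)).astype(np.int8)
    calls = np.empty((n_rows, n_snps), dtype=np.int8)
    for row, draw in founder_draw_of_row:
        calls[row] = founders[draw]
    if child_slots:
        mothers = calls[np.asarray(mother_idx)]
        fathers = founders[np.asarray(father_idx)]
        kids = _transmit(mothers, rng) + _transmit(fathers, rng)
        calls[np.asarray(child_slots)] = kids
    return GenotypeMatrix(sample_ids, snp_table(n_snps), calls, family_ids)


def _inverse_cumulative(m: IncidenceModel, target: np.ndarray) -> np.ndarray:
    """Solve Lambda0(T) = target on [0, 80]; inf where target exceeds Lambda0(80)."""
    edges = np.asarray(m.age_band_edges, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(edges) * np.asarray(m.rates))])
    t = np.interp(target, cum, edges)
    return np.where(target > cum[-1], np.inf, t)


def simulate_phenotypes(
    g_causal: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[EventHistory]:
    """Breast cancer onset by inverse-transform sampling of the PH model.

    Onset age T solves Lambda0(T) * exp(beta * g) = -log(U), U ~ Uniform(0,1).
    Ovarian cancer and BPM occur as independent constant-hazard competing
    censoring events from age 30; all events after the interview age are
    unrecorded (the raw history keeps only what a study would observe).
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    g = np.asarray(g_causal, dtype=float)
    n = g.size
    e = rng.exponential(size=n)
    onset = _inverse_cumulative(cfg.incidence, e * np.exp(-cfg.beta * g))
    obs = rng.uniform(cfg.min_obs_age, cfg.max_obs_age, size=n)
    with np.errstate(divide="ignore"):
        t_ov = 30.0 + (
            rng.exponential(1.0 / cfg.ovarian_rate, size=n)
            if cfg.ovarian_rate > 0
            else np.full(n, np.inf)
        )
        t_bpm = 30.0 + (
            rng.exponential(1.0 / cfg.bpm_rate, size=n)
            if cfg.bpm_rate > 0
            else np.full(n, np.inf)
        )
    birth = rng.integers(1920, 1981, size=n)

    histories = []
    for i in range(n):
        histories.append(
            EventHistory(
                breast_dx_age=round(onset[i], 2) if onset[i] <= obs[i] else None,
                ovarian_dx_age=round(t_ov[i], 2) if t_ov[i] <= obs[i] else None,
                bpm_age=round(t_bpm[i], 2) if t_bpm[i] <= obs[i] else None,
                last_obs_age=round(obs[i], 2),
                birth_year=int(birth[i]),
            )
        )
    return histories


def build_carriers(
    fams: FamilySet, histories: Sequence[EventHistory], stage: int = 1
) -> list[Carrier]:
    """Apply the censoring rules to raw histories, in typed-member order."""
    ids = fams.all_typed()
    fam_of = {i: ped.family_id for ped in fams.pedigrees for i in fams.typed_ids[ped.family_id]}
    if len(ids) != len(histories):
        raise ValidationError("one history per typed member required")
    out = []
    for iid, h in zip(ids, histories):
        age, affected, _reason = derive_time_at_risk(h)
        country, delt = fams.strata[fam_of[iid]]
        out.append(
            Carrier(
                individual_id=iid,
                family_id=fam_of[iid],
                country=country,
                delt_carrier=delt,
                censor_age=age,
                affected=affected,
                stage=stage,
                birth_year=h.birth_year,
            )
        )
    return out


def apply_ascertainment(
    carriers: Sequence[Carrier],
    scheme: AscertainmentScheme,
    rng: np.random.Generator | None = None,
) -> list[Carrier]:
    """Select cases and controls by phenotype alone.

    Eligible cases: affected with diagnosis age <= ``case_max_dx``; eligible
    controls: unaffected with censor age > ``control_min_censor``.  When
    target counts are set, cases are subsampled with extra weight on
    diagnoses under ``case_young_age`` (young-onset enrichment) and controls
    uniformly.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    cases = [c for c in carriers if c.affected and c.censor_age <= scheme.case_max_dx]
    controls = [
        c for c in carriers if not c.affected and c.censor_age > scheme.control_min_censor
    ]

    def pick(pool: list[Carrier], k: int, weights: np.ndarray | None) -> list[Carrier]:
        if k >= len(pool):
            return list(pool)
        p = None if weights is None else weights / weights.sum()
        idx = rng.choice(len(pool), size=k, replace=False, p=p)
        return [pool[i] for i in sorted(idx)]

    if scheme.n_cases is not None:
        w = np.asarray(
            [
                scheme.case_young_weight if c.censor_age < scheme.case_young_age else 1.0
                for c in cases
            ]
        )
        cases = pick(cases, scheme.n_cases, w)
    if scheme.n_controls is not None:
        controls = pick(controls, scheme.n_controls, None)
    selected = cases + controls
    if not selected:
        raise ValidationError("ascertainment scheme selected zero carriers")
    return selected


def inject_artifacts(
    gm: GenotypeMatrix,
    acfg: ArtifactConfig,
    affected: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Corrupt a clean matrix with planted, ledgered defects.

    Plants (in this order, each on the current state): ancestry-shifted
    samples (Balding-Nichols frequency drift with the configured Fst),
    heterozygosity-inflated samples, HWE-violating SNPs (het deficit),
    exact duplicate samples (appended rows), background missingness, and
    differential missingness by phenotype and by batch.  Returns the
    corrupted matrix and a truth ledger naming every planted defect.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    out = gm.copy()
    n, m = out.n_samples, out.n_snps
    ledger: dict = {
        "ancestry_outliers": [],
        "het_outliers": [],
        "hwe_snps": [],
        "duplicates": [],
        "diff_missing_pheno_snps": [],
        "diff_missing_batch_snps": [],
        "batch": {},
    }

    p = np.nan_to_num(gm.allele_freq(), nan=0.5).clip(0.01, 0.99)
    if acfg.n_ancestry > 0:
        idx = rng.choice(n, size=min(acfg.n_ancestry, n), replace=False)
        f = acfg.ancestry_fst
        a, b = p * (1 - f) / f, (1 - p) * (1 - f) / f
        p_shift = rng.beta(a, b)
        for i in idx:
            out.calls[i] = rng.binomial(2, p_shift).astype(np.int8)
        ledger["ancestry_outliers"] = [out.sample_ids[i] for i in idx]

    if acfg.n_het_outliers > 0:
        avail = [i for i in range(n) if out.sample_ids[i] not in set(ledger["ancestry_outliers"])]
        idx = rng.choice(avail, size=min(acfg.n_het_outliers, len(avail)), replace=False)
        for i in idx:
            hom = np.flatnonzero((out.calls[i] == 0) | (out.calls[i] == 2))
            flip = hom[rng.random(hom.size) < acfg.het_boost]
            out.calls[i, flip] = 1
        ledger["het_outliers"] = [out.sample_ids[i] for i in idx]

    if acfg.n_hwe_snps > 0:
        jdx = rng.choice(m, size=min(acfg.n_hwe_snps, m), replace=False)
        for j in jdx:
            het = np.flatnonzero(out.calls[:, j] == 1)
            flip = het[rng.random(het.size) < acfg.hwe_het_deficit]
            out.calls[flip, j] = rng.choice([0, 2], size=flip.size).astype(np.int8)
        ledger["hwe_snps"] = [out.snps["snp_id"].iloc[j] for j in jdx]

    if acfg.n_duplicates > 0:
        idx = rng.choice(n, size=min(acfg.n_duplicates, n), replace=False)
        dup_rows = out.calls[idx].copy()
        dup_ids = [f"{out.sample_ids[i]}_dup" for i in idx]
        ledger["duplicates"] = [(out.sample_ids[i], d) for i, d in zip(idx, dup_ids)]
        out = GenotypeMatrix(
            out.sample_ids + dup_ids,
            out.snps,
            np.concatenate([out.calls, dup_rows]),
            out.family_ids + [out.family_ids[i] for i in idx],
        )
        if affected is not None:
            affected = np.concatenate([affected, np.asarray(affected)[idx]])
        n = out.n_samples

    if acfg.background_missing > 0:
        mask = rng.random(out.calls.shape) < acfg.background_missing
        out.calls[mask] = MISSING

    if acfg.pheno_diff_snps > 0:
        if affected is None:
            raise ValidationError("phenotype-differential missingness needs affected flags")
        aff = np.asarray(affected, dtype=bool)
        jdx = rng.choice(m, size=min(acfg.pheno_diff_snps, m), replace=False)
        for j in jdx:
            rows = np.flatnonzero(aff)
            hit = rows[rng.random(rows.size) < acfg.pheno_missing_delta]
            out.calls[hit, j] = MISSING
        ledger["diff_missing_pheno_snps"] = [out.snps["snp_id"].iloc[j] for j in jdx]

    batch = rng.integers(0, acfg.n_batches, size=n)
    ledger["batch"] = {out.sample_ids[i]: int(batch[i]) for i in range(n)}
    if acfg.batch_diff_snps > 0:
        jdx = rng.choice(m, size=min(acfg.batch_diff_snps, m), replace=False)
        for j in jdx:
            rows = np.flatnonzero(batch == 0)
            hit = rows[rng.random(rows.size) < acfg.batch_missing_delta]
            out.calls[hit, j] = MISSING
        ledger["diff_missing_batch_snps"] = [out.snps["snp_id"].iloc[j] for j in jdx]

    return out, ledger


def simulate_null_scan_cohort(
    cfg: SimConfig, n_snps: int
) -> tuple[GenotypeMatrix, list[Carrier]]:
    """Null-effect cohort for genome-scan calibration studies.

    Equivalent to :func:`simulate_cohort` with ``beta = 0`` but generating
    only null SNPs through a vectorised path, so tens of thousands of
    markers are feasible.  Returns the ascertained carriers and their
    genotypes, row-aligned.
    """
    if cfg.beta != 0.0:
        raise ValidationError("null scan cohort requires beta = 0")
    rng = np.random.default_rng(cfg.seed)
    fams = simulate_families(cfg, rng)
    gm = _fast_null_genotypes(fams, n_snps, cfg.null_maf_range, rng)
    histories = simulate_phenotypes(np.zeros(gm.n_samples), cfg, rng)
    carriers = build_carriers(fams, histories)
    selected = apply_ascertainment(carriers, cfg.ascertainment, rng)
    order = {iid: k for k, iid in enumerate(gm.sample_ids)}
    selected.sort(key=lambda c: order[c.individual_id])
    keep = {c.individual_id for c in selected}
    idx = [i for i, s in enumerate(gm.sample_ids) if s in keep]
    return gm.subset(sample_idx=idx), selected


@dataclass
class CohortData:
    """One simulated cohort end to end."""

    config: SimConfig
    families: FamilySet
    genotypes: GenotypeMatrix  # clean, all typed members
    carriers: list[Carrier]  # all typed members, censoring applied
    selected: list[Carrier]  # after ascertainment
    corrupted: GenotypeMatrix | None = None
    truth: dict | None = None

    def selected_genotypes(self) -> GenotypeMatrix:
        keep = {c.individual_id for c in self.selected}
        idx = [i for i, s in enumerate(self.genotypes.sample_ids) if s in keep]
        return self.genotypes.subset(sample_idx=idx)


def simulate_cohort(cfg: SimConfig, with_artifacts: bool = False) -> CohortData:
    """Families -> genotypes -> phenotypes -> ascertainment (-> artifacts)."""
    rng = np.random.default_rng(cfg.seed)
    fams = simulate_families(cfg, rng)
    gm = simulate_genotypes(fams, cfg, rng)
    histories = simulate_phenotypes(gm.calls[:, 0], cfg, rng)
    carriers = build_carriers(fams, histories)
    selected = apply_ascertainment(carriers, cfg.ascertainment, rng)
    order = {iid: k for k, iid in enumerate(gm.sample_ids)}
    selected.sort(key=lambda c: order[c.individual_id])  # genotype-row order
    corrupted = truth = None
    if with_artifacts:
        affected = np.asarray([c.affected for c in carriers], dtype=bool)
        keep = {c.individual_id for c in carriers}
        assert keep  # all typed members retained pre-ascertainment
        corrupted, truth = inject_artifacts(gm, cfg.artifacts, affected, rng)
    return CohortData(
        config=dataclasses.replace(cfg),
        families=fams,
        genotypes=gm,
        carriers=carriers,
        selected=selected,
        corrupted=corrupted,
        truth=truth,
    )
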