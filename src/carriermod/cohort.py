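"""Core cohort model: carriers, censoring, pedigree kinship, strata, baseline incidence.

The analyses in this package treat each mutation carrier as a survival unit:
time at risk runs from birth to the first breast cancer, ovarian cancer,
bilateral prophylactic mastectomy (BPM) or end of observation, capped at 80
years (no reliable carrier incidence rates exist beyond that age).  Carriers
censored at breast cancer are cases; carriers censored at ovarian cancer or
BPM are treated as unaffected.  Familial correlation enters through the
pedigree kinship matrix, and the external baseline incidence enters through a
piecewise-constant hazard model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "EventHistory",
    "Carrier",
    "Pedigree",
    "KinshipMatrix",
    "IncidenceModel",
    "StratumScheme",
    "derive_time_at_risk",
    "kinship_matrix",
    "cumulative_hazard",
    "assign_strata",
    "CENSOR_CAP",
]

CENSOR_CAP = 80.0


class ValidationError(ValueError):
    """Raised when input data violate a structural precondition."""


@dataclass(frozen=True)
class EventHistory:
    """Per-carrier event ages in years; ``None`` marks an unrecorded event.

    ``last_obs_age`` may be absent when a terminating event (cancer or BPM)
    is recorded.  Raw-data inconsistencies such as an event postdating the
    last observation are rejected by :func:`derive_time_at_risk`.
    """

    breast_dx_age: float | None = None
    ovarian_dx_age: float | None = None
    bpm_age: float | None = None
    last_obs_age: float | None = None
    birth_year: int | None = None


@dataclass(frozen=True)
class Carrier:
    """A mutation carrier as the phenotype unit of the retrospective likelihood."""

    individual_id: str
    family_id: str
    country: str | None
    delt_carrier: bool | None
    censor_age: float
    affected: bool
    stage: int = 1
    birth_year: int | None = None

    def __post_init__(self) -> None:
        if self.censor_age <= 0 or self.censor_age > CENSOR_CAP:
            raise ValidationError(
                f"censor_age must lie in (0, {CENSOR_CAP}]: {self.censor_age}"
            )


@dataclass
class Pedigree:
    """One family: (individual_id, father_id, mother_id, sex) tuples.

    ``sex`` follows the PLINK convention (1 = male, 2 = female, 0 = unknown).
    Absent parents are ``None``.
    """

    family_id: str
    members: list[tuple[str, str | None, str | None, int]] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [m[0] for m in self.members]


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients phi over a fixed carrier ordering."""

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.phi[self.index[a], self.index[b]])


@dataclass
class IncidenceModel:
    """Piecewise-constant baseline breast cancer incidence for carriers.

    ``age_band_edges`` are ascending band boundaries starting at 0 and ending
    at 80; ``rates`` holds one hazard (events/person-year) per band.  An
    optional mapping from birth decade (e.g. 1950) to a multiplier scales the
    hazard for calendar-cohort effects; unknown decades use 1.
    """

    age_band_edges: Sequence[float]
    rates: Sequence[float]
    cohort_multipliers: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        edges = np.asarray(self.age_band_edges, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValidationError("need at least two band edges")
        if edges[0] != 0.0 or not np.all(np.diff(edges) > 0):
            raise ValidationError("band edges must be ascending and start at 0")
        if edges[-1] != CENSOR_CAP:
            raise ValidationError(f"last band edge must be {CENSOR_CAP}")
        if rates.size != edges.size - 1:
            raise ValidationError("need one rate per band")
        if np.any(rates < 0):
            raise ValidationError("rates must be >= 0")
        self.age_band_edges = edges
        self.rates = rates

    def multiplier(self, birth_year: int | None) -> float:
        if birth_year is None or not self.cohort_multipliers:
            return 1.0
        decade = int(birth_year) // 10 * 10
        return float(self.cohort_multipliers.get(decade, 1.0))

    def cumulative(self, t: float | np.ndarray, birth_year: int | None = None) -> np.ndarray:
        """Vectorised cumulative hazard Lambda0(t) (see :func:`cumulative_hazard`)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0) or np.any(t_arr > CENSOR_CAP):
            raise ValidationError("t outside [0, 80]")
        lo = self.age_band_edges[:-1]
        hi = self.age_band_edges[1:]
        overlap = np.clip(t_arr[:, None], lo, hi) - lo  # years spent in each band
        lam = overlap @ self.rates
        return lam * self.multiplier(birth_year)


def derive_time_at_risk(
    h: EventHistory, cap: float = CENSOR_CAP
) -> tuple[float, bool, str]:
    """Derive (censor_age, affected, censor_reason) from an event history.

    Censoring occurs at the first breast cancer, ovarian cancer or BPM,
    otherwise at last observation, always capped at ``cap``.  A BPM recorded
    more than one year before the first cancer overrides that cancer (to
    avoid censoring at mastectomies performed because of the diagnosis
    itself, given that ages are often rounded).  Only breast cancer makes a
    carrier affected; ovarian-cancer and BPM censoring yield unaffected
    status, as does hitting the age cap.
    """
    ages = {
        "breast": h.breast_dx_age,
        "ovarian": h.ovarian_dx_age,
        "bpm": h.bpm_age,
        "last_obs": h.last_obs_age,
    }
    recorded = {k: v for k, v in ages.items() if v is not None}
    if not recorded:
        raise ValidationError("no observation: event history is empty")
    for k, v in recorded.items():
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"invalid age for {k}: {v}")
    if h.last_obs_age is not None:
        for k in ("breast", "ovarian", "bpm"):
            if recorded.get(k, -np.inf) > h.last_obs_age:
                raise ValidationError(
                    f"{k} event at {recorded[k]} postdates last observation "
                    f"at {h.last_obs_age}"
                )

    cancers = {k: recorded[k] for k in ("breast", "ovarian") if k in recorded}
    first_cancer = min(cancers, key=cancers.get) if cancers else None
    bpm = recorded.get("bpm")

    if first_cancer is not None:
        cancer_age = cancers[first_cancer]
        if bpm is not None and cancer_age - bpm > 1.0:
            age, reason = bpm, "bpm"
        elif bpm is not None and bpm <= cancer_age:
            # BPM within a year of the cancer: attribute censoring to the cancer
            age, reason = cancer_age, first_cancer
        elif bpm is not None and bpm < cancer_age:  # pragma: no cover - subsumed
            age, reason = bpm, "bpm"
        else:
            age, reason = cancer_age, first_cancer
    elif bpm is not None:
        age, reason = bpm, "bpm"
    else:
        age, reason = recorded["last_obs"], "last_obs"

    if age > cap:
        return cap, False, "age_cap"
    return age, reason == "breast", reason


def _topological_depths(ped_members: dict[str, tuple[str | None, str | None]]) -> dict[str, int]:
    """Generation depth per individual; raises on pedigree cycles."""
    depths: dict[str, int] = {}
    WORKING = object()
    state: dict[str, object] = {}

    def depth(i: str) -> int:
        if i in depths:
            return depths[i]
        if state.get(i) is WORKING:
            raise ValidationError(f"cyclic pedigree at individual {i}")
        state[i] = WORKING
        f, m = ped_members.get(i, (None, None))
        d = 0
        for p in (f, m):
            if p is not None and p in ped_members:
                d = max(d, depth(p) + 1)
        depths[i] = d
        state[i] = None
        return d

    for i in ped_members:
        depth(i)
    return depths


def kinship_matrix(
    pedigrees: Pedigree | Iterable[Pedigree], subjects: Sequence[str]
) -> KinshipMatrix:
    """Recursive pedigree kinship over ``subjects``.

    phi(i,i) = 1/2 (1 + phi(father_i, mother_i)); for i a descendant side,
    phi(i,j) = 1/2 [phi(father_i, j) + phi(mother_i, j)].  Individuals from
    different families (or absent from every pedigree) are unrelated
    founders with off-diagonal phi = 0.
    """
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
    parents: dict[str, tuple[str | None, str | None]] = {}
    fam_of: dict[str, str] = {}
    for ped in pedigrees:
        for iid, f, m, _sex in ped.members:
            parents[iid] = (f, m)
            fam_of[iid] = ped.family_id
    depths = _topological_depths(parents)
    cache: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        if a not in parents and b not in parents:
            return 0.5 if a == b else 0.0
        if a not in parents or b not in parents:
            known = a if a in parents else b
            other = b if a in parents else a
            if a == b:
                return phi_self(known)
            return 0.0 if other not in parents else phi(known, other)
        if fam_of[a] != fam_of[b]:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in cache:
            return cache[key]
        if a == b:
            val = phi_self(a)
        else:
            # recurse on the deeper individual (cannot be the other's ancestor)
            x, y = (a, b) if depths.get(a, 0) >= depths.get(b, 0) else (b, a)
            f, m = parents.get(x, (None, None))
            val = 0.5 * ((phi(f, y) if f is not None else 0.0) + (phi(m, y) if m is not None else 0.0))
        cache[key] = val
        return val

    def phi_self(a: str) -> float:
        f, m = parents.get(a, (None, None))
        inb = phi(f, m) if (f is not None and m is not None) else 0.0
        return 0.5 * (1.0 + inb)

    n = len(subjects)
    out = np.zeros((n, n))
    for i, a in enumerate(subjects):
        for j in range(i, n):
            out[i, j] = out[j, i] = phi(a, subjects[j])
    return KinshipMatrix(list(subjects), out)


def cumulative_hazard(
    t: float, birth_cohort: int | None, m: IncidenceModel
) -> float:
    """Cumulative baseline hazard Lambda0(t): exact piecewise-linear integral."""
    return float(m.cumulative(t, birth_cohort)[0])


@dataclass(frozen=True)
class StratumScheme:
    """Country x founder-mutation stratification, optionally also by stage."""

    include_stage: bool = False
    min_carriers: int = 2


def assign_strata(
    carriers: Sequence[Carrier], scheme: StratumScheme = StratumScheme()
) -> tuple[dict[str, str], "pd.DataFrame", list[tuple[str, str]]]:
    """Map each carrier to its stratum key.

    Returns ``(key_by_id, summary, excluded)`` where ``summary`` is a
    DataFrame with one row per non-empty stratum (n, n_affected) and
    ``excluded`` lists (individual_id, reason) for carriers with a missing
    stratum field.  Strata smaller than ``scheme.min_carriers`` are pooled
    into a country-level "rest" stratum.
    """
    import pandas as pd

    excluded: list[tuple[str, str]] = []
    raw: dict[str, str] = {}
    for c in carriers:
        if c.country is None or c.delt_carrier is None:
            excluded.append((c.individual_id, "missing stratum field"))
            continue
        key = f"{c.country}|delT={int(c.delt_carrier)}"
        if scheme.include_stage:
            key += f"|stage={c.stage}"
        raw[c.individual_id] = key

    counts: dict[str, int] = {}
    for key in raw.values():
        counts[key] = counts.get(key, 0) + 1
    remap: dict[str, str] = {}
    for key, n in counts.items():
        if n < scheme.min_carriers:
            parts = key.split("|")
            rest = f"{parts[0]}|rest"
            if scheme.include_stage:
                rest += f"|{parts[2]}"
            remap[key] = rest
    key_by_id = {iid: remap.get(k, k) for iid, k in raw.items()}

    by_c = {c.individual_id: c for c in carriers}
    rows = {}
    for iid, key in key_by_id.items():
        r = rows.setdefault(key, {"stratum": key, "n": 0, "n_affected": 0})
        r["n"] += 1
        r["n_affected"] += int(by_c[iid].affected)
    summary = pd.DataFrame(sorted(rows.values(), key=lambda r: r["stratum"]))
    return key_by_id, summary, excluded
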