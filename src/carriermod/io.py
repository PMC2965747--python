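"""Readers and writers for the non-genotype inputs and result tables.

Formats: a delimited pedigree/phenotype table (one row per individual),
YAML/JSON incidence-rate configs, BED-like gene annotations (0-based
half-open, converted centrally to 1-based inclusive), GMT-like gene-set
lists, and genetic-map text.  All coordinate conversions happen here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Carrier,
    EventHistory,
    IncidenceModel,
    Pedigree,
    ValidationError,
    derive_time_at_risk,
)
from .enrichment import GeneAnnotation

__all__ = [
    "PHENO_COLUMNS",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_incidence",
    "write_incidence",
    "read_annotations_bed",
    "read_gene_sets",
]

PHENO_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "country",
    "delT",
    "breast_dx_age",
    "ovarian_dx_age",
    "bpm_age",
    "last_obs_age",
    "birth_year",
]


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_phenotype_table(
    path: str | Path, stage: int = 1, sep: str = "\t"
) -> tuple[list[Carrier], list[Pedigree], list[tuple[str, str]]]:
    """Parse the pedigree/phenotype table into carriers and pedigrees.

    Empty fields are absent values.  Rows failing validation (male carriers,
    no observation, inconsistent event ages, missing stratum fields are kept
    but flagged downstream) are excluded with a logged reason; pedigree
    structure retains every row so kinship is still defined.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = set(PHENO_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing_cols)}")
    carriers: list[Carrier] = []
    excluded: list[tuple[str, str]] = []
    peds: dict[str, Pedigree] = {}
    for _, row in df.iterrows():
        fid, iid = row["family_id"], row["individual_id"]
        sex = int(row["sex"]) if row["sex"] != "" else 0
        ped = peds.setdefault(fid, Pedigree(family_id=fid))
        ped.members.append(
            (iid, row["father_id"] or None, row["mother_id"] or None, sex)
        )
        if sex == 1:
            excluded.append((iid, "male carrier"))
            continue
        try:
            h = EventHistory(
                breast_dx_age=_opt_float(row["breast_dx_age"]),
                ovarian_dx_age=_opt_float(row["ovarian_dx_age"]),
                bpm_age=_opt_float(row["bpm_age"]),
                last_obs_age=_opt_float(row["last_obs_age"]),
                birth_year=int(row["birth_year"]) if row["birth_year"] != "" else None,
            )
            age, affected, _ = derive_time_at_risk(h)
        except ValidationError as e:
            excluded.append((iid, str(e)))
            continue
        delt = None if row["delT"] == "" else row["delT"].strip().lower() in ("1", "true", "yes")
        carriers.append(
            Carrier(
                individual_id=iid,
                family_id=fid,
                country=row["country"] or None,
                delt_carrier=delt,
                censor_age=age,
                affected=affected,
                stage=stage,
                birth_year=h.birth_year,
            )
        )
    return carriers, list(peds.values()), excluded


def write_phenotype_table(
    path: str | Path,
    pedigrees: Sequence[Pedigree],
    histories_by_id: dict[str, EventHistory],
    country_by_family: dict[str, tuple[str, bool]],
    sep: str = "\t",
) -> None:
    rows = []
    for ped in pedigrees:
        country, delt = country_by_family[ped.family_id]
        for iid, father, mother, sex in ped.members:
            h = histories_by_id.get(iid)
            rows.append(
                {
                    "family_id": ped.family_id,
                    "individual_id": iid,
                    "father_id": father or "",
                    "mother_id": mother or "",
                    "sex": sex,
                    "country": country,
                    "delT": int(delt),
                    "breast_dx_age": "" if h is None or h.breast_dx_age is None else h.breast_dx_age,
                    "ovarian_dx_age": ""
                    if h is None or h.ovarian_dx_age is None
                    else h.ovarian_dx_age,
                    "bpm_age": "" if h is None or h.bpm_age is None else h.bpm_age,
                    "last_obs_age": "" if h is None or h.last_obs_age is None else h.last_obs_age,
                    "birth_year": "" if h is None or h.birth_year is None else h.birth_year,
                }
            )
    pd.DataFrame(rows, columns=PHENO_COLUMNS).to_csv(path, sep=sep, index=False)


def read_incidence(path: str | Path) -> IncidenceModel:
    """Incidence config: YAML/JSON with age_band_edges, rates, optional cohort_multipliers."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return IncidenceModel(
        age_band_edges=cfg["age_band_edges"],
        rates=cfg["rates"],
        cohort_multipliers={int(k): float(v) for k, v in cfg.get("cohort_multipliers", {}).items()},
    )


def write_incidence(path: str | Path, m: IncidenceModel) -> None:
    cfg = {
        "age_band_edges": [float(e) for e in m.age_band_edges],
        "rates": [float(r) for r in m.rates],
        "cohort_multipliers": {int(k): float(v) for k, v in m.cohort_multipliers.items()},
    }
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(cfg, fh, indent=1)
        else:
            yaml.safe_dump(cfg, fh)


def read_annotations_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED-like annotation (chrom, start, end, gene, [score,] strand).

    BED coordinates are 0-based half-open; they are converted here, once, to
    the 1-based inclusive convention used everywhere else in the package.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 4:
                raise ValidationError(f"BED line with <4 fields: {line!r}")
            strand = "+"
            if len(parts) >= 6 and parts[5] in "+-":
                strand = parts[5]
            elif len(parts) == 5 and parts[4] in "+-":
                strand = parts[4]
            out.append(
                GeneAnnotation(
                    gene=parts[3],
                    chrom=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    strand=strand,
                )
            )
    return out


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """GMT-like gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
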