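"""Run configuration with the pipeline's canonical threshold defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import ValidationError
from .qc import QCThresholds

__all__ = ["RunConfig", "DEFAULTS"]

# canonical defaults for every tunable threshold (see QCThresholds for QC)
DEFAULTS = {
    "snp_call_rate": 0.95,
    "sample_call_rate": 0.95,
    "maf": 0.01,
    "hwe_p": 1e-6,
    "hwe_p_stringent": 1e-7,
    "diff_miss_pheno_p": 1e-3,
    "diff_miss_neighbor_p": 1e-10,
    "ibs_dup": 0.95,
    "het_fdr": 0.001,
    "mds_cutoff": 0.11,
    "ld_prune_r2": 0.80,
    "gsea_up_kb": 110,
    "gsea_down_kb": 40,
    "gsea_percentile": 95,
    "gsea_n_random": 10_000,
    "ibd_min_cm": 5.0,
    "ibd_grid_cm": 2.5,
    "censor_cap": 80,
    "top_k_regions": 79,
}


@dataclass
class RunConfig:
    """Paths plus every tunable threshold, defaulting to the canonical values."""

    genotypes: str | None = None  # PLINK prefix (.ped/.map or .bed/.bim/.fam)
    phenotypes: str | None = None
    genotypes2: str | None = None  # optional stage-2 prefix
    phenotypes2: str | None = None
    incidence: str | None = None
    genetic_map: str | None = None
    annotations: str | None = None
    gene_sets: str | None = None
    mask: str | None = None
    out_dir: str = "carriermod_out"
    seed: int = 0

    qc: QCThresholds = field(default_factory=QCThresholds)
    ld_prune_r2: float = DEFAULTS["ld_prune_r2"]
    top_k_regions: int = DEFAULTS["top_k_regions"]
    forced_snps: list[str] = field(default_factory=list)
    gsea_up_kb: int = DEFAULTS["gsea_up_kb"]
    gsea_down_kb: int = DEFAULTS["gsea_down_kb"]
    gsea_percentile: float = DEFAULTS["gsea_percentile"]
    gsea_n_random: int = DEFAULTS["gsea_n_random"]
    ibd_min_cm: float = DEFAULTS["ibd_min_cm"]
    ibd_grid_cm: float = DEFAULTS["ibd_grid_cm"]
    censor_cap: float = DEFAULTS["censor_cap"]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_raw = raw.pop("qc", {})
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        return cls(qc=QCThresholds(**qc_raw), **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def self_test(self) -> None:
        """Assert that an untouched config carries the canonical defaults."""
        qc = QCThresholds()
        assert qc.snp_call_rate == DEFAULTS["snp_call_rate"]
        assert qc.sample_call_rate == DEFAULTS["sample_call_rate"]
        assert qc.maf == DEFAULTS["maf"]
        assert qc.hwe_p == DEFAULTS["hwe_p"]
        assert qc.hwe_p_stringent == DEFAULTS["hwe_p_stringent"]
        assert qc.diff_miss_pheno_p == DEFAULTS["diff_miss_pheno_p"]
        assert qc.diff_miss_neighbor_p == DEFAULTS["diff_miss_neighbor_p"]
        assert qc.ibs_dup == DEFAULTS["ibs_dup"]
        assert qc.het_fdr == DEFAULTS["het_fdr"]
        assert qc.mds_cutoff == DEFAULTS["mds_cutoff"]
        assert RunConfig().ld_prune_r2 == DEFAULTS["ld_prune_r2"]
        assert RunConfig().gsea_up_kb == DEFAULTS["gsea_up_kb"]
        assert RunConfig().gsea_down_kb == DEFAULTS["gsea_down_kb"]
        assert RunConfig().gsea_percentile == DEFAULTS["gsea_percentile"]
        assert RunConfig().gsea_n_random == DEFAULTS["gsea_n_random"]
        assert RunConfig().ibd_min_cm == DEFAULTS["ibd_min_cm"]
        assert RunConfig().ibd_grid_cm == DEFAULTS["ibd_grid_cm"]
        assert RunConfig().censor_cap == DEFAULTS["censor_cap"]
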