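"""Shared domain containers for the interaction-analysis pipeline.

Genotypes are stored as minor-allele-style dosages counting copies of the
first allele listed in the variant map (``a1``), values in {0, 1, 2} with a
sentinel for missing calls.  Coordinates are 1-based inclusive throughout,
matching the PLINK ``.bim`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call. Distinct from all valid
#: dosages {0, 1, 2}; every statistic in the package uses pairwise-complete
#: samples over this sentinel.
MISSING: int = -1

AUTOSOMES = {str(c) for c in range(1, 23)}


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass
class GenotypeDataset:
    """A sample x SNP dosage matrix with sample and variant metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` int8 array of allele1 dosages, ``MISSING``
        for no-calls.
    samples
        DataFrame with columns ``sample_id``, ``cohort``, ``phenotype``
        (0 = control, 1 = case).
    snps
        DataFrame with columns ``snp_id``, ``chrom``, ``pos`` (1-based),
        ``a1``, ``a2``.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        n, m = self.genotypes.shape
        if len(self.samples) != n or len(self.snps) != m:
            raise ValueError(
                f"genotype matrix is {n}x{m} but metadata describe "
                f"{len(self.samples)} samples / {len(self.snps)} SNPs"
            )
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype dosages must be in {0,1,2} or MISSING")
        if not self.snps["snp_id"].is_unique:
            raise ValueError("snp_ids must be unique within a dataset")
        if (pd.to_numeric(self.snps["pos"]) <= 0).any():
            raise ValueError("base-pair positions must be strictly positive")
        phen = self.samples["phenotype"].to_numpy()
        if not np.isin(phen, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy(dtype=np.int64)

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == 1

    def subset(
        self,
        sample_idx: Optional[Sequence[int]] = None,
        snp_idx: Optional[Sequence[int]] = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given row/column indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            genotypes=self.genotypes[np.ix_(si, vi)].copy(),
            samples=self.samples.iloc[si].reset_index(drop=True),
            snps=self.snps.iloc[vi].reset_index(drop=True),
        )


@dataclass
class ExpressionDataset:
    """Probe x sample log2 expression with probe position annotation."""

    values: np.ndarray  # (n_probes, n_samples), log2 scale
    probes: pd.DataFrame  # probe_id, gene, chrom, pos (1-based)
    samples: list  # sample_ids, linking columns to genotyped individuals

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probes = self.probes.reset_index(drop=True)
        self.samples = list(self.samples)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError("expression matrix shape does not match metadata")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must all be finite")
        if not self.probes["probe_id"].is_unique:
            raise ValueError("probe_ids must be unique")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def subset_probes(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            values=self.values[idx].copy(),
            probes=self.probes.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )


@dataclass
class PipelineConfig:
    """Thresholds, cohort definitions and paths steering a pipeline run."""

    marginal_alpha: float = 1e-3
    gw_alpha: float = 5e-10
    maf_min: float = 0.01
    callrate_min: float = 0.95
    hwe_alpha: float = 1e-5
    ibs_max: float = 0.80
    cis_window: int = 1_000_000
    family_alpha: float = 0.05
    flank: int = 20_000
    lifetime_risk: float = 0.007
    seed: int = 0
    out_dir: str = "episcan_out"
    cohorts: tuple = ("UK", "DE")

    def __post_init__(self) -> None:
        for name in ("marginal_alpha", "gw_alpha", "hwe_alpha", "family_alpha"):
            a = getattr(self, name)
            if not (0 <= a < 1) and name != "marginal_alpha":
                raise ValueError(f"{name}={a} must lie in [0,1)")
        if not (0 < self.gw_alpha < 1 and 0 < self.hwe_alpha < 1
                and 0 < self.family_alpha < 1):
            raise ValueError("alphas must lie in (0,1)")
        if self.cis_window <= 0:
            raise ValueError("cis-window must be positive")
        if not (0 < self.lifetime_risk < 1):
            raise ValueError("lifetime risk must lie in (0,1)")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")


@dataclass
class PairResult:
    """One SNP pair's correlation-contrast and logistic interaction results."""

    snp1_id: str
    snp2_id: str
    r_cases: float = np.nan
    r_controls: float = np.nan
    var_r_cases: float = np.nan
    var_r_controls: float = np.nan
    t_wz: float = np.nan
    p_wz: float = np.nan
    n_cases_used: int = 0
    n_controls_used: int = 0
    or_int: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_logistic: float = np.nan
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class MetaPairResult:
    """Two-cohort combined interaction result for one SNP pair."""

    snp1_id: str
    snp2_id: str
    p_per_cohort: tuple = ()
    x_comb: float = np.nan
    df: int = 0
    p_meta: float = np.nan
    or_meta: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    significant: bool = False


@dataclass
class EqtlRecord:
    """Per (SNP, probe) robust-regression eQTL effect."""

    snp_id: str
    probe_id: str
    gene: str
    beta_zx: float
    se_zx: float
    p_eqtl: float
    n_used: int


@dataclass
class SmrRecord:
    """Ratio-based causal estimate linking a GWAS and an eQTL effect."""

    snp_id: str
    probe_id: str
    beta_zy: float
    se_zy: float
    beta_zx: float
    se_zx: float
    beta_xy: float
    t_smr: float
    p_smr: float


@dataclass
class GeneScore:
    gene_or_fusion_id: str
    member_snp_ids: tuple
    chi2_sum: float
    df: int
    p_gene: float


@dataclass
class PathwayResult:
    pathway_id: str
    fused_member_ids: tuple
    score: float
    df: int
    p_pathway: float
    p_sources: dict = field(default_factory=dict)
    p_combined: float = np.nan


def records_to_frame(records) -> pd.DataFrame:
    """Flatten a list of result dataclasses into a DataFrame."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in records])
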