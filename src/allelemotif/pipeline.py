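"""End-to-end orchestration: genome + VCF + motifs + FPKM -> hit report.

The scan walks every quality-passing biallelic SNP, reconstructs the
reference/alternative allele windows for each motif model, computes the
four allele x strand scores with delta statistics, annotates the nearest
gene, joins the gene's Z expression-response statistic, and writes the
published-style report (rounded) next to a full-precision machine-readable
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pyfaidx
import yaml

from .expression import DEFAULT_PSEUDOCOUNT, compute_z_table
from .interaction import (
    DEFAULT_DELTA_CUT,
    DEFAULT_P_LEVEL,
    DEFAULT_Z_CUT,
    IntegratedHit,
    MotifScoreResult,
    hits_to_frame,
    integrate,
    score_snp_motif,
)
from .pwm import PositionWeightMatrix, parse_pwm
from .variants import iter_allele_windows, load_snps

log = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = ["chrom", "start", "end", "strand", "symbol"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one scan run."""

    genome: Path
    vcf: Path
    pwm_dir: Path
    genes: Path
    fpkm: Path
    methylation: Path | None = None
    delta_cut: float = DEFAULT_DELTA_CUT
    z_cut: float = DEFAULT_Z_CUT
    p_level: float = DEFAULT_P_LEVEL
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    report_decimals: int = 2

    def __post_init__(self) -> None:
        for name in ("genome", "vcf", "pwm_dir", "genes", "fpkm"):
            setattr(self, name, Path(getattr(self, name)))
        if self.methylation is not None:
            self.methylation = Path(self.methylation)
        if min(self.delta_cut, self.z_cut, self.p_level, self.pseudocount) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("genome", "vcf", "pwm_dir", "genes", "fpkm"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")


@dataclass
class ScanResult:
    hits: list[IntegratedHit]
    results: list[MotifScoreResult] = field(repr=False, default_factory=list)
    n_snps: int = 0
    pwm_names: tuple[str, ...] = ()


def load_pwm_dir(pwm_dir: str | Path) -> list[PositionWeightMatrix]:
    """Parse every ``*.pwm`` model (with companion thresholds) in a directory."""
    paths = sorted(Path(pwm_dir).glob("*.pwm"))
    if not paths:
        raise FileNotFoundError(f"no *.pwm files in {pwm_dir}")
    return [parse_pwm(p) for p in paths]


def load_gene_table(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"{path}: gene table lacks columns {missing}")
    return genes


def run_scan(config: PipelineConfig) -> ScanResult:
    """Execute the full SNP x motif x expression scan."""
    config.validate_paths()
    pwms = load_pwm_dir(config.pwm_dir)
    genes = load_gene_table(config.genes)
    fpkm = pd.read_csv(config.fpkm, sep="\t", index_col="gene")
    zmap = compute_z_table(fpkm, pseudocount=config.pseudocount).to_dict()
    genome = pyfaidx.Fasta(str(config.genome))

    snps = list(load_snps(config.vcf))
    results: list[MotifScoreResult] = []
    for pwm in pwms:
        for pair in iter_allele_windows(snps, genome, pwm.length):
            results.append(score_snp_motif(pair, pwm, p_level=config.p_level))
    hits = integrate(results, zmap, genes, delta_cut=config.delta_cut, z_cut=config.z_cut)
    log.info("scan: %d SNPs x %d motifs -> %d hits", len(snps), len(pwms), len(hits))
    return ScanResult(
        hits=hits, results=results, n_snps=len(snps), pwm_names=tuple(p.name for p in pwms)
    )


def write_reports(
    scan: ScanResult, out_dir: str | Path, decimals: int = 2
) -> tuple[Path, Path]:
    """Write the rounded report and the full-precision table; return their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = out_dir / "hits.tsv"
    full = out_dir / "hits_full.tsv"
    hits_to_frame(scan.hits, decimals=decimals).to_csv(report, sep="\t", index=False)
    hits_to_frame(scan.hits, decimals=None).to_csv(full, sep="\t", index=False)
    return report, full
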