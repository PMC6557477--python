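"""Promoter regions, methylation levels and methylation-expression integration.

Two distinct promoter flavors are used deliberately:

* ``methylation``: [TSS-2000, TSS+200) — the 2.2 kb region over which
  capture-sequencing read counts are normalized per CpG;
* ``motif_scan``: [TSS-2000, TSS) — the 2 kb strictly-upstream region
  scanned for transcription-factor binding sites.

"Upstream" is strand-aware: reverse-strand genes mirror around their
5' end.  Methylation level is read_count / cpg_count.  The
methylation-expression relation is summarized by Kendall's tau and
Spearman's rho rank correlations over the gene intersection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .pwm import PositionWeightMatrix, count_sites

log = logging.getLogger(__name__)

UPSTREAM = 2000
METHYLATION_DOWNSTREAM = 200


def promoter_region(
    tss: int,
    strand: str,
    flavor: str = "methylation",
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """Strand-aware promoter interval, 0-based half-open.

    ``tss`` is the 1-based transcription start site.  The methylation
    flavor spans 2000 bp upstream to 200 bp downstream of the 5' end
    (2200 bp); the motif_scan flavor spans the 2000 bp strictly upstream.
    Regions are truncated (and logged) at contig edges.
    """
    if flavor not in ("methylation", "motif_scan"):
        raise ValueError(f"unknown promoter flavor {flavor!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    down = METHYLATION_DOWNSTREAM if flavor == "methylation" else 0
    tss0 = tss - 1
    if strand == "+":
        start, end = tss0 - UPSTREAM, tss0 + down
    else:
        start, end = tss0 - down + 1, tss0 + UPSTREAM + 1
    if start < 0:
        log.warning("promoter at TSS %d truncated at contig start", tss)
        start = 0
    if chrom_length is not None and end > chrom_length:
        log.warning("promoter at TSS %d truncated at contig end", tss)
        end = chrom_length
    return start, end


def methylation_level(read_count: int, cpg_count: int) -> float:
    """Capture reads per CpG over the probed promoter region.

    Undefined (NaN, flagged) when the region has no CpG.
    """
    if read_count < 0 or cpg_count < 0:
        raise ValueError("counts must be non-negative")
    if cpg_count == 0:
        log.warning("promoter region with 0 CpG: methylation level undefined")
        return math.nan
    return read_count / cpg_count


@dataclass(frozen=True)
class MethExprCorrelation:
    kendall_tau: float
    kendall_p: float
    spearman_rho: float
    spearman_p: float
    n_genes: int


def correlate_meth_expr(
    levels: Mapping[str, float], fpkm: Mapping[str, float]
) -> MethExprCorrelation | None:
    """Rank correlations between promoter methylation level and expression.

    Computed over the genes present in both maps (NaN levels dropped);
    ties are mid-ranked; p-values are two-sided.  Returns ``None`` with a
    warning when fewer than 3 genes are shared.
    """
    common = sorted(
        g for g in set(levels) & set(fpkm)
        if not (isinstance(levels[g], float) and math.isnan(levels[g]))
    )
    if len(common) < 3:
        log.warning("only %d genes shared between methylation and expression", len(common))
        return None
    x = [levels[g] for g in common]
    y = [fpkm[g] for g in common]
    tau = stats.kendalltau(x, y)
    rho = stats.spearmanr(x, y)
    return MethExprCorrelation(
        kendall_tau=float(tau.statistic),
        kendall_p=float(tau.pvalue),
        spearman_rho=float(rho.statistic),
        spearman_p=float(rho.pvalue),
        n_genes=len(common),
    )


def count_promoter_sites(
    pwms: Sequence[PositionWeightMatrix],
    promoters: Mapping[str, str],
    p_level: float = 1e-4,
) -> pd.DataFrame:
    """Binding-site census: gene x motif table of super-threshold window counts.

    Counts window start positions on both strands scoring at or above the
    motif's threshold for ``p_level``.  Raises ``KeyError`` when a motif
    lacks a threshold for the requested level.
    """
    thresholds = {pwm.name: pwm.threshold(p_level) for pwm in pwms}
    table = {
        pwm.name: {
            gene: count_sites(pwm, seq, thresholds[pwm.name])
            for gene, seq in promoters.items()
        }
        for pwm in pwms
    }
    df = pd.DataFrame(table)
    df.index.name = "gene"
    return df.sort_index()
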