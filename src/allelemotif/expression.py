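"""Strain-specific treatment-response statistic Z and condition comparisons.

The Z statistic contrasts the treatment-vs-control expression log-ratio
between two strains::

    Z = log2((FPKM_FVB.D300.F1 + c) / (FPKM_FVB.CTL.F1 + c))
      - log2((FPKM_C57.D300.F1 + c) / (FPKM_C57.CTL.F1 + c))

with pseudocount c = 0.1 added to every FPKM before division.  Z > 0 marks
genes induced by exposure specifically in the FVB strain or repressed
specifically in C57BL/6J; |Z| > 7 was the working threshold for calling a
strain-specific transcriptional response.

Condition-level FPKM is the quantification granularity; when per-replicate
values are supplied the condition level is their mean (logged).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

FVB_TREATED = "FVB.D300.F1"
FVB_CONTROL = "FVB.CTL.F1"
C57_TREATED = "C57.D300.F1"
C57_CONTROL = "C57.CTL.F1"
Z_CONDITIONS = (FVB_TREATED, FVB_CONTROL, C57_TREATED, C57_CONTROL)

DEFAULT_PSEUDOCOUNT = 0.1


def compute_z(
    fpkm: Mapping[str, float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gene: str = "?",
) -> float | None:
    """Double log2 fold-change between strains for one gene.

    Returns ``None`` (with a warning) when any of the four required
    condition labels is missing.
    """
    try:
        vals = [float(fpkm[c]) for c in Z_CONDITIONS]
    except KeyError as missing:
        log.warning("gene %s: condition %s missing, Z undefined", gene, missing)
        return None
    fvb_t, fvb_c, c57_t, c57_c = (v + pseudocount for v in vals)
    return math.log2(fvb_t / fvb_c) - math.log2(c57_t / c57_c)


def compute_z_table(
    fpkm: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Z for every row of a gene x condition FPKM table.

    ``fpkm`` must carry the four condition columns
    ``FVB.D300.F1, FVB.CTL.F1, C57.D300.F1, C57.CTL.F1``.
    """
    missing = [c for c in Z_CONDITIONS if c not in fpkm.columns]
    if missing:
        raise ValueError(f"FPKM table lacks condition columns {missing}")
    shifted = fpkm[list(Z_CONDITIONS)].astype(float) + pseudocount
    z = np.log2(shifted[FVB_TREATED] / shifted[FVB_CONTROL]) - np.log2(
        shifted[C57_TREATED] / shifted[C57_CONTROL]
    )
    z.name = "Z"
    return z


def condition_means(replicates: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Collapse per-replicate FPKM to condition-level means (logged)."""
    log.info("collapsing replicate FPKM to condition means for %d conditions", len(replicates))
    return {cond: float(np.mean(vals)) for cond, vals in replicates.items()}


def _rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= 8 values and the
    pooled sample is tie-free; otherwise the normal approximation with
    continuity correction (ties handled by mid-ranks).
    """
    pooled = list(x) + list(y)
    tie_free = len(set(pooled)) == len(pooled)
    if len(x) <= 8 and len(y) <= 8 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def pairwise_wilcoxon_bh(
    replicates: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], float]:
    """All pairwise rank-sum tests with Benjamini-Hochberg adjustment.

    Returns a map (condition_a, condition_b) -> adjusted two-sided p-value
    for every unordered condition pair (labels in sorted order).  Pairs
    involving a condition with fewer than 2 values are reported as NaN and
    excluded from the adjustment family.
    """
    conditions = sorted(replicates)
    pairs = list(itertools.combinations(conditions, 2))
    raw: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        if len(replicates[a]) < 2 or len(replicates[b]) < 2:
            log.warning("pair (%s, %s): fewer than 2 values, p undefined", a, b)
            raw[(a, b)] = math.nan
        else:
            raw[(a, b)] = _rank_sum_p(replicates[a], replicates[b])
    defined = [p for p in pairs if not math.isnan(raw[p])]
    if defined:
        adjusted = multipletests([raw[p] for p in defined], method="fdr_bh")[1]
        for pair, padj in zip(defined, adjusted):
            raw[pair] = float(padj)
    return raw
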