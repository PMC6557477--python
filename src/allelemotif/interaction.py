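"""Join motif disruption (delta) with expression response (Z) per SNP.

For each SNP x motif pair, the four clamped best-window scores (reference
and alternative allele, each on both strands, restricted to windows
overlapping the SNP) yield the motif-specificity statistic::

    delta     = ref     - alt        (forward strand)
    delta_rev = ref_rev - alt_rev    (reverse strand)

delta > 0 means the reference-strain allele carries the stronger site
(strain-specific site in C57BL/6J role); delta < 0 the alternative strain
(FVB/NJ role).  A SNP x motif pair is *significant* when any of the four
scores reaches the motif's p < p_level threshold.  Integration retains
significant pairs with |delta| above the cut on either strand whose
nearest gene shows |Z| above the expression cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pwm import PositionWeightMatrix, best_strand_scores, reverse_complement
from .variants import AlleleWindowPair, SnpRecord

log = logging.getLogger(__name__)

DEFAULT_DELTA_CUT = 1.0
DEFAULT_Z_CUT = 7.0
DEFAULT_P_LEVEL = 1e-4


@dataclass(frozen=True)
class MotifScoreResult:
    """The four allele x strand scores with delta statistics for one SNP x motif."""

    snp_id: str
    pwm_name: str
    chrom: str
    pos: int
    ref: float
    ref_rev: float
    alt: float
    alt_rev: float
    delta: float
    delta_rev: float
    significant: bool
    ref_seq: str = ""
    alt_seq: str = ""

    @classmethod
    def from_scores(
        cls,
        snp_id: str,
        pwm_name: str,
        ref: float,
        ref_rev: float,
        alt: float,
        alt_rev: float,
        threshold: float,
        chrom: str = "",
        pos: int = 0,
        ref_seq: str = "",
        alt_seq: str = "",
    ) -> "MotifScoreResult":
        """Build a result from four clamped scores; deltas and the
        significance flag follow from them."""
        return cls(
            snp_id=snp_id,
            pwm_name=pwm_name,
            chrom=chrom,
            pos=pos,
            ref=ref,
            ref_rev=ref_rev,
            alt=alt,
            alt_rev=alt_rev,
            delta=ref - alt,
            delta_rev=ref_rev - alt_rev,
            significant=max(ref, alt, ref_rev, alt_rev) >= threshold,
            ref_seq=ref_seq,
            alt_seq=alt_seq,
        )


@dataclass(frozen=True)
class IntegratedHit:
    """A SNP x motif result joined to its nearest gene and that gene's Z."""

    result: MotifScoreResult
    gene: str
    distance: int
    z: float
    passes_delta: bool
    passes_z: bool


def _best_window_seq(pwm: PositionWeightMatrix, seq: str, plus, minus) -> str:
    """Forward-strand subsequence at the overall best-scoring window."""
    L = pwm.length
    if plus.raw_score >= minus.raw_score:
        start = plus.start_offset
    else:
        start = len(seq) - L - minus.start_offset  # map rc offset to forward coords
    return seq[start : start + L].upper()


def score_snp_motif(
    pair: AlleleWindowPair,
    pwm: PositionWeightMatrix,
    p_level: float = DEFAULT_P_LEVEL,
) -> MotifScoreResult:
    """Score both alleles of a SNP window on both strands.

    Only windows overlapping the SNP are eligible: the statistic measures
    SNP-dependent binding, not nearby constant sites.
    """
    ref_plus, ref_minus = best_strand_scores(pwm, pair.ref_seq, must_overlap=pair.snp_offset)
    alt_plus, alt_minus = best_strand_scores(pwm, pair.alt_seq, must_overlap=pair.snp_offset)
    return MotifScoreResult.from_scores(
        snp_id=pair.snp.id,
        pwm_name=pwm.name,
        chrom=pair.snp.chrom,
        pos=pair.snp.pos,
        ref=ref_plus.score,
        ref_rev=ref_minus.score,
        alt=alt_plus.score,
        alt_rev=alt_minus.score,
        threshold=pwm.threshold(p_level),
        ref_seq=_best_window_seq(pwm, pair.ref_seq, ref_plus, ref_minus),
        alt_seq=_best_window_seq(pwm, pair.alt_seq, alt_plus, alt_minus),
    )


def annotate_nearest_gene(
    chrom: str, pos: int, genes: pd.DataFrame
) -> tuple[str, int | None]:
    """Nearest gene symbol and distance in bp (0 when the position is inside).

    ``genes`` needs columns chrom, start, end, strand, symbol with 1-based
    inclusive start/end.  Ties resolve to the smaller distance, then the
    lexicographically smaller symbol.  No gene on the chromosome gives
    ("NA", None).
    """
    on_chrom = genes[genes["chrom"] == chrom]
    if on_chrom.empty:
        return "NA", None
    best: tuple[int, str] | None = None
    for start, end, symbol in zip(on_chrom["start"], on_chrom["end"], on_chrom["symbol"]):
        if start <= pos <= end:
            dist = 0
        elif pos < start:
            dist = int(start - pos)
        else:
            dist = int(pos - end)
        cand = (dist, str(symbol))
        if best is None or cand < best:
            best = cand
    return best[1], best[0]


def integrate(
    results: Iterable[MotifScoreResult],
    zmap: Mapping[str, float],
    genes: pd.DataFrame,
    delta_cut: float = DEFAULT_DELTA_CUT,
    z_cut: float = DEFAULT_Z_CUT,
) -> list[IntegratedHit]:
    """Filter SNP x motif results to the combined-impact hit list.

    A hit must be significant, have |delta| > delta_cut on either strand,
    and its nearest gene must have |Z| > z_cut.  Results whose nearest gene
    is missing from ``zmap`` are dropped with a log entry.  The report is
    sorted by (motif, chrom, pos, snp).
    """
    hits: list[IntegratedHit] = []
    for res in results:
        if not res.significant:
            continue
        passes_delta = abs(res.delta) > delta_cut or abs(res.delta_rev) > delta_cut
        if not passes_delta:
            continue
        gene, distance = annotate_nearest_gene(res.chrom, res.pos, genes)
        if distance is None:
            log.warning("%s x %s: no gene on chromosome %s, dropped", res.snp_id, res.pwm_name, res.chrom)
            continue
        if gene not in zmap or zmap[gene] is None:
            log.warning("%s x %s: nearest gene %s has no Z, dropped", res.snp_id, res.pwm_name, gene)
            continue
        z = float(zmap[gene])
        passes_z = abs(z) > z_cut
        if not passes_z:
            continue
        hits.append(
            IntegratedHit(
                result=res,
                gene=gene,
                distance=distance,
                z=z,
                passes_delta=passes_delta,
                passes_z=passes_z,
            )
        )
    hits.sort(key=lambda h: (h.result.pwm_name, h.result.chrom, h.result.pos, h.result.snp_id))
    return hits


def hits_to_frame(hits: Sequence[IntegratedHit], decimals: int | None = None) -> pd.DataFrame:
    """Tabular report in the published column layout.

    ``decimals`` rounds the score/delta/Z columns for display; ``None``
    keeps full precision (the machine-readable form).
    """
    rows = []
    for h in hits:
        r = h.result
        rows.append(
            {
                "pwm": r.pwm_name,
                "snp": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref.seq": r.ref_seq,
                "alt.seq": r.alt_seq,
                "delta": r.delta,
                "delta.rev": r.delta_rev,
                "ref": r.ref,
                "ref.rev": r.ref_rev,
                "alt": r.alt,
                "alt.rev": r.alt_rev,
                "gene": h.gene,
                "distance": h.distance,
                "Z": h.z,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pwm", "snp", "chrom", "pos", "ref.seq", "alt.seq",
            "delta", "delta.rev", "ref", "ref.rev", "alt", "alt.rev",
            "gene", "distance", "Z",
        ],
    )
    if decimals is not None and not df.empty:
        for col in ("delta", "delta.rev", "ref", "ref.rev", "alt", "alt.rev", "Z"):
            df[col] = df[col].round(decimals)
    return df
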