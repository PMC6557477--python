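"""Position weight matrix models and strand-resolved log-odds scanning.

A PWM here is a per-position, per-base table of log-odds weights over the
DNA alphabet A, C, G, T.  A window of sequence is scored additively; the
best window on each strand summarizes how well a region matches the motif.
Score-to-p-value thresholds (as published alongside curated motif
collections such as HOCOMOCO) turn raw scores into a significance call.

Scoring conventions:

* Reported best-window scores are clamped at 0; a negative best score means
  "no match" and prints as 0.00.  The unclamped value is kept on the
  :class:`StrandScore` for diagnostics.
* An ``N`` base contributes the minimum weight of its position
  (pessimistic, deterministic).
* Ties between equally scoring windows resolve to the smallest start
  offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PwmParseError(ValueError):
    """Raised when a motif-model or threshold file is malformed."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string over {A,C,G,T,N}.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if not seq:
        raise ValueError("cannot reverse-complement an empty sequence")
    _validate_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal DNA characters: {sorted(bad)}")


def _encode(seq: str) -> np.ndarray:
    _validate_alphabet(seq)
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


@dataclass
class PositionWeightMatrix:
    """Log-odds motif model with optional score->p-value thresholds.

    ``weights`` is an (L, 4) array in A, C, G, T column order.
    ``thresholds`` maps a p-value level to the minimum score reaching it;
    smaller p-values require larger scores (monotone).
    """

    name: str
    weights: np.ndarray
    thresholds: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError(f"{self.name}: weights must be (L, 4), got {self.weights.shape}")
        if self.weights.shape[0] < 1:
            raise ValueError(f"{self.name}: motif length must be >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"{self.name}: weights must be finite")
        levels = sorted(self.thresholds)
        for lo, hi in zip(levels, levels[1:]):
            if self.thresholds[lo] < self.thresholds[hi]:
                raise ValueError(
                    f"{self.name}: thresholds must be monotone (smaller p => larger score)"
                )

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])

    def threshold(self, p_level: float) -> float:
        try:
            return self.thresholds[p_level]
        except KeyError:
            raise KeyError(
                f"{self.name}: no score threshold for p-value level {p_level!r}"
            ) from None

    # minimum weight per position, used for N bases
    @property
    def _min_weights(self) -> np.ndarray:
        return self.weights.min(axis=1)


@dataclass(frozen=True)
class StrandScore:
    """Best-window score on one strand.

    ``score`` is clamped at 0 (no-match prints as 0.00); ``raw_score`` is
    the unclamped best-window score.  ``start_offset`` is the 0-based
    offset of the best window within the sequence that was scored (the
    reverse complement, for the minus strand).
    """

    score: float
    raw_score: float
    start_offset: int
    strand: str  # "+" or "-"


def parse_pwm(path: str | Path, thresholds_path: str | Path | None = None) -> PositionWeightMatrix:
    """Read a motif model in HOCOMOCO plain-text layout.

    Layout: a ``>NAME`` header line followed by L rows of 4 whitespace
    separated reals in A C G T order.  If ``thresholds_path`` is not given,
    a companion file ``<path>.thr`` is loaded when present.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise PwmParseError(f"{path}: expected '>NAME' header on line 1")
    name = lines[0][1:].strip()
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != 4:
            raise PwmParseError(f"{path}: line {i}: expected 4 columns, got {len(parts)}")
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            raise PwmParseError(f"{path}: line {i}: non-numeric weight") from None
    if not rows:
        raise PwmParseError(f"{path}: no weight rows")

    if thresholds_path is None:
        companion = path.with_name(path.name + ".thr")
        thresholds = parse_threshold_table(companion) if companion.exists() else {}
    else:
        thresholds = parse_threshold_table(thresholds_path)
    return PositionWeightMatrix(name=name, weights=np.array(rows), thresholds=thresholds)


def parse_threshold_table(path: str | Path) -> dict[float, float]:
    """Read a 2-column TSV mapping p-value level to minimum score."""
    path = Path(path)
    thresholds: dict[float, float] = {}
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise PwmParseError(f"{path}: line {i}: expected 2 columns (p_level, score)")
        try:
            p, s = float(parts[0]), float(parts[1])
        except ValueError:
            raise PwmParseError(f"{path}: line {i}: non-numeric entry") from None
        thresholds[p] = s
    return thresholds


def write_pwm(pwm: PositionWeightMatrix, path: str | Path, decimals: int = 6) -> None:
    """Write a motif model back in HOCOMOCO plain-text layout.

    ``parse_pwm(write_pwm(p))`` round-trips within the float formatting.
    A companion ``<path>.thr`` table is written when thresholds exist.
    """
    path = Path(path)
    out = [f">{pwm.name}"]
    for row in pwm.weights:
        out.append("\t".join(f"{w:.{decimals}f}" for w in row))
    path.write_text("\n".join(out) + "\n")
    if pwm.thresholds:
        thr = path.with_name(path.name + ".thr")
        lines = [f"{p:g}\t{s:.{decimals}f}" for p, s in sorted(pwm.thresholds.items())]
        thr.write_text("\n".join(lines) + "\n")


def score_window(pwm: PositionWeightMatrix, seq: str) -> float:
    """Score one window of length exactly L: sum of per-position weights."""
    if len(seq) != pwm.length:
        raise ValueError(
            f"{pwm.name}: window length {len(seq)} != motif length {pwm.length}"
        )
    idx = _encode(seq.upper())
    # append the per-position minimum as a 5th column for N lookups
    table = np.concatenate([pwm.weights, pwm._min_weights[:, None]], axis=1)
    return float(table[np.arange(pwm.length), idx].sum())


def _window_scores(pwm: PositionWeightMatrix, idx: np.ndarray) -> np.ndarray:
    """Scores of every L-window of an encoded sequence (vectorized)."""
    L = pwm.length
    n = idx.size - L + 1
    table = np.concatenate([pwm.weights, pwm._min_weights[:, None]], axis=1)
    scores = np.zeros(n)
    for i in range(L):
        scores += table[i][idx[i : i + n]]
    return scores


def _best(scores: np.ndarray, eligible: np.ndarray | None = None) -> tuple[float, int]:
    if eligible is not None:
        masked = np.full_like(scores, -math.inf)
        masked[eligible] = scores[eligible]
        scores = masked
    off = int(np.argmax(scores))  # argmax takes the first maximum: smallest offset
    return float(scores[off]), off


def best_strand_scores(
    pwm: PositionWeightMatrix,
    seq: str,
    must_overlap: int | None = None,
) -> tuple[StrandScore, StrandScore]:
    """Best-window scores on the plus strand and on the reverse complement.

    When ``must_overlap`` is given (a 0-based offset into ``seq``), only
    windows covering that position are eligible on either strand — this is
    how SNP-dependent scores are restricted to windows the variant can
    actually change.
    """
    seq = seq.upper()
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"{pwm.name}: sequence length {len(seq)} < motif length {L}")
    n = len(seq) - L + 1

    def eligible_for(offset: int) -> np.ndarray:
        lo = max(0, offset - L + 1)
        hi = min(n - 1, offset)
        if hi < lo:
            raise ValueError(f"no window of length {L} overlaps offset {offset}")
        mask = np.zeros(n, dtype=bool)
        mask[lo : hi + 1] = True
        return mask

    idx_fwd = _encode(seq)
    raw_fwd, off_fwd = _best(
        _window_scores(pwm, idx_fwd),
        eligible_for(must_overlap) if must_overlap is not None else None,
    )

    rc = reverse_complement(seq)
    idx_rev = _encode(rc)
    overlap_rev = len(seq) - 1 - must_overlap if must_overlap is not None else None
    raw_rev, off_rev = _best(
        _window_scores(pwm, idx_rev),
        eligible_for(overlap_rev) if overlap_rev is not None else None,
    )

    plus = StrandScore(score=max(0.0, raw_fwd), raw_score=raw_fwd, start_offset=off_fwd, strand="+")
    minus = StrandScore(score=max(0.0, raw_rev), raw_score=raw_rev, start_offset=off_rev, strand="-")
    return plus, minus


def count_sites(pwm: PositionWeightMatrix, seq: str, min_score: float) -> int:
    """Number of window start positions (both strands) scoring >= min_score.

    Each start position on each strand counts once; overlapping matches at
    different offsets each count.
    """
    seq = seq.upper()
    if len(seq) < pwm.length:
        return 0
    total = 0
    for s in (seq, reverse_complement(seq)):
        total += int(np.sum(_window_scores(pwm, _encode(s)) >= min_score))
    return total
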