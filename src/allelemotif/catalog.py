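"""Catalog of the 62 exposure-dysregulated sperm RNAs and its summaries.

The shipped fixture transcribes the published characterization of the 62
RNAs most differentially expressed across the strain x treatment
conditions: the expression-change pattern each gene belongs to
(DEHP-resistance, DEHP-susceptibility, or generational), the tissue it is
expressed in, its germ-cell stage expression triple (spermatogonia,
spermatocytes, spermatids, on a log scale from an independent microarray
study), the printed increasing-in-spermatogenesis label, and the verbatim
hormonal-regulation annotation.

The free-text hormonal annotations are mapped onto five hormone classes
(androgen, glucocorticoid, ppar, t3, estrogen) or none; the mapping for
each non-literal annotation is recorded in :data:`HORMONE_CLASS_MAP` /
:data:`NON_HORMONAL_ANNOTATIONS` and is the unique mapping consistent with
the published totals (47 hormonally regulated, 25 androgen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

PATTERNS = ("DEHP-resistance", "DEHP-susceptibility", "generational")
HORMONE_CLASSES = ("androgen", "glucocorticoid", "ppar", "t3", "estrogen", "none")

# verbatim annotation (lower-cased) -> hormone class
HORMONE_CLASS_MAP: Mapping[str, str] = {
    "androgen": "androgen",
    "androgen regulator": "androgen",
    "regulator of androgens activity": "androgen",
    "testosterone hydroxylation": "androgen",
    "glucocorticoid": "glucocorticoid",
    "ppar": "ppar",
    "t3-thyroid hormone": "t3",
    "estrogen": "estrogen",
}

# annotations that do not name a specific regulating hormone
NON_HORMONAL_ANNOTATIONS = frozenset(
    {
        "?",
        "-",
        "hormone",
        "taurine-regulated",
        "peptide hormone",
        "immuno-regulation",
        "regulator of sex hormones",
        "regulator of lipids hormones",
        "h-response enhancer",
        "regulated by cis-acting elements",
    }
)


def hormone_class(annotation: str) -> str:
    """Map a verbatim hormonal-regulation annotation onto a hormone class."""
    key = annotation.strip().lower()
    if key in HORMONE_CLASS_MAP:
        return HORMONE_CLASS_MAP[key]
    if key in NON_HORMONAL_ANNOTATIONS:
        return "none"
    raise ValueError(f"unrecognized hormonal-regulation annotation: {annotation!r}")


def classify_spermatogenesis_trend(
    triple: tuple[float | None, float | None, float | None],
) -> str:
    """Label a stage-expression triple as increasing through spermatogenesis.

    'yes' iff spermatogonia < spermatocytes < spermatids strictly; 'NA'
    when any stage value is missing; otherwise 'no'.  The strict rule
    reproduces every printed label in the fixture (a 0.01 dip counts as
    'no').
    """
    sg, sc, st = triple
    for v in (sg, sc, st):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "NA"
    return "yes" if sg < sc < st else "no"


def load_targets() -> pd.DataFrame:
    """Load the transcribed 62-gene catalog fixture.

    Adds a ``hormone_class`` column from the verbatim annotation and a
    ``trend`` column recomputed from the stage triple.
    """
    with resources.files("allelemotif.data").joinpath("table1_targets.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"gene": str})
    # stage columns use NaN for missing values; the printed label keeps
    # the literal string "NA"
    df["trend_label"] = df["trend_label"].fillna("NA")
    df["hormone_class"] = df["hormone_annotation"].map(hormone_class)
    df["trend"] = [
        classify_spermatogenesis_trend((sg, sc, st))
        for sg, sc, st in zip(df["spermatogonia"], df["spermatocytes"], df["spermatids"])
    ]
    return df


@dataclass(frozen=True)
class TargetAnnotation:
    """One catalog row."""

    gene_symbol: str
    pattern: str
    tissue: str
    hormone_class: str
    stage_expression: tuple[float | None, float | None, float | None]
    spermatogenesis_increase_label: str


@dataclass(frozen=True)
class CatalogSummary:
    n_total: int
    n_hormonal: int
    class_counts: dict[str, int]
    n_androgen: int
    n_yes: int
    n_no: int
    n_na: int
    percent_increasing: int


def catalog_summaries(targets: pd.DataFrame | None = None) -> CatalogSummary:
    """Headline tallies of the catalog.

    ``percent_increasing`` is rounded over the classifiable rows only
    (rows with stage data), matching the published 80%.
    Raises on duplicate gene symbols.
    """
    df = load_targets() if targets is None else targets
    if df["gene"].duplicated().any():
        dupes = sorted(df.loc[df["gene"].duplicated(), "gene"])
        raise ValueError(f"duplicate gene symbols in catalog: {dupes}")
    class_counts = df["hormone_class"].value_counts().to_dict()
    n_hormonal = int(sum(v for k, v in class_counts.items() if k != "none"))
    trend = df["trend"].value_counts().to_dict()
    n_yes, n_no = int(trend.get("yes", 0)), int(trend.get("no", 0))
    classifiable = n_yes + n_no
    return CatalogSummary(
        n_total=int(len(df)),
        n_hormonal=n_hormonal,
        class_counts={k: int(v) for k, v in class_counts.items()},
        n_androgen=int(class_counts.get("androgen", 0)),
        n_yes=n_yes,
        n_no=n_no,
        n_na=int(trend.get("NA", 0)),
        percent_increasing=round(100 * n_yes / classifiable) if classifiable else 0,
    )


def load_table2_reference() -> pd.DataFrame:
    """The transcribed published SNP x motif score table (8 rows).

    Carries the printed per-allele scores, deltas, nearest genes and the
    p < 0.0001 score thresholds of the five motif models.
    """
    with resources.files("allelemotif.data").joinpath("table2_snp_motifs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
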