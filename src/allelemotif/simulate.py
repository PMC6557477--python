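"""Fully in-silico datasets with planted SNP -> motif -> expression structure.

The generator emulates the study design at toy scale: a small random
genome, a catalogue of strain-difference SNPs, sharply informative
synthetic motif models, condition-level FPKM tables for the four
strain x treatment conditions, and a per-promoter methylation count table.
A configurable number of *planted interactions* wire the stages together:

* ``create_site`` — the alternative-strain allele completes a consensus
  motif the reference allele lacks (delta strongly negative) and the
  nearby target gene is induced by treatment in the alternative strain
  (resistance-like);
* ``destroy_site`` — the reference allele carries a consensus motif the
  alternative allele breaks (delta strongly positive) and the target gene
  is repressed by treatment in the reference strain (susceptibility-like).

Both regimes plant Z > 0, as in the real hit set.  Everything else is
null: uniform background sequence, SNPs that touch no motif, and
log-normal FPKM noise.  A truth manifest records every planted
interaction so recovery can be scored exactly.  All randomness flows from
the single seeded generator; identical configs produce byte-identical
bundles.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import C57_CONTROL, C57_TREATED, FVB_CONTROL, FVB_TREATED, Z_CONDITIONS
from .interaction import IntegratedHit
from .pwm import PositionWeightMatrix, write_pwm

EFFECTS = ("create_site", "destroy_site")

# default synthetic motif consensi (names carry a SYN marker: these are
# synthetic stand-ins built for the simulator, not curated models)
DEFAULT_CONSENSI: Mapping[str, str] = {
    "FOXA_SYN": "TGTTTACACA",
    "AR_SYN": "AGAACAGGGTGT",
}


def make_synthetic_pwm(
    name: str,
    consensus: str,
    match_weight: float = 2.0,
    mismatch_weight: float = -6.0,
) -> PositionWeightMatrix:
    """A sharply informative synthetic motif: consensus base scores
    ``match_weight`` per position, any other base ``mismatch_weight``.

    Thresholds are placed halfway between the k- and (k+1)-mismatch score
    levels: p<0.0001 admits only the exact consensus, p<0.001 also one
    mismatch.
    """
    L = len(consensus)
    gap = match_weight - mismatch_weight
    weights = np.full((L, 4), mismatch_weight)
    for i, base in enumerate(consensus):
        weights[i, "ACGT".index(base)] = match_weight
    perfect = L * match_weight
    thresholds = {1e-4: perfect - gap / 2, 1e-3: perfect - 1.5 * gap}
    return PositionWeightMatrix(name=name, weights=weights, thresholds=thresholds)


@dataclass(frozen=True)
class PlantedInteraction:
    """One SNP -> motif -> gene effect to plant."""

    pwm_name: str
    effect: str  # create_site | destroy_site
    target_gene: str
    z_effect: float  # planted |Z|, > 0; sign of Z is + in both regimes

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"effect must be one of {EFFECTS}, got {self.effect!r}")
        if self.z_effect <= 0:
            raise ValueError("z_effect must be positive (planted |Z|)")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 60_000
    n_null_snps: int = 500
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    n_genes: int = 60
    fpkm_noise_sd: float = 0.5  # log2 scale
    meth_baseline: float = 2.0  # reads per CpG
    meth_silencing_shift: float = 2.0
    gene_length_bp: int = 1_000
    target_gene_distance_bp: int = 2_000
    annotation_limit_bp: int = 10_000
    # planted targets emulate abundant transcripts (log2 FPKM mean/sd); a
    # repression of 2^-z only registers as |Z| ~ z when baseline expression
    # is well above the pseudocount
    target_fpkm_log2_mean: float = 6.5
    target_fpkm_log2_sd: float = 0.5
    pwm_consensi: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONSENSI)
    )

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_genes) <= 0:
            raise ValueError("chromosome/gene counts must be positive")
        if self.n_null_snps < 0:
            raise ValueError("n_null_snps must be >= 0")
        if self.target_gene_distance_bp > self.annotation_limit_bp:
            raise ValueError(
                "planted target genes would lie beyond the annotation search limit"
            )
        for p in self.planted_interactions:
            if p.pwm_name not in self.pwm_consensi:
                raise ValueError(f"planted interaction references unknown motif {p.pwm_name!r}")


def benchmark_config(seed: int = 7, n_null_snps: int = 500) -> SimulationConfig:
    """The standard planted benchmark: 5 interactions against a null background.

    Planted effects are large and unambiguous (|delta| >= 8 score units,
    planted Z = 10) so that recovery at the working thresholds
    (|delta| > 1, |Z| > 7) measures pipeline correctness, not luck.
    """
    planted = (
        PlantedInteraction("FOXA_SYN", "create_site", "DefbSim1", 10.0),
        PlantedInteraction("FOXA_SYN", "create_site", "DefbSim2", 10.0),
        PlantedInteraction("AR_SYN", "destroy_site", "SvsSim1", 10.0),
        PlantedInteraction("AR_SYN", "destroy_site", "SvsSim2", 10.0),
        PlantedInteraction("FOXA_SYN", "destroy_site", "SvsSim3", 10.0),
    )
    return SimulationConfig(seed=seed, n_null_snps=n_null_snps, planted_interactions=planted)


@dataclass(frozen=True)
class TruthManifest:
    """One row per planted interaction, plus the bundle identity."""

    table: pd.DataFrame
    bundle_id: str

    @property
    def n_planted(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class SimulatedBundle:
    out_dir: Path
    genome_path: Path
    vcf_path: Path
    genes_path: Path
    pwm_dir: Path
    fpkm_path: Path
    methylation_path: Path
    truth_path: Path
    truth: TruthManifest
    config: SimulationConfig


def _bundle_id(cfg: SimulationConfig) -> str:
    digest = hashlib.sha1(repr(cfg).encode()).hexdigest()[:8]
    return f"seed{cfg.seed}-{digest}"


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(len(choices)))]


def simulate_dataset(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedBundle:
    """Generate and write a complete synthetic bundle.

    Files written: ``genome.fa``, ``snps.vcf``, ``genes.tsv``,
    ``pwms/<name>.pwm`` (+ ``.thr`` threshold tables), ``fpkm.tsv``,
    ``methylation.tsv`` and ``truth.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    pwms = {name: make_synthetic_pwm(name, cons) for name, cons in cfg.pwm_consensi.items()}
    max_L = max((p.length for p in pwms.values()), default=10)

    genome = {
        c: rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=cfg.chrom_length_bp).astype("U1")
        for c in chroms
    }

    # ---- planted sites, SNPs and target genes ----------------------------
    margin = max(5_000, cfg.annotation_limit_bp // 2)
    n_planted = len(cfg.planted_interactions)
    per_chrom = max(1, math.ceil(n_planted / cfg.n_chromosomes))
    span = cfg.chrom_length_bp - 2 * margin - cfg.target_gene_distance_bp - cfg.gene_length_bp
    if n_planted and span < per_chrom * 2 * cfg.annotation_limit_bp:
        raise ValueError("chromosomes too short for the requested planted layout")
    spacing = span // per_chrom if n_planted else 0

    snps: list[dict] = []
    planted_rows: list[dict] = []
    gene_rows: list[dict] = []
    exclusions: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    for i, planted in enumerate(cfg.planted_interactions):
        chrom = chroms[i % cfg.n_chromosomes]
        slot = i // cfg.n_chromosomes
        pwm = pwms[planted.pwm_name]
        consensus = cfg.pwm_consensi[planted.pwm_name]
        L = pwm.length
        site_start = margin + slot * spacing
        j = L // 2
        snp_pos0 = site_start + j
        cons_base = consensus[j]
        other = _other_base(rng, cons_base)

        site_seq = list(consensus)
        if planted.effect == "destroy_site":
            ref_allele, alt_allele, sign = cons_base, other, +1
        else:  # create_site: genome (reference) carries the broken site
            site_seq[j] = other
            ref_allele, alt_allele, sign = other, cons_base, -1
        genome[chrom][site_start : site_start + L] = list("".join(site_seq))

        snp_id = f"splant{i + 1}"
        snps.append(
            dict(id=snp_id, chrom=chrom, pos=snp_pos0 + 1, ref=ref_allele, alt=alt_allele)
        )
        gene_start = snp_pos0 + 1 + cfg.target_gene_distance_bp
        gene_rows.append(
            dict(
                chrom=chrom,
                start=gene_start,
                end=gene_start + cfg.gene_length_bp - 1,
                strand="+",
                symbol=planted.target_gene,
            )
        )
        planted_rows.append(
            dict(
                snp_id=snp_id,
                chrom=chrom,
                pos=snp_pos0 + 1,
                pwm=planted.pwm_name,
                effect=planted.effect,
                expected_delta_sign=sign,
                target_gene=planted.target_gene,
                planted_z=planted.z_effect,
            )
        )
        # keep null SNPs and null genes away from the planted neighborhood
        exclusions[chrom].append(
            (site_start - 2 * max_L, gene_start + cfg.gene_length_bp + 2 * max_L)
        )

    # ---- null genes on a deterministic grid ------------------------------
    # the grid over-provisions slots so that slots lost to planted
    # neighborhoods still leave room for n_genes placements
    gene_margin = 2_000
    per_chrom_capacity = math.ceil(cfg.n_genes / cfg.n_chromosomes) + max(4, 3 * n_planted)
    gstep = (cfg.chrom_length_bp - 2 * gene_margin) // per_chrom_capacity
    if gstep <= cfg.gene_length_bp:
        raise ValueError("chromosomes too short for the requested gene density")
    placed = 0
    g = 0
    while placed < cfg.n_genes:
        chrom = chroms[g % cfg.n_chromosomes]
        slot = g // cfg.n_chromosomes
        g += 1
        if slot >= per_chrom_capacity:
            raise ValueError("not enough room to place the requested null genes")
        start = gene_margin + slot * gstep
        end = start + cfg.gene_length_bp - 1
        if any(start - 2_000 < hi and end + 2_000 > lo for lo, hi in exclusions[chrom]):
            continue
        placed += 1
        gene_rows.append(
            dict(chrom=chrom, start=start, end=end, strand="+" if placed % 2 else "-",
                 symbol=f"G{placed:04d}")
        )

    # ---- null SNPs --------------------------------------------------------
    taken = {(s["chrom"], s["pos"]) for s in snps}
    n_null = 0
    while n_null < cfg.n_null_snps:
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        pos0 = int(rng.integers(max_L, cfg.chrom_length_bp - max_L))
        if any(lo <= pos0 <= hi for lo, hi in exclusions[chrom]):
            continue
        if (chrom, pos0 + 1) in taken:
            continue
        taken.add((chrom, pos0 + 1))
        n_null += 1
        ref = str(genome[chrom][pos0])
        snps.append(
            dict(id=f"snull{n_null:05d}", chrom=chrom, pos=pos0 + 1, ref=ref,
                 alt=_other_base(rng, ref))
        )

    # ---- expression tables -----------------------------------------------
    genes_df = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "symbol"])
    genes_df = genes_df.sort_values(["chrom", "start", "symbol"]).reset_index(drop=True)
    symbols = list(genes_df["symbol"])
    baseline = 2.0 ** rng.normal(4.5, 1.0, size=len(symbols))
    target_symbols = {row["target_gene"] for row in planted_rows}
    for k, sym in enumerate(symbols):
        if sym in target_symbols:
            baseline[k] = 2.0 ** rng.normal(
                cfg.target_fpkm_log2_mean, cfg.target_fpkm_log2_sd
            )
    fpkm = pd.DataFrame(index=pd.Index(symbols, name="gene"))
    for cond in Z_CONDITIONS:
        fpkm[cond] = baseline * 2.0 ** rng.normal(0.0, cfg.fpkm_noise_sd, size=len(symbols))
    for row in planted_rows:
        gene = row["target_gene"]
        if row["effect"] == "create_site":  # induced by treatment in the alt strain
            fpkm.loc[gene, FVB_TREATED] = fpkm.loc[gene, FVB_CONTROL] * 2.0 ** row["planted_z"]
        else:  # repressed by treatment in the reference strain
            fpkm.loc[gene, C57_TREATED] = fpkm.loc[gene, C57_CONTROL] * 2.0 ** -row["planted_z"]
    fpkm = fpkm[list(Z_CONDITIONS)].round(4)

    # ---- promoter methylation counts --------------------------------------
    # level anti-correlates with expression across genes (silencing trend);
    # silenced/induced targets additionally gain promoter methylation in the
    # affected strain's treated condition
    cpg = rng.integers(15, 40, size=len(symbols))
    meth = pd.DataFrame(index=pd.Index(symbols, name="gene"))
    meth["cpg_count"] = cpg
    shifts = {
        row["target_gene"]: (C57_TREATED if row["effect"] == "destroy_site" else FVB_TREATED)
        for row in planted_rows
    }
    for cond in Z_CONDITIONS:
        log_expr = np.log2(fpkm[cond].to_numpy() + 0.1)
        level = cfg.meth_baseline - 0.35 * (log_expr - 4.5) + rng.normal(0, 0.2, len(symbols))
        level = np.clip(level, 0.05, None)
        for k, gene in enumerate(symbols):
            if shifts.get(gene) == cond:
                level[k] += cfg.meth_silencing_shift
        meth[cond] = np.rint(level * cpg).astype(int)

    # ---- write the bundle --------------------------------------------------
    genome_path = out_dir / "genome.fa"
    with genome_path.open("w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = "".join(genome[c])
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")

    vcf_path = out_dir / "snps.vcf"
    chrom_order = {c: i for i, c in enumerate(chroms)}
    snps.sort(key=lambda s: (chrom_order[s["chrom"]], s["pos"]))
    with vcf_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={cfg.chrom_length_bp}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(f"{s['chrom']}\t{s['pos']}\t{s['id']}\t{s['ref']}\t{s['alt']}\t60\tPASS\t.\n")

    genes_path = out_dir / "genes.tsv"
    genes_df.to_csv(genes_path, sep="\t", index=False)

    pwm_dir = out_dir / "pwms"
    pwm_dir.mkdir(exist_ok=True)
    for name in sorted(pwms):
        write_pwm(pwms[name], pwm_dir / f"{name}.pwm")

    fpkm_path = out_dir / "fpkm.tsv"
    fpkm.to_csv(fpkm_path, sep="\t")
    methylation_path = out_dir / "methylation.tsv"
    meth.to_csv(methylation_path, sep="\t")

    truth_df = pd.DataFrame(
        planted_rows,
        columns=["snp_id", "chrom", "pos", "pwm", "effect", "expected_delta_sign",
                 "target_gene", "planted_z"],
    )
    bundle_id = _bundle_id(cfg)
    truth_path = out_dir / "truth.tsv"
    with truth_path.open("w") as fh:
        fh.write(f"#bundle_id={bundle_id}\n")
        truth_df.to_csv(fh, sep="\t", index=False)

    return SimulatedBundle(
        out_dir=out_dir,
        genome_path=genome_path,
        vcf_path=vcf_path,
        genes_path=genes_path,
        pwm_dir=pwm_dir,
        fpkm_path=fpkm_path,
        methylation_path=methylation_path,
        truth_path=truth_path,
        truth=TruthManifest(table=truth_df, bundle_id=bundle_id),
        config=cfg,
    )


def load_truth(path: str | Path) -> TruthManifest:
    """Read a truth manifest written by :func:`simulate_dataset`."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("#bundle_id="):
            raise ValueError(f"{path}: missing #bundle_id header")
        bundle_id = first.split("=", 1)[1]
        table = pd.read_csv(fh, sep="\t")
    return TruthManifest(table=table, bundle_id=bundle_id)


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float | None  # None when nothing was planted
    false_positives: int
    sign_concordance: float | None


def evaluate_recovery(
    hits: Sequence[IntegratedHit],
    truth: TruthManifest,
    bundle_id: str | None = None,
) -> RecoveryReport:
    """Score pipeline hits against a truth manifest.

    ``bundle_id``, when supplied, must match the manifest's (guards against
    crossing bundles).  A planted interaction is recovered when some hit
    matches its (snp_id, pwm); sign concordance uses the strand with the
    larger |delta|.
    """
    if bundle_id is not None and bundle_id != truth.bundle_id:
        raise ValueError(f"bundle mismatch: {bundle_id} vs manifest {truth.bundle_id}")
    expected = {
        (r.snp_id, r.pwm): int(r.expected_delta_sign) for r in truth.table.itertuples()
    }
    recovered: dict[tuple[str, str], bool] = {}
    false_positives = 0
    for h in hits:
        key = (h.result.snp_id, h.result.pwm_name)
        if key not in expected:
            false_positives += 1
            continue
        d = h.result.delta if abs(h.result.delta) >= abs(h.result.delta_rev) else h.result.delta_rev
        recovered[key] = math.copysign(1, d) == expected[key]
    if not expected:
        return RecoveryReport(None, false_positives, None)
    sens = len(recovered) / len(expected)
    concordance = (
        sum(recovered.values()) / len(recovered) if recovered else None
    )
    return RecoveryReport(sens, false_positives, concordance)


def null_config(cfg: SimulationConfig | None = None, seed: int = 0) -> SimulationConfig:
    """A copy of ``cfg`` (default: benchmark sizes) with nothing planted."""
    base = cfg if cfg is not None else benchmark_config()
    return replace(base, seed=seed, planted_interactions=())
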