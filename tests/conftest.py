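"""Shared fixtures: toy motifs, toy genomes, and the planted benchmark bundle."""

from __future__ import annotations

import numpy as np
import pyfaidx
import pytest

from allelemotif.pipeline import PipelineConfig, run_scan
from allelemotif.pwm import PositionWeightMatrix
from allelemotif.simulate import benchmark_config, simulate_dataset

# ---------------------------------------------------------------------------
# independent naive scoring oracle (pure python, no shared code paths with
# allelemotif.pwm beyond the weight convention)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_score(weights: list[dict[str, float]], window: str) -> float:
    total = 0.0
    for i, base in enumerate(window):
        total += min(weights[i].values()) if base == "N" else weights[i][base]
    return total


def naive_best(weights: list[dict[str, float]], seq: str) -> tuple[float, int]:
    """Best raw window score and smallest best offset on one strand."""
    L = len(weights)
    best, best_off = None, None
    for off in range(len(seq) - L + 1):
        s = naive_score(weights, seq[off : off + L])
        if best is None or s > best:
            best, best_off = s, off
    return best, best_off


def weights_as_dicts(pwm: PositionWeightMatrix) -> list[dict[str, float]]:
    return [dict(zip("ACGT", row)) for row in pwm.weights]


def random_pwm(rng: np.random.Generator, length: int, name: str = "RND") -> PositionWeightMatrix:
    return PositionWeightMatrix(name=name, weights=rng.normal(0, 2, size=(length, 4)))


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------


@pytest.fixture
def toy_dimer_pwm() -> PositionWeightMatrix:
    """2-position matrix w=[[1,0,0,0],[0,0,0,2]]: scores A at pos 1, T at pos 2."""
    return PositionWeightMatrix(name="TOY2", weights=[[1, 0, 0, 0], [0, 0, 0, 2]])


@pytest.fixture
def toy_genome(tmp_path):
    """A fixed 60 bp single-chromosome genome as an indexed FASTA."""
    seq = "ACGTACGTACGTTTTTGCACAACGTACGTACGTACGTACGTGGGGCCCCAAAATTTTGC"
    assert len(seq) == 59
    seq += "A"
    fa = tmp_path / "toy.fa"
    fa.write_text(">chrT\n" + seq + "\n")
    return pyfaidx.Fasta(str(fa)), seq


@pytest.fixture(scope="session")
def bench_bundle(tmp_path_factory):
    """The standard planted benchmark: 5 interactions vs 500 null SNPs, seed 7."""
    out = tmp_path_factory.mktemp("bench")
    return simulate_dataset(benchmark_config(seed=7, n_null_snps=500), out)


@pytest.fixture(scope="session")
def bench_scan(bench_bundle):
    """Full pipeline run over the benchmark bundle."""
    cfg = PipelineConfig(
        genome=bench_bundle.genome_path,
        vcf=bench_bundle.vcf_path,
        pwm_dir=bench_bundle.pwm_dir,
        genes=bench_bundle.genes_path,
        fpkm=bench_bundle.fpkm_path,
    )
    return run_scan(cfg)
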