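"""Delta statistics, nearest-gene annotation and hit integration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allelemotif.catalog import load_table2_reference
from allelemotif.interaction import (
    MotifScoreResult,
    annotate_nearest_gene,
    hits_to_frame,
    integrate,
    score_snp_motif,
)
from allelemotif.pwm import PositionWeightMatrix
from allelemotif.variants import AlleleWindowPair, SnpRecord

from conftest import random_pwm, random_seq


def make_pair(ref_seq: str, alt_seq: str, snp_offset: int, snp_id: str = "s1"):
    snp = SnpRecord(
        id=snp_id, chrom="chr1", pos=100 + snp_offset,
        ref_allele=ref_seq[snp_offset], alt_allele=alt_seq[snp_offset],
    )
    return AlleleWindowPair(
        snp=snp, window_start=99, window_end=99 + len(ref_seq),
        ref_seq=ref_seq, alt_seq=alt_seq, snp_offset=snp_offset,
    )


class TestFromScores:
    def test_published_rows_delta_follows_ref_minus_alt(self):
        # every transcribed row: delta recomputed from the printed
        # per-allele scores agrees with the printed delta (0.01 rounding)
        table = load_table2_reference()
        for row in table.itertuples():
            res = MotifScoreResult.from_scores(
                snp_id=row.snp, pwm_name=row.pwm,
                ref=row.ref, ref_rev=getattr(row, "ref_rev"),
                alt=row.alt, alt_rev=getattr(row, "alt_rev"),
                threshold=row.threshold_p0001,
            )
            assert res.delta == pytest.approx(row.delta, abs=0.015)
            assert res.delta_rev == pytest.approx(getattr(row, "delta_rev"), abs=0.015)
            # each published row reaches its motif's p<0.0001 threshold
            # through at least one of the four allele x strand scores
            assert res.significant

    def test_significance_requires_any_score_at_threshold(self):
        below = MotifScoreResult.from_scores("s", "m", 5.0, 4.0, 3.0, 2.0, threshold=8.0)
        assert not below.significant
        alt_only = MotifScoreResult.from_scores("s", "m", 0.0, 0.0, 8.5, 0.0, threshold=8.0)
        assert alt_only.significant


class TestScoreSnpMotif:
    def test_strain_swap_negates_delta(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            L = int(rng.integers(2, 9))
            pwm = random_pwm(rng, L)
            pwm.thresholds[1e-4] = 100.0
            seq = random_seq(rng, 2 * L)
            off = L - 1
            alt_base = "A" if seq[off] != "A" else "G"
            alt = seq[:off] + alt_base + seq[off + 1 :]
            fwd = score_snp_motif(make_pair(seq, alt, off), pwm)
            rev = score_snp_motif(make_pair(alt, seq, off), pwm)
            assert rev.delta == pytest.approx(-fwd.delta, abs=1e-9)
            assert rev.delta_rev == pytest.approx(-fwd.delta_rev, abs=1e-9)

    def test_only_snp_overlapping_windows_are_scored(self):
        # a strong consensus placed beyond the SNP-overlapping windows
        # must not contribute to either allele's score
        weights = np.full((4, 4), -5.0)
        for i, b in enumerate("ACGT"):
            weights[i, "ACGT".index(b)] = 2.0
        pwm = PositionWeightMatrix(name="C", weights=weights, thresholds={1e-4: 7.0})
        # window 2L = 8 with SNP at offset 3; window starting at 4 holds
        # the consensus but does not overlap the SNP
        ref = "TTTT" + "ACGT"
        alt = "TTTG" + "ACGT"
        res = score_snp_motif(make_pair(ref, alt, 3), pwm)
        assert max(res.ref, res.alt, res.ref_rev, res.alt_rev) < 8.0

    def test_disrupting_a_site_gives_positive_delta(self):
        weights = np.full((4, 4), -5.0)
        for i, b in enumerate("ACGT"):
            weights[i, "ACGT".index(b)] = 2.0
        pwm = PositionWeightMatrix(name="C", weights=weights, thresholds={1e-4: 7.0})
        ref = "TTACGTTT"  # consensus at offset 2..5, SNP at offset 3
        alt = "TTAGGTTT"
        res = score_snp_motif(make_pair(ref, alt, 3), pwm)
        assert res.ref == pytest.approx(8.0)
        assert res.alt < 8.0
        assert res.delta > 0
        assert res.significant
        assert res.ref_seq == "ACGT"


GENES = pd.DataFrame(
    {
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "start": [100, 1000, 5000, 50],
        "end": [200, 2000, 6000, 99],
        "strand": ["+", "-", "+", "+"],
        "symbol": ["Svs4", "Aaa", "Bbb", "Ccc"],
    }
)


class TestNearestGene:
    def test_inside_gene_distance_zero(self):
        assert annotate_nearest_gene("chr1", 150, GENES) == ("Svs4", 0)

    def test_one_bp_past_gene_end(self):
        assert annotate_nearest_gene("chr1", 201, GENES) == ("Svs4", 1)

    def test_nearest_boundary_wins(self):
        gene, dist = annotate_nearest_gene("chr1", 2600, GENES)
        assert (gene, dist) == ("Aaa", 600)

    def test_tie_resolves_lexicographically(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 300],
                "end": [150, 400],
                "strand": ["+", "+"],
                "symbol": ["Zzz", "Aaa"],
            }
        )
        # position 225: 75 bp from both Zzz end (150) and Aaa start (300)
        assert annotate_nearest_gene("chr1", 225, genes) == ("Aaa", 75)

    def test_no_gene_on_chromosome(self):
        assert annotate_nearest_gene("chrX", 100, GENES) == ("NA", None)


def result(snp_id, pwm, delta, delta_rev, significant, chrom="chr1", pos=150):
    ref = max(delta, 0.0) + 9.0
    return MotifScoreResult(
        snp_id=snp_id, pwm_name=pwm, chrom=chrom, pos=pos,
        ref=ref, ref_rev=max(delta_rev, 0.0) + 9.0, alt=ref - delta,
        alt_rev=max(delta_rev, 0.0) + 9.0 - delta_rev,
        delta=delta, delta_rev=delta_rev, significant=significant,
    )


class TestIntegrate:
    ZMAP = {"Svs4": 9.5, "Aaa": -8.0, "Bbb": 0.5, "Ccc": 12.0}

    def test_empty_results_give_empty_report(self):
        assert integrate([], self.ZMAP, GENES) == []

    def test_all_three_filters_are_required(self):
        results = [
            result("pass", "M", 2.0, 0.0, True),
            result("weak_delta", "M", 0.5, 0.2, True),
            result("not_significant", "M", 2.0, 0.0, False),
            result("weak_z", "M", 2.0, 0.0, True, pos=5500),  # Bbb, |Z|=0.5
        ]
        hits = integrate(results, self.ZMAP, GENES)
        assert [h.result.snp_id for h in hits] == ["pass"]
        assert hits[0].gene == "Svs4" and hits[0].distance == 0

    def test_either_strand_may_carry_the_delta(self):
        res = result("rev_only", "M", 0.0, 3.5, True)
        hits = integrate([res], self.ZMAP, GENES)
        assert len(hits) == 1

    def test_raising_cuts_never_adds_hits(self):
        rng = np.random.default_rng(4)
        results = [
            result(f"s{i}", "M", float(rng.normal(0, 2)), float(rng.normal(0, 2)), True,
                   pos=int(rng.integers(100, 7000)))
            for i in range(50)
        ]
        zmap = {g: float(rng.normal(0, 6)) for g in GENES["symbol"]}
        baseline = {h.result.snp_id for h in integrate(results, zmap, GENES, 1.0, 4.0)}
        for dcut, zcut in [(1.5, 4.0), (1.0, 6.0), (2.5, 8.0)]:
            tighter = {h.result.snp_id for h in integrate(results, zmap, GENES, dcut, zcut)}
            assert tighter <= baseline

    def test_hit_flags_recompute_from_stored_values(self, bench_scan):
        for h in bench_scan.hits:
            r = h.result
            assert r.delta == pytest.approx(r.ref - r.alt)
            assert r.delta_rev == pytest.approx(r.ref_rev - r.alt_rev)
            assert h.passes_delta == (abs(r.delta) > 1.0 or abs(r.delta_rev) > 1.0)
            assert h.passes_z == (abs(h.z) > 7.0)

    def test_missing_z_drops_hit_with_log(self, caplog):
        res = result("orphan", "M", 2.0, 0.0, True)
        with caplog.at_level("WARNING"):
            hits = integrate([res], {}, GENES)
        assert hits == []
        assert any("no Z" in m for m in caplog.messages)

    def test_report_sorted_by_pwm_then_position(self):
        results = [
            result("b", "M2", 2.0, 0.0, True, pos=150),
            result("a", "M1", 2.0, 0.0, True, pos=5500),
            result("c", "M1", 2.0, 0.0, True, pos=150),
        ]
        zmap = {"Svs4": 9.5, "Bbb": 9.5}
        hits = integrate(results, zmap, GENES)
        assert [h.result.snp_id for h in hits] == ["c", "a", "b"]


def test_hits_to_frame_rounds_for_display_only():
    res = MotifScoreResult.from_scores("s", "M", 7.7249, 0.0, 10.3212, 3.4811, threshold=8.11)
    hit_list = integrate(
        [MotifScoreResult(**{**res.__dict__, "chrom": "chr1", "pos": 150})],
        {"Svs4": 9.5}, GENES,
    )
    rounded = hits_to_frame(hit_list, decimals=2)
    full = hits_to_frame(hit_list, decimals=None)
    assert rounded.loc[0, "delta"] == pytest.approx(-2.60)
    assert full.loc[0, "delta"] == pytest.approx(7.7249 - 10.3212)
    assert list(rounded.columns)[:6] == ["pwm", "snp", "chrom", "pos", "ref.seq", "alt.seq"]
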