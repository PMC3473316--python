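"""Pileup construction, calling thresholds, SNP/INDEL classification, merging."""

import numpy as np
import pytest

from conftest import write_sam
from poolsnv.calling import (INDEL, SNP, AlleleObservation, CallParams,
                             PileupColumn, PileupError, PoolCall, PoolProfile,
                             call_column, call_pool_variants, classify_kind,
                             covered_length, merge_pool_calls, pileup_columns,
                             pool_profile)

PARAMS = CallParams()
REF = {"s1": "A" * 200}
Q30 = chr(33 + 30)


def col(obs, ref="A", pos=50, scaffold="s1"):
    observations = {a: AlleleObservation(a, d, q) for a, (d, q) in obs.items()}
    return PileupColumn(scaffold, pos, ref, observations)


class TestPileup:
    def test_no_alignments_empty_stream(self, tmp_path):
        sam = write_sam(tmp_path / "e.sam", {"s1": 200}, [])
        assert list(pileup_columns(sam, REF)) == []

    def test_uniform_reference_reads_single_observation(self, tmp_path):
        reads = [(f"r{i}", 0, "s1", 11, 60, "5M", "AAAAA", Q30 * 5) for i in range(7)]
        sam = write_sam(tmp_path / "u.sam", {"s1": 200}, reads)
        cols = list(pileup_columns(sam, REF))
        assert len(cols) == 5
        for c in cols:
            assert c.depth == 7 and list(c.observations) == ["A"]
            assert c.observations["A"].qual_sum == 7 * 30

    def test_mixed_alleles_two_observations(self, tmp_path):
        reads = [(f"ref{i}", 0, "s1", 11, 60, "3M", "AAA", Q30 * 3) for i in range(4)]
        reads += [(f"alt{i}", 0, "s1", 11, 60, "3M", "AGA", Q30 * 3) for i in range(3)]
        sam = write_sam(tmp_path / "m.sam", {"s1": 200}, reads)
        cols = {c.pos: c for c in pileup_columns(sam, REF)}
        c = cols[12]
        assert c.observations["A"].depth == 4 and c.observations["G"].depth == 3

    def test_n_and_quality_zero_bases_do_not_count(self, tmp_path):
        q = Q30 + chr(33 + 0) + Q30  # middle base quality 0
        reads = [("r1", 0, "s1", 11, 60, "3M", "ANA", Q30 * 3),
                 ("r2", 0, "s1", 11, 60, "3M", "AAA", q)]
        sam = write_sam(tmp_path / "n.sam", {"s1": 200}, reads)
        cols = {c.pos: c for c in pileup_columns(sam, REF)}
        assert 12 not in cols  # both middle bases excluded entirely
        assert cols[11].depth == 2

    def test_low_mapq_and_unmapped_excluded(self, tmp_path):
        reads = [("r1", 0, "s1", 11, 0, "3M", "AAA", Q30 * 3),   # mapq 0 < 1
                 ("r2", 4, "s1", 11, 60, "3M", "AAA", Q30 * 3)]  # unmapped flag
        sam = write_sam(tmp_path / "f.sam", {"s1": 200}, reads)
        assert list(pileup_columns(sam, REF)) == []

    def test_insertion_and_deletion_become_composite_alleles(self, tmp_path):
        reads = [("i1", 0, "s1", 11, 60, "2M2I2M", "AATGAA", Q30 * 6),
                 ("d1", 0, "s1", 11, 60, "2M1D2M", "AAAA", Q30 * 4)]
        sam = write_sam(tmp_path / "i.sam", {"s1": 200}, reads)
        cols = {c.pos: c for c in pileup_columns(sam, REF)}
        assert "A+TG" in cols[12].observations
        assert "A-1" in cols[12].observations
        assert cols[12].depth == 2
        assert 13 in cols and cols[13].depth == 1  # deleted column: only i1's base

    def test_unsorted_input_rejected(self, tmp_path):
        reads = [("r1", 0, "s1", 50, 60, "3M", "AAA", Q30 * 3),
                 ("r2", 0, "s1", 11, 60, "3M", "AAA", Q30 * 3)]
        sam = write_sam(tmp_path / "x.sam", {"s1": 200}, reads)
        with pytest.raises(PileupError):
            list(pileup_columns(sam, REF))

    def test_reference_name_mismatch_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "y.sam", {"other": 200}, [])
        with pytest.raises(PileupError):
            list(pileup_columns(sam, REF))


class TestCovered:
    def test_all_below_threshold(self):
        cols = [col({"A": (5, 150)}, pos=p) for p in range(10)]
        assert covered_length(cols, PARAMS) == 0

    def test_direct_count(self):
        depths = [6, 6, 7, 5]
        cols = [col({"A": (d, d * 30)}, pos=i) for i, d in enumerate(depths)]
        assert covered_length(cols, PARAMS) == 3


class TestCallRules:
    def test_below_coverage_no_call(self):
        assert call_column(col({"A": (5, 150)}), PARAMS) is None

    def test_polymorphic_when_quality_reached(self):
        c = col({"A": (4, 120), "G": (3, 90)})
        call = call_column(c, PARAMS)
        assert call.polymorphic and call.quality == 90
        assert call.alleles == ["A", "G"]

    def test_demoted_to_monomorphic_when_quality_low(self):
        c = col({"A": (4, 120), "G": (3, 60)})
        call = call_column(c, PARAMS)
        assert not call.polymorphic and call.alleles == ["A"] and call.quality is None

    def test_two_reads_never_support_an_allele(self):
        c = col({"A": (4, 120), "G": (2, 80)})
        call = call_column(c, PARAMS)
        assert call.alleles == ["A"]

    def test_majority_tie_broken_lexicographically(self):
        c = col({"T": (3, 120), "C": (3, 120)})
        call = call_column(c, PARAMS)
        assert call.supported_alleles[0].allele == "C"

    def test_monomorphic_nonref_retained_without_quality_test(self):
        c = col({"G": (6, 60)}, ref="A")  # qual_sum 60 < 70 but monomorphic
        call = call_column(c, PARAMS)
        assert call.alleles == ["G"] and call.quality is None


class TestKind:
    @pytest.mark.parametrize("alleles,kind", [
        (["A", "G"], SNP),
        (["A", "A+TG"], INDEL),
        (["A", "G", "A-1"], INDEL),
    ])
    def test_classification(self, alleles, kind):
        call = PoolCall("s1", 5, "A",
                        [AlleleObservation(a, 3, 90) for a in alleles], 90)
        assert classify_kind(call) == kind


def profile_from(pool_id, calls):
    return PoolProfile(pool_id, len(calls), {(c.scaffold, c.pos): c for c in calls})


def mono(pos, allele, ref="A", depth=10):
    return PoolCall("s1", pos, ref, [AlleleObservation(allele, depth, depth * 30)], None)


class TestMerge:
    def test_monomorphic_reference_yields_nothing(self):
        prof = profile_from(1, [mono(p, "A") for p in range(1, 20)])
        assert merge_pool_calls([prof]) == []

    def test_fixed_difference_between_pools(self):
        p1 = profile_from(1, [mono(7, "A")])
        p8 = profile_from(8, [mono(7, "G")])
        recs = merge_pool_calls([p1, p8])
        assert len(recs) == 1
        r = recs[0]
        assert r.alleles == ["A", "G"]
        assert r.pool_maf[1] == 1.0 and r.pool_maf[8] == 1.0
        assert r.fixed_allele(1) == "A" and r.fixed_allele(8) == "G"
        assert r.status(3) == "no_coverage"

    def test_duplicate_pool_ids_rejected(self):
        p = profile_from(1, [mono(7, "G")])
        with pytest.raises(ValueError):
            merge_pool_calls([p, p])

    def test_fixed_nonref_single_pool_emitted(self):
        recs = merge_pool_calls([profile_from(2, [mono(7, "G")])])
        assert len(recs) == 1 and recs[0].status(2) == "fixed_alt"


class TestOracleEquivalence:
    """The pileup+calling path agrees with a brute-force evaluation of the
    rules on randomly generated small fixtures (≤ 50 columns)."""

    def brute_force(self, reads, ref, params):
        """Independent per-column tally straight from the read tuples."""
        columns = {}
        for pos, seq, quals in reads:
            for k, (b, q) in enumerate(zip(seq, quals)):
                if b == "N" or q == 0:
                    continue
                slot = columns.setdefault(pos + k, {})
                d, qs = slot.get(b, (0, 0))
                slot[b] = (d + 1, qs + q)
        calls = {}
        for pos in sorted(columns):
            obs = columns[pos]
            if sum(d for d, _ in obs.values()) < params.min_coverage:
                continue
            supported = {a: v for a, v in obs.items()
                         if v[0] >= params.min_allele_reads}
            if not supported:
                continue
            ranked = sorted(supported, key=lambda a: (-supported[a][0], a))
            if len(ranked) >= 2 and min(supported[a][1] for a in ranked[1:]) >= params.min_quality:
                calls[pos] = sorted(ranked)
            else:
                calls[pos] = [ranked[0]]
        return calls

    def test_matches_brute_force_on_random_fixtures(self, tmp_path):
        rng = np.random.default_rng(42)
        ref_seq = "".join(rng.choice(list("ACGT"), size=60))
        for trial in range(8):
            reads = []
            n_reads = int(rng.integers(5, 40))
            for i in range(n_reads):
                pos = int(rng.integers(1, 50))
                length = int(rng.integers(3, 12))
                seq = "".join(rng.choice(list("ACGTN"), p=[0.3, 0.3, 0.15, 0.15, 0.1],
                                         size=length))
                quals = [int(q) for q in rng.integers(0, 41, size=length)]
                reads.append((pos, seq, quals))
            reads.sort(key=lambda r: r[0])
            sam = write_sam(
                tmp_path / f"t{trial}.sam", {"s1": 100},
                [(f"r{i}", 0, "s1", pos, 60, f"{len(seq)}M", seq,
                  "".join(chr(33 + q) for q in quals))
                 for i, (pos, seq, quals) in enumerate(reads)])
            calls = call_pool_variants(
                pileup_columns(sam, {"s1": ref_seq + "A" * 40}), PARAMS)
            got = {c.pos: sorted(c.alleles) for c in calls}
            assert got == self.brute_force(reads, ref_seq, PARAMS)


class TestProfileOnSimulatedData:
    def test_covered_length_close_to_exonic_span(self, study_run):
        cfg = study_run.config
        exon_bp = sum(e - s + 1 for m in study_run.models for s, e in m.exons)
        for prof in study_run.profiles:
            assert 0.9 * exon_bp <= prof.covered_length_bp <= exon_bp

    def test_snp_plus_indel_conservation(self, study_run):
        records = study_run.records
        n_snp = sum(1 for r in records if r.kind == SNP)
        n_indel = sum(1 for r in records if r.kind == INDEL)
        assert n_snp + n_indel == len(records)
        assert n_indel > 0
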