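"""Per-pool pileups, SNV calling and multi-pool merging.

Calling criteria follow a stringent pooled-pileup recipe: only positions with
at least ``min_coverage`` (default 6X) reads are mined; an allele is
*supported* when at least ``min_allele_reads`` (default 3) reads carry it; a
position is called polymorphic when at least two alleles are supported and the
call quality — the minimum summed Phred of the supporting bases over the
non-majority supported alleles — reaches ``min_quality`` (default 70).
Covered positions with exactly one supported allele are retained as
monomorphic calls (no quality test) so that fixed differences between pools
remain computable.

Pileup conventions: only primary, mapped, non-duplicate alignments with
mapping quality ≥ ``min_mapq`` contribute; 'N' bases and quality-0 bases are
excluded entirely (they do not count toward depth).  A read carrying an
insertion contributes the composite allele ``<anchor base>+<inserted seq>`` at
the anchor column; a deletion contributes ``<anchor base>-<length>`` at its
anchor and nothing at the deleted columns, so column depth always equals the
number of contributing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
import pyfaidx

SNP = "SNP"
INDEL = "INDEL"


@dataclass(frozen=True)
class CallParams:
    min_coverage: int = 6
    min_allele_reads: int = 3
    min_quality: int = 70
    min_mapq: int = 1


@dataclass
class AlleleObservation:
    allele: str
    depth: int
    qual_sum: int


@dataclass
class PileupColumn:
    scaffold: str
    pos: int  # 1-based
    ref_allele: str
    observations: dict[str, AlleleObservation]

    @property
    def depth(self) -> int:
        return sum(o.depth for o in self.observations.values())


@dataclass
class PoolCall:
    scaffold: str
    pos: int
    ref_allele: str
    supported_alleles: list[AlleleObservation]
    quality: int | None  # None for monomorphic calls (no quality test applied)

    @property
    def polymorphic(self) -> bool:
        return len(self.supported_alleles) >= 2

    @property
    def alleles(self) -> list[str]:
        return [o.allele for o in self.supported_alleles]

    @property
    def kind(self) -> str:
        return classify_kind(self)


def classify_kind(call: PoolCall) -> str:
    """INDEL if any supported allele carries an insertion/deletion descriptor."""
    return INDEL if any(_is_indel_allele(a) for a in call.alleles) else SNP


def _is_indel_allele(allele: str) -> bool:
    return "+" in allele or "-" in allele


@dataclass
class PoolProfile:
    """One pool's calling result: ≥min-coverage length and per-position calls."""

    pool_id: int
    covered_length_bp: int
    calls: dict[tuple[str, int], PoolCall]
    covered_positions: dict[str, np.ndarray] = field(default_factory=dict)


class PileupError(ValueError):
    pass


def pileup_columns(sam_path: str | Path, reference: Mapping[str, str] | str | Path,
                   params: CallParams = CallParams()) -> Iterator[PileupColumn]:
    """Build pileup columns from a coordinate-sorted SAM/BAM file.

    ``reference`` is a FASTA path or a mapping of scaffold name to sequence.
    Raises on unsorted input or on reference/alignment name mismatch.
    """
    ref = _as_reference(reference)
    cols: dict[tuple[str, int], dict[str, list[int]]] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as af:
        for name in af.references:
            if name not in ref:
                raise PileupError(f"alignment reference {name!r} not in FASTA")
        last: tuple[int, int] | None = None
        for aln in af:
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or aln.is_duplicate or aln.mapping_quality < params.min_mapq):
                continue
            key = (aln.reference_id, aln.reference_start)
            if last is not None and key < last:
                raise PileupError("input alignments are not coordinate-sorted")
            last = key
            _accumulate(cols, aln, af.get_reference_name(aln.reference_id))
    for (scaffold, pos) in sorted(cols):
        obs = {
            allele: AlleleObservation(allele, d, q)
            for allele, (d, q) in sorted(cols[(scaffold, pos)].items())
        }
        yield PileupColumn(scaffold, pos, ref[scaffold][pos - 1], obs)


def _as_reference(reference) -> Mapping[str, str]:
    if isinstance(reference, (str, Path)):
        fa = pyfaidx.Fasta(str(reference))
        return {name: str(fa[name]) for name in fa.keys()}
    return reference


def _accumulate(cols, aln: pysam.AlignedSegment, scaffold: str) -> None:
    seq = aln.query_sequence
    quals = aln.query_qualities
    rpos = aln.reference_start  # 0-based
    qpos = 0
    events: dict[int, tuple[str, int]] = {}
    for op, ln in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            for k in range(ln):
                base = seq[qpos + k]
                q = quals[qpos + k]
                if base != "N" and q > 0:
                    events[rpos + k] = (base, q)
            rpos += ln
            qpos += ln
        elif op == 1:  # I: composite allele at the anchor (previous ref base)
            anchor = rpos - 1
            if anchor in events:
                b, q = events[anchor]
                events[anchor] = (b + "+" + seq[qpos:qpos + ln], q)
            qpos += ln
        elif op == 2:  # D: composite allele at the anchor; deleted bases silent
            anchor = rpos - 1
            if anchor in events:
                b, q = events[anchor]
                events[anchor] = (b + f"-{ln}", q)
            rpos += ln
        elif op == 4:  # S
            qpos += ln
        elif op == 3:  # N (skip)
            rpos += ln
        # H/P consume nothing we track
    for p0, (allele, q) in events.items():
        slot = cols.setdefault((scaffold, p0 + 1), {}).setdefault(allele, [0, 0])
        slot[0] += 1
        slot[1] += q


def covered_length(columns: Iterable[PileupColumn],
                   params: CallParams = CallParams()) -> int:
    """Number of positions with depth ≥ min_coverage."""
    return sum(1 for c in columns if c.depth >= params.min_coverage)


def call_column(col: PileupColumn, params: CallParams = CallParams()) -> PoolCall | None:
    """Apply the coverage / allele-support / quality rules to one column."""
    if col.depth < params.min_coverage:
        return None
    supported = [o for o in col.observations.values()
                 if o.depth >= params.min_allele_reads]
    if not supported:
        return None
    # majority allele: highest depth, lexicographic tie-break
    supported.sort(key=lambda o: (-o.depth, o.allele))
    if len(supported) >= 2:
        quality = min(o.qual_sum for o in supported[1:])
        if quality >= params.min_quality:
            return PoolCall(col.scaffold, col.pos, col.ref_allele,
                            supported, quality)
        # demote: keep the majority allele as a monomorphic call
        return PoolCall(col.scaffold, col.pos, col.ref_allele, supported[:1], None)
    return PoolCall(col.scaffold, col.pos, col.ref_allele, supported, None)


def call_pool_variants(columns: Iterable[PileupColumn],
                       params: CallParams = CallParams()) -> list[PoolCall]:
    out = []
    for col in columns:
        call = call_column(col, params)
        if call is not None:
            out.append(call)
    return out


def pool_profile(pool_id: int, sam_path: str | Path,
                 reference: Mapping[str, str] | str | Path,
                 params: CallParams = CallParams()) -> PoolProfile:
    """Pileup + covered length + calls for one pool's alignments."""
    columns = list(pileup_columns(sam_path, reference, params))
    calls = {}
    covered: dict[str, list[int]] = {}
    n_covered = 0
    for col in columns:
        if col.depth >= params.min_coverage:
            n_covered += 1
            covered.setdefault(col.scaffold, []).append(col.pos)
        call = call_column(col, params)
        if call is not None:
            calls[(col.scaffold, col.pos)] = call
    covered_arr = {k: np.asarray(v, dtype=np.int64) for k, v in covered.items()}
    return PoolProfile(pool_id, n_covered, calls, covered_arr)


# ---------------------------------------------------------------------------
# merging across pools

POLYMORPHIC = "polymorphic"
FIXED_REF = "fixed_ref"
FIXED_ALT = "fixed_alt"
NO_COVERAGE = "no_coverage"


@dataclass
class VariantRecord:
    """A merged multi-pool variant."""

    scaffold: str
    pos: int
    ref_allele: str
    alleles: list[str]
    kind: str                                  # SNP | INDEL
    pool_depths: dict[int, dict[str, int] | None]   # None: pool below min coverage
    pool_status: dict[int, str]
    pool_maf: dict[int, float]
    global_maf: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold, self.pos)

    def status(self, pool_id: int) -> str:
        return self.pool_status.get(pool_id, NO_COVERAGE)

    def fixed_allele(self, pool_id: int) -> str | None:
        """The single supported allele in a fixed pool, else None."""
        if self.status(pool_id) not in (FIXED_REF, FIXED_ALT):
            return None
        depths = self.pool_depths[pool_id]
        return next(iter(depths))


def merge_pool_calls(profiles: Sequence[PoolProfile]) -> list[VariantRecord]:
    """Merge per-pool calls into a variant table.

    A record is emitted where at least two distinct alleles are supported
    across pools combined, or where a single non-reference allele is fixed in
    at least one pool.
    """
    ids = [p.pool_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pool ids in profiles")
    keys = sorted(set().union(*(p.calls.keys() for p in profiles))) if profiles else []
    records: list[VariantRecord] = []
    for key in keys:
        per_pool = {p.pool_id: p.calls.get(key) for p in profiles}
        alleles: set[str] = set()
        ref = None
        for call in per_pool.values():
            if call is not None:
                ref = call.ref_allele
                alleles.update(call.alleles)
        if ref is None:
            continue
        if not (len(alleles) >= 2 or (len(alleles) == 1 and next(iter(alleles)) != ref)):
            continue
        pool_depths: dict[int, dict[str, int] | None] = {}
        pool_status: dict[int, str] = {}
        pool_maf: dict[int, float] = {}
        totals: dict[str, int] = {}
        for pid, call in per_pool.items():
            if call is None:
                pool_depths[pid] = None
                pool_status[pid] = NO_COVERAGE
                continue
            depths = {o.allele: o.depth for o in call.supported_alleles}
            pool_depths[pid] = depths
            for a, d in depths.items():
                totals[a] = totals.get(a, 0) + d
            if call.polymorphic:
                pool_status[pid] = POLYMORPHIC
            else:
                only = next(iter(depths))
                pool_status[pid] = FIXED_REF if only == ref else FIXED_ALT
            pool_maf[pid] = max(depths.values()) / sum(depths.values())
        grand = sum(totals.values())
        global_maf = max(totals.values()) / grand if grand else float("nan")
        sorted_alleles = sorted(alleles)
        kind = INDEL if any(_is_indel_allele(a) for a in sorted_alleles) else SNP
        records.append(VariantRecord(key[0], key[1], ref, sorted_alleles, kind,
                                     pool_depths, pool_status, pool_maf, global_maf))
    return records


def build_coverage_mask(profiles: Sequence[PoolProfile],
                        scaffold_lengths: Mapping[str, int]):
    """Union ≥min-coverage mask over pools (for feature-density denominators)."""
    from .genemodels import CoverageMask

    mask = CoverageMask(scaffold_lengths)
    for p in profiles:
        for scaffold, positions in p.covered_positions.items():
            mask.add_positions(scaffold, positions.tolist())
    return mask


# ---------------------------------------------------------------------------
# output

def _vcf_alleles(rec: VariantRecord, reference: Mapping[str, str]) -> tuple[str, list[str], dict[str, int]]:
    """VCF-normalized REF/ALT for possibly composite indel alleles."""
    seq = reference[rec.scaffold]
    max_del = 0
    for a in rec.alleles:
        if "-" in a and a[0] in "ACGTN":
            max_del = max(max_del, int(a.split("-")[1]))
    ref_str = seq[rec.pos - 1:rec.pos + max_del]
    alts: list[str] = []
    index: dict[str, int] = {}
    for a in rec.alleles:
        if "+" in a:
            base, ins = a.split("+")
            norm = base + ins + ref_str[1:]
        elif "-" in a:
            base, k = a.split("-")
            k = int(k)
            norm = base + ref_str[1 + k:]
        else:
            norm = a + ref_str[1:]
        if norm == ref_str:
            index[a] = 0
        else:
            if norm not in alts:
                alts.append(norm)
            index[a] = alts.index(norm) + 1
    return ref_str, alts, index


def write_vcf(records: Sequence[VariantRecord], reference: Mapping[str, str],
              pools: Sequence[int], path: str | Path) -> None:
    """One merged VCF with per-pool allele depths as per-sample AD fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Global major allele frequency">\n')
        fh.write('##INFO=<ID=KIND,Number=1,Type=String,Description="SNP or INDEL">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Supported allele depths">\n')
        fh.write('##FORMAT=<ID=MF,Number=1,Type=Float,Description="Pool major allele frequency">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [f"pool{p}" for p in pools]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            ref_str, alts, index = _vcf_alleles(rec, reference)
            n_all = 1 + len(alts)
            row = [rec.scaffold, str(rec.pos), ".", ref_str,
                   ",".join(alts) if alts else ".", ".", "PASS",
                   f"MAF={rec.global_maf:.4f};KIND={rec.kind}", "AD:MF"]
            for p in pools:
                depths = rec.pool_depths.get(p)
                if depths is None:
                    row.append(".:.")
                    continue
                ad = [0] * n_all
                for a, d in depths.items():
                    ad[index[a]] += d
                mf = rec.pool_maf.get(p)
                row.append(",".join(map(str, ad)) + (f":{mf:.4f}" if mf is not None else ":."))
            fh.write("\t".join(row) + "\n")


def records_to_table(records: Sequence[VariantRecord], pools: Sequence[int]):
    """Long-form table of the merged collection (positions, alleles, per-pool
    status/MAF, global MAF)."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {
            "scaffold": rec.scaffold, "pos": rec.pos, "ref": rec.ref_allele,
            "alleles": "/".join(rec.alleles), "kind": rec.kind,
            "global_maf": round(rec.global_maf, 4),
        }
        for p in pools:
            row[f"status_pool{p}"] = rec.status(p)
            maf = rec.pool_maf.get(p)
            row[f"maf_pool{p}"] = round(maf, 4) if maf is not None else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
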