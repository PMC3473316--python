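"""Truth-known synthetic data: toy genome, gene models, planted variants and
per-pool exonic short reads.

The generator emulates a pooled transcriptome resequencing experiment: several
pools, each a mixture of genotypes, sequenced as 49-bp reads confined to single
exons (mirroring unspliced cDNA-to-genome mapping, so no read ever spans an
exon-intron junction).  Variants are planted with pool-structured alternate
allele frequencies:

* ``shared_all``        — polymorphic (0 < f < 1) in every pool,
* ``pool_specific``     — polymorphic in exactly one pool,
* ``fixed_differential``— fixed alternate (f=1) in one pool of a designated
                          pair and absent (f=0) in the other,
* ``background``        — random per-pool frequencies,
* ``near_intron``       — shared-type sites planted < 60 bp from an
                          exon-intron junction (exercise for the
                          intron-proximity filter),
* ``clustered``         — pairs of shared-type sites ≤ 60 bp apart (exercise
                          for the flanking-polymorphism filter),
* ``indel``             — short insertion/deletion alleles (exercise for the
                          SNP/INDEL separation).

All other sites keep a mutual spacing of at least 61 bp and sit at least 61 bp
from every exon edge, so flanking-window filters and read-coverage edge
effects do not interfere with recovery statistics.

Base qualities follow a two-level model (high-quality body, decaying 3' tail);
substitution errors are drawn per base and their bases carry low qualities, so
quality carries information about error probability as in real base callers.
Missing calls are emitted as 'N' with quality 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .genemodels import GeneModel

VARIANT_CLASSES = (
    "shared_all", "pool_specific", "fixed_differential", "background",
    "near_intron", "clustered", "indel",
)

_BASES = np.array(list("ACGT"))


def _default_class_counts() -> dict[str, int]:
    return {
        "shared_all": 60,
        "pool_specific": 40,
        "fixed_differential": 30,
        "background": 40,
        "near_intron": 20,
        "clustered": 15,   # pairs
        "indel": 15,
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults reproduce the conditions the downstream property checks assume:
    8 pools of 49-bp exonic reads at 30X mean coverage, 1% substitution error,
    0.5% missing calls.
    """

    seed: int = 1
    n_scaffolds: int = 3
    scaffold_len: int = 22_000
    genes_per_scaffold: int = 6
    exons_per_gene: int = 4
    exon_len: int = 450
    intron_len: int = 150
    utr_len: int = 120
    n_pools: int = 8
    read_len: int = 49
    per_pool_depth: float | tuple[float, ...] = 30.0
    error_rate: float = 0.01
    missing_rate: float = 0.005
    # base-quality model
    body_quality: int = 34
    quality_jitter: int = 3
    tail_len: int = 10
    tail_drop: int = 8
    error_quality: tuple[int, int] = (12, 22)   # inclusive range for error bases
    # planted-frequency structure
    shared_freq: float = 0.5
    specific_freq: float = 0.5
    differential_pairs: tuple[tuple[int, int], ...] = ((1, 8),)
    near_intron_dist: tuple[int, int] = (20, 59)
    cluster_gap: tuple[int, int] = (10, 60)
    min_spacing: int = 61
    n_variants_per_class: Mapping[str, int] = field(default_factory=_default_class_counts)

    def __post_init__(self) -> None:
        for d in self.depths():
            if d < 0:
                raise ValueError("per_pool_depth must be non-negative")
        if not (0 <= self.error_rate < 0.1 and 0 <= self.missing_rate < 0.1):
            raise ValueError("error_rate and missing_rate must be in [0, 0.1)")
        if self.read_len > self.exon_len:
            raise ValueError("read_len must not exceed exon_len")
        if not (0 < self.shared_freq < 1 and 0 < self.specific_freq < 1):
            raise ValueError("planted polymorphic frequencies must be in (0, 1)")
        gene_span = (self.exons_per_gene * self.exon_len
                     + (self.exons_per_gene - 1) * self.intron_len)
        if self.genes_per_scaffold * gene_span > self.scaffold_len:
            raise ValueError("gene structure exceeds scaffold length")
        if self.utr_len >= self.exon_len:
            raise ValueError("utr_len must be smaller than exon_len")
        for k in self.n_variants_per_class:
            if k not in VARIANT_CLASSES:
                raise ValueError(f"unknown variant class {k!r}")
        for a, b in self.differential_pairs:
            if not (1 <= a <= self.n_pools and 1 <= b <= self.n_pools) or a == b:
                raise ValueError("differential_pairs must name two distinct pools")

    def depths(self) -> tuple[float, ...]:
        if isinstance(self.per_pool_depth, (int, float)):
            return tuple(float(self.per_pool_depth) for _ in range(self.n_pools))
        if len(self.per_pool_depth) != self.n_pools:
            raise ValueError("per_pool_depth sequence must have n_pools entries")
        return tuple(float(d) for d in self.per_pool_depth)

    def pools(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_pools + 1))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthRecord:
    """A planted variant with its per-pool alternate-allele frequencies."""

    scaffold: str
    pos: int            # 1-based
    ref_allele: str
    alt_allele: str     # single base, or "+SEQ" insertion / "-N" deletion
    vclass: str
    per_pool_freq: dict[int, float]

    @property
    def is_indel(self) -> bool:
        return self.alt_allele.startswith(("+", "-"))

    def polymorphic_pools(self) -> list[int]:
        return [p for p, f in self.per_pool_freq.items() if 0.0 < f < 1.0]


# ---------------------------------------------------------------------------
# genome and gene models

def make_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus regularly laid-out gene models.

    Each gene is ``exons_per_gene`` exons of ``exon_len`` bp separated by
    ``intron_len`` bp introns; the first ``utr_len`` bases of the first exon
    are 5' UTR and the last ``utr_len`` of the last exon 3' UTR (swapped for
    minus-strand genes), the rest CDS.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng((config.seed, 0))
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_span = (config.exons_per_gene * config.exon_len
                 + (config.exons_per_gene - 1) * config.intron_len)
    n_genes = config.genes_per_scaffold
    for si in range(config.n_scaffolds):
        name = f"scaffold{si + 1:02d}"
        seq = "".join(rng.choice(_BASES, size=config.scaffold_len))
        genome[name] = seq
        if n_genes == 0:
            continue
        gap = (config.scaffold_len - n_genes * gene_span) // (n_genes + 1)
        for gi in range(n_genes):
            start = gap + gi * (gene_span + gap) + 1  # 1-based
            exons = []
            for ei in range(config.exons_per_gene):
                s = start + ei * (config.exon_len + config.intron_len)
                exons.append((s, s + config.exon_len - 1))
            strand = "+" if (si + gi) % 2 == 0 else "-"
            left_utr = (exons[0][0], exons[0][0] + config.utr_len - 1)
            right_utr = (exons[-1][1] - config.utr_len + 1, exons[-1][1])
            cds = [(left_utr[1] + 1, exons[0][1])]
            cds += exons[1:-1]
            cds.append((exons[-1][0], right_utr[0] - 1))
            if strand == "+":
                utr5, utr3 = [left_utr], [right_utr]
            else:
                utr5, utr3 = [right_utr], [left_utr]
            models.append(GeneModel(
                gene_id=f"gene_{name}_{gi + 1:02d}", scaffold=name, strand=strand,
                exons=exons, cds_segments=cds,
                utr5_segments=utr5, utr3_segments=utr3,
            ))
    return genome, models


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(models: Sequence[GeneModel], genome: Mapping[str, str],
               path: str | Path) -> None:
    src = "poolsnv_sim"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for m in models:
            gid = m.gene_id
            mid = gid + ".mRNA1"
            fh.write("\t".join([m.scaffold, src, "gene", str(m.start), str(m.end),
                                ".", m.strand, ".", f"ID={gid}"]) + "\n")
            fh.write("\t".join([m.scaffold, src, "mRNA", str(m.start), str(m.end),
                                ".", m.strand, ".", f"ID={mid};Parent={gid}"]) + "\n")
            rows = []
            for s, e in m.exons:
                rows.append(("exon", s, e, "."))
            for s, e in m.cds_segments:
                rows.append(("CDS", s, e, "0"))
            for s, e in m.utr5_segments:
                rows.append(("five_prime_UTR", s, e, "."))
            for s, e in m.utr3_segments:
                rows.append(("three_prime_UTR", s, e, "."))
            for ftype, s, e, frame in sorted(rows, key=lambda r: (r[1], r[0])):
                fh.write("\t".join([m.scaffold, src, ftype, str(s), str(e), ".",
                                    m.strand, frame, f"Parent={mid}"]) + "\n")


# ---------------------------------------------------------------------------
# variant planting

class GenerationError(RuntimeError):
    pass


def _interior_slots(models: Sequence[GeneModel], margin: int) -> list[tuple[str, int, int]]:
    """(scaffold, lo, hi) candidate windows ≥ margin bp from every exon edge."""
    out = []
    for m in models:
        for s, e in m.exons:
            lo, hi = s + margin, e - margin
            if hi >= lo:
                out.append((m.scaffold, lo, hi))
    return out


def plant_variants(genome: Mapping[str, str], models: Sequence[GeneModel],
                   config: SimConfig, max_tries: int = 20_000) -> list[TruthRecord]:
    """Plant the requested truth variants; see module docstring for classes."""
    rng = np.random.default_rng((config.seed, 1))
    counts = {k: 0 for k in VARIANT_CLASSES}
    counts.update(config.n_variants_per_class)
    if all(v == 0 for v in counts.values()):
        return []

    occupied: dict[str, list[int]] = {name: [] for name in genome}
    spacing = config.min_spacing

    def spaced_ok(scaffold: str, pos: int, exempt: int | None = None) -> bool:
        return all(abs(pos - q) >= spacing for q in occupied[scaffold] if q != exempt)

    slots = _interior_slots(models, spacing)
    if not slots and any(v > 0 for k, v in counts.items() if k != "near_intron"):
        raise GenerationError("no exonic space for planting with required margins")

    def draw_interior(exempt: int | None = None) -> tuple[str, int]:
        for _ in range(max_tries):
            scaffold, lo, hi = slots[rng.integers(len(slots))]
            pos = int(rng.integers(lo, hi + 1))
            if spaced_ok(scaffold, pos, exempt):
                return scaffold, pos
        raise GenerationError("could not place variant: exonic space exhausted")

    def alt_base(scaffold: str, pos: int) -> tuple[str, str]:
        ref = genome[scaffold][pos - 1]
        choices = [b for b in "ACGT" if b != ref]
        return ref, choices[rng.integers(3)]

    pools = config.pools()
    truth: list[TruthRecord] = []

    def add(scaffold: str, pos: int, alt: str | None, vclass: str,
            freqs: dict[int, float]) -> TruthRecord:
        ref = genome[scaffold][pos - 1]
        if alt is None:
            ref, alt = alt_base(scaffold, pos)
        rec = TruthRecord(scaffold, pos, ref, alt, vclass, freqs)
        truth.append(rec)
        occupied[scaffold].append(pos)
        return rec

    def shared_freqs() -> dict[int, float]:
        return {p: config.shared_freq for p in pools}

    for _ in range(counts.get("shared_all", 0)):
        sc, pos = draw_interior()
        add(sc, pos, None, "shared_all", shared_freqs())

    for i in range(counts.get("pool_specific", 0)):
        sc, pos = draw_interior()
        target = pools[i % len(pools)]
        freqs = {p: (config.specific_freq if p == target else 0.0) for p in pools}
        add(sc, pos, None, "pool_specific", freqs)

    for i in range(counts.get("fixed_differential", 0)):
        sc, pos = draw_interior()
        a, b = config.differential_pairs[i % len(config.differential_pairs)]
        freqs = {p: (1.0 if p == a else 0.0) for p in pools}
        add(sc, pos, None, "fixed_differential", freqs)

    for _ in range(counts.get("background", 0)):
        sc, pos = draw_interior()
        freqs = {}
        for p in pools:
            freqs[p] = 0.0 if rng.random() < 0.5 else round(float(rng.uniform(0.1, 0.9)), 2)
        if all(f == 0.0 for f in freqs.values()):
            freqs[pools[int(rng.integers(len(pools)))]] = 0.5
        add(sc, pos, None, "background", freqs)

    # near-intron: < 60 bp from an exon-intron junction, exercising IS60
    junctions = []
    for m in models:
        for s, e in m.introns:
            junctions.append((m.scaffold, s - 1, -1))  # exon end left of intron
            junctions.append((m.scaffold, e + 1, +1))  # exon start right of intron
    n_near = counts.get("near_intron", 0)
    if n_near and not junctions:
        raise GenerationError("near_intron variants requested but no introns exist")
    placed = 0
    ji = 0
    tries = 0
    while placed < n_near:
        if tries > max_tries:
            raise GenerationError("could not place near-intron variants")
        tries += 1
        sc, j, direction = junctions[ji % len(junctions)]
        ji += 1
        d = int(rng.integers(config.near_intron_dist[0], config.near_intron_dist[1] + 1))
        pos = j + direction * d
        if spaced_ok(sc, pos):
            add(sc, pos, None, "near_intron", shared_freqs())
            placed += 1

    # clustered pairs ≤ 60 bp apart, exercising CS60 / CS60_MAF; partner
    # frequencies cycle through common and rare so global MAF varies
    partner_freq_cycle = (0.5, 0.1, 0.05)
    for i in range(counts.get("clustered", 0)):
        for _ in range(max_tries):
            sc, anchor = draw_interior()
            gap = int(rng.integers(config.cluster_gap[0], config.cluster_gap[1] + 1))
            partner = anchor + gap
            in_slot = any(s == sc and lo <= partner <= hi for s, lo, hi in slots)
            if in_slot and spaced_ok(sc, partner, exempt=anchor):
                break
        else:
            raise GenerationError("could not place clustered pair")
        add(sc, anchor, None, "clustered", shared_freqs())
        pf = partner_freq_cycle[i % len(partner_freq_cycle)]
        add(sc, partner, None, "clustered", {p: pf for p in pools})

    for i in range(counts.get("indel", 0)):
        sc, pos = draw_interior()
        if i % 2 == 0:
            ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
            alt = "+" + ins
        else:
            alt = f"-{int(rng.integers(1, 3))}"
        add(sc, pos, alt, "indel", shared_freqs())

    truth.sort(key=lambda t: (t.scaffold, t.pos))
    return truth


def write_truth_tsv(truth: Sequence[TruthRecord], config: SimConfig,
                    path: str | Path) -> None:
    pools = config.pools()
    with open(path, "w") as fh:
        cols = ["scaffold", "pos", "ref", "alt", "class"] + [f"freq_pool{p}" for p in pools]
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            row = [t.scaffold, str(t.pos), t.ref_allele, t.alt_allele, t.vclass]
            row += [f"{t.per_pool_freq[p]:g}" for p in pools]
            fh.write("\t".join(row) + "\n")


def write_truth_vcf(truth: Sequence[TruthRecord], genome: Mapping[str, str],
                    config: SimConfig, path: str | Path) -> None:
    """Standard VCF rendering of the truth table (indels VCF-normalized)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Planted variant class">\n')
        fh.write('##INFO=<ID=PF,Number=.,Type=Float,Description="Per-pool alternate frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for t in truth:
            seq = genome[t.scaffold]
            if t.alt_allele.startswith("+"):
                ref, alt = t.ref_allele, t.ref_allele + t.alt_allele[1:]
            elif t.alt_allele.startswith("-"):
                k = int(t.alt_allele[1:])
                ref = seq[t.pos - 1:t.pos + k]
                alt = t.ref_allele
            else:
                ref, alt = t.ref_allele, t.alt_allele
            pf = ",".join(f"{t.per_pool_freq[p]:g}" for p in config.pools())
            fh.write(f"{t.scaffold}\t{t.pos}\t.\t{ref}\t{alt}\t.\t.\t"
                     f"CLASS={t.vclass};PF={pf}\n")


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimRead:
    qname: str
    scaffold: str
    pos: int        # 1-based leftmost reference position
    cigar: str
    seq: str
    quals: np.ndarray  # uint8 Phred


def _exon_intervals(models: Sequence[GeneModel]) -> list[tuple[str, int, int]]:
    return [(m.scaffold, s, e) for m in models for s, e in m.exons]


def simulate_pool_reads(genome: Mapping[str, str], models: Sequence[GeneModel],
                        truth: Sequence[TruthRecord], pool_id: int,
                        config: SimConfig) -> list[SimRead]:
    """Simulate one pool's aligned exonic reads; deterministic per (seed, pool).

    Read starts are uniform within single exons.  At each truth site a covering
    read carries the alternate allele with probability ``per_pool_freq[pool]``,
    independently per read.  Substitution errors (low-quality bases) and
    missing calls ('N', Q0) are then applied per base.
    """
    if pool_id not in config.pools():
        raise ValueError(f"pool {pool_id} not in configuration")
    depth = config.depths()[pool_id - 1]
    rng = np.random.default_rng((config.seed, 100 + pool_id))
    L = config.read_len
    reads: list[SimRead] = []
    serial = 0
    truth_by_scaffold: dict[str, list[TruthRecord]] = {}
    for t in truth:
        truth_by_scaffold.setdefault(t.scaffold, []).append(t)

    for scaffold, ex_s, ex_e in _exon_intervals(models):
        exon_len = ex_e - ex_s + 1
        n = int(rng.poisson(depth * exon_len / L)) if depth > 0 else 0
        if n == 0:
            continue
        ref = genome[scaffold]
        starts = rng.integers(0, exon_len - L + 1, size=n)  # 0-based within exon
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        exon_seq = np.frombuffer(ref[ex_s - 1:ex_e].encode(), dtype="u1")
        mat = exon_seq[starts[:, None] + np.arange(L)]

        # plant alleles at truth sites covered by this exon
        indel_rows: dict[int, TruthRecord] = {}
        for t in truth_by_scaffold.get(scaffold, []):
            if not (ex_s <= t.pos <= ex_e):
                continue
            f = t.per_pool_freq[pool_id]
            if f <= 0.0:
                continue
            rel = t.pos - ex_s
            rows = np.where((starts <= rel) & (starts > rel - L))[0]
            if rows.size == 0:
                continue
            carriers = rows[rng.random(rows.size) < f]
            if t.is_indel:
                for r in carriers:
                    indel_rows[int(r)] = t
            else:
                mat[carriers, rel - starts[carriers]] = ord(t.alt_allele)

        # substitution errors (low quality) and missing calls
        err = rng.random(mat.shape) < config.error_rate
        miss = rng.random(mat.shape) < config.missing_rate
        err &= ~miss
        lut = np.zeros(256, dtype="u1")
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        idx = lut[mat]
        shifted = (idx + rng.integers(1, 4, size=mat.shape)) % 4
        err_bases = np.frombuffer(b"ACGT", dtype="u1")[shifted]
        mat = np.where(err, err_bases, mat)
        mat = np.where(miss, ord("N"), mat)

        quals = (config.body_quality
                 + rng.integers(-config.quality_jitter, config.quality_jitter + 1,
                                size=mat.shape)).astype(np.int16)
        if config.tail_len > 0:
            ramp = np.round(np.linspace(config.tail_drop / config.tail_len,
                                        config.tail_drop, config.tail_len)).astype(np.int16)
            quals[:, L - config.tail_len:] -= ramp
        eq_lo, eq_hi = config.error_quality
        quals = np.where(err, rng.integers(eq_lo, eq_hi + 1, size=mat.shape), quals)
        quals = np.clip(quals, 2, 41)
        quals = np.where(miss, 0, quals).astype(np.uint8)

        for r in range(n):
            qname = f"pool{pool_id}_{scaffold}_{serial:07d}"
            serial += 1
            start_ref = ex_s + int(starts[r])  # 1-based
            if r in indel_rows:
                read = _make_indel_read(qname, scaffold, ref, start_ref,
                                        indel_rows[r], config, rng)
            else:
                read = SimRead(qname, scaffold, start_ref, f"{L}M",
                               mat[r].tobytes().decode(), quals[r].copy())
            reads.append(read)

    reads.sort(key=lambda rd: (rd.scaffold, rd.pos, rd.qname))
    return reads


def _make_indel_read(qname: str, scaffold: str, ref: str, start: int,
                     t: TruthRecord, config: SimConfig,
                     rng: np.random.Generator) -> SimRead:
    """Construct a single read carrying an insertion/deletion allele."""
    L = config.read_len
    off = t.pos - start  # 0-based offset of anchor within read
    if t.alt_allele.startswith("+"):
        ins = t.alt_allele[1:]
        k = len(ins)
        if off >= L - k - 1:   # anchor too close to read end: emit plain read
            seq = ref[start - 1:start - 1 + L]
            cigar = f"{L}M"
        else:
            head = ref[start - 1:t.pos]
            tail = ref[t.pos:t.pos + (L - off - 1 - k)]
            seq = head + ins + tail
            cigar = f"{off + 1}M{k}I{L - off - 1 - k}M"
    else:
        k = int(t.alt_allele[1:])
        if off >= L - 1:
            seq = ref[start - 1:start - 1 + L]
            cigar = f"{L}M"
        else:
            head = ref[start - 1:t.pos]
            tail = ref[t.pos + k:t.pos + k + (L - off - 1)]
            seq = head + tail
            cigar = f"{off + 1}M{k}D{L - off - 1}M"
    seq_arr = np.frombuffer(seq.encode(), dtype="u1").copy()
    err = rng.random(len(seq_arr)) < config.error_rate
    miss = rng.random(len(seq_arr)) < config.missing_rate
    err &= ~miss
    lut = np.zeros(256, dtype="u1")
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    shifted = (lut[seq_arr] + rng.integers(1, 4, size=len(seq_arr))) % 4
    seq_arr = np.where(err, np.frombuffer(b"ACGT", dtype="u1")[shifted], seq_arr)
    seq_arr = np.where(miss, ord("N"), seq_arr)
    quals = (config.body_quality
             + rng.integers(-config.quality_jitter, config.quality_jitter + 1,
                            size=len(seq_arr))).astype(np.int16)
    if config.tail_len > 0 and len(seq_arr) >= config.tail_len:
        ramp = np.round(np.linspace(config.tail_drop / config.tail_len,
                                    config.tail_drop, config.tail_len)).astype(np.int16)
        quals[len(seq_arr) - config.tail_len:] -= ramp
    eq_lo, eq_hi = config.error_quality
    quals = np.where(err, rng.integers(eq_lo, eq_hi + 1, size=len(seq_arr)), quals)
    quals = np.clip(quals, 2, 41)
    quals = np.where(miss, 0, quals).astype(np.uint8)
    return SimRead(qname, scaffold, start, cigar, seq_arr.tobytes().decode(), quals)


def write_sam(reads: Sequence[SimRead], genome: Mapping[str, str],
              path: str | Path) -> None:
    """Coordinate-sorted SAM, one pool per file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rd in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rd.qname
            a.query_sequence = rd.seq
            a.flag = 0
            a.reference_id = ref_ids[rd.scaffold]
            a.reference_start = rd.pos - 1
            a.mapping_quality = 60
            a.cigarstring = rd.cigar
            a.query_qualities = rd.quals.tolist()
            out.write(a)


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rd in reads:
            q = "".join(chr(33 + int(v)) for v in rd.quals)
            fh.write(f"@{rd.qname}\n{rd.seq}\n+\n{q}\n")
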