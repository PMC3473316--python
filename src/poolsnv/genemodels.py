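"""Gene models, variant-to-feature assignment and feature-stratified densities.

Gene models carry exon, CDS and UTR segments as 1-based inclusive intervals on
the forward strand of the reference (the ``strand`` field records transcription
direction but does not flip coordinates).  Introns are derived as the gaps
between consecutive exons.  Variants are assigned to CDS, then UTR, then intron
of every overlapping gene, with the distance to the nearest exon-intron
junction recorded for the intron-proximity marker filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from intervaltree import IntervalTree

Interval = tuple[int, int]  # 1-based inclusive


def _merged_length(intervals: Iterable[Interval]) -> int:
    ivs = sorted(intervals)
    total = 0
    prev_end = 0
    for s, e in ivs:
        s = max(s, prev_end + 1)
        if e >= s:
            total += e - s + 1
            prev_end = max(prev_end, e)
    return total


@dataclass
class GeneModel:
    """A protein-coding gene with exon / CDS / UTR structure."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[Interval]
    cds_segments: list[Interval]
    utr5_segments: list[Interval] = field(default_factory=list)
    utr3_segments: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        self.utr5_segments = sorted(self.utr5_segments)
        self.utr3_segments = sorted(self.utr3_segments)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        """Inter-exon gaps, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def junctions(self) -> list[int]:
        """Exonic edge positions adjacent to an intron (both sides of each intron)."""
        out = []
        for s, e in self.introns:
            out.extend((s - 1, e + 1))
        return out

    def utr_segments(self) -> list[Interval]:
        return sorted(self.utr5_segments + self.utr3_segments)

    def feature_at(self, pos: int) -> str | None:
        """CDS / UTR / intron at ``pos``, or None if outside the gene span."""
        for s, e in self.cds_segments:
            if s <= pos <= e:
                return "CDS"
        for s, e in self.utr_segments():
            if s <= pos <= e:
                return "UTR"
        for s, e in self.introns:
            if s <= pos <= e:
                return "intron"
        # inside span but outside annotated segments (should not happen for
        # well-formed models); treat as exonic-unannotated
        if self.start <= pos <= self.end:
            for s, e in self.exons:
                if s <= pos <= e:
                    return "UTR"
            return "intron"
        return None

    def dist_to_nearest_junction(self, pos: int) -> int | None:
        """Distance (bp) from ``pos`` to the nearest exon-intron junction.

        Junctions are anchored at the exonic edge base flanking each intron, so
        a variant 40 bp upstream of an exon end that adjoins an intron has
        distance 40.  ``None`` for intron-free genes.
        """
        js = self.junctions
        if not js:
            return None
        return min(abs(pos - j) for j in js)


@dataclass
class FeatureAssignment:
    scaffold: str
    pos: int
    gene_id: str | None
    feature: str  # CDS | UTR | intron | intergenic
    dist_to_nearest_intron_boundary: int | None = None


class GeneIndex:
    """Interval lookup of gene models per scaffold."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        for m in self.models:
            tree = self._trees.setdefault(m.scaffold, IntervalTree())
            # intervaltree is half-open; +1 to include the end base
            tree.addi(m.start, m.end + 1, m)

    def overlapping(self, scaffold: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=lambda m: m.gene_id)
        return hits


def load_gene_models(gff3_path: str) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` records.

    Genes whose CDS segments fall outside their exons are rejected with a
    warning.  Overlapping genes are allowed.
    """
    try:
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(gene.id):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        if not exons:
            warnings.warn(f"gene {gene.id} has no exons; skipped")
            continue
        model = GeneModel(gene.id, gene.seqid, gene.strand, exons, cds, utr5, utr3)
        ok = all(
            any(es <= cs and ce <= ee for es, ee in model.exons)
            for cs, ce in model.cds_segments
        )
        if not ok:
            warnings.warn(f"gene {gene.id}: CDS outside exons; model rejected")
            continue
        models.append(model)
    return models


def assign_feature(scaffold: str, pos: int, index: GeneIndex) -> list[FeatureAssignment]:
    """Assign one variant position to gene features.

    Returns one assignment per overlapping gene, or a single intergenic
    assignment when no gene overlaps.
    """
    genes = index.overlapping(scaffold, pos)
    if not genes:
        return [FeatureAssignment(scaffold, pos, None, "intergenic", None)]
    out = []
    for g in genes:
        feature = g.feature_at(pos) or "intergenic"
        out.append(FeatureAssignment(scaffold, pos, g.gene_id, feature,
                                     g.dist_to_nearest_junction(pos)))
    return out


def density(count: int, length_bp: int) -> float:
    """Variants per kilobase: ``count / length_bp * 1000``."""
    if length_bp <= 0:
        raise ValueError("length must be positive for a per-kb density")
    return count / length_bp * 1000.0


class CoverageMask:
    """Boolean per-position coverage mask over the reference (1-based access)."""

    def __init__(self, scaffold_lengths: Mapping[str, int]):
        self.arrays = {name: np.zeros(n, dtype=bool) for name, n in scaffold_lengths.items()}

    def add_positions(self, scaffold: str, positions: Iterable[int]) -> None:
        arr = self.arrays[scaffold]
        idx = np.fromiter((p - 1 for p in positions), dtype=np.int64)
        if idx.size:
            arr[idx] = True

    def union(self, other: "CoverageMask") -> "CoverageMask":
        out = CoverageMask({k: len(v) for k, v in self.arrays.items()})
        for k in out.arrays:
            out.arrays[k] = self.arrays[k] | other.arrays[k]
        return out

    def covered_length(self) -> int:
        return int(sum(a.sum() for a in self.arrays.values()))

    def covered_length_in(self, scaffold: str, intervals: Iterable[Interval]) -> int:
        arr = self.arrays.get(scaffold)
        if arr is None:
            return 0
        total = 0
        for s, e in intervals:
            total += int(arr[s - 1:e].sum())
        return total


@dataclass
class FeatureDensityReport:
    counts: dict[str, int]
    covered_bp: dict[str, int]
    densities_per_kb: dict[str, float]
    genes_with_variants: int
    mean_variants_per_gene: float
    mean_defined: bool


def gene_summary(
    positions: Sequence[tuple[str, int]],
    models: Sequence[GeneModel],
    mask: CoverageMask | None = None,
) -> FeatureDensityReport:
    """Feature-stratified variant counts/densities and per-gene summaries.

    ``positions`` are (scaffold, 1-based pos) of variants.  A variant
    overlapping several genes counts once per gene for the per-gene statistics
    and once in the genome-wide feature totals (classified by its first
    overlapping gene).  Densities use the ≥min-coverage mask intersected with
    feature intervals when a mask is supplied; otherwise annotated lengths.
    """
    index = GeneIndex(models)
    counts = {"CDS": 0, "UTR": 0, "intron": 0, "intergenic": 0}
    per_gene: dict[str, int] = {}
    for scaffold, pos in positions:
        assigns = assign_feature(scaffold, pos, index)
        counts[assigns[0].feature] += 1
        for a in assigns:
            if a.gene_id is not None and a.feature in ("CDS", "UTR"):
                per_gene[a.gene_id] = per_gene.get(a.gene_id, 0) + 1

    covered = {}
    for feat in ("CDS", "UTR"):
        total = 0
        for m in models:
            ivs = m.cds_segments if feat == "CDS" else m.utr_segments()
            if mask is not None:
                total += mask.covered_length_in(m.scaffold, ivs)
            else:
                total += _merged_length(ivs)
        covered[feat] = total
    dens = {f: (density(counts[f], covered[f]) if covered[f] > 0 else 0.0)
            for f in ("CDS", "UTR")}
    n_genes = len(per_gene)
    total_in_genes = sum(per_gene.values())
    mean_defined = n_genes > 0
    mean = total_in_genes / n_genes if mean_defined else 0.0
    return FeatureDensityReport(counts, covered, dens, n_genes, mean, mean_defined)
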