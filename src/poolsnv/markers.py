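"""Marker-filter cascade and genotyping-panel selection.

Filters (a *flagged* variant fails the filter):

* VKS      — the variant is an INDEL (only substitution SNPs are assayable);
* IS60     — the variant lies in an intron-containing gene closer than 60 bp
             to an exon-intron junction (primers would span the junction);
* CS60     — another SNV sits within ±60 bp on the same scaffold;
* CS60_MAF(t) — like CS60 but only flanking SNVs whose global MAF is *below*
             ``t`` flag the variant; rare flanking variants (MAF ≥ t) are
             tolerated, so lowering t enlarges the pass set monotonically.

"Closer than 60 bp" is read strictly: distance < 60 flags, distance = 60
passes.  Panel selection draws a reproducible random subset of the candidates
satisfying within/between-pool monomorphism/differential criteria.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import INDEL, POLYMORPHIC, VariantRecord
from .genemodels import GeneIndex, assign_feature


# ---------------------------------------------------------------------------
# flags

def flag_vks(record: VariantRecord) -> bool:
    return record.kind == INDEL


def flag_is60(record: VariantRecord, index: GeneIndex, window: int = 60) -> bool:
    """Flag variants closer than ``window`` bp to an exon-intron junction.

    A variant overlapping several genes is flagged if it is junction-proximal
    in any of them.  Intergenic variants and variants in intron-free genes are
    never flagged.
    """
    for a in assign_feature(record.scaffold, record.pos, index):
        if a.gene_id is None:
            continue
        d = a.dist_to_nearest_intron_boundary
        if d is not None and d < window:
            return True
    return False


def cs60_maf_flags(records: Sequence[VariantRecord], window: int = 60,
                   t: float | None = None) -> dict[tuple[str, int], bool]:
    """CS60 / CS60_MAF(t) flags for a whole variant table.

    A variant is flagged when any *other* SNV (SNPs and INDELs both disturb
    primer design) within ±window bp on the same scaffold has global MAF below
    ``t``.  ``t=None`` (or 1.0 with all-polymorphic neighbours) reproduces the
    plain CS60 filter where any neighbour flags.
    """
    by_scaffold: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_scaffold.setdefault(r.scaffold, []).append(r)
    flags: dict[tuple[str, int], bool] = {}
    for scaffold, recs in by_scaffold.items():
        recs.sort(key=lambda r: r.pos)
        positions = [r.pos for r in recs]
        for i, r in enumerate(recs):
            lo = bisect_left(positions, r.pos - window)
            hi = bisect_right(positions, r.pos + window)
            flagged = False
            for j in range(lo, hi):
                if j == i:
                    continue
                if t is None or recs[j].global_maf < t:
                    flagged = True
                    break
            flags[r.key] = flagged
    return flags


def flag_cs60_maf(record: VariantRecord, records: Sequence[VariantRecord],
                  window: int = 60, t: float | None = None) -> bool:
    """Single-variant convenience wrapper over :func:`cs60_maf_flags`."""
    return cs60_maf_flags(records, window, t)[record.key]


# ---------------------------------------------------------------------------
# filter table (pass counts per combination)

def filter_table(records: Sequence[VariantRecord], index: GeneIndex,
                 thresholds: Sequence[float | None] = (None, 0.99, 0.95, 0.7),
                 pools: Sequence[int] | None = None,
                 window: int = 60) -> pd.DataFrame:
    """Counts of SNPs passing filter combinations, one row per MAF threshold.

    Columns: SNPs passing CS60_MAF(t) alone; additionally passing IS60 (with
    percentage of the SNP total); additionally polymorphic in all pools.
    INDELs are removed first (VKS).
    """
    snps = [r for r in records if not flag_vks(r)]
    n_total = len(snps)
    is60 = {r.key: flag_is60(r, index, window) for r in snps}
    rows = []
    for t in thresholds:
        cs = cs60_maf_flags(records, window, t)  # neighbours include INDELs
        pass_cs = [r for r in snps if not cs[r.key]]
        pass_both = [r for r in pass_cs if not is60[r.key]]
        row = {
            "maf_threshold": "CS60" if t is None else f"{t:g}",
            "no_cs60_maf": len(pass_cs),
            "no_cs60_maf_no_is60": len(pass_both),
            "pct_no_cs60_maf_no_is60": round(100.0 * len(pass_both) / n_total, 2)
            if n_total else 0.0,
        }
        if pools is not None:
            row["variable_in_all_pools"] = sum(
                1 for r in pass_both
                if all(r.status(p) == POLYMORPHIC for p in pools))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# panel selection

@dataclass(frozen=True)
class PanelCriteria:
    """Within/between-pool criteria for a genotyping panel.

    ``polymorphic_between`` pairs require a fixed difference between the two
    pools (so the marker segregates in crosses between the groups);
    ``monomorphic_within`` pools must each show a single supported allele.
    """

    monomorphic_within: tuple[int, ...] = ()
    polymorphic_between: tuple[tuple[int, int], ...] = ()
    maf_max: float | None = None
    cs60_maf_t: float | None = None
    n_select: int = 0
    seed: int = 0


def panel_candidates(records: Sequence[VariantRecord], index: GeneIndex,
                     criteria: PanelCriteria, window: int = 60) -> list[VariantRecord]:
    """All filter-passing variants satisfying the panel criteria."""
    cs = cs60_maf_flags(records, window, criteria.cs60_maf_t)
    out = []
    for r in records:
        if flag_vks(r) or cs[r.key] or flag_is60(r, index, window):
            continue
        if criteria.maf_max is not None and r.global_maf >= criteria.maf_max:
            continue
        if any(r.fixed_allele(p) is None for p in criteria.monomorphic_within):
            continue
        ok = True
        for a, b in criteria.polymorphic_between:
            fa, fb = r.fixed_allele(a), r.fixed_allele(b)
            if fa is None or fb is None or fa == fb:
                ok = False
                break
        if ok:
            out.append(r)
    return out


def select_panel(records: Sequence[VariantRecord], index: GeneIndex,
                 criteria: PanelCriteria, window: int = 60) -> list[VariantRecord]:
    """Draw ``n_select`` candidates uniformly without replacement (seeded)."""
    candidates = panel_candidates(records, index, criteria, window)
    n = criteria.n_select
    if n == 0 or n >= len(candidates):
        if n > len(candidates):
            warnings.warn(f"requested {n} panel members but only "
                          f"{len(candidates)} candidates; returning all")
        return candidates
    rng = np.random.default_rng(criteria.seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def panel_table(selected: Sequence[VariantRecord],
                pools: Sequence[int]) -> pd.DataFrame:
    rows = []
    for r in selected:
        freqs = _global_allele_freqs(r)
        rows.append({
            "scaffold": r.scaffold, "pos": r.pos, "alleles": "/".join(r.alleles),
            "global_maf": round(r.global_maf, 4),
            "pic": round(pic(list(freqs.values())), 4),
            **{f"status_pool{p}": r.status(p) for p in pools},
        })
    return pd.DataFrame(rows)


def _global_allele_freqs(record: VariantRecord) -> dict[str, float]:
    totals: dict[str, int] = {}
    for depths in record.pool_depths.values():
        if depths:
            for a, d in depths.items():
                totals[a] = totals.get(a, 0) + d
    grand = sum(totals.values())
    return {a: d / grand for a, d in totals.items()}


# ---------------------------------------------------------------------------
# marker statistics

def pic(frequencies: Sequence[float]) -> float:
    """Polymorphism information content: 1 - Σp_i² - Σ_{i<j} 2 p_i² p_j²."""
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0):
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must sum to 1")
    sq = p ** 2
    cross = (sq.sum() ** 2 - (sq ** 2).sum()) / 2.0  # Σ_{i<j} p_i² p_j²
    return float(1.0 - sq.sum() - 2.0 * cross)


def validation_ratio(n_assayed: int, n_monomorphic: int) -> float:
    """Percentage of assayed markers confirmed polymorphic, to the nearest
    whole percent (monomorphic assays count as failures)."""
    if n_assayed <= 0:
        raise ValueError("need at least one assayed marker")
    return round(100.0 * (n_assayed - n_monomorphic) / n_assayed)
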