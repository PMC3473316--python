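"""Per-pool diversity statistics and pairwise pool comparisons.

A site is *shared* between two pools when it is polymorphic within both; it is
*fixed-differential* when each pool shows exactly one supported allele and the
two alleles differ.  Pools without ≥min-coverage at a position are excluded
from that position's pairwise statistics.  The major allele frequency (MAF) of
a pool at a site is the depth of its most frequent supported allele over the
pool's total supported depth, so MAF lives in (0, 1] and lower MAF means
higher within-pool variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calling import POLYMORPHIC, SNP, PoolProfile, VariantRecord


def pool_maf(allele_depths: Mapping[str, int]) -> float:
    """Major allele frequency from one pool's supported allele depths."""
    total = sum(allele_depths.values())
    if total <= 0:
        raise ValueError("MAF undefined at zero depth")
    return max(allele_depths.values()) / total


def maf_histogram(mafs: Iterable[float], bin_width: float = 0.05) -> "pd.Series":
    """Right-closed bins over [0.5, 1.0]; the first bin also includes 0.5.

    Values below 0.5 (possible only for >2-allele sites) are clamped into the
    first bin so the histogram mass equals the site count.
    """
    edges = np.round(np.arange(0.5, 1.0 + bin_width / 2, bin_width), 10)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins, dtype=int)
    for v in mafs:
        if v <= edges[0]:
            idx = 0
        else:
            # right-closed: a value equal to an edge belongs to the bin ending there
            idx = min(max(int(np.searchsorted(edges, v, side="left")) - 1, 0), n_bins - 1)
        counts[idx] += 1
    labels = [f"({edges[i]:.2f},{edges[i+1]:.2f}]" for i in range(n_bins)]
    labels[0] = f"[{edges[0]:.2f},{edges[1]:.2f}]"
    return pd.Series(counts, index=labels, name="n_snps")


def high_variability_fraction(mafs: Sequence[float],
                              threshold: float = 0.7) -> tuple[int, float]:
    """Count and percentage (one decimal) of sites with MAF below threshold."""
    mafs = list(mafs)
    n = sum(1 for v in mafs if v < threshold)
    pct = round(100.0 * n / len(mafs), 1) if mafs else 0.0
    return n, pct


def _pool_polymorphic_keys(records: Sequence[VariantRecord], pool_id: int,
                           kind: str | None = SNP) -> set[tuple[str, int]]:
    return {r.key for r in records
            if r.status(pool_id) == POLYMORPHIC and (kind is None or r.kind == kind)}


class SharedCount(NamedTuple):
    count: int
    pct_of_a: float
    pct_of_b: float


def pairwise_shared(records: Sequence[VariantRecord], pool_a: int, pool_b: int,
                    kind: str | None = SNP) -> SharedCount:
    """Sites polymorphic within both pools, plus the two per-pool percentages."""
    if pool_a == pool_b:
        raise ValueError("pairwise_shared requires two distinct pools")
    set_a = _pool_polymorphic_keys(records, pool_a, kind)
    set_b = _pool_polymorphic_keys(records, pool_b, kind)
    n = len(set_a & set_b)
    pct_a = round(100.0 * n / len(set_a), 1) if set_a else 0.0
    pct_b = round(100.0 * n / len(set_b), 1) if set_b else 0.0
    return SharedCount(n, pct_a, pct_b)


def pairwise_fixed_differential(records: Sequence[VariantRecord],
                                pool_a: int, pool_b: int,
                                kind: str | None = SNP) -> int:
    """Sites fixed within each pool with different alleles between the two."""
    n = 0
    for r in records:
        if kind is not None and r.kind != kind:
            continue
        a = r.fixed_allele(pool_a)
        b = r.fixed_allele(pool_b)
        if a is not None and b is not None and a != b:
            n += 1
    return n


def shared_across_all(records: Sequence[VariantRecord], pools: Sequence[int],
                      kind: str | None = SNP) -> int:
    """Sites polymorphic in every listed pool."""
    if len(pools) < 2:
        raise ValueError("need at least two pools")
    sets = [_pool_polymorphic_keys(records, p, kind) for p in pools]
    return len(set.intersection(*sets))


@dataclass
class DiversitySummary:
    table: pd.DataFrame          # one row per pool (Table-2-like layout)
    histograms: pd.DataFrame     # long format: pool, bin, n_snps


def summarize_pools(records: Sequence[VariantRecord],
                    profiles: Sequence[PoolProfile],
                    maf_threshold: float = 0.7,
                    bin_width: float = 0.05) -> DiversitySummary:
    """Per-pool SNP counts, densities and MAF-distribution statistics."""
    rows = []
    hist_rows = []
    for prof in profiles:
        pid = prof.pool_id
        mafs = [r.pool_maf[pid] for r in records
                if r.kind == SNP and r.status(pid) == POLYMORPHIC]
        n_snps = len(mafs)
        n_low, pct_low = high_variability_fraction(mafs, maf_threshold)
        dens = (n_snps / prof.covered_length_bp * 1000.0
                if prof.covered_length_bp else 0.0)
        rows.append({
            "pool": pid,
            "covered_length_bp": prof.covered_length_bp,
            "n_snps": n_snps,
            "snps_per_kb": round(dens, 1),
            "n_maf_below_threshold": n_low,
            "pct_maf_below_threshold": pct_low,
        })
        hist = maf_histogram(mafs, bin_width)
        for label, count in hist.items():
            hist_rows.append({"pool": pid, "maf_bin": label, "n_snps": count})
    return DiversitySummary(pd.DataFrame(rows), pd.DataFrame(hist_rows))


def pairwise_matrix(records: Sequence[VariantRecord],
                    pools: Sequence[int], kind: str | None = SNP) -> pd.DataFrame:
    """Square pool matrix: shared counts above the diagonal, fixed-differential
    counts below (Table-3-like layout)."""
    labels = [f"pool{p}" for p in pools]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i, a in enumerate(pools):
        for j, b in enumerate(pools):
            if i < j:
                mat.iloc[i, j] = pairwise_shared(records, a, b, kind).count
            elif i > j:
                mat.iloc[i, j] = pairwise_fixed_differential(records, a, b, kind)
    return mat
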