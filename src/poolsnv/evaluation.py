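"""Truth-aware evaluation of a synthetic pipeline run.

Compares the merged variant table against the planted truth: detection recall
and precision, per-pool MAF calibration against binomial sampling noise, and
recovery rates of the pool-structured variant classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .calling import POLYMORPHIC, VariantRecord
from .simulate import SimConfig, TruthRecord

RECALL_FREQ_BAND = (0.2, 0.8)


def _recall_eligible(t: TruthRecord) -> bool:
    """Planted sites the caller is expected to find: fixed differentials, plus
    any site polymorphic at a workable frequency (0.2-0.8) in some pool."""
    lo, hi = RECALL_FREQ_BAND
    if t.vclass == "fixed_differential":
        return True
    return any(lo <= f <= hi for f in t.per_pool_freq.values())


@dataclass
class RecallPrecision:
    n_eligible: int
    n_recovered: int
    n_called: int
    n_true_positive: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else float("nan")

    @property
    def precision(self) -> float:
        return self.n_true_positive / self.n_called if self.n_called else float("nan")


def recall_precision(truth: Sequence[TruthRecord],
                     records: Sequence[VariantRecord]) -> RecallPrecision:
    truth_keys = {(t.scaffold, t.pos) for t in truth}
    called_keys = {r.key for r in records}
    eligible = [t for t in truth if _recall_eligible(t)]
    recovered = sum(1 for t in eligible if (t.scaffold, t.pos) in called_keys)
    tp = len(called_keys & truth_keys)
    return RecallPrecision(len(eligible), recovered, len(called_keys), tp)


def maf_calibration(truth: Sequence[TruthRecord],
                    records: Sequence[VariantRecord],
                    n_sd: float = 3.0) -> tuple[int, int]:
    """(within, total) over (site, pool) pairs with planted 0 < freq < 1:
    is the estimated pool MAF within ``n_sd`` binomial standard deviations of
    the planted major-allele frequency, at the observed pool depth?"""
    by_key = {r.key: r for r in records}
    within = total = 0
    for t in truth:
        rec = by_key.get((t.scaffold, t.pos))
        if rec is None:
            continue
        for pool, f in t.per_pool_freq.items():
            if not (0.0 < f < 1.0):
                continue
            est = rec.pool_maf.get(pool)
            depths = rec.pool_depths.get(pool)
            if est is None or not depths:
                continue
            n = sum(depths.values())
            m = max(f, 1.0 - f)
            sd = math.sqrt(m * (1.0 - m) / n)
            total += 1
            if abs(est - m) <= n_sd * sd:
                within += 1
    return within, total


def class_recovery(truth: Sequence[TruthRecord],
                   records: Sequence[VariantRecord],
                   config: SimConfig) -> dict[str, tuple[int, int]]:
    """(recovered, planted) per pool-structured class.

    shared_all: reported polymorphic in every pool; pool_specific: polymorphic
    in its designated pool; fixed_differential: fixed with differing alleles
    between its designated pool pair.
    """
    by_key = {r.key: r for r in records}
    pools = config.pools()
    out: dict[str, list[int]] = {
        "shared_all": [0, 0], "pool_specific": [0, 0], "fixed_differential": [0, 0],
    }
    for t in truth:
        if t.vclass not in out:
            continue
        out[t.vclass][1] += 1
        rec = by_key.get((t.scaffold, t.pos))
        if t.vclass == "fixed_differential":
            # the designated pair is the one whose first pool carries freq 1.0
            pair = next(((a, b) for a, b in config.differential_pairs
                         if t.per_pool_freq.get(a) == 1.0
                         and t.per_pool_freq.get(b) == 0.0), None)
            if rec is not None and pair is not None:
                fa, fb = rec.fixed_allele(pair[0]), rec.fixed_allele(pair[1])
                if fa is not None and fb is not None and fa != fb:
                    out[t.vclass][0] += 1
            continue
        if rec is None:
            continue
        if t.vclass == "shared_all":
            if all(rec.status(p) == POLYMORPHIC for p in pools):
                out[t.vclass][0] += 1
        elif t.vclass == "pool_specific":
            target = t.polymorphic_pools()
            if target and rec.status(target[0]) == POLYMORPHIC:
                out[t.vclass][0] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}
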