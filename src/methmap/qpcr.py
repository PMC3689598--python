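"""Digestion-resistance q-PCR quantification and the between-stage test.

The marked (digestion-resistant) proportion of a locus is estimated from
paired threshold cycles of a sensitive-enzyme-digested aliquot and an
undigested aliquot of equal input mass: dCt = Ct_digested - Ct_undigested
and, assuming perfect doubling per cycle, resistant_fraction =
efficiency**(-dCt), clamped to [0, 1] (a negative dCt is flagged as
out-of-range noise). Stages are compared per target with an exact two-sided
Wilcoxon rank-sum test over the replicate pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _sstats


@dataclass(frozen=True)
class QpcrRecord:
    target: str
    stage: str
    pool: str
    ct_digested: float
    ct_undigested: float

    def __post_init__(self) -> None:
        if self.ct_digested <= 0 or self.ct_undigested <= 0:
            raise ValueError("cycle values must be positive")


@dataclass(frozen=True)
class ResistanceEstimate:
    target: str
    stage: str
    pool: str
    delta_ct: float
    resistant_fraction: float
    flag_out_of_range: bool


def resistance(record: QpcrRecord, efficiency: float = 2.0) -> ResistanceEstimate:
    """Marked proportion from one digested/undigested Ct pair."""
    delta = record.ct_digested - record.ct_undigested
    raw = efficiency ** (-delta)
    return ResistanceEstimate(record.target, record.stage, record.pool,
                              delta, min(raw, 1.0), raw > 1.0)


def wilcoxon_exact(group_a: Sequence[float], group_b: Sequence[float],
                   max_exact_n: int = 12) -> float:
    """Exact two-sided rank-sum p-value.

    Enumerates all C(n, n_a) assignments of the pooled mid-ranks; the
    two-sided p is the doubled smaller tail, capped at 1. For combined n
    beyond ``max_exact_n`` a normal approximation is used with a warning.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    n_a, n = len(a), len(a) + len(b)
    pooled = a + b
    ranks = _sstats.rankdata(pooled)  # mid-ranks for ties
    w_obs = float(np.sum(ranks[:n_a]))
    if n > max_exact_n:
        warnings.warn(f"combined n={n} too large for exact enumeration; "
                      "using the normal approximation", stacklevel=2)
        return float(_sstats.mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic").pvalue)
    total = comb(n, n_a)
    lo = hi = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        w = float(np.sum(ranks[list(idx)]))
        if w <= w_obs + eps:
            lo += 1
        if w >= w_obs - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


@dataclass
class StageComparison:
    target: str
    stage_means: Dict[str, float]
    p_value: float
    significant: bool
    letters: Dict[str, str]


def compare_stages(estimates: Sequence[ResistanceEstimate], alpha: float = 0.05
                   ) -> List[StageComparison]:
    """Per-target two-stage comparison of resistant fractions.

    Requires >=2 replicate pools per stage per target (insufficient
    replication is reported as an error, never silently skipped).
    Significance letter groups: stages share a letter when not
    distinguishable at ``alpha``.
    """
    by_target: Dict[str, Dict[str, List[float]]] = {}
    for e in estimates:
        by_target.setdefault(e.target, {}).setdefault(e.stage, []).append(
            e.resistant_fraction)
    out: List[StageComparison] = []
    for target in sorted(by_target):
        stages = sorted(by_target[target])
        if len(stages) != 2:
            raise ValueError(f"target {target}: expected two stages, got {stages}")
        a, b = (by_target[target][s] for s in stages)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"target {target}: needs >=2 replicate pools per stage "
                             f"(got {len(a)} and {len(b)})")
        p = wilcoxon_exact(a, b)
        sig = p < alpha
        letters = {stages[0]: "a", stages[1]: "b" if sig else "a"}
        out.append(StageComparison(
            target, {stages[0]: float(np.mean(a)), stages[1]: float(np.mean(b))},
            p, sig, letters))
    return out


def read_qpcr_csv(path) -> List[QpcrRecord]:
    """Read a q-PCR table (CSV: target,stage,pool,ct_digested,ct_undigested)."""
    records: List[QpcrRecord] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                header = [p.lower() for p in parts]
                expected = ["target", "stage", "pool", "ct_digested", "ct_undigested"]
                if header != expected:
                    raise ValueError(f"{path}:{lineno}: header must be "
                                     f"{','.join(expected)}")
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            records.append(QpcrRecord(parts[0], parts[1], parts[2],
                                      float(parts[3]), float(parts[4])))
    return records
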