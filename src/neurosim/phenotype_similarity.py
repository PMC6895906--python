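"""Relating similarity layers to phenotype (DMN-style) scores.

Three operations close the loop between genotype-derived similarity and
phenotype similarity:

* :func:`average_phenotype` — a disease pair with several matchings in the
  phenotype resource gets the arithmetic mean of its scores;
* :func:`correlate` — Pearson or Spearman correlation (two-sided p) between
  a similarity measure (proportion of shared genes, or a profile distance)
  and the averaged phenotype score over the pairs present in both;
* :func:`group_compare` — the three-group contrast of ranked pairs: the k
  pairs with the lowest distance, a stated middle rank range, and the k
  highest, compared by per-group mean phenotype score with Welch two-sample
  t-tests between the groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import InputError, PhenotypeScoreTable, pair_key


@dataclass(frozen=True)
class PairedScore:
    pair: tuple[str, str]
    similarity_value: float
    dmn_score: float


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    n: int
    n_dropped: int = 0


@dataclass
class GroupComparison:
    group_defs: dict[str, tuple[int, int]]  # group -> inclusive 1-based rank range
    group_sizes: dict[str, int]
    group_means: dict[str, float]
    t_p_values: dict[tuple[str, str], float]


def average_phenotype(table: PhenotypeScoreTable) -> dict[tuple[str, str], float]:
    """Arithmetic mean score per unordered pair (order-swapped rows pooled)."""
    if not table.entries:
        raise InputError("phenotype score table is empty")
    acc: dict[tuple[str, str], list[float]] = {}
    for a, b, s in table.entries:
        acc.setdefault(pair_key(a, b), []).append(s)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def pair_scores(similarity: Mapping[tuple[str, str], float],
                dmn: Mapping[tuple[str, str], float]
                ) -> tuple[list[PairedScore], int]:
    """Join a similarity map with averaged phenotype scores on the pair key.

    Pairs missing from either side, or with an undefined (NaN) similarity
    value, are dropped; the dropped count is returned so the retained n is
    always reportable.
    """
    paired: list[PairedScore] = []
    dropped = 0
    for pair, value in sorted(similarity.items()):
        k = pair_key(*pair)
        if k not in dmn or not np.isfinite(value):
            dropped += 1
            continue
        paired.append(PairedScore(pair=k, similarity_value=float(value),
                                  dmn_score=float(dmn[k])))
    return paired, dropped


def correlate(paired: Sequence[PairedScore], method: str = "pearson",
              n_dropped: int = 0) -> CorrelationResult:
    """Correlation between similarity values and phenotype scores."""
    if method not in ("pearson", "spearman"):
        raise InputError(f"method must be 'pearson' or 'spearman', got {method!r}")
    finite = [p for p in paired if np.isfinite(p.similarity_value)]
    n_dropped += len(paired) - len(finite)
    if len(finite) < 3:
        raise InputError(f"need at least 3 complete pairs, got {len(finite)}")
    x = np.array([p.similarity_value for p in finite])
    y = np.array([p.dmn_score for p in finite])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance in one of the correlated vectors")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    else:
        r = stats.spearmanr(x, y)
    return CorrelationResult(method=method, coefficient=float(r.statistic),
                             p_value=float(r.pvalue), n=len(finite),
                             n_dropped=n_dropped)


def group_compare(ranked: Sequence[tuple[tuple[str, str], float]], k: int = 20,
                  mid: tuple[int, int] = (21, 51)) -> GroupComparison:
    """Three-group phenotype comparison of distance-ranked pairs.

    ``ranked`` is (pair, phenotype score) in ascending-distance order.
    Groups: ranks 1..k (lowest distance), the inclusive 1-based range
    ``mid``, and the k highest-distance pairs.  Group definitions must be
    disjoint.  Welch t-tests compare every pair of groups.
    """
    n = len(ranked)
    lo, hi = mid
    if k < 1 or lo > hi:
        raise InputError("invalid group definition")
    if lo <= k or hi > n - k:
        raise InputError(
            f"overlapping group definitions: k={k}, mid={mid}, n={n}")
    defs = {"lowest": (1, k), "middle": (lo, hi), "highest": (n - k + 1, n)}
    scores = [s for _, s in ranked]
    groups = {name: np.array(scores[a - 1:b]) for name, (a, b) in defs.items()}
    means = {name: float(np.mean(v)) for name, v in groups.items()}
    tps: dict[tuple[str, str], float] = {}
    names = list(defs)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            t = stats.ttest_ind(groups[g1], groups[g2], equal_var=False)
            tps[(g1, g2)] = float(t.pvalue)
    return GroupComparison(group_defs=defs,
                           group_sizes={name: len(v) for name, v in groups.items()},
                           group_means=means, t_p_values=tps)
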