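"""Pairwise genetic similarity of diseases from shared genes or mutations.

For each unordered disease pair the screen builds the 2×2 membership table
over the gene universe

    a = |A ∩ B|        b = |A \\ B|
    c = |B \\ A|       d = |U \\ (A ∪ B)|

and tests independence of the two memberships with a Pearson chi-square on
1 df (no continuity correction by default).  Alongside the test the screen
reports the proportion of shared genes, |A ∩ B| / min(|A|, |B|), the
similarity measure later correlated with phenotype scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_model import DiseaseGeneCatalog, InputError


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairSimilarity:
    disease_a: str
    disease_b: str
    n_a: int
    n_b: int
    n_overlap: int
    chi2_stat: float
    chi2_p: float
    proportion_shared: float
    level: str = "gene"
    degenerate: bool = False


def enumerate_pairs(diseases: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n,2) unordered pairs, lexicographically ordered, no self-pairs."""
    if len(diseases) < 2:
        raise InputError(f"need at least 2 diseases, got {len(diseases)}")
    if len(set(diseases)) != len(diseases):
        raise InputError("duplicate disease names")
    ordered = sorted(diseases)
    return [(a, b) for i, a in enumerate(ordered) for b in ordered[i + 1:]]


def shared_set_test(set_a: Iterable[str], set_b: Iterable[str],
                    universe: Iterable[str], yates: bool = False) -> Chi2Result:
    """Pearson chi-square (1 df, upper tail) for shared membership of two sets.

    A zero row or column margin (either set empty, or either set equal to
    the universe) makes the table degenerate: statistic 0, p = 1, flagged.
    """
    A, B, U = frozenset(set_a), frozenset(set_b), frozenset(universe)
    if not A <= U or not B <= U:
        raise InputError("sets must be subsets of the universe")
    if len(U) < 2:
        raise InputError("universe must contain at least 2 genes")
    n = len(U)
    a = len(A & B)
    b = len(A) - a
    c = len(B) - a
    d = n - a - b - c
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return Chi2Result(0.0, 1.0, degenerate=True)
    expected = np.outer(rows, cols) / n
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev ** 2 / expected))
    return Chi2Result(stat, float(stats.chi2.sf(stat, df=1)))


def proportion_shared(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Overlap divided by the smaller set size, in [0, 1]."""
    A, B = frozenset(set_a), frozenset(set_b)
    if not A or not B:
        raise InputError("proportion_shared needs two non-empty sets")
    return len(A & B) / min(len(A), len(B))


def similarity_screen(catalog: DiseaseGeneCatalog, level: str = "gene",
                      alpha: float = 0.05,
                      universe: Iterable[str] | None = None,
                      yates: bool = False
                      ) -> tuple[list[PairSimilarity], int]:
    """Chi-square screen over all disease pairs of a catalog.

    The test universe defaults to the union of the catalog's gene sets
    (pass ``universe=catalog.universe`` or a genome-wide list to widen it).
    Returns the per-pair results (lexicographic pair order) and the number
    of pairs with p < ``alpha``.
    """
    if not 0 < alpha <= 1:
        raise InputError(f"alpha must be in (0, 1], got {alpha}")
    U = frozenset(universe) if universe is not None else catalog.union
    results: list[PairSimilarity] = []
    n_sig = 0
    for a, b in enumerate_pairs(catalog.diseases):
        A, B = catalog.gene_sets[a], catalog.gene_sets[b]
        chi = shared_set_test(A, B, U, yates=yates)
        res = PairSimilarity(
            disease_a=a, disease_b=b, n_a=len(A), n_b=len(B),
            n_overlap=len(A & B), chi2_stat=chi.statistic, chi2_p=chi.p_value,
            proportion_shared=proportion_shared(A, B), level=level,
            degenerate=chi.degenerate)
        if res.chi2_p < alpha:
            n_sig += 1
        results.append(res)
    return results, n_sig
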