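"""Enrichment of disease gene sets in contexts (cell types or brain regions).

For a disease gene set G1 and a context marker set G2 over a background of
N genes, enrichment is summarized two ways:

* the enrichment score  N_over / (N_G1 × N_G2)  — the shared-gene count
  normalized by the product of the two set sizes;
* a two-tailed Fisher exact test on the 2×2 membership table, two-tailed by
  the minimum-likelihood rule (sum of all hypergeometric outcomes no more
  probable than the observed one).  A context is called enriched when the
  FET p-value is below alpha; no multiple-testing correction is applied to
  the context family (a BH-adjusted column is available for users).

One profile per disease — the vector of records across all contexts in
catalog order — is the object later fed to the profile distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import DiseaseGeneCatalog, InputError, MarkerCatalog


@dataclass(frozen=True)
class EnrichmentRecord:
    disease: str
    context: str
    n_over: int
    n_g1: int
    n_g2: int
    score: float
    fet_p: float
    significant: bool
    degenerate: bool = False


@dataclass
class EnrichmentProfile:
    disease: str
    contexts: list[str]
    records: list[EnrichmentRecord]

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records], dtype=float)

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([r.fet_p for r in self.records], dtype=float)

    @property
    def significant(self) -> np.ndarray:
        return np.array([r.significant for r in self.records], dtype=bool)


def enrichment_score(n_over: int, n_g1: int, n_g2: int) -> float:
    """Overlap count divided by the product of the two set sizes."""
    if n_g1 < 1 or n_g2 < 1:
        raise InputError("both gene sets must be non-empty")
    if not 0 <= n_over <= min(n_g1, n_g2):
        raise InputError(
            f"overlap {n_over} impossible for set sizes {n_g1}, {n_g2}")
    return n_over / (n_g1 * n_g2)


def fisher_two_tail(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise InputError("table cells must be non-negative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_enrichment(disease_genes, marker_genes, background) -> float:
    """Two-tailed FET p for disease-set × marker-set membership over a background.

    The disease set must be non-empty and both sets must lie inside the
    background.  An empty marker set is degenerate and returns p = 1.
    """
    G1, G2, bg = frozenset(disease_genes), frozenset(marker_genes), frozenset(background)
    if not G1:
        raise InputError("disease gene set is empty")
    if not G1 <= bg or not G2 <= bg:
        raise InputError("gene sets must be subsets of the background")
    if not G2:
        return 1.0
    a = len(G1 & G2)
    b = len(G1) - a
    c = len(G2) - a
    d = len(bg) - a - b - c
    return fisher_two_tail(a, b, c, d)


def build_profiles(catalog: DiseaseGeneCatalog, markers: MarkerCatalog,
                   alpha: float = 0.05) -> list[EnrichmentProfile]:
    """One enrichment profile per disease over every context of the catalog.

    Disease genes are first intersected with the marker background (the
    enrichment universe); a disease with no genes in the background yields
    an all-zero profile with a warning.  Context order is identical across
    profiles.
    """
    if not 0 < alpha <= 1:
        raise InputError(f"alpha must be in (0, 1], got {alpha}")
    profiles: list[EnrichmentProfile] = []
    bg = markers.background
    for disease in catalog.diseases:
        genes = catalog.gene_sets[disease] & bg
        records: list[EnrichmentRecord] = []
        if not genes:
            warnings.warn(
                f"disease {disease!r} has no genes in the enrichment background; "
                f"profile is all zeros", stacklevel=2)
        for context in markers.contexts:
            mset = markers.marker_sets[context]
            if not genes or not mset:
                records.append(EnrichmentRecord(
                    disease=disease, context=context, n_over=0,
                    n_g1=len(genes), n_g2=len(mset), score=0.0, fet_p=1.0,
                    significant=False, degenerate=True))
                continue
            n_over = len(genes & mset)
            p = fisher_enrichment(genes, mset, bg)
            records.append(EnrichmentRecord(
                disease=disease, context=context, n_over=n_over,
                n_g1=len(genes), n_g2=len(mset),
                score=enrichment_score(n_over, len(genes), len(mset)),
                fet_p=p, significant=bool(p < alpha)))
        profiles.append(EnrichmentProfile(disease=disease,
                                          contexts=list(markers.contexts),
                                          records=records))
    return profiles


def _matrix(profiles: list[EnrichmentProfile], attr: str) -> pd.DataFrame:
    if not profiles:
        raise InputError("no profiles")
    contexts = profiles[0].contexts
    for p in profiles:
        if p.contexts != contexts:
            raise InputError("profiles have inconsistent context order")
    return pd.DataFrame([getattr(p, attr) for p in profiles],
                        index=[p.disease for p in profiles], columns=contexts)


def score_matrix(profiles: list[EnrichmentProfile]) -> pd.DataFrame:
    return _matrix(profiles, "scores")


def pvalue_matrix(profiles: list[EnrichmentProfile]) -> pd.DataFrame:
    return _matrix(profiles, "pvalues")


def significance_matrix(profiles: list[EnrichmentProfile]) -> pd.DataFrame:
    """Disease × context boolean matrix (the star matrix of enrichment plots)."""
    return _matrix(profiles, "significant")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (for the optional user column)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float))
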