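"""Merging of the curated and ClinVar-style mutation catalogs.

The merged dataset keeps one record per (mutation key, disease), where the
mutation key is (chrom, pos, ref, alt) — the same variant recorded for two
diseases counts once in the mutation totals but contributes to both disease
gene sets.  :class:`MergeSummary` carries the inclusion–exclusion accounting
at both the mutation and gene level, plus the split of genes linked to one
vs several diseases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .io_model import DiseaseGeneCatalog, InputError, MutationRecord


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MergeSummary:
    n_mut_curated: int
    n_mut_clinvar: int
    n_mut_shared: int
    n_mut_union: int
    n_gene_curated: int
    n_gene_clinvar: int
    n_gene_shared: int
    n_gene_union: int
    ratio_mut: float
    ratio_gene: float
    n_gene_multi: int
    n_gene_single: int

    def check(self) -> None:
        assert self.n_mut_union == (
            self.n_mut_curated + self.n_mut_clinvar - self.n_mut_shared)
        assert self.n_gene_union == (
            self.n_gene_curated + self.n_gene_clinvar - self.n_gene_shared)
        assert self.n_gene_multi + self.n_gene_single == self.n_gene_union

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, getattr(self, k)) for k in self.__dataclass_fields__]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def merge_catalogs(curated: Sequence[MutationRecord],
                   clinvar: Sequence[MutationRecord]
                   ) -> tuple[list[MutationRecord], MergeSummary]:
    """Combine two mutation catalogs into one de-duplicated dataset.

    All records must share one genome build.  Returns the merged records
    (one per mutation-key × disease, source set to ``both`` where the key
    occurs in both inputs) and the accounting summary.  Count ratios
    (curated / clinvar) are rounded half-up to one decimal.
    """
    builds = {r.build for r in curated} | {r.build for r in clinvar}
    if len(builds) > 1:
        raise InputError(f"mixed genome builds in merge: {sorted(builds)}")

    keys_cur = {r.key for r in curated}
    keys_clv = {r.key for r in clinvar}
    genes_cur = {r.gene for r in curated}
    genes_clv = {r.gene for r in clinvar}
    shared_keys = keys_cur & keys_clv

    merged: dict[tuple, MutationRecord] = {}
    for r in list(curated) + list(clinvar):
        k = (r.key, r.disease)
        if k in merged:
            continue
        source = "both" if r.key in shared_keys else r.source
        merged[k] = MutationRecord(
            disease=r.disease, gene=r.gene, build=r.build, chrom=r.chrom,
            pos=r.pos, ref=r.ref, alt=r.alt, source=source,
            pathogenicity=r.pathogenicity)
    merged_records = sorted(merged.values(),
                            key=lambda r: (r.chrom, r.pos, r.ref, r.alt, r.disease))

    catalog = DiseaseGeneCatalog.from_records(merged_records, level="gene")
    multi, single = single_multi_gene_split(catalog)

    summary = MergeSummary(
        n_mut_curated=len(keys_cur),
        n_mut_clinvar=len(keys_clv),
        n_mut_shared=len(shared_keys),
        n_mut_union=len(keys_cur | keys_clv),
        n_gene_curated=len(genes_cur),
        n_gene_clinvar=len(genes_clv),
        n_gene_shared=len(genes_cur & genes_clv),
        n_gene_union=len(genes_cur | genes_clv),
        ratio_mut=_round_half_up(len(keys_cur) / len(keys_clv)) if keys_clv else float("nan"),
        ratio_gene=_round_half_up(len(genes_cur) / len(genes_clv)) if genes_clv else float("nan"),
        n_gene_multi=len(multi),
        n_gene_single=len(single),
    )
    summary.check()
    return merged_records, summary


def single_multi_gene_split(catalog: DiseaseGeneCatalog
                            ) -> tuple[frozenset[str], frozenset[str]]:
    """Partition genes that occur in ≥1 disease set into (≥2 diseases, exactly 1)."""
    counts: dict[str, int] = {}
    for s in catalog.gene_sets.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    multi = frozenset(g for g, n in counts.items() if n >= 2)
    single = frozenset(g for g, n in counts.items() if n == 1)
    return multi, single
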