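"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the study's five input kinds at the study's scale —
20 diseases over a 424-gene universe, 25 marker contexts, 10 brain regions
— with planted, exactly recoverable structure:

* disease gene sets with *constructively* allocated pairwise overlaps
  (dedicated shared blocks, then unique fills), so realized overlaps equal
  the planted counts exactly and stage tests are deterministic given the
  seed;
* curated and ClinVar-style mutation tables consistent with those gene sets;
* marker catalogs with planted enrichment (a stated fraction of a disease's
  genes seeded into one context's marker set);
* a log2-scale expression study with planted per-region fold changes under
  Gaussian noise;
* phenotype scores generated as a monotone function of the planted
  proportion of shared genes plus truncated Gaussian noise, on the ~0.02
  score scale of DMN-style resources.

All randomness flows from one root seed through named substreams, so any
single input kind can be regenerated independently and reproducibly.
Passing ``planted_overlaps=None`` switches the catalog generator to
independent uniform draws — the null model used for calibration checks —
whereas an empty/zero overlap list means constructively disjoint sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .genetic_similarity import enumerate_pairs, proportion_shared
from .io_model import (DiseaseGeneCatalog, ExpressionStudy, InputError,
                       MarkerCatalog, MutationRecord, PhenotypeScoreTable)

_STREAMS = {"catalog": 1, "mutations": 2, "markers": 3, "expression": 4,
            "phenotype": 5}


def _default_overlaps() -> list[tuple[int, int, int]]:
    # chain of 14 overlapping neighbour pairs; overlap counts cycle so the
    # planted proportions spread over 0.2-0.45 and every planted pair is
    # unambiguously significant at the default universe size
    pattern = (9, 4, 8, 5, 7, 6)
    return [(i, i + 1, pattern[i % len(pattern)]) for i in range(14)]


def _default_enrichment() -> list[tuple[int, int, float]]:
    # both members of planted pair i share marker context i
    out: list[tuple[int, int, float]] = []
    for i, (a, b, _o) in enumerate(_default_overlaps()):
        out.append((a, i, 0.6))
        out.append((b, i, 0.6))
    return out


def _default_region_effects() -> list[tuple[int, int, float]]:
    # two planted high genes per region, +2 on the log2 scale
    return [(i, i // 2, 2.0) for i in range(20)]


@dataclass
class SimConfig:
    """Ground-truth configuration of one synthetic cohort."""

    seed: int = 0
    n_diseases: int = 20
    universe_size: int = 424
    genes_per_disease: int | tuple[int, int] = 20
    planted_overlaps: list[tuple[int, int, int]] | None = field(
        default_factory=_default_overlaps)
    n_contexts: int = 25
    markers_per_context: int = 30
    planted_enrichment: list[tuple[int, int, float]] = field(
        default_factory=_default_enrichment)
    n_regions: int = 10
    samples_per_region: int = 10
    n_genes_expr: int = 1000
    region_effects: list[tuple[int, int, float]] = field(
        default_factory=_default_region_effects)
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    dmn_slope: float = 0.1
    dmn_noise_sd: float = 0.005
    n_matchings: int = 1
    muts_per_gene: tuple[int, int] = (1, 3)
    clinvar_gene_fraction: float = 0.3
    shared_mutation_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_diseases", "universe_size", "n_contexts",
                     "markers_per_context", "n_regions", "samples_per_region",
                     "n_genes_expr", "n_matchings"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be positive")
        if self.noise_sd < 0 or self.dmn_noise_sd < 0:
            raise InputError("noise standard deviations must be non-negative")
        for _d, _c, f in self.planted_enrichment:
            if not 0 <= f <= 1:
                raise InputError(f"planted enrichment fraction {f} outside [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))


def _set_sizes(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    g = cfg.genes_per_disease
    if isinstance(g, int):
        return [g] * cfg.n_diseases
    lo, hi = g
    return [int(v) for v in rng.integers(lo, hi + 1, size=cfg.n_diseases)]


def gen_disease_catalog(cfg: SimConfig
                        ) -> tuple[DiseaseGeneCatalog, dict[str, Any]]:
    """Disease gene sets with exactly realized planted pairwise overlaps.

    With ``planted_overlaps=None`` each disease set is an independent
    uniform draw from the universe (the no-signal null model).
    """
    rng = cfg.rng("catalog")
    genes = [f"G{i:04d}" for i in range(cfg.universe_size)]
    diseases = [f"disease_{i:02d}" for i in range(cfg.n_diseases)]
    sizes = _set_sizes(cfg, rng)
    sets: dict[str, set[str]] = {d: set() for d in diseases}

    if cfg.planted_overlaps is None:
        for d, size in zip(diseases, sizes):
            if size > cfg.universe_size:
                raise InputError("set size exceeds the universe")
            sets[d] = set(rng.choice(genes, size=size, replace=False))
        truth_overlaps = None
    else:
        per_disease_planted = [0] * cfg.n_diseases
        for i, j, o in cfg.planted_overlaps:
            if not (0 <= i < cfg.n_diseases and 0 <= j < cfg.n_diseases and i != j):
                raise InputError(f"invalid planted pair ({i}, {j})")
            if o > min(sizes[i], sizes[j]):
                raise InputError(
                    f"planted overlap {o} for pair ({i}, {j}) exceeds the "
                    f"set sizes ({sizes[i]}, {sizes[j]})")
            per_disease_planted[i] += o
            per_disease_planted[j] += o
        for idx, tot in enumerate(per_disease_planted):
            if tot > sizes[idx]:
                raise InputError(
                    f"disease {idx} cannot hold {tot} planted shared genes in a "
                    f"set of size {sizes[idx]}")
        total_needed = (sum(o for _, _, o in cfg.planted_overlaps)
                        + sum(sizes) - 2 * sum(o for _, _, o in cfg.planted_overlaps))
        if total_needed > cfg.universe_size:
            raise InputError(
                f"allocation needs {total_needed} genes but the universe has "
                f"{cfg.universe_size}")
        pool = list(genes)
        rng.shuffle(pool)
        ptr = 0
        truth_overlaps = {}
        for i, j, o in cfg.planted_overlaps:
            block = pool[ptr:ptr + o]
            ptr += o
            sets[diseases[i]].update(block)
            sets[diseases[j]].update(block)
            truth_overlaps[(diseases[i], diseases[j])] = o
        for d, size in zip(diseases, sizes):
            fill = size - len(sets[d])
            sets[d].update(pool[ptr:ptr + fill])
            ptr += fill

    catalog = DiseaseGeneCatalog(
        diseases=diseases,
        gene_sets={d: frozenset(s) for d, s in sets.items()},
        universe=frozenset(genes))
    truth = {"overlaps": truth_overlaps, "sizes": dict(zip(diseases, sizes))}
    return catalog, truth


def gen_mutation_tables(cfg: SimConfig, catalog: DiseaseGeneCatalog
                        ) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Curated and ClinVar-style mutation records consistent with a catalog.

    Mutations are generated per gene (1–3 variants each) and every disease
    linked to that gene carries a subset of them (each variant kept with
    probability 0.7, at least one), so genes shared between diseases share
    some — but usually not all — of their variants, mirroring the weaker
    mutation-level overlap of real catalogs.  A fraction of genes
    additionally appears in the ClinVar-style table, occasionally reusing a
    curated mutation key so the merge step sees genuinely shared variants.
    """
    rng = cfg.rng("mutations")
    bases = ("A", "C", "G", "T")
    gene_diseases: dict[str, list[str]] = {}
    for disease in catalog.diseases:
        for gene in catalog.gene_sets[disease]:
            gene_diseases.setdefault(gene, []).append(disease)
    curated: list[MutationRecord] = []
    clinvar: list[MutationRecord] = []
    pos = 10_000
    for gene in sorted(gene_diseases):
        lo, hi = cfg.muts_per_gene
        n_mut = int(rng.integers(lo, hi + 1))
        variants: list[tuple[int, str, str]] = []
        for _ in range(n_mut):
            pos += int(rng.integers(1, 50))
            ref, alt = rng.choice(bases, size=2, replace=False)
            variants.append((pos, str(ref), str(alt)))
        for disease in gene_diseases[gene]:
            keep = [v for v in variants if rng.random() < 0.7] or [variants[0]]
            for vpos, ref, alt in keep:
                curated.append(MutationRecord(
                    disease=disease, gene=gene, build="hg19", chrom="chr1",
                    pos=vpos, ref=ref, alt=alt, source="curated",
                    pathogenicity="pathogenic"))
        if rng.random() < cfg.clinvar_gene_fraction:
            disease = gene_diseases[gene][0]
            if rng.random() < cfg.shared_mutation_fraction:
                vpos, ref, alt = variants[0]
                clinvar.append(MutationRecord(
                    disease=disease, gene=gene, build="hg19", chrom="chr1",
                    pos=vpos, ref=ref, alt=alt, source="clinvar",
                    pathogenicity="pathogenic"))
            else:
                pos += int(rng.integers(1, 50))
                ref, alt = rng.choice(bases, size=2, replace=False)
                clinvar.append(MutationRecord(
                    disease=disease, gene=gene, build="hg19", chrom="chr1",
                    pos=pos, ref=str(ref), alt=str(alt), source="clinvar",
                    pathogenicity="likely_pathogenic"))
    return curated, clinvar


def gen_marker_catalog(cfg: SimConfig, catalog: DiseaseGeneCatalog
                       ) -> tuple[MarkerCatalog, dict[str, Any]]:
    """Marker sets with planted disease-gene enrichment.

    For each planted (disease, context, f), ``ceil(f * |genes|)`` of the
    disease's genes are seeded into the context's marker set; every context
    is then filled to ``markers_per_context`` with uniform draws from the
    universe.  Background = union of all marker sets.
    """
    rng = cfg.rng("markers")
    contexts = [f"ctx_{k:02d}" for k in range(cfg.n_contexts)]
    sets: dict[str, set[str]] = {c: set() for c in contexts}
    planted_truth: list[tuple[str, str, int]] = []
    for d_idx, c_idx, f in cfg.planted_enrichment:
        if not (0 <= d_idx < cfg.n_diseases and 0 <= c_idx < cfg.n_contexts):
            raise InputError(f"invalid planted enrichment ({d_idx}, {c_idx})")
        disease = catalog.diseases[d_idx]
        context = contexts[c_idx]
        dgenes = sorted(catalog.gene_sets[disease])
        n_pl = math.ceil(f * len(dgenes))
        if n_pl > cfg.markers_per_context:
            raise InputError(
                f"planted enrichment ({d_idx}, {c_idx}) needs {n_pl} markers "
                f"but contexts hold {cfg.markers_per_context}")
        chosen = rng.choice(dgenes, size=n_pl, replace=False)
        sets[context].update(str(g) for g in chosen)
        planted_truth.append((disease, context, n_pl))
    universe = sorted(catalog.universe)
    for context in contexts:
        if len(sets[context]) > cfg.markers_per_context:
            raise InputError(
                f"context {context!r} overfilled by planted enrichment "
                f"({len(sets[context])} > {cfg.markers_per_context})")
        candidates = [g for g in universe if g not in sets[context]]
        fill = cfg.markers_per_context - len(sets[context])
        sets[context].update(
            str(g) for g in rng.choice(candidates, size=fill, replace=False))
    background: set[str] = set()
    for s in sets.values():
        background |= s
    markers = MarkerCatalog(contexts=contexts,
                            marker_sets={c: frozenset(s) for c, s in sets.items()},
                            background=frozenset(background))
    return markers, {"planted": planted_truth}


def gen_expression(cfg: SimConfig
                   ) -> tuple[ExpressionStudy, dict[str, Any]]:
    """Log2-scale expression with planted region-specific fold changes.

    Gene list = the disease universe padded with extra genes up to
    ``n_genes_expr``.  Per gene, a Normal(baseline_mean, baseline_sd) log2
    baseline; planted (gene, region) effects are added on the log2 scale;
    i.i.d. Normal(0, noise_sd) noise per sample.
    """
    rng = cfg.rng("expression")
    universe = [f"G{i:04d}" for i in range(cfg.universe_size)]
    if cfg.n_genes_expr <= cfg.universe_size:
        genes = universe[:cfg.n_genes_expr]
    else:
        genes = universe + [f"EX{i:04d}"
                            for i in range(cfg.n_genes_expr - cfg.universe_size)]
    regions = [f"region_{r:02d}" for r in range(cfg.n_regions)]
    samples: list[str] = []
    region_of: dict[str, str] = {}
    for region in regions:
        for s in range(cfg.samples_per_region):
            name = f"{region}_s{s:02d}"
            samples.append(name)
            region_of[name] = region
    G, S = len(genes), len(samples)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)[:, None]
    values = baseline + rng.normal(0.0, cfg.noise_sd, size=(G, S))
    effects_truth: list[tuple[str, str, float]] = []
    for g_idx, r_idx, lfc in cfg.region_effects:
        if not (0 <= g_idx < G and 0 <= r_idx < cfg.n_regions):
            raise InputError(f"invalid region effect ({g_idx}, {r_idx})")
        cols = [k for k, s in enumerate(samples)
                if region_of[s] == regions[r_idx]]
        values[g_idx, cols] += lfc
        effects_truth.append((genes[g_idx], regions[r_idx], float(lfc)))
    study = ExpressionStudy(genes=genes, samples=samples, values=values,
                            region_of=region_of, regions=regions, scale="log2")
    return study, {"effects": effects_truth}


def gen_phenotype_scores(cfg: SimConfig, catalog: DiseaseGeneCatalog
                         ) -> PhenotypeScoreTable:
    """Phenotype scores: max(0, slope · proportion_shared + noise) per pair.

    With ``n_matchings > 1`` each pair receives several independently
    noised scores, exercising downstream averaging.
    """
    rng = cfg.rng("phenotype")
    entries: list[tuple[str, str, float]] = []
    for a, b in enumerate_pairs(catalog.diseases):
        prop = proportion_shared(catalog.gene_sets[a], catalog.gene_sets[b])
        for _ in range(cfg.n_matchings):
            score = cfg.dmn_slope * prop + rng.normal(0.0, cfg.dmn_noise_sd)
            entries.append((a, b, max(0.0, float(score))))
    return PhenotypeScoreTable(entries=entries)


def gen_merge_pair(n_mut_curated: int, n_gene_curated: int,
                   n_mut_clinvar: int, n_gene_clinvar: int,
                   n_mut_shared: int, n_gene_shared: int,
                   n_diseases: int = 20
                   ) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Two mutation catalogs with exactly planted merge accounting.

    Constructs curated/clinvar record lists whose unique-mutation and
    unique-gene counts, and shared counts, equal the requested values — so
    merge arithmetic (inclusion–exclusion, count ratios) can be checked
    against stated set sizes without any real data.
    """
    if n_mut_shared > min(n_mut_curated, n_mut_clinvar):
        raise InputError("shared mutation count exceeds a catalog size")
    if n_gene_shared > min(n_gene_curated, n_gene_clinvar):
        raise InputError("shared gene count exceeds a catalog size")
    if n_mut_curated < n_gene_curated or n_mut_clinvar < n_gene_clinvar:
        raise InputError("need at least one mutation per gene")
    if n_mut_shared > n_gene_shared:
        raise InputError("construction requires n_mut_shared <= n_gene_shared")
    genes_cur = [f"CG{i:04d}" for i in range(n_gene_curated)]
    genes_clv = (genes_cur[:n_gene_shared]
                 + [f"CV{i:04d}" for i in range(n_gene_clinvar - n_gene_shared)])

    def disease(i: int) -> str:
        return f"disease_{i % n_diseases:02d}"

    curated = [MutationRecord(disease=disease(i), gene=genes_cur[i % n_gene_curated],
                              build="hg19", chrom="chr1", pos=1_000 + i,
                              ref="A", alt="C", source="curated")
               for i in range(n_mut_curated)]
    clinvar: list[MutationRecord] = []
    for i in range(n_mut_clinvar):
        if i < n_mut_shared:
            base = curated[i]  # gene index i < n_gene_shared keeps genes consistent
            clinvar.append(MutationRecord(
                disease=base.disease, gene=base.gene, build="hg19",
                chrom=base.chrom, pos=base.pos, ref=base.ref, alt=base.alt,
                source="clinvar"))
        else:
            clinvar.append(MutationRecord(
                disease=disease(i), gene=genes_clv[i % n_gene_clinvar],
                build="hg19", chrom="chr2", pos=1_000 + i, ref="G", alt="T",
                source="clinvar"))
    return curated, clinvar


def generate_bundle(cfg: SimConfig) -> dict[str, Any]:
    """All five input kinds plus the ground-truth record, in one call."""
    catalog, catalog_truth = gen_disease_catalog(cfg)
    curated, clinvar = gen_mutation_tables(cfg, catalog)
    markers, marker_truth = gen_marker_catalog(cfg, catalog)
    study, expr_truth = gen_expression(cfg)
    phenotype = gen_phenotype_scores(cfg, catalog)
    return {
        "config": cfg,
        "catalog": catalog,
        "curated": curated,
        "clinvar": clinvar,
        "markers": markers,
        "expression": study,
        "phenotype": phenotype,
        "truth": {"catalog": catalog_truth, "markers": marker_truth,
                  "expression": expr_truth},
    }
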