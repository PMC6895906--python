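"""Domain types and tabular I/O.

Everything the pipeline consumes or emits is plain UTF-8, tab-separated
text with a header line (GMT for gene-set catalogs).  The types here are
thin, validated containers shared by all analysis modules:

* :class:`MutationRecord` — one pathogenic variant tied to one disease.
* :class:`DiseaseGeneCatalog` — disease → gene-set map over a gene universe.
* :class:`MarkerCatalog` — context (cell subtype or brain region) → marker
  gene set, with the background used as the enrichment universe.
* :class:`ExpressionStudy` — gene × sample matrix with a sample → region map.
* :class:`PhenotypeScoreTable` — phenotype-similarity scores for unordered
  disease pairs (DMN-style; a pair may carry several scores).

Coordinates are 1-based and fully closed (VCF convention); no lift-over is
performed here — inputs are expected to be on a single, already-normalized
genome build.  Gene symbols are compared case-sensitively after whitespace
trimming; disease names are normalized to lowercase with collapsed internal
whitespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SOURCE_TAGS = ("curated", "clinvar", "both")
PATHOGENICITY_CLASSES = ("pathogenic", "likely_pathogenic")

#: column order for mutation tables, on disk and in memory
MUTATION_COLUMNS = (
    "disease", "gene", "build", "chrom", "pos", "ref", "alt",
    "source", "pathogenicity",
)


class InputError(ValueError):
    """An input file or record violates the format contract."""


def normalize_disease(name: str) -> str:
    """Lowercase, trim and collapse internal whitespace of a disease name."""
    return " ".join(str(name).strip().lower().split())


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Order-insensitive key for a disease pair (names are normalized)."""
    na, nb = normalize_disease(a), normalize_disease(b)
    return (na, nb) if na <= nb else (nb, na)


@dataclass(frozen=True)
class MutationRecord:
    """One pathogenic variant linked to one disease.

    ``pos`` is 1-based.  ``source`` records which catalog the variant came
    from (``both`` appears only after merging).
    """

    disease: str
    gene: str
    build: str
    chrom: str
    pos: int
    ref: str
    alt: str
    source: str
    pathogenicity: str = "pathogenic"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Mutation identity: (chrom, pos, ref, alt) — the disease is not part of it."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def problems(self) -> list[str]:
        """Invariant violations as human-readable strings (empty = valid)."""
        out: list[str] = []
        if not self.disease:
            out.append("empty disease name")
        if not self.gene:
            out.append("empty gene symbol")
        if not isinstance(self.pos, (int, np.integer)) or self.pos < 1:
            out.append(f"pos must be a positive integer, got {self.pos!r}")
        if self.ref == self.alt:
            out.append(f"ref equals alt ({self.ref!r})")
        if self.source not in SOURCE_TAGS:
            out.append(f"unknown source {self.source!r}")
        if self.pathogenicity not in PATHOGENICITY_CLASSES:
            out.append(f"unknown pathogenicity {self.pathogenicity!r}")
        return out


def read_mutation_table(path: str | Path, source_tag: str) -> list[MutationRecord]:
    """Read a disease–mutation TSV into validated records.

    Rows that violate record invariants are dropped and reported (with their
    1-based file line numbers) via a warning; a file with zero valid rows is
    a hard error, as is a missing required column.  Duplicate rows are kept —
    de-duplication is the merge step's job.
    """
    if source_tag not in ("curated", "clinvar"):
        raise InputError(f"source_tag must be 'curated' or 'clinvar', got {source_tag!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in MUTATION_COLUMNS if c not in ("source", "pathogenicity")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[MutationRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        rowd = dict(zip(df.columns, row))
        try:
            pos = int(rowd["pos"])
        except (TypeError, ValueError):
            bad.append((line_no, f"non-integer pos {rowd['pos']!r}"))
            continue
        rec = MutationRecord(
            disease=normalize_disease(rowd["disease"]),
            gene=str(rowd["gene"]).strip(),
            build=str(rowd["build"]).strip(),
            chrom=str(rowd["chrom"]).strip(),
            pos=pos,
            ref=str(rowd["ref"]).strip(),
            alt=str(rowd["alt"]).strip(),
            source=source_tag,
            pathogenicity=str(rowd.get("pathogenicity", "pathogenic")).strip()
            or "pathogenic",
        )
        probs = rec.problems()
        if probs:
            bad.append((line_no, "; ".join(probs)))
        else:
            records.append(rec)
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad[:20])
        warnings.warn(f"{path}: dropped {len(bad)} invalid row(s): {detail}", stacklevel=2)
    if not records:
        raise InputError(f"{path}: no valid mutation rows")
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in MUTATION_COLUMNS} for r in records],
                      columns=list(MUTATION_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


@dataclass
class DiseaseGeneCatalog:
    """Ordered disease → gene-set map plus the gene universe in scope.

    The "genes" may equally be mutation identity keys (for mutation-level
    similarity screens); the container does not care.
    """

    diseases: list[str]
    gene_sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for d in self.gene_sets:
            if d not in self.diseases:
                raise InputError(f"gene_sets key {d!r} not listed in diseases")
        for d in self.diseases:
            s = self.gene_sets.get(d)
            if not s:
                raise InputError(f"disease {d!r} has an empty gene set")
            extra = s - self.universe
            if extra:
                raise InputError(
                    f"disease {d!r} has genes outside the universe: {sorted(extra)[:5]}")

    @property
    def union(self) -> frozenset[str]:
        """Union of all disease gene sets (≤ universe)."""
        out: set[str] = set()
        for s in self.gene_sets.values():
            out |= s
        return frozenset(out)

    @classmethod
    def from_records(cls, records: Sequence[MutationRecord], level: str = "gene",
                     universe: Iterable[str] | None = None) -> "DiseaseGeneCatalog":
        """Build a catalog from mutation records.

        ``level='gene'`` groups gene symbols per disease; ``level='mutation'``
        groups ``chrom:pos:ref:alt`` identity strings instead, so the same
        similarity screen runs at either resolution.
        """
        if level not in ("gene", "mutation"):
            raise InputError(f"level must be 'gene' or 'mutation', got {level!r}")
        sets: dict[str, set[str]] = {}
        for r in records:
            item = r.gene if level == "gene" else f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
            sets.setdefault(r.disease, set()).add(item)
        diseases = sorted(sets)
        gene_sets = {d: frozenset(s) for d, s in sets.items()}
        if universe is None:
            uni: set[str] = set()
            for s in gene_sets.values():
                uni |= s
        else:
            uni = set(universe)
        return cls(diseases=diseases, gene_sets=gene_sets, universe=frozenset(uni))


@dataclass
class MarkerCatalog:
    """Context → marker-gene-set map with the enrichment background."""

    contexts: list[str]
    marker_sets: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        if not self.contexts:
            raise InputError("marker catalog has no contexts")
        if len(set(self.contexts)) != len(self.contexts):
            raise InputError("context names are not unique")
        for c in self.contexts:
            if c not in self.marker_sets:
                raise InputError(f"context {c!r} has no marker set")
            extra = self.marker_sets[c] - self.background
            if extra:
                raise InputError(
                    f"context {c!r} has markers outside the background: {sorted(extra)[:5]}")


def read_marker_gmt(path: str | Path,
                    background: Iterable[str] | None = None) -> MarkerCatalog:
    """Read a GMT file (name, description, genes..., tab-separated).

    Background defaults to the union of all marker sets.  Context order is
    the file's line order.
    """
    path = Path(path)
    contexts: list[str] = []
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            while fields and not fields[-1]:
                fields.pop()
            if len(fields) < 3:
                raise InputError(
                    f"{path}: line {line_no}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} field(s))")
            name, _desc, *genes = fields
            if name in sets:
                raise InputError(f"{path}: line {line_no}: duplicate set name {name!r}")
            contexts.append(name)
            sets[name] = frozenset(g for g in genes if g)
    if not contexts:
        raise InputError(f"{path}: empty GMT file")
    if background is None:
        bg: set[str] = set()
        for s in sets.values():
            bg |= s
    else:
        bg = set(background)
    return MarkerCatalog(contexts=contexts, marker_sets=sets, background=frozenset(bg))


def write_marker_gmt(catalog: MarkerCatalog, path: str | Path,
                     description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in catalog.contexts:
            genes = sorted(catalog.marker_sets[c])
            fh.write("\t".join([c, description] + genes) + "\n")


@dataclass
class ExpressionStudy:
    """Gene × sample expression matrix with a sample → region map.

    ``scale`` declares how ``values`` are stored: ``"log2"`` (contrasts are
    differences) or ``"linear"`` (log2-transformed with a pseudocount before
    testing).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    region_of: dict[str, str]
    regions: list[str]
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples")
        for s in self.samples:
            if s not in self.region_of:
                raise InputError(f"sample {s!r} has no region assignment")
        if self.scale not in ("log2", "linear"):
            raise InputError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        for s, r in self.region_of.items():
            if r not in self.regions:
                raise InputError(f"sample {s!r} maps to unknown region {r!r}")

    def region_samples(self, region: str) -> list[str]:
        return [s for s in self.samples if self.region_of[s] == region]


def read_expression(matrix_path: str | Path, region_map_path: str | Path,
                    scale: str = "log2") -> ExpressionStudy:
    """Read a gene × sample TSV plus a sample → region map TSV.

    Samples present in the matrix but absent from the map are a hard error;
    map entries absent from the matrix are dropped with a warning.
    A non-numeric cell is a hard error reported with its coordinates.
    """
    matrix_path, region_map_path = Path(matrix_path), Path(region_map_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    bad = df.select_dtypes(exclude="number")
    if not bad.empty:
        for sample in bad.columns:
            col = pd.to_numeric(bad[sample], errors="coerce")
            for gene in bad.index[col.isna() & bad[sample].notna()]:
                raise InputError(
                    f"{matrix_path}: non-numeric value {bad.at[gene, sample]!r} "
                    f"at gene {gene!r}, sample {sample!r}")
        df = df.apply(pd.to_numeric)
    rmap = pd.read_csv(region_map_path, sep="\t", dtype=str)
    if not {"sample", "region"} <= set(rmap.columns):
        raise InputError(f"{region_map_path}: needs columns 'sample' and 'region'")
    region_of = dict(zip(rmap["sample"].str.strip(), rmap["region"].str.strip()))
    samples = [str(s) for s in df.columns]
    unmapped = [s for s in samples if s not in region_of]
    if unmapped:
        raise InputError(
            f"{matrix_path}: sample(s) missing from region map: {unmapped[:10]}")
    extra = sorted(set(region_of) - set(samples))
    if extra:
        warnings.warn(
            f"{region_map_path}: {len(extra)} map entr(ies) not in matrix, dropped: "
            f"{extra[:10]}", stacklevel=2)
        region_of = {s: r for s, r in region_of.items() if s in set(samples)}
    regions = sorted(set(region_of.values()))
    return ExpressionStudy(genes=[str(g) for g in df.index], samples=samples,
                           values=df.to_numpy(dtype=float), region_of=region_of,
                           regions=regions, scale=scale)


@dataclass
class PhenotypeScoreTable:
    """Phenotype-similarity scores for unordered disease pairs.

    A pair may appear several times (multiple matchings in the source
    resource); all scores are retained, averaging happens downstream.
    """

    entries: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm: list[tuple[str, str, float]] = []
        for a, b, s in self.entries:
            s = float(s)
            if s < 0:
                raise InputError(f"negative phenotype score {s} for pair ({a}, {b})")
            ka, kb = pair_key(a, b)
            norm.append((ka, kb, s))
        self.entries = norm

    def scores(self, a: str, b: str) -> list[float]:
        k = pair_key(a, b)
        return [s for x, y, s in self.entries if (x, y) == k]

    def pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.entries}


def read_phenotype_scores(path: str | Path,
                          synonym_map: Mapping[str, str] | None = None
                          ) -> PhenotypeScoreTable:
    """Read a disease_a / disease_b / score TSV.

    ``synonym_map`` (normalized name → catalog name) lets externally named
    diseases be matched to the catalog's controlled names.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"disease_a": str, "disease_b": str})
    needed = {"disease_a", "disease_b", "score"}
    if not needed <= set(df.columns):
        raise InputError(f"{path}: needs columns disease_a, disease_b, score")
    syn = {normalize_disease(k): normalize_disease(v)
           for k, v in (synonym_map or {}).items()}

    def rename(d: str) -> str:
        n = normalize_disease(d)
        return syn.get(n, n)

    entries = [(rename(a), rename(b), float(s))
               for a, b, s in zip(df["disease_a"], df["disease_b"], df["score"])]
    for a, b, s in entries:
        if s < 0:
            raise InputError(f"{path}: negative score {s} for pair ({a}, {b})")
    return PhenotypeScoreTable(entries=entries)


def write_phenotype_scores(table: PhenotypeScoreTable, path: str | Path) -> None:
    df = pd.DataFrame(table.entries, columns=["disease_a", "disease_b", "score"])
    df.to_csv(path, sep="\t", index=False)
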