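"""Asymmetric-binary distance between enrichment profiles and pair rankings.

Profiles are binarized (entry nonzero vs zero) and compared with the
asymmetric binary ("Jaccard-type") distance: with

    a = positions nonzero in both,
    b = nonzero only in the first,
    c = nonzero only in the second,

distance = (b + c) / (a + b + c).  Joint-zero positions carry no
information and are ignored; when no position is nonzero in either profile
the distance is undefined (NaN) and excluded from rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context_enrichment import EnrichmentProfile
from .io_model import InputError


@dataclass
class DistanceMatrix:
    diseases: list[str]
    values: np.ndarray  # symmetric, NaN where undefined, 0 diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.diseases, columns=self.diseases)


def binary_distance(profile_a, profile_b) -> float:
    """Asymmetric binary distance between two equal-length profiles (NaN if undefined)."""
    x = np.asarray(profile_a, dtype=float)
    y = np.asarray(profile_b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"profile length mismatch: {x.shape} vs {y.shape}")
    bx, by = x != 0, y != 0
    a = int(np.sum(bx & by))
    b = int(np.sum(bx & ~by))
    c = int(np.sum(~bx & by))
    if a + b + c == 0:
        return float("nan")
    return (b + c) / (a + b + c)


def distance_matrix(profiles: list[EnrichmentProfile],
                    binarize: str = "nonzero") -> DistanceMatrix:
    """Pairwise distances between disease profiles.

    ``binarize='nonzero'`` thresholds on enrichment score ≠ 0 (any overlap);
    ``binarize='significant'`` uses the FET significance flags instead.
    """
    if binarize not in ("nonzero", "significant"):
        raise InputError(f"binarize must be 'nonzero' or 'significant'")
    vecs = [p.scores if binarize == "nonzero" else p.significant.astype(float)
            for p in profiles]
    names = [p.disease for p in profiles]
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = 0.0 if np.any(vecs[i] != 0) else np.nan
        for j in range(i + 1, n):
            d = binary_distance(vecs[i], vecs[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(diseases=names, values=values)


def rank_pairs(dm: DistanceMatrix
               ) -> tuple[list[tuple[tuple[str, str], float]],
                          list[tuple[str, str]]]:
    """Disease pairs ranked by ascending distance.

    Ties break lexicographically by pair name.  Pairs with undefined
    distance are excluded from the ranking and returned separately; it is a
    hard error if every off-diagonal entry is undefined.
    """
    ranked: list[tuple[tuple[str, str], float]] = []
    undefined: list[tuple[str, str]] = []
    n = len(dm.diseases)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((dm.diseases[i], dm.diseases[j]))
            d = dm.values[i, j]
            if np.isnan(d):
                undefined.append((a, b))
            else:
                ranked.append(((a, b), float(d)))
    if not ranked:
        raise InputError("all pairwise distances are undefined")
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked, undefined
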