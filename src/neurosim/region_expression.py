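"""Region-vs-rest expression contrasts and "highly expressed" gene calls.

Each gene is contrasted between one brain region and the pooled samples of
all other regions.  Two test variants are offered:

``plain``
    ordinary two-sample t with pooled variance.
``eb`` (default)
    empirical-Bayes moderated t: per-gene sample variances are shrunk toward
    a prior variance ``s0²`` with prior degrees of freedom ``d0`` estimated
    by method of moments on the log sample variances (the scaled-F
    hierarchical model used by moderated differential-expression analyses);
    the moderated statistic is referred to a t distribution on d0 + dg df.

A gene is called *highly expressed* in a region when its fold change is at
least 2 (boundary inclusive) and the contrast p-value is below ``alpha``.
Fold change is reported on the declared scale: for log2 data it is
``2**(mean_in − mean_out)`` (a geometric-mean ratio); for linear data it is
the ratio of arithmetic means, while the t-test runs on
``log2(x + pseudocount)``.  The out-group mean is the pooled mean over all
non-region samples (not the mean of per-region means) unless requested
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .io_model import ExpressionStudy, InputError, MarkerCatalog

FOLD_THRESHOLD = 2.0  # "at least one time higher", i.e. +100%


@dataclass(frozen=True)
class RegionContrastResult:
    gene: str
    region: str
    mean_in: float
    mean_out: float
    fold: float
    t_stat: float
    p_value: float
    high_flag: bool


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: float,
                       prior_df: float | None = None,
                       prior_var: float | None = None
                       ) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene sample variances toward an estimated prior.

    Returns (posterior variances, d0, s0²).  With ``prior_df=0`` the
    posterior equals the sample variances; with ``prior_df=inf`` every
    posterior equals the prior variance.  When not supplied, (d0, s0²) are
    estimated by method of moments on log sample variances: for
    z = log(s²), E[z] = log(s0²) + ψ(dg/2) − log(dg/2) − ψ(d0/2) + log(d0/2)
    and Var[z] = ψ′(dg/2) + ψ′(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is None:
        ok = np.isfinite(s2) & (s2 > 0)
        if ok.sum() < 2:
            prior_df = math.inf
            prior_var = float(np.nanmean(s2[np.isfinite(s2)])) if np.isfinite(s2).any() else 1.0
        else:
            z = np.log(s2[ok])
            e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
            evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
            emean = float(np.mean(e))
            if evar <= 0:
                prior_df = math.inf
                prior_var = math.exp(emean)
            else:
                prior_df = 2.0 * trigamma_inverse(evar)
                prior_var = math.exp(
                    emean + special.digamma(prior_df / 2.0) - math.log(prior_df / 2.0))
    if prior_var is None:
        raise InputError("prior_var must accompany an explicit prior_df")
    if math.isinf(prior_df):
        post = np.full_like(s2, prior_var)
    else:
        post = (prior_df * prior_var + df * s2) / (prior_df + df)
    return post, float(prior_df), float(prior_var)


def _analysis_matrix(study: ExpressionStudy, pseudocount: float) -> np.ndarray:
    if study.scale == "log2":
        return study.values
    return np.log2(study.values + pseudocount)


def region_contrast(study: ExpressionStudy, region: str, alpha: float = 0.05,
                    moderation: str = "eb", pseudocount: float = 1.0,
                    out_mean: str = "pooled",
                    prior_df: float | None = None,
                    prior_var: float | None = None
                    ) -> list[RegionContrastResult]:
    """Region-vs-rest contrast for every gene of the study."""
    if region not in study.regions:
        raise InputError(f"unknown region {region!r}")
    if moderation not in ("eb", "plain"):
        raise InputError(f"moderation must be 'eb' or 'plain', got {moderation!r}")
    if out_mean not in ("pooled", "region_mean"):
        raise InputError(f"out_mean must be 'pooled' or 'region_mean'")
    mask = np.array([study.region_of[s] == region for s in study.samples])
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise InputError(
            f"region {region!r} needs >=2 samples in and out of the region "
            f"(got {n1} in, {n2} out)")

    X = _analysis_matrix(study, pseudocount)
    x_in, x_out = X[:, mask], X[:, ~mask]
    m1 = x_in.mean(axis=1)
    m2 = x_out.mean(axis=1)
    diff = m1 - m2
    df = n1 + n2 - 2
    s2 = (x_in.var(axis=1, ddof=0) * n1 + x_out.var(axis=1, ddof=0) * n2) / df

    if moderation == "eb":
        s2_use, d0, _s0 = moderate_variances(s2, df, prior_df=prior_df,
                                             prior_var=prior_var)
        t_df = np.inf if math.isinf(d0) else d0 + df
    else:
        s2_use, t_df = s2, float(df)

    se = np.sqrt(s2_use * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=t_df)
    p = np.where(np.isinf(t), 0.0, p)

    if study.scale == "log2":
        fold = 2.0 ** diff
        rep_in, rep_out = m1, m2
    else:
        lin_in = study.values[:, mask].mean(axis=1)
        if out_mean == "pooled":
            lin_out = study.values[:, ~mask].mean(axis=1)
        else:
            others = [r for r in study.regions if r != region]
            per = [study.values[:, np.array([study.region_of[s] == r
                                             for s in study.samples])].mean(axis=1)
                   for r in others]
            lin_out = np.mean(per, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(lin_out > 0, lin_in / lin_out,
                            np.where(lin_in > 0, np.inf, np.nan))
        rep_in, rep_out = lin_in, lin_out

    if out_mean == "region_mean" and study.scale == "log2":
        others = [r for r in study.regions if r != region]
        per = [X[:, np.array([study.region_of[s] == r for s in study.samples])
                 ].mean(axis=1) for r in others]
        m2_alt = np.mean(per, axis=0)
        fold = 2.0 ** (m1 - m2_alt)
        rep_out = m2_alt

    high = (fold >= FOLD_THRESHOLD) & (p < alpha)
    return [RegionContrastResult(gene=g, region=region, mean_in=float(rep_in[i]),
                                 mean_out=float(rep_out[i]), fold=float(fold[i]),
                                 t_stat=float(t[i]), p_value=float(p[i]),
                                 high_flag=bool(high[i]))
            for i, g in enumerate(study.genes)]


def region_high_sets(study: ExpressionStudy, alpha: float = 0.05,
                     **contrast_kwargs) -> MarkerCatalog:
    """Per-region sets of highly expressed genes, as a MarkerCatalog.

    The background is the full gene list of the study, so downstream
    enrichment runs the same machinery as the cell-type analysis.
    """
    if len(study.regions) < 2:
        raise InputError("need at least 2 regions")
    sets: dict[str, frozenset[str]] = {}
    for region in study.regions:
        res = region_contrast(study, region, alpha=alpha, **contrast_kwargs)
        sets[region] = frozenset(r.gene for r in res if r.high_flag)
    return MarkerCatalog(contexts=list(study.regions), marker_sets=sets,
                         background=frozenset(study.genes))


def contrast_frame(results: list[RegionContrastResult]):
    """Per-gene contrast results as a pandas DataFrame (for TSV output)."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
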