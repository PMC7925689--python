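"""Gene-signature scoring and gene-effect co-dependency ranking.

A cohort is scored for a gene set by summing per-gene z-scores: expression is
standardized gene-wise within the cohort (so each gene contributes on a
common scale regardless of its absolute expression) and the signature score
of a sample is the sum of its z-scores over the set. Scores are invariant to
any per-gene affine rescaling of the raw expression and additive over
disjoint gene sets.

Co-dependency ranks every gene in a knockout-fitness (gene-effect) matrix by
the Spearman correlation of its effect profile with an anchor gene across
cell lines, with Benjamini-Hochberg control of the false-discovery rate:
genes whose knockouts track the anchor's are candidate functional partners.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .survival import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "detection_filter",
    "gene_zscores",
    "signature_score",
    "codependency_profile",
]


def detection_filter(expr: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep genes detected (value > 0) in at least ``min_fraction`` of samples."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = (expr > 0).mean(axis=1)
    return expr.loc[frac >= min_fraction]


def gene_zscores(expr: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each gene across samples (sample sd, n-1 denominator).

    Zero-variance genes are dropped with a warning; a single-sample cohort
    cannot be standardized and raises.
    """
    if expr.shape[1] < 2:
        raise ValueError("cannot z-score a single-sample cohort")
    sd = expr.std(axis=1, ddof=ddof)
    flat = sd == 0
    if flat.any():
        logger.warning("gene_zscores: dropping %d constant gene(s)", int(flat.sum()))
        expr = expr.loc[~flat]
        sd = sd.loc[~flat]
    return expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)


def signature_score(zscores: pd.DataFrame, gene_set) -> pd.Series:
    """Per-sample sum of z-scores over the genes of the set.

    Missing gene-set members are dropped (logged, not imputed); an empty
    intersection raises. The result carries the number of genes actually
    used in ``.attrs["n_genes_used"]``.
    """
    wanted = list(dict.fromkeys(gene_set))
    if not wanted:
        raise ValueError("empty gene set")
    present = [g for g in wanted if g in zscores.index]
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")
    if len(present) < len(wanted):
        logger.warning("signature_score: %d of %d gene(s) absent from matrix",
                       len(wanted) - len(present), len(wanted))
    score = zscores.loc[present].sum(axis=0)
    score.name = "score"
    score.attrs["n_genes_used"] = len(present)
    return score


def _spearman_exact_p(rho_obs: float, n: int) -> float:
    """Two-sided permutation p for Spearman rho at small n (full enumeration)."""
    base = np.arange(1, n + 1, dtype=float)
    denom = np.sum((base - base.mean()) ** 2)
    hits = total = 0
    for perm in itertools.permutations(base):
        r = np.sum((np.asarray(perm) - base.mean()) * (base - base.mean())) / denom
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def codependency_profile(
    effects: pd.DataFrame, anchor: str, min_complete: int = 10
) -> pd.DataFrame:
    """Spearman correlation of every gene's effect profile with the anchor.

    ``effects`` is genes x cell lines. Correlations use average ranks for
    ties and pairwise-complete observations; two-sided p-values come from the
    t approximation (exact permutation enumeration for n <= 9 complete
    pairs). BH q-values are computed across all non-anchor genes and the
    table is sorted by rho (descending) with a dense 1-based rank.
    """
    if anchor not in effects.index:
        raise ValueError(f"anchor {anchor!r} not in matrix")
    x = effects.loc[anchor].to_numpy(dtype=float)
    if np.nanstd(x) == 0:
        raise ValueError("anchor profile is constant")

    rhos, ps, ns = {}, {}, {}
    for g, row in effects.iterrows():
        y = row.to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < min_complete and g != anchor:
            raise ValueError(
                f"gene {g!r}: only {n} pairwise-complete observations "
                f"(need >= {min_complete})")
        xr = stats.rankdata(x[ok])
        yr = stats.rankdata(y[ok])
        sx, sy = xr.std(), yr.std()
        if sy == 0:
            rho = 0.0
        else:
            rho = float(np.corrcoef(xr, yr)[0, 1])
        rhos[g], ns[g] = rho, n
        if g == anchor:
            ps[g] = 0.0
        elif n <= 9:
            ps[g] = _spearman_exact_p(rho, n)
        elif abs(rho) >= 1.0:
            ps[g] = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            ps[g] = 2.0 * stats.t.sf(abs(t), n - 2)

    out = pd.DataFrame(dict(rho=pd.Series(rhos), p=pd.Series(ps),
                            n=pd.Series(ns)))
    others = out.index != anchor
    q = pd.Series(np.nan, index=out.index)
    q[others] = bh_adjust(out.loc[others, "p"].to_numpy())
    out["q"] = q
    out = out.sort_values("rho", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
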