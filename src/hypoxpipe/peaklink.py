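"""Peak-to-gene association, enhancer productivity, and gene-set partitions.

Binding peaks are linked to genes by an association factor (AF) combining the
peak's normalized read density (pnrd) with an exponential decay in the
distance dc between peak center and TSS:

    AF = pnrd * exp(-|dc| / d0),   d0 = 500 bp by default

so AF halves every d0*ln(2) ~= 346.6 bp. Links with AF above a threshold
(0.1) are high-confidence promoter/TSS-proximal; remaining peaks 5-50 kb from
the nearest TSS are distal candidates for enhancer activity, and those beyond
50 kb intergenic. Distal peaks whose linked gene is transcriptionally
upregulated are "productive" enhancer candidates; productive sites typically
show bidirectional nascent signal within +/-250 bp of the peak center.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .nascent import window_values

logger = logging.getLogger(__name__)

DISTAL_MIN = 5_000
DISTAL_MAX = 50_000

__all__ = [
    "association_factor",
    "nearest_tss",
    "classify_peak_gene",
    "link_peaks",
    "common_peak_scaling",
    "classify_enhancer_productivity",
    "overlap_stats",
    "acute_late_partition",
    "conservation_groups",
]


def association_factor(pnrd, dc, d0: float = 500.0, decay: bool = True):
    """Distance-decay association factor between a peak and a TSS.

    ``decay=True`` (default) uses exp(-|dc|/d0) so the factor falls with
    distance and AF <= pnrd; ``decay=False`` reproduces the growing form
    exp(+|dc|/d0) for comparison only.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    pnrd = np.asarray(pnrd, dtype=float)
    if (pnrd < 0).any():
        raise ValueError("pnrd must be >= 0")
    sign = -1.0 if decay else 1.0
    return pnrd * np.exp(sign * np.abs(np.asarray(dc, dtype=float)) / d0)


def nearest_tss(peaks: pd.DataFrame, models: pd.DataFrame) -> pd.DataFrame:
    """Nearest annotated TSS per peak center.

    Returns peak_id, gene_id, dc (non-negative magnitude) and dc_signed
    (positive when the peak center lies downstream of the TSS in
    transcription direction). Peaks on chromosomes without any model get
    dc = inf and a missing gene_id.
    """
    out = []
    by_chrom = {c: g.sort_values("tss") for c, g in models.groupby("chrom")}
    for rec in peaks.itertuples():
        sub = by_chrom.get(rec.chrom)
        if sub is None or sub.empty:
            out.append((rec.peak_id, pd.NA, np.inf, np.nan))
            continue
        tss = sub["tss"].to_numpy()
        i = np.searchsorted(tss, rec.center)
        cand = [j for j in (i - 1, i) if 0 <= j < len(tss)]
        j = min(cand, key=lambda j: abs(int(tss[j]) - rec.center))
        g = sub.iloc[j]
        delta = rec.center - int(g["tss"])
        signed = delta if g["strand"] == "+" else -delta
        out.append((rec.peak_id, g["gene_id"], abs(delta), signed))
    return pd.DataFrame(out, columns=["peak_id", "gene_id", "dc", "dc_signed"])


def classify_peak_gene(links: pd.DataFrame, af_threshold: float = 0.1) -> pd.Series:
    """Assign proximal / distal / intergenic / other classes.

    proximal iff AF > af_threshold; otherwise distal iff 5,000 <= dc <=
    50,000 (closed bounds); intergenic iff dc > 50,000; the remainder
    (low AF within 5 kb) is "other". Classes are exhaustive and exclusive.
    """
    af = links["af"].to_numpy(dtype=float)
    dc = links["dc"].to_numpy(dtype=float)
    klass = np.where(
        af > af_threshold, "proximal",
        np.where((dc >= DISTAL_MIN) & (dc <= DISTAL_MAX), "distal",
                 np.where(dc > DISTAL_MAX, "intergenic", "other")),
    )
    return pd.Series(klass, index=links.index, name="klass")


def link_peaks(
    peaks: pd.DataFrame,
    models: pd.DataFrame,
    pnrd_col: str = "pnrd_hypoxia",
    d0: float = 500.0,
    af_threshold: float = 0.1,
    decay: bool = True,
) -> pd.DataFrame:
    """Link every peak to its nearest TSS and classify the relationship.

    Returns one row per peak (nearest-TSS link) with columns peak_id,
    gene_id, dc, dc_signed, pnrd, af, klass. When a peak's AF clears the
    threshold for additional genes, those extra qualifying proximal links are
    appended with ``primary=False`` (the nearest-TSS row has
    ``primary=True``).
    """
    links = nearest_tss(peaks, models).merge(
        peaks[["peak_id", "chrom", "center", pnrd_col]], on="peak_id"
    )
    links = links.rename(columns={pnrd_col: "pnrd"})
    links["af"] = association_factor(links["pnrd"], links["dc"], d0=d0, decay=decay)
    links["klass"] = classify_peak_gene(links, af_threshold)
    links["primary"] = True

    # secondary proximal links: any other TSS close enough that AF > threshold
    extra = []
    by_chrom = {c: g for c, g in models.groupby("chrom")}
    for rec in links.itertuples():
        if rec.pnrd <= af_threshold:
            continue
        reach = d0 * np.log(rec.pnrd / af_threshold)
        sub = by_chrom.get(rec.chrom)
        if sub is None:
            continue
        near = sub[(sub["tss"] - rec.center).abs() <= reach]
        for g in near.itertuples():
            if g.gene_id == rec.gene_id:
                continue
            dc = abs(rec.center - g.tss)
            af = float(association_factor(rec.pnrd, dc, d0=d0, decay=decay))
            if af > af_threshold:
                extra.append(dict(
                    peak_id=rec.peak_id, gene_id=g.gene_id, dc=dc,
                    dc_signed=(rec.center - g.tss) if g.strand == "+" else (g.tss - rec.center),
                    chrom=rec.chrom, center=rec.center, pnrd=rec.pnrd, af=af,
                    klass="proximal", primary=False,
                ))
    if extra:
        links = pd.concat([links, pd.DataFrame(extra)], ignore_index=True)
    return links


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/touching sorted [start, end) intervals."""
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def _intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append([s, e])
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out).reshape(-1, 2)


def common_peak_scaling(
    peak_sets: Mapping[str, pd.DataFrame],
    tag_col: str = "tags",
    base_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-sample scale factors from tags in peaks common to all samples.

    Common regions are the genomic intersection (>= 1 bp overlap after
    merging) of every sample's peak calls. factor[s] = (tags in common peaks
    in s) / (mean across samples); factors average to 1 by construction. When
    ``base_threshold`` is given, an ``adjusted_threshold`` column scales it
    per sample — the mechanism used to control for sample-specific IP
    efficiencies when harmonizing peak calling across cell lines.
    """
    names = list(peak_sets)
    if len(names) < 2:
        raise ValueError("need >= 2 samples")
    chroms = set().union(*(set(df["chrom"]) for df in peak_sets.values()))
    common: dict[str, np.ndarray] = {}
    for c in chroms:
        acc = None
        for name in names:
            df = peak_sets[name]
            iv = _merge_intervals(df.loc[df["chrom"] == c, ["start", "end"]].to_numpy())
            acc = iv if acc is None else _intersect(acc, iv)
            if len(acc) == 0:
                break
        if len(acc):
            common[c] = acc
    if not common:
        pairs = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ov = 0
                for c in chroms:
                    ia = _merge_intervals(
                        peak_sets[a].loc[peak_sets[a]["chrom"] == c, ["start", "end"]].to_numpy())
                    ib = _merge_intervals(
                        peak_sets[b].loc[peak_sets[b]["chrom"] == c, ["start", "end"]].to_numpy())
                    x = _intersect(ia, ib)
                    ov += int((x[:, 1] - x[:, 0]).sum()) if len(x) else 0
                pairs.append(f"{a}~{b}: {ov} bp")
        raise ValueError("no peaks common to all samples; pairwise overlaps: "
                         + "; ".join(pairs))

    tags = {}
    for name in names:
        df = peak_sets[name]
        total = 0.0
        for c, iv in common.items():
            sub = df[df["chrom"] == c]
            if sub.empty:
                continue
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            t = sub[tag_col].to_numpy(dtype=float)
            for cs, ce in iv:
                total += t[(e > cs) & (s < ce)].sum()
        tags[name] = total
    tags = pd.Series(tags)
    factors = tags / tags.mean()
    out = pd.DataFrame(dict(tags_in_common=tags, factor=factors))
    if base_threshold is not None:
        out["adjusted_threshold"] = base_threshold * factors
    return out


def classify_enhancer_productivity(
    links: pd.DataFrame,
    de_labels: pd.Series,
    signal: Mapping[tuple[str, str], pd.DataFrame],
    peaks: pd.DataFrame,
    window: int = 250,
) -> pd.DataFrame:
    """Call distal peaks productive/unproductive and quantify their windows.

    A distal peak is productive iff any of its linked genes is classified
    "up". ``window_signal_<condition>`` sums plus- plus minus-strand signal
    over [center - window, center + window); windows with no recorded signal
    count as 0 with a warning. Productivity is defined only for distal-class
    peaks.
    """
    distal_ids = links.loc[links["klass"] == "distal", "peak_id"].unique()
    gene_lists = (
        links[links["peak_id"].isin(distal_ids)]
        .groupby("peak_id")["gene_id"].apply(list)
    )
    conditions = sorted({cond for (_, cond) in signal})
    centers = peaks.set_index("peak_id")[["chrom", "center"]]
    rows = []
    n_empty = 0
    for pid in distal_ids:
        genes = gene_lists.get(pid, [])
        up = any(de_labels.get(g) == "up" for g in genes if g is not pd.NA)
        chrom, center = centers.loc[pid, "chrom"], int(centers.loc[pid, "center"])
        row = dict(peak_id=pid,
                   productivity="productive" if up else "unproductive")
        for cond in conditions:
            tot = 0.0
            for strand in ("+", "-"):
                df = signal.get((strand, cond))
                if df is not None:
                    tot += window_values(df, chrom, center - window, center + window).sum()
            if tot == 0.0:
                n_empty += 1
            row[f"window_signal_{cond}"] = tot
        rows.append(row)
    if n_empty:
        logger.warning(
            "classify_enhancer_productivity: %d window/condition pairs without "
            "signal recorded as 0", n_empty)
    return pd.DataFrame(rows)


def _fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher p by hypergeometric enumeration (pmf-ordering rule)."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def overlap_stats(
    set_a: Iterable, set_b: Iterable, universe: Iterable
) -> dict:
    """Odds ratio and two-sided Fisher exact p for the overlap of two sets.

    The 2x2 table is (in A & B, A only, B only, neither) over ``universe``.
    An infinite odds ratio (a zero off-diagonal cell) is reported as inf with
    ``or_capped=True``.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a = set(set_a) & u
    b = set(set_b) & u
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(u) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]])
    capped = n10 * n01 == 0 and n11 * n00 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.divide(n11 * n00, n10 * n01) if n10 * n01 else (
            np.inf if n11 * n00 else np.nan)
    return dict(odds_ratio=float(odds), p=_fisher_exact_p(table),
                table=table, or_capped=bool(capped))


def acute_late_partition(nascent_up: Iterable, mrna_up: Iterable) -> dict[str, set]:
    """Split up-calls into acute (both assays), late (mRNA only), nascent-only.

    Acute-response genes are induced at both the nascent level (early time
    point) and the steady-state mRNA level (late time point); late-response
    genes appear only in the mRNA data. The three sets are disjoint and
    cover the union of the inputs.
    """
    nasc, mrna = set(nascent_up), set(mrna_up)
    return dict(acute=nasc & mrna, late=mrna - nasc, nascent_only=nasc - mrna)


def conservation_groups(
    up_calls: Mapping[str, Iterable], reference: str
) -> pd.DataFrame:
    """Group the reference cell type's up-genes by cross-cell-type support.

    For each gene upregulated in ``reference``: "core" if up in every assayed
    cell type, "reference_only" if up in the reference alone, otherwise
    "shared<k>" where k is the number of supporting cell types (shared3 /
    shared2 in the four-cell-type design). Groups partition the reference
    up-set.
    """
    if reference not in up_calls:
        raise ValueError(f"reference {reference!r} missing from up_calls")
    if len(up_calls) < 2:
        raise ValueError("need up-calls for >= 2 cell types")
    sets = {k: set(v) for k, v in up_calls.items()}
    n_types = len(sets)
    rows = []
    for g in sorted(sets[reference]):
        k = sum(g in s for s in sets.values())
        if k == n_types:
            group = "core"
        elif k == 1:
            group = "reference_only"
        else:
            group = f"shared{k}"
        rows.append(dict(gene_id=g, group=group, n_cell_types=k))
    return pd.DataFrame(rows, columns=["gene_id", "group", "n_cell_types"])
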