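"""Synthetic-data generators for the acute-hypoxia pipeline.

Every downstream stage of the package can be exercised without sequencing or
cohort downloads: this module fabricates gene annotations, nascent-transcription
counts, ChIP-style peak sets with strand-specific enhancer signal,
expression-linked survival cohorts, and CRISPR gene-effect matrices — each with
truth labels sufficient to score the corresponding classifier.

All randomness flows from ``config.seed`` through named substreams
(:func:`substream`), so a fixed seed reproduces every output exactly.
"""

from __future__ import annotations

import re
import zlib
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .nascent import RegionCountMatrix

_STANDARD_RE = re.compile(r"^chr(\d+|X|Y)$")
_FIRST_ANCHOR = 60_000
_DUP_PROB = 0.1  # chance a gene carries an exact duplicate transcript record

__all__ = [
    "substream",
    "GeneModelSim",
    "simulate_gene_models",
    "simulate_nascent_counts",
    "simulate_mrna_counts",
    "simulate_signal_tracks",
    "simulate_peaks",
    "simulate_cohort",
    "simulate_effect_scores",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of the root seed (stable across runs/platforms)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def is_standard_chrom(name: str) -> bool:
    return bool(_STANDARD_RE.match(name))


def _negbin(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu**2."""
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mu, dtype=float) * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# gene models


class GeneModelSim(NamedTuple):
    """Transcript records, per-candidate TSS window counts, and gene truth."""

    transcripts: pd.DataFrame
    tss_counts: pd.DataFrame
    truth: pd.DataFrame


def simulate_gene_models(config: SimulationConfig) -> GeneModelSim:
    """Emit 1-4 transcripts per gene plus truth labels.

    Each gene has one canonical transcript (its 5' end is the intended
    "most-active" TSS and its 3' end the shortest gene body). Extras are
    longer 3' variants, alternative upstream TSS variants, sub-1500 bp
    transcripts (per-gene probability ``short_fraction``), copies on a
    non-standard chromosome (``nonstandard_fraction``), and occasional exact
    duplicate records — all of which the annotation stage must filter away.
    """
    cfg = config
    rng = substream(cfg.seed, "gene_models")

    standard = sorted(c for c in cfg.chrom_sizes if is_standard_chrom(c))
    if not standard:
        raise ValueError("chrom_sizes contains no standard chromosome")
    nonstandard = sorted(c for c in cfg.chrom_sizes if not is_standard_chrom(c))

    capacity = {
        c: max(0, (int(cfg.chrom_sizes[c]) - 2 * _FIRST_ANCHOR) // cfg.gene_spacing + 1)
        for c in standard
    }
    if sum(capacity.values()) < cfg.n_genes:
        raise ValueError(
            f"chrom_sizes too small: capacity {sum(capacity.values())} genes "
            f"at spacing {cfg.gene_spacing}, requested {cfg.n_genes}"
        )

    slots: list[tuple[str, int]] = []
    for c in standard:
        slots.extend((c, _FIRST_ANCHOR + i * cfg.gene_spacing) for i in range(capacity[c]))
    slots = slots[: cfg.n_genes]

    induced = rng.random(cfg.n_genes) < cfg.induced_fraction
    conv = rng.random(cfg.n_genes)
    induced_mrna = (induced & (conv < cfg.mrna_conversion)) | (
        ~induced & (conv < cfg.late_fraction)
    )
    lfc = np.where(
        induced, rng.normal(cfg.body_log2fc_mean, cfg.body_log2fc_sd, cfg.n_genes), 0.0
    )

    tx_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i, (chrom, anchor) in enumerate(slots):
        gid = f"G{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        length = int(rng.integers(cfg.min_gene_length, cfg.max_gene_length + 1))
        if strand == "+":
            start, end, tss = anchor, anchor + length, anchor
        else:
            start, end, tss = anchor - length, anchor, anchor
        t = 1

        def add(s: int, e: int, c: str = chrom) -> None:
            nonlocal t
            tx_rows.append(
                dict(gene_id=gid, transcript_id=f"{gid}.t{t}", chrom=c,
                     start=int(s), end=int(e), strand=strand, short=(e - s) < 1500)
            )
            t += 1

        add(start, end)  # canonical: shortest standard-chromosome transcript
        for _ in range(int(rng.integers(0, 3))):  # longer / alt-TSS variants
            delta = int(rng.integers(500, 3000))
            if rng.random() < 0.5:  # longer 3' end, same TSS
                if strand == "+":
                    add(start, end + delta)
                else:
                    add(start - delta, end)
            else:  # alternative upstream TSS, same 3' end
                shift = int(rng.integers(1200, 3000))
                if strand == "+":
                    add(start - shift, end)
                else:
                    add(start, end + shift)
        if rng.random() < cfg.short_fraction:
            short_len = int(rng.integers(600, 1400))
            if strand == "+":
                add(start, start + short_len)
            else:
                add(end - short_len, end)
        if nonstandard and rng.random() < cfg.nonstandard_fraction:
            size = int(cfg.chrom_sizes[nonstandard[0]])
            s = int(rng.integers(1000, max(2000, size - length - 1000)))
            add(s, s + length, c=nonstandard[0])
        if rng.random() < _DUP_PROB:
            add(start, end)  # exact duplicate coordinates, new transcript_id

        truth_rows.append(
            dict(gene_id=gid, chrom=chrom, strand=strand, tss=int(tss),
                 body_end=int(end if strand == "+" else start),
                 length=length, induced=bool(induced[i]),
                 induced_mrna=bool(induced_mrna[i]), log2fc=float(lfc[i]))
        )

    transcripts = pd.DataFrame(tx_rows)
    truth = pd.DataFrame(truth_rows)

    # Candidate-TSS window counts: the canonical TSS dominates sense reads.
    truth_tss = truth.set_index("gene_id")["tss"]
    tss_pos = np.where(
        transcripts["strand"].to_numpy() == "+",
        transcripts["start"].to_numpy(),
        transcripts["end"].to_numpy(),
    )
    canonical = (
        (tss_pos == truth_tss.reindex(transcripts["gene_id"]).to_numpy())
        & transcripts["chrom"].map(is_standard_chrom).to_numpy()
    )
    crng = substream(cfg.seed, "tss_counts")
    sense = np.where(canonical, crng.poisson(300.0, len(transcripts)),
                     crng.poisson(30.0, len(transcripts)))
    antisense = crng.poisson(np.where(canonical, 90.0, 9.0))
    tss_counts = transcripts[["gene_id", "transcript_id"]].copy()
    tss_counts["sense"] = sense
    tss_counts["antisense"] = antisense
    return GeneModelSim(transcripts, tss_counts, truth)


# ---------------------------------------------------------------------------
# nascent counts


def _sample_sheet(cfg: SimulationConfig, genotypes: Iterable[str],
                  conditions: Iterable[str]) -> pd.DataFrame:
    rows = [
        dict(sample=f"{g}_{c}_r{r + 1}", genotype=g, condition=c, replicate=r + 1)
        for g in genotypes for c in conditions for r in range(cfg.n_samples_per_group)
    ]
    return pd.DataFrame(rows).set_index("sample")


def simulate_nascent_counts(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[str, RegionCountMatrix]:
    """Negative-binomial TSS and gene-body counts across condition/genotype.

    Region mean = density x region length x gene abundance x library factor.
    Induced genes receive the full body log2 fold change under the induced
    condition but only ``tss_fc_ratio`` of it at the TSS (so their pausing
    index drops); the knockout genotype multiplies log2 effects by
    ``genotype_attenuation``.
    """
    cfg = config
    if len(truth) == 0:
        raise ValueError("truth/models table is empty")
    rng = substream(cfg.seed, "nascent_counts")

    samples = _sample_sheet(cfg, ["WT", "KO"], ["normoxia", "hypoxia"])
    genes = truth["gene_id"].to_numpy()
    tss_len = np.full(len(truth), 550)
    body_len = truth["length"].to_numpy() - 1001
    if (body_len < 1).any():
        raise ValueError("simulated gene shorter than the 1001 bp body offset")

    abundance = rng.lognormal(0.0, cfg.gene_abundance_sigma, len(truth))
    lib = rng.lognormal(0.0, cfg.library_size_sigma, len(samples))
    lfc = truth["log2fc"].to_numpy()

    mats: dict[str, np.ndarray] = {}
    for region, length, density, ratio in (
        ("tss", tss_len, cfg.tss_density_mean, cfg.tss_fc_ratio),
        ("body", body_len, cfg.body_density_mean, 1.0),
    ):
        base = density * length * abundance
        cols = []
        for j, (_, meta) in enumerate(samples.iterrows()):
            eff = lfc * ratio
            if meta["genotype"] == "KO":
                eff = eff * cfg.genotype_attenuation
            fold = 2.0 ** eff if meta["condition"] == "hypoxia" else 1.0
            mu = base * fold * lib[j]
            cols.append(_negbin(rng, mu, cfg.dispersion))
        mats[region] = np.column_stack(cols)

    library_sizes = pd.Series(
        (mats["tss"] + mats["body"]).sum(axis=0), index=samples.index, dtype=float,
        name="library_size",
    )
    out = {}
    for region, length in (("tss", tss_len), ("body", body_len)):
        out[region] = RegionCountMatrix(
            region_class=region,
            counts=pd.DataFrame(mats[region], index=genes, columns=samples.index),
            region_lengths=pd.Series(length, index=genes, dtype=float),
            library_sizes=library_sizes,
            samples=samples,
        )
    return out


def simulate_mrna_counts(truth: pd.DataFrame, config: SimulationConfig) -> RegionCountMatrix:
    """Steady-state mRNA counts (wild type, normoxia vs. induced condition).

    Genes flagged ``induced_mrna`` in the truth table change at the mRNA level;
    together with the nascent arm this defines the planted acute (both),
    late (mRNA-only) and nascent-only response classes.
    """
    cfg = config
    rng = substream(cfg.seed, "mrna_counts")
    samples = _sample_sheet(cfg, ["WT"], ["normoxia", "hypoxia"])
    genes = truth["gene_id"].to_numpy()
    abundance = rng.lognormal(0.0, cfg.gene_abundance_sigma, len(truth))
    lib = rng.lognormal(0.0, cfg.library_size_sigma, len(samples))
    lfc = np.where(truth["induced_mrna"].to_numpy(), cfg.body_log2fc_mean, 0.0)
    cols = []
    for j, (_, meta) in enumerate(samples.iterrows()):
        fold = 2.0 ** lfc if meta["condition"] == "hypoxia" else 1.0
        cols.append(_negbin(rng, cfg.mrna_mean_counts * abundance * fold * lib[j],
                            cfg.dispersion))
    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=samples.index)
    return RegionCountMatrix(
        region_class="mrna",
        counts=counts,
        region_lengths=pd.Series(1.0, index=genes),
        library_sizes=counts.sum(axis=0).astype(float),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# signal tracks and peaks


def simulate_signal_tracks(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[tuple[str, str], pd.DataFrame]:
    """Strand-specific nascent signal (bedGraph-style intervals) per condition.

    Each gene contributes a dense sense-strand block over its TSS window
    [-50, +500) and a sparse block over its body (+1001 to end); induced genes
    scale up under the induced condition. Keys are ``(strand, condition)``.
    """
    cfg = config
    rng = substream(cfg.seed, "signal_tracks")
    jitter = rng.lognormal(0.0, 0.2, len(truth))
    tracks: dict[tuple[str, str], list] = {
        (s, c): [] for s in "+-" for c in ("normoxia", "hypoxia")
    }
    for i, row in enumerate(truth.itertuples()):
        sense = row.strand
        if sense == "+":
            tss_iv = (row.tss - 50, row.tss + 500)
            body_iv = (row.tss + 1001, row.body_end)
        else:
            tss_iv = (row.tss - 500, row.tss + 50)
            body_iv = (row.body_end, row.tss - 1001)
        for cond in ("normoxia", "hypoxia"):
            fold = 2.0 ** row.log2fc if cond == "hypoxia" else 1.0
            tss_fold = fold ** cfg.tss_fc_ratio
            tracks[(sense, cond)].append(
                (row.chrom, *tss_iv, cfg.tss_density_mean * jitter[i] * tss_fold)
            )
            tracks[(sense, cond)].append(
                (row.chrom, *body_iv, cfg.body_density_mean * jitter[i] * fold)
            )
    out = {}
    for key, rows in tracks.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        out[key] = df.sort_values(["chrom", "start"], ignore_index=True)
    return out


class PeakSim(NamedTuple):
    peaks: pd.DataFrame
    signal: dict[tuple[str, str], pd.DataFrame]
    truth: pd.DataFrame


def simulate_peaks(truth: pd.DataFrame, config: SimulationConfig) -> PeakSim:
    """Plant proximal / distal / intergenic peaks with known classes.

    Proximal peaks sit within 400 bp of a TSS with high enrichment (their
    distance-decay association factor clears the 0.1 proximal threshold);
    distal peaks sit 5.1-45 kb away, intergenic ones > 55 kb from any TSS.
    Half of the distal peaks are planted "productive": they target induced
    genes and carry bidirectional strand signal within +/-250 bp of the peak
    center that scales by ``enhancer_fold_change`` under the induced
    condition. Unproductive distal peaks target non-induced genes and carry
    faint, condition-independent signal.
    """
    cfg = config
    rng = substream(cfg.seed, "peaks")
    p_prox, p_dist, _ = cfg.peak_class_props
    n_prox = int(round(p_prox * cfg.n_peaks))
    n_dist = int(round(p_dist * cfg.n_peaks))
    n_inter = cfg.n_peaks - n_prox - n_dist

    std = truth[truth["chrom"].map(is_standard_chrom)].reset_index(drop=True)
    induced_idx = np.flatnonzero(std["induced"].to_numpy())
    quiet_idx = np.flatnonzero(~std["induced"].to_numpy())
    max_distal = min(45_000, cfg.gene_spacing // 2 - 15_000)
    if max_distal <= 5_100 + 100:
        raise ValueError("gene spacing too small to place distal peaks")

    half = cfg.peak_width // 2
    rows, truth_rows, signal_rows = [], [], {
        (s, c): [] for s in "+-" for c in ("normoxia", "hypoxia")
    }
    pid = 0

    def emit(chrom, center, pnrd0, klass, gene_id, productive, dc_planted):
        nonlocal pid
        pid += 1
        name = f"peak{pid:04d}"
        rows.append(dict(
            peak_id=name, chrom=chrom, start=int(center - half),
            end=int(center + half), center=int(center),
            pnrd_normoxia=float(pnrd0),
            pnrd_hypoxia=float(pnrd0 * rng.uniform(1.5, 2.5)),
        ))
        truth_rows.append(dict(
            peak_id=name, klass=klass, gene_id=gene_id,
            productive=productive, dc_planted=dc_planted,
        ))
        return name, center

    for k in range(n_prox):
        g = std.iloc[int(rng.choice(len(std)))]
        dc = int(rng.integers(0, 401)) * int(rng.choice([-1, 1]))
        emit(g.chrom, g.tss + dc, rng.uniform(1.0, 5.0), "proximal",
             g.gene_id, pd.NA, abs(dc))

    n_prod = n_dist // 2
    for k in range(n_dist):
        productive = k < n_prod
        pool = induced_idx if productive else quiet_idx
        if len(pool) == 0:
            raise ValueError("no genes available for the requested distal class")
        g = std.iloc[int(rng.choice(pool))]
        dc = int(rng.integers(5_100, max_distal + 1)) * int(rng.choice([-1, 1]))
        name, center = emit(g.chrom, g.tss + dc, rng.uniform(0.3, 2.0), "distal",
                            g.gene_id, productive, abs(dc))
        base = rng.uniform(0.5, 2.0) if productive else rng.uniform(0.02, 0.1)
        fold = cfg.enhancer_fold_change if productive else 1.0
        for strand, frac in (("+", 1.0), ("-", 0.8)):
            for cond, f in (("normoxia", 1.0), ("hypoxia", fold)):
                signal_rows[(strand, cond)].append(
                    (g.chrom, int(center - 250), int(center + 250), base * frac * f)
                )

    nonstd = [c for c in cfg.chrom_sizes if not is_standard_chrom(c)]
    gaps = std[std["chrom"] == std["chrom"].shift(-1)].reset_index(drop=True)
    for k in range(n_inter):
        if nonstd and rng.random() < 0.3:
            chrom = nonstd[0]
            center = int(rng.integers(10_000, int(cfg.chrom_sizes[chrom]) - 10_000))
            emit(chrom, center, rng.uniform(0.3, 2.0), "intergenic", pd.NA, pd.NA, pd.NA)
        else:
            g = gaps.iloc[int(rng.choice(len(gaps)))]
            center = int(g.tss + cfg.gene_spacing // 2 + rng.integers(-4000, 4001))
            emit(g.chrom, center, rng.uniform(0.3, 2.0), "intergenic", pd.NA, pd.NA, pd.NA)

    signal = {
        key: pd.DataFrame(v, columns=["chrom", "start", "end", "value"])
        .sort_values(["chrom", "start"], ignore_index=True)
        for key, v in signal_rows.items()
    }
    return PeakSim(pd.DataFrame(rows), signal, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# survival cohort


class CohortSim(NamedTuple):
    expression: pd.DataFrame  # genes x samples
    survival: pd.DataFrame  # sample, time, event
    truth: pd.DataFrame  # sample, latent, high
    cutpoint_value: float


def simulate_cohort(
    config: SimulationConfig, gene_set: list[str] | None = None
) -> CohortSim:
    """Expression-linked proportional-hazards cohort with a known cutpoint.

    A latent per-sample score drives the expression of the signature genes;
    event times are exponential, with hazard multiplied by ``hazard_ratio``
    for samples above the ``cutpoint_percentile`` of the latent score.
    Censoring is independent exponential, tuned to the requested rate.
    """
    cfg = config
    if cfg.n_cohort < 30:
        raise ValueError("cohort requires n_cohort >= 30")
    rng = substream(cfg.seed, "cohort")
    n = cfg.n_cohort
    sig_genes = list(gene_set) if gene_set else [f"SIG{i + 1:03d}" for i in range(cfg.signature_size)]
    bg_genes = [f"BG{i + 1:03d}" for i in range(cfg.n_background_genes)]
    samples = [f"S{i + 1:04d}" for i in range(n)]

    u = rng.normal(0.0, 1.0, n)
    mats = []
    for g in sig_genes:
        eps = rng.normal(0.0, 1.0, n)
        mats.append(np.exp(1.0 + 0.9 * u + 0.3 * eps) * rng.uniform(20, 200))
    for g in bg_genes:
        eps = rng.normal(0.0, 1.0, n)
        mats.append(np.exp(1.0 + 0.6 * eps) * rng.uniform(20, 200))
    expr = pd.DataFrame(np.vstack(mats), index=sig_genes + bg_genes, columns=samples)

    # nearest-rank percentile of the latent score defines the truth split
    order = np.sort(u)
    k = max(1, int(np.ceil(cfg.cutpoint_percentile / 100.0 * n)))
    cut = float(order[k - 1])
    high = u > cut

    h0 = cfg.baseline_hazard
    hazard = np.where(high, h0 * cfg.hazard_ratio, h0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        mean_h = float(hazard.mean())
        hc = mean_h * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / hc, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    surv = pd.DataFrame(dict(sample=samples, time=time, event=event))
    truth = pd.DataFrame(dict(sample=samples, latent=u, high=high))
    return CohortSim(expr, surv, truth, cut)


# ---------------------------------------------------------------------------
# gene-effect screens


class ScreenSim(NamedTuple):
    effects: pd.DataFrame  # genes x cell lines
    truth_pairs: pd.DataFrame


def simulate_effect_scores(
    config: SimulationConfig,
    planted_pairs: list[tuple[str, str, float]] | None = None,
) -> ScreenSim:
    """Gene-effect matrix with independent normal background and planted pairs.

    ``planted_pairs`` is a list of ``(anchor, partner, rho)``; the partner
    shares a latent factor with the anchor at Pearson correlation ``rho``.
    """
    cfg = config
    if cfg.n_cell_lines < 50:
        raise ValueError("need >= 50 cell lines for stable rank correlations")
    if planted_pairs is None:
        planted_pairs = [("HIF1A", "DDIT4", 0.8)]
    for a, b, r in planted_pairs:
        if not -1.0 < r < 1.0:
            raise ValueError(f"planted correlation must be in (-1, 1), got {r}")
    rng = substream(cfg.seed, "effect_scores")
    n = cfg.n_cell_lines
    lines = [f"CL{i + 1:04d}" for i in range(n)]

    anchors = sorted({a for a, _, _ in planted_pairs})
    latent = {a: rng.normal(0.0, 1.0, n) for a in anchors}
    rows: dict[str, np.ndarray] = {}
    scale, loc = 0.4, -0.1  # CERES-like units
    for a in anchors:
        rows[a] = loc + scale * latent[a]
    for a, b, r in planted_pairs:
        z = r * latent[a] + np.sqrt(1.0 - r * r) * rng.normal(0.0, 1.0, n)
        rows[b] = loc + scale * z
    for i in range(cfg.n_screen_genes):
        rows[f"NULL{i + 1:04d}"] = loc + scale * rng.normal(0.0, 1.0, n)

    effects = pd.DataFrame(rows, index=lines).T
    truth = pd.DataFrame(planted_pairs, columns=["anchor", "partner", "rho"])
    return ScreenSim(effects, truth)
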