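"""Simulation configuration for the synthetic acute-hypoxia study.

A single :class:`SimulationConfig` drives every generator in
:mod:`hypoxpipe.simulate`. The defaults describe the study conditions the
package's simulation-based checks assume: negative-binomial nascent counts
with a dense TSS window and sparse gene bodies, condition effects
concentrated in gene bodies of induced genes, genotype-dependent
attenuation of those effects, proportional-hazards cohorts with a known
score cutpoint, and gene-effect matrices with planted co-dependent pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping


def _default_chrom_sizes() -> dict[str, int]:
    # Two standard pseudo-chromosomes plus one non-standard name so the
    # annotation chromosome filter is exercised end to end.
    return {"chr1": 25_000_000, "chr2": 25_000_000, "chrUn_random": 2_000_000}


@dataclass
class SimulationConfig:
    """Parameters shared by all synthetic-data generators.

    Attributes
    ----------
    seed:
        Root seed. Every generator draws from a named substream derived from
        it, so a fixed seed reproduces all outputs byte-for-byte.
    n_genes, n_samples_per_group:
        Number of simulated genes and replicates per condition/genotype group.
    chrom_sizes:
        Pseudo-genome, chromosome name -> length in bp.
    tss_density_mean, body_density_mean:
        Mean nascent read density (reads/bp) in the TSS window and gene body.
        The TSS window is denser, emulating promoter-proximal pausing.
    induced_fraction:
        Fraction of genes transcriptionally induced by the stimulus.
    body_log2fc_mean, body_log2fc_sd:
        Gene-body induction effect (log2 units) for induced genes.
    tss_fc_ratio:
        TSS effect as a fraction of the body effect (induced genes change
        comparatively little at the TSS, so their pausing index falls).
    genotype_attenuation:
        Multiplier in [0, 1] applied to log2 effects in the knockout
        genotype; 0 nulls the response entirely.
    dispersion:
        Negative-binomial dispersion (var = mu + dispersion * mu^2).
    censoring_rate, hazard_ratio, cutpoint_percentile:
        Survival-cohort structure: independent censoring fraction, hazard
        multiplier for samples above the cutpoint, and the percentile of the
        latent score at which the hazard changes.
    """

    seed: int = 0
    # gene models
    n_genes: int = 300
    short_fraction: float = 0.1
    nonstandard_fraction: float = 0.05
    min_gene_length: int = 2500
    max_gene_length: int = 9000
    gene_spacing: int = 120_000
    chrom_sizes: Mapping[str, int] = field(default_factory=_default_chrom_sizes)
    # nascent counts
    n_samples_per_group: int = 2
    tss_density_mean: float = 0.5
    body_density_mean: float = 0.05
    induced_fraction: float = 0.2
    body_log2fc_mean: float = 1.5
    body_log2fc_sd: float = 0.0
    tss_fc_ratio: float = 0.25
    genotype_attenuation: float = 0.3
    dispersion: float = 0.05
    library_size_sigma: float = 0.1
    gene_abundance_sigma: float = 0.4
    # steady-state mRNA arm
    mrna_conversion: float = 0.6
    late_fraction: float = 0.15
    mrna_mean_counts: float = 500.0
    # peaks
    n_peaks: int = 200
    peak_class_props: tuple[float, float, float] = (0.4, 0.4, 0.2)
    peak_width: int = 500
    enhancer_fold_change: float = 2.0
    # survival cohort
    n_cohort: int = 500
    signature_size: int = 20
    n_background_genes: int = 80
    censoring_rate: float = 0.2
    hazard_ratio: float = 3.0
    cutpoint_percentile: int = 40
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    # gene-effect screens
    n_cell_lines: int = 600
    n_screen_genes: int = 200

    def __post_init__(self) -> None:
        for name in ("short_fraction", "nonstandard_fraction", "induced_fraction",
                     "mrna_conversion", "late_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.genotype_attenuation <= 1.0:
            raise ValueError("genotype_attenuation must be in [0, 1]")
        for name in ("tss_density_mean", "body_density_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 1 <= self.cutpoint_percentile <= 99:
            raise ValueError("cutpoint_percentile must be an integer in 1..99")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["chrom_sizes"] = dict(d["chrom_sizes"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "peak_class_props" in d:
            d["peak_class_props"] = tuple(d["peak_class_props"])
        return cls(**d)
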