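"""End-to-end orchestration of the synthetic acute-hypoxia study.

`run_end_to_end` wires the stages together the way the analysis is meant to
be run against real data: simulate raw inputs, rebuild the one-TSS-per-gene
annotation from the transcript records, quantify TSS/body activity and
pausing, call differential transcription at both the nascent and mRNA
levels, link peaks to genes and call enhancer productivity, and partition
the up-calls into acute / late / nascent-only response sets. Truth labels
ride along so callers can score every classifier.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

from . import annotation, nascent, peaklink, simulate
from .config import SimulationConfig

__all__ = ["EndToEndResult", "run_end_to_end", "recovery_rates"]


class EndToEndResult(NamedTuple):
    models: pd.DataFrame
    truth: pd.DataFrame
    pausing: pd.DataFrame
    de_nascent: pd.DataFrame
    de_mrna: pd.DataFrame
    links: pd.DataFrame
    enhancers: pd.DataFrame
    partition: dict[str, set]


def run_end_to_end(config: SimulationConfig) -> EndToEndResult:
    """Simulate all inputs and run every pipeline stage on them."""
    sim = simulate.simulate_gene_models(config)
    models = annotation.build_annotation(sim.transcripts, sim.tss_counts)

    counts = simulate.simulate_nascent_counts(sim.truth, config)
    tss, body = counts["tss"], counts["body"]
    keep = nascent.filter_low_expression([tss, body])
    ptable = nascent.pausing_index(tss, body)

    meta = tss.samples
    wt = meta[meta["genotype"] == "WT"]
    norm = wt.index[wt["condition"] == "normoxia"].tolist()
    hyp = wt.index[wt["condition"] == "hypoxia"].tolist()
    fc = nascent.fold_changes(tss, body, norm, hyp)
    de_body = nascent.de_test(body, norm, hyp)
    de_nascent = nascent.classify_de(de_body["log2fc"], de_body["q"])
    de_nascent = de_nascent.loc[de_nascent.index.isin(keep)]

    mrna = simulate.simulate_mrna_counts(sim.truth, config)
    mnorm = mrna.samples.index[mrna.samples["condition"] == "normoxia"].tolist()
    mhyp = mrna.samples.index[mrna.samples["condition"] == "hypoxia"].tolist()
    de_m = nascent.de_test(mrna, mnorm, mhyp)
    de_mrna = nascent.classify_de(de_m["log2fc"], de_m["q"])

    peaks = simulate.simulate_peaks(sim.truth, config)
    links = peaklink.link_peaks(peaks.peaks, models)
    enhancers = peaklink.classify_enhancer_productivity(
        links, de_nascent["label"], peaks.signal, peaks.peaks)

    nascent_up = set(de_nascent.index[de_nascent["label"] == "up"])
    mrna_up = set(de_mrna.index[de_mrna["label"] == "up"])
    partition = peaklink.acute_late_partition(nascent_up, mrna_up)

    truth = sim.truth.copy()
    result = EndToEndResult(models, truth, ptable, de_nascent, de_mrna,
                            links, enhancers, partition)
    # stash the peak truth alongside for scoring convenience
    result.truth.attrs["peaks"] = peaks.truth
    result.truth.attrs["fold_changes"] = fc
    return result


def recovery_rates(result: EndToEndResult) -> dict[str, float]:
    """Sensitivity/specificity of acute-response recovery against truth."""
    truth = result.truth
    acute_truth = set(truth.loc[truth["induced"] & truth["induced_mrna"], "gene_id"])
    universe = set(truth["gene_id"])
    called = result.partition["acute"]
    tp = len(called & acute_truth)
    fn = len(acute_truth - called)
    fp = len(called - acute_truth)
    tn = len(universe) - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return dict(sensitivity=sens, specificity=spec,
                n_acute_truth=len(acute_truth), n_acute_called=len(called))
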