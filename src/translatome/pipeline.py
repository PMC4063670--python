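"""End-to-end workflow: pools -> loads -> shifts -> patterns -> classes -> report.

The pipeline mirrors the combined translatome analysis: polysome pool
signals become sampling-corrected pool distributions and ribosome loads;
stimulated-vs-control log2(H/L) is fit by orthogonal regression and
shifted mRNAs are called; the count time course is classified into
pattern groups; shift calls and groups combine into active/passive
regulation classes; ARE scores and unique-k-mer rpkm complete the
per-gene report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import arescore, integration, io, patterns, polysome, rpkm, shifts

REPORT_COLUMNS = [
    "gene_id",
    "d_mean",
    "call",
    "group",
    "regulation",
    "n_pentamers",
    "are_score",
    "rpkm_before",
    "rpkm_after",
]


@dataclass
class PipelineConfig:
    """Inputs and stage parameters; defaults are the reference analysis values."""

    signals: str = "signals.tsv"
    fractions: str = "fractions.tsv"
    counts: str = "counts.tsv"
    fasta: str = "utrs.fa"
    outdir: str = "results"
    k_sd: float = 2.0
    min_replicates: int = 2
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    boundary_minutes: float = 60.0
    window_nt: int = 25
    kmer: int = 58
    log2_input: bool = False
    arescore_params: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k_sd <= 0 or self.min_replicates < 1:
            raise ValueError("k_sd must be positive and min_replicates >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0 or self.window_nt < 0 or self.kmer < 1:
            raise ValueError("thresholds must be nonnegative and kmer >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**io.read_yaml(path))


def load_pairs(loads: pd.DataFrame) -> pd.DataFrame:
    """Reshape a per-(gene, condition, replicate) load table into (x, y) pairs."""
    wide = loads.pivot_table(
        index=["gene_id", "replicate"], columns="condition", values="log2_hl", aggfunc="first"
    ).reset_index()
    return wide.rename(columns={"control": "x", "stimulated": "y"})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the per-gene report plus QC sidecar."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    signals = io.read_signals(config.signals)
    if config.log2_input:
        signals = signals.assign(signal=2.0 ** signals["signal"])
    fractions = io.read_fractions(config.fractions)
    corrected = polysome.correct_sampling(signals, fractions)
    dists = polysome.pool_distribution(corrected)
    loads = polysome.ribosome_load(dists)

    pairs = load_pairs(loads)
    calls, fit_info = shifts.call_shifts(
        pairs, k_sd=config.k_sd, min_replicates=config.min_replicates
    )

    counts = io.read_counts(config.counts)
    groups, pattern_info = patterns.classify_counts(
        counts,
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha,
        boundary_minutes=config.boundary_minutes,
    )

    regulation = integration.classify_regulation_table(calls, groups)

    seqs = io.read_fasta(config.fasta)
    params = (
        arescore.AREScoreParams.from_yaml(config.arescore_params)
        if config.arescore_params
        else arescore.AREScoreParams.default()
    )
    scores = arescore.score_fasta(seqs.items(), params)

    kmer_index = rpkm.unique_kmers({g: [s] for g, s in seqs.items()}, k=config.kmer)
    tps = list(counts.columns)
    before, after = tps[0], min((t for t in tps if t >= config.boundary_minutes), default=tps[-1])
    rpkms = rpkm.rpkm_table(counts[[before, after]], kmer_index)
    rpkms.columns = ["rpkm_before", "rpkm_after"]

    report = (
        calls[["gene_id", "d_mean", "call"]]
        .merge(groups[["gene_id", "group"]], on="gene_id", how="inner")
        .merge(regulation[["gene_id", "regulation"]], on="gene_id", how="left")
        .merge(scores.rename(columns={"score": "are_score"}), on="gene_id", how="left")
        .merge(rpkms.reset_index(), on="gene_id", how="left")
    )[REPORT_COLUMNS]
    if report["gene_id"].duplicated().any():
        raise RuntimeError("duplicate gene in report")

    qc = fit_info["qc"].copy()
    invalid = dists.loc[~dists["valid"], "gene_id"].drop_duplicates()
    if len(invalid):
        qc = pd.concat(
            [qc, pd.DataFrame({"gene_id": invalid, "reason": "all_zero_pool_signals"})],
            ignore_index=True,
        )

    io.write_table(report, outdir / "report.tsv")
    io.write_table(qc, outdir / "qc.tsv")
    mean_line = fit_info["mean_line"]
    io.write_yaml(
        {
            "tls_mean_fit": {
                "slope": float(mean_line.slope),
                "intercept": float(mean_line.intercept),
                "sd_d": float(mean_line.sd_d),
            },
            "dispersion_trend": {
                "a0": float(pattern_info["dispersion"].a0),
                "a1": float(pattern_info["dispersion"].a1),
            },
            "parameters": {k: v for k, v in asdict(config).items() if not isinstance(v, str) or k == "arescore_params"},
            "n_genes_report": int(len(report)),
        },
        outdir / "fit_parameters.yaml",
    )
    return {
        "report": report,
        "qc": qc,
        "calls": calls,
        "groups": groups,
        "fit_info": fit_info,
        "pattern_info": pattern_info,
    }
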