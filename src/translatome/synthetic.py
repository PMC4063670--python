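"""Synthetic data with known ground truth for the whole pipeline.

Three generators emulate the pipeline inputs:

* polysome pool signals for control and LPS-stimulated macrophages, with
  a global polysome shift (a trend on log2(H/L)) plus designated actively
  shifted genes,
* negative-binomial count time courses following the five pattern
  archetypes g0-g4 (one library per timepoint, as in a high-resolution
  single-replicate course),
* 3'UTR sequences with a controlled number of planted AUUUA pentamers in
  the actively up-regulated genes.

Every generator is deterministic given the config seed (one RNG stream
per generator call, no hidden global state), and every emitted gene has
exactly one ground-truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .polysome import POOLS

__all__ = [
    "SimConfig",
    "gen_truth",
    "gen_polysome_dataset",
    "gen_timecourse",
    "gen_utr_sequences",
]

_DEFAULT_FRACTIONS = {
    # protocol-anchored values: 14.2% of the free pool and 0.4% of the heavy
    # pool (control) are used for cDNA synthesis; the others interpolate.
    ("F", "control"): 0.142,
    ("S", "control"): 0.10,
    ("L", "control"): 0.02,
    ("H", "control"): 0.004,
    ("F", "stimulated"): 0.15,
    ("S", "stimulated"): 0.095,
    ("L", "stimulated"): 0.022,
    ("H", "stimulated"): 0.0045,
}

_DEFAULT_MIX = {"g0": 0.80, "g1": 0.08, "g2": 0.08, "g3": 0.03, "g4": 0.01}


@dataclass
class SimConfig:
    """Study conditions for the synthetic translatome.

    The defaults mirror the reference experiment: three biological
    replicates of four polysome pools in two conditions, a global
    log2(H/L) trend of slope 1 with intercept 0.3, a latent pool
    distribution concentrated in L+H (baseline medians ~3/3/25/69%), and
    an 8-sample LPS time course with one library per timepoint.
    """

    n_genes: int = 2000
    seed: int = 0
    pools: tuple = POOLS
    sampling_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    trend_slope: float = 1.0
    trend_intercept: float = 0.3
    n_replicates: int = 3
    n_active_up: int = 30
    n_active_down: int = 40
    effect_size_sd: float = 4.0
    replicate_noise_sd: float = 0.2
    baseline_concentration: tuple = (0.03, 0.03, 0.25, 0.69)
    dirichlet_scale: float = 30.0
    abundance_log2_sd: float = 1.0
    abundance_scale: float = 500.0
    timepoints: tuple = (0, 15, 30, 45, 60, 75, 90, 120)
    # one culture sampled along the course: between-sample dispersion is
    # technical (library prep), near-Poisson
    nb_dispersion: float = 0.005
    archetype_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    lfc_amplitude: float = 2.0
    depth_log2_sd: float = 0.15
    base_mean_range: tuple = (100.0, 10000.0)
    utr_length_range: tuple = (100, 300)
    are_enrichment: int = 3
    orf_length_range: tuple = (300, 3000)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_active_up + self.n_active_down > self.n_genes:
            raise ValueError("more designated active genes than genes")
        for key, f in self.sampling_fractions.items():
            if not (0 < f <= 1):
                raise ValueError(f"sampling fraction {key} outside (0, 1]")
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")
        tps = np.asarray(self.timepoints, dtype=float)
        if tps[0] != 0 or not np.all(np.diff(tps) > 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.lfc_amplitude <= 0:
            raise ValueError("lfc_amplitude must be positive")
        if self.replicate_noise_sd < 0 or self.effect_size_sd <= 0:
            raise ValueError("noise/effect parameters must be nonnegative/positive")
        if self.utr_length_range[0] < 5:
            raise ValueError("utr_length_range must allow at least one pentamer (>= 5 nt)")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene{i + 1:0{width}d}" for i in range(self.n_genes)]

    # the effect unit is the residual SD; when noise is switched off a
    # small fixed unit keeps designated effects nonzero
    @property
    def effect_unit(self) -> float:
        return self.replicate_noise_sd if self.replicate_noise_sd > 0 else 0.1


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def gen_truth(config: SimConfig) -> pd.DataFrame:
    """Per-gene ground-truth labels shared by all generators."""
    rng = _rng(config, 0)
    genes = config.gene_ids
    order = rng.permutation(config.n_genes)
    shift = np.full(config.n_genes, "none", dtype=object)
    shift[order[: config.n_active_up]] = "up"
    shift[order[config.n_active_up : config.n_active_up + config.n_active_down]] = "down"
    groups = list(config.archetype_mix)
    probs = np.array([config.archetype_mix[g] for g in groups])
    group = rng.choice(groups, size=config.n_genes, p=probs)
    orf = rng.integers(config.orf_length_range[0], config.orf_length_range[1] + 1, config.n_genes)
    last_tp = config.timepoints[-1]
    peak = np.where(
        np.isin(group, ["g3", "g4"]), 30.0, np.where(group == "g0", np.nan, float(last_tp))
    )
    return pd.DataFrame(
        {
            "gene_id": genes,
            "true_shift": shift,
            "true_group": group,
            "peak_time": peak,
            "amplitude": np.where(group == "g0", 0.0, config.lfc_amplitude),
            "orf_length": orf,
            "n_pentamers_planted": np.where(shift == "up", config.are_enrichment, 0),
        }
    )


def gen_polysome_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Polysome pool signals with a global trend plus designated active shifts.

    Latent pool distributions are Dirichlet-distributed around the
    baseline concentration; the stimulated condition applies the global
    trend to log2(H/L) as mass transfer between L and H (pF, pS and
    pL+pH are preserved), designated genes get an extra orthogonal offset
    of ``effect_size_sd`` residual SDs, and each replicate adds Gaussian
    noise on the log2(H/L) scale. Observed signals are the proportions
    times a lognormal gene-abundance factor times the per-(pool,
    condition) sampling fraction.

    Returns (signal table, sampling-fraction table, truth table).
    """
    truth = gen_truth(config)
    rng = _rng(config, 1)
    n = config.n_genes
    base = rng.dirichlet(np.asarray(config.baseline_concentration) * config.dirichlet_scale, n)
    pF, pS, pL, pH = base.T
    x_latent = np.log2(pH / pL)
    lh_total = pL + pH

    sign = np.where(truth["true_shift"] == "up", 1.0, np.where(truth["true_shift"] == "down", -1.0, 0.0))
    delta_d = sign * config.effect_size_sd * config.effect_unit
    delta_y = delta_d * math.sqrt(1.0 + config.trend_slope**2)

    abundance = config.abundance_scale * 2.0 ** rng.normal(0.0, config.abundance_log2_sd, n)

    rows = []
    for rep in range(1, config.n_replicates + 1):
        noise_x = rng.normal(0.0, config.replicate_noise_sd, n) if config.replicate_noise_sd else 0.0
        noise_y = rng.normal(0.0, config.replicate_noise_sd, n) if config.replicate_noise_sd else 0.0
        x_rep = x_latent + noise_x
        y_rep = config.trend_slope * x_latent + config.trend_intercept + delta_y + noise_y
        for condition, logratio in (("control", x_rep), ("stimulated", y_rep)):
            odds = 2.0**logratio
            pH_c = lh_total * odds / (1.0 + odds)
            pL_c = lh_total - pH_c
            props = np.column_stack([pF, pS, pL_c, pH_c])
            for j, pool in enumerate(POOLS):
                frac = config.sampling_fractions[(pool, condition)]
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": config.gene_ids,
                            "condition": condition,
                            "replicate": rep,
                            "pool": pool,
                            "signal": props[:, j] * abundance * frac,
                        }
                    )
                )
    signals = pd.concat(rows, ignore_index=True)
    fractions = pd.DataFrame(
        [
            {"pool": pool, "condition": cond, "fraction": f}
            for (pool, cond), f in config.sampling_fractions.items()
        ]
    )
    return signals, fractions, truth


def _archetype_lfc(group: str, timepoints: np.ndarray, amplitude: float) -> np.ndarray:
    """log2 fold-change trajectory of one archetype on the given grid."""
    t = np.asarray(timepoints, dtype=float)
    a = amplitude
    end = max(float(t[-1]), 120.0)
    if group == "g0":
        return np.zeros_like(t)
    if group in ("g1", "g2"):
        # late monotonic response: first extremum lands on the last timepoint
        lfc = a * np.clip((t - 30.0) / (end - 30.0), 0.0, 1.0)
        return lfc if group == "g1" else -lfc
    # transient early response peaking at 30 min, crossing baseline around
    # 70 min and drifting slightly beyond it so the return extremum lands
    # late (at or after the 60-min boundary)
    knots_t = np.array([0.0, 15.0, 30.0, 45.0, 60.0, end])
    knots_v = np.array([0.0, 0.6, 1.0, 0.5, 0.05, -0.15]) * a
    lfc = np.interp(t, knots_t, knots_v)
    return lfc if group == "g3" else -lfc


def gen_timecourse(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count time course (one library per timepoint) following the archetypes.

    Per gene the mean trajectory is ``base_mean * 2**lfc(t)`` with the
    archetype's log2 trajectory; per-sample sequencing-depth distortions
    are lognormal; counts are negative binomial with the configured
    dispersion (Poisson when it is 0).

    Returns (count matrix with timepoint columns, truth table).
    """
    truth = gen_truth(config)
    rng = _rng(config, 2)
    n = config.n_genes
    tps = np.asarray(config.timepoints, dtype=float)
    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    depth = 2.0 ** rng.normal(0.0, config.depth_log2_sd, len(tps))
    lfc = np.zeros((n, len(tps)))
    for g in set(truth["true_group"]):
        mask = (truth["true_group"] == g).to_numpy()
        lfc[mask] = _archetype_lfc(g, tps, config.lfc_amplitude)
    mean = base[:, None] * 2.0**lfc * depth[None, :]
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mean))
    else:
        counts = rng.poisson(mean)
    mat = pd.DataFrame(counts, index=pd.Index(config.gene_ids, name="gene_id"),
                       columns=[int(t) for t in tps])
    return mat, truth


def gen_utr_sequences(config: SimConfig) -> tuple[dict, pd.DataFrame]:
    """Random-background 3'UTRs with planted AUUUA pentamers for active-up genes.

    Background bases are uniform over ACGT; each designated translationally
    up-regulated gene receives ``are_enrichment`` extra non-overlapping
    ATTTA pentamers at random positions (background occurrences may arise
    on top). Returns (gene_id -> DNA sequence, truth table).
    """
    truth = gen_truth(config)
    rng = _rng(config, 3)
    lo, hi = config.utr_length_range
    seqs = {}
    bases = np.array(list("ACGT"))
    for gid, shift in zip(truth["gene_id"], truth["true_shift"]):
        length = int(rng.integers(lo, hi + 1))
        n_plant = config.are_enrichment if shift == "up" else 0
        if 5 * n_plant > length:
            raise ValueError(f"cannot plant {n_plant} pentamers in {length} nt")
        seq = rng.choice(bases, size=length)
        placed = []
        attempts = 0
        while len(placed) < n_plant:
            pos = int(rng.integers(0, length - 4))
            if all(abs(pos - p) >= 5 for p in placed):
                placed.append(pos)
            attempts += 1
            if attempts > 10_000:
                raise ValueError("could not place non-overlapping pentamers; UTR too short")
        for pos in placed:
            seq[pos : pos + 5] = list("ATTTA")
        seqs[gid] = "".join(seq)
    return seqs, truth
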