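"""Polysome pool quantification.

Sucrose-gradient fractions are pooled into four RNA pools per condition:
free RNA (F), 40S-associated (S), light polysomes with 1-3 ribosomes (L)
and heavy polysomes with >3 ribosomes (H). Because different volume
fractions of each pool are used for cDNA synthesis, observed signals must
first be corrected by the per-pool sampling fraction; the corrected signal
of a gene in one pool divided by the sum over all four pools gives the
pool distribution. The ratio of the heavy to the light proportion (H/L)
is the ribosome load, a per-mRNA proxy for translation efficiency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

POOLS = ("F", "S", "L", "H")
PROP_COLS = ("pF", "pS", "pL", "pH")

__all__ = [
    "POOLS",
    "PROP_COLS",
    "correct_sampling",
    "pool_distribution",
    "ribosome_load",
    "median_pool_proportions",
    "percent_polysomal",
]


def correct_sampling(table: pd.DataFrame, fractions: pd.DataFrame) -> pd.DataFrame:
    """Divide each observed pool signal by its (pool, condition) sampling fraction.

    Parameters
    ----------
    table
        Long-format signal table with columns
        ``gene_id, condition, replicate, pool, signal`` (linear scale).
    fractions
        Table with columns ``pool, condition, fraction``; each fraction is
        the proportion of the pool used for cDNA synthesis, in (0, 1].

    Returns
    -------
    A copy of ``table`` with ``signal`` replaced by ``signal / fraction``.
    """
    required = {"gene_id", "condition", "replicate", "pool", "signal"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"signal table lacks columns: {sorted(missing)}")
    frac = fractions.set_index(["pool", "condition"])["fraction"]
    if (frac <= 0).any() or (frac > 1).any():
        raise ValueError("sampling fractions must lie in (0, 1]")
    key = pd.MultiIndex.from_frame(table[["pool", "condition"]])
    mapped = frac.reindex(key).to_numpy()
    if np.isnan(mapped).any():
        bad = sorted(set(map(tuple, table.loc[np.isnan(mapped), ["pool", "condition"]].to_numpy())))
        raise ValueError(f"missing sampling fraction for (pool, condition): {bad}")
    out = table.copy()
    out["signal"] = table["signal"].to_numpy(dtype=float) / mapped
    return out


def pool_distribution(corrected: pd.DataFrame) -> pd.DataFrame:
    """Normalize corrected signals of each (gene, condition, replicate) over the four pools.

    Returns a wide table with columns ``gene_id, condition, replicate,
    pF, pS, pL, pH, valid``. Quadruples whose four corrected signals are
    all zero are flagged ``valid=False`` (proportions NaN) and are meant
    to be excluded downstream.
    """
    wide = corrected.pivot_table(
        index=["gene_id", "condition", "replicate"],
        columns="pool",
        values="signal",
        aggfunc="first",
    )
    for pool in POOLS:
        if pool not in wide.columns or wide[pool].isna().any():
            bad = wide.index[wide[pool].isna()].get_level_values("gene_id") if pool in wide else wide.index.get_level_values("gene_id")
            raise ValueError(f"missing pool {pool!r} record(s), e.g. gene {bad[0]!r}")
    mat = wide[list(POOLS)].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("corrected signals must be nonnegative")
    total = mat.sum(axis=1)
    valid = total > 0
    props = np.full_like(mat, np.nan)
    props[valid] = mat[valid] / total[valid, None]
    out = wide.reset_index()[["gene_id", "condition", "replicate"]]
    for j, col in enumerate(PROP_COLS):
        out[col] = props[:, j]
    out["valid"] = valid
    return out


def ribosome_load(dist: pd.DataFrame) -> pd.DataFrame:
    """Compute the ribosome load H/L (and its log2) per distribution row.

    Rows with pL == 0 or an invalid distribution get non-finite values
    (never an exception); they carry ``valid=False`` in the output.
    """
    pL = dist["pL"].to_numpy(dtype=float)
    pH = dist["pH"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hl = np.where(pL > 0, pH / pL, np.nan)
        log2_hl = np.log2(hl, where=hl > 0, out=np.full_like(hl, np.nan))
    out = dist[["gene_id", "condition", "replicate"]].copy()
    out["hl"] = hl
    out["log2_hl"] = log2_hl
    out["valid"] = dist["valid"].to_numpy() & np.isfinite(log2_hl)
    return out


def median_pool_proportions(dists: pd.DataFrame, condition: str) -> pd.Series:
    """Per-pool median proportion over genes for one condition.

    Replicates of a gene are averaged first (mean distribution), then the
    componentwise median over genes is taken. Invalid rows are dropped.
    """
    sub = dists[(dists["condition"] == condition) & dists["valid"]]
    if sub.empty:
        raise ValueError(f"no valid distributions for condition {condition!r}")
    per_gene = sub.groupby("gene_id")[list(PROP_COLS)].mean()
    return per_gene.median()


def _interp(positions: np.ndarray, values: np.ndarray, x: float) -> float:
    return float(np.interp(x, positions, values))


def percent_polysomal(
    positions: np.ndarray,
    absorbance: np.ndarray,
    start_80s: float,
    poly_start: float,
    poly_end: float,
    baseline: str = "endpoints",
) -> float:
    """Percentage of polysomal ribosomes from a UV profile trace.

    The trace is baseline-subtracted (straight line between the first and
    last point by default) and integrated by the trapezoidal rule over the
    80S region ``[start_80s, poly_start]`` and the polysome region
    ``[poly_start, poly_end]``. Returns
    ``100 * area(polysomes) / (area(80S) + area(polysomes))``: the 40S/60S
    subunit peaks do not count as ribosomes, and the 80S peak enters the
    denominator only.
    """
    positions = np.asarray(positions, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    if positions.ndim != 1 or positions.shape != absorbance.shape:
        raise ValueError("trace must be two equal-length 1-D arrays")
    if not np.all(np.diff(positions) > 0):
        raise ValueError("trace positions must be strictly increasing")
    if not (positions[0] <= start_80s <= poly_start <= poly_end <= positions[-1]):
        raise ValueError("boundaries must be ordered and inside the trace range")
    if baseline == "endpoints":
        base = np.interp(positions, positions[[0, -1]], absorbance[[0, -1]])
        values = absorbance - base
    elif baseline == "none":
        values = absorbance
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")

    def segment_area(a: float, b: float) -> float:
        inside = (positions > a) & (positions < b)
        xs = np.concatenate(([a], positions[inside], [b]))
        ys = np.concatenate(([_interp(positions, values, a)], values[inside], [_interp(positions, values, b)]))
        return float(np.trapezoid(ys, xs))

    area_80s = segment_area(start_80s, poly_start)
    area_poly = segment_area(poly_start, poly_end)
    denom = area_80s + area_poly
    if denom <= 0:
        raise ValueError("nonpositive total ribosomal area; check boundaries/baseline")
    return 100.0 * area_poly / denom
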