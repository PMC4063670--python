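"""Orthogonal-regression detection of translationally shifted mRNAs.

Stimulated log2(H/L) is regressed against control log2(H/L) over all
genes by total least squares (the first principal axis of the centered
point cloud). The bulk of genes follows a global trend; a gene's signed
perpendicular deviation d from that trend measures its individual change
in translation. Genes are called shifted when the replicate-mean d
exceeds ``k_sd`` empirical SDs of the signed distances and at least
``min_replicates`` biological replicates independently agree.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

__all__ = ["TLSLine", "tls_fit", "orthogonal_distance", "call_shifts"]


@dataclass(frozen=True)
class TLSLine:
    slope: float
    intercept: float
    sd_d: float

    @property
    def vertical(self) -> bool:
        return math.isinf(self.slope)


def tls_fit(x: np.ndarray, y: np.ndarray, robust: bool = False) -> TLSLine:
    """Total-least-squares line through a 2-D cloud.

    Uses the closed-form solution for the major axis: with centered
    second moments Sxx, Syy, Sxy, the slope is
    ``(Syy - Sxx + sqrt((Syy - Sxx)^2 + 4 Sxy^2)) / (2 Sxy)``. The line
    passes through the centroid. ``sd_d`` is the standard deviation
    (ddof=1) of the signed orthogonal distances of the fitted points; with
    ``robust=True`` it is the normal-consistent MAD instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points for a TLS fit")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite coordinates in TLS input")
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    if sxx == 0 and syy == 0:
        raise ValueError("degenerate TLS input: all points identical")
    if sxy == 0:
        if sxx >= syy:
            slope = 0.0
        else:  # vertical major axis
            return TLSLine(math.inf, xm, _sd(x - xm, robust))
    else:
        slope = (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    intercept = ym - slope * xm
    d = _signed_distance(x, y, slope, intercept)
    return TLSLine(slope, intercept, _sd(d, robust))


def _sd(d: np.ndarray, robust: bool) -> float:
    if robust:
        return float(1.4826 * np.median(np.abs(d - np.median(d))))
    return float(np.std(d, ddof=1))


def _signed_distance(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    return (y - slope * x - intercept) / math.sqrt(1.0 + slope * slope)


def orthogonal_distance(x, y, line: TLSLine):
    """Signed perpendicular distance from the line; positive = above.

    Positive d means the stimulated ribosome load increased more than the
    global trend predicts (translational up-shift).
    """
    if line.vertical:
        return np.asarray(x, dtype=float) - line.intercept
    return _signed_distance(np.asarray(x, dtype=float), np.asarray(y, dtype=float), line.slope, line.intercept)


def call_shifts(
    pairs: pd.DataFrame,
    k_sd: float = 2.0,
    min_replicates: int = 2,
    per_replicate_fits: bool = True,
    robust: bool = False,
    min_abs_d: float = 1e-9,
) -> tuple[pd.DataFrame, dict]:
    """Call per-gene translational shifts with the 2-SD + replicate-consensus rule.

    Parameters
    ----------
    pairs
        Long table with columns ``gene_id, replicate, x, y`` where x is
        control and y is stimulated log2(H/L). Genes with a non-finite
        value in any replicate are excluded from fitting and calling (they
        are returned in the QC frame).
    k_sd
        Cutoff in units of the empirical SD of signed orthogonal distances.
    min_replicates
        Minimum number of replicates that must lie beyond the cutoff on
        the same side as the mean.
    per_replicate_fits
        If True (default) each replicate is measured against its own TLS
        fit; otherwise replicates are projected onto the mean-pair fit.

    Returns
    -------
    (calls, info) where ``calls`` has columns ``gene_id, d_mean,
    d_rep<i>..., n_support, call`` and ``info`` carries the fitted lines
    and the excluded-gene QC table.
    """
    required = {"gene_id", "replicate", "x", "y"}
    if not required <= set(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    wide_x = pairs.pivot(index="gene_id", columns="replicate", values="x")
    wide_y = pairs.pivot(index="gene_id", columns="replicate", values="y")
    reps = list(wide_x.columns)
    finite = np.isfinite(wide_x.to_numpy()).all(axis=1) & np.isfinite(wide_y.to_numpy()).all(axis=1)
    qc = pd.DataFrame({"gene_id": wide_x.index[~finite], "reason": "nonfinite_log2_hl"})
    wide_x, wide_y = wide_x[finite], wide_y[finite]
    if len(wide_x) < 3:
        raise ValueError("fewer than 3 genes with finite values in all replicates")

    x_mean = wide_x.mean(axis=1).to_numpy()
    y_mean = wide_y.mean(axis=1).to_numpy()
    mean_line = tls_fit(x_mean, y_mean, robust=robust)
    d_mean = orthogonal_distance(x_mean, y_mean, mean_line)

    d_reps = np.empty((len(wide_x), len(reps)))
    rep_lines = {}
    for j, rep in enumerate(reps):
        xr = wide_x[rep].to_numpy()
        yr = wide_y[rep].to_numpy()
        line = tls_fit(xr, yr, robust=robust) if per_replicate_fits else mean_line
        rep_lines[rep] = line
        d_reps[:, j] = orthogonal_distance(xr, yr, line)

    # the absolute floor only matters for degenerate zero-residual fits,
    # where the empirical SD is rounding noise
    cut_mean = max(k_sd * mean_line.sd_d, min_abs_d)
    cuts_rep = np.maximum([k_sd * rep_lines[rep].sd_d for rep in reps], min_abs_d)
    up_support = (d_reps > cuts_rep).sum(axis=1)
    down_support = (d_reps < -cuts_rep).sum(axis=1)
    call = np.full(len(wide_x), "none", dtype=object)
    n_support = np.zeros(len(wide_x), dtype=int)
    up = (d_mean > cut_mean) & (up_support >= min_replicates)
    down = (d_mean < -cut_mean) & (down_support >= min_replicates)
    call[up] = "up"
    call[down] = "down"
    n_support[up] = up_support[up]
    n_support[down] = down_support[down]

    calls = pd.DataFrame({"gene_id": wide_x.index.to_numpy(), "d_mean": d_mean})
    for j, rep in enumerate(reps):
        calls[f"d_rep{rep}"] = d_reps[:, j]
    calls["n_support"] = n_support
    calls["call"] = call
    info = {"mean_line": mean_line, "replicate_lines": rep_lines, "qc": qc, "k_sd": k_sd, "min_replicates": min_replicates}
    return calls, info
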