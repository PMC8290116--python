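"""Windowed four-taxon introgression statistics.

Sites carry derived-allele frequencies p1, p2, p3, p4 for populations
P1, P2, P3 and the outgroup, with the topology (((P1,P2),P3),O).  All
statistics use the frequency (not count) forms:

* per-site weights  ABBA = (1-p1) p2 p3 (1-p4),  BABA = p1 (1-p2) p3 (1-p4)
* Patterson's D = sum(ABBA-BABA) / sum(ABBA+BABA), with a weighted 1-Mb
  block jackknife for the genome-wide standard error,
* f_dM — the signed, dynamic-donor admixture-fraction statistic: the
  denominator substitutes the donor frequency max(p2,p3) (or max(p1,p3),
  negated) for the sharing pair, depending on which ingroup the site
  favours,
* D_XY — mean per-site pairwise divergence p_A(1-p_B) + p_B(1-p_A),
* RND — relative node depth, D_XY(focal,target) / D_XY(focal,normalizer),
* +/-3 SD outlier flagging over retained windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "site_weights",
    "patterson_d",
    "block_jackknife",
    "JackknifeSummary",
    "f_dm",
    "dxy",
    "rnd",
    "flag_outliers",
    "window_statistics",
]


@dataclass
class JackknifeSummary:
    D: float
    se: float
    z: float
    p: float
    n_blocks: int
    block_size: int


def site_weights(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site ABBA/BABA weights and f_dM denominator contributions.

    Returns a frame with columns abba, baba, fdm_denom, informative.
    A site is informative when its ABBA+BABA weight is positive.
    """
    p1 = sites["p1"].to_numpy(dtype=float)
    p2 = sites["p2"].to_numpy(dtype=float)
    p3 = sites["p3"].to_numpy(dtype=float)
    p4 = sites["p4"].to_numpy(dtype=float)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    # dynamic-donor denominator
    pd23 = np.maximum(p2, p3)   # site favours P2–P3 sharing (p2 >= p1)
    pd13 = np.maximum(p1, p3)   # site favours P1–P3 sharing (p1 > p2)
    denom23 = (1 - p1) * pd23 * pd23 * (1 - p4) - p1 * (1 - pd23) * pd23 * (1 - p4)
    denom13 = -((1 - pd13) * p2 * pd13 * (1 - p4) - pd13 * (1 - p2) * pd13 * (1 - p4))
    fdm_denom = np.where(p2 >= p1, denom23, denom13)
    out = sites[["chrom", "pos"]].copy() if {"chrom", "pos"} <= set(sites.columns) else pd.DataFrame(index=sites.index)
    out["abba"] = abba
    out["baba"] = baba
    out["fdm_denom"] = fdm_denom
    out["informative"] = (abba + baba) > 0
    return out


def patterson_d(sites: pd.DataFrame) -> Optional[float]:
    """Patterson's D over a set of sites; None when the denominator is 0."""
    w = site_weights(sites)
    denom = float((w["abba"] + w["baba"]).sum())
    if denom == 0:
        return None
    return float((w["abba"] - w["baba"]).sum() / denom)


def f_dm(sites: pd.DataFrame) -> Optional[float]:
    """Signed dynamic-donor admixture statistic over a window of sites.

    Positive values mean excess P3–P2 sharing, negative excess P3–P1
    sharing.  None when the denominator is zero (window dropped)."""
    w = site_weights(sites)
    denom = float(w["fdm_denom"].sum())
    if denom == 0:
        return None
    return float((w["abba"] - w["baba"]).sum() / denom)


def dxy(p_a: Sequence[float], p_b: Sequence[float]) -> Optional[float]:
    """Mean per-site pairwise divergence between two populations.

    Sites monomorphic and identical in both contribute 0; a window with no
    genotyped sites yields None (missing, not zero)."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.size == 0:
        return None
    return float(np.mean(p_a * (1 - p_b) + p_b * (1 - p_a)))


def rnd(dxy_focal_target: Optional[float], dxy_focal_normalizer: Optional[float]) -> Optional[float]:
    """Relative node depth: divergence to the target normalized by
    divergence to the normalizer lineage; None on a missing or zero
    denominator."""
    if dxy_focal_target is None or dxy_focal_normalizer is None or dxy_focal_normalizer == 0:
        return None
    return dxy_focal_target / dxy_focal_normalizer


def block_jackknife(
    sites: pd.DataFrame,
    block_size: int = 1_000_000,
) -> JackknifeSummary:
    """Genome-wide D with a weighted block jackknife standard error.

    Blocks are contiguous ``block_size`` segments per chromosome; block
    weights are the per-block denominator (ABBA+BABA) mass, the standard
    weighting for a ratio statistic.  Delete-one estimates feed the
    weighted-jackknife variance (Busing's formulas).  With identical
    blocks the SE degenerates to 0; p is then reported as 0 when D != 0
    (and 1 otherwise) with a warning.
    """
    w = site_weights(sites)
    if "chrom" not in w.columns:
        w = w.copy()
        w["chrom"] = "0"
        w["pos"] = np.arange(1, len(w) + 1)
    w["block"] = list(zip(w["chrom"], (w["pos"].astype(int) - 1) // block_size))
    grouped = w.groupby("block", sort=True)
    num_j = (grouped["abba"].sum() - grouped["baba"].sum()).to_numpy()
    den_j = (grouped["abba"].sum() + grouped["baba"].sum()).to_numpy()
    nonempty = den_j > 0
    num_j, den_j = num_j[nonempty], den_j[nonempty]
    g = len(num_j)
    if g < 2:
        raise ValueError("block jackknife requires at least 2 nonempty blocks")
    num_tot, den_tot = num_j.sum(), den_j.sum()
    d_hat = num_tot / den_tot
    d_minus = (num_tot - num_j) / (den_tot - den_j)
    m = den_j
    n = den_tot
    h = n / m
    theta_j = g * d_hat - float(((1 - m / n) * d_minus).sum())
    pseudo = h * d_hat - (h - 1) * d_minus
    var = float(np.sum((pseudo - theta_j) ** 2 / (h - 1)) / g)
    se = np.sqrt(max(var, 0.0))
    if se == 0:
        warnings.warn("degenerate jackknife: all blocks identical; SE = 0")
        z = np.inf if d_hat != 0 else 0.0
        p = 0.0 if d_hat != 0 else 1.0
    else:
        z = d_hat / se
        p = 2 * sps.norm.sf(abs(z))
    return JackknifeSummary(D=float(d_hat), se=float(se), z=float(z), p=float(p), n_blocks=g, block_size=block_size)


def flag_outliers(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Flag values strictly outside mean ± k·SD over all finite entries."""
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values")
    mean = arr[finite].mean()
    sd = arr[finite].std(ddof=0)
    flags = np.zeros(arr.shape, dtype=bool)
    flags[finite] = (arr[finite] < mean - k * sd) | (arr[finite] > mean + k * sd)
    return flags


def window_statistics(
    sites: pd.DataFrame,
    d_window: int = 1_000_000,
    fdm_window: int = 100_000,
    min_sites: int = 100,
    outlier_sd: float = 3.0,
) -> Dict[str, pd.DataFrame]:
    """Windowed D, f_dM, D_XY and RND tables with outlier flags.

    Window grids are anchored at coordinate 0 of each chromosome;
    positions are 1-based.  Windows with fewer than ``min_sites``
    informative sites are absent from the D/f_dM output.  D_XY and RND are
    computed on the f_dM grid over all genotyped sites; both RND
    orientations (P1- and P2-normalized divergence of P3) are emitted.

    Returns {"d_windows": ..., "fdm_windows": ...} frames.
    """
    w = site_weights(sites)
    df = pd.concat([sites.reset_index(drop=True), w[["abba", "baba", "fdm_denom", "informative"]].reset_index(drop=True)], axis=1)

    def _assign(frame, size):
        return (frame["pos"].astype(int) - 1) // size

    d_rows = []
    df["win"] = _assign(df, d_window)
    for (chrom, win), sub in df.groupby(["chrom", "win"], sort=True):
        n_inf = int(sub["informative"].sum())
        if n_inf < min_sites:
            continue
        denom = (sub["abba"] + sub["baba"]).sum()
        d_rows.append(
            {
                "chrom": chrom,
                "start": int(win * d_window),
                "end": int((win + 1) * d_window),
                "n_informative": n_inf,
                "D": (sub["abba"] - sub["baba"]).sum() / denom if denom > 0 else np.nan,
            }
        )
    d_windows = pd.DataFrame(d_rows, columns=["chrom", "start", "end", "n_informative", "D"])

    f_rows = []
    df["win"] = _assign(df, fdm_window)
    for (chrom, win), sub in df.groupby(["chrom", "win"], sort=True):
        n_inf = int(sub["informative"].sum())
        if n_inf < min_sites:
            continue
        fdenom = sub["fdm_denom"].sum()
        d13 = dxy(sub["p1"], sub["p3"])
        d23 = dxy(sub["p2"], sub["p3"])
        d12 = dxy(sub["p1"], sub["p2"])
        f_rows.append(
            {
                "chrom": chrom,
                "start": int(win * fdm_window),
                "end": int((win + 1) * fdm_window),
                "n_informative": n_inf,
                "f_dM": (sub["abba"] - sub["baba"]).sum() / fdenom if fdenom != 0 else np.nan,
                "dxy_p1_p3": d13,
                "dxy_p2_p3": d23,
                "dxy_p1_p2": d12,
                # divergence of each ingroup to P3, normalized by the
                # between-ingroup divergence (both orientations emitted)
                "rnd_p2": rnd(d23, d12),
                "rnd_p1": rnd(d13, d12),
            }
        )
    fdm_windows = pd.DataFrame(
        f_rows,
        columns=[
            "chrom", "start", "end", "n_informative", "f_dM",
            "dxy_p1_p3", "dxy_p2_p3", "dxy_p1_p2", "rnd_p2", "rnd_p1",
        ],
    )
    for col, flag in [("f_dM", "f_dM_outlier"), ("rnd_p2", "rnd_outlier")]:
        if len(fdm_windows) >= 2:
            fdm_windows[flag] = flag_outliers(fdm_windows[col].to_numpy(), k=outlier_sd)
        else:
            fdm_windows[flag] = False
    return {"d_windows": d_windows, "fdm_windows": fdm_windows}
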