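"""Genome-wide 5hmC/5mC summaries and high-5hmC locus selection.

The high-5hmC set — the top fraction of loci ranked by median tumor 5hmC —
anchors every downstream enrichment, differential and clustering analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CpGAnnotation, CytosineProportions, SampleFrame
from .exceptions import ConfigurationError, DegenerateDataError

logger = logging.getLogger(__name__)


@dataclass
class WelchResult:
    statistic: float
    df: float
    p_value: float
    degenerate: bool = False
    reason: str | None = None


def sample_medians(
    props: CytosineProportions, samples: SampleFrame
) -> tuple[pd.DataFrame, dict]:
    """Per-sample median 5hmC and 5mC over all loci, with a Welch two-sample
    t-test comparing tumor vs non-tumor per-sample medians for each mark.

    Returns ``(medians, tests)`` where ``medians`` has columns
    ``median_5hmc`` / ``median_5mc`` / ``group`` and ``tests`` maps mark name
    to a :class:`WelchResult`. Groups with fewer than two samples, or
    zero-variance medians, yield a degenerate (skipped) test with a logged
    reason; the medians are still returned.
    """
    med = pd.DataFrame(
        {
            "median_5hmc": props.p_5hmc.median(axis=0),
            "median_5mc": props.p_5mc.median(axis=0),
        }
    )
    med["group"] = samples.table.loc[med.index, "group"]
    tests: dict[str, WelchResult] = {}
    tum = med[med["group"] == "tumor"]
    non = med[med["group"] == "nontumor"]
    for mark in ("median_5hmc", "median_5mc"):
        x, y = tum[mark].to_numpy(), non[mark].to_numpy()
        if len(x) < 2 or len(y) < 2:
            reason = "a group has fewer than 2 samples"
            logger.warning("Welch test skipped for %s: %s", mark, reason)
            tests[mark] = WelchResult(np.nan, np.nan, np.nan, True, reason)
            continue
        if np.var(x) == 0 and np.var(y) == 0:
            reason = "zero variance in both groups"
            logger.warning("Welch test degenerate for %s: %s", mark, reason)
            tests[mark] = WelchResult(np.nan, np.nan, np.nan, True, reason)
            continue
        res = stats.ttest_ind(x, y, equal_var=False)
        tests[mark] = WelchResult(float(res.statistic), float(res.df), float(res.pvalue))
    return med, tests


def select_high_5hmc(
    props: CytosineProportions, tumor_ids, frac: float = 0.05
) -> pd.DataFrame:
    """Mark the top ``floor(frac * N)`` loci by median tumor 5hmC.

    Ranking is by median 5hmC across all tumor samples pooled, descending;
    ties are broken by lexicographic locus ID so selection is deterministic.
    Returns a LocusSummary table (median_5hmc_tumor, median_5mc_tumor,
    percentile_rank, is_high_5hmc) with the realised selection threshold
    stored in ``df.attrs["threshold_median"]``.
    """
    if not (0.0 < frac < 1.0):
        raise ConfigurationError(f"frac must be in (0,1), got {frac!r}")
    tumor_ids = list(tumor_ids)
    n = len(props.locus_ids)
    k = int(np.floor(frac * n))
    if k == 0:
        raise ConfigurationError(
            f"frac={frac} selects 0 of {n} loci; increase frac or the universe"
        )
    med_h = props.p_5hmc[tumor_ids].median(axis=1)
    med_m = props.p_5mc[tumor_ids].median(axis=1)
    # mergesort is stable; pre-sorting by locus ID makes ties deterministic
    order = (
        pd.DataFrame({"m": med_h})
        .sort_index()
        .sort_values(by="m", ascending=False, kind="mergesort")
    )
    selected = order.index[:k]
    summary = pd.DataFrame(
        {
            "median_5hmc_tumor": med_h,
            "median_5mc_tumor": med_m,
            "percentile_rank": med_h.rank(method="average", pct=True),
            "is_high_5hmc": med_h.index.isin(selected),
        }
    )
    summary.attrs["threshold_median"] = float(order["m"].iloc[k - 1])
    summary.attrs["n_selected"] = int(k)
    return summary


def per_locus_correlation(
    props: CytosineProportions, tumor_ids
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Spearman correlation between 5mC and 5hmC across tumors, per locus.

    Uses average ranks for ties. Loci with zero variance in either mark are
    recorded as NaN, excluded from the ECDF and counted. Returns
    ``(rho, ecdf, n_undefined)`` where ``ecdf`` has columns ``rho`` and
    ``cumulative_fraction``.
    """
    tumor_ids = list(tumor_ids)
    if len(tumor_ids) < 3:
        raise DegenerateDataError("per-locus correlation needs >= 3 tumor samples")
    h = props.p_5hmc[tumor_ids].to_numpy(dtype=float)
    m = props.p_5mc[tumor_ids].to_numpy(dtype=float)
    rh = stats.rankdata(h, axis=1)
    rm = stats.rankdata(m, axis=1)
    rh_c = rh - rh.mean(axis=1, keepdims=True)
    rm_c = rm - rm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rh_c**2).sum(axis=1) * (rm_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rh_c * rm_c).sum(axis=1) / denom, np.nan)
    rho_s = pd.Series(rho, index=props.locus_ids, name="spearman_5mc_5hmc")
    n_undefined = int(np.isnan(rho).sum())
    if n_undefined:
        logger.warning("%d loci with undefined correlation (zero variance)", n_undefined)
    vals = np.sort(rho[~np.isnan(rho)])
    ecdf = pd.DataFrame(
        {"rho": vals, "cumulative_fraction": np.arange(1, len(vals) + 1) / len(vals)}
    )
    return rho_s, ecdf, n_undefined


def tss_profile(
    props: CytosineProportions,
    ann: CpGAnnotation,
    samples: SampleFrame,
    window_bp: int = 10_000,
    bin_bp: int = 500,
) -> pd.DataFrame:
    """Median 5hmC and 5mC in half-open TSS-distance bins, per group.

    Bins partition [-window_bp, +window_bp) as ``[lo, lo + bin_bp)``; loci
    outside the window are ignored; empty bins report NaN, not zero.
    Negative distances are upstream of the TSS.
    """
    if window_bp <= 0 or bin_bp <= 0:
        raise ConfigurationError("window_bp and bin_bp must be positive")
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    d = ann.table.loc[props.locus_ids, "tss_distance"].to_numpy()
    in_window = (d >= -window_bp) & (d < window_bp)
    bin_idx = np.searchsorted(edges, d, side="right") - 1

    rows = []
    groups = {
        "tumor": list(samples.tumor_ids),
        "nontumor": list(samples.nontumor_ids),
    }
    for b in range(len(edges) - 1):
        mask = in_window & (bin_idx == b)
        row = {"bin_lo": int(edges[b]), "bin_hi": int(edges[b + 1])}
        for gname, gids in groups.items():
            if mask.any() and gids:
                row[f"median_5hmc_{gname}"] = float(
                    np.median(props.p_5hmc.loc[mask, gids].to_numpy())
                )
                row[f"median_5mc_{gname}"] = float(
                    np.median(props.p_5mc.loc[mask, gids].to_numpy())
                )
            else:
                row[f"median_5hmc_{gname}"] = np.nan
                row[f"median_5mc_{gname}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def total_5hmc_index(
    props: CytosineProportions, tumor_ids
) -> tuple[pd.Series, float]:
    """Label each tumor High/Low by mean 5hmC over all loci.

    A tumor is "High Total 5hmC" if its mean is strictly greater than the
    median of the per-tumor means; otherwise Low. Returns ``(labels,
    threshold)``.
    """
    tumor_ids = list(tumor_ids)
    if len(tumor_ids) < 2:
        raise DegenerateDataError("total 5hmC index needs >= 2 tumor samples")
    means = props.p_5hmc[tumor_ids].mean(axis=0)
    if means.nunique() == 1:
        raise DegenerateDataError("all per-tumor means identical; index undefined")
    threshold = float(means.median())
    labels = pd.Series(
        np.where(means > threshold, "High", "Low"), index=means.index, name="total_5hmc"
    )
    return labels, threshold
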