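"""Per-CpG covariate-adjusted differential hydroxymethylation.

Each locus gets an ordinary least squares fit of its 5hmC beta values on a
group indicator plus age and sex, vectorised across loci (one shared design
matrix, closed-form normal equations). Benjamini–Hochberg q-values are
assigned across all tested loci; DHMRs are the loci passing the FDR and
direction filter. An optional limma-style empirical-Bayes moderation
shrinks the residual variances toward a common prior fitted by method of
moments on the log-variances; it never touches the effect estimates.

The group effect is reported on the beta scale; a log2 fold change of group
mean 5hmC (1e-6 floor) is reported alongside it, since volcano-style
displays conventionally use the latter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CytosineProportions, SampleFrame
from .exceptions import ConfigurationError, DegenerateDataError, IngestError

logger = logging.getLogger(__name__)

_LOG2_FLOOR = 1e-6


def _resolve_contrast(samples: SampleFrame, contrast) -> tuple[list, list]:
    """Map (case_label, control_label) to sample ID lists.

    Labels are matched against the ``group`` column first, then ``subtype``.
    """
    case_label, control_label = contrast
    tab = samples.table

    def ids_for(label):
        hit = tab.index[tab["group"] == label]
        if len(hit) == 0:
            hit = tab.index[tab["subtype"] == label]
        if len(hit) == 0:
            raise ConfigurationError(f"contrast label {label!r} matches no samples")
        return list(hit)

    return ids_for(case_label), ids_for(control_label)


def _design_matrix(samples: SampleFrame, case_ids, control_ids, covariates):
    ids = list(case_ids) + list(control_ids)
    tab = samples.table.loc[ids]
    cols = {"intercept": np.ones(len(ids)), "group": np.r_[np.ones(len(case_ids)), np.zeros(len(control_ids))]}
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "age":
            cols["age"] = tab["age"].to_numpy(dtype=float)
            names.append("age")
        elif cov == "sex":
            cols["sex_male"] = (tab["sex"] == "M").to_numpy(dtype=float)
            names.append("sex_male")
        else:
            raise ConfigurationError(f"unsupported covariate {cov!r}")
    X = np.column_stack([cols[n] for n in names])
    return X, names, ids


def _check_rank(X: np.ndarray, names) -> None:
    n, p = X.shape
    if n < p + 1:
        raise DegenerateDataError(
            f"{n} samples cannot support {p} parameters with residual df >= 1"
        )
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    aliased = [names[j] for j in range(p) if diag[j] < tol]
    if aliased:
        raise DegenerateDataError(f"design matrix rank-deficient; aliased columns: {aliased}")


def _trigamma_inverse(x: float) -> float:
    """Invert the trigamma function by Newton iteration (for the
    empirical-Bayes prior df fit)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink residual variances toward a common prior (method of moments on
    log variances). Returns (posterior variances, prior df)."""
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    ebar = np.nanmean(e)
    evar = np.nanvar(e, ddof=1)
    rhs = evar - special.polygamma(1, df / 2)
    if not np.isfinite(rhs) or rhs <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(ebar + special.digamma(df / 2) - np.log(df / 2)))
        return np.full_like(s2, s0_sq), d0
    d0 = 2 * _trigamma_inverse(rhs)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0


def fit_locus_models(
    props: CytosineProportions,
    samples: SampleFrame,
    contrast=("tumor", "nontumor"),
    covariates=("age", "sex"),
    universe=None,
    moderated: bool = False,
) -> pd.DataFrame:
    """OLS of 5hmC beta on group + covariates, per locus.

    Returns a DataFrame indexed by locus with columns effect / log2_fc /
    t_stat / p_value / q_value / direction. ``universe`` restricts the
    tested loci (e.g. the high-5hmC set); default is all loci.
    """
    case_ids, control_ids = _resolve_contrast(samples, contrast)
    X, names, ids = _design_matrix(samples, case_ids, control_ids, covariates)
    _check_rank(X, names)
    n, p = X.shape
    df = n - p

    loci = props.locus_ids if universe is None else pd.Index(universe)
    Y = props.p_5hmc.loc[loci, ids].to_numpy(dtype=float).T  # n x L

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y  # p x L
    resid = Y - X @ coef
    s2 = (resid**2).sum(axis=0) / df
    c_group = xtx_inv[1, 1]

    if moderated:
        s2_used, d0 = _squeeze_var(s2, df)
        df_used = df + d0 if np.isfinite(d0) else np.inf
    else:
        s2_used, df_used = s2, df

    effect = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_used * c_group)
        t = np.where(se > 0, effect / se, 0.0)
    if np.isfinite(df_used):
        pvals = 2 * stats.t.sf(np.abs(t), df_used)
    else:
        pvals = 2 * stats.norm.sf(np.abs(t))

    mean_case = props.p_5hmc.loc[loci, case_ids].mean(axis=1).to_numpy()
    mean_ctrl = props.p_5hmc.loc[loci, control_ids].mean(axis=1).to_numpy()
    log2_fc = np.log2(
        np.maximum(mean_case, _LOG2_FLOOR) / np.maximum(mean_ctrl, _LOG2_FLOOR)
    )

    out = pd.DataFrame(
        {
            "effect": effect,
            "log2_fc": log2_fc,
            "t_stat": t,
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
            "direction": np.where(effect < 0, "hypo", "hyper"),
        },
        index=loci,
    )
    out.attrs["residual_df"] = df
    out.attrs["moderated"] = bool(moderated)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise IngestError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def extract_dhmr(
    rows: pd.DataFrame, fdr: float = 0.1, direction: str = "hypo"
) -> pd.Index:
    """Loci with q-value below ``fdr`` and matching effect direction."""
    if direction not in {"hypo", "hyper", "both"}:
        raise ConfigurationError(f"direction must be hypo/hyper/both, got {direction!r}")
    keep = rows["q_value"] < fdr
    if direction != "both":
        keep &= rows["direction"] == direction
    selected = rows.index[keep]
    logger.info("extract_dhmr: %d loci at FDR < %s (%s)", len(selected), fdr, direction)
    return selected


def stratified_contrasts(
    props: CytosineProportions,
    samples: SampleFrame,
    subtypes,
    covariates=("age", "sex"),
    universe=None,
    moderated: bool = False,
) -> dict:
    """Run the subtype-vs-nontumor differential model for each subtype.

    Subtypes with fewer than two samples are skipped with a logged reason.
    Returns a dict mapping subtype to its results table.
    """
    results = {}
    for subtype in subtypes:
        n_sub = int((samples.table["subtype"] == subtype).sum())
        if n_sub < 2:
            logger.warning(
                "subtype %r skipped: %d sample(s), need >= 2", subtype, n_sub
            )
            continue
        results[subtype] = fit_locus_models(
            props,
            samples,
            contrast=(subtype, "nontumor"),
            covariates=covariates,
            universe=universe,
            moderated=moderated,
        )
    return results
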