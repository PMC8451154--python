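"""5hmC-profile clustering of tumors and survival association.

The pipeline here mirrors the standard methylation-survival workflow:
select the most variable 5hmC loci across tumors, cluster tumor profiles
with the recursively partitioned beta-mixture model, label the two leaves
high/low 5hmC by mean level, and relate class membership to death and
recurrence through multivariable Cox proportional hazards models (Efron tie
handling, Wald intervals, Harrell concordance) and Kaplan–Meier / log-rank
comparisons. Cox and KM estimation are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .datatypes import CytosineProportions, SampleFrame
from .exceptions import ConfigurationError, DegenerateDataError
from .rpmm import ClusterTree, rpmm_cluster

logger = logging.getLogger(__name__)

_OUTCOMES = {
    "death": ("death_time", "death_event"),
    "recurrence": ("recurrence_time", "recurrence_event"),
}

#: reference levels of the Cox design (female, glioma, high-5hmC class)
SUBTYPE_REFERENCE = "glioma"
CLUSTER_REFERENCE = "high5hmC"


def top_variable_loci(
    props: CytosineProportions, tumor_ids, n: int
) -> pd.Index:
    """The ``n`` loci with largest 5hmC sample variance across tumors.

    Variance uses the n-1 denominator and is computed over tumor samples
    only; ties are broken by lexicographic locus ID.
    """
    tumor_ids = list(tumor_ids)
    if n > len(props.locus_ids):
        raise ConfigurationError(
            f"n={n} exceeds universe size {len(props.locus_ids)}"
        )
    if len(tumor_ids) < 2:
        raise DegenerateDataError("variance needs >= 2 tumor samples")
    var = props.p_5hmc[tumor_ids].var(axis=1, ddof=1)
    order = var.sort_index().sort_values(ascending=False, kind="mergesort")
    return pd.Index(order.index[: int(n)])


def cluster_tumors(
    props: CytosineProportions, tumor_ids, loci, **rpmm_kwargs
) -> ClusterTree:
    """Run RPMM on the tumors x selected-loci 5hmC matrix."""
    betas = props.p_5hmc.loc[list(loci), list(tumor_ids)].T
    return rpmm_cluster(betas, **rpmm_kwargs)


def label_clusters(
    tree: ClusterTree, props: CytosineProportions, samples: SampleFrame | None = None
) -> tuple[pd.Series, dict]:
    """Name the two leaves high5hmC / low5hmC by mean 5hmC level.

    Requires a tree with exactly two leaves. Also reports a Kruskal–Wallis
    test of per-sample mean 5hmC by class and, when a sample table is given,
    Fisher tests of class vs tumor subtype (one-vs-rest per subtype).
    Returns ``(labels, diagnostics)``.
    """
    leaves = tree.leaves()
    if len(leaves) != 2:
        raise DegenerateDataError(
            f"expected exactly 2 leaves, found {len(leaves)}; "
            "review max_depth / min_leaf / locus selection"
        )
    loci = tree.locus_ids
    means = {}
    for leaf in leaves:
        means[leaf.node_id] = float(
            props.p_5hmc.loc[loci, leaf.members].to_numpy().mean()
        )
    ids = list(means)
    if means[ids[0]] == means[ids[1]]:
        raise DegenerateDataError("leaf mean 5hmC levels tie; labels undefined")
    high_id = max(ids, key=lambda i: means[i])
    labels = tree.assignments().map(
        lambda nid: "high5hmC" if nid == high_id else "low5hmC"
    )
    labels.name = "cluster_5hmc"

    per_sample_mean = props.p_5hmc.loc[loci, labels.index].mean(axis=0)
    groups = [
        per_sample_mean[labels == "high5hmC"].to_numpy(),
        per_sample_mean[labels == "low5hmC"].to_numpy(),
    ]
    kw_stat, kw_p = stats.kruskal(*groups)
    diagnostics = {
        "leaf_means": means,
        "high_leaf": high_id,
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
    }
    if samples is not None:
        fisher = {}
        subtypes = samples.table.loc[labels.index, "subtype"]
        for st in sorted(subtypes.unique()):
            a = int(((labels == "low5hmC") & (subtypes == st)).sum())
            b = int(((labels == "low5hmC") & (subtypes != st)).sum())
            c = int(((labels == "high5hmC") & (subtypes == st)).sum())
            d = int(((labels == "high5hmC") & (subtypes != st)).sum())
            or_, p = stats.fisher_exact([[a, b], [c, d]])
            fisher[st] = {"odds_ratio": float(or_), "p_value": float(p)}
        diagnostics["fisher_cluster_vs_subtype"] = fisher
    return labels, diagnostics


@dataclass
class SurvivalFit:
    """Cox model results: per-covariate log-hazards, hazard ratios with 95%
    Wald CIs, p-values, concordance and bookkeeping."""

    summary: pd.DataFrame  # index covariate; coef, hr, ci_low, ci_high, p
    concordance: float
    n_subjects: int
    n_events: int
    dropped_ids: list = field(default_factory=list)
    non_estimable: list = field(default_factory=list)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _cox_frame(samples, outcome, covariates, cluster_labels):
    if outcome not in _OUTCOMES:
        raise ConfigurationError(f"outcome must be death or recurrence, got {outcome!r}")
    tcol, ecol = _OUTCOMES[outcome]
    tab = samples.table.loc[samples.tumor_ids].copy()
    df = pd.DataFrame(index=tab.index)
    df["time"] = tab[tcol].astype(float)
    df["event"] = tab[ecol].astype(float)
    for cov in covariates:
        if cov == "age":
            df["age"] = tab["age"].astype(float)
        elif cov == "sex":
            df["sex_male"] = (tab["sex"] == "M").astype(float)
        elif cov in ("tumor_type", "subtype"):
            for st in sorted(tab["subtype"].unique()):
                if st == SUBTYPE_REFERENCE:
                    continue
                df[f"subtype_{st}"] = (tab["subtype"] == st).astype(float)
        elif cov == "cluster":
            if cluster_labels is None:
                raise ConfigurationError("cluster covariate requires cluster_labels")
            aligned = cluster_labels.reindex(tab.index)
            df["cluster_low"] = (aligned == "low5hmC").astype(float)
            df.loc[aligned.isna(), "cluster_low"] = np.nan
        else:
            raise ConfigurationError(f"unsupported covariate {cov!r}")
    return df


def cox_fit(
    samples: SampleFrame,
    outcome: str = "death",
    covariates=("age", "sex", "subtype", "cluster"),
    cluster_labels: pd.Series | None = None,
) -> SurvivalFit:
    """Multivariable Cox proportional hazards fit (Efron ties).

    Subjects with missing time/event (or missing cluster label) are dropped
    with their IDs logged. Reference levels: female, glioma, high-5hmC
    class. Zero observed events raise a degenerate-data error; covariates
    with monotone likelihood (perfect separation) are flagged as
    non-estimable rather than trusted.
    """
    df = _cox_frame(samples, outcome, covariates, cluster_labels)
    complete = df.dropna()
    dropped = [str(i) for i in df.index.difference(complete.index)]
    if dropped:
        logger.warning("cox_fit dropped %d subjects with missing data: %s", len(dropped), dropped)
    if len(complete) == 0 or complete["event"].sum() == 0:
        raise DegenerateDataError(f"no observed {outcome} events; Cox fit undefined")
    # constant covariate columns carry no information and break the fit
    keep = [c for c in complete.columns if c in ("time", "event") or complete[c].nunique() > 1]
    const = [c for c in complete.columns if c not in keep]
    if const:
        logger.warning("cox_fit dropped constant covariates: %s", const)
    complete = complete[keep]

    cph = CoxPHFitter()  # Efron tie handling is the lifelines default
    try:
        cph.fit(complete, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise DegenerateDataError(f"Cox fit did not converge: {err}") from err
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    # monotone likelihood shows up as runaway coefficients / huge SEs
    non_est = [str(c) for c in out.index[(out["se"] > 100) | (out["coef"].abs() > 50)]]
    if non_est:
        logger.warning("cox_fit: non-estimable covariates (separation): %s", non_est)
    return SurvivalFit(
        summary=out,
        concordance=float(cph.concordance_index_),
        n_subjects=int(len(complete)),
        n_events=int(complete["event"].sum()),
        dropped_ids=dropped,
        non_estimable=non_est,
    )


def km_logrank(
    samples: SampleFrame, group_labels: pd.Series, outcome: str = "death"
) -> tuple[dict, float, float]:
    """Kaplan–Meier curves per group and the two-group log-rank test.

    Returns ``(curves, statistic, p_value)`` where ``curves`` maps group
    name to the KM survival function (a DataFrame indexed by time).
    """
    if outcome not in _OUTCOMES:
        raise ConfigurationError(f"outcome must be death or recurrence, got {outcome!r}")
    tcol, ecol = _OUTCOMES[outcome]
    tab = samples.table
    aligned = group_labels.dropna()
    groups = sorted(aligned.unique())
    if len(groups) != 2:
        raise DegenerateDataError(f"log-rank needs exactly 2 groups, got {groups}")
    data = {}
    for g in groups:
        ids = aligned.index[aligned == g]
        sub = tab.loc[ids, [tcol, ecol]].dropna()
        if len(sub) == 0:
            raise DegenerateDataError(f"group {g!r} has no subjects with follow-up")
        data[g] = sub
    total_events = sum(d[ecol].sum() for d in data.values())
    if total_events == 0:
        raise DegenerateDataError("no observed events; log-rank undefined")
    curves = {}
    for g, sub in data.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub[tcol], event_observed=sub[ecol], label=str(g))
        curves[g] = kmf.survival_function_
    res = logrank_test(
        data[groups[0]][tcol], data[groups[1]][tcol],
        event_observed_A=data[groups[0]][ecol],
        event_observed_B=data[groups[1]][ecol],
    )
    return curves, float(res.test_statistic), float(res.p_value)
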