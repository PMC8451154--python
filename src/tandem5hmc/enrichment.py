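"""Enrichment of locus sets in genomic contexts, regulatory flags and
region-set collections, plus gene-level high-5hmC scoring.

2x2 tables are built as (in query x in feature) over an explicit universe:
the high-5hmC set against the full measured universe for context analyses,
or DHMRs against the high-5hmC set. The odds ratio is the unconditional
cross-product ratio with a Woolf (log-OR normal) 95% CI; p-values are
two-sided Fisher exact, or Cochran–Mantel–Haenszel when stratified by
probe design type. Zero cells get a Haldane–Anscombe 0.5 correction for the
OR/CI only and are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from .datatypes import CONTEXTS, CpGAnnotation
from .exceptions import ConfigurationError, DegenerateDataError, IngestError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass
class RegionCollection:
    """A named set of 0-based half-open genomic intervals (BED semantics)."""

    name: str
    trees: dict  # chrom -> IntervalTree
    source: str | None = None

    @classmethod
    def from_intervals(cls, name, intervals, source=None) -> "RegionCollection":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise IngestError(
                    f"invalid interval {chrom}:{start}-{end} (start >= end)"
                )
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        return cls(name=name, trees=trees, source=source)

    @property
    def chroms(self) -> set:
        return set(self.trees)

    def to_sorted_list(self) -> list:
        out = []
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def contains_point(self, chrom: str, pos: int) -> bool:
        """A single-base locus at 0-based position p is inside [start, end)
        iff start <= p < end."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree[pos])


@dataclass
class EnrichmentRow:
    feature: str
    a: int  # query & feature
    b: int  # query & not feature
    c: int  # complement & feature
    d: int  # complement & not feature
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    q_value: float = np.nan
    continuity_corrected: bool = False
    strata: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "test": self.test,
            "continuity_corrected": self.continuity_corrected,
        }


def _feature_mask(ann: CpGAnnotation, feature, universe: pd.Index) -> np.ndarray:
    """Resolve a feature spec into a boolean membership mask over universe.

    Accepts a CpG context label, a boolean annotation column name, or an
    explicit locus collection.
    """
    if isinstance(feature, str):
        if feature in CONTEXTS:
            return (ann.table.loc[universe, "context"] == feature).to_numpy()
        if feature in ann.table.columns and ann.table[feature].dtype == bool:
            return ann.table.loc[universe, feature].to_numpy()
        raise ConfigurationError(f"unknown feature {feature!r}")
    members = set(feature)
    return universe.isin(members)


def _counts(query, universe: pd.Index, in_feature: np.ndarray):
    qset = set(query)
    if not qset <= set(universe):
        raise ConfigurationError("query must be a subset of the universe")
    if len(qset) == len(universe):
        raise DegenerateDataError("query equals universe: no complement to test")
    in_query = universe.isin(qset)
    a = int((in_query & in_feature).sum())
    b = int((in_query & ~in_feature).sum())
    c = int((~in_query & in_feature).sum())
    d = int((~in_query & ~in_feature).sum())
    return a, b, c, d


def _or_ci(a, b, c, d):
    """Cross-product OR with Woolf CI; Haldane–Anscombe 0.5 on zero cells."""
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(or_) - Z95 * se), np.exp(np.log(or_) + Z95 * se)
    return float(or_), float(lo), float(hi), corrected


def fisher_context_enrichment(query, universe, ann: CpGAnnotation, feature) -> EnrichmentRow:
    """Fisher exact enrichment of a locus set in one annotation feature.

    ``feature`` may be a context label (island/shore/shelf/open_sea), a
    boolean annotation column (enhancer, tfbs, utr5), or an explicit locus
    set. Margins that are zero (feature absent, or covering the whole
    universe) are degenerate and raise.
    """
    universe = pd.Index(universe)
    mask = _feature_mask(ann, feature, universe)
    a, b, c, d = _counts(query, universe, mask)
    if a + c == 0:
        raise DegenerateDataError("feature margin is zero: no locus in feature")
    if b + d == 0:
        raise DegenerateDataError(
            "feature margin is zero: feature covers the whole universe"
        )
    or_, lo, hi, corrected = _or_ci(a, b, c, d)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    name = feature if isinstance(feature, str) else "locus_set"
    return EnrichmentRow(
        feature=name,
        a=a, b=b, c=c, d=d,
        odds_ratio=or_, ci_low=lo, ci_high=hi,
        p_value=float(p), test="fisher",
        continuity_corrected=corrected,
    )


def cmh_enrichment(
    query, universe, ann: CpGAnnotation, feature, stratum: str = "probe_type"
) -> EnrichmentRow:
    """Cochran–Mantel–Haenszel enrichment stratified by a categorical
    annotation column (default Infinium probe design type).

    Reports the Mantel–Haenszel common odds ratio, its 95% CI and the CMH
    chi-square p-value. Strata with a zero margin are dropped with a logged
    count; if all strata are degenerate an error is raised. With a single
    stratum the common OR reduces to the sample OR of that table.
    """
    universe = pd.Index(universe)
    mask = _feature_mask(ann, feature, universe)
    strata_labels = ann.table.loc[universe, stratum]
    tables = []
    kept = []
    for label in sorted(strata_labels.unique()):
        sub = universe[(strata_labels == label).to_numpy()]
        sub_mask = mask[universe.isin(sub)]
        sub_set = set(sub)
        q_sub = [x for x in query if x in sub_set]
        try:
            a, b, c, d = _counts(q_sub, sub, sub_mask)
        except DegenerateDataError:
            logger.warning("stratum %r degenerate, dropped", label)
            continue
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            logger.warning("stratum %r has a zero margin, dropped", label)
            continue
        tables.append(np.array([[a, b], [c, d]], dtype=float))
        kept.append((str(label), a, b, c, d))
    if not tables:
        raise DegenerateDataError("all strata degenerate; CMH test undefined")
    st = StratifiedTable(tables)
    or_ = float(st.oddsratio_pooled)
    lo, hi = st.oddsratio_pooled_confint(alpha=0.05)
    p = float(st.test_null_odds(correction=False).pvalue)
    tot = np.sum(tables, axis=0).astype(int)
    name = feature if isinstance(feature, str) else "locus_set"
    return EnrichmentRow(
        feature=name,
        a=int(tot[0, 0]), b=int(tot[0, 1]), c=int(tot[1, 0]), d=int(tot[1, 1]),
        odds_ratio=or_, ci_low=float(lo), ci_high=float(hi),
        p_value=p, test="cmh", strata=kept,
    )


def regionset_enrichment(
    query, universe, ann: CpGAnnotation, collections
) -> list[EnrichmentRow]:
    """Fisher enrichment of a locus set in each region collection.

    A locus is "in" a collection iff its single-base coordinate intersects
    any interval (0-based half-open). Benjamini–Hochberg q-values are
    assigned across collections and rows are sorted by q. Chromosomes
    present in a collection but absent from the annotation raise an error
    listing them.
    """
    universe = pd.Index(universe)
    coords = ann.table.loc[universe, ["chrom", "pos"]]
    ann_chroms = set(coords["chrom"].unique())
    rows = []
    for coll in collections:
        unmatched = coll.chroms - ann_chroms
        if unmatched:
            raise IngestError(
                f"collection {coll.name!r} has chromosomes absent from the "
                f"annotation: {sorted(unmatched)}"
            )
        in_feat = np.array(
            [coll.contains_point(ch, int(p)) for ch, p in coords.itertuples(index=False)]
        )
        a, b, c, d = _counts(query, universe, in_feat)
        if a + c == 0 or b + d == 0:
            # degenerate margin: report a flagged row rather than failing the batch
            or_, lo, hi, _ = _or_ci(a, b, c, d)
            rows.append(
                EnrichmentRow(
                    feature=coll.name, a=a, b=b, c=c, d=d,
                    odds_ratio=or_, ci_low=lo, ci_high=hi,
                    p_value=np.nan, test="fisher", continuity_corrected=True,
                )
            )
            continue
        or_, lo, hi, corrected = _or_ci(a, b, c, d)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            EnrichmentRow(
                feature=coll.name, a=a, b=b, c=c, d=d,
                odds_ratio=or_, ci_low=lo, ci_high=hi,
                p_value=float(p), test="fisher", continuity_corrected=corrected,
            )
        )
    testable = [r for r in rows if np.isfinite(r.p_value)]
    if testable:
        qs = multipletests([r.p_value for r in testable], method="fdr_bh")[1]
        for r, q in zip(testable, qs):
            r.q_value = float(q)
    rows.sort(key=lambda r: (np.inf if np.isnan(r.q_value) else r.q_value, r.feature))
    return rows


def gene_high5hmc_score(
    high_set, ann: CpGAnnotation, min_high: int = 10
) -> pd.DataFrame:
    """Score genes by the proportion of their measured CpGs that are high
    5hmC, keeping genes with at least ``min_high`` high-5hmC loci.

    Returns columns gene / n_measured / n_high / percent_high sorted by
    percent descending (gene ID breaks ties).
    """
    if min_high < 1:
        raise ConfigurationError(f"min_high must be >= 1, got {min_high}")
    high = set(high_set)
    tab = ann.table
    grouped = tab.groupby("gene", sort=True)
    n_measured = grouped.size()
    n_high = grouped.apply(
        lambda g: int(g.index.isin(high).sum()), include_groups=False
    )
    df = pd.DataFrame({"n_measured": n_measured, "n_high": n_high})
    df = df[df["n_high"] >= min_high].copy()
    df["percent_high"] = 100.0 * df["n_high"] / df["n_measured"]
    df = df.sort_index().sort_values(
        by="percent_high", ascending=False, kind="mergesort"
    )
    df.index.name = "gene"
    return df.reset_index()


def set_overlap(a, b) -> dict:
    """Venn-style overlap summary of two locus sets."""
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "n_intersection": inter,
        "frac_of_a": inter / len(sa) if sa else 0.0,
        "frac_of_b": inter / len(sb) if sb else 0.0,
    }


def variable_cpg_set(
    betas: pd.DataFrame, sd_threshold: float | None = None, top_n: int | None = None
) -> pd.Index:
    """Select loci by cross-sample standard deviation (n-1 denominator).

    Exactly one of ``sd_threshold`` (strict >) or ``top_n`` must be given;
    top-n ties are broken by lexicographic locus ID.
    """
    if (sd_threshold is None) == (top_n is None):
        raise ConfigurationError("give exactly one of sd_threshold or top_n")
    if betas.shape[1] < 2:
        raise DegenerateDataError("standard deviation needs >= 2 samples")
    sd = betas.std(axis=1, ddof=1)
    if sd_threshold is not None:
        return sd.index[sd > sd_threshold]
    if top_n > len(sd):
        raise ConfigurationError(
            f"top_n={top_n} exceeds universe size {len(sd)}"
        )
    order = sd.sort_index().sort_values(ascending=False, kind="mergesort")
    return pd.Index(order.index[: int(top_n)])
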