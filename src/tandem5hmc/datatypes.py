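"""Core data containers for paired BS/OxBS methylation analysis.

All matrices are pandas DataFrames with CpG locus IDs as the row index and
sample IDs as columns; the containers below enforce alignment and the
probability-simplex constraint on deconvolved cytosine proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, IngestError, StructuralError

logger = logging.getLogger(__name__)

SIMPLEX_TOL = 1e-9

#: genomic context classes by distance from CpG islands
CONTEXTS = ("island", "shore", "shelf", "open_sea")

#: required columns of a CpG annotation table
ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "context",
    "probe_type",
    "gene",
    "tss_distance",
    "enhancer",
    "tfbs",
    "utr5",
)


@dataclass
class PairedBetaSet:
    """Aligned beta-value matrices from the two treatments of each sample.

    ``beta_bs`` (bisulfite) reads 5mC + 5hmC; ``beta_oxbs`` (oxidative
    bisulfite) reads 5mC only.
    """

    beta_bs: pd.DataFrame
    beta_oxbs: pd.DataFrame

    def __post_init__(self) -> None:
        bs, ox = self.beta_bs, self.beta_oxbs
        if not bs.index.equals(ox.index) or not bs.columns.equals(ox.columns):
            raise StructuralError(
                "BS and OxBS matrices must share identical locus and sample ordering"
            )
        for name, mat in (("beta_bs", bs), ("beta_oxbs", ox)):
            vals = mat.to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise IngestError(
                    f"{name} contains missing values; apply drop_incomplete_loci first"
                )
            if (vals < 0).any() or (vals > 1).any():
                r, c = np.argwhere((vals < 0) | (vals > 1))[0]
                raise IngestError(
                    f"{name} value out of [0,1] at locus {mat.index[r]!r}, "
                    f"sample {mat.columns[c]!r}"
                )

    @property
    def locus_ids(self) -> pd.Index:
        return self.beta_bs.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta_bs.columns

    @classmethod
    def from_raw(cls, beta_bs: pd.DataFrame, beta_oxbs: pd.DataFrame) -> "PairedBetaSet":
        """Build from possibly-incomplete matrices, dropping loci with any
        missing value in either treatment (logged count)."""
        common = beta_bs.index.intersection(beta_oxbs.index)
        bs = beta_bs.loc[common]
        ox = beta_oxbs.loc[common, bs.columns]
        keep = ~(bs.isna().any(axis=1) | ox.isna().any(axis=1))
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("dropped %d loci with missing beta values", dropped)
        return cls(bs.loc[keep], ox.loc[keep])


@dataclass
class CytosineProportions:
    """Per-cell proportions of unmethylated (p_c), methylated (p_5mc) and
    hydroxymethylated (p_5hmc) cytosine, constrained to the simplex."""

    p_c: pd.DataFrame
    p_5mc: pd.DataFrame
    p_5hmc: pd.DataFrame

    def __post_init__(self) -> None:
        for mat in (self.p_5mc, self.p_5hmc):
            if not mat.index.equals(self.p_c.index) or not mat.columns.equals(
                self.p_c.columns
            ):
                raise StructuralError("proportion matrices are not aligned")
        total = (
            self.p_c.to_numpy() + self.p_5mc.to_numpy() + self.p_5hmc.to_numpy()
        )
        if not np.allclose(total, 1.0, atol=SIMPLEX_TOL, rtol=0):
            raise StructuralError(
                "proportions do not sum to 1 within tolerance "
                f"(max deviation {np.abs(total - 1).max():.3g})"
            )
        for name, mat in (
            ("p_c", self.p_c),
            ("p_5mc", self.p_5mc),
            ("p_5hmc", self.p_5hmc),
        ):
            v = mat.to_numpy()
            if (v < -SIMPLEX_TOL).any() or (v > 1 + SIMPLEX_TOL).any():
                raise StructuralError(f"{name} outside [0,1]")

    @property
    def locus_ids(self) -> pd.Index:
        return self.p_c.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.p_c.columns

    def subset_samples(self, sample_ids) -> "CytosineProportions":
        cols = list(sample_ids)
        return CytosineProportions(
            self.p_c[cols], self.p_5mc[cols], self.p_5hmc[cols]
        )


@dataclass
class CpGAnnotation:
    """Per-locus genomic annotation: coordinate, CpG-island context, probe
    design type, gene membership, signed TSS distance and regulatory flags."""

    table: pd.DataFrame  # index: locus IDs; columns: ANNOTATION_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise StructuralError(f"annotation missing columns: {missing}")
        bad = set(self.table["context"].unique()) - set(CONTEXTS)
        if bad:
            raise IngestError(f"unknown context labels: {sorted(bad)}")

    @property
    def locus_ids(self) -> pd.Index:
        return self.table.index

    def loci_in_context(self, context: str) -> pd.Index:
        return self.table.index[self.table["context"] == context]

    def coordinates(self) -> pd.DataFrame:
        return self.table[["chrom", "pos"]]


@dataclass
class SampleFrame:
    """Per-sample covariates and survival outcomes.

    Columns: ``group`` (tumor / nontumor), ``subtype``, ``age`` (years),
    ``sex`` (F / M), and outcome pairs ``death_time`` / ``death_event`` and
    ``recurrence_time`` / ``recurrence_event`` (NaN where not followed).
    """

    table: pd.DataFrame

    REQUIRED = (
        "group",
        "subtype",
        "age",
        "sex",
        "death_time",
        "death_event",
        "recurrence_time",
        "recurrence_event",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise StructuralError(f"sample table missing columns: {missing}")
        bad_group = set(self.table["group"].unique()) - {"tumor", "nontumor"}
        if bad_group:
            raise IngestError(f"unknown group labels: {sorted(bad_group)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def tumor_ids(self) -> pd.Index:
        return self.table.index[self.table["group"] == "tumor"]

    @property
    def nontumor_ids(self) -> pd.Index:
        return self.table.index[self.table["group"] == "nontumor"]

    def subtype_counts(self) -> pd.Series:
        return self.table.loc[self.tumor_ids, "subtype"].value_counts()

    def validate_bookkeeping(self) -> dict:
        """Check that tumor subtype counts sum to the tumor cohort size and
        return the bookkeeping summary."""
        counts = self.subtype_counts()
        n_tumor = len(self.tumor_ids)
        if int(counts.sum()) != n_tumor:
            raise DegenerateDataError(
                f"subtype counts {counts.to_dict()} sum to {int(counts.sum())}, "
                f"expected tumor cohort size {n_tumor}"
            )
        return {
            "n_tumor": n_tumor,
            "n_nontumor": len(self.nontumor_ids),
            "subtype_counts": {str(k): int(v) for k, v in counts.items()},
            "subtype_total": int(counts.sum()),
        }


@dataclass
class SimTruth:
    """Ground truth emitted by the synthetic-data generator: the acceptance
    surface for all recovery tests."""

    proportions: CytosineProportions
    high5hmc_loci_true: frozenset
    dhmr_loci: frozenset
    cluster_labels: pd.Series  # per-tumor, values in {high5hmC, low5hmC}
    hazard_per_sample: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.dhmr_loci <= self.high5hmc_loci_true:
            raise StructuralError("dhmr_loci must be a subset of high5hmc_loci_true")
        bad = set(self.cluster_labels.unique()) - {"high5hmC", "low5hmC"}
        if bad:
            raise StructuralError(f"unknown cluster labels: {sorted(bad)}")
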