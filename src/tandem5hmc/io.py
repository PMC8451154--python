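"""Reading and writing of the pipeline's tabular and interval formats.

All tabular outputs are TSV with a header row and stable column order;
matrices carry the locus ID in the first column. Genomic intervals use BED
semantics throughout: 0-based, half-open. Internal coordinates are already
0-based half-open, so no conversion happens at the BED boundary.
"""

from __future__ import annotations

import os

import pandas as pd

from .datatypes import CpGAnnotation, CytosineProportions, PairedBetaSet, SampleFrame
from .enrichment import RegionCollection
from .exceptions import IngestError


def write_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="locus_id")


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_id")


def write_paired(paired: PairedBetaSet, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "beta_bs": os.path.join(outdir, "beta_bs.tsv"),
        "beta_oxbs": os.path.join(outdir, "beta_oxbs.tsv"),
    }
    write_matrix(paired.beta_bs, paths["beta_bs"])
    write_matrix(paired.beta_oxbs, paths["beta_oxbs"])
    return paths


def read_paired(bs_path: str, oxbs_path: str) -> PairedBetaSet:
    return PairedBetaSet.from_raw(read_matrix(bs_path), read_matrix(oxbs_path))


def write_proportions(props: CytosineProportions, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, mat in (
        ("p_c", props.p_c),
        ("p_5mc", props.p_5mc),
        ("p_5hmc", props.p_5hmc),
    ):
        paths[name] = os.path.join(outdir, f"{name}.tsv")
        write_matrix(mat, paths[name])
    return paths


def read_proportions(outdir: str) -> CytosineProportions:
    return CytosineProportions(
        read_matrix(os.path.join(outdir, "p_c.tsv")),
        read_matrix(os.path.join(outdir, "p_5mc.tsv")),
        read_matrix(os.path.join(outdir, "p_5hmc.tsv")),
    )


def write_annotation(ann: CpGAnnotation, path: str) -> None:
    ann.table.to_csv(path, sep="\t", index_label="locus_id")


def read_annotation(path: str) -> CpGAnnotation:
    return CpGAnnotation(pd.read_csv(path, sep="\t", index_col="locus_id"))


def write_samples(samples: SampleFrame, path: str) -> None:
    samples.table.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path: str) -> SampleFrame:
    return SampleFrame(pd.read_csv(path, sep="\t", index_col="sample_id"))


def read_bed(path: str, name: str | None = None) -> RegionCollection:
    """Parse a BED3+ file into a region collection.

    Comment (#), ``track`` and ``browser`` lines are tolerated; coordinates
    must be integers with start < end (0-based half-open). Parse errors
    carry the offending line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IngestError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as err:
                raise IngestError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from err
            if start >= end:
                raise IngestError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            intervals.append((chrom, start, end))
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return RegionCollection.from_intervals(name, intervals)


def write_bed(obj, path: str) -> None:
    """Write a region collection, or a locus list with an annotation, as BED.

    ``obj`` is either a :class:`RegionCollection`, or a tuple
    ``(locus_ids, annotation)`` in which case each locus becomes a
    single-base interval named by its locus ID (e.g. for query/background
    exports to external region-enrichment tools).
    """
    with open(path, "w") as fh:
        if isinstance(obj, RegionCollection):
            for chrom, start, end in obj.to_sorted_list():
                fh.write(f"{chrom}\t{start}\t{end}\n")
        else:
            loci, ann = obj
            coords = ann.table.loc[list(loci), ["chrom", "pos"]]
            coords = coords.sort_values(["chrom", "pos"])
            for locus, row in coords.iterrows():
                fh.write(f"{row.chrom}\t{int(row.pos)}\t{int(row.pos) + 1}\t{locus}\n")


def write_truth(truth, outdir: str) -> dict:
    """Persist the generator's ground truth as a documented TSV sidecar set."""
    os.makedirs(outdir, exist_ok=True)
    paths = write_proportions(truth.proportions, outdir)
    paths["high5hmc_loci"] = os.path.join(outdir, "high5hmc_loci_true.tsv")
    pd.Series(sorted(truth.high5hmc_loci_true), name="locus_id").to_csv(
        paths["high5hmc_loci"], sep="\t", index=False
    )
    paths["dhmr_loci"] = os.path.join(outdir, "dhmr_loci.tsv")
    pd.Series(sorted(truth.dhmr_loci), name="locus_id").to_csv(
        paths["dhmr_loci"], sep="\t", index=False
    )
    paths["cluster_labels"] = os.path.join(outdir, "cluster_labels.tsv")
    truth.cluster_labels.rename("cluster").to_csv(
        paths["cluster_labels"], sep="\t", index_label="sample_id"
    )
    paths["hazards"] = os.path.join(outdir, "hazard_per_sample.tsv")
    truth.hazard_per_sample.rename("hazard").to_csv(
        paths["hazards"], sep="\t", index_label="sample_id"
    )
    return paths
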