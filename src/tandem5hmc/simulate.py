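"""Synthetic paired BS/OxBS data generator with planted ground truth.

The generator emulates the structure of a tandem bisulfite / oxidative
bisulfite EPIC-array study of pediatric CNS tumors: a small cohort, ~5% of
CpGs with appreciable 5hmC concentrated in open-sea/enhancer contexts,
epigenome-wide tumor hypohydroxymethylation with locus-specific 5mC gain at
differentially hydroxymethylated loci (DHMRs), a low-5hmC tumor class with
an additional global 5hmC deficit, and survival hazard tied to that class.

The measurement model is the one the deconvolution stage inverts: the BS
beta reads p5mC + p5hmC, the OxBS beta reads p5mC, each observed through a
beta distribution with configurable precision.

Every draw is governed by the single ``SimConfig.seed`` through fixed
per-stage seed derivations, so each stage can be regenerated independently
and identical configs give bit-identical outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SUBTYPE_PROBS, SimConfig
from .datatypes import (
    CONTEXTS,
    CpGAnnotation,
    CytosineProportions,
    PairedBetaSet,
    SampleFrame,
    SimTruth,
)
from .exceptions import StructuralError

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets for the hierarchical seeding scheme
_STAGE_ANNOTATION = 1
_STAGE_TRUTH = 2
_STAGE_OBSERVED = 3
_STAGE_SURVIVAL = 4
_STAGE_REGIONS = 5

# sampling weights drawing high-5hmC loci preferentially into open-sea /
# enhancer contexts (yields island depletion, open-sea enrichment)
_CONTEXT_WEIGHT = {"island": 0.1, "shore": 0.7, "shelf": 1.0, "open_sea": 2.0}
_ENHANCER_BOOST = 1.6

# baseline beta-scale levels; high-5hmC loci are uniform on this interval
HIGH_5HMC_RANGE = (0.10, 0.40)
_BACKGROUND_5HMC_AB = (1.5, 60.0)  # mean ~2.4%, light right tail
_M_LOW_AB = (1.5, 8.0)
_M_HIGH_AB = (6.0, 2.5)
_M_LOW_PROB = 0.30
_BIO_CV_SHAPE = 25.0  # per-sample gamma variability of true 5hmC (CV = 0.2)
_M_CV_SHAPE = 400.0  # per-sample gamma variability of true 5mC (CV = 0.05)


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def _locus_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="locus_id")


def _sample_ids(cfg: SimConfig) -> tuple[list, list]:
    tumors = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    nontumors = [f"N{i + 1:03d}" for i in range(cfg.n_nontumor)]
    return tumors, nontumors


def simulate_annotation(cfg: SimConfig) -> CpGAnnotation:
    """Draw a per-locus annotation table: coordinates on 22 autosomes, CpG
    context from ``context_probs``, probe type, gene blocks of varying size,
    signed TSS distance within the configured window and regulatory flags."""
    cfg.validate()
    rng = _rng(cfg, _STAGE_ANNOTATION)
    n = cfg.n_cpg
    idx = _locus_ids(n)

    chrom_idx = (np.arange(n) * 22) // n
    chrom = np.array([f"chr{i + 1}" for i in chrom_idx])
    gaps = rng.integers(100, 5_000, size=n)
    pos = np.empty(n, dtype=np.int64)
    for c in range(22):
        mask = chrom_idx == c
        pos[mask] = 10_000 + np.cumsum(gaps[mask])

    probs = np.array([cfg.context_probs[c] for c in CONTEXTS], dtype=float)
    context = rng.choice(np.array(CONTEXTS), size=n, p=probs)
    probe_type = np.where(rng.random(n) < 0.15, "I", "II")

    # genes as contiguous blocks along the genome with Dirichlet-varying sizes
    sizes = rng.multinomial(n, rng.dirichlet(np.full(cfg.n_genes, 1.0)))
    gene = np.repeat([f"G{i:05d}" for i in range(cfg.n_genes)], sizes)

    tss = rng.integers(-cfg.tss_window_bp, cfg.tss_window_bp + 1, size=n)
    enh_p = np.array([cfg.enhancer_prob_by_context[c] for c in context])
    enhancer = rng.random(n) < enh_p
    tfbs = rng.random(n) < 0.25
    utr5 = rng.random(n) < 0.05

    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "context": context,
            "probe_type": probe_type,
            "gene": gene,
            "tss_distance": tss,
            "enhancer": enhancer,
            "tfbs": tfbs,
            "utr5": utr5,
        },
        index=idx,
    )
    return CpGAnnotation(table)


def expected_dhmr_gap(cfg: SimConfig) -> float:
    """Closed-form expectation of the tumor vs non-tumor difference in true
    p5hmC at DHMR loci implied by the generator design (no-clipping regime).

    Non-tumors carry the baseline level; tumors carry the DHMR decrement
    followed by the global tumor scale and, for the low-5hmC class, the
    additional class scale.
    """
    lo, hi = HIGH_5HMC_RANGE
    base = 0.5 * (lo + hi)
    mean_scale = cfg.tumor_5hmc_scale * (
        cfg.cluster_split * cfg.low_cluster_scale + (1.0 - cfg.cluster_split)
    )
    return base - max(base - cfg.delta_5hmc, 0.0) * mean_scale


def simulate_truth(cfg: SimConfig, ann: CpGAnnotation) -> SimTruth:
    """Plant ground-truth cytosine proportions on the annotated universe.

    High-5hmC loci (``frac_high5hmc`` of the universe, drawn preferentially
    from open-sea/enhancer contexts) receive elevated baseline p5hmC; a
    ``dhmr_frac`` subset of them receives a tumor-specific 5hmC decrement and
    5mC increment; tumors are globally hypohydroxymethylated and the planted
    low-5hmC tumor class receives a further multiplicative 5hmC deficit.
    True 5mC is coupled anti-monotonically to true 5hmC (oxidation converts
    one into the other), giving the predominantly negative per-CpG 5mC–5hmC
    correlation seen in tandem-array data.
    """
    cfg.validate()
    if len(ann.locus_ids) != cfg.n_cpg:
        raise StructuralError(
            f"annotation has {len(ann.locus_ids)} loci, config expects {cfg.n_cpg}"
        )
    rng = _rng(cfg, _STAGE_TRUTH)
    n = cfg.n_cpg
    idx = ann.locus_ids

    k_high = int(np.floor(cfg.frac_high5hmc * n))
    w = np.array([_CONTEXT_WEIGHT[c] for c in ann.table["context"]])
    w = w * np.where(ann.table["enhancer"].to_numpy(), _ENHANCER_BOOST, 1.0)
    high_pos = rng.choice(n, size=k_high, replace=False, p=w / w.sum())
    is_high = np.zeros(n, dtype=bool)
    is_high[high_pos] = True

    base_h = rng.beta(*_BACKGROUND_5HMC_AB, size=n)
    base_h[is_high] = rng.uniform(*HIGH_5HMC_RANGE, size=k_high)

    low_m = rng.random(n) < _M_LOW_PROB
    base_m = np.where(low_m, rng.beta(*_M_LOW_AB, size=n), rng.beta(*_M_HIGH_AB, size=n))

    k_dhmr = int(np.floor(cfg.dhmr_frac * k_high))
    dhmr_pos = rng.choice(high_pos, size=k_dhmr, replace=False)
    is_dhmr = np.zeros(n, dtype=bool)
    is_dhmr[dhmr_pos] = True

    tumors, nontumors = _sample_ids(cfg)
    samples = tumors + nontumors
    n_low = int(round(cfg.cluster_split * cfg.n_tumor))
    low_set = rng.permutation(cfg.n_tumor)[:n_low]
    labels = np.array(["high5hmC"] * cfg.n_tumor, dtype=object)
    labels[low_set] = "low5hmC"
    cluster_labels = pd.Series(labels, index=pd.Index(tumors, name="sample_id"))

    # per-sample deterministic scale on true 5hmC
    scale = np.ones(len(samples))
    for i in range(cfg.n_tumor):
        s = cfg.tumor_5hmc_scale
        if labels[i] == "low5hmC":
            s *= cfg.low_cluster_scale
        scale[i] = s

    h_loc = np.tile(base_h[:, None], (1, len(samples)))
    m_loc = np.tile(base_m[:, None], (1, len(samples)))
    # tumor-specific DHMR effects (applied before the global scalings)
    h_dec = h_loc[is_dhmr, : cfg.n_tumor] - cfg.delta_5hmc
    n_clipped = int((h_dec < 0).sum())
    if n_clipped:
        logger.warning(
            "clipped %d DHMR cells with negative 5hmC after decrement", n_clipped
        )
    h_loc[np.ix_(is_dhmr, np.arange(cfg.n_tumor))] = np.maximum(h_dec, 0.0)
    m_loc[np.ix_(is_dhmr, np.arange(cfg.n_tumor))] += cfg.delta_5mc

    g_h = rng.gamma(_BIO_CV_SHAPE, 1.0 / _BIO_CV_SHAPE, size=(n, len(samples)))
    g_m = rng.gamma(_M_CV_SHAPE, 1.0 / _M_CV_SHAPE, size=(n, len(samples)))
    h_true = np.minimum(h_loc * scale[None, :] * g_h, 0.98)
    m_true = np.minimum(m_loc * g_m, 1.0) * (1.0 - h_true)
    c_true = 1.0 - m_true - h_true

    cols = pd.Index(samples, name="sample_id")
    props = CytosineProportions(
        pd.DataFrame(c_true, index=idx, columns=cols),
        pd.DataFrame(m_true, index=idx, columns=cols),
        pd.DataFrame(h_true, index=idx, columns=cols),
    )
    hazards = pd.Series(
        [
            cfg.baseline_hazard
            * (cfg.hazard_ratio_low if labels[i] == "low5hmC" else 1.0)
            for i in range(cfg.n_tumor)
        ],
        index=cluster_labels.index,
    )
    return SimTruth(
        proportions=props,
        high5hmc_loci_true=frozenset(idx[is_high]),
        dhmr_loci=frozenset(idx[is_dhmr]),
        cluster_labels=cluster_labels,
        hazard_per_sample=hazards,
    )


def simulate_observed(truth: SimTruth, cfg: SimConfig) -> PairedBetaSet:
    """Push the true proportions through the paired measurement model.

    BS betas are beta-distributed around p5mC + p5hmC, OxBS betas around
    p5mC, with shared precision ``noise_precision`` and independent draws per
    treatment. With ``no_noise`` set the means are returned exactly.
    """
    cfg.validate()
    mu_bs = (truth.proportions.p_5mc + truth.proportions.p_5hmc).to_numpy()
    mu_ox = truth.proportions.p_5mc.to_numpy()
    idx = truth.proportions.locus_ids
    cols = truth.proportions.sample_ids
    if cfg.no_noise:
        bs, ox = mu_bs, mu_ox
    else:
        rng = _rng(cfg, _STAGE_OBSERVED)
        phi = float(cfg.noise_precision)
        eps = 1e-6  # nudge degenerate means off the boundary before sampling
        mb = np.clip(mu_bs, eps, 1 - eps)
        mo = np.clip(mu_ox, eps, 1 - eps)
        bs = rng.beta(mb * phi, (1 - mb) * phi)
        ox = rng.beta(mo * phi, (1 - mo) * phi)
        tiny = 1e-12
        bs = np.clip(bs, tiny, 1 - tiny)
        ox = np.clip(ox, tiny, 1 - tiny)
    return PairedBetaSet(
        pd.DataFrame(bs, index=idx, columns=cols),
        pd.DataFrame(ox, index=idx, columns=cols),
    )


def simulate_survival(truth: SimTruth, cfg: SimConfig) -> SampleFrame:
    """Draw covariates and survival outcomes for the emulated cohort.

    Death and recurrence times are independent exponentials with the
    per-sample hazard (recurrence at twice the death rate), administratively
    censored at ``censor_time``. Tumor ages are integer-uniform on 1–18
    years, control ages on 0–11; sex is Bernoulli(``sex_prob``).
    """
    cfg.validate()
    rng = _rng(cfg, _STAGE_SURVIVAL)
    tumors, nontumors = _sample_ids(cfg)
    rates = truth.hazard_per_sample.reindex(tumors).to_numpy()

    death_raw = rng.exponential(1.0 / rates)
    rec_raw = rng.exponential(1.0 / (2.0 * rates))
    ct = float(cfg.censor_time)
    death_time = np.minimum(death_raw, ct)
    death_event = (death_raw <= ct).astype(int)
    rec_time = np.minimum(rec_raw, ct)
    rec_event = (rec_raw <= ct).astype(int)

    age_t = rng.integers(1, 19, size=cfg.n_tumor)
    age_n = rng.integers(0, 12, size=cfg.n_nontumor)
    sex = np.where(
        rng.random(cfg.n_tumor + cfg.n_nontumor) < cfg.sex_prob, "M", "F"
    )
    subtype_names = list(SUBTYPE_PROBS)
    subtype_t = rng.choice(
        subtype_names, size=cfg.n_tumor, p=[SUBTYPE_PROBS[s] for s in subtype_names]
    )

    table = pd.DataFrame(
        {
            "group": ["tumor"] * cfg.n_tumor + ["nontumor"] * cfg.n_nontumor,
            "subtype": list(subtype_t) + ["nontumor"] * cfg.n_nontumor,
            "age": np.concatenate([age_t, age_n]),
            "sex": sex,
            "death_time": np.concatenate([death_time, np.full(cfg.n_nontumor, np.nan)]),
            "death_event": np.concatenate(
                [death_event.astype(float), np.full(cfg.n_nontumor, np.nan)]
            ),
            "recurrence_time": np.concatenate(
                [rec_time, np.full(cfg.n_nontumor, np.nan)]
            ),
            "recurrence_event": np.concatenate(
                [rec_event.astype(float), np.full(cfg.n_nontumor, np.nan)]
            ),
        },
        index=pd.Index(tumors + nontumors, name="sample_id"),
    )
    return SampleFrame(table)


def simulate_region_sets(cfg: SimConfig, ann: CpGAnnotation, n_collections: int = 2):
    """Build synthetic region-set collections (super-enhancer-like BED
    intervals) anchored on enhancer-flagged loci plus random background
    intervals, for exercising region-set enrichment.

    Returns a list of ``(name, intervals)`` pairs, intervals as sorted
    0-based half-open ``(chrom, start, end)`` triples.
    """
    from .enrichment import RegionCollection

    rng = _rng(cfg, _STAGE_REGIONS)
    tab = ann.table
    out = []
    for i in range(n_collections):
        take = tab["enhancer"].to_numpy() & (rng.random(len(tab)) < 0.5)
        anchors = tab.loc[take, ["chrom", "pos"]]
        background = tab.sample(
            n=max(1, len(tab) // 100), random_state=int(rng.integers(2**31))
        )[["chrom", "pos"]]
        pieces = pd.concat([anchors, background])
        intervals = [
            (row.chrom, max(0, int(row.pos) - 500), int(row.pos) + 500)
            for row in pieces.itertuples()
        ]
        out.append(
            RegionCollection.from_intervals(f"sim_superenhancer_{chr(65 + i)}", intervals)
        )
    return out


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper running all generator stages.

    Returns ``(paired, annotation, samples, truth)``.
    """
    ann = simulate_annotation(cfg)
    truth = simulate_truth(cfg, ann)
    paired = simulate_observed(truth, cfg)
    samples = simulate_survival(truth, cfg)
    return paired, ann, samples, truth
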