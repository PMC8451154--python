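"""Configuration objects for the synthetic-data generator and the pipeline.

The ``SimConfig`` defaults define the emulated study conditions: a small
pediatric CNS tumor cohort (27 tumors: 13 gliomas, 8 ependymomas, 6
embryonal; 3 non-tumor brain controls) profiled with tandem BS/OxBS
treatments, with ~5% of loci carrying appreciable 5hmC, global tumor
hypohydroxymethylation, locus-specific 5mC gain at differentially
hydroxymethylated loci, 5hmC concentrated in open-sea/enhancer contexts,
and survival hazard tied to a low-5hmC tumor class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .exceptions import ConfigurationError

#: tumor subtype mix of the emulated cohort (glioma, ependymoma, embryonal)
SUBTYPE_PROBS = {"glioma": 13 / 27, "ependymoma": 8 / 27, "embryonal": 6 / 27}


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 < float(value) < 1.0):
        raise ConfigurationError(f"{name} must be in (0,1), got {value!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic paired BS/OxBS generator.

    Fractions are on the beta scale; times are in years; ``noise_precision``
    is the precision (a+b) of the beta observation distribution.
    """

    n_cpg: int = 50_000
    n_tumor: int = 27
    n_nontumor: int = 3
    frac_high5hmc: float = 0.05
    context_probs: dict = field(
        default_factory=lambda: {
            "island": 0.20,
            "shore": 0.18,
            "shelf": 0.07,
            "open_sea": 0.55,
        }
    )
    enhancer_prob_by_context: dict = field(
        default_factory=lambda: {
            "island": 0.03,
            "shore": 0.08,
            "shelf": 0.10,
            "open_sea": 0.12,
        }
    )
    n_genes: int = 2_000
    tss_window_bp: int = 10_000
    dhmr_frac: float = 0.2
    delta_5hmc: float = 0.05
    delta_5mc: float = 0.05
    noise_precision: float = 200.0
    no_noise: bool = False
    tumor_5hmc_scale: float = 0.45
    cluster_split: float = 0.5
    low_cluster_scale: float = 0.2
    hazard_ratio_low: float = 6.47
    baseline_hazard: float = 0.02
    censor_time: float = 15.0
    sex_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        _check_fraction("frac_high5hmc", self.frac_high5hmc)
        _check_fraction("dhmr_frac", self.dhmr_frac)
        _check_fraction("sex_prob", self.sex_prob)
        if not (0.0 <= self.cluster_split <= 1.0):
            raise ConfigurationError(
                f"cluster_split must be in [0,1], got {self.cluster_split!r}"
            )
        for name in ("tumor_5hmc_scale", "low_cluster_scale"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0,1], got {v!r}")
        if self.n_cpg < 100:
            raise ConfigurationError(f"n_cpg must be >= 100, got {self.n_cpg}")
        if self.n_tumor < 2:
            raise ConfigurationError(f"n_tumor must be >= 2, got {self.n_tumor}")
        if self.n_nontumor < 1:
            raise ConfigurationError(f"n_nontumor must be >= 1, got {self.n_nontumor}")
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.tss_window_bp <= 0:
            raise ConfigurationError("tss_window_bp must be positive")
        probs = self.context_probs
        expected = {"island", "shore", "shelf", "open_sea"}
        if set(probs) != expected:
            raise ConfigurationError(
                f"context_probs must have keys {sorted(expected)}, got {sorted(probs)}"
            )
        if any(p < 0 for p in probs.values()):
            raise ConfigurationError("context_probs entries must be >= 0")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"context_probs must sum to 1 within 1e-12, got {sum(probs.values())!r}"
            )
        for ctx, p in self.enhancer_prob_by_context.items():
            if ctx not in expected:
                raise ConfigurationError(f"enhancer_prob_by_context: unknown context {ctx!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"enhancer_prob_by_context[{ctx!r}] must be in [0,1]")
        if not self.no_noise and self.noise_precision <= 0:
            raise ConfigurationError(
                f"noise_precision must be > 0, got {self.noise_precision!r}"
            )
        if self.delta_5hmc < 0 or self.delta_5mc < 0:
            raise ConfigurationError("delta_5hmc and delta_5mc must be >= 0")
        if self.hazard_ratio_low <= 0:
            raise ConfigurationError("hazard_ratio_low must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.censor_time < 0:
            raise ConfigurationError("censor_time must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: either a simulate block or paths
    to pre-computed inputs, plus the per-stage analysis parameters."""

    outdir: str
    simulate: SimConfig | None = None
    bs_path: str | None = None
    oxbs_path: str | None = None
    annotation_path: str | None = None
    samples_path: str | None = None
    region_bed_paths: list = field(default_factory=list)
    deconvolution_method: str = "naive"
    ml_precision: float = 100.0
    frac_high5hmc: float = 0.05
    fdr: float = 0.1
    top_n_variable: int = 10_000
    min_high: int = 10
    tss_bin_bp: int = 500
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "select": True,
            "enrich": True,
            "differential": True,
            "cluster_survival": True,
        }
    )

    def validate(self) -> None:
        import os

        if self.simulate is None:
            paths = {
                "bs_path": self.bs_path,
                "oxbs_path": self.oxbs_path,
                "annotation_path": self.annotation_path,
                "samples_path": self.samples_path,
            }
            for name, p in paths.items():
                if p is None:
                    raise ConfigurationError(
                        f"{name} is required when no simulate block is given"
                    )
                if not os.path.exists(p):
                    raise ConfigurationError(f"{name} does not exist: {p}")
        else:
            self.simulate.validate()
        for p in self.region_bed_paths:
            if not os.path.exists(p):
                raise ConfigurationError(f"region BED does not exist: {p}")
        if self.deconvolution_method not in {"naive", "ml"}:
            raise ConfigurationError(
                f"deconvolution_method must be naive or ml, got {self.deconvolution_method!r}"
            )
        _check_fraction("frac_high5hmc", self.frac_high5hmc)
        _check_fraction("fdr", self.fdr)
        if self.top_n_variable < 2:
            raise ConfigurationError("top_n_variable must be >= 2")
        if self.min_high < 1:
            raise ConfigurationError("min_high must be >= 1")
        if self.tss_bin_bp <= 0:
            raise ConfigurationError("tss_bin_bp must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig.from_dict(sim)
        cfg.validate()
        return cfg
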