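"""Three-state cytosine deconvolution from paired BS/OxBS beta values.

The bisulfite (BS) beta reads the sum p5mC + p5hmC, the oxidative bisulfite
(OxBS) beta reads p5mC alone, so the hydroxymethylated fraction is the
difference of the two treatments. Two estimators are provided:

* ``deconvolve_naive`` — the constrained subtraction estimator: the 5hmC
  signal is the BS−OxBS difference truncated at zero, with p5mC capped so
  the three proportions stay on the probability simplex.
* ``deconvolve_ml`` — a per-cell maximum-likelihood estimator under a beta
  observation model with a shared precision nuisance parameter; it agrees
  with the naive estimator in the no-noise limit and pools the two
  treatments when they are inconsistent (BS < OxBS).

The ML estimator solves one small constrained optimisation per cell and is
intended for locus panels, not full arrays.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import CytosineProportions, PairedBetaSet
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

_MU_EPS = 1e-6
_OBS_EPS = 1e-9


def deconvolve_naive(paired: PairedBetaSet) -> CytosineProportions:
    """Constrained subtraction estimator.

    p5hmC = max(βBS − βOxBS, 0); p5mC = min(βOxBS, βBS); pC is the simplex
    remainder. Negative 5hmC differences (measurement noise) are truncated
    at zero and the 5mC estimate is capped at βBS so the simplex holds.
    """
    bs = paired.beta_bs.to_numpy(dtype=float)
    ox = paired.beta_oxbs.to_numpy(dtype=float)
    p_5hmc = np.maximum(bs - ox, 0.0)
    p_5mc = np.minimum(ox, bs)
    p_c = 1.0 - p_5mc - p_5hmc
    idx, cols = paired.locus_ids, paired.sample_ids
    return CytosineProportions(
        pd.DataFrame(p_c, index=idx, columns=cols),
        pd.DataFrame(p_5mc, index=idx, columns=cols),
        pd.DataFrame(p_5hmc, index=idx, columns=cols),
    )


def _cell_nll(params, bs, ox, phi):
    m, h = params
    mu_bs = min(max(m + h, _MU_EPS), 1 - _MU_EPS)
    mu_ox = min(max(m, _MU_EPS), 1 - _MU_EPS)
    ll = stats.beta.logpdf(bs, mu_bs * phi, (1 - mu_bs) * phi)
    ll += stats.beta.logpdf(ox, mu_ox * phi, (1 - mu_ox) * phi)
    return -ll


def _ml_cell(bs: float, ox: float, phi: float, coarse: np.ndarray):
    """Maximise the paired beta likelihood over the simplex for one cell.

    A coarse simplex scan picks the basin; SLSQP refines it. Returns
    (m, h, converged).
    """
    bs = min(max(bs, _OBS_EPS), 1 - _OBS_EPS)
    ox = min(max(ox, _OBS_EPS), 1 - _OBS_EPS)

    # candidate starts: coarse grid plus the naive estimate
    best = None
    for m0, h0 in coarse:
        v = _cell_nll((m0, h0), bs, ox, phi)
        if best is None or v < best[0]:
            best = (v, (m0, h0))
    naive = (min(ox, bs), max(bs - ox, 0.0))
    naive = (
        min(max(naive[0], 1e-4), 1 - 1e-4),
        min(max(naive[1], 1e-4), 1 - 1e-4),
    )
    if _cell_nll(naive, bs, ox, phi) < best[0]:
        best = (_cell_nll(naive, bs, ox, phi), naive)

    res = optimize.minimize(
        _cell_nll,
        x0=np.array(best[1]),
        args=(bs, ox, phi),
        method="SLSQP",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if res.success and np.isfinite(res.fun) and res.fun <= best[0] + 1e-9:
        m, h = res.x
        m = float(min(max(m, 0.0), 1.0))
        h = float(min(max(h, 0.0), 1.0 - m))
        return m, h, True
    # non-convergence: fall back to the best scanned point (naive-anchored)
    m, h = best[1]
    return float(m), float(h), False


def deconvolve_ml(paired: PairedBetaSet, precision: float) -> CytosineProportions:
    """Per-cell maximum-likelihood deconvolution under a beta noise model.

    Each treatment's beta value is modelled as Beta-distributed with mean
    p5mC + p5hmC (BS) or p5mC (OxBS) and shared ``precision``; the joint
    likelihood is maximised over the simplex cell by cell. Cells where the
    optimiser fails fall back to the naive estimate and are counted in a
    single logged warning.
    """
    if precision <= 0:
        raise ConfigurationError(f"precision must be > 0, got {precision!r}")
    bs = paired.beta_bs.to_numpy(dtype=float)
    ox = paired.beta_oxbs.to_numpy(dtype=float)
    # coarse simplex scan (step 0.05) to select the optimisation basin
    step = 0.05
    grid = np.arange(0.0, 1.0 + step / 2, step)
    coarse = np.array(
        [(m, h) for m in grid for h in grid if m + h <= 1.0 + 1e-12]
    )
    coarse = np.clip(coarse, 1e-4, 1 - 1e-4)

    m_hat = np.empty_like(bs)
    h_hat = np.empty_like(bs)
    n_fallback = 0
    for i in range(bs.shape[0]):
        for j in range(bs.shape[1]):
            m, h, ok = _ml_cell(bs[i, j], ox[i, j], float(precision), coarse)
            if not ok:
                n_fallback += 1
            m_hat[i, j] = m
            h_hat[i, j] = h
    if n_fallback:
        logger.warning(
            "ML deconvolution fell back to scan/naive estimate at %d cells",
            n_fallback,
        )
    p_c = 1.0 - m_hat - h_hat
    idx, cols = paired.locus_ids, paired.sample_ids
    return CytosineProportions(
        pd.DataFrame(p_c, index=idx, columns=cols),
        pd.DataFrame(m_hat, index=idx, columns=cols),
        pd.DataFrame(h_hat, index=idx, columns=cols),
    )
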