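"""Two-state (telegraph) transcription model: likelihood, MLE and comparisons.

A gene switches ON<->OFF at rates k_on / k_off and transcribes at rate
k_syn while ON; with mRNA degradation rate fixed to 1 (all rates in units
of the degradation rate), the steady-state mRNA copy number follows the
Poisson-beta mixture

    n ~ Poisson(k_syn * p),   p ~ Beta(k_on, k_off).

Burst frequency is k_on (bursts per mRNA lifetime) and burst size
k_syn / k_off (transcripts per burst).  The marginal pmf is evaluated by
fixed-order Gauss-Jacobi quadrature over the Beta mixing density with
log-domain accumulation; per-gene maximum likelihood uses bounded
quasi-Newton optimization from a method-of-moments start plus jittered
restarts.  Allelic counts flagged as missing (NaN) are excluded per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from scipy.special import (betaln, gammaln, logsumexp, roots_genlaguerre,
                           roots_jacobi)

from .dosage import rank_sum_test

logger = logging.getLogger(__name__)

QUAD_NODES = 50
#: below this k_on/k_off the Beta density is too boundary-singular for the
#: fixed rule; the pmf entry point falls back to adaptive quadrature
SINGULAR_LIMIT = 0.05

BOUNDS_KON = (1e-3, 1e3)
BOUNDS_KOFF = (1e-3, 1e3)
BOUNDS_KSYN = (1e-2, 1e4)


@dataclass
class BurstKinetics:
    """Per-gene, per-allele telegraph-model parameter estimates."""

    feature_id: str
    allele: str
    k_on: float
    k_off: float
    k_syn: float
    converged: bool
    n_cells: int
    reason: str = ""

    @property
    def burst_frequency(self) -> float:
        return self.k_on

    @property
    def burst_size(self) -> float:
        return self.k_syn / self.k_off


@dataclass
class BurstComparison:
    """X-vs-autosome comparison of burst parameter distributions."""

    allele: str
    group: str | None
    fold_frequency: float
    fold_size: float
    p_frequency: float
    p_size: float
    n_x: int
    n_autosomal: int


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _check_rates(k_on, k_off, k_syn):
    for name, v in (("k_on", k_on), ("k_off", k_off), ("k_syn", k_syn)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {v}")


_LEGENDRE = np.polynomial.legendre.leggauss(QUAD_NODES)


def _log_pois_mix(n, lam, logw):
    lam = np.maximum(lam, 1e-300)
    n = np.asarray(n)
    log_pois = (n[:, None] * np.log(lam)[None, :] - lam[None, :]
                - gammaln(n + 1.0)[:, None])
    return logsumexp(log_pois + logw[None, :], axis=1)


def _log_pmf_quadrature(n: np.ndarray, k_on: float, k_off: float,
                        k_syn: float, nodes: int = QUAD_NODES) -> np.ndarray:
    """log P(n) via fixed-order quadrature over the Beta mixing density.

    With p = (1+t)/2, the Beta(k_on, k_off) integral over [0,1] becomes a
    Jacobi-weighted integral with alpha = k_off - 1, beta = k_on - 1; the
    quadrature is exact for polynomial integrands and integrates the Beta
    density itself exactly, so the pmf normalizes to 1 up to truncation.
    Very large k_on + k_off overflows the Jacobi weight computation, so a
    concentrated (near-Gaussian) Beta is instead integrated by
    Gauss-Legendre over a +-10 sd window, and the boundary-singular large
    rate corner falls back to per-count adaptive quadrature.
    """
    s = k_on + k_off
    if s > 800.0:
        if min(k_on, k_off) >= 1.0:
            mu = k_on / s
            sd = np.sqrt(k_on * k_off / (s * s * (s + 1.0)))
            lo, hi = max(mu - 10 * sd, 0.0), min(mu + 10 * sd, 1.0)
            t, w = _LEGENDRE
            p = lo + (t + 1.0) / 2.0 * (hi - lo)
            logw = np.log(w * (hi - lo) / 2.0) + stats.beta.logpdf(p, k_on, k_off)
            return _log_pois_mix(n, k_syn * p, logw)
        # boundary-singular limit: with one rate small and the other huge
        # the Beta tends to a (possibly reflected) scaled Gamma; integrate
        # it with generalized Gauss-Laguerre in the Gamma variable
        small, reflected = (k_on, False) if k_on < k_off else (k_off, True)
        g, w = roots_genlaguerre(nodes, small - 1.0)
        p = np.clip(g / s, 0.0, 1.0)
        lam = k_syn * (1.0 - p if reflected else p)
        logw = np.log(w) - gammaln(small)
        return _log_pois_mix(n, lam, logw)
    t, w = roots_jacobi(nodes, k_off - 1.0, k_on - 1.0)
    log_const = -(s - 1.0) * np.log(2.0) - betaln(k_on, k_off)
    return _log_pois_mix(n, k_syn * (1.0 + t) / 2.0,
                         np.log(w) + log_const)


def poisson_beta_pmf(n, k_on: float, k_off: float, k_syn: float) -> np.ndarray:
    """Steady-state telegraph-model pmf P(n) at copy numbers ``n``.

    Uses the fixed Gauss-Jacobi rule; when k_on or k_off is below
    ``SINGULAR_LIMIT`` the Beta density is boundary-singular and each
    probability is instead computed by adaptive quadrature.
    """
    _check_rates(k_on, k_off, k_syn)
    arr = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    if min(k_on, k_off) >= SINGULAR_LIMIT:
        out = np.exp(_log_pmf_quadrature(arr, k_on, k_off, k_syn))
    else:
        out = np.array([_pmf_adaptive(int(v), k_on, k_off, k_syn) for v in arr])
    return out if np.ndim(n) else float(out[0])


def _pmf_adaptive(n: int, k_on: float, k_off: float, k_syn: float) -> float:
    def integrand(p):
        return np.exp(n * np.log(k_syn * p) - k_syn * p - gammaln(n + 1)
                      + stats.beta.logpdf(p, k_on, k_off)) if p > 0 else 0.0

    if n == 0:
        def integrand(p):  # noqa: F811 - zero-count branch avoids log(0)
            return np.exp(-k_syn * p + stats.beta.logpdf(p, k_on, k_off)) \
                if 0 < p < 1 else 0.0
    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200, points=[0.0, 1.0])
    return float(val)


def poisson_beta_mean(k_on, k_off, k_syn) -> float:
    """Closed-form mean k_syn * k_on / (k_on + k_off)."""
    return k_syn * k_on / (k_on + k_off)


def poisson_beta_variance(k_on, k_off, k_syn) -> float:
    """Law-of-total-variance closed form: mean + k_syn^2 Var(Beta)."""
    s = k_on + k_off
    return poisson_beta_mean(k_on, k_off, k_syn) \
        + k_syn ** 2 * k_on * k_off / (s ** 2 * (s + 1.0))


def truncation_bound(k_on, k_off, k_syn, tail: float = 1e-10) -> int:
    """Count beyond which the pmf mass is below ``tail`` (Poisson bound at
    the largest mixing intensity)."""
    return int(stats.poisson.isf(tail, k_syn)) + 2


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def moment_estimate(counts: np.ndarray) -> tuple[float, float, float] | None:
    """Method-of-moments (factorial moments) start point for the MLE.

    Solves the first three factorial moments of the Poisson-beta mixture
    for (k_on, k_off, k_syn); returns None when the sample moments are
    inconsistent with the model (degenerate denominators or non-positive
    solutions).
    """
    x = np.asarray(counts, dtype=float)
    m1 = x.mean()
    m2 = (x * (x - 1)).mean()
    m3 = (x * (x - 1) * (x - 2)).mean()
    if m1 <= 0 or m2 <= 0 or m3 <= 0:
        return None
    r1, r2, r3 = m1, m2 / m1, m3 / m2
    den_syn = r1 - 2 * r2 + r3
    den_on = r1 * r2 - 2 * r1 * r3 + r2 * r3
    if den_syn == 0 or den_on == 0:
        return None
    k_syn = (2 * r1 * r3 - r1 * r2 - r2 * r3) / den_syn
    k_on = 2 * r1 * (r3 - r2) / den_on
    k_off = (2 * (r3 - r2) * (r1 - r3) * (r2 - r1)) / (den_on * den_syn)
    if not all(np.isfinite(v) and v > 0 for v in (k_on, k_off, k_syn)):
        return None
    return float(k_on), float(k_off), float(k_syn)


def _neg_log_likelihood(log_params, unique, weights):
    k_on, k_off, k_syn = np.exp(log_params)
    ll = _log_pmf_quadrature(unique, k_on, k_off, k_syn)
    return -float(np.dot(weights, ll))


_JITTERS = ((1.6487212707001282, 0.6065306597126334, 1.0),   # e^±0.5 pattern
            (0.6065306597126334, 1.6487212707001282, 0.6065306597126334))


def fit_two_state_mle(counts, feature_id: str = "", allele: str = "",
                      min_cells: int = 50) -> BurstKinetics:
    """Maximum-likelihood telegraph-model fit for one gene and allele.

    ``counts`` are per-cell allelic values; NaN entries (missing allelic
    information) are dropped, remaining values are rounded to integers.
    The optimizer is bounded L-BFGS-B in log-parameter space, started from
    the method-of-moments solution plus two deterministically jittered
    starts.  ``converged`` is False when the optimizer fails, the optimum
    sits on a bound, or the data are uninformative (all zeros).
    """
    x = np.asarray(counts, dtype=float)
    x = x[np.isfinite(x)]
    n_cells = x.size
    result = lambda kon, koff, ksyn, ok, reason="": BurstKinetics(  # noqa: E731
        feature_id, allele, kon, koff, ksyn, ok, n_cells, reason)
    if n_cells < min_cells:
        return result(np.nan, np.nan, np.nan, False,
                      f"only {n_cells} cells (minimum {min_cells})")
    x = np.round(np.maximum(x, 0.0))
    if np.all(x == 0):
        return result(np.nan, np.nan, np.nan, False, "all counts zero")
    unique, weights = np.unique(x, return_counts=True)
    weights = weights.astype(float)

    mm = moment_estimate(x)
    if mm is None:
        mm = (1.0, 10.0, max(10.0 * x.mean() * 11.0 / 10.0, 1.0))
    lo = np.log([BOUNDS_KON[0], BOUNDS_KOFF[0], BOUNDS_KSYN[0]])
    hi = np.log([BOUNDS_KON[1], BOUNDS_KOFF[1], BOUNDS_KSYN[1]])
    start0 = np.clip(np.log(mm), lo + 1e-6, hi - 1e-6)
    starts = [start0] + [np.clip(start0 + np.log(j), lo + 1e-6, hi - 1e-6)
                         for j in _JITTERS]

    def interior(res):
        return bool(res.success) and not (
            np.any(res.x <= lo + 1e-4) or np.any(res.x >= hi - 1e-4))

    # lazy multi-start: the jittered restarts only run when the
    # moment-started fit fails or lands on a bound
    best = None
    for s in starts:
        try:
            res = optimize.minimize(
                _neg_log_likelihood, s, args=(unique, weights),
                method="L-BFGS-B", bounds=list(zip(lo, hi)),
                options={"maxiter": 150})
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or res.fun < best.fun:
            best = res
        if interior(best):
            break
    if best is None or not np.all(np.isfinite(best.x)):
        return result(np.nan, np.nan, np.nan, False, "optimizer failure")
    k_on, k_off, k_syn = np.exp(best.x)
    on_bound = bool(np.any(best.x <= lo + 1e-4) or np.any(best.x >= hi - 1e-4))
    ok = bool(best.success) and not on_bound
    return result(float(k_on), float(k_off), float(k_syn), ok,
                  "" if ok else ("parameter at bound" if on_bound
                                 else str(best.message)))


def fit_burst_table(counts: pd.DataFrame, allele: str = "",
                    min_cells: int = 50,
                    max_missing_fraction: float = 0.9) -> pd.DataFrame:
    """Fit the telegraph model for every row (gene) of a genes x cells frame.

    NaN entries follow the missing-data convention; genes with more than
    ``max_missing_fraction`` missing cells are skipped.  Returns a frame of
    per-gene estimates with burst_frequency / burst_size columns.
    """
    rows = []
    for fid, row in counts.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.mean(~np.isfinite(vals)) > max_missing_fraction:
            rows.append(BurstKinetics(fid, allele, np.nan, np.nan, np.nan,
                                      False, int(np.isfinite(vals).sum()),
                                      "mostly missing"))
            continue
        rows.append(fit_two_state_mle(vals, feature_id=fid, allele=allele,
                                      min_cells=min_cells))
    out = pd.DataFrame(
        {"allele": [r.allele for r in rows],
         "k_on": [r.k_on for r in rows],
         "k_off": [r.k_off for r in rows],
         "k_syn": [r.k_syn for r in rows],
         "converged": [r.converged for r in rows],
         "n_cells": [r.n_cells for r in rows],
         "reason": [r.reason for r in rows]},
        index=pd.Index([r.feature_id for r in rows], name="feature_id"))
    out["burst_frequency"] = out["k_on"]
    out["burst_size"] = out["k_syn"] / out["k_off"]
    return out


# ---------------------------------------------------------------------------
# normalization and comparison
# ---------------------------------------------------------------------------

def rpkm_normalize(counts, gene_lengths, library_sizes):
    """Reads per kilobase per million: count * 1e9 / (length * library)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be > 0")
    if counts.ndim == 2:
        return counts * 1e9 / (lengths[:, None] * libs[None, :])
    return counts * 1e9 / (lengths * libs)


def compare_burst(kinetics: pd.DataFrame, x_features, autosomal_features,
                  allele: str = "", group: str | None = None,
                  min_converged: int = 20) -> BurstComparison:
    """X-vs-autosome fold of median burst frequency and burst size.

    Only converged genes enter; fewer than ``min_converged`` per side is an
    error.  P-values are two-sided rank-sum tests on the per-gene
    estimates.
    """
    conv = kinetics[kinetics["converged"]]
    xk = conv.loc[conv.index.intersection(pd.Index(x_features))]
    ak = conv.loc[conv.index.intersection(pd.Index(autosomal_features))]
    if len(xk) < min_converged or len(ak) < min_converged:
        raise ValueError(
            f"too few converged genes (X: {len(xk)}, autosomal: {len(ak)}, "
            f"minimum {min_converged})")
    _, p_f = rank_sum_test(xk["burst_frequency"], ak["burst_frequency"])
    _, p_s = rank_sum_test(xk["burst_size"], ak["burst_size"])
    return BurstComparison(
        allele=allele, group=group,
        fold_frequency=float(xk["burst_frequency"].median()
                             / ak["burst_frequency"].median()),
        fold_size=float(xk["burst_size"].median() / ak["burst_size"].median()),
        p_frequency=p_f, p_size=p_s, n_x=len(xk), n_autosomal=len(ak))
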