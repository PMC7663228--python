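"""Mixed-indicator latent class model fitted by EM with FIML missing data.

The model is a K-component finite mixture over 8 continuous indicators
(unit-interval Gaussians with class-specific means and variances) and 4
binary indicators (class-specific Bernoulli probabilities). All indicators
are conditionally independent given class, except one designated continuous
pair (weekday MVPA and sedentary minutes) which shares a single covariance
parameter c across all classes: within class k the pair is bivariate normal
with covariance matrix [[s2_mvpa_k, c], [c, s2_sed_k]].

Missing cells simply drop out of each row's likelihood (full-information
maximum likelihood): a row contributes the product of densities of its
observed cells only; when only one member of the covariance pair is observed
it contributes its univariate marginal. Estimation is by EM with random
multi-start (short runs, best continued), log-sum-exp stabilized E-steps, a
variance floor and Bernoulli clamp against degenerate spikes, and canonical
class ordering (descending mixing weight) for reproducibility.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocessing import IndicatorMatrix

log = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ModelSpec:
    """Structure of the mixture: column layout and numerical guards."""

    n_classes: int
    n_continuous: int = 8
    n_binary: int = 4
    shared_pair: Optional[tuple] = (5, 6)  # (mvpa, sedentary) column indices
    var_floor: float = 1e-4
    prob_clamp: float = 1e-4

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.var_floor <= 0 or self.prob_clamp <= 0:
            raise ValueError("floors must be positive")
        if self.shared_pair is not None:
            a, b = self.shared_pair
            if not (0 <= a < self.n_continuous and 0 <= b < self.n_continuous
                    and a != b):
                raise ValueError("shared_pair must index two distinct "
                                 "continuous columns")

    @property
    def n_columns(self) -> int:
        return self.n_continuous + self.n_binary


@dataclass
class LcaParameters:
    mixing: np.ndarray       # (K,)
    means: np.ndarray        # (K, n_continuous)
    variances: np.ndarray    # (K, n_continuous)
    shared_cov: float        # scalar, 0.0 when no shared pair
    probs: np.ndarray        # (K, n_binary)

    def __post_init__(self):
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        self.shared_cov = float(self.shared_cov)

    @property
    def n_classes(self) -> int:
        return len(self.mixing)

    def validate(self, spec: ModelSpec) -> None:
        if abs(self.mixing.sum() - 1) > 1e-8:
            raise ValueError("mixing must sum to 1")
        if not np.isfinite(self.means).all() or not np.isfinite(self.variances).all():
            raise ValueError("non-finite parameters")
        if (self.variances < spec.var_floor * (1 - 1e-9)).any():
            raise ValueError("variances below floor")
        if spec.shared_pair is not None:
            a, b = spec.shared_pair
            det = self.variances[:, a] * self.variances[:, b] - self.shared_cov ** 2
            if (det <= 0).any():
                raise ValueError("shared-covariance block not positive definite")

    def to_dict(self) -> dict:
        return {
            "mixing": self.mixing.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "shared_cov": self.shared_cov,
            "probs": self.probs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LcaParameters":
        return cls(mixing=np.array(d["mixing"]), means=np.array(d["means"]),
                   variances=np.array(d["variances"]),
                   shared_cov=d["shared_cov"], probs=np.array(d["probs"]))


@dataclass
class FitResult:
    params: LcaParameters
    log_likelihood: float
    n_parameters: int
    posteriors: np.ndarray
    modal: np.ndarray
    converged: bool
    n_iter: int
    n_starts_used: int
    best_start_seed: int
    max_ll_decrease: float = 0.0  # largest relative EM decrease observed

    def save(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_parameters": self.n_parameters,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_starts_used": int(self.n_starts_used),
            "best_start_seed": int(self.best_start_seed),
            "max_ll_decrease": float(self.max_ll_decrease),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def count_parameters(spec: ModelSpec) -> int:
    """Free parameters: (K-1) mixing + K means + K variances per continuous
    column + one shared covariance per pair + K Bernoulli probabilities."""
    k = spec.n_classes
    n_pairs = 0 if spec.shared_pair is None else 1
    return (k - 1) + 2 * k * spec.n_continuous + n_pairs + k * spec.n_binary


def _coerce(matrix) -> tuple:
    """Accept IndicatorMatrix, ndarray or (values, mask); return (values, mask)."""
    if isinstance(matrix, tuple):
        return matrix
    if isinstance(matrix, IndicatorMatrix):
        values = matrix.values
    else:
        values = np.asarray(matrix, dtype=float)
    return values, ~np.isnan(values)


def log_class_density(row, mask, params: LcaParameters, k: int,
                      spec: ModelSpec) -> float:
    """Log density of one row's observed cells under class k.

    Reference (loop) implementation; the vectorized path used by the E-step
    must agree with it. A fully missing row has log density 0.
    """
    row = np.asarray(row, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (np.isfinite(params.means[k]).all()
            and np.isfinite(params.variances[k]).all()):
        raise ValueError("non-finite parameters")
    nc = spec.n_continuous
    pair = spec.shared_pair
    total = 0.0
    for j in range(nc):
        if not mask[j]:
            continue
        if pair is not None and j == pair[1] and mask[pair[0]]:
            continue  # handled jointly below
        mu, v = params.means[k, j], params.variances[k, j]
        total += -0.5 * (_LOG2PI + math.log(v) + (row[j] - mu) ** 2 / v)
    if pair is not None and mask[pair[0]] and mask[pair[1]]:
        a, b = pair
        va, vb, c = params.variances[k, a], params.variances[k, b], params.shared_cov
        # joint = marginal(a) already added; add conditional b | a
        mu_cond = params.means[k, b] + (c / va) * (row[a] - params.means[k, a])
        v_cond = vb - c * c / va
        total += -0.5 * (_LOG2PI + math.log(v_cond)
                         + (row[b] - mu_cond) ** 2 / v_cond)
    for j in range(spec.n_binary):
        if not mask[nc + j]:
            continue
        x, p = row[nc + j], params.probs[k, j]
        total += x * math.log(p) + (1 - x) * math.log(1 - p)
    return total


def _log_density_matrix(values: np.ndarray, mask: np.ndarray,
                        params: LcaParameters, spec: ModelSpec) -> np.ndarray:
    """(n, K) matrix of per-row, per-class log densities (vectorized)."""
    nc = spec.n_continuous
    xc = np.nan_to_num(values[:, :nc])
    mc = mask[:, :nc].astype(float)
    mu, var = params.means, params.variances  # (K, nc)
    inv = 1.0 / var
    # sum_j m_ij * [ -0.5(log 2 pi v_kj) - 0.5 (x_ij - mu_kj)^2 / v_kj ]
    const = -0.5 * (_LOG2PI + np.log(var))                     # (K, nc)
    out = mc @ const.T
    out -= 0.5 * ((mc * xc * xc) @ inv.T
                  - 2.0 * (mc * xc) @ (mu * inv).T
                  + mc @ (mu * mu * inv).T)
    if spec.shared_pair is not None and params.shared_cov != 0.0:
        a, b = spec.shared_pair
        both = mask[:, a] & mask[:, b]
        if both.any():
            xa = values[both, a][:, None]
            xb = values[both, b][:, None]
            va, vb, c = var[None, :, a], var[None, :, b], params.shared_cov
            mua, mub = mu[None, :, a], mu[None, :, b]
            # replace the univariate b-term with the conditional b | a term
            uni_b = -0.5 * (_LOG2PI + np.log(vb) + (xb - mub) ** 2 / vb)
            mu_cond = mub + (c / va) * (xa - mua)
            v_cond = vb - c * c / va
            cond_b = -0.5 * (_LOG2PI + np.log(v_cond)
                             + (xb - mu_cond) ** 2 / v_cond)
            out[both] += (cond_b - uni_b)
    if spec.n_binary:
        xb_ = np.nan_to_num(values[:, nc:])
        mb = mask[:, nc:].astype(float)
        logp = np.log(params.probs)        # (K, nb)
        log1p_ = np.log1p(-params.probs)
        out += (mb * xb_) @ (logp - log1p_).T + mb @ log1p_.T
    return out


def e_step(matrix, params: LcaParameters, spec: ModelSpec) -> tuple:
    """Posterior class probabilities and observed-data log likelihood."""
    values, mask = _coerce(matrix)
    logdens = _log_density_matrix(values, mask, params, spec)
    logw = np.log(params.mixing)[None, :] + logdens
    m = logw.max(axis=1, keepdims=True)
    if not np.isfinite(m).all():
        bad = int(np.flatnonzero(~np.isfinite(m.ravel()))[0])
        raise FloatingPointError(
            f"all class densities vanish for row {bad}; data inconsistent "
            "with parameters")
    lse = m + np.log(np.exp(logw - m).sum(axis=1, keepdims=True))
    posteriors = np.exp(logw - lse)
    return posteriors, float(lse.sum())


def m_step(matrix, posteriors: np.ndarray, spec: ModelSpec,
           min_class_mass: float = 1e-8) -> LcaParameters:
    """Posterior-weighted moment updates over observed cells.

    The shared covariance pools the posterior-weighted cross-moment of the
    designated pair over classes, using only rows where both members are
    observed; it is then shrunk if needed so every class's 2x2 block stays
    positive definite. Floors and clamps are applied (and logged).
    """
    values, mask = _coerce(matrix)
    r = np.asarray(posteriors, dtype=float)
    n, k = r.shape
    nc = spec.n_continuous
    xc = np.nan_to_num(values[:, :nc])
    mc = mask[:, :nc].astype(float)

    mixing = r.mean(axis=0)
    mixing = np.maximum(mixing, 1e-12)
    mixing = mixing / mixing.sum()

    denom = r.T @ mc                       # (K, nc) effective counts
    degenerate = denom < min_class_mass
    if degenerate.any():
        log.warning("m_step: %d class/column cells have ~zero posterior "
                    "mass; flooring", int(degenerate.sum()))
    denom = np.maximum(denom, min_class_mass)
    s1 = r.T @ (mc * xc)
    s2 = r.T @ (mc * xc * xc)
    means = s1 / denom
    variances = s2 / denom - means ** 2
    n_floored = int((variances < spec.var_floor).sum())
    if n_floored:
        log.info("m_step: variance floor active on %d cells", n_floored)
    variances = np.maximum(variances, spec.var_floor)

    shared_cov = 0.0
    if spec.shared_pair is not None:
        a, b = spec.shared_pair
        both = mask[:, a] & mask[:, b]
        if both.any():
            rp = r[both]
            xa, xb = values[both, a], values[both, b]
            s_w = rp.sum(axis=0)
            s_a = rp.T @ xa
            s_b = rp.T @ xb
            s_ab = rp.T @ (xa * xb)
            cross = (s_ab - means[:, a] * s_b - means[:, b] * s_a
                     + means[:, a] * means[:, b] * s_w)
            shared_cov = float(cross.sum() / max(s_w.sum(), min_class_mass))
            # keep every class's 2x2 block positive definite
            bound = float(np.sqrt((variances[:, a] * variances[:, b]).min()))
            limit = 0.999 * bound
            if abs(shared_cov) > limit:
                log.info("m_step: shared covariance %.3g shrunk to PD bound "
                         "%.3g", shared_cov, math.copysign(limit, shared_cov))
                shared_cov = math.copysign(limit, shared_cov)

    probs = np.empty((k, spec.n_binary))
    if spec.n_binary:
        xb_ = np.nan_to_num(values[:, nc:])
        mb = mask[:, nc:].astype(float)
        db = np.maximum(r.T @ mb, min_class_mass)
        probs = (r.T @ (mb * xb_)) / db
        clamped = (probs < spec.prob_clamp) | (probs > 1 - spec.prob_clamp)
        if clamped.any():
            log.info("m_step: Bernoulli clamp active on %d cells",
                     int(clamped.sum()))
        probs = np.clip(probs, spec.prob_clamp, 1 - spec.prob_clamp)

    return LcaParameters(mixing=mixing, means=means, variances=variances,
                         shared_cov=shared_cov, probs=probs)


def canonical_order(params: LcaParameters,
                    posteriors: Optional[np.ndarray] = None) -> tuple:
    """Relabel classes by descending mixing weight (ties: first continuous
    column mean, descending)."""
    order = np.lexsort((-params.means[:, 0], -params.mixing))
    reordered = LcaParameters(
        mixing=params.mixing[order], means=params.means[order],
        variances=params.variances[order], shared_cov=params.shared_cov,
        probs=params.probs[order])
    if posteriors is not None:
        posteriors = posteriors[:, order]
    return reordered, posteriors


def _em_run(values, mask, spec, params, max_iter, tol):
    """Run EM from given parameters; returns (params, R, ll, iters, converged,
    max relative ll dip refused).

    The pooled shared-covariance update, its positive-definiteness clamp and
    the variance/probability floors are constrained (generalized-EM) updates
    that can occasionally decrease the likelihood — typically at convergence
    (machine-scale dips) or on degenerate starts where a class collapses. If
    an iteration would decrease the log likelihood, the run reverts to the
    previous (better) state and stops, so the reported trajectory is always
    monotone; the largest refused dip is recorded for diagnostics. Multi-start
    makes ending such a run early harmless.
    """
    prev = -np.inf
    prev_state = None
    max_drop = 0.0
    posteriors = None
    converged = False
    it = 0
    ll = -np.inf
    for it in range(1, max_iter + 1):
        posteriors, ll = _e_step_raw(values, mask, params, spec)
        if np.isfinite(prev):
            if ll < prev:
                drop = (prev - ll) / max(1.0, abs(prev))
                max_drop = max(max_drop, drop)
                params, posteriors, ll = prev_state
                converged = True
                break
            if (ll - prev) <= tol * abs(prev):
                converged = True
                break
        prev_state = (params, posteriors, ll)
        params = m_step((values, mask), posteriors, spec)
        prev = ll
    return params, posteriors, ll, it, converged, max_drop


def _e_step_raw(values, mask, params, spec):
    logdens = _log_density_matrix(values, mask, params, spec)
    logw = np.log(params.mixing)[None, :] + logdens
    m = logw.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(logw - m).sum(axis=1, keepdims=True))
    return np.exp(logw - lse), float(lse.sum())


def fit(matrix, spec: ModelSpec, n_starts: int = 50, max_iter: int = 2000,
        tol: float = 1e-7, seed: int = 0, short_iters: int = 30,
        n_final: int = 2) -> FitResult:
    """Multi-start EM fit.

    Starts are random posterior initializations (Dirichlet rows); every start
    runs ``short_iters`` EM iterations, the best ``n_final`` continue to
    convergence, and the overall best log likelihood wins. Within-run
    monotonicity of the log likelihood is tracked and enforced.
    """
    values, mask = _coerce(matrix)
    n = values.shape[0]
    if n < spec.n_classes:
        raise ValueError("need at least K rows")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    if spec.n_classes == 1:
        r = np.ones((n, 1))
        params = m_step((values, mask), r, spec)
        posteriors, ll = _e_step_raw(values, mask, params, spec)
        # one refinement pass settles the shared covariance
        params = m_step((values, mask), posteriors, spec)
        posteriors, ll = _e_step_raw(values, mask, params, spec)
        return FitResult(params, ll, count_parameters(spec), posteriors,
                         np.zeros(n, dtype=int), True, 2, 1, seed)

    # Short phase.
    candidates = []
    for s in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11, s)))
        r0 = rng.dirichlet(np.ones(spec.n_classes), size=n)
        params0 = m_step((values, mask), r0, spec)
        params_s, _, ll_s, _, conv_s, drop_s = _em_run(
            values, mask, spec, params0, short_iters, tol)
        candidates.append((ll_s, s, params_s, conv_s, drop_s))
    candidates.sort(key=lambda t: t[0], reverse=True)

    # Long phase: continue the best starts to convergence.
    best = None
    for ll_s, s, params_s, conv_s, drop_s in candidates[:max(1, n_final)]:
        params_f, post_f, ll_f, it_f, conv_f, drop_f = _em_run(
            values, mask, spec, params_s, max_iter, tol)
        drop = max(drop_s, drop_f)
        if drop > 0:
            log.debug("EM: refused a near-convergence relative LL dip of "
                      "%.2e", drop)
        if best is None or ll_f > best[0]:
            best = (ll_f, s, params_f, post_f, it_f, conv_f, drop)

    ll, s, params, posteriors, iters, converged, drop = best
    if not converged:
        log.warning("fit(K=%d): best start did not converge in %d iterations",
                    spec.n_classes, max_iter)
    params, posteriors = canonical_order(params, posteriors)
    modal = posteriors.argmax(axis=1)
    return FitResult(params=params, log_likelihood=ll,
                     n_parameters=count_parameters(spec),
                     posteriors=posteriors, modal=modal, converged=converged,
                     n_iter=iters, n_starts_used=n_starts, best_start_seed=s,
                     max_ll_decrease=drop)


def simulate_from_params(params: LcaParameters, spec: ModelSpec, n: int,
                         rng: np.random.Generator) -> tuple:
    """Draw a complete dataset from fitted parameters (for the bootstrap LRT).

    Returns (values, classes) on the model scale; no bounds are applied.
    """
    cum = np.cumsum(params.mixing)
    cls = np.searchsorted(cum, rng.random(n))
    cls = np.minimum(cls, params.n_classes - 1)
    nc = spec.n_continuous
    z = rng.standard_normal((n, nc))
    values = np.empty((n, spec.n_columns))
    values[:, :nc] = params.means[cls] + np.sqrt(params.variances[cls]) * z
    if spec.shared_pair is not None:
        a, b = spec.shared_pair
        va = params.variances[cls, a]
        vb = params.variances[cls, b]
        c = params.shared_cov
        # Cholesky of [[va, c], [c, vb]] applied to fresh normals
        z2 = rng.standard_normal((n, 2))
        l11 = np.sqrt(va)
        l21 = c / l11
        l22 = np.sqrt(np.maximum(vb - c * c / va, 1e-12))
        values[:, a] = params.means[cls, a] + l11 * z2[:, 0]
        values[:, b] = params.means[cls, b] + l21 * z2[:, 0] + l22 * z2[:, 1]
    if spec.n_binary:
        u = rng.random((n, spec.n_binary))
        values[:, nc:] = (u < params.probs[cls]).astype(float)
    return values, cls
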