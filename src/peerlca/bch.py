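"""BCH three-step distal outcomes: classification-error-corrected proportions.

After a latent class fit, the proportion of each class with a binary outcome
(here: being selected as a peer supporter) is estimated with the
Bolck-Croon-Hagenaars correction: individuals are weighted by the row of the
inverse classification-error matrix indexed by their modal class, which
undoes the bias of the naive modal crosstab. Uncertainty comes from a
percentile cluster bootstrap that resamples whole schools, honouring the
clustering of pupils within schools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rng import child_rng

log = logging.getLogger(__name__)


def classification_error_matrix(posteriors: np.ndarray,
                                modal: np.ndarray) -> np.ndarray:
    """Q[k, s] = posterior-mass-weighted P(modal class = s | true class = k)."""
    p = np.asarray(posteriors, dtype=float)
    modal = np.asarray(modal)
    n, k = p.shape
    if modal.shape != (n,):
        raise ValueError("modal must align with posteriors")
    mass = p.sum(axis=0)
    if (mass <= 0).any():
        raise ValueError("a class has zero total posterior mass")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), modal] = 1.0
    q = (p.T @ onehot) / mass[:, None]
    return q


def bch_weights(q: np.ndarray, modal: np.ndarray,
                cond_threshold: float = 1e8) -> np.ndarray:
    """Per-individual BCH weights: row of Q^-1 indexed by the modal class.

    Weights may be negative by construction; their column sums estimate
    class sizes. A near-singular Q means classification is too poor (entropy
    too low) for the correction to be stable.
    """
    q = np.asarray(q, dtype=float)
    cond = np.linalg.cond(q)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise np.linalg.LinAlgError(
            f"classification-error matrix is near-singular (cond={cond:.3g}); "
            "classification entropy is too low for BCH weighting")
    qinv = np.linalg.inv(q)
    return qinv[np.asarray(modal)]


@dataclass
class DistalEstimate:
    class_index: int
    proportion: float
    lower: float
    upper: float
    weight_sum: float
    truncated: bool = False
    unstable: bool = False


def class_outcome_proportions(weights: np.ndarray, outcome: np.ndarray,
                              school_ids: np.ndarray, n_boot: int = 500,
                              seed: int = 0, ci_level: float = 0.95) -> list:
    """BCH-weighted outcome proportion per class with cluster-bootstrap CIs.

    proportion_k = sum_i w_ik y_i / sum_i w_ik, truncated to [0,1] (the
    weights themselves are left untouched). Intervals are percentile
    intervals over ``n_boot`` resamples of whole schools.
    """
    w = np.asarray(weights, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if w.shape[0] != len(y) or len(y) != len(school_ids):
        raise ValueError("weights, outcome and school_ids must align")
    k = w.shape[1]

    def props(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = num / den
        return np.clip(p, 0.0, 1.0), p

    schools = pd.unique(pd.Series(school_ids))
    s_index = pd.Series(np.arange(len(schools)), index=schools)
    sid = s_index[pd.Series(school_ids)].to_numpy()
    n_s = len(schools)
    den_s = np.zeros((n_s, k))
    num_s = np.zeros((n_s, k))
    np.add.at(den_s, sid, w)
    np.add.at(num_s, sid, w * y[:, None])

    den = den_s.sum(axis=0)
    num = num_s.sum(axis=0)
    est, raw = props(num, den)
    truncated = ~np.isclose(est, raw, equal_nan=True)
    if truncated.any():
        log.info("BCH proportions truncated to [0,1] for classes %s",
                 np.flatnonzero(truncated).tolist())
    unstable = den <= 0
    if unstable.any():
        log.warning("BCH weight sums non-positive for classes %s; estimates "
                    "flagged unstable", np.flatnonzero(unstable).tolist())

    rng = child_rng(seed, "bootstrap")
    idx = rng.integers(0, n_s, size=(n_boot, n_s))
    boot_num = num_s[idx].sum(axis=1)          # (n_boot, K)
    boot_den = den_s[idx].sum(axis=1)
    boot_p, _ = props(boot_num, boot_den)
    alpha = (1.0 - ci_level) / 2.0
    lower = np.nanpercentile(boot_p, 100 * alpha, axis=0)
    upper = np.nanpercentile(boot_p, 100 * (1 - alpha), axis=0)
    lower = np.minimum(lower, est)
    upper = np.maximum(upper, est)

    return [DistalEstimate(class_index=kk, proportion=float(est[kk]),
                           lower=float(lower[kk]), upper=float(upper[kk]),
                           weight_sum=float(den[kk]),
                           truncated=bool(truncated[kk]),
                           unstable=bool(unstable[kk]))
            for kk in range(k)]
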