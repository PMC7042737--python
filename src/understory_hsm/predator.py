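"""Nest-predator occurrence as a function of distance to human settlements.

Eurasian jays — the main nest predator in this system — overwinter at bird
feeders and are therefore tied to settlements.  Their occurrence near nests
is modelled as a logistic regression on distance; the "switch distance" is
where the fitted probability crosses 0.5 (d* = -alpha0/alpha1), with a
delta-method standard error.  Because a variance-explained
summary for a binary fit has no single canonical definition, three common
candidates are reported side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = ["OccurrenceFit", "fit_occurrence", "switch_distance", "variance_explained"]


@dataclass
class OccurrenceFit:
    alpha0: float
    alpha1: float
    se_alpha0: float
    se_alpha1: float
    p_value_slope: float
    cov: np.ndarray
    n_obs: int
    loglik: float
    loglik_null: float
    fitted: np.ndarray
    separated: bool = False
    separation_threshold: float | None = None


def _check_separation(d: np.ndarray, y: np.ndarray) -> float | None:
    """Complete separation along distance; returns the separating midpoint."""
    d1, d0 = d[y == 1], d[y == 0]
    if d1.size == 0 or d0.size == 0:
        return None
    if d1.max() < d0.min():  # presence only close by
        return float((d1.max() + d0.min()) / 2)
    if d0.max() < d1.min():  # presence only far away
        return float((d0.max() + d1.min()) / 2)
    return None


def fit_occurrence(distances, presence) -> OccurrenceFit:
    """Maximum-likelihood logistic regression of presence on distance (m)."""
    d = np.asarray(distances, dtype=float)
    y = np.asarray(presence, dtype=float)
    if d.size != y.size:
        raise ValueError("distances and presence differ in length")
    if np.unique(d).size < 2:
        raise ValueError("need at least two distinct distances")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both outcome classes must be present")
    if d.size < 10:
        log.warning("only %d observations; the occurrence fit will be unstable", d.size)

    sep = _check_separation(d, y)
    X = sm.add_constant(d)
    null_ll = float(sm.Logit(y, np.ones((y.size, 1))).fit(disp=0).llf)
    if sep is not None:
        # complete separation: the MLE diverges; report the separating
        # threshold with infinite uncertainty
        log.warning("complete separation at %.1f m; slope SE is infinite", sep)
        sign = -1.0 if d[y == 1].mean() < d[y == 0].mean() else 1.0
        return OccurrenceFit(
            alpha0=-sign * sep,
            alpha1=sign,
            se_alpha0=np.inf,
            se_alpha1=np.inf,
            p_value_slope=np.nan,
            cov=np.full((2, 2), np.inf),
            n_obs=d.size,
            loglik=0.0,
            loglik_null=null_ll,
            fitted=(y).astype(float),
            separated=True,
            separation_threshold=sep,
        )

    res = sm.Logit(y, X).fit(disp=0)
    cov = np.asarray(res.cov_params())
    fit = OccurrenceFit(
        alpha0=float(res.params[0]),
        alpha1=float(res.params[1]),
        se_alpha0=float(res.bse[0]),
        se_alpha1=float(res.bse[1]),
        p_value_slope=float(res.pvalues[1]),
        cov=cov,
        n_obs=d.size,
        loglik=float(res.llf),
        loglik_null=null_ll,
        fitted=np.asarray(res.predict(X)),
        separated=False,
    )
    return fit


def switch_distance(fit: OccurrenceFit) -> tuple[float, float]:
    """Distance where predicted occurrence crosses 0.5, with delta-method SE.

    d* = -alpha0 / alpha1; gradient (-1/alpha1, alpha0/alpha1^2) against the
    coefficient covariance.  For a separated fit the separating threshold is
    returned with an infinite SE.
    """
    if fit.separated:
        return float(fit.separation_threshold), np.inf
    if fit.alpha1 == 0.0:
        raise ValueError("switch distance undefined for zero slope")
    if abs(fit.alpha1) < 2 * fit.se_alpha1:
        log.warning("slope within 2 SE of zero; switch distance is ill-determined")
    d_star = -fit.alpha0 / fit.alpha1
    grad = np.array([-1.0 / fit.alpha1, fit.alpha0 / fit.alpha1**2])
    var = float(grad @ fit.cov @ grad)
    return float(d_star), float(np.sqrt(max(var, 0.0)))


def variance_explained(fit: OccurrenceFit, presence) -> dict[str, float]:
    """Three variance-explained summaries for the binary occurrence fit.

    - corr_squared: squared Pearson correlation of fitted probability and
      outcome (the default headline metric),
    - mcfadden: 1 - loglik / loglik_null,
    - tjur: mean fitted probability difference between the classes.
    Degenerate (constant) fits return 0 for the correlation metric.
    """
    y = np.asarray(presence, dtype=float)
    p = np.asarray(fit.fitted, dtype=float)
    if np.ptp(p) < 1e-14 or np.ptp(y) == 0:
        corr2 = 0.0
        log.info("constant fitted probabilities; correlation-based R2 reported as 0")
    else:
        corr2 = float(np.corrcoef(p, y)[0, 1] ** 2)
    mcfadden = (
        1.0 - fit.loglik / fit.loglik_null if fit.loglik_null != 0 else np.nan
    )
    tjur = float(p[y == 1].mean() - p[y == 0].mean())
    return {"corr_squared": corr2, "mcfadden": float(mcfadden), "tjur": tjur}
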