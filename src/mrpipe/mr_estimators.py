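"""Causal-effect estimators on harmonized instruments.

Given J harmonized instruments with SNP-exposure effects gamma_j (se_gamma_j)
and SNP-outcome effects Gamma_j (se_Gamma_j), each variant's Wald ratio
beta_j = Gamma_j / gamma_j estimates the causal effect of the exposure on the
outcome under the instrumental-variable assumptions.  The estimators here
pool those ratios with different robustness/efficiency trade-offs:

* :func:`ivw` — inverse-variance weighted mean of the ratios (equivalently a
  weighted regression of Gamma on gamma through the origin); efficient when
  all instruments are valid, biased by directional pleiotropy.
* :func:`cochran_q` — heterogeneity of the per-variant ratios around the
  fixed-effect IVW estimate; an omnibus pleiotropy signal.
* :func:`weighted_median` — consistent as long as instruments carrying at
  least half the weight are valid.
* :func:`mr_egger` — weighted regression *with* an intercept; the slope is
  consistent under the InSIDE assumption even with directional pleiotropy,
  and the intercept estimates the average pleiotropic effect.

Binary outcomes are handled on the log-odds scale throughout and
exponentiated only at reporting time (``MREstimate.or_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "RatioEstimate", "MREstimate", "EggerResult",
    "wald_ratio", "ivw", "cochran_q", "weighted_median", "mr_egger",
]


@dataclass
class RatioEstimate:
    """One variant's Wald-ratio causal estimate."""

    variant_id: str
    ratio: float
    se: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


@dataclass
class MREstimate:
    """One method's pooled causal estimate with 95% CI.

    ``beta`` is per exposure unit on the outcome's analysis scale (log-odds
    for binary outcomes).  ``heterogeneity`` carries (Q, df, p) when
    computed.  ``or_scale`` is the exponentiated (OR, low, high) triple,
    populated by :meth:`with_or_scale` for binary outcomes.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    heterogeneity: tuple | None = None
    or_scale: tuple | None = field(default=None)

    def with_or_scale(self) -> "MREstimate":
        self.or_scale = (
            float(np.exp(self.beta)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )
        return self

    def to_dict(self) -> dict:
        d = {
            "method": self.method, "nsnp": self.n_snps, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue,
        }
        if self.or_scale is not None:
            d["OR"], d["OR_ci_low"], d["OR_ci_high"] = self.or_scale
        if self.heterogeneity is not None:
            d["Q"], d["Q_df"], d["Q_p"] = self.heterogeneity
        return d


@dataclass
class EggerResult:
    """MR-Egger slope plus the pleiotropy-intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _columns(instruments: pd.DataFrame):
    g = instruments["gamma"].to_numpy(dtype=float)
    sg = instruments["se_gamma"].to_numpy(dtype=float)
    G = instruments["Gamma"].to_numpy(dtype=float)
    sG = instruments["se_Gamma"].to_numpy(dtype=float)
    if np.any(g == 0):
        raise AnalysisError("instruments with gamma == 0 must be pre-filtered")
    if np.any(sg <= 0) or np.any(sG <= 0):
        raise AnalysisError("standard errors must be positive")
    return g, sg, G, sG


def wald_ratio(inst, delta_order: str = "first_full") -> RatioEstimate:
    """Per-variant causal estimate Gamma/gamma with a delta-method SE.

    ``delta_order`` selects the Taylor expansion used for the SE:

    * ``first_simple`` — se_Gamma/|gamma| (exposure treated as known);
    * ``first_full`` (default) — adds the gamma-uncertainty term,
      sqrt(se_Gamma²/gamma² + Gamma²·se_gamma²/gamma⁴);
    * ``second`` — adds the second-order cross term
      se_Gamma²·se_gamma²/gamma⁴.

    ``inst`` may be a mapping/Series with keys ``variant_id, gamma,
    se_gamma, Gamma, se_Gamma``.
    """
    g, sg = float(inst["gamma"]), float(inst["se_gamma"])
    G, sG = float(inst["Gamma"]), float(inst["se_Gamma"])
    if g == 0:
        raise AnalysisError("Wald ratio undefined for gamma == 0")
    ratio = G / g
    if delta_order == "first_simple":
        var = sG**2 / g**2
    elif delta_order == "first_full":
        var = sG**2 / g**2 + G**2 * sg**2 / g**4
    elif delta_order == "second":
        var = sG**2 / g**2 + G**2 * sg**2 / g**4 + sG**2 * sg**2 / g**4
    else:
        raise ConfigurationError(f"unknown delta_order {delta_order!r}")
    return RatioEstimate(
        variant_id=str(inst.get("variant_id", "")), ratio=ratio,
        se=float(np.sqrt(var)),
    )


def _ratios_and_weights(instruments, delta_order="first_full"):
    g, sg, G, sG = _columns(instruments)
    ratios = G / g
    if delta_order == "first_simple":
        var = sG**2 / g**2
    elif delta_order == "first_full":
        var = sG**2 / g**2 + G**2 * sg**2 / g**4
    else:
        var = sG**2 / g**2 + G**2 * sg**2 / g**4 + sG**2 * sg**2 / g**4
    return ratios, 1.0 / var


def _normal_estimate(method, beta, se, n_snps, heterogeneity=None) -> MREstimate:
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - half), ci_high=float(beta + half),
        pvalue=max(p, np.finfo(float).tiny), n_snps=int(n_snps),
        heterogeneity=heterogeneity,
    )


def ivw(
    instruments: pd.DataFrame,
    re_model: str = "multiplicative",
    delta_order: str = "first_simple",
) -> MREstimate:
    """Inverse-variance weighted pooled causal estimate.

    The point estimate is Σ w_j β_j / Σ w_j with β_j the Wald ratios and
    w_j = 1/se_j² from the simple delta SE — algebraically identical to the
    weighted regression of Gamma on gamma through the origin with weights
    1/se_Gamma².  The SE depends on ``re_model``:

    * ``fixed`` — 1/√Σw;
    * ``multiplicative`` (default) — the fixed SE inflated by
      max(1, √(Q/(J−1))), the conventional "random-effects IVW";
    * ``additive_dl`` — DerSimonian–Laird between-variant variance τ² added
      to each variant's variance before pooling.

    A single instrument degrades to its Wald ratio (method noted).
    """
    if re_model not in ("fixed", "multiplicative", "additive_dl"):
        raise ConfigurationError(f"unknown re_model {re_model!r}")
    if len(instruments) == 0:
        raise AnalysisError("ivw requires at least one instrument")
    if len(instruments) == 1:
        r = wald_ratio(instruments.iloc[0], delta_order="first_full")
        return _normal_estimate("ivw (single-variant wald)", r.ratio, r.se, 1)

    ratios, w = _ratios_and_weights(instruments, delta_order)
    beta = float(np.sum(w * ratios) / np.sum(w))
    J = len(ratios)
    Q = float(np.sum(w * (ratios - beta) ** 2))
    df = J - 1
    het = (Q, df, float(stats.chi2.sf(Q, df)))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))

    if re_model == "fixed":
        se = se_fixed
    elif re_model == "multiplicative":
        se = se_fixed * max(1.0, np.sqrt(Q / df))
    else:  # additive DerSimonian–Laird
        s1 = np.sum(w)
        tau2 = max(0.0, (Q - df) / (s1 - np.sum(w**2) / s1))
        w_star = 1.0 / (1.0 / w + tau2)
        beta = float(np.sum(w_star * ratios) / np.sum(w_star))
        se = float(1.0 / np.sqrt(np.sum(w_star)))
    return _normal_estimate(f"ivw ({re_model})", beta, se, J, heterogeneity=het)


def cochran_q(instruments: pd.DataFrame, delta_order: str = "first_simple"):
    """Cochran's Q heterogeneity test of the per-variant Wald ratios.

    Q = Σ w_j (β_j − β_IVW,fixed)², referred to χ²(J−1).  Returns
    ``(Q, df, p)``.
    """
    if len(instruments) < 2:
        raise AnalysisError("Cochran Q requires at least 2 instruments")
    ratios, w = _ratios_and_weights(instruments, delta_order)
    beta = np.sum(w * ratios) / np.sum(w)
    Q = float(np.sum(w * (ratios - beta) ** 2))
    df = len(ratios) - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def weighted_median(
    instruments: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    delta_order: str = "first_simple",
) -> MREstimate:
    """Weighted-median causal estimate (majority-valid robust estimator).

    Wald ratios are ordered; the estimate is the linear interpolation of the
    ratios at normalized cumulative weight 0.5 (cumulative weights taken at
    interval midpoints).  It is consistent whenever valid instruments carry
    more than half the total weight.  The SE comes from a seeded parametric
    bootstrap: gamma and Gamma resampled from their normal sampling
    distributions ``n_boot`` times.
    """
    J = len(instruments)
    if J < 3:
        raise AnalysisError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; SE will be noisy", stacklevel=2)

    g, sg, G, sG = _columns(instruments)
    point = _weighted_median_point(G / g, _ratios_and_weights(instruments, delta_order)[1])

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sg, size=(n_boot, J))
    G_star = rng.normal(G, sG, size=(n_boot, J))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = g_star[b]
        ok = gb != 0
        rb = G_star[b, ok] / gb[ok]
        if delta_order == "first_simple":
            var = sG[ok] ** 2 / gb[ok] ** 2
        else:
            var = sG[ok] ** 2 / gb[ok] ** 2 + G_star[b, ok] ** 2 * sg[ok] ** 2 / gb[ok] ** 4
        boots[b] = _weighted_median_point(rb, 1.0 / var)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", point, se, J)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    # midpoint cumulative weights: cw_j = sum_{k<=j} w_k - w_j/2
    cw = np.cumsum(w) - 0.5 * w
    if 0.5 <= cw[0]:
        return float(r[0])
    if 0.5 >= cw[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cw, r))


def mr_egger(instruments: pd.DataFrame) -> EggerResult:
    """MR-Egger regression: pleiotropy-robust slope plus intercept test.

    Weighted least squares of Gamma on gamma *with* an intercept, weights
    1/se_Gamma².  Instruments must be oriented exposure-increasing (the fit
    is not invariant to per-variant sign flips).  SEs use multiplicative
    residual dispersion floored at 1 and t(J−2) reference distributions.
    A nonzero intercept indicates unbalanced directional pleiotropy; the
    slope remains consistent for the causal effect under InSIDE.
    """
    J = len(instruments)
    if J < 3:
        raise AnalysisError("MR-Egger requires at least 3 instruments")
    g, sg, G, sG = _columns(instruments)
    if np.allclose(g, g[0]):
        raise AnalysisError("zero variance in gamma: Egger slope unidentifiable")

    import statsmodels.api as sm

    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=1.0 / sG**2).fit()
    # multiplicative overdispersion floored at 1 (never deflate below the
    # fixed-effect SE); built from the residual-free normalized covariance so
    # an exact fit (scale 0) stays well defined
    scale = max(1.0, float(fit.scale))
    bse = np.sqrt(np.diag(fit.normalized_cov_params) * scale)
    df = J - 2

    def t_p(est, se):
        return float(2.0 * stats.t.sf(abs(est / se), df))

    slope, slope_se = float(fit.params[1]), float(bse[1])
    tcrit = stats.t.ppf(0.975, df)
    slope_est = MREstimate(
        method="mr_egger", beta=slope, se=slope_se,
        ci_low=slope - tcrit * slope_se, ci_high=slope + tcrit * slope_se,
        pvalue=t_p(slope, slope_se), n_snps=J,
    )
    return EggerResult(
        slope=slope_est,
        intercept=float(fit.params[0]),
        intercept_se=float(bse[0]),
        intercept_p=t_p(fit.params[0], bse[0]),
    )
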