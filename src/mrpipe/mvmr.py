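"""Multivariable Mendelian randomization (MVMR).

When several genetically proxied exposures share instruments — for example
endophenotype clusters of disease-associated variants, each variant loading
on several mechanisms — the per-exposure direct effects are estimated
jointly by weighted least squares of the SNP-outcome effects on the K
columns of SNP-exposure effects, without an intercept, weighted by
1/se_Gamma².  Cluster exposures are built from a variant→(cluster, weight)
table: a variant's effect on cluster k is its trait effect scaled by its
weight in that cluster (0 where it does not load).  An adjustment trait
(e.g. the variants' effects on a downstream biomarker) can be appended as
one more exposure column, which conditions the cluster effects on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .mr_estimators import MREstimate

__all__ = ["build_cluster_exposures", "mvmr_ivw", "GAMMA_PREFIX"]

GAMMA_PREFIX = "gamma_"


def read_cluster_weights(path, sep="\t") -> pd.DataFrame:
    """Read a 3-column (variant_id, cluster_label, weight) table."""
    df = pd.read_csv(path, sep=sep)
    df.columns = ["variant_id", "cluster_label", "weight"][: df.shape[1]]
    return df


def build_cluster_exposures(
    variants: pd.DataFrame,
    weights: pd.DataFrame,
    adjustment: pd.DataFrame | None = None,
    adjustment_name: str = "adjustment",
) -> pd.DataFrame:
    """Assemble the multivariable design from cluster weights.

    Parameters
    ----------
    variants
        Summary statistics for the variants on the anchor trait
        (``variant_id, beta, se, ...``).
    weights
        Rows of ``(variant_id, cluster_label, weight)``; (variant, cluster)
        pairs must be unique.  Every weighted variant must appear in
        ``variants``.
    adjustment
        Optional second summary-statistics frame; its beta per variant is
        appended as an extra exposure column named
        ``gamma_<adjustment_name>``, so downstream estimates are adjusted
        for that trait.

    Returns
    -------
    DataFrame with one row per variant: ``variant_id`` plus one
    ``gamma_<cluster>`` column per cluster (weight × variant effect; 0 where
    the variant has no weight) and matching ``se_gamma_<cluster>`` columns
    (|weight| × variant se).
    """
    dup = weights.duplicated(subset=["variant_id", "cluster_label"])
    if dup.any():
        raise ConfigurationError(
            f"duplicate (variant, cluster) weight rows: "
            f"{weights.loc[dup, 'variant_id'].tolist()}"
        )
    known = set(variants["variant_id"])
    missing = sorted(set(weights["variant_id"]) - known)
    if missing:
        raise AnalysisError(f"weights reference absent variants: {missing}")

    base = variants.set_index("variant_id")
    wide_w = weights.pivot(
        index="variant_id", columns="cluster_label", values="weight"
    ).fillna(0.0)
    out = pd.DataFrame({"variant_id": wide_w.index})
    for cluster in wide_w.columns:
        wv = wide_w[cluster].to_numpy()
        out[f"{GAMMA_PREFIX}{cluster}"] = wv * base.loc[wide_w.index, "beta"].to_numpy()
        out[f"se_{GAMMA_PREFIX}{cluster}"] = np.abs(wv) * base.loc[
            wide_w.index, "se"
        ].to_numpy()
    if adjustment is not None:
        adj = adjustment.set_index("variant_id")
        missing_adj = sorted(set(wide_w.index) - set(adj.index))
        if missing_adj:
            raise AnalysisError(
                f"adjustment trait missing variants: {missing_adj}"
            )
        out[f"{GAMMA_PREFIX}{adjustment_name}"] = adj.loc[
            wide_w.index, "beta"
        ].to_numpy()
        out[f"se_{GAMMA_PREFIX}{adjustment_name}"] = adj.loc[
            wide_w.index, "se"
        ].to_numpy()
    return out.reset_index(drop=True)


def exposure_names(design: pd.DataFrame) -> list[str]:
    return [
        c[len(GAMMA_PREFIX):]
        for c in design.columns
        if c.startswith(GAMMA_PREFIX) and not c.startswith("se_")
    ]


def mvmr_ivw(instruments: pd.DataFrame) -> dict[str, MREstimate]:
    """Multivariable IVW: joint direct effects of K exposures.

    ``instruments`` carries ``gamma_<name>`` columns (the design), plus
    ``Gamma`` and ``se_Gamma`` for the outcome.  Weighted least squares of
    Gamma on the gamma columns without intercept, weights 1/se_Gamma²;
    SEs use multiplicative residual dispersion floored at 1 and t(J−K)
    reference distributions.

    Returns a mapping exposure name → :class:`MREstimate`.
    """
    from scipy import stats as sps
    import statsmodels.api as sm

    names = exposure_names(instruments)
    K = len(names)
    if K < 1:
        raise ConfigurationError("no gamma_<exposure> columns found")
    J = len(instruments)
    if J <= K:
        raise AnalysisError(f"need more instruments ({J}) than exposures ({K})")

    X = instruments[[f"{GAMMA_PREFIX}{n}" for n in names]].to_numpy(dtype=float)
    y = instruments["Gamma"].to_numpy(dtype=float)
    w = 1.0 / instruments["se_Gamma"].to_numpy(dtype=float) ** 2

    rank = np.linalg.matrix_rank(X)
    if rank < K:
        # name the offending columns by checking each against the others
        collinear = []
        for k in range(K):
            others = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                collinear.append(names[k])
        raise AnalysisError(f"rank-deficient design; collinear exposures: {collinear}")

    fit = sm.WLS(y, X, weights=w).fit()
    scale = max(1.0, float(fit.scale))
    bse = np.sqrt(np.diag(fit.normalized_cov_params) * scale)
    df = J - K
    tcrit = sps.t.ppf(0.975, df)

    out = {}
    for k, name in enumerate(names):
        b, se = float(fit.params[k]), float(bse[k])
        out[name] = MREstimate(
            method="mvmr_ivw", beta=b, se=se,
            ci_low=b - tcrit * se, ci_high=b + tcrit * se,
            pvalue=float(2.0 * sps.t.sf(abs(b / se), df)), n_snps=J,
        )
    return out
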