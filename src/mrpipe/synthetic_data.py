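"""Synthetic GWAS summary statistics with known causal truth.

Every estimator in this package is verifiable offline by parameter
recovery: summary statistics are simulated directly on the two-sample
model

    gamma_hat_j  ~ Normal(gamma_j,  se_gamma_j)
    Gamma_hat_j  ~ Normal(beta_true * gamma_j + alpha_j,  se_Gamma_j)

where gamma_j are latent SNP-exposure effects, alpha_j horizontal-pleiotropy
effects drawn from a configurable model (none / balanced / directional /
InSIDE-violating / sparse outliers), and the standard errors carry the
textbook GWAS scaling 1/sqrt(2 * eaf * (1-eaf) * n).  Exposure and outcome
noise are independent (strict two-sample setting, no sample overlap).
Individual-level genotypes are never simulated; the summary-level model is
sufficient for every estimator here and runs in milliseconds.

Binary outcomes are simulated on the log-odds scale with a case/control
effective sample size, matching how the pipeline treats disease GWAS.

:func:`study_shaped_fixture` bundles scenarios shaped like a published
diabetes→stroke MR study: a binary "T2D-like" exposure with 289 instruments,
a continuous "HbA1c-like" exposure with 333, and stroke-scale case/control
outcomes, with the study's reported odds ratios planted as generative truth
so the full pipeline can be exercised end to end in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .instruments import LDTable

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class Pleiotropy:
    """Horizontal-pleiotropy model for the alpha_j draws.

    kind:
      * ``none`` — alpha_j = 0 (all instruments valid; IVW consistent).
      * ``balanced`` — alpha_j ~ Normal(0, sd); inflates heterogeneity but
        leaves IVW unbiased.
      * ``directional`` — alpha_j ~ Normal(mean, sd), independent of
        gamma_j (InSIDE holds); biases IVW, Egger slope stays consistent
        and the Egger intercept estimates ``mean``.
      * ``inside_violating`` — alpha_j correlated with gamma_j (correlation
        ``rho``); biases Egger too.
      * ``outliers`` — a fraction of instruments receive a fixed pleiotropic
        ``offset`` (in units of their outcome se); the targets of
        PRESSO-style detection and the weighted median.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    rho: float = 0.0
    fraction: float = 0.0
    offset: float = 0.0

    def draw(self, rng, gamma_true, se_Gamma):
        """Draw alpha_j.  Directional parameters (``mean``, ``offset``) are
        defined relative to the exposure-increasing allele of each variant,
        so the drawn alpha is re-signed by sign(gamma_true); estimators that
        orient instruments exposure-increasing then see the intended
        direction regardless of how each variant's effect allele was
        labelled."""
        J = len(gamma_true)
        sign = np.where(gamma_true < 0, -1.0, 1.0)
        if self.kind == "none":
            return np.zeros(J), np.zeros(J, dtype=bool)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, J), np.zeros(J, dtype=bool)
        if self.kind == "directional":
            return sign * rng.normal(self.mean, self.sd, J), np.zeros(J, dtype=bool)
        if self.kind == "inside_violating":
            # pleiotropy correlated with instrument strength |gamma|
            mag = np.abs(gamma_true)
            g_std = (mag - mag.mean()) / (mag.std() or 1.0)
            noise = rng.normal(0.0, 1.0, J)
            alpha = self.sd * (self.rho * g_std + np.sqrt(1 - self.rho**2) * noise)
            return sign * (alpha + self.mean), np.zeros(J, dtype=bool)
        if self.kind == "outliers":
            is_out = rng.random(J) < self.fraction
            alpha = np.where(is_out, sign * self.offset * se_Gamma, 0.0)
            return alpha, is_out
        raise ConfigurationError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass
class SimulationScenario:
    """Generative parameters for one exposure→outcome dataset.

    Defaults describe a well-powered continuous-trait MR: J=100
    instruments, exposure GWAS n=200,000, outcome n=100,000, SNP-exposure
    effect scale tau=0.03 SD per allele, allele frequencies uniform on
    (0.05, 0.95), 20% palindromic variants.  ``min_abs_gamma`` truncates
    the effect-size distribution from below, emulating that published
    instrument lists contain only detected (genome-wide-significant) hits.
    """

    J: int = 100
    beta_true: float = 0.0
    tau: float = 0.03
    min_abs_gamma: float = 0.0
    n_exposure: int = 200_000
    n_outcome: int = 100_000
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    outcome_type: str = "continuous"
    palindromic_fraction: float = 0.2
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    id_prefix: str = "rs"
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing_bp: int = 2_000_000
    seed: int | None = None

    def __post_init__(self):
        if self.J < 1:
            raise ConfigurationError("J must be >= 1")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ConfigurationError("palindromic_fraction must be in [0, 1]")
        if not (0 < self.eaf_low < self.eaf_high < 1):
            raise ConfigurationError(
                f"degenerate eaf bounds ({self.eaf_low}, {self.eaf_high})"
            )


def _pvalues(beta, se):
    from scipy import stats

    return np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny)


def _assign_alleles(rng, J, palindromic_fraction):
    pal = rng.random(J) < palindromic_fraction
    pairs = np.empty((J, 2), dtype=object)
    idx_np = rng.integers(0, len(_NONPALINDROMIC_PAIRS), J)
    idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), J)
    for j in range(J):
        pairs[j] = _PALINDROMIC_PAIRS[idx_p[j]] if pal[j] else _NONPALINDROMIC_PAIRS[idx_np[j]]
    return pairs


def simulate_summary_stats(scenario: SimulationScenario):
    """Simulate one exposure table, one outcome table, and the truth record.

    Both tables share variant ids, positions and allele coding (the
    harmonizer's flip/strand handling is exercised separately via
    :func:`scramble_alleles`).  Identical scenario (including seed) gives
    byte-identical tables.

    Returns ``(exposure, outcome, truth)`` where truth holds the latent
    ``gamma_true``, ``alpha`` (pleiotropy), outlier flags and the scenario.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    J = sc.J

    eaf = rng.uniform(sc.eaf_low, sc.eaf_high, J)
    gamma_true = rng.normal(0.0, sc.tau, J)
    if sc.min_abs_gamma > 0:
        gamma_true = np.sign(gamma_true) * np.maximum(np.abs(gamma_true), sc.min_abs_gamma)

    se_gamma = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * sc.n_exposure)
    se_Gamma = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * sc.n_outcome)

    alpha, is_outlier = sc.pleiotropy.draw(rng, gamma_true, se_Gamma)
    gamma_hat = rng.normal(gamma_true, se_gamma)
    Gamma_true = sc.beta_true * gamma_true + alpha
    Gamma_hat = rng.normal(Gamma_true, se_Gamma)

    ids = np.array([f"{sc.id_prefix}{j + 1}" for j in range(J)])
    pos = sc.start_pos + sc.spacing_bp * np.arange(J)
    alleles = _assign_alleles(rng, J, sc.palindromic_fraction)

    def table(beta, se, n):
        return pd.DataFrame({
            "variant_id": ids,
            "chrom": sc.chrom,
            "pos": pd.array(pos, dtype="Int64"),
            "effect_allele": alleles[:, 0],
            "other_allele": alleles[:, 1],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _pvalues(beta, se),
            "n": float(n),
        })

    exposure = table(gamma_hat, se_gamma, sc.n_exposure)
    exposure.attrs["trait_type"] = "continuous"
    outcome = table(Gamma_hat, se_Gamma, sc.n_outcome)
    outcome.attrs["trait_type"] = (
        "binary" if sc.outcome_type == "binary_logodds" else "continuous"
    )
    truth = {
        "beta_true": sc.beta_true,
        "gamma_true": gamma_true,
        "alpha": alpha,
        "is_outlier": is_outlier,
        "scenario": sc,
    }
    return exposure, outcome, truth


def to_harmonized(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Merge generator output into a harmonized frame directly.

    Valid only for tables that share the generator's allele coding (as
    :func:`simulate_summary_stats` guarantees); real data must go through
    :func:`mrpipe.sumstats.harmonize`.
    """
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"))
    return pd.DataFrame({
        "variant_id": merged["variant_id"],
        "gamma": merged["beta_exp"],
        "se_gamma": merged["se_exp"],
        "Gamma": merged["beta_out"],
        "se_Gamma": merged["se_out"],
        "eaf": merged["eaf_exp"],
        "harmonization_action": "direct",
    })


def scramble_alleles(
    table: pd.DataFrame,
    seed: int | None = None,
    swap_fraction: float = 0.5,
    strand_fraction: float = 0.3,
) -> pd.DataFrame:
    """Randomly swap effect/other alleles and/or strand-flip rows.

    Swapping negates beta and complements eaf, so the scrambled table
    describes the same associations in a different convention — the
    harmonizer must undo it exactly.  Useful for round-trip tests.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rng = np.random.default_rng(seed)
    out = table.copy()
    swap = rng.random(len(out)) < swap_fraction
    strand = rng.random(len(out)) < strand_fraction

    ea = out["effect_allele"].to_numpy(dtype=object).copy()
    oa = out["other_allele"].to_numpy(dtype=object).copy()
    beta = out["beta"].to_numpy(dtype=float).copy()
    eaf = out["eaf"].to_numpy(dtype=float).copy()

    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    beta[swap] *= -1.0
    eaf[swap] = 1.0 - eaf[swap]
    for j in np.flatnonzero(strand):
        ea[j], oa[j] = comp[ea[j]], comp[oa[j]]

    out["effect_allele"], out["other_allele"] = ea, oa
    out["beta"], out["eaf"] = beta, eaf
    return out


def simulate_ld_block(
    n_variants: int,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing_bp: int = 50_000,
    decay_bp: float = 100_000.0,
    seed: int | None = None,
    id_prefix: str = "ld",
):
    """Regular-grid LD block with exponential distance decay.

    r²(i, j) = exp(−distance/decay_bp), values below 1e-4 dropped.  Returns
    ``(position table, LDTable)``; the position table has variant_id, chrom,
    pos columns ready to join onto association frames.
    """
    if n_variants < 1:
        raise ConfigurationError("n_variants must be >= 1")
    ids = [f"{id_prefix}{j + 1}" for j in range(n_variants)]
    pos = start_pos + spacing_bp * np.arange(n_variants)
    positions = pd.DataFrame({"variant_id": ids, "chrom": chrom, "pos": pos})
    tbl = LDTable()
    for i in range(n_variants):
        for j in range(i + 1, n_variants):
            r2 = float(np.exp(-abs(pos[j] - pos[i]) / decay_bp)) if decay_bp > 0 else 0.0
            if r2 >= 1e-4:
                tbl.add(ids[i], ids[j], r2)
    return positions, tbl


# ---------------------------------------------------------------------------
# study-shaped fixture

#: planted generative truths (log odds ratios) mirroring a published
#: diabetes→stroke MR: T2D per 1-log-odds, HbA1c per 1% increment
_STUDY_TRUTH = {
    ("t2d", "any_ischemic_stroke"): float(np.log(1.11)),
    ("t2d", "large_artery_stroke"): float(np.log(1.22)),
    ("t2d", "small_vessel_stroke"): float(np.log(1.18)),
    ("hba1c", "any_ischemic_stroke"): float(np.log(1.36)),
    ("hba1c", "large_artery_stroke"): float(np.log(2.06)),
    ("hba1c", "small_vessel_stroke"): float(np.log(1.85)),
}

#: effective outcome sample sizes at MEGASTROKE-like case/control scales
#: (4 / (1/n_case + 1/n_control))
_STUDY_OUTCOME_NEFF = {
    "any_ischemic_stroke": int(4 / (1 / 60_341 + 1 / 454_450)),
    "large_artery_stroke": int(4 / (1 / 6_688 + 1 / 454_450)),
    "small_vessel_stroke": int(4 / (1 / 11_710 + 1 / 454_450)),
}

#: instrument counts of the study's two hyperglycemia exposures
STUDY_INSTRUMENT_COUNTS = {"t2d": 289, "hba1c": 333}


def study_shaped_fixture(seed: int = 0, beta_true: dict | None = None) -> dict:
    """Bundle of synthetic tables shaped like the diabetes→stroke study.

    Two exposures — a binary "T2D-like" trait with 289 instruments (effects
    on the log-odds scale) and a continuous "HbA1c-like" trait with 333 —
    and three case/control stroke-like outcomes at MEGASTROKE-scale
    effective sample sizes.  The default generative truths are the study's
    reported odds ratios; pass ``beta_true`` (mapping (exposure, outcome) →
    log-OR, missing pairs = 0) to override, e.g. an all-null bundle.

    Instrument effect magnitudes are truncated well above the
    genome-wide-significance noise floor so that instrument counts are
    exact by construction.  Returns a dict with ``exposures`` (name →
    table), ``outcomes`` (name → table, one table carrying all exposures'
    variants), ``truth`` and ``trait_types``.
    """
    truths = dict(_STUDY_TRUTH) if beta_true is None else dict(beta_true)
    root = np.random.SeedSequence(seed)
    exp_seeds = {name: s for name, s in zip(
        ["t2d", "hba1c"], root.spawn(2)
    )}

    exposure_cfg = {
        # T2D-like: log-OR per allele, DIAGRAM-like effective n; effect
        # floor ~11 noise-SDs above zero so all 289 stay genome-wide
        # significant after sampling noise
        "t2d": dict(J=289, tau=0.08, min_abs_gamma=0.05,
                    n_exposure=int(4 / (1 / 74_124 + 1 / 824_006)),
                    eaf_low=0.1, eaf_high=0.9, chrom="1", id_prefix="rsT"),
        # HbA1c-like: % units per allele, UKB-like n
        "hba1c": dict(J=333, tau=0.05, min_abs_gamma=0.04,
                      n_exposure=421_923,
                      eaf_low=0.1, eaf_high=0.9, chrom="2", id_prefix="rsH"),
    }
    exposures, truth, pieces = {}, {}, {}
    for name, cfg in exposure_cfg.items():
        sub = exp_seeds[name].spawn(len(_STUDY_OUTCOME_NEFF) + 1)
        base_seed = int(sub[0].generate_state(1)[0] % (2**31))
        # one latent exposure GWAS; outcome tables below reuse its latent
        # gamma_true through per-outcome scenarios sharing the same seed
        for k, (oname, neff) in enumerate(_STUDY_OUTCOME_NEFF.items()):
            sc = SimulationScenario(
                beta_true=truths.get((name, oname), 0.0),
                n_outcome=neff,
                outcome_type="binary_logodds",
                exposure_name=name,
                outcome_name=oname,
                seed=base_seed,
                **cfg,
            )
            exp_tab, out_tab, tr = simulate_summary_stats(sc)
            if name not in exposures:
                exposures[name] = exp_tab
            pieces.setdefault(oname, []).append(out_tab)
            truth[(name, oname)] = {
                "beta_true": tr["beta_true"],
                "or_true": float(np.exp(tr["beta_true"])),
            }

    outcomes = {
        oname: pd.concat(tabs, ignore_index=True)
        for oname, tabs in pieces.items()
    }
    for tab in outcomes.values():
        tab.attrs["trait_type"] = "binary"
    exposures["t2d"].attrs["trait_type"] = "binary"
    exposures["hba1c"].attrs["trait_type"] = "continuous"
    return {
        "exposures": exposures,
        "outcomes": outcomes,
        "truth": truth,
        "trait_types": {"t2d": "binary", "hba1c": "continuous",
                        **{o: "binary" for o in outcomes}},
    }
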