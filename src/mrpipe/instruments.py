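"""Instrument selection and instrument-strength metrics.

Instruments are genetic variants robustly associated with the exposure
(p below a genome-wide threshold, 5e-8 by default) and approximately
independent of each other.  Independence is enforced by greedy, p-ordered LD
clumping in the PLINK tradition: keep the most significant remaining variant,
discard every variant on the same chromosome within the window whose r^2 with
it exceeds the cutoff, repeat.  Defaults follow common practice for
polygenic exposures: r^2 < 0.01 within a +/-10,000 kb window.

The module also quantifies how much phenotypic variance an instrument set
explains — via summary-statistic formulas for continuous traits and via a
liability-threshold construction (So et al. style) for binary diseases — and
the mean F-statistic used to judge weak-instrument bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AnalysisError, ConfigurationError, NumericalError


class LDTable:
    """Sparse symmetric table of pairwise r² values.

    Absent pairs are treated as r² = 0; the diagonal is implicitly 1.
    Built from an iterable of ``(id_a, id_b, r2)`` triples or read from a
    3-column delimited file with :meth:`from_file`.
    """

    def __init__(self, pairs=()):
        self._r2: dict[frozenset, float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise ConfigurationError(f"r2 {r2} outside [0, 1] for pair ({a}, {b})")
        if a != b:
            self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path, sep=None) -> "LDTable":
        df = pd.read_csv(path, sep=sep if sep is not None else r"\s+|,|\t",
                         engine="python", header=0)
        if df.shape[1] < 3:
            raise ConfigurationError("LD file needs 3 columns: id_a, id_b, r2")
        return cls(df.iloc[:, :3].itertuples(index=False, name=None))

    @classmethod
    def from_matrix(cls, variant_ids, r2_matrix) -> "LDTable":
        r2_matrix = np.asarray(r2_matrix)
        tbl = cls()
        for i, a in enumerate(variant_ids):
            for j, b in enumerate(variant_ids):
                if j > i and r2_matrix[i, j] > 0:
                    tbl.add(a, b, r2_matrix[i, j])
        return tbl


@dataclass
class InstrumentSet:
    """A selected set of approximately independent instruments.

    ``members`` is a canonical summary-statistics frame restricted to the
    retained variants; ``selection_params`` records ``(p_threshold, r2_max,
    window_kb)``; ``total_r2`` is the summed per-variant variance explained
    when it has been computed (``attach_variance_explained``).
    """

    exposure_name: str
    members: pd.DataFrame
    selection_params: tuple = (None, None, None)
    total_r2: float = field(default=float("nan"))

    def __len__(self) -> int:
        return len(self.members)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.members["variant_id"])

    def to_tsv(self, path) -> None:
        self.members.to_csv(path, sep="\t", index=False)


def _tie_break_order(candidates: pd.DataFrame) -> pd.DataFrame:
    # deterministic: ascending p, then chrom, pos, variant_id
    return candidates.sort_values(
        ["pvalue", "chrom", "pos", "variant_id"],
        kind="mergesort",
    ).reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    ld: LDTable | None,
    r2_max: float = 0.01,
    window_kb: float = 10_000,
) -> list[str]:
    """Greedy p-ordered LD clumping; returns retained variant_ids.

    Repeatedly retains the most significant remaining variant (ties broken
    by chrom, pos, variant_id) and discards every remaining variant on the
    same chromosome within ±``window_kb`` whose r² with it exceeds
    ``r2_max``.  An empty or ``None`` LD table means all pairs are
    independent, so only the p-filter upstream matters.
    """
    if not 0 < r2_max < 1:
        raise ConfigurationError(f"r2_max must be in (0, 1), got {r2_max}")
    if window_kb <= 0:
        raise ConfigurationError(f"window_kb must be positive, got {window_kb}")
    if len(candidates) == 0:
        return []
    if ld is not None and len(ld) > 0 and candidates["pos"].isna().any():
        missing = candidates.loc[candidates["pos"].isna(), "variant_id"].tolist()
        raise AnalysisError(f"candidates missing positions with non-empty LD: {missing}")

    ordered = _tie_break_order(candidates)
    window_bp = window_kb * 1000.0
    retained: list[str] = []
    alive = np.ones(len(ordered), dtype=bool)
    ids = ordered["variant_id"].to_numpy()
    chroms = ordered["chrom"].to_numpy()
    pos = ordered["pos"].to_numpy(dtype=float, na_value=np.nan)

    for i in range(len(ordered)):
        if not alive[i]:
            continue
        retained.append(ids[i])
        if ld is None or len(ld) == 0:
            continue
        for j in range(i + 1, len(ordered)):
            if not alive[j] or chroms[j] != chroms[i]:
                continue
            if abs(pos[j] - pos[i]) <= window_bp and ld.r2(ids[i], ids[j]) > r2_max:
                alive[j] = False
    return retained


def select_instruments(
    assocs: pd.DataFrame,
    p_threshold: float = 5e-8,
    ld: LDTable | None = None,
    r2_max: float = 0.01,
    window_kb: float = 10_000,
    exposure_name: str = "exposure",
) -> InstrumentSet:
    """Filter to ``p <= p_threshold``, then clump.

    Deterministic given the tie-break order (p, chrom, pos, variant_id).
    An empty result (no variant reaches the threshold) is returned with a
    warning rather than raised, mirroring how a multi-outcome grid should
    degrade.
    """
    if not 0 < p_threshold < 1:
        raise ConfigurationError(f"p_threshold must be in (0, 1), got {p_threshold}")
    sig = assocs.loc[assocs["pvalue"] <= p_threshold]
    if sig.empty:
        import warnings

        warnings.warn(
            f"no variant reaches p <= {p_threshold:g} for {exposure_name}",
            stacklevel=2,
        )
        members = assocs.iloc[0:0]
    else:
        keep = clump(sig, ld, r2_max=r2_max, window_kb=window_kb)
        members = (
            sig.set_index("variant_id").loc[keep].reset_index()[assocs.columns]
        )
    out = InstrumentSet(
        exposure_name=exposure_name,
        members=members.reset_index(drop=True),
        selection_params=(p_threshold, r2_max, window_kb),
    )
    out.members.attrs.update(assocs.attrs)
    return out


# ---------------------------------------------------------------------------
# variance explained


def variance_explained_continuous(
    beta: float,
    eaf: float | None = None,
    n: float | None = None,
    se: float | None = None,
    mode: str = "z_based",
) -> float:
    """Fraction of a continuous trait's variance explained by one variant.

    ``freq_based`` uses the allele-frequency formula 2·eaf·(1−eaf)·beta²
    (valid when beta is on the standardized, unit-variance trait scale);
    ``z_based`` (default) uses only summary statistics:
    z²/(z² + n − 2) with z = beta/se, the squared sample correlation implied
    by the Wald test.  The result is clipped to [0, 1].
    """
    if mode == "freq_based":
        if eaf is None or not np.isfinite(eaf):
            raise ConfigurationError("freq_based mode requires eaf")
        r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    elif mode == "z_based":
        if se is None or not np.isfinite(se) or se <= 0:
            raise ConfigurationError("z_based mode requires a positive se")
        if n is None or not np.isfinite(n) or n <= 2:
            raise ConfigurationError("z_based mode requires n > 2")
        z2 = (beta / se) ** 2
        r2 = z2 / (z2 + n - 2.0)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return float(np.clip(r2, 0.0, 1.0))


def _liability_penetrances(odds_ratio, raf, prevalence):
    """Genotype penetrances under HWE + multiplicative per-allele odds."""
    q = 1.0 - raf
    geno_freq = np.array([q * q, 2 * q * raf, raf * raf])

    def prev_at(log_odds0):
        odds = np.exp(log_odds0) * odds_ratio ** np.arange(3)
        f = odds / (1.0 + odds)
        return float(geno_freq @ f) - prevalence

    try:
        sol = optimize.brentq(prev_at, -50.0, 50.0, xtol=1e-14)
    except ValueError as exc:  # pragma: no cover - requires extreme inputs
        raise NumericalError(
            f"no penetrance solution for OR={odds_ratio}, raf={raf}, "
            f"prevalence={prevalence}"
        ) from exc
    odds = np.exp(sol) * odds_ratio ** np.arange(3)
    return geno_freq, odds / (1.0 + odds)


def variance_explained_binary_liability(
    odds_ratio: float,
    raf: float,
    prevalence: float,
) -> float:
    """Liability-scale variance explained by one risk variant.

    Under a liability-threshold model the disease occurs when a latent
    standard-normal liability exceeds the threshold T = Φ⁻¹(1 − K) set by
    the prevalence K.  Genotype penetrances f_g consistent with the
    per-allele odds ratio (multiplicative) and overall prevalence are solved
    under Hardy–Weinberg genotype frequencies, each genotype's mean liability
    is recovered as μ_g = T − Φ⁻¹(1 − f_g), and the explained fraction is the
    variance of the genotype means (total liability variance 1).
    """
    if odds_ratio <= 0:
        raise ConfigurationError(f"odds_ratio must be positive, got {odds_ratio}")
    if not 0 < raf < 1:
        raise ConfigurationError(f"raf must be in (0, 1), got {raf}")
    if not 0 < prevalence < 1:
        raise ConfigurationError(f"prevalence must be in (0, 1), got {prevalence}")
    if odds_ratio == 1.0:
        return 0.0
    geno_freq, f = _liability_penetrances(odds_ratio, raf, prevalence)
    if np.any(f <= 0) or np.any(f >= 1):
        raise NumericalError("penetrance outside (0, 1)")
    threshold = stats.norm.isf(prevalence)
    mu = threshold - stats.norm.isf(f)
    mu_bar = geno_freq @ mu
    return float(np.clip(geno_freq @ (mu - mu_bar) ** 2, 0.0, 1.0))


def attach_variance_explained(
    instrument_set: InstrumentSet,
    trait_type: str | None = None,
    prevalence: float = 0.085,
    mode: str = "z_based",
) -> InstrumentSet:
    """Compute per-variant and total variance explained for a set.

    Binary exposures use the liability method (beta interpreted as a
    log-OR; the effect allele is treated as the risk allele, using eaf);
    continuous exposures use :func:`variance_explained_continuous`.
    Adds a ``variance_explained`` column and fills ``total_r2``.
    """
    members = instrument_set.members.copy()
    if trait_type is None:
        trait_type = members.attrs.get("trait_type", "continuous")
    ve = []
    for _, row in members.iterrows():
        if trait_type == "binary":
            orr, raf = np.exp(row["beta"]), row["eaf"]
            if orr < 1:  # express for the risk allele
                orr, raf = 1.0 / orr, 1.0 - raf
            ve.append(variance_explained_binary_liability(orr, raf, prevalence))
        else:
            ve.append(
                variance_explained_continuous(
                    row["beta"], eaf=row.get("eaf"), n=row.get("n"),
                    se=row["se"], mode=mode,
                )
            )
    members["variance_explained"] = ve
    return InstrumentSet(
        exposure_name=instrument_set.exposure_name,
        members=members,
        selection_params=instrument_set.selection_params,
        total_r2=float(np.sum(ve)),
    )


def mean_f_statistic(instruments) -> float:
    """Mean per-variant F ≈ (effect/se)²; the standard strength screen.

    Accepts an :class:`InstrumentSet`, a summary-statistics frame
    (``beta``/``se``) or a harmonized frame (``gamma``/``se_gamma``).
    """
    if isinstance(instruments, InstrumentSet):
        frame = instruments.members
    else:
        frame = instruments
    if len(frame) == 0:
        raise AnalysisError("cannot compute mean F of an empty instrument set")
    if "gamma" in frame.columns:
        z = frame["gamma"] / frame["se_gamma"]
    else:
        z = frame["beta"] / frame["se"]
    return float(np.mean(np.square(z)))
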