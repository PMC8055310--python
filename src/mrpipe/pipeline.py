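"""Study orchestration: exposure×outcome grids, FDR, bidirectional checks.

The full design of a multi-outcome MR study is expressed as an
:class:`AnalysisConfig`: named exposure and outcome summary-statistic
sources, instrument-selection parameters, the methods to run, annotation
based exclusion lists (sensitivity variants), an FDR level and one master
seed.  :func:`run_grid` executes every exposure×outcome×analysis-variant
cell — select, harmonize, orient, estimate, attach heterogeneity and Egger
intercept diagnostics — applies Benjamini–Hochberg FDR across the
primary-method family, and returns a flat :class:`ResultsTable`.  Cells that
fail (too few instruments, no overlap) are flagged, never fatal.

All randomness (weighted-median bootstrap, PRESSO simulations) derives from
the one config seed through per-cell deterministic substreams keyed by
(exposure, outcome, method), so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mr_estimators as est
from . import sumstats
from .errors import AnalysisError, ConfigurationError
from .instruments import InstrumentSet, LDTable, select_instruments
from .presso import presso_test

__all__ = [
    "AnalysisConfig", "ResultsTable", "bh_fdr", "exclude_annotated",
    "run_grid", "bidirectional",
]

RESULT_COLUMNS = [
    "exposure", "outcome", "analysis_variant", "method", "nsnp",
    "beta", "se", "ci_low", "ci_high", "pvalue",
    "OR", "OR_ci_low", "OR_ci_high",
    "Q", "Q_df", "Q_p", "egger_intercept", "egger_intercept_p",
    "raw_p", "q_value", "significance_tier", "error",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    q_(i) = min_{k>=i} p_(k)·m/k after sorting; monotonicity enforced.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def exclude_annotated(
    instrument_set: InstrumentSet,
    annotation: pd.DataFrame,
    p_cut: float = 0.001,
    audit: list | None = None,
) -> InstrumentSet:
    """Drop instruments annotated with a secondary-trait association.

    ``annotation`` has columns (variant_id, trait, p); any instrument with
    an annotation row at p strictly below ``p_cut`` is removed — e.g. the
    sensitivity analysis excluding glycation instruments acting through
    erythrocyte biology.  Removals are appended to ``audit``.
    """
    if not 0 < p_cut < 1:
        raise ConfigurationError(f"p_cut must be in (0, 1), got {p_cut}")
    if len(annotation) == 0:
        return instrument_set
    hits = annotation.loc[annotation["p"] < p_cut, "variant_id"]
    drop = set(hits) & set(instrument_set.variant_ids)
    members = instrument_set.members
    kept_members = members.loc[~members["variant_id"].isin(drop)].reset_index(drop=True)
    if audit is not None:
        for vid in sorted(drop):
            traits = annotation.loc[
                (annotation["variant_id"] == vid) & (annotation["p"] < p_cut),
                "trait",
            ].tolist()
            audit.append({
                "variant_id": vid, "stage": "annotation_exclusion",
                "reason": f"associated with {','.join(map(str, traits))} at p < {p_cut:g}",
            })
    out = InstrumentSet(
        exposure_name=instrument_set.exposure_name,
        members=kept_members,
        selection_params=instrument_set.selection_params,
    )
    out.members.attrs.update(members.attrs)
    return out


@dataclass
class DataSource:
    """A named summary-statistics source: in-memory frame or file path."""

    name: str
    data: pd.DataFrame | str | Path
    trait_type: str = "continuous"
    column_map: dict | None = None
    scale_note: str = ""

    def load(self) -> pd.DataFrame:
        if isinstance(self.data, pd.DataFrame):
            frame = self.data.copy()
            frame.attrs["trait_type"] = self.trait_type
            return frame
        return sumstats.read_summary_stats(
            self.data, column_map=self.column_map, trait_type=self.trait_type
        )


@dataclass
class AnalysisConfig:
    """Everything needed to run (and re-run) the study grid."""

    exposures: dict[str, DataSource]
    outcomes: dict[str, DataSource]
    p_threshold: float = 5e-8
    r2_max: float = 0.01
    window_kb: float = 10_000
    methods: tuple = ("ivw", "weighted_median", "egger", "presso")
    fdr_alpha: float = 0.05
    bidirectional_p_threshold: float = 1e-6
    exclusion_lists: dict[str, pd.DataFrame] = field(default_factory=dict)
    exclusion_p_cut: float = 0.001
    ld: LDTable | None = None
    palindrome_policy: str = "infer_by_frequency"
    maf_ambiguity_threshold: float = 0.42
    n_boot: int = 1000
    n_sim_presso: int = 1000
    re_model: str = "multiplicative"
    min_snps_primary: int = 2
    min_snps_sensitivity: int = 3
    seed: int = 0

    def __post_init__(self):
        for name, thr in (
            ("p_threshold", self.p_threshold),
            ("fdr_alpha", self.fdr_alpha),
            ("bidirectional_p_threshold", self.bidirectional_p_threshold),
        ):
            if not 0 < thr < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {thr}")
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def sources(block):
            out = {}
            for name, spec in block.items():
                p = Path(spec["path"])
                out[name] = DataSource(
                    name=name,
                    data=p if p.is_absolute() else base / p,
                    trait_type=spec.get("trait_type", "continuous"),
                    column_map=spec.get("column_map"),
                    scale_note=spec.get("scale_note", ""),
                )
            return out

        exclusion = {}
        for name, spec in raw.get("exclusion_lists", {}).items():
            p = Path(spec["path"])
            exclusion[name] = pd.read_csv(
                p if p.is_absolute() else base / p, sep="\t"
            )
        sel = raw.get("selection", {})
        ld = None
        if raw.get("ld_table"):
            lp = Path(raw["ld_table"])
            ld = LDTable.from_file(lp if lp.is_absolute() else base / lp)
        return cls(
            exposures=sources(raw["exposures"]),
            outcomes=sources(raw["outcomes"]),
            p_threshold=float(sel.get("p_threshold", 5e-8)),
            r2_max=float(sel.get("r2_max", 0.01)),
            window_kb=float(sel.get("window_kb", 10_000)),
            methods=tuple(raw.get("methods", ("ivw", "weighted_median", "egger", "presso"))),
            fdr_alpha=float(raw.get("fdr_alpha", 0.05)),
            bidirectional_p_threshold=float(raw.get("bidirectional_p_threshold", 1e-6)),
            exclusion_lists=exclusion,
            exclusion_p_cut=float(raw.get("exclusion_p_cut", 0.001)),
            ld=ld,
            seed=int(raw.get("seed", 0)),
        )


def cell_seed(master_seed: int, exposure: str, outcome: str, method: str) -> int:
    """Deterministic per-cell substream seed below 2^31."""
    key = f"{master_seed}|{exposure}|{outcome}|{method}".encode()
    return zlib.crc32(key) % (2**31)


@dataclass
class ResultsTable:
    """Flat exposure×outcome×method grid with FDR annotations."""

    frame: pd.DataFrame
    audit: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "ResultsTable":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                            dtype={c: object for c in (
                                "exposure", "outcome", "analysis_variant",
                                "method", "significance_tier", "error")})
        for col in frame.columns:
            if col not in ("exposure", "outcome", "analysis_variant", "method",
                           "significance_tier", "error"):
                frame[col] = pd.to_numeric(frame[col], errors="coerce")
        return cls(frame=frame)

    def to_json(self, path) -> None:
        payload = self.frame.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    def write_audit(self, path) -> None:
        pd.DataFrame(self.audit, columns=["variant_id", "stage", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def _estimate_row(base: dict, estimate: est.MREstimate | None, **extra) -> dict:
    row = dict.fromkeys(RESULT_COLUMNS, np.nan)
    row.update(base)
    row["error"] = ""
    if estimate is not None:
        row.update({
            "method": estimate.method.split(" ")[0], "nsnp": estimate.n_snps,
            "beta": estimate.beta, "se": estimate.se,
            "ci_low": estimate.ci_low, "ci_high": estimate.ci_high,
            "pvalue": estimate.pvalue,
        })
        if estimate.or_scale is not None:
            row["OR"], row["OR_ci_low"], row["OR_ci_high"] = estimate.or_scale
        if estimate.heterogeneity is not None:
            row["Q"], row["Q_df"], row["Q_p"] = estimate.heterogeneity
    row.update(extra)
    return row


def _run_cell(config, exp_name, out_name, variant_name, instruments, binary_outcome):
    """Run all configured methods on one harmonized, oriented frame."""
    rows = []
    base = {"exposure": exp_name, "outcome": out_name,
            "analysis_variant": variant_name}
    J = len(instruments)

    def finish(e: est.MREstimate):
        return e.with_or_scale() if binary_outcome else e

    if "ivw" in config.methods:
        if J >= config.min_snps_primary:
            ivw_est = finish(est.ivw(instruments, re_model=config.re_model))
            extra = {}
            if J >= 3:
                egger = est.mr_egger(instruments)
                extra = {"egger_intercept": egger.intercept,
                         "egger_intercept_p": egger.intercept_p}
            rows.append(_estimate_row(base | {"method": "ivw"}, ivw_est, **extra))
        else:
            rows.append(_estimate_row(
                base | {"method": "ivw", "nsnp": J}, None,
                error=f"too few instruments ({J} < {config.min_snps_primary})",
            ))
    for method in config.methods:
        if method == "ivw":
            continue
        mbase = base | {"method": method}
        min_j = {"presso": 4}.get(method, config.min_snps_sensitivity)
        if J < min_j:
            rows.append(_estimate_row(
                mbase | {"nsnp": J}, None,
                error=f"too few instruments ({J} < {min_j})",
            ))
            continue
        seed = cell_seed(config.seed, exp_name, out_name, method)
        try:
            if method == "weighted_median":
                e = finish(est.weighted_median(
                    instruments, n_boot=config.n_boot, seed=seed))
                rows.append(_estimate_row(mbase, e))
            elif method == "egger":
                egger = est.mr_egger(instruments)
                e = finish(egger.slope)
                rows.append(_estimate_row(
                    mbase, e,
                    egger_intercept=egger.intercept,
                    egger_intercept_p=egger.intercept_p,
                ))
            elif method == "presso":
                pres = presso_test(
                    instruments, n_sim=config.n_sim_presso, seed=seed)
                if pres.corrected is not None:
                    rows.append(_estimate_row(
                        mbase | {"method": "presso_corrected"}, finish(pres.corrected),
                        Q=pres.global_rss, Q_p=pres.global_p,
                    ))
                else:
                    rows.append(_estimate_row(
                        mbase | {"method": "presso_global", "nsnp": J}, None,
                        Q=pres.global_rss, Q_p=pres.global_p,
                    ))
            else:
                rows.append(_estimate_row(
                    mbase | {"nsnp": J}, None, error=f"unknown method {method!r}"))
        except AnalysisError as exc:
            rows.append(_estimate_row(mbase | {"nsnp": J}, None, error=str(exc)))
    return rows


def _prepare_instruments(config, exp_name, exp_frame, audit):
    """Select + optionally exclusion-filter instruments for one exposure.

    Returns {analysis_variant_name: InstrumentSet}.
    """
    selected = select_instruments(
        exp_frame,
        p_threshold=config.p_threshold,
        ld=config.ld,
        r2_max=config.r2_max,
        window_kb=config.window_kb,
        exposure_name=exp_name,
    )
    dropped = set(exp_frame.loc[
        exp_frame["pvalue"] <= config.p_threshold, "variant_id"
    ]) - set(selected.variant_ids)
    for vid in sorted(dropped):
        audit.append({"variant_id": vid, "stage": "clumping",
                      "reason": f"in LD (r2 > {config.r2_max:g}) with a more significant variant"})
    variants = {"primary": selected}
    for list_name, annotation in config.exclusion_lists.items():
        variants[f"excluding_{list_name}"] = exclude_annotated(
            selected, annotation, p_cut=config.exclusion_p_cut, audit=audit
        )
    return variants


def run_grid(config: AnalysisConfig) -> ResultsTable:
    """Execute the full exposure×outcome grid and apply FDR.

    FDR (Benjamini–Hochberg) is applied across the primary-method (IVW)
    p-values of the primary analysis variant — one family per grid, the
    study's figure/table equivalent.  Tiers: ``fdr_significant`` (q <
    fdr_alpha), ``nominal`` (raw p < 0.05 but q >= fdr_alpha), else
    ``null``.  Per-cell failures are recorded in the ``error`` column and
    never abort the grid.
    """
    audit: list = []
    all_rows: list[dict] = []

    exposure_frames = {n: src.load() for n, src in config.exposures.items()}
    outcome_frames = {n: src.load() for n, src in config.outcomes.items()}

    for exp_name, exp_frame in exposure_frames.items():
        try:
            variants = _prepare_instruments(config, exp_name, exp_frame, audit)
        except (AnalysisError, ConfigurationError) as exc:
            for out_name in outcome_frames:
                all_rows.append(_estimate_row(
                    {"exposure": exp_name, "outcome": out_name,
                     "analysis_variant": "primary", "method": "ivw"},
                    None, error=str(exc)))
            continue
        for variant_name, inst_set in variants.items():
            for out_name, out_frame in outcome_frames.items():
                base = {"exposure": exp_name, "outcome": out_name,
                        "analysis_variant": variant_name}
                try:
                    if len(inst_set) == 0:
                        raise AnalysisError("no instruments selected")
                    harmonized = sumstats.harmonize(
                        inst_set.members, out_frame,
                        palindrome_policy=config.palindrome_policy,
                        maf_ambiguity_threshold=config.maf_ambiguity_threshold,
                    )
                    if variant_name == "primary":
                        for _, r in harmonized.iterrows():
                            if r["harmonization_action"] not in sumstats.KEPT_ACTIONS:
                                audit.append({
                                    "variant_id": r["variant_id"],
                                    "stage": f"harmonization:{exp_name}→{out_name}",
                                    "reason": r["harmonization_action"],
                                })
                    usable = sumstats.orient_exposure_increasing(
                        sumstats.kept(harmonized))
                    binary = out_frame.attrs.get("trait_type") == "binary"
                    all_rows.extend(_run_cell(
                        config, exp_name, out_name, variant_name, usable, binary))
                except (AnalysisError, ConfigurationError) as exc:
                    all_rows.append(_estimate_row(
                        base | {"method": "ivw"}, None, error=str(exc)))

    frame = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)

    # FDR family: primary-variant IVW tests
    fam = (frame["method"] == "ivw") & (frame["analysis_variant"] == "primary") \
        & frame["pvalue"].notna()
    frame["raw_p"] = np.where(frame["pvalue"].notna(), frame["pvalue"], np.nan)
    if fam.any():
        frame.loc[fam, "q_value"] = bh_fdr(frame.loc[fam, "pvalue"])
    tier = np.where(
        fam & (frame["q_value"] < config.fdr_alpha), "fdr_significant",
        np.where(fam & (frame["raw_p"] < 0.05), "nominal",
                 np.where(fam, "null", "")),
    )
    frame["significance_tier"] = tier
    frame["error"] = frame["error"].fillna("")
    return ResultsTable(frame=frame, audit=audit)


def bidirectional(
    forward_exposure: DataSource,
    forward_outcome: DataSource,
    config: AnalysisConfig | None = None,
    p_threshold: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Forward MR plus the reverse analysis at a relaxed threshold.

    The forward direction runs at the config's genome-wide threshold; the
    reverse direction selects instruments from the former *outcome* at the
    relaxed ``bidirectional_p_threshold`` (default 1e-6 — outcome GWAS
    typically offer few genome-wide hits) and estimates outcome→exposure.
    Returns ``{"forward": frame, "reverse": frame}``; an inestimable
    reverse direction yields a flagged empty-result frame, not an error.
    """
    if config is None:
        config = AnalysisConfig(
            exposures={forward_exposure.name: forward_exposure},
            outcomes={forward_outcome.name: forward_outcome},
        )
    relaxed = p_threshold if p_threshold is not None \
        else config.bidirectional_p_threshold

    fwd_cfg = AnalysisConfig(
        exposures={forward_exposure.name: forward_exposure},
        outcomes={forward_outcome.name: forward_outcome},
        p_threshold=config.p_threshold, r2_max=config.r2_max,
        window_kb=config.window_kb, methods=config.methods,
        fdr_alpha=config.fdr_alpha, ld=config.ld,
        palindrome_policy=config.palindrome_policy,
        maf_ambiguity_threshold=config.maf_ambiguity_threshold,
        n_boot=config.n_boot, n_sim_presso=config.n_sim_presso,
        re_model=config.re_model, seed=config.seed,
    )
    forward = run_grid(fwd_cfg).frame

    rev_cfg = AnalysisConfig(
        exposures={forward_outcome.name: forward_outcome},
        outcomes={forward_exposure.name: forward_exposure},
        p_threshold=relaxed, r2_max=config.r2_max,
        window_kb=config.window_kb, methods=config.methods,
        fdr_alpha=config.fdr_alpha, ld=config.ld,
        palindrome_policy=config.palindrome_policy,
        maf_ambiguity_threshold=config.maf_ambiguity_threshold,
        n_boot=config.n_boot, n_sim_presso=config.n_sim_presso,
        re_model=config.re_model, seed=config.seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reverse = run_grid(rev_cfg).frame
    return {"forward": forward, "reverse": reverse}
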