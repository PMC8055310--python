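"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines per-variant association
estimates from an exposure GWAS (``gamma``, the SNP-exposure effect) with
estimates from an outcome GWAS (``Gamma``, the SNP-outcome effect).  The two
studies almost never report effects for the same allele of every variant, and
may use opposite strand conventions, so before any estimator can run the
effects must be *harmonized*: re-expressed per copy of one common effect
allele.

Summary statistics live in :class:`pandas.DataFrame` objects with the
canonical columns

``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue, n``

(``eaf`` = effect-allele frequency; ``beta`` is a log-odds ratio for binary
traits and a slope in trait or SD units for continuous traits).  Harmonized
instruments carry ``gamma, se_gamma, Gamma, se_Gamma`` plus a
``harmonization_action`` column recording what happened to each shared
variant — every input variant is accounted for by exactly one action.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics frame
SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: default header names in input files, keyed by canonical name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP", "chrom": "CHR", "pos": "POS",
    "effect_allele": "EA", "other_allele": "OA", "eaf": "EAF",
    "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization actions that keep a variant in the analysis
KEPT_ACTIONS = frozenset({"direct", "flipped", "frequency_inferred"})

HARMONIZED_COLUMNS = [
    "variant_id", "gamma", "se_gamma", "Gamma", "se_Gamma",
    "eaf", "harmonization_action",
]


def _complement_pair(a1: str, a2: str) -> tuple[str, str]:
    return _COMPLEMENT[a1], _COMPLEMENT[a2]


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G variants read the same on both strands."""
    return _COMPLEMENT.get(a1) == a2


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical frame.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Mapping from canonical names (:data:`SUMSTAT_COLUMNS`) to the file's
        header names; unspecified entries fall back to
        :data:`DEFAULT_COLUMN_MAP`.  ``eaf`` and ``n`` may be absent from the
        file; all other mapped columns must exist.
    trait_type
        ``"binary"`` (beta is a log-OR) or ``"continuous"``; recorded in
        ``frame.attrs["trait_type"]``.
    sep
        Field delimiter; sniffed from the header line (tab, else comma) when
        ``None``.

    Raises
    ------
    ConfigurationError
        A required mapped column is missing from the header.
    ValidationError
        One or more rows violate the invariants (non-positive SE, p outside
        (0, 1], eaf outside [0, 1], identical alleles, unparseable numbers);
        the offending 1-based data-row numbers are listed.
    """
    if trait_type not in ("binary", "continuous"):
        raise ConfigurationError(f"unknown trait_type {trait_type!r}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)

    optional = {"eaf", "n"}
    missing = [
        cmap[k] for k in SUMSTAT_COLUMNS
        if cmap[k] not in raw.columns and k not in optional
    ]
    if missing:
        raise ConfigurationError(
            f"mapped column(s) {missing} not found in {path.name}; "
            f"header has {list(raw.columns)}"
        )

    out = pd.DataFrame(index=raw.index)
    for canon in SUMSTAT_COLUMNS:
        src = cmap[canon]
        out[canon] = raw[src] if src in raw.columns else np.nan

    bad: dict[int, str] = {}

    def _numeric(col):
        converted = pd.to_numeric(out[col], errors="coerce")
        was_given = out[col].notna()
        for idx in out.index[was_given & converted.isna()]:
            bad.setdefault(idx, f"unparseable {col} {out.loc[idx, col]!r}")
        return converted

    out["pos"] = _numeric("pos")
    out["eaf"] = _numeric("eaf")
    out["beta"] = _numeric("beta")
    out["se"] = _numeric("se")
    out["pvalue"] = _numeric("pvalue")
    out["n"] = _numeric("n")
    out["chrom"] = out["chrom"].astype(str).str.strip()
    out["effect_allele"] = out["effect_allele"].astype(str).str.strip().str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.strip().str.upper()

    valid_alleles = set(_COMPLEMENT)
    for idx, row in out.iterrows():
        if idx in bad:
            continue
        if row["effect_allele"] not in valid_alleles or row["other_allele"] not in valid_alleles:
            bad[idx] = f"invalid alleles {row['effect_allele']}/{row['other_allele']}"
        elif row["effect_allele"] == row["other_allele"]:
            bad[idx] = "effect and other allele identical"
        elif not np.isfinite(row["se"]) or row["se"] <= 0:
            bad[idx] = f"se must be positive, got {row['se']}"
        elif not np.isfinite(row["beta"]):
            bad[idx] = "missing beta"
        elif not (0 < row["pvalue"] <= 1):
            bad[idx] = f"pvalue {row['pvalue']} outside (0, 1]"
        elif np.isfinite(row["eaf"]) and not (0 <= row["eaf"] <= 1):
            bad[idx] = f"eaf {row['eaf']} outside [0, 1]"

    if bad:
        lines = "; ".join(f"row {i + 1}: {msg}" for i, msg in sorted(bad.items()))
        raise ValidationError(
            f"{len(bad)} invalid row(s) in {path.name}: {lines}",
            rows=sorted(i + 1 for i in bad),
        )

    out["pos"] = out["pos"].astype("Int64")
    out["n"] = out["n"].astype("Float64")
    out.attrs["trait_type"] = trait_type
    return out.reset_index(drop=True)


def write_summary_stats(frame: pd.DataFrame, path, column_map=None) -> None:
    """Write a canonical frame back to TSV, optionally renaming headers."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame.rename(columns=cmap).to_csv(path, sep="\t", index=False)


def _align_literal(row) -> tuple[float, float, str] | None:
    """Match outcome alleles to exposure alleles by letter, trying the
    reverse-strand complement before giving up.

    Returns (Gamma, outcome eaf expressed for the exposure effect allele,
    'direct'|'flipped'), or None for incompatible pairs.
    """
    ea, oa = row["effect_allele_exp"], row["other_allele_exp"]
    ea_o, oa_o = row["effect_allele_out"], row["other_allele_out"]
    beta_o, eaf_o = row["beta_out"], row["eaf_out"]
    for a1, a2 in ((ea_o, oa_o), _complement_pair(ea_o, oa_o)):
        if (a1, a2) == (ea, oa):
            return beta_o, eaf_o, "direct"
        if (a1, a2) == (oa, ea):
            eaf_flip = 1.0 - eaf_o if np.isfinite(eaf_o) else np.nan
            return -beta_o, eaf_flip, "flipped"
    return None


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "infer_by_frequency",
    maf_ambiguity_threshold: float = 0.42,
) -> pd.DataFrame:
    """Align exposure and outcome effects to the exposure's effect alleles.

    For each variant present in both frames:

    * identical allele pair, same orientation → ``direct``;
    * swapped alleles → outcome beta negated, eaf complemented (``flipped``);
    * strand-complement pair → complemented first, then matched as above;
    * palindromic (A/T, C/G) variants, whose strand cannot be resolved from
      allele letters, are handled per ``palindrome_policy``:

      - ``drop_all``: always ``dropped_palindromic``;
      - ``keep_as_is``: aligned by allele letters alone (assumes both studies
        report the same strand);
      - ``infer_by_frequency`` (default): after letter alignment the variant
        is kept (``frequency_inferred``) only when both effect-allele
        frequencies fall on the same side of 0.5 and both minor-allele
        frequencies are below ``maf_ambiguity_threshold``; otherwise
        ``dropped_palindromic``.  Missing frequencies also drop the variant,
        with a warning.

    * any other allele pair → ``dropped_mismatch``.

    Returns a frame with :data:`HARMONIZED_COLUMNS`; dropped variants are
    retained as rows (with their action) so the accounting
    ``|direct| + |flipped| + |frequency_inferred| + |dropped| = |shared|``
    always holds.  Use :func:`kept` to filter to estimable instruments.
    """
    if palindrome_policy not in ("drop_all", "infer_by_frequency", "keep_as_is"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")

    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise AnalysisError("exposure and outcome share no variant_id")

    records = []
    n_missing_eaf = 0
    for _, row in merged.iterrows():
        gamma, se_gamma = row["beta_exp"], row["se_exp"]
        se_Gamma = row["se_out"]
        eaf_exp = row["eaf_exp"]
        palindromic = is_palindromic(
            row["effect_allele_exp"], row["other_allele_exp"]
        ) or is_palindromic(row["effect_allele_out"], row["other_allele_out"])

        aligned = _align_literal(row)
        action = "dropped_mismatch"
        Gamma = np.nan

        if aligned is None:
            action = "dropped_mismatch"
        elif not palindromic:
            Gamma, _, action = aligned
        elif palindrome_policy == "drop_all":
            action = "dropped_palindromic"
        elif palindrome_policy == "keep_as_is":
            Gamma, _, action = aligned
        else:  # infer_by_frequency
            Gamma_cand, eaf_out_aligned, _ = aligned
            if not (np.isfinite(eaf_exp) and np.isfinite(eaf_out_aligned)):
                n_missing_eaf += 1
                action = "dropped_palindromic"
            else:
                same_side = (eaf_exp - 0.5) * (eaf_out_aligned - 0.5) > 0
                maf_ok = (
                    min(eaf_exp, 1 - eaf_exp) < maf_ambiguity_threshold
                    and min(eaf_out_aligned, 1 - eaf_out_aligned) < maf_ambiguity_threshold
                )
                if same_side and maf_ok:
                    Gamma = Gamma_cand
                    action = "frequency_inferred"
                else:
                    action = "dropped_palindromic"

        records.append({
            "variant_id": row["variant_id"],
            "gamma": gamma, "se_gamma": se_gamma,
            "Gamma": Gamma, "se_Gamma": se_Gamma,
            "eaf": eaf_exp,
            "harmonization_action": action,
        })

    if n_missing_eaf:
        warnings.warn(
            f"{n_missing_eaf} palindromic variant(s) lacked eaf for frequency "
            "inference and were dropped",
            stacklevel=2,
        )
    out = pd.DataFrame.from_records(records, columns=HARMONIZED_COLUMNS)
    logger.info(
        "harmonized %d shared variants: %s", len(out),
        out["harmonization_action"].value_counts().to_dict(),
    )
    return out


def kept(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Subset of harmonized variants usable for estimation."""
    mask = harmonized["harmonization_action"].isin(KEPT_ACTIONS)
    return harmonized.loc[mask].reset_index(drop=True)


def orient_exposure_increasing(instruments: pd.DataFrame) -> pd.DataFrame:
    """Re-sign instruments so every exposure effect is positive.

    The Wald ratio Gamma/gamma is invariant to jointly negating both effects,
    but MR-Egger and the weighted median are not invariant to the sign
    convention, so the conventional orientation (each effect allele increases
    the exposure) is applied before running them.  Variants with gamma
    exactly 0 cannot be oriented (nor used in a ratio) and are excluded with
    a warning.
    """
    inst = instruments.copy()
    zero = inst["gamma"] == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} variant(s) with exposure effect "
            "exactly 0; they cannot be oriented",
            stacklevel=2,
        )
        inst = inst.loc[~zero]
    neg = inst["gamma"] < 0
    inst.loc[neg, ["gamma", "Gamma"]] *= -1.0
    if "eaf" in inst.columns:
        inst.loc[neg, "eaf"] = 1.0 - inst.loc[neg, "eaf"]
    return inst.reset_index(drop=True)


def write_harmonized(harmonized: pd.DataFrame, path) -> None:
    """Write the harmonized instrument table (all actions included) as TSV."""
    harmonized.to_csv(path, sep="\t", index=False)
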