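"""Reading, QC filtering, allele harmonization and sign flipping of GWAS
summary statistics.

Every downstream step consumes the canonical column layout

    rsid chrom pos effect_allele other_allele eaf info beta se p

with ``beta`` a log odds ratio reported for ``effect_allele``, ``se`` its
standard error, ``eaf`` the effect-allele frequency and ``info`` the
imputation quality. ``eaf`` and ``info`` may be absent (some source GWAS do
not report them); records then pass the corresponding QC filter untouched.

The screen's sign convention: autoimmune-disease betas are multiplied by -1
(:func:`flip_sign`) so that variants with *opposite* effects on cancer and
autoimmune disease become concordant and can reach combined significance
under a fixed-effect meta-analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alleles import VALID_ALLELES, is_palindromic, match_alleles
from .exceptions import FormatError, PipelineError, StateError

CANONICAL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "info", "beta", "se", "p",
]

#: columns that must be present (``se`` may be replaced by ``p``)
MANDATORY = ["rsid", "effect_allele", "other_allele", "beta"]

_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


@dataclass
class ReadReport:
    """Per-file accounting of rows dropped during parsing/validation."""

    n_input: int = 0
    n_retained: int = 0
    rejected: dict = field(default_factory=dict)
    n_duplicates_removed: int = 0

    def reject(self, reason: str, n: int) -> None:
        if n:
            self.rejected[reason] = self.rejected.get(reason, 0) + int(n)


def _normalize_chrom(series: pd.Series) -> pd.Series:
    return series.astype(str).str.replace(_CHR_PREFIX, "", regex=True)


def _parse_float(series: pd.Series) -> np.ndarray:
    """String column -> float64 with correctly rounded parsing (numpy's
    strtod round-trips 17-digit output exactly; pandas' fast parser does
    not). Unparseable entries become NaN."""
    mask = pd.to_numeric(series, errors="coerce").notna().to_numpy()
    out = np.full(len(series), np.nan)
    if mask.any():
        out[mask] = series.to_numpy()[mask].astype(np.float64)
    return out


def read_sumstats(path, column_map: dict | None = None) -> tuple[pd.DataFrame, ReadReport]:
    """Read a summary-statistic table into the canonical layout.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited text file with a header row; gzip is
        handled transparently by pandas.
    column_map
        Optional mapping ``canonical name -> file column name`` for files
        whose headers differ from the canonical ones.

    Returns
    -------
    (DataFrame, ReadReport)
        Validated records plus counts of rejected rows by reason.
        Duplicate rsids are resolved by keeping the record with the
        smallest p-value. A missing ``p`` column is recomputed as
        ``2*Phi(-|beta/se|)``; a missing ``se`` is derived from ``p``.

    Raises
    ------
    FormatError
        Missing mandatory column, or no valid records.
    """
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if raw.empty:
        raise FormatError(f"{path}: no data rows")

    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)

    missing = [c for c in MANDATORY if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {missing}")
    if "se" not in raw.columns and "p" not in raw.columns:
        raise FormatError(f"{path}: needs at least one of 'se' or 'p'")

    report = ReadReport(n_input=len(raw))
    df = pd.DataFrame(index=raw.index)
    df["rsid"] = raw["rsid"].astype(str)
    df["chrom"] = _normalize_chrom(raw["chrom"]) if "chrom" in raw.columns else pd.NA
    df["pos"] = pd.to_numeric(raw["pos"], errors="coerce") if "pos" in raw.columns else np.nan
    df["effect_allele"] = raw["effect_allele"].astype(str).str.upper()
    df["other_allele"] = raw["other_allele"].astype(str).str.upper()
    for col in ("eaf", "info", "beta", "se", "p"):
        df[col] = _parse_float(raw[col]) if col in raw.columns else np.nan

    # row-level validation, counted by reason
    bad_allele = (~df["effect_allele"].isin(VALID_ALLELES)
                  | ~df["other_allele"].isin(VALID_ALLELES)
                  | (df["effect_allele"] == df["other_allele"]))
    report.reject("invalid_alleles", bad_allele.sum())
    df = df[~bad_allele]

    bad_beta = df["beta"].isna()
    report.reject("missing_beta", bad_beta.sum())
    df = df[~bad_beta]

    bad_se = df["se"].notna() & (df["se"] <= 0)
    report.reject("nonpositive_se", bad_se.sum())
    df = df[~bad_se]

    bad_p = df["p"].notna() & ((df["p"] <= 0) | (df["p"] > 1))
    report.reject("p_out_of_range", bad_p.sum())
    df = df[~bad_p]

    bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    report.reject("eaf_out_of_range", bad_eaf.sum())
    df = df[~bad_eaf]

    no_scale = df["se"].isna() & df["p"].isna()
    report.reject("missing_se_and_p", no_scale.sum())
    df = df[~no_scale]

    # fill whichever of se / p is absent from the other
    need_se = df["se"].isna()
    if need_se.any():
        z = stats.norm.isf(df.loc[need_se, "p"] / 2)
        with np.errstate(divide="ignore"):
            derived = np.abs(df.loc[need_se, "beta"]) / z
        ok = np.isfinite(derived) & (derived > 0)
        report.reject("se_underivable", (~ok).sum())
        df.loc[need_se, "se"] = np.where(ok, derived, np.nan)
        df = df[df["se"].notna()]
    need_p = df["p"].isna()
    if need_p.any():
        df.loc[need_p, "p"] = 2 * stats.norm.sf(
            np.abs(df.loc[need_p, "beta"] / df.loc[need_p, "se"]))

    if df.empty:
        raise FormatError(f"{path}: no valid records after validation")

    # duplicate rsids: keep smallest p
    before = len(df)
    df = df.sort_values(["p", "rsid"], kind="mergesort").drop_duplicates("rsid", keep="first")
    report.n_duplicates_removed = before - len(df)
    df = df.sort_values(["chrom", "pos", "rsid"], kind="mergesort").reset_index(drop=True)

    df = df[CANONICAL_COLUMNS]
    df.attrs["sign_flipped"] = False
    report.n_retained = len(df)
    return df, report


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write canonical summary statistics as tab-delimited text.

    Floats are written at 17 significant digits, so read→write→read
    preserves values exactly.
    """
    df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False,
                                 float_format="%.17g")


def apply_qc_filters(df: pd.DataFrame, maf_min: float = 0.005,
                     info_min: float = 0.3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude SNPs with minor allele frequency below ``maf_min`` or
    imputation quality below ``info_min``.

    Boundary values pass (the exclusions are strict ``<`` on MAF and info).
    Records lacking ``eaf`` or ``info`` pass the corresponding filter, as
    some source GWAS do not report these metrics.

    Returns the filtered table and a QC report with one row per filter
    (columns ``filter``, ``n_removed``).
    """
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    fail_maf = maf.notna() & (maf < maf_min)
    fail_info = df["info"].notna() & (df["info"] < info_min)
    out = df[~(fail_maf | fail_info)].reset_index(drop=True)
    out.attrs = dict(df.attrs)
    report = pd.DataFrame({
        "filter": [f"maf<{maf_min}", f"info<{info_min}"],
        "n_removed": [int(fail_maf.sum()), int(fail_info.sum())],
    })
    return out, report


def flip_sign(df: pd.DataFrame, trait_role: str) -> pd.DataFrame:
    """Apply the autoimmune sign reversal.

    For ``trait_role="autoimmune"`` every beta is multiplied by -1 while the
    effect allele, se and p are left untouched; for ``trait_role="cancer"``
    the table is returned unchanged. The flip is recorded in
    ``df.attrs["sign_flipped"]`` and may be applied at most once.
    """
    if trait_role not in ("autoimmune", "cancer"):
        raise ValueError(f"unknown trait_role: {trait_role!r}")
    out = df.copy()
    out.attrs = dict(df.attrs)
    if trait_role == "cancer":
        return out
    if out.attrs.get("sign_flipped"):
        raise StateError("sign flip already applied to this table")
    out["beta"] = -out["beta"]
    out.attrs["sign_flipped"] = True
    return out


@dataclass
class HarmonizedPair:
    """Per-SNP join of two trait tables on a shared effect-allele frame.

    ``df`` carries one row per retained SNP with ``_a``/``_b`` suffixed
    statistics, both expressed for the *same* effect allele, plus boolean
    ``strand_flipped`` / ``allele_swapped`` flags describing how trait B's
    record was brought onto trait A's allele frame. ``drops`` counts SNPs
    removed during harmonization by reason. ``b_flipped`` records whether
    trait B's betas carry the autoimmune sign reversal.
    """

    df: pd.DataFrame
    drops: dict
    b_flipped: bool = False
    trait_a: str = "trait_a"
    trait_b: str = "trait_b"


def harmonize_pair(df_a: pd.DataFrame, df_b: pd.DataFrame,
                   ambiguous_eaf_window: tuple[float, float] = (0.4, 0.6),
                   trait_a: str = "trait_a", trait_b: str = "trait_b",
                   ) -> HarmonizedPair:
    """Join two QC'd tables on rsid+position and reconcile allele frames.

    If trait B reports the swapped effect/other alleles its beta is negated
    and eaf complemented; if B's alleles are the reverse complement of A's
    the labels are strand-corrected first. Palindromic SNPs (A/T, C/G) are
    dropped when either side's eaf lies inside ``ambiguous_eaf_window`` or
    is missing; otherwise eaf concordance resolves the strand. Incompatible
    allele sets are dropped. Every drop is counted by reason.
    """
    lo, hi = ambiguous_eaf_window
    merged = df_a.merge(df_b, on="rsid", suffixes=("_a", "_b"), how="inner")
    drops: dict[str, int] = {}
    if merged.empty:
        raise PipelineError("zero overlapping SNPs between the two tables")

    pos_mismatch = (merged["pos_a"].notna() & merged["pos_b"].notna()
                    & (merged["pos_a"] != merged["pos_b"]))
    if pos_mismatch.any():
        drops["position_mismatch"] = int(pos_mismatch.sum())
        merged = merged[~pos_mismatch]

    keep, swapped, flipped, drop_reason = [], [], [], []
    for ea_a, oa_a, ea_b, oa_b, eaf_a, eaf_b in zip(
            merged["effect_allele_a"], merged["other_allele_a"],
            merged["effect_allele_b"], merged["other_allele_b"],
            merged["eaf_a"], merged["eaf_b"]):
        if is_palindromic(ea_a, oa_a):
            in_window = (pd.isna(eaf_a) or lo < eaf_a < hi
                         or pd.isna(eaf_b) or lo < eaf_b < hi)
            if in_window or not is_palindromic(ea_b, oa_b):
                keep.append(False); swapped.append(False); flipped.append(False)
                drop_reason.append("palindromic_ambiguous")
                continue
            if {ea_b, oa_b} != {ea_a, oa_a}:
                keep.append(False); swapped.append(False); flipped.append(False)
                drop_reason.append("incompatible_alleles")
                continue
            # frequency concordance decides orientation
            swap = (eaf_a - 0.5) * ((eaf_b if ea_b == ea_a else 1 - eaf_b) - 0.5) < 0
            keep.append(True)
            swapped.append(bool(swap) != (ea_b != ea_a))
            flipped.append(False)
            drop_reason.append("")
            continue
        rel = match_alleles(ea_a, oa_a, ea_b, oa_b)
        if rel is None:
            keep.append(False); swapped.append(False); flipped.append(False)
            drop_reason.append("incompatible_alleles")
            continue
        keep.append(True)
        swapped.append(rel in ("swap", "flip_swap"))
        flipped.append(rel in ("flip", "flip_swap"))
        drop_reason.append("")

    merged = merged.assign(_keep=keep, allele_swapped=swapped,
                           strand_flipped=flipped, _reason=drop_reason)
    for reason, n in merged.loc[~merged["_keep"], "_reason"].value_counts().items():
        drops[reason] = drops.get(reason, 0) + int(n)
    merged = merged[merged["_keep"]].copy()
    if merged.empty:
        raise PipelineError("no SNPs retained after allele harmonization")

    swap = merged["allele_swapped"]
    merged.loc[swap, "beta_b"] = -merged.loc[swap, "beta_b"]
    merged.loc[swap, "eaf_b"] = 1 - merged.loc[swap, "eaf_b"]

    out = pd.DataFrame({
        "rsid": merged["rsid"],
        "chrom": merged["chrom_a"],
        "pos": merged["pos_a"],
        "effect_allele": merged["effect_allele_a"],
        "other_allele": merged["other_allele_a"],
        "eaf_a": merged["eaf_a"], "info_a": merged["info_a"],
        "beta_a": merged["beta_a"], "se_a": merged["se_a"], "p_a": merged["p_a"],
        "eaf_b": merged["eaf_b"], "info_b": merged["info_b"],
        "beta_b": merged["beta_b"], "se_b": merged["se_b"], "p_b": merged["p_b"],
        "strand_flipped": merged["strand_flipped"],
        "allele_swapped": merged["allele_swapped"],
    }).reset_index(drop=True)

    return HarmonizedPair(
        df=out, drops=drops,
        b_flipped=bool(df_b.attrs.get("sign_flipped", False)),
        trait_a=trait_a, trait_b=trait_b,
    )
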