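"""Tumor-expression-based target prioritization.

Candidate genes are correlated (Spearman) with four immune-infiltration
marker transcripts — CD4, CD8A, CD11B (HGNC symbol ITGAM) and CD45
(PTPRC) — in each tumor cohort's Z-scored bulk expression matrix. A gene
is *prioritized* when in **every** cohort its correlation with at least
one marker exceeds ``rho_min`` (strictly), i.e. its tumor expression
tracks immune infiltration in all cancer types examined.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, PipelineError
from .meta import ScreenConfig

#: marker protein names -> acceptable expression-matrix row symbols
MARKER_ALIASES = {
    "CD4": ("CD4",),
    "CD8A": ("CD8A",),
    "CD11B": ("CD11B", "ITGAM"),
    "CD45": ("CD45", "PTPRC"),
}

DEFAULT_MARKERS = ("CD4", "CD8A", "CD11B", "CD45")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene symbols")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with mid-ranks for ties.

    Pairwise-complete: pairs where either value is missing are excluded.
    A constant vector has no rank variance; the correlation is then
    undefined and returned as NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _resolve_marker(marker: str, index: pd.Index,
                    alias_map=MARKER_ALIASES) -> str:
    for symbol in alias_map.get(marker, (marker,)):
        if symbol.upper() in index:
            return symbol.upper()
    raise PipelineError(f"marker {marker!r} not found in expression matrix "
                        f"(aliases tried: {alias_map.get(marker, (marker,))})")


def correlation_matrix(candidates, markers, cohorts: dict,
                       alias_map=MARKER_ALIASES) -> pd.DataFrame:
    """One Spearman rho per (candidate gene, marker, cohort).

    ``cohorts`` maps cohort label -> genes x samples matrix. Markers are
    mandatory in every cohort (resolved through ``alias_map``); candidate
    genes absent from a cohort yield rows flagged ``missing`` with NaN rho
    so downstream rules can see the gap explicitly.
    """
    candidates = [str(g).upper() for g in candidates]
    rows = []
    for label, expr in cohorts.items():
        marker_rows = {m: expr.loc[_resolve_marker(m, expr.index, alias_map)].to_numpy()
                       for m in markers}
        for gene in candidates:
            for marker in markers:
                if gene not in expr.index:
                    rows.append({"gene": gene, "marker": marker, "cohort": label,
                                 "rho": np.nan, "n_samples": 0, "missing": True})
                    continue
                x = expr.loc[gene].to_numpy()
                rows.append({
                    "gene": gene, "marker": marker, "cohort": label,
                    "rho": spearman_rho(x, marker_rows[marker]),
                    "n_samples": int(np.sum(~(np.isnan(x)
                                              | np.isnan(marker_rows[marker])))),
                    "missing": False,
                })
    return pd.DataFrame(rows)


def wide_matrix(cells: pd.DataFrame) -> pd.DataFrame:
    """Gene x (cohort, marker) pivot of the correlation table."""
    return cells.pivot_table(index="gene", columns=["cohort", "marker"],
                             values="rho", aggfunc="first")


def prioritize(cells: pd.DataFrame, config: ScreenConfig | None = None
               ) -> tuple[list, pd.DataFrame]:
    """Apply the all-cohorts rule: keep genes whose max marker correlation
    strictly exceeds ``config.rho_min`` in every cohort.

    Genes with any missing cohort are never prioritized. Returns the
    sorted prioritized gene list and a per-gene audit table with each
    cohort's max rho and the final decision.
    """
    if config is None:
        config = ScreenConfig()
    per_cohort = (cells.groupby(["gene", "cohort"])
                  .agg(max_rho=("rho", "max"), missing=("missing", "any"))
                  .reset_index())
    audit = per_cohort.pivot(index="gene", columns="cohort", values="max_rho")
    any_missing = (per_cohort.groupby("gene")["missing"].any()
                   | audit.isna().any(axis=1))
    passes = (audit > config.rho_min).all(axis=1) & ~any_missing
    audit = audit.assign(prioritized=passes)
    return sorted(audit.index[passes]), audit
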