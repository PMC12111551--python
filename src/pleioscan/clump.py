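"""Greedy LD clumping of screened SNPs into independent lead SNPs and loci.

Mirrors plink-style clumping at a single r^2 level: the most
significant unassigned SNP becomes a lead and absorbs every unassigned
same-chromosome SNP correlated with it at r^2 >= ``r2_lead``; once all
SNPs are assigned, clumps whose member spans lie within ``merge_distance``
of each other on one chromosome are merged into a single locus while each
clump's lead is retained as a distinct lead SNP.

Ties on p-value break deterministically by position, then rsid, so runs
are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PipelineError
from .meta import ScreenConfig


@dataclass
class LDMatrix:
    """Symmetric r^2 matrix over a fixed SNP list.

    ``r2`` has unit diagonal and values in [0, 1]. SNPs that were
    monomorphic in the source genotypes are flagged and carry zero
    off-diagonal r^2.
    """

    rsids: list
    r2: np.ndarray
    provenance: str = "supplied"
    monomorphic: list = field(default_factory=list)

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match SNP list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if np.any(self.r2 < -1e-12) or np.any(self.r2 > 1 + 1e-12):
            raise ValueError("r2 values must lie in [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    @classmethod
    def from_genotypes(cls, genotypes, rsids) -> "LDMatrix":
        """Squared Pearson correlation of dosage columns (individuals x SNPs)."""
        g = np.asarray(genotypes, dtype=float)
        if g.ndim != 2 or g.shape[0] < 2:
            raise ValueError("need a 2-D genotype matrix with >= 2 individuals")
        if g.shape[1] != len(rsids):
            raise ValueError("number of genotype columns != number of rsids")
        if np.any(np.all(np.isnan(g), axis=0)):
            raise ValueError("genotype matrix contains an all-missing SNP")
        sd = np.nanstd(g, axis=0)
        mono = sd == 0
        centred = g - np.nanmean(g, axis=0)
        sd_safe = np.where(mono, 1.0, sd)
        zs = centred / sd_safe
        r = (zs.T @ zs) / g.shape[0]
        r2 = np.clip(r * r, 0.0, 1.0)
        r2[mono, :] = 0.0
        r2[:, mono] = 0.0
        np.fill_diagonal(r2, 1.0)
        return cls(rsids=list(rsids), r2=r2, provenance="genotype-derived",
                   monomorphic=[rs for rs, m in zip(rsids, mono) if m])

    def contains(self, rsid) -> bool:
        return rsid in self._index

    def pairwise(self, rsid_i, rsid_j) -> float:
        return float(self.r2[self._index[rsid_i], self._index[rsid_j]])


@dataclass
class LeadLocus:
    """A clump lead with its absorbed members and merged-locus bounds."""

    lead_rsid: str
    chrom: str
    pos: int
    p_meta: float
    members: list
    locus_start: int
    locus_end: int
    locus_id: int = -1
    pair_label: tuple = ("", "")


def clump(meta_records: pd.DataFrame, ld: LDMatrix,
          config: ScreenConfig | None = None,
          pair_label: tuple = ("", ""),
          on_missing_snp: str = "drop") -> list[LeadLocus]:
    """Greedy clumping of one pair's screened meta records.

    Parameters
    ----------
    meta_records
        Output of :func:`pleioscan.meta.screen_pair` (columns ``rsid``,
        ``chrom``, ``pos``, ``p_meta``); all records from one pair.
    ld
        LD matrix covering (at least) the screened SNPs.
    on_missing_snp
        ``"drop"`` (default) removes SNPs absent from the LD matrix with a
        warning; ``"error"`` raises.

    Returns the lead loci sorted by chromosome and position. Leads are
    pairwise below ``config.r2_lead``; clumps whose member spans are
    within ``config.merge_distance`` share a ``locus_id`` and merged
    ``locus_start``/``locus_end`` bounds.
    """
    if config is None:
        config = ScreenConfig()
    df = meta_records
    missing = [rs for rs in df["rsid"] if not ld.contains(rs)]
    if missing:
        if on_missing_snp == "error":
            raise PipelineError(f"SNPs absent from LD matrix: {missing[:5]}...")
        warnings.warn(f"dropping {len(missing)} SNP(s) absent from the LD matrix")
        df = df[~df["rsid"].isin(missing)]
    if df.empty:
        return []

    # rank by significance: a -log10 p column (stable under p underflow)
    # takes precedence when present, then position, then rsid
    if "mlog10_p_meta" in df.columns:
        order = df.sort_values(["mlog10_p_meta", "pos", "rsid"],
                               ascending=[False, True, True], kind="mergesort")
    else:
        order = df.sort_values(["p_meta", "pos", "rsid"], kind="mergesort")
    rsid = order["rsid"].to_numpy()
    chrom = order["chrom"].astype(str).to_numpy()
    pos = order["pos"].to_numpy()
    pvals = order["p_meta"].to_numpy()
    idx = np.array([ld._index[rs] for rs in rsid])

    assigned = np.zeros(len(order), dtype=bool)
    clumps: list[LeadLocus] = []
    for i in range(len(order)):
        if assigned[i]:
            continue
        same_chrom = (chrom == chrom[i]) & ~assigned
        r2_row = ld.r2[idx[i], idx]
        member_mask = same_chrom & (r2_row >= config.r2_lead)
        member_mask[i] = True
        assigned |= member_mask
        member_pos = pos[member_mask]
        clumps.append(LeadLocus(
            lead_rsid=str(rsid[i]), chrom=str(chrom[i]), pos=int(pos[i]),
            p_meta=float(pvals[i]), members=list(rsid[member_mask]),
            locus_start=int(member_pos.min()), locus_end=int(member_pos.max()),
            pair_label=pair_label,
        ))

    # merge clumps whose member spans lie within merge_distance
    locus_id = 0
    for ch in sorted({c.chrom for c in clumps}):
        group = sorted((c for c in clumps if c.chrom == ch),
                       key=lambda c: (c.locus_start, c.locus_end, c.lead_rsid))
        current: list[LeadLocus] = []
        span_end = None
        for c in group:
            if current and c.locus_start - span_end > config.merge_distance:
                _assign_locus(current, locus_id)
                locus_id += 1
                current, span_end = [], None
            current.append(c)
            span_end = c.locus_end if span_end is None else max(span_end, c.locus_end)
        if current:
            _assign_locus(current, locus_id)
            locus_id += 1

    return sorted(clumps, key=lambda c: (c.chrom, c.pos, c.lead_rsid))


def _assign_locus(group: list[LeadLocus], locus_id: int) -> None:
    start = min(c.locus_start for c in group)
    end = max(c.locus_end for c in group)
    for c in group:
        c.locus_id = locus_id
        c.locus_start = start
        c.locus_end = end


def leads_to_frame(leads: list[LeadLocus]) -> pd.DataFrame:
    """Tabular view of lead loci (one row per lead SNP)."""
    return pd.DataFrame({
        "pair": ["|".join(c.pair_label) for c in leads],
        "lead_rsid": [c.lead_rsid for c in leads],
        "chrom": [c.chrom for c in leads],
        "pos": [c.pos for c in leads],
        "p_meta": [c.p_meta for c in leads],
        "locus_id": [c.locus_id for c in leads],
        "locus_start": [c.locus_start for c in leads],
        "locus_end": [c.locus_end for c in leads],
        "n_members": [len(c.members) for c in leads],
    })


def dedupe_leads(per_pair_leads: dict) -> tuple[pd.DataFrame, dict]:
    """Deduplicate lead SNPs across pairwise analyses by rsid.

    Parameters
    ----------
    per_pair_leads
        Mapping ``pair label -> list of LeadLocus`` from each pairwise
        screen.

    Returns
    -------
    (DataFrame, dict)
        One row per unique lead rsid with the list of pairs where it was
        identified and its multiplicity, plus summary counts:
        ``n_total`` (with multiplicity), ``n_unique``, ``n_single_pair``,
        ``n_multi_pair``; ``n_unique == n_single_pair + n_multi_pair``.
    """
    if not per_pair_leads:
        raise PipelineError("dedupe_leads requires at least one analyzed pair")
    rows: dict[str, dict] = {}
    n_total = 0
    for pair, leads in per_pair_leads.items():
        label = pair if isinstance(pair, str) else "|".join(pair)
        for c in leads:
            n_total += 1
            entry = rows.setdefault(c.lead_rsid, {
                "lead_rsid": c.lead_rsid, "chrom": c.chrom, "pos": c.pos,
                "best_p_meta": c.p_meta, "pairs": []})
            entry["pairs"].append(label)
            entry["best_p_meta"] = min(entry["best_p_meta"], c.p_meta)
    table = pd.DataFrame(sorted(rows.values(),
                                key=lambda r: (r["chrom"], r["pos"], r["lead_rsid"])))
    table["multiplicity"] = table["pairs"].map(len)
    n_unique = len(table)
    n_multi = int((table["multiplicity"] > 1).sum())
    summary = {
        "n_total": n_total,
        "n_unique": n_unique,
        "n_single_pair": n_unique - n_multi,
        "n_multi_pair": n_multi,
    }
    return table, summary
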