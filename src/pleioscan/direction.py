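"""Alignment of a lead SNP's cancer-risk allele with its eQTL effect.

For each prioritized gene the corresponding lead SNP is looked up in
cis-eQTL records for that gene. The *cancer-risk allele* is the lead's
effect allele when its cancer beta is positive, otherwise the other
allele. The eQTL Z-score is re-expressed for the risk allele (negated on
allele swap, strand-corrected for complements) and the sign of the
harmonized Z classifies the variant:

* ``risk_allele_increases_expression``
* ``risk_allele_decreases_expression``
* ``unresolvable`` (palindromic ambiguity, incompatible alleles, zero or
  undefined effect)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alleles import is_palindromic, is_valid_allele, match_alleles
from .exceptions import FormatError

INCREASES = "risk_allele_increases_expression"
DECREASES = "risk_allele_decreases_expression"
UNRESOLVABLE = "unresolvable"


@dataclass
class EqtlRecord:
    """One cis-eQTL association: SNP -> gene expression effect."""

    rsid: str
    gene: str
    effect_allele: str
    other_allele: str
    z: float
    p: float = float("nan")

    def __post_init__(self):
        if not (is_valid_allele(self.effect_allele)
                and is_valid_allele(self.other_allele)):
            raise ValueError(f"{self.rsid}: alleles must be single bases")
        if not pd.notna(self.z) or self.z in (float("inf"), float("-inf")):
            raise ValueError(f"{self.rsid}: eQTL z must be finite")


def read_eqtl(path) -> list[EqtlRecord]:
    """Read eQTL records from a TSV ``rsid gene effect_allele other_allele z p``."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "gene": str})
    needed = ["rsid", "gene", "effect_allele", "other_allele", "z"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing eQTL columns {missing}")
    return [EqtlRecord(rsid=r.rsid, gene=r.gene,
                       effect_allele=str(r.effect_allele).upper(),
                       other_allele=str(r.other_allele).upper(),
                       z=float(r.z),
                       p=float(getattr(r, "p", float("nan"))))
            for r in df.itertuples()]


def risk_allele(effect_allele: str, other_allele: str, beta_cancer: float):
    """The allele that increases cancer risk, or None when beta is 0/NaN."""
    if not pd.notna(beta_cancer) or beta_cancer == 0:
        return None
    return effect_allele if beta_cancer > 0 else other_allele


def align_direction(lead, eqtl: EqtlRecord) -> tuple[str, str]:
    """Classify the eQTL direction for the lead's cancer-risk allele.

    ``lead`` is any mapping with ``effect_allele``, ``other_allele`` and
    ``beta_a`` (the cancer-scale beta for the effect allele). Returns
    ``(classification, reason)`` where reason explains unresolvable calls.
    """
    ea, oa = str(lead["effect_allele"]).upper(), str(lead["other_allele"]).upper()
    risk = risk_allele(ea, oa, lead["beta_a"])
    if risk is None:
        return UNRESOLVABLE, "cancer beta is zero or missing"
    nonrisk = oa if risk == ea else ea

    if is_palindromic(risk, nonrisk) or is_palindromic(eqtl.effect_allele,
                                                       eqtl.other_allele):
        return UNRESOLVABLE, "palindromic alleles: strand ambiguous"
    rel = match_alleles(risk, nonrisk, eqtl.effect_allele, eqtl.other_allele)
    if rel is None:
        return UNRESOLVABLE, "incompatible allele sets"
    z = eqtl.z if rel in ("same", "flip") else -eqtl.z
    if z > 0:
        return INCREASES, ""
    if z < 0:
        return DECREASES, ""
    return UNRESOLVABLE, "eQTL z is zero"


def align_table(leads: pd.DataFrame, eqtls: list[EqtlRecord]) -> pd.DataFrame:
    """Align every lead against the eQTL record for its nearest gene.

    ``leads`` needs columns ``lead_rsid``, ``nearest_gene``,
    ``effect_allele``, ``other_allele``, ``beta_a``. Leads without a
    matching (rsid, gene) eQTL record are reported unresolvable.
    """
    lookup = {(e.rsid, e.gene.upper()): e for e in eqtls}
    rows = []
    for _, lead in leads.iterrows():
        key = (str(lead["lead_rsid"]), str(lead["nearest_gene"]).upper())
        eqtl = lookup.get(key)
        if eqtl is None:
            cls, reason = UNRESOLVABLE, "no eQTL record for (SNP, gene)"
            z = float("nan")
        else:
            cls, reason = align_direction(lead, eqtl)
            z = eqtl.z
        rows.append({"lead_rsid": key[0], "gene": key[1],
                     "risk_allele": risk_allele(str(lead["effect_allele"]).upper(),
                                                str(lead["other_allele"]).upper(),
                                                lead["beta_a"]),
                     "eqtl_z": z, "classification": cls, "reason": reason})
    return pd.DataFrame(rows)
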