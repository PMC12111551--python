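"""Published headline tables as machine-readable fixtures, with count
verifiers.

The bundled TSVs transcribe the study's printed results: the 32
immune-related nearest genes with their ImmPort/Enrichr flags, the eleven
source GWAS sample sizes (cancer subtypes carried as attributes of their
parent GWAS), the per-analysis lead-SNP counts, the headline totals, and
the per-allele direction pattern of the five prioritized lead SNP / gene
pairs. :func:`verify_counts` recomputes every headline total from the
row-level fixtures by integer arithmetic and compares it to the printed
value.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exceptions import FormatError

_SCHEMAS = {
    "table1": ["gene", "immport", "enrichr", "category"],
    "sample_sizes": ["trait", "disease_class", "cases", "controls",
                     "subtype_cases"],
    "lead_counts": ["analysis", "n_leads"],
    "headline_counts": ["name", "value"],
    "figure3b_directions": ["rsid", "gene", "stated_allele",
                            "cancer_direction", "expression_direction",
                            "risk_allele_expression"],
}

_INT_COLUMNS = {
    "table1": ["immport", "enrichr"],
    "sample_sizes": ["cases", "controls"],
    "lead_counts": ["n_leads"],
    "headline_counts": ["value"],
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled fixture table by name with schema validation.

    Raises ``LookupError`` for an unknown name and ``FormatError`` when a
    bundled file no longer matches its schema.
    """
    if name not in _SCHEMAS:
        raise LookupError(
            f"unknown fixture {name!r}; available: {sorted(_SCHEMAS)}")
    path = resources.files("pleioscan").joinpath(f"data/{name}.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    missing = [c for c in _SCHEMAS[name] if c not in df.columns]
    if missing:
        raise FormatError(f"fixture {name}: missing columns {missing}")
    for col in _INT_COLUMNS.get(name, []):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise FormatError(f"fixture {name}: column {col} must be integer")
    if df.empty:
        raise FormatError(f"fixture {name}: no rows")
    return df[_SCHEMAS[name]]


def verify_counts() -> tuple[pd.DataFrame, bool]:
    """Recompute every headline total from the row-level fixtures.

    Returns a report with columns ``name``, ``recomputed``, ``printed``,
    ``ok`` plus the overall boolean. All identities are integer
    arithmetic: the seven per-analysis lead counts sum to the total; the
    unique-lead decomposition adds up; the Table-1 flag counts obey
    inclusion-exclusion; case/control sums over the overall cancer GWAS
    and the seven autoimmune GWAS match the stated totals (cancer
    subtypes are nested in their parent GWAS and are not added).
    """
    table1 = load_fixture("table1")
    sizes = load_fixture("sample_sizes")
    leads = load_fixture("lead_counts")
    printed = load_fixture("headline_counts").set_index("name")["value"]

    cancer = sizes[sizes["disease_class"] == "cancer"]
    autoimmune = sizes[sizes["disease_class"] == "autoimmune"]
    both = (table1["immport"] == 1) & (table1["enrichr"] == 1)

    recomputed = {
        "total_lead_snps": int(leads["n_leads"].sum()),
        "unique_lead_snps": int(printed["single_pair_lead_snps"]
                                + printed["multi_pair_lead_snps"]),
        "immune_nearest_genes": len(table1),
        "immport_flagged": int(table1["immport"].sum()),
        "enrichr_flagged": int(table1["enrichr"].sum()),
        "dual_flagged": int(both.sum()),
        "cancer_cases": int(cancer["cases"].sum()),
        "cancer_controls": int(cancer["controls"].sum()),
        "autoimmune_cases": int(autoimmune["cases"].sum()),
        "autoimmune_controls": int(autoimmune["controls"].sum()),
    }
    # inclusion-exclusion on the Table-1 flags must reproduce the gene total
    recomputed["table1_inclusion_exclusion"] = (
        recomputed["immport_flagged"] + recomputed["enrichr_flagged"]
        - recomputed["dual_flagged"])

    rows = []
    for name, value in recomputed.items():
        target = ("immune_nearest_genes"
                  if name == "table1_inclusion_exclusion" else name)
        rows.append({"name": name, "recomputed": value,
                     "printed": int(printed[target]),
                     "ok": value == int(printed[target])})
    report = pd.DataFrame(rows)
    return report, bool(report["ok"].all())


def figure3b_alignment_inputs() -> tuple[pd.DataFrame, list]:
    """Lead/eQTL record pairs for the five prioritized genes.

    The allelic *directions* follow the transcribed fixture; the other
    alleles and the beta / Z magnitudes are synthetic stand-ins (the
    publication prints the pattern, not reusable numeric records), chosen
    non-palindromic so strand handling is exact.
    """
    from .direction import EqtlRecord

    partner = {"A": "G", "G": "A", "C": "A", "T": "C"}
    fx = load_fixture("figure3b_directions")
    leads, eqtls = [], []
    for _, row in fx.iterrows():
        ea = row["stated_allele"]
        oa = partner[ea]
        beta_a = 0.1 if row["cancer_direction"] == "increase" else -0.1
        z = 6.0 if row["expression_direction"] == "increase" else -6.0
        leads.append({"lead_rsid": row["rsid"], "nearest_gene": row["gene"],
                      "effect_allele": ea, "other_allele": oa,
                      "beta_a": beta_a})
        eqtls.append(EqtlRecord(rsid=row["rsid"], gene=row["gene"],
                                effect_allele=ea, other_allele=oa, z=z))
    return pd.DataFrame(leads), eqtls
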