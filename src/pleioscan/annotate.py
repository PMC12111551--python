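"""Lead SNP annotation: nearest-gene mapping, immune gene-list overlap and
hypergeometric pathway overrepresentation.

Gene intervals use 1-based inclusive coordinates. A SNP inside a gene body
has distance 0; otherwise the distance is the smaller of the distances to
the gene's start and end. Gene symbols are case-folded before any join.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, FormatError

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "symbol"]

#: substrings (case-insensitive) that mark a pathway name as immune-related
DEFAULT_IMMUNE_KEYWORDS = (
    "interferon", "tcr", "bcr", "cytokine", "inflammat", "immun",
    "leukocyte", "t-cell", "t cell", "natural killer", "dendritic",
)


@dataclass
class GeneSet:
    """A named gene collection (immune list or pathway)."""

    name: str
    description: str = ""
    members: frozenset = frozenset()
    database: str = ""

    def __post_init__(self):
        self.members = frozenset(str(m).upper() for m in self.members)


def read_gene_table(path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV (1-based inclusive bounds)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene columns {missing}")
    if (df["start"] > df["end"]).any():
        raise FormatError(f"{path}: gene with start > end")
    df["chrom"] = df["chrom"].str.replace("^chr", "", regex=True, case=False)
    return df[GENE_COLUMNS]


def write_gene_table(df: pd.DataFrame, path) -> None:
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path, database: str = "") -> list[GeneSet]:
    """Read GMT-like lines ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(name=parts[0], description=parts[1],
                                members=frozenset(parts[2:]) - {""},
                                database=database or parts[1]))
    if not sets:
        raise FormatError(f"{path}: no gene sets parsed")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def nearest_gene(pos: int, chrom: str, genes: pd.DataFrame):
    """Nearest gene to a position, with its distance in bp.

    Distance is 0 when the position falls inside the gene body, else
    ``min(|pos - start|, |pos - end|)``. Ties break by smaller distance to
    the gene start, then lexicographic symbol, so results are stable.
    Returns ``(gene_row, distance)`` or ``(None, None)`` when the
    chromosome carries no gene.
    """
    on_chrom = genes[genes["chrom"].astype(str) == str(chrom)]
    if on_chrom.empty:
        return None, None
    start = on_chrom["start"].to_numpy()
    end = on_chrom["end"].to_numpy()
    inside = (pos >= start) & (pos <= end)
    dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
    order = np.lexsort((on_chrom["symbol"].to_numpy(),
                        np.abs(pos - start), dist))
    best = order[0]
    return on_chrom.iloc[best], int(dist[best])


def annotate_nearest_genes(leads: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map each lead SNP row (``lead_rsid``, ``chrom``, ``pos``) to its
    nearest gene. SNPs on gene-free chromosomes get a missing symbol."""
    symbols, gene_ids, dists = [], [], []
    for chrom, pos in zip(leads["chrom"], leads["pos"]):
        row, dist = nearest_gene(int(pos), chrom, genes)
        if row is None:
            symbols.append(pd.NA); gene_ids.append(pd.NA); dists.append(pd.NA)
        else:
            symbols.append(row["symbol"]); gene_ids.append(row["gene_id"])
            dists.append(dist)
    out = leads.copy()
    out["nearest_gene"] = symbols
    out["nearest_gene_id"] = gene_ids
    out["distance_bp"] = dists
    return out


def immune_overlap(nearest: pd.DataFrame, immune: GeneSet) -> pd.DataFrame:
    """Flag nearest genes that belong to a curated immune gene list.

    ``nearest`` must carry a ``nearest_gene`` column; provenance columns
    (which lead SNP maps to each gene) are preserved.
    """
    out = nearest.copy()
    sym = out["nearest_gene"].astype("string").str.upper()
    out["immune_flag"] = sym.isin(immune.members).fillna(False).astype(bool)
    return out


def hypergeom_enrich(query, pathway_sets: list[GeneSet],
                     universe_size: int) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each pathway set.

    For a pathway of size K in a universe of N genes and a query of n
    genes with overlap k, the enrichment p-value is the exact upper tail
    ``P(X >= k)`` for X ~ Hypergeometric(N, K, n). Results are ranked by
    ascending p (ties by database then name) and carry
    Benjamini-Hochberg-adjusted p-values across all tested sets.
    """
    query = {str(g).upper() for g in query}
    if not query:
        raise ValueError("query gene list is empty")
    n = len(query)
    if n > universe_size:
        raise ValueError("query larger than universe")
    rows = []
    for s in pathway_sets:
        K = len(s.members)
        if K > universe_size:
            raise ValueError(f"set {s.name!r} larger than universe")
        overlap = sorted(query & s.members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, universe_size, K, n)) if k else 1.0
        rows.append({"set": s.name, "database": s.database, "k": k, "K": K,
                     "n": n, "N": universe_size, "p": min(p, 1.0),
                     "driver_genes": ",".join(overlap)})
    out = pd.DataFrame(rows).sort_values(["p", "database", "set"],
                                         kind="mergesort").reset_index(drop=True)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def select_immune_pathway_genes(results: pd.DataFrame,
                                immune_keywords=DEFAULT_IMMUNE_KEYWORDS,
                                top_n: int = 10) -> set:
    """Union of driver genes from immune-related pathways in each
    database's top ``top_n`` results (ranked by raw p).

    A pathway counts as immune-related when its name contains any of the
    configured keywords (case-insensitive substring match).
    """
    if "database" not in results.columns or results["database"].eq("").all():
        raise ConfigError("enrichment results carry no database tags")
    keywords = [k.lower() for k in immune_keywords]
    genes: set[str] = set()
    for _, group in results.groupby("database", sort=True):
        top = group.sort_values(["p", "set"], kind="mergesort").head(top_n)
        for _, row in top.iterrows():
            name = str(row["set"]).lower()
            if any(k in name for k in keywords) and row["driver_genes"]:
                genes.update(row["driver_genes"].split(","))
    return genes
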