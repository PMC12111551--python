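"""Map unique leads to nearest genes and flag the immune-related subset.

Nearest-gene annotation of every unique lead SNP, overlap with the
immune gene list, hypergeometric pathway enrichment of the full nearest
gene list (per database, BH-adjusted), top-10 immune-pathway selection,
and the union list the expression step will consume. Outputs under
results/annotation/.
"""

import pandas as pd

import pleioscan as ps
from _common import outdir


def main():
    syn = outdir("synthetic")
    screen = outdir("screen")
    out = outdir("annotation")

    leads = pd.read_csv(screen / "unique_leads.tsv", sep="\t",
                        dtype={"chrom": str})
    genes = ps.read_gene_table(syn / "genes.tsv")
    annotated = ps.annotate_nearest_genes(
        leads.rename(columns={"lead_rsid": "lead_rsid"}), genes)

    immune_list = ps.read_gmt(syn / "immune_list.gmt", database="immune_list")[0]
    flagged = ps.immune_overlap(annotated, immune_list)
    flagged.to_csv(out / "nearest_genes.tsv", sep="\t", index=False)
    n_imm = int(flagged["immune_flag"].sum())
    print(f"{len(flagged)} unique leads -> "
          f"{flagged['nearest_gene'].nunique()} nearest genes, "
          f"{n_imm} immune-list hits")

    pathways = ps.read_gmt(syn / "pathways.gmt")
    query = set(flagged["nearest_gene"].dropna())
    enrich = ps.hypergeom_enrich(query, pathways, universe_size=len(genes))
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    pathway_genes = ps.select_immune_pathway_genes(enrich)
    print(f"enrichment: top set {enrich.loc[0, 'set']} "
          f"(p={enrich.loc[0, 'p']:.2e}); "
          f"{len(pathway_genes)} genes from immune pathways in the top 10")

    immune_union = sorted(
        set(flagged.loc[flagged["immune_flag"], "nearest_gene"])
        | (pathway_genes & query))
    pd.Series(immune_union, name="gene").to_csv(
        out / "immune_genes.tsv", sep="\t", index=False)
    print(f"immune-related nearest genes (list or pathway): "
          f"{len(immune_union)}")


if __name__ == "__main__":
    main()
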