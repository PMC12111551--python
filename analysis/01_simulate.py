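"""Generate every input of the synthetic cross-disorder study.

Writes, under results/synthetic/: per-pair cancer and autoimmune summary
statistics (tab-delimited, with a fraction of trait-B rows allele-swapped
or strand-complemented to exercise harmonization), the gene annotation,
the immune gene list and pathway GMT files, four Z-scored tumor
expression cohorts, and eQTL records with planted directions for the
opposite-effect loci.
"""

import json

import pleioscan as ps
from _common import (MARKER_SYMBOLS, N_DRIVEN, SEED, outdir, pair_config,
                     panel_config)


def main():
    out = outdir("synthetic")
    meta = {"seed": SEED}

    causal_rsids = {}
    for pair in ("pair1", "pair2"):
        cfg = pair_config(pair)
        genotypes, snp_map = ps.simulate_ld_genotypes(cfg)
        table_a, table_b = ps.simulate_pair_sumstats(genotypes, snp_map, cfg)
        ps.write_sumstats(table_a, out / f"{pair}_cancer.tsv")
        ps.write_sumstats(table_b, out / f"{pair}_autoimmune.tsv")
        causal_rsids[pair] = [snp_map.loc[e.snp_index, "rsid"]
                              for e in cfg.planted_effects
                              if e.effect_class == "opposite"]
        print(f"{pair}: {len(table_a)} SNPs, "
              f"{len(causal_rsids[pair])} opposite-effect loci planted")

    base = panel_config()
    genes = ps.simulate_gene_annotation(base)
    ps.write_gene_table(genes, out / "genes.tsv")

    # immune list = nearest genes of the planted opposite loci + background
    cfg1 = pair_config("pair1")
    _, snp_map = ps.simulate_ld_genotypes(cfg1)
    planted_pos = {}
    for pair in ("pair1", "pair2"):
        cfgp = pair_config(pair)
        _, smp = ps.simulate_ld_genotypes(cfgp)
        for e in cfgp.planted_effects:
            if e.effect_class == "opposite":
                planted_pos[smp.loc[e.snp_index, "rsid"]] = \
                    int(smp.loc[e.snp_index, "pos"])
    planted_nearest = sorted({
        ps.nearest_gene(pos, base.chrom, genes)[0]["symbol"]
        for pos in planted_pos.values()})
    background = [s for s in genes["symbol"] if s not in planted_nearest][:30]
    immune_set, pathways = ps.simulate_gene_sets(
        genes["symbol"], planted_nearest + background, seed=SEED)
    ps.write_gmt([immune_set], out / "immune_list.gmt")
    ps.write_gmt(pathways, out / "pathways.gmt")
    print(f"immune list: {len(immune_set.members)} genes "
          f"({len(planted_nearest)} are nearest genes of planted loci)")

    # expression: the first N_DRIVEN planted nearest genes track infiltration
    driven = planted_nearest[:N_DRIVEN]
    cohorts = ps.simulate_expression(
        base, driven, MARKER_SYMBOLS,
        gene_universe=list(genes["symbol"]) + MARKER_SYMBOLS)
    for label, expr in cohorts.items():
        ps.write_expression(expr, out / f"expression_{label}.tsv")
    print(f"expression: {len(cohorts)} cohorts x "
          f"{base.n_samples_expr} samples; driven genes: {', '.join(driven)}")

    meta.update({"driven_genes": driven, "planted_nearest": planted_nearest,
                 "causal_rsids": causal_rsids})
    (out / "study.json").write_text(json.dumps(meta, indent=2))
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
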