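"""Align prioritized leads' cancer-risk alleles with eQTL directions.

For each prioritized gene, takes the corresponding lead SNP from the
screen, generates a planted-direction eQTL record, harmonizes the eQTL
alleles to the cancer-risk allele and classifies the regulatory
direction; then repeats the classification on the packaged fixture of
the five published lead SNP / gene pairs. Outputs under
results/direction/.
"""

import json

import pandas as pd

import pleioscan as ps
from _common import SEED, outdir


def main():
    ann = outdir("annotation")
    prio = outdir("prioritization")
    out = outdir("direction")

    nearest = pd.read_csv(ann / "nearest_genes.tsv", sep="\t",
                          dtype={"chrom": str})
    prioritized = set(json.loads((prio / "prioritized.json").read_text()))
    leads = nearest[nearest["nearest_gene"].isin(prioritized)].copy()

    # attach the cancer-scale stats of each lead from its best pair
    screen = outdir("screen")
    meta = pd.concat([pd.read_csv(screen / f"{p}_meta.tsv", sep="\t")
                      for p in ("pair1", "pair2")])
    meta = (meta.sort_values("mlog10_p_meta", ascending=False)
            .drop_duplicates("rsid").set_index("rsid"))
    for col in ("effect_allele", "other_allele", "beta_a"):
        leads[col] = meta.loc[leads["lead_rsid"], col].to_numpy()

    # planted eQTL truth: effect allele raises expression for every other lead
    planted = {rs: (+1 if i % 2 == 0 else -1)
               for i, rs in enumerate(sorted(leads["lead_rsid"]))}
    eqtl_df = ps.simulate_eqtl_records(leads, planted, seed=SEED)
    eqtl_path = out / "eqtl_records.tsv"
    eqtl_df.to_csv(eqtl_path, sep="\t", index=False)
    aligned = ps.align_table(leads, ps.read_eqtl(eqtl_path))
    aligned.to_csv(out / "synthetic_alignment.tsv", sep="\t", index=False)
    print("synthetic leads:")
    for _, row in aligned.iterrows():
        print(f"  {row['lead_rsid']} -> {row['gene']}: "
              f"{row['classification']}")

    fx_leads, fx_eqtls = ps.figure3b_alignment_inputs()
    fx_out = ps.align_table(
        fx_leads, fx_eqtls)
    fx_out.to_csv(out / "published_pattern.tsv", sep="\t", index=False)
    print("published five-gene pattern:")
    for _, row in fx_out.iterrows():
        print(f"  {row['lead_rsid']} ({row['gene']}): {row['classification']}")


if __name__ == "__main__":
    main()
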