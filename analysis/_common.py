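"""Shared study definition for the numbered analysis scripts.

The synthetic study mirrors the structure of the real screen at desk
scale: two cancer-autoimmune trait pairs over one 400-SNP chromosome of
50 tight LD blocks, with opposite-effect loci planted in both pairs
(six loci shared between them, so lead deduplication has real work),
concordant and heterogeneous decoy loci, a 200-gene annotation, an
immune gene list covering the planted loci's nearest genes, pathway
collections, four tumor-expression cohorts driven by a latent
infiltration factor, and eQTL records with planted directions.
"""

from pathlib import Path

import pleioscan as ps

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260925 % (2**31 - 1)

MARKER_SYMBOLS = ["CD4", "CD8A", "ITGAM", "PTPRC"]

# blocks carrying planted opposite-effect loci, per pair (6 shared)
OPPOSITE_BLOCKS = {"pair1": list(range(0, 12)),
                   "pair2": list(range(6, 18))}
CONCORDANT_BLOCKS = {"pair1": list(range(20, 26)),
                     "pair2": list(range(26, 32))}
N_DRIVEN = 5


def panel_config(seed_offset: int = 0) -> ps.SimulationConfig:
    return ps.SimulationConfig(seed=SEED + seed_offset, n_snps=400,
                               n_blocks=50, block_rho=0.95,
                               maf_range=(0.15, 0.45), n_individuals=2000,
                               n_genes=200, n_samples_expr=500, n_cohorts=4,
                               infiltration_loading=0.9,
                               allele_perturb_rate=0.15)


def pair_config(pair: str) -> ps.SimulationConfig:
    offset = {"pair1": 0, "pair2": 1000}[pair]
    cfg = panel_config(offset)
    blocks, _ = ps.simulate.block_assignments(cfg)
    effects = []
    for b in OPPOSITE_BLOCKS[pair]:
        idx = int(blocks[b][len(blocks[b]) // 2])
        effects.append(ps.PlantedEffect(idx, "opposite", 0.15, -0.15))
    for b in CONCORDANT_BLOCKS[pair]:
        idx = int(blocks[b][len(blocks[b]) // 2])
        effects.append(ps.PlantedEffect(idx, "concordant", 0.15, 0.15))
    cfg.planted_effects = effects
    return cfg


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
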