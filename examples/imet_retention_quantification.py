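"""Peptide-level quantification of initiator-methionine retention.

Generates a label-free peptide table for two strains (WT and MUT) in which
iMet-retained N-terminal peptides carry a planted log2 fold-change shift of
3, then runs the full downstream procedure: confidence filtering (high FDR
class, > 2 PSMs), total-intensity normalisation, low-abundance imputation,
per-biological-replicate fold changes, N-terminal peptidoform
classification, the retained-vs-all Wilcoxon comparison, the 5-fold
partition with second-residue composition, and paralog-collapsed protein
medians.
"""

from nmekit.ntermomics import nterm_pipeline
from nmekit.synthetic_data import PeptideSimConfig, gen_peptide_table

SEED = 11
sim = gen_peptide_table(PeptideSimConfig(delta=3.0, sigma=0.5, seed=SEED))
sequences = {p.protein_id: p.sequence for p in sim.proteins}
result = nterm_pipeline(
    sim.records, sim.run_design, sequences, sim.paralog_map, seed=SEED
)

c = result.comparison
print(
    f"{c.n_all} peptide fold changes, {c.n_imet} from iMet-retained peptides"
)
print(
    f"Wilcoxon retained vs all (two-sided): p = {c.p_value:.3g}; "
    f"medians {c.median_imet:.2f} vs {c.median_all:.2f} "
    f"(planted shift was {sim.truth['delta']} log2 units)"
)

part = result.partition
print(
    f"\nretained peptides at >= {part.threshold:g}-fold: {len(part.high)}; "
    f"below: {len(part.low)}"
)
print(f"  second residues in the high group: {dict(part.high_composition)}")
print(f"  second residues in the low group:  {dict(part.low_composition)}")

print("\nparalog-family median log2 fold changes (expected ~0 after closure):")
for protein in result.proteins[:5]:
    print(
        f"  {protein.family}: median {protein.median_log2fc:+.2f} "
        f"({protein.n_peptides} peptides, BH-adjusted p {protein.fdr:.2f})"
    )
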