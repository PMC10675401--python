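"""Quantify a protein sequence and its PSSM with the sequence-side operators.

Shows the 420-dim composition+dipeptide descriptor, the 3675-dim lagged
physicochemical-property correlation descriptor, and the PSSM descriptors
(DP-PSSM 240, AAC-PSSM 20, PSSM-composition 400).
"""

from locfuse import (
    SyntheticConfig,
    aac_pssm,
    dp_pssm,
    pc_correlation,
    pseaac_dipeptide,
    pssm_composition,
    simulate_dataset,
)

records, pssms, _, _ = simulate_dataset(SyntheticConfig(n_per_class=1, seed=0))
record = records[0]
pssm = pssms[record.id]

pse = pseaac_dipeptide(record)
pc = pc_correlation(record)
print(f"{record.id}: L={len(record)}")
print(f"  PseAAC         dim={pse.dimension}  comp sum={pse.values[:20].sum():.3f} "
      f"dipep sum={pse.values[20:].sum():.3f}")
print(f"  PC correlation dim={pc.dimension}  range=[{pc.values.min():+.3f}, "
      f"{pc.values.max():+.3f}]")
for fv in (dp_pssm(pssm), aac_pssm(pssm), pssm_composition(pssm)):
    print(f"  {fv.operator_name:16s} dim={fv.dimension}")
# Both PseAAC blocks are probability distributions (each sums to 1); the PC
# values are Pearson correlations, hence bounded by [-1, 1].
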