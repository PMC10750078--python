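"""Score every l-mer with a trained model and rebuild the motif as a PWM.

A trained model induces a weight for each canonical l-mer (a word and its
reverse complement score identically, so only 4^l/2 keys exist). Aligning
the top-scoring words to the best one reconstructs the learned motif as a
position weight matrix — the model's interpretable summary.

This example trains at word length 9 to stay fast; the l=11 table used in
the full pipeline behaves identically (2,097,152 canonical words).
"""

import numpy as np

from gkmprior import (
    ModelConfig,
    build_kmer_weight_table,
    build_pwm_from_top_kmers,
    enumerate_canonical_kmers,
    pwm_information_content,
    simulate_study,
)
from gkmprior import dna
from gkmprior.model import build_training_set, train_gkm_svm

print("canonical 11-mers:", len(enumerate_canonical_kmers(11)))  # 4^11 / 2

study = simulate_study(seed=1)
train = build_training_set(study.genome, study.peaks, n_top=300, seed=1)
config = ModelConfig(l=9, k=6, d=3)
model = train_gkm_svm(train, config, seed=1)

table = build_kmer_weight_table(model)
codes, weights = table.top(5)
print("\ntop-scoring 9-mers (positive = predicted TF binding):")
for code, w in zip(codes, weights):
    print(f"  {dna.code_to_kmer(int(code), table.l)}  {w:+.3f}")

pwm = build_pwm_from_top_kmers(table, top_n=500)
ic = pwm_information_content(pwm)
print("\nrecovered PWM consensus:", pwm.consensus)
print("planted motif consensus:", study.motif.consensus)
print("information content (bits):", np.round(ic, 2))
# High-information positions mark the motif core the model learned; they
# should line up with the planted consensus.
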