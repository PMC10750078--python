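"""deltaSVM allele scoring and eQTL-gated prioritization, end to end.

Each variant's reference and alternate alleles are embedded in the 2l-1 bp
window centered on it; the deltaSVM score is the difference of the summed
l-mer weights. Variants that disrupt a planted motif get strongly negative
deltas; prioritization keeps candidates with a large |delta| AND a
significant heart-tissue eQTL, ranked by |delta|.

Uses a word length of 9 to keep the example under a minute.
"""

import tempfile
from pathlib import Path

import numpy as np

from gkmprior import ModelConfig, build_kmer_weight_table, run_catalog, simulate_study
from gkmprior.delta import delta_svm_batch, prioritize
from gkmprior.model import build_training_set, train_gkm_svm

study = simulate_study(seed=1)
train = build_training_set(study.genome, study.peaks, n_top=300, seed=1)
model = train_gkm_svm(train, ModelConfig(l=9, k=6, d=3), seed=1)
table = build_kmer_weight_table(model)

with tempfile.TemporaryDirectory() as d:
    study.write(d)
    result = run_catalog(Path(d) / "gwas_catalog.tsv", study.enhancers, study.footprints,
                         study.ld_table, study.eqtl_table)

results, unsuitable, summary = delta_svm_batch(table, study.genome, result.expanded)
print(f"scored {summary['n_scored']} variants; "
      f"delta mean {summary['mean']:.3f}, sd {summary['sd']:.3f}")

prio = prioritize({"NKX-like": results}, result.eqtl_pairs)
truth = set(study.ground_truth["prioritized_rsids"])
print("\nprioritized variants (|delta| descending, heart-eQTL gated):")
for p in prio:
    mark = "planted" if p.variant.rsid in truth else "??"
    print(f"  #{p.rank} {p.variant.rsid}  delta={p.delta_per_model['NKX-like']:+.2f}  "
          f"eQTL pairs={len(p.eqtl_pairs)}  [{mark}]")
print("\nrecovered exactly the planted set:", {p.variant.rsid for p in prio} == truth)
# Background variants center on delta ~ 0; only the five variants planted on
# consensus motif instances inside nested footprints clear the 99th-percentile
# |delta| threshold AND carry a cardiac eQTL.
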