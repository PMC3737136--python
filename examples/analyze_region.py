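"""Simulate a small rare-variant region, write it to VCF, and run the full
BSVM association analysis from the files.

Ten risk variants with a total population-attributable risk of 3% are mixed
with ten neutral variants in 500 cases and 500 controls.  The analysis
weights each variant by its Poisson likelihood-ratio risk measure, collapses
the weighted minor-allele counts into a risk and a protective burden
covariate, prunes uninformative variants by backward elimination under the
RBF-kernel SVM, and assesses the region by label permutation.
"""

import tempfile
from pathlib import Path

import numpy as np

import bsvm

scenario = bsvm.Scenario(n_risk=10, n_protective=0, n_neutral=10,
                         total_par=0.03, n1=500, n2=500)
rng = np.random.default_rng(2024)
truth = bsvm.simulate_truth(scenario, rng)
data = bsvm.generate_dataset(scenario, rng, truth=truth)

workdir = Path(tempfile.mkdtemp())
bsvm.write_genotypes(data, workdir / "region.vcf", workdir / "pheno.tsv")
data = bsvm.read_genotypes(workdir / "region.vcf", workdir / "pheno.tsv")
data, dropped = bsvm.drop_monomorphic(data)
print(f"analysing {data.n_variants} polymorphic variants "
      f"({len(dropped)} monomorphic dropped)")

summaries = bsvm.compute_weights(data, scheme="RM")
trace = bsvm.backward_select(data, summaries)
removed = {v for v, _ in trace.removed}
print(f"backward selection removed {len(removed)} variants, "
      f"final R^2 = {trace.r2_final:.4f}")

result = bsvm.region_test(data, "RM", B=999, seed=7)
print(f"region permutation p = {result.p_value:.4f}  "
      f"(observed R^2 {result.observed_stat:.4f}, B = {result.B})")

pvals = bsvm.variant_test(data, "RM", retained=trace.retained, B=999,
                          seed=7)
role = dict(zip(truth.variant_id, truth.role))
print("retained variants (p-value, true simulated role):")
for vid, p in sorted(pvals.items(), key=lambda kv: kv[1]):
    print(f"  {vid}  p = {p:.3f}  [{role[vid]}]")
# A small region p-value says the retained set is jointly associated with
# disease; individually small per-variant p-values point at the variants
# whose removal would cost the model the most fit.
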