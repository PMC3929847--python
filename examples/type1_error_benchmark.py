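"""Type I error of the naive vs moment-adjusted Lancaster test under LD.

Runs a reduced benchmark cell: 30-SNP pathway, n = 200 subjects, moderate
within-gene LD (D = 0.15), null phenotype.  Per replicate the per-variant
score-test p-values are combined (a) against the naive chi-square reference
that assumes independence and (b) with the permutation-adjusted scaled
chi-square (T_A).  At 150 replicates this takes a few seconds; a
publication-scale run uses 1000 replicates with 1000 permutations.
"""

from lancaster import LDConfig, ScenarioSpec, disease_model, rejection_rate_experiment

spec = ScenarioSpec(
    ld_config=LDConfig(n_subjects=200, D=0.15),
    model=disease_model("I", beta=0.0),
    reps=150,
    m_perm=200,
    alpha=0.05,
    weighting="gene_size",
    weight_scheme="inv",
    seed=17,
)
out = rejection_rate_experiment(spec)

print(f"nominal level: {spec.alpha}, replicates: {out['n_ok']}")
for name, rate in out["rates"].items():
    tag = "(naive, assumes independence)" if name == "independent" else ""
    print(f"  {name:12s} rejection rate = {rate:.3f} {tag}")
print(
    "\nThe naive reference rejects about twice the nominal 5% because LD"
    "\ncorrelates the p-values; the adjusted methods stay near the nominal level."
)
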