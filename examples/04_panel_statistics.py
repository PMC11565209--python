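"""Run the full panel pipeline and the post-hoc statistics on a small panel.

Simulates a panel of accessions (several plants each), extracts every trait,
and shows the accession-level ANOVA + Tukey compact letter display for
A_sat and the cross-accession trait correlations.  Accessions sharing a
letter are statistically indistinguishable at alpha = 0.05.
"""

from gasxkit import RunConfig, run_pipeline
from gasxkit.synthetic_data import GeneratorConfig

config = RunConfig(
    simulate=GeneratorConfig(n_accessions=6, n_plants=4),
    seed=11,
)
result = run_pipeline(config)

print(f"{result.manifest['n_accessions']} accessions x "
      f"{result.manifest['n_plants'] // result.manifest['n_accessions']} plants")
print("\nAsat Tukey letter display (share a letter = not significantly different):")
print(result.letters["Asat"].to_string(index=False))

print("\nStrongest cross-accession trait correlations:")
top = result.correlations.reindex(
    result.correlations["r"].abs().sort_values(ascending=False).index
).head(5)
print(top.to_string(index=False))
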