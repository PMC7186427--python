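"""Run the full pipeline on a cohort with planted genotype effects.

Simulates 60 subjects whose L.dLPFC -> R.dLPFC coupling is shifted by
+0.2 in carriers of the rs11146020 variant, runs conditioning, Granger
estimation over all 90 directed connections, two-SNP subgrouping and
the three-family GLM with per-family FDR at q = 0.01, then prints the
flagged connections.
"""

import logging

from fstgc import EffectSpec, RunConfig, run_pipeline

logging.disable(logging.INFO)

config = RunConfig(
    seed=2,
    log_level="ERROR",
    simulate=dict(
        n_subjects=60,
        n_timepoints=170,
        effect_map=[EffectSpec("L.dLPFC", "R.dLPFC", "snp1", 0.2)],
        behavior_couplings=[],
    ),
)
result = run_pipeline(config)

print(f"analysed {len(result.subgroups)} subjects "
      f"({len(result.excluded_motion)} motion-excluded, "
      f"{len(result.excluded_genotype)} rare-genotype-excluded)")
print(f"subgroup cells: {result.subgroups.value_counts().to_dict()}\n")

eff = result.inference.effects
flagged = eff[eff["significant"]]
cols = ["connection", "family", "estimate", "F", "p", "q"]
print("flagged connections (q <= 0.01, per-family BH-FDR over 90 tests):")
print(flagged[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# The planted connection surfaces in the snp1 family; its 'estimate' is
# the covariate-adjusted difference between variant and reference
# carriers on the signed path-coefficient scale.  The reverse direction
# may co-flag: a shifted forward coupling genuinely changes the
# bivariate lagged cross-covariance both ways.
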