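"""The full derivation/validation protocol on a synthetic planted-signal cohort.

80/20 stratified split; multiscale dictionaries learned on the derivation
split only; internal validation by 100 stratified 12.5% hold-outs (median
AUC); a single AUC with Hanley 95% CI on the untouched validation split.
Expect a median hold-out AUC well above 0.85 on the 'easy' preset and near
0.5 on 'null'. Runtime: a few minutes per preset.
"""

import warnings

from dcipred.experiments import pipeline_recovery

warnings.filterwarnings("ignore")

for preset in ("easy", "null"):
    res = pipeline_recovery(preset, runs=100, seed=0)
    lo, hi = res["validation_ci"]
    print(f"{preset:>5}: median hold-out AUC {res['median_cv_auc']:.3f} | "
          f"validation AUC {res['validation_auc']:.3f} "
          f"(95% CI {lo:.2f}-{hi:.2f}) | "
          f"n={res['n_derivation']}+{res['n_validation']}")
# 'easy' shows the pipeline recovers planted class-specific motifs;
# 'null' confirms it does not hallucinate signal where none exists.
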