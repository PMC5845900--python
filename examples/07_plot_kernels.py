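"""Visualize learned kernels and classifier feature weights.

Writes two PNGs to a temporary directory; requires matplotlib (the `plot`
extra). The kernel waterfall is the qualitative check that learned atoms
look like the planted motifs; the weight chart shows which (variable,
scale, kernel) features drive the classifier.
"""

import tempfile
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import dcipred as dp
from dcipred.plotting import plot_atoms, plot_feature_weights

cs, ms = dp.preset("tiny", seed=3)
cohort = dp.generate_cohort(cs, ms)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bank = dp.learn_multiscale(
        cohort, variables=("HR",), ds_periods=(5,), kernel_lengths=(6,), K=4,
        config=dp.CDLConfig(max_outer_iters=6, max_admm_iters=30,
                            max_series=10, seed=3))
    fm = dp.assemble_baseline(cohort).hstack(dp.build_feature_matrix(cohort, bank))

out = Path(tempfile.mkdtemp())
ax = plot_atoms(bank.entries[("HR", 5.0, 6)])
ax.figure.savefig(out / "kernels.png", dpi=100, bbox_inches="tight")

# PLS weights over the combined features
from sklearn.cross_decomposition import PLSRegression

Ft, _, _ = dp.impute_and_standardize(fm)
pls = PLSRegression(n_components=3, scale=False).fit(Ft.values,
                                                     cohort.labels().astype(float))
ax2 = plot_feature_weights(pls.coef_.ravel(), Ft.tags, top=10)
ax2.figure.savefig(out / "weights.png", dpi=100, bbox_inches="tight")
plt.close("all")
print(f"wrote {out/'kernels.png'} and {out/'weights.png'}")
print("kernels.png: one trace per learned atom, most-activated on top;")
print("weights.png: the 10 features with the largest |PLS weight| and their provenance.")
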