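"""Render the three figures: cumulative barplot, ROC comparison, boxplots.

Each figure gets a JSON sidecar with the plotted numbers (same basename), so
the values can be inspected without opening the image.  Output lands in
./example_figures/.
"""

from pathlib import Path

from ensemblefs import RunConfig, SyntheticSpec, efs_eval, generate, run_efs
from ensemblefs.viz import cumulative_barplot, roc_plot, variance_boxplot

outdir = Path("example_figures")
outdir.mkdir(exist_ok=True)

table, _ = generate(
    SyntheticSpec(n_samples=100, n_informative=3, effect_size=1.5, n_noise=7, seed=5)
)
config = RunConfig(runs=5, n_trees=50, seed=5)
result = run_efs(table, config)
report = efs_eval(table, result, logreg=True, variances=True, bs_num=10, seed=5)

bar = cumulative_barplot(result, outdir / "importances.pdf")
roc = roc_plot(report.roc_all, report.roc_selected, report.delong_p, outdir / "demo_ROC.pdf")
box = variance_boxplot(report.bootstrap_scores, outdir / "demo_Variances.pdf",
                       order=list(result.ranking))
for path in (bar, roc, box):
    print(f"wrote {path} (+ {path.with_suffix('.json').name})")
print(f"AUC selected {report.auc_selected:.3f} vs all {report.auc_all:.3f}, "
      f"DeLong p = {report.delong_p:.3g}")
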