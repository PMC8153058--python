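#!/usr/bin/env python
"""Classification-behavior correlations with default Bayes factors.

Correlates per-participant decoding and generalization accuracies with
behavioral performance and squared math achievement: Pearson r, Spearman
rho, Kendall tau-b, one- and two-tailed p-values, and default Bayes
factors (stretched beta prior, width 1).  The cohort is generated with a
latent negative correlation between cross-format sharing and math scores,
so the format-generalization x math row is where a negative association is
expected.  Writes results/05_correlate/.
"""

from pathlib import Path

from numdecode.pipeline import PipelineRunner

from importlib import import_module
sim = import_module("01_simulate")

OUT = Path("results/05_correlate")


def main() -> None:
    runner = PipelineRunner(config=sim.COHORT, out_dir=OUT, seed=11,
                            roi_names=("L_parietal", "R_parietal"),
                            n_select=120, max_folds=150)
    runner.run(stages=("simulate", "decode", "generalize", "behavior",
                       "correlate"))
    table = runner.correlation_table
    print("brain x behavior correlations "
          "(BF-0 = evidence for a negative correlation):")
    for row in table.itertuples():
        print(f"  {row.roi:12s} {row.analysis:24s} x {row.behavior:12s} "
              f"r={row.pearson_r:+.3f} rho={row.spearman_rho:+.3f} "
              f"BF10={row.bf10:5.2f} BF01={row.bf01:5.2f} "
              f"BF-0={row.bf_minus0:5.2f}")


if __name__ == "__main__":
    main()
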