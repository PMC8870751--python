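#!/usr/bin/env python
"""Three-class classification (D/T/C) over the five feature selections.

Decision tree, random forest and gradient boosting under stratified
5-fold cross-validation; prints the pooled accuracy / per-class
sensitivity table and the random-forest feature importances.
"""

import sys
from pathlib import Path

from kneemorph.pipeline import RunConfig, run_pipeline

OUT = Path("results/analysis")


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 42
    cfg = RunConfig(seed=seed, out_dir=str(OUT))
    res = run_pipeline(cfg, stages=("classify",), resume=True)
    reports = res["reports"]
    print(f"{'selection':<10}{'alg':<5}{'acc':>6}"
          f"{'sensD':>7}{'sensT':>7}{'sensC':>7}")
    for r in sorted(reports, key=lambda r: -r.accuracy):
        print(f"{r.selection:<10}{r.algorithm:<5}{r.accuracy:>6.1f}"
              f"{r.sensitivity['D']:>7.1f}{r.sensitivity['T']:>7.1f}"
              f"{r.sensitivity['C']:>7.1f}")
    best_rf = max((r for r in reports if r.algorithm == "RF"),
                  key=lambda r: r.accuracy)
    print(f"\ntop random-forest importances ({best_rf.selection}):")
    for name, pct in best_rf.importance[:8]:
        print(f"  {name:<28}{pct:5.2f}%")
    print(f"reports -> {OUT / 'classification'}")


if __name__ == "__main__":
    main()
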