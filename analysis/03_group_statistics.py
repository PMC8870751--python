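#!/usr/bin/env python
"""Nonparametric group comparison over every extracted feature.

Shapiro-Wilk normality screen per group, tie-corrected Kruskal-Wallis
omnibus across D/T/C, and Dunn's post hoc z tests on (C-D, D-T, T-C)
wherever the omnibus is significant at the 0.05 level.
"""

import sys
from pathlib import Path

from kneemorph.pipeline import RunConfig, run_pipeline

OUT = Path("results/analysis")


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 42
    cfg = RunConfig(seed=seed, out_dir=str(OUT))
    res = run_pipeline(cfg, stages=("stats",), resume=True)
    stats = res["stats"]
    sig = stats[stats["significant"]].sort_values("kw_p")
    print(f"{len(sig)}/{len(stats)} features differ across groups "
          f"(Kruskal-Wallis p < 0.05)")
    print("strongest separations:")
    print(sig[["feature", "kw_H", "kw_p", "dunn_CD_p", "dunn_DT_p",
               "dunn_TC_p"]].head(10).to_string(index=False))
    print(f"full table -> {OUT / 'stats.csv'}")


if __name__ == "__main__":
    main()
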