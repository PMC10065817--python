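"""Pairwise differential expression on both panels.

Median-based log2 fold changes with Wilcoxon rank-sum tests and
Benjamini–Yekutieli adjustment for the three diagnosis contrasts, plus the
cross-panel retest correlation of top-20 fold changes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, processed

from ncounter_reject.dge import dge_table, retest_correlation, top_degs, volcano_frame

COMPARISONS = (("AMR", "NoRejection"), ("AMR", "BLorTCMR"),
               ("BLorTCMR", "NoRejection"))


def main():
    tables = {}
    for name in ("large_panel", "small_panel"):
        _, _, _, _, norm = processed(name)
        out = RESULTS / name
        out.mkdir(parents=True, exist_ok=True)
        for a, b in COMPARISONS:
            table = dge_table(norm, a, b)
            tables[(name, a, b)] = table
            table.to_csv(out / f"dge_{a}_vs_{b}.csv")
            volcano_frame(table).to_csv(out / f"volcano_{a}_vs_{b}.csv")
            print(
                f"{name} {a} vs {b}: {table.significant.shape[0]} genes at "
                f"BY-FDR < 0.05; top: {', '.join(top_degs(table, 5))}"
            )

    r = retest_correlation(
        tables[("large_panel", "AMR", "NoRejection")],
        tables[("small_panel", "AMR", "NoRejection")],
        k=20,
    )
    print(f"retest correlation of top-20 log2FC across panels "
          f"(AMR vs NoRejection): r = {r:.3f}")


if __name__ == "__main__":
    main()
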