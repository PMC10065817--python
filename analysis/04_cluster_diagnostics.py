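"""Unsupervised structure of the normalized expression matrices.

Ward/Canberra hierarchical clustering with the three validation
statistics: Hopkins clustering tendency, cophenetic correlation, and the
C-index curve across candidate cluster numbers.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, processed

from ncounter_reject._utils import derive_seed
from ncounter_reject.cluster import cluster_diagnostics, linkage_to_newick


def main():
    for name in ("large_panel", "small_panel"):
        _, _, _, _, norm = processed(name)
        diag = cluster_diagnostics(norm, seed=derive_seed(SEED, f"cluster:{name}"))
        out = RESULTS / name
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "cluster_report.json", "w") as fh:
            json.dump(diag.summary(), fh, indent=1, sort_keys=True)
        with open(out / "dendrogram.nwk", "w") as fh:
            fh.write(linkage_to_newick(diag.linkage, list(norm.values.columns)))
        print(
            f"{name}: Hopkins H = {diag.hopkins_H:.3f}, cophenetic r = "
            f"{diag.cophenetic_r:.3f}, optimal clusters = {diag.optimal_k} "
            f"(C-index {diag.c_index_by_k[diag.optimal_k]:.3f})"
        )


if __name__ == "__main__":
    main()
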