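"""Simulate the two-panel study cohorts.

Writes a large discovery-panel cohort (758 endogenous + 12 reference genes,
32 biopsies per diagnosis group, 8 injected lane failures) and a small
AMR-focused panel re-assay of the same design (90 + 6 genes, shared gene
symbols, independent counts) as RCC datasets under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import LARGE_QC_FAILURES, RESULTS, SEED

from ncounter_reject._utils import derive_seed
from ncounter_reject.synthetic import (
    bhot_like_spec,
    elements_like_spec,
    generate_dataset,
    write_dataset,
)


def main():
    large_spec = bhot_like_spec(
        seed=derive_seed(SEED, "large"), qc_failures=LARGE_QC_FAILURES
    )
    small_spec = elements_like_spec(seed=derive_seed(SEED, "small"))
    for name, spec in (("large_panel", large_spec), ("small_panel", small_spec)):
        lanes, panel, metadata, truth = generate_dataset(spec)
        out = RESULTS / "data" / name
        write_dataset(out, lanes, panel, metadata, truth)
        n_fail = sum(1 for s in metadata if s.sample_id in spec.qc_failures)
        print(
            f"{name}: {len(lanes)} lanes, {len(panel.probe_ids)} probes, "
            f"{n_fail} injected QC failures -> {out}"
        )


if __name__ == "__main__":
    main()
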