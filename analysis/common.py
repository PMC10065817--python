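"""Shared constants and helpers for the numbered analysis drivers."""

from pathlib import Path

import ncounter_reject as nr
from ncounter_reject.pipeline import load_dataset_dir

SEED = 20230901
RESULTS = Path(__file__).resolve().parents[1] / "results"

# lane failures injected into the large-panel cohort (mirrors the attrition
# scale of a real multi-center FFPE run: ~8 of 96 lanes)
LARGE_QC_FAILURES = {
    "NR05": "low_fov",
    "NR12": "low_refs",
    "BT03": "low_fov",
    "BT17": "flat_positives",
    "BT22": "low_refs",
    "AMR04": "low_refs",
    "AMR11": "flat_positives",
    "AMR27": "low_fov",
}


def processed(name):
    """Dataset dir -> (QC report, background result, geNorm, normalized)."""
    matrix = load_dataset_dir(RESULTS / "data" / name)
    report = nr.lane_qc(matrix)
    kept = nr.filter_samples(matrix, report)
    bg = nr.apply_probe_filter(kept)
    gn = nr.genorm_rank(bg.kept_matrix)
    norm = nr.normalize(bg.kept_matrix, gn.selected_references)
    return matrix, report, bg, gn, norm
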