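"""Lane QC, background filtering, reference selection and normalization.

For each simulated panel: apply the flag windows and exclusion rules
(including the binding-density exception), derive the study-level
detection threshold from the negative controls, rank reference genes by
geNorm stability, and write the normalized matrices plus per-stage
reports under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, processed


def main():
    for name in ("large_panel", "small_panel"):
        matrix, report, bg, gn, norm = processed(name)
        out = RESULTS / name
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "qc_report.csv")
        bg.to_frame().to_csv(out / "background.csv")
        norm.values.to_csv(out / "normalized.csv")

        import pandas as pd

        pd.Series(gn.stability_M, name="stability_M").sort_values().to_csv(
            out / "genorm_stability.csv"
        )
        refs = [norm.panel.probe(p).gene_symbol for p in norm.references_used]
        print(
            f"{name}: excluded {len(report.excluded_samples)}/{matrix.n_samples} "
            f"samples ({', '.join(report.excluded_samples) or 'none'}); "
            f"detection threshold {bg.study_threshold:.1f} counts removed "
            f"{len(bg.excluded_probes)} probes; references: {', '.join(refs)}"
        )


if __name__ == "__main__":
    main()
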