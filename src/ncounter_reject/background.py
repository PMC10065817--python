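"""Background threshold estimation and low-expression probe filtering.

Each sample's background is the mean of its negative-control probes plus
two sample standard deviations; the study-level detection threshold doubles
the highest per-sample background.  An endogenous probe is excluded when
its raw count falls below that threshold in at least 50% of samples
(inclusive: exactly half counts as failing).  Housekeeping probes failing
the rule are flagged but retained so normalization candidacy stays
auditable; control probes are never part of the content matrix downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import sample_sd
from .panelio import CountMatrix


@dataclass
class BackgroundResult:
    per_sample_background: pd.Series
    study_threshold: float
    excluded_probes: list[str]  # endogenous probes removed
    flagged_housekeeping: list[str]  # failed the rule but retained
    kept_matrix: CountMatrix

    def to_frame(self) -> pd.DataFrame:
        df = self.per_sample_background.rename("background").to_frame()
        df["study_threshold"] = self.study_threshold
        return df


def sample_background(negative_counts, sd_multiplier: float = 2.0) -> float:
    """mean + 2*SD of the negative-control counts (sample SD, n-1)."""
    neg = np.asarray(negative_counts, dtype=float)
    if neg.size < 2:
        raise ValueError("need >=2 negative probes for a background estimate")
    return float(np.mean(neg)) + sd_multiplier * sample_sd(neg)


def apply_probe_filter(matrix: CountMatrix) -> BackgroundResult:
    """Apply the detection threshold to a QC-passed raw matrix.

    Probe p is excluded iff ``#{samples: count_p < T} >= ceil(n/2)`` with
    ``T = 2 * max_i(background_i)``.  Decisions are invariant to sample and
    probe order; raising any negative-control count can only raise T and
    therefore only grow the excluded set.
    """
    neg = matrix.class_values("Negative").astype(float)
    bg = pd.Series(
        {sid: sample_background(neg[sid]) for sid in neg.columns},
        name="background",
    )
    threshold = 2.0 * float(bg.max())

    n = matrix.n_samples
    need = math.ceil(n / 2)
    below = (matrix.values.astype(float) < threshold).sum(axis=1)

    endo = matrix.panel.ids_of("Endogenous")
    hk = matrix.panel.ids_of("Housekeeping")
    excluded = [pid for pid in endo if below[pid] >= need]
    flagged_hk = [pid for pid in hk if below[pid] >= need]

    keep = [pid for pid in matrix.panel.probe_ids if pid not in set(excluded)]
    return BackgroundResult(
        per_sample_background=bg,
        study_threshold=threshold,
        excluded_probes=excluded,
        flagged_housekeeping=flagged_hk,
        kept_matrix=matrix.subset_probes(keep),
    )
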