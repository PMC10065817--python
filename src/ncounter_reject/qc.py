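"""Per-lane quality control: metrics, flag windows, and exclusion rules.

Metrics mirror the digital analyzer's default flagging: imaging (fraction
of fields of view counted), binding density (reporter spots/um^2),
positive-control linearity (R^2 of log2 count on log2 spike concentration),
limit of detection (the 0.5 fM positive against negative-control
background), and the two per-sample normalization factors (positive-control
technical factor, reference-gene content factor) with their acceptance
windows.

Exclusion follows the study rules: a sample is dropped when a normalization
factor leaves its window, when the reference-gene geometric mean falls
under 30 counts, or when imaging / detection fail.  An out-of-window
binding density alone does not exclude when positive-control linearity and
both correction factors pass (the binding-density exception); it is flagged
either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import geomean, sample_sd
from .panelio import CountMatrix, PanelDefinition


class EmptyCohortError(ValueError):
    """Every sample failed QC."""


@dataclass(frozen=True)
class QCThresholds:
    fov_pass_ratio: float = 0.75
    binding_density_window: tuple[float, float] = (0.1, 2.25)
    pos_linearity_min_r2: float = 0.95
    lod_sd_multiplier: float = 2.0
    pos_norm_factor_window: tuple[float, float] = (0.1, 2.0)
    content_norm_factor_window: tuple[float, float] = (0.1, 8.0)
    refgene_geomean_min_counts: float = 30.0
    lod_excludes: bool = True

    def __post_init__(self):
        for lo, hi in (self.binding_density_window, self.pos_norm_factor_window,
                       self.content_norm_factor_window):
            if not lo < hi:
                raise ValueError("threshold windows must be nonempty")
        if self.lod_sd_multiplier <= 0 or not 0 < self.fov_pass_ratio <= 1:
            raise ValueError("multipliers must be positive, pass ratio in (0,1]")


@dataclass
class QCFlagReport:
    """Per-sample QC metrics, flags and exclusion decisions."""

    table: pd.DataFrame  # indexed by sample_id
    thresholds: QCThresholds
    flags: dict[str, set[str]] = field(default_factory=dict)
    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def excluded_samples(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])

    @property
    def passing_samples(self) -> list[str]:
        return list(self.table.index[~self.table["excluded"]])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["flags"] = [";".join(sorted(self.flags[s])) for s in out.index]
        out["reasons"] = [";".join(self.reasons[s]) for s in out.index]
        out.to_csv(path)


def pos_control_linearity(counts, panel: PanelDefinition) -> float:
    """R^2 of the log2(count) ~ log2(concentration fM) positive-control fit.

    Degenerate fits (all positive counts equal, or no variance after the
    zero-protection pseudocount) return 0.0.
    """
    conc = panel.positive_concentrations()
    y = np.asarray([counts[pid] for pid in conc.index], dtype=float)
    if len(conc) < 3:
        raise ValueError("need >=3 positive probes for a linearity fit")
    if np.all(y == y[0]):
        return 0.0
    y = np.maximum(y, 0.5)  # guard log2 against zero counts
    logy = np.log2(y)
    if np.allclose(logy, logy[0]):
        return 0.0
    fit = stats.linregress(np.log2(conc.values), logy)
    return float(fit.rvalue**2)


def limit_of_detection(counts, panel: PanelDefinition,
                       thresholds: QCThresholds = QCThresholds()) -> bool:
    """True iff the 0.5 fM positive clears negative mean + k*SD (sample SD)."""
    conc = panel.positive_concentrations()
    half_fm = [pid for pid in conc.index if conc[pid] == 0.5]
    if not half_fm:
        raise ValueError("panel has no 0.5 fM positive probe for the LOD rule")
    neg = np.asarray([counts[pid] for pid in panel.ids_of("Negative")], dtype=float)
    cutoff = float(np.mean(neg)) + thresholds.lod_sd_multiplier * sample_sd(neg)
    return float(counts[half_fm[0]]) >= cutoff


def norm_factors(matrix: CountMatrix, probe_ids: list[str]) -> pd.Series:
    """Per-sample factor = mean over samples of probe geomeans / sample geomean.

    Scaling each sample's values by its factor equalizes the probe-set
    geometric mean across samples while conserving the cohort mean level.
    """
    gms = {}
    for sid in matrix.values.columns:
        col = matrix.values.loc[probe_ids, sid].astype(float)
        if (col <= 0).any():
            raise ValueError(f"sample {sid}: zero count among normalization probes")
        gms[sid] = geomean(col)
    gms = pd.Series(gms)
    return gms.mean() / gms


def technical_norm_factor(matrix: CountMatrix) -> pd.Series:
    """Positive-control (technical variation) correction factor per sample."""
    return norm_factors(matrix, matrix.panel.ids_of("Positive"))


def content_norm_factor(matrix: CountMatrix,
                        ref_candidates: list[str] | None = None) -> pd.Series:
    """Reference-gene (RNA input) correction factor per sample.

    For QC this uses all declared Housekeeping probes; reference selection
    (geNorm) later refines which genes actually normalize the data.
    """
    probe_ids = ref_candidates or matrix.panel.ids_of("Housekeeping")
    return norm_factors(matrix, probe_ids)


def refgene_geomean(matrix: CountMatrix,
                    ref_candidates: list[str] | None = None) -> pd.Series:
    probe_ids = ref_candidates or matrix.panel.ids_of("Housekeeping")
    vals = matrix.values.loc[probe_ids].astype(float).clip(lower=1e-9)
    return pd.Series(
        {sid: geomean(vals[sid]) for sid in vals.columns}, name="refgene_geomean"
    )


def lane_qc(
    matrix: CountMatrix,
    ref_candidates: list[str] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCFlagReport:
    """Compute all lane metrics and decide exclusions.

    Decisions depend only on each sample's own metrics plus cohort-level
    normalization-factor means, and are invariant to sample order.
    """
    t = thresholds
    panel = matrix.panel
    pos_f = technical_norm_factor(matrix)
    content_f = content_norm_factor(matrix, ref_candidates)
    ref_gm = refgene_geomean(matrix, ref_candidates)

    rows, flags, reasons = {}, {}, {}
    for sid in matrix.values.columns:
        counts = matrix.values[sid]
        attrs = matrix.samples.loc[sid]
        fov_ratio = attrs["fov_counted"] / attrs["fov_attempted"]
        bd = float(attrs["binding_density"])
        r2 = pos_control_linearity(counts, panel)
        lod = limit_of_detection(counts, panel, t)

        f: set[str] = set()
        why: list[str] = []
        if fov_ratio < t.fov_pass_ratio:
            f.add("fov")
            why.append(f"FOV ratio {fov_ratio:.3f} < {t.fov_pass_ratio}")
        bd_out = not t.binding_density_window[0] <= bd <= t.binding_density_window[1]
        if bd_out:
            f.add("binding_density")
        if r2 <= t.pos_linearity_min_r2:
            f.add("pos_linearity")
        if not lod:
            f.add("lod")
            if t.lod_excludes:
                why.append("0.5 fM positive below negative-control LOD")
        pf, cf = float(pos_f[sid]), float(content_f[sid])
        pf_ok = t.pos_norm_factor_window[0] <= pf <= t.pos_norm_factor_window[1]
        cf_ok = t.content_norm_factor_window[0] <= cf <= t.content_norm_factor_window[1]
        if not pf_ok:
            f.add("pos_norm_factor")
            why.append(f"positive-control factor {pf:.3f} outside "
                       f"{t.pos_norm_factor_window}")
        if not cf_ok:
            f.add("content_norm_factor")
            why.append(f"reference-gene factor {cf:.3f} outside "
                       f"{t.content_norm_factor_window}")
        if ref_gm[sid] < t.refgene_geomean_min_counts:
            f.add("refgene_geomean")
            why.append(f"reference geomean {ref_gm[sid]:.1f} < "
                       f"{t.refgene_geomean_min_counts:g}")
        if bd_out:
            # exception: accepted when linearity and both factors pass
            if not (r2 > t.pos_linearity_min_r2 and pf_ok and cf_ok):
                why.append(f"binding density {bd:.3f} outside "
                           f"{t.binding_density_window}")

        rows[sid] = {
            "fov_ratio": float(fov_ratio),
            "binding_density": bd,
            "pos_r2": r2,
            "lod_pass": lod,
            "pos_norm_factor": pf,
            "content_norm_factor": cf,
            "refgene_geomean": float(ref_gm[sid]),
            "excluded": bool(why),
        }
        flags[sid], reasons[sid] = f, why

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    table = table.loc[matrix.values.columns]
    return QCFlagReport(table=table, thresholds=t, flags=flags, reasons=reasons)


def filter_samples(matrix: CountMatrix, report: QCFlagReport) -> CountMatrix:
    """Drop excluded samples, preserving survivor order."""
    missing = set(matrix.values.columns) - set(report.table.index)
    if missing:
        raise ValueError(f"report does not cover samples: {sorted(missing)[:5]}")
    keep = [s for s in matrix.values.columns if not report.table.loc[s, "excluded"]]
    if not keep:
        raise EmptyCohortError("all samples excluded by QC")
    return matrix.subset_samples(keep)
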