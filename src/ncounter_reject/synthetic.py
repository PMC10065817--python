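"""Synthetic nCounter cohorts with known ground truth.

Emulates a three-group kidney-transplant biopsy cohort (NoRejection,
BLorTCMR, AMR) assayed on a large discovery panel and a small AMR-focused
panel: negative-binomial endogenous counts with group-specific log2 shifts,
housekeeping genes in stability tiers (no group effect), positive controls
linear in spike-in concentration, Poisson negative-control background, and
deterministically injectable lane-QC failures.  Everything is a pure
function of the spec's seed, so a run can be reproduced byte for byte.

The generator models RNA-input variation (a per-sample biological size
factor on endogenous + housekeeping probes) separately from lane technical
variation (a factor on every probe including positives); positive-control
normalization can therefore correct the latter and reference-gene
normalization the former, as on the real platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import derive_seed, geomean
from .panelio import (
    DIAGNOSES,
    CountMatrix,
    LaneRecord,
    PanelDefinition,
    ProbeRecord,
    SampleMeta,
    assemble_matrix,
    write_panel_csv,
    write_rcc,
    write_sample_sheet,
)

QC_FAILURE_MODES = (
    "low_fov",
    "high_binding_density",
    "low_binding_density",
    "flat_positives",
    "low_refs",
)

_GROUP_PREFIX = {"NoRejection": "NR", "BLorTCMR": "BT", "AMR": "AMR"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated cohort/panel.

    ``group_effects`` maps a diagnosis to per-gene-symbol log2 shifts
    relative to the cohort baseline; a gene absent from every map is null.
    ``housekeeping_cv_tiers`` assigns a biological coefficient of variation
    to each housekeeping gene in order (tiers of decreasing stability).
    ``qc_failures`` maps sample ids to a failure mode injected after
    generation.
    """

    panel_name: str = "SynthPanel"
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NoRejection": 32, "BLorTCMR": 32, "AMR": 32}
    )
    n_endogenous: int = 758
    n_housekeeping: int = 12
    n_positive: int = 6
    n_negative: int = 8
    positive_concentrations_fM: tuple[float, ...] = (128, 32, 8, 2, 0.5, 0.125)
    positive_scale_counts_per_fM: float = 200.0
    size_factor_log2_sd: float = 0.25
    technical_log2_sd: float = 0.1
    dispersion: float = 0.08
    baseline_log2_mean_range: tuple[float, float] = (4.0, 10.0)
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    housekeeping_cv_tiers: tuple[float, ...] = (
        0.05, 0.05, 0.05, 0.08, 0.08, 0.08, 0.12, 0.12, 0.2, 0.2, 0.3, 0.3,
    )
    background_mean: float = 5.0
    #: effect-carrying genes get baselines at or above this level: disease
    #: signature content on curated panels is chosen to be reliably detected
    effect_baseline_min_log2: float = 6.0
    fov_attempted: int = 490
    gene_symbols: tuple[str, ...] | None = None
    qc_failures: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_housekeeping < 2 or self.n_negative < 2:
            raise ValueError("need >=2 housekeeping and >=2 negative probes")
        if self.n_positive < 2 or len(self.positive_concentrations_fM) != self.n_positive:
            raise ValueError("positive concentrations must match n_positive (>=2)")
        if len(set(self.positive_concentrations_fM)) != self.n_positive:
            raise ValueError("positive concentrations must be distinct")
        if len(self.housekeeping_cv_tiers) < self.n_housekeeping:
            raise ValueError("need one CV tier per housekeeping gene")
        if self.gene_symbols is not None and len(self.gene_symbols) != self.n_endogenous:
            raise ValueError("gene_symbols length must equal n_endogenous")
        symbols = set(self.symbols())
        for shifts in self.group_effects.values():
            unknown = set(shifts) - symbols
            if unknown:
                raise ValueError(f"effect genes not in panel: {sorted(unknown)[:5]}")
        for sid, mode in self.qc_failures.items():
            if mode not in QC_FAILURE_MODES:
                raise ValueError(f"unknown QC failure mode {mode!r} for {sid}")
        for grp in self.n_per_group:
            if grp not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {grp!r}")

    def symbols(self) -> tuple[str, ...]:
        if self.gene_symbols is not None:
            return tuple(self.gene_symbols)
        return tuple(f"G{i:04d}" for i in range(1, self.n_endogenous + 1))

    def housekeeping_symbols(self) -> tuple[str, ...]:
        return tuple(f"HK{i:02d}" for i in range(1, self.n_housekeeping + 1))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    #: comparison "A_vs_B" -> gene_symbol -> signed log2 effect (A relative to B)
    true_de_genes: dict[str, dict[str, float]]
    #: housekeeping symbols ordered most-stable first (ascending CV), with CVs
    reference_ranking: tuple[tuple[str, float], ...]
    #: sample_id -> injected failure mode
    qc_failures: dict[str, str]


def _comparisons() -> list[tuple[str, str]]:
    return [("AMR", "NoRejection"), ("AMR", "BLorTCMR"), ("BLorTCMR", "NoRejection")]


def build_panel(spec: SyntheticSpec) -> PanelDefinition:
    probes = []
    for sym in spec.symbols():
        probes.append(ProbeRecord(f"{spec.panel_name}_{sym}", sym, "Endogenous"))
    for i, sym in enumerate(spec.housekeeping_symbols()):
        probes.append(ProbeRecord(f"{spec.panel_name}_{sym}", sym, "Housekeeping"))
    for i, conc in enumerate(spec.positive_concentrations_fM):
        letter = chr(ord("A") + i)
        probes.append(
            ProbeRecord(f"{spec.panel_name}_POS_{letter}", f"POS_{letter}",
                        "Positive", float(conc))
        )
    for i in range(spec.n_negative):
        letter = chr(ord("A") + i)
        probes.append(
            ProbeRecord(f"{spec.panel_name}_NEG_{letter}", f"NEG_{letter}", "Negative")
        )
    return PanelDefinition(spec.panel_name, tuple(probes))


def _symbol_uniform(symbol: str) -> float:
    """Deterministic uniform(0,1) draw keyed by gene symbol."""
    import hashlib

    digest = hashlib.sha256(symbol.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2.0**64


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial draws with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[LaneRecord], PanelDefinition, list[SampleMeta], GroundTruth]:
    """Simulate one cohort on one panel.

    Endogenous probe counts are negative binomial with mean
    ``technical_i * size_i * 2**(baseline_g + shift_{g,group(i)})``;
    housekeeping probes get lognormal biological noise at their tier CV and
    no group effect; positives are linear in spike concentration; negatives
    are Poisson background.  Identical specs produce identical output.
    """
    spec.validate()
    panel = build_panel(spec)
    rng = np.random.default_rng(spec.seed)

    metadata: list[SampleMeta] = []
    for grp in ("NoRejection", "BLorTCMR", "AMR"):
        for i in range(spec.n_per_group.get(grp, 0)):
            sid = f"{_GROUP_PREFIX[grp]}{i + 1:02d}"
            center = "CenterA" if i % 2 == 0 else "CenterB"
            metadata.append(SampleMeta(sid, grp, center))
    n = len(metadata)
    if n == 0:
        raise ValueError("empty cohort")

    symbols = spec.symbols()
    # baselines are a pure function of the gene symbol so that the same
    # transcript has the same abundance on every panel assaying it
    lo, hi = spec.baseline_log2_mean_range
    effect_syms = set().union(*spec.group_effects.values()) if spec.group_effects else set()
    eff_lo = min(max(lo, spec.effect_baseline_min_log2), hi - 1.0)
    baseline = np.array(
        [
            (eff_lo if s in effect_syms else lo)
            + _symbol_uniform(s) * (hi - (eff_lo if s in effect_syms else lo))
            for s in symbols
        ]
    )
    hk_lo = max(lo, 6.0)
    hk_baseline = np.array(
        [hk_lo + _symbol_uniform(s) * (hi - hk_lo)
         for s in spec.housekeeping_symbols()]
    )

    shift = np.zeros((len(symbols), n))
    for j, meta in enumerate(metadata):
        eff = spec.group_effects.get(meta.diagnosis, {})
        for g, sym in enumerate(symbols):
            if sym in eff:
                shift[g, j] = eff[sym]

    size_f = 2.0 ** rng.normal(0.0, spec.size_factor_log2_sd, size=n)
    tech_f = 2.0 ** rng.normal(0.0, spec.technical_log2_sd, size=n)

    endo_mean = tech_f * size_f * 2.0 ** (baseline[:, None] + shift)
    endo = _nb_counts(rng, endo_mean, spec.dispersion)

    cvs = np.asarray(spec.housekeeping_cv_tiers[: spec.n_housekeeping], dtype=float)
    s_ln = np.sqrt(np.log1p(cvs**2))  # lognormal sigma giving the tier CV
    hk_noise = np.exp(rng.normal(0.0, 1.0, size=(spec.n_housekeeping, n)) * s_ln[:, None])
    hk_mean = tech_f * size_f * (2.0 ** hk_baseline[:, None]) * hk_noise
    hk = rng.poisson(hk_mean)

    conc = np.asarray(spec.positive_concentrations_fM, dtype=float)
    pos_noise = np.exp(rng.normal(0.0, 0.05, size=(spec.n_positive, n)))
    pos_mean = tech_f * spec.positive_scale_counts_per_fM * conc[:, None] * pos_noise
    pos = rng.poisson(pos_mean)

    neg = rng.poisson(spec.background_mean, size=(spec.n_negative, n))

    counts_block = np.vstack([endo, hk, pos, neg])
    probe_ids = panel.probe_ids

    fov_counted = spec.fov_attempted - rng.integers(0, 25, size=n)
    binding = rng.uniform(0.6, 2.0, size=n)

    lanes: list[LaneRecord] = []
    for j, meta in enumerate(metadata):
        lane = LaneRecord(
            sample_id=meta.sample_id,
            fov_attempted=spec.fov_attempted,
            fov_counted=int(fov_counted[j]),
            binding_density=round(float(binding[j]), 4),
            counts={pid: int(counts_block[g, j]) for g, pid in enumerate(probe_ids)},
        )
        if meta.sample_id in spec.qc_failures:
            lane = inject_qc_failure(lane, panel, spec.qc_failures[meta.sample_id])
        lanes.append(lane)

    true_de: dict[str, dict[str, float]] = {}
    for a, b in _comparisons():
        eff_a = spec.group_effects.get(a, {})
        eff_b = spec.group_effects.get(b, {})
        diff = {
            sym: eff_a.get(sym, 0.0) - eff_b.get(sym, 0.0)
            for sym in set(eff_a) | set(eff_b)
            if eff_a.get(sym, 0.0) != eff_b.get(sym, 0.0)
        }
        true_de[f"{a}_vs_{b}"] = diff
    ranking = tuple(
        sorted(zip(spec.housekeeping_symbols(), cvs.tolist()), key=lambda t: (t[1], t[0]))
    )
    truth = GroundTruth(
        true_de_genes=true_de,
        reference_ranking=ranking,
        qc_failures=dict(spec.qc_failures),
    )
    return lanes, panel, metadata, truth


def inject_qc_failure(lane: LaneRecord, panel: PanelDefinition, mode: str) -> LaneRecord:
    """Return a copy of ``lane`` deterministically violating one QC criterion."""
    if mode not in QC_FAILURE_MODES:
        raise ValueError(f"unknown QC failure mode {mode!r}")
    if mode == "low_fov":
        return dataclasses.replace(lane, fov_counted=int(0.5 * lane.fov_attempted))
    if mode == "high_binding_density":
        return dataclasses.replace(lane, binding_density=2.6)
    if mode == "low_binding_density":
        return dataclasses.replace(lane, binding_density=0.05)
    counts = dict(lane.counts)
    if mode == "flat_positives":
        for pid in panel.ids_of("Positive"):
            counts[pid] = 50
        return dataclasses.replace(lane, counts=counts)
    # low_refs: scale housekeeping counts so their geometric mean falls to ~20
    hk_ids = panel.ids_of("Housekeeping")
    gm = geomean([max(lane.counts[p], 1) for p in hk_ids])
    scale = 20.0 / gm
    for pid in hk_ids:
        counts[pid] = max(int(round(lane.counts[pid] * scale)), 1)
    return dataclasses.replace(lane, counts=counts)


# ---------------------------------------------------------------------------
# Presets


def fast_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Small preset (10/10/10 samples, 60 genes) for quick runs and tests."""
    effects = {f"G{i:04d}": 1.5 for i in range(1, 21)}
    kwargs = dict(
        panel_name="FastPanel",
        n_per_group={"NoRejection": 10, "BLorTCMR": 10, "AMR": 10},
        n_endogenous=60,
        n_housekeeping=6,
        n_negative=6,
        housekeeping_cv_tiers=(0.05, 0.05, 0.05, 0.12, 0.2, 0.3),
        group_effects={"AMR": effects},
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def bhot_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Large-panel preset: ~758 endogenous + 12 reference genes, 32/32/32 cohort."""
    effects_amr = {f"G{i:04d}": (1.5 if i % 2 else -1.5) for i in range(1, 81)}
    effects_tcmr = {f"G{i:04d}": (1.2 if i % 2 else -1.2) for i in range(61, 121)}
    kwargs = dict(
        panel_name="BHOTLike",
        group_effects={"AMR": effects_amr, "BLorTCMR": effects_tcmr},
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def elements_like_spec(seed: int = 1, parent: SyntheticSpec | None = None,
                       **overrides) -> SyntheticSpec:
    """Small-panel preset: 90 endogenous + 6 reference genes.

    Gene symbols are a subset of the large panel's so a classifier trained
    on one panel can be transferred to the other by symbol; counts are an
    independent realization (a re-assay of the same cohort design).
    """
    if parent is None:
        parent = bhot_like_spec()
    # enrich for AMR-effect genes, as an AMR-focused custom panel would
    amr_genes = sorted(parent.group_effects.get("AMR", {}))[:60]
    other = [s for s in parent.symbols() if s not in set(amr_genes)][:30]
    symbols = tuple(sorted(amr_genes + other))
    effects = {
        grp: {s: e for s, e in eff.items() if s in set(symbols)}
        for grp, eff in parent.group_effects.items()
    }
    kwargs = dict(
        panel_name="ElementsLike",
        n_per_group=dict(parent.n_per_group),
        n_endogenous=len(symbols),
        n_housekeeping=6,
        n_negative=6,
        housekeeping_cv_tiers=(0.05, 0.05, 0.05, 0.12, 0.2, 0.3),
        gene_symbols=symbols,
        group_effects=effects,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


# ---------------------------------------------------------------------------
# Disk round trip


def write_dataset(out_dir, lanes, panel, metadata, truth: GroundTruth) -> None:
    """Write RCC files, panel CSV, sample sheet and ground-truth JSON."""
    out = Path(out_dir)
    (out / "rcc").mkdir(parents=True, exist_ok=True)
    for lane in lanes:
        write_rcc(lane, panel, out / "rcc" / f"{lane.sample_id}.RCC")
    write_panel_csv(panel, out / "panel.csv")
    write_sample_sheet(metadata, out / "samples.csv")
    payload = {
        "true_de_genes": truth.true_de_genes,
        "reference_ranking": [[s, cv] for s, cv in truth.reference_ranking],
        "qc_failures": truth.qc_failures,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def generate_matrix(spec: SyntheticSpec) -> tuple[CountMatrix, GroundTruth]:
    """Generate and assemble in one step (no files touched)."""
    lanes, panel, metadata, truth = generate_dataset(spec)
    return assemble_matrix(lanes, panel, metadata), truth
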