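import numpy as np
import pandas as pd
import pytest

import ncounter_reject as nr
from ncounter_reject.panelio import (
    CountMatrix,
    LaneRecord,
    PanelDefinition,
    ProbeRecord,
    SampleMeta,
    assemble_matrix,
)
from ncounter_reject.synthetic import fast_spec, generate_matrix


def toy_panel(name="ToyPanel", n_endo=3, n_hk=2, n_neg=4) -> PanelDefinition:
    """Small hand-buildable panel: endogenous + housekeeping + 6 pos + negatives."""
    concs = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
    probes = (
        [ProbeRecord(f"E{i}", f"GENE{i}", "Endogenous") for i in range(1, n_endo + 1)]
        + [ProbeRecord(f"H{i}", f"HK{i}", "Housekeeping") for i in range(1, n_hk + 1)]
        + [
            ProbeRecord(f"P{i}", f"POS_{chr(64 + i)}", "Positive", c)
            for i, c in enumerate(concs, start=1)
        ]
        + [ProbeRecord(f"N{i}", f"NEG_{chr(64 + i)}", "Negative") for i in range(1, n_neg + 1)]
    )
    return PanelDefinition(name, tuple(probes))


def make_lane(panel, sample_id="S1", fov=(490, 480), binding_density=1.2,
              overrides=None, base=100):
    """A clean lane: proportional positives, low negatives, constant content."""
    counts = {}
    for p in panel.probes:
        if p.code_class == "Positive":
            counts[p.probe_id] = int(round(200 * p.concentration_fM)) or 1
        elif p.code_class == "Negative":
            counts[p.probe_id] = 5
        else:
            counts[p.probe_id] = base
    if overrides:
        counts.update(overrides)
    return LaneRecord(sample_id, fov[0], fov[1], binding_density, counts)


def matrix_from_lanes(panel, lanes, diagnoses=None):
    diagnoses = diagnoses or ["NoRejection"] * len(lanes)
    metadata = [
        SampleMeta(lane.sample_id, dx, "CenterA")
        for lane, dx in zip(lanes, diagnoses)
    ]
    return assemble_matrix(lanes, panel, metadata)


def background_toy():
    """6 endogenous probes x 4 samples with hand-evaluated detection calls.

    Per-sample backgrounds (negative mean + 2 sample SD): 12.16, 5, 10.16, 15
    -> study threshold T = 2 * 15 = 30.  With n = 4 a probe needs >= 2
    samples below T for exclusion: E2 (2 below), E4 (3), E6 (4) go;
    E3 (1 below) and E5 (all exactly 30, not below) stay; H1 sits at 25
    everywhere so it is flagged but, as a reference candidate, retained.
    """
    panel = toy_panel(n_endo=6, n_hk=2, n_neg=4)
    negatives = {
        "S1": [4, 6, 8, 10],
        "S2": [5, 5, 5, 5],
        "S3": [2, 4, 6, 8],
        "S4": [10, 10, 10, 14],
    }
    endo = {
        "E1": [100, 100, 100, 100],
        "E2": [10, 10, 100, 100],
        "E3": [29, 31, 35, 40],
        "E4": [5, 8, 31, 29],
        "E5": [30, 30, 30, 30],
        "E6": [1, 2, 3, 4],
    }
    hk = {"H1": [25, 25, 25, 25], "H2": [200, 210, 190, 205]}
    lanes = []
    for j, sid in enumerate(["S1", "S2", "S3", "S4"]):
        overrides = {pid: vals[j] for pid, vals in {**endo, **hk}.items()}
        overrides.update(
            {f"N{i + 1}": c for i, c in enumerate(negatives[sid])}
        )
        lanes.append(make_lane(panel, sample_id=sid, overrides=overrides))
    matrix = matrix_from_lanes(panel, lanes)
    expected = {
        "threshold": 30.0,
        "excluded": ["E2", "E4", "E6"],
        "flagged_hk": ["H1"],
    }
    return matrix, expected


def make_norm(values_by_gene, diagnoses):
    """Build a NormalizedMatrix directly from per-gene value lists.

    ``values_by_gene`` maps gene index (1-based, -> probe E<i>/symbol
    GENE<i>) to a list of per-sample values; all control probes get
    constant filler.
    """
    from ncounter_reject.refnorm import NormalizedMatrix

    n_genes = len(values_by_gene)
    n_samples = len(next(iter(values_by_gene.values())))
    panel = toy_panel(n_endo=n_genes, n_hk=2, n_neg=4)
    sids = [f"S{i}" for i in range(n_samples)]
    rows = {}
    for i, vals in values_by_gene.items():
        rows[f"E{i}"] = list(map(float, vals))
    for pid in panel.ids_of("Housekeeping"):
        rows[pid] = [100.0] * n_samples
    for p in panel.probes:
        if p.code_class == "Positive":
            rows[p.probe_id] = [200.0 * p.concentration_fM] * n_samples
        elif p.code_class == "Negative":
            rows[p.probe_id] = [5.0] * n_samples
    values = pd.DataFrame(rows, index=sids).T.loc[panel.probe_ids]
    samples = pd.DataFrame(
        {
            "diagnosis": diagnoses,
            "center": ["CenterA"] * n_samples,
            "fov_attempted": [490] * n_samples,
            "fov_counted": [480] * n_samples,
            "binding_density": [1.2] * n_samples,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    ones = pd.Series(1.0, index=sids)
    return NormalizedMatrix(
        panel=panel,
        samples=samples,
        values=values,
        pos_factors=ones,
        content_factors=ones.copy(),
        references_used=panel.ids_of("Housekeeping"),
    )


@pytest.fixture(scope="session")
def panel():
    return toy_panel()


@pytest.fixture(scope="session")
def fast_bundle():
    """Fast synthetic cohort taken through QC, background filter, normalization."""
    matrix, truth = generate_matrix(fast_spec(seed=11))
    report = nr.lane_qc(matrix)
    kept = nr.filter_samples(matrix, report)
    bg = nr.apply_probe_filter(kept)
    gn = nr.genorm_rank(bg.kept_matrix)
    norm = nr.normalize(bg.kept_matrix, gn.selected_references)
    return {
        "matrix": matrix,
        "truth": truth,
        "qc_report": report,
        "background": bg,
        "genorm": gn,
        "norm": norm,
    }
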