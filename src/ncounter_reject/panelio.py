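"""Reading and writing nCounter lane files, panel definitions and sample sheets.

The lane format is the sectioned-CSV RCC dialect exported by the digital
analyzer: ``<Header>``, ``<Sample_Attributes>``, ``<Lane_Attributes>`` and
``<Code_Summary>`` blocks, the last carrying one ``CodeClass,Name,Accession,
Count`` row per probe.  Probe identity is the accession (probe id), not the
gene symbol: the same transcript can carry different probe ids on different
panels, and cross-panel work maps through gene symbols explicitly.

Quoted and unquoted fields are both accepted; unknown sections are carried
through a read/write round trip untouched.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import format_float

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")
DIAGNOSES = ("NoRejection", "BLorTCMR", "AMR")

#: per-sample lane attributes carried into the assembled matrix for QC
LANE_ATTR_COLUMNS = ("fov_attempted", "fov_counted", "binding_density")


class RCCFormatError(ValueError):
    """A lane file does not conform to the sectioned RCC layout."""


class ConsistencyError(ValueError):
    """Inputs that should describe the same panel/cohort disagree."""


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    gene_symbol: str
    code_class: str
    concentration_fM: float | None = None

    def __post_init__(self):
        if self.code_class not in CODE_CLASSES:
            raise ValueError(f"unknown code class {self.code_class!r}")
        if (self.concentration_fM is not None) != (self.code_class == "Positive"):
            raise ValueError(
                f"probe {self.probe_id}: concentration_fM must be present "
                "iff code_class is Positive"
            )
        if self.concentration_fM is not None and self.concentration_fM < 0:
            raise ValueError(f"probe {self.probe_id}: negative concentration")


@dataclass(frozen=True)
class PanelDefinition:
    """A probe set: endogenous content plus housekeeping and ERCC-style controls."""

    name: str
    probes: tuple[ProbeRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "probes", tuple(self.probes))
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"panel {self.name}: duplicate probe ids")
        if len(self.ids_of("Housekeeping")) < 2:
            raise ValueError(f"panel {self.name}: need >=2 Housekeeping probes")
        pos = [p for p in self.probes if p.code_class == "Positive"]
        if len(pos) < 2 or len({p.concentration_fM for p in pos}) < len(pos):
            raise ValueError(
                f"panel {self.name}: need >=2 Positive probes with distinct "
                "concentrations"
            )
        if len(self.ids_of("Negative")) < 2:
            raise ValueError(f"panel {self.name}: need >=2 Negative probes")

    def ids_of(self, code_class: str) -> list[str]:
        return [p.probe_id for p in self.probes if p.code_class == code_class]

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def probe(self, probe_id: str) -> ProbeRecord:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def symbol_map(self) -> dict[str, str]:
        """probe_id -> gene_symbol."""
        return {p.probe_id: p.gene_symbol for p in self.probes}

    def positive_concentrations(self) -> pd.Series:
        """fM concentration per Positive probe id, descending."""
        s = pd.Series(
            {p.probe_id: p.concentration_fM for p in self.probes
             if p.code_class == "Positive"},
            dtype=float,
        )
        return s.sort_values(ascending=False)


@dataclass(frozen=True)
class LaneRecord:
    """One cartridge lane: imaging/saturation attributes plus raw probe counts."""

    sample_id: str
    fov_attempted: int
    fov_counted: int
    binding_density: float
    counts: dict[str, int]
    extra_sections: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.fov_attempted <= 0:
            raise ValueError("fov_attempted must be positive")
        if not 0 <= self.fov_counted <= self.fov_attempted:
            raise ValueError("fov_counted must lie in [0, fov_attempted]")
        if self.binding_density < 0:
            raise ValueError("binding_density must be nonnegative")
        for pid, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for probe {pid}")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    diagnosis: str
    center: str

    def __post_init__(self):
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")


@dataclass
class CountMatrix:
    """Probes x samples expression values with panel and sample annotation.

    ``values`` is a DataFrame indexed by probe_id with one column per
    sample_id; ``samples`` is a DataFrame indexed by sample_id carrying
    diagnosis, center and the lane attributes needed by QC.  ``stage_tag``
    tracks how far through processing the values are (raw counts are
    integers; every later stage is real-valued).
    """

    panel: PanelDefinition
    samples: pd.DataFrame
    values: pd.DataFrame
    stage_tag: str = "raw"

    def __post_init__(self):
        if list(self.values.columns) != list(self.samples.index):
            raise ConsistencyError("value columns must match sample sheet order")
        if (np.asarray(self.values.values, dtype=float) < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.values.isna().any().any():
            raise ValueError("missing entries are not allowed")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_values(self, code_class: str) -> pd.DataFrame:
        return self.values.loc[self.panel.ids_of(code_class)]

    def sample_ids_for(self, diagnosis: str) -> list[str]:
        return list(self.samples.index[self.samples["diagnosis"] == diagnosis])

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            panel=self.panel,
            samples=self.samples.loc[sample_ids].copy(),
            values=self.values[sample_ids].copy(),
            stage_tag=self.stage_tag,
        )

    def subset_probes(self, probe_ids: list[str]) -> "CountMatrix":
        keep = set(probe_ids)
        panel = PanelDefinition(
            self.panel.name, tuple(p for p in self.panel.probes if p.probe_id in keep)
        )
        return CountMatrix(
            panel=panel,
            samples=self.samples.copy(),
            values=self.values.loc[panel.probe_ids].copy(),
            stage_tag=self.stage_tag,
        )


# ---------------------------------------------------------------------------
# RCC lane files

_REQUIRED_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")


def _split_sections(text: str, path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped and current is None:
            continue
        if stripped.startswith("<") and stripped.endswith(">"):
            tag = stripped[1:-1]
            if tag.startswith("/"):
                current = None
            else:
                current = tag
                sections.setdefault(current, [])
            continue
        if current is not None:
            sections[current].append(line)
    for name in _REQUIRED_SECTIONS:
        if name not in sections:
            raise RCCFormatError(f"{path}: missing <{name}> section")
    return sections


def _parse_csv_line(line: str) -> list[str]:
    # csv handles both quoted and unquoted dialects
    return next(csv.reader(io.StringIO(line)))


def _attrs(lines: list[str]) -> dict[str, str]:
    out = {}
    for line in lines:
        if not line.strip():
            continue
        fields = _parse_csv_line(line)
        out[fields[0]] = fields[1] if len(fields) > 1 else ""
    return out


def read_rcc(path) -> LaneRecord:
    """Parse one RCC lane file into a :class:`LaneRecord`."""
    with open(path, newline="") as fh:
        sections = _split_sections(fh.read(), path)

    sample_attrs = _attrs(sections["Sample_Attributes"])
    lane_attrs = _attrs(sections["Lane_Attributes"])
    counts: dict[str, int] = {}
    rows = sections["Code_Summary"]
    if not rows:
        raise RCCFormatError(f"{path}: empty <Code_Summary> section")
    header = _parse_csv_line(rows[0])
    try:
        i_acc, i_count = header.index("Accession"), header.index("Count")
    except ValueError as err:
        raise RCCFormatError(f"{path}: Code_Summary header lacks {err}") from None
    for rownum, line in enumerate(rows[1:], start=2):
        if not line.strip():
            continue
        fields = _parse_csv_line(line)
        raw = fields[i_count]
        try:
            value = int(raw)
        except ValueError:
            raise ValueError(
                f"{path}: Code_Summary row {rownum}: non-integer count {raw!r}"
            ) from None
        if value < 0:
            raise ValueError(
                f"{path}: Code_Summary row {rownum}: negative count {value}"
            )
        counts[fields[i_acc]] = value

    extra = {
        name: tuple(lines)
        for name, lines in sections.items()
        if name not in _REQUIRED_SECTIONS
    }
    try:
        return LaneRecord(
            sample_id=sample_attrs["ID"],
            fov_attempted=int(lane_attrs["FovCount"]),
            fov_counted=int(lane_attrs["FovCounted"]),
            binding_density=float(lane_attrs["BindingDensity"]),
            counts=counts,
            extra_sections=extra,
        )
    except KeyError as err:
        raise RCCFormatError(f"{path}: missing lane attribute {err}") from None


def write_rcc(lane: LaneRecord, panel: PanelDefinition, path) -> None:
    """Emit ``lane`` as an RCC file; lossless under :func:`read_rcc`.

    The lane's counts must cover exactly the panel's probe ids.
    """
    lane_ids, panel_ids = set(lane.counts), set(panel.probe_ids)
    if lane_ids != panel_ids:
        missing = sorted(panel_ids - lane_ids)
        surplus = sorted(lane_ids - panel_ids)
        raise ConsistencyError(
            f"lane {lane.sample_id} does not match panel {panel.name}: "
            f"missing={missing[:5]} surplus={surplus[:5]}"
        )
    lines = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,4.0.0.3",
        "</Header>",
        "<Sample_Attributes>",
        f"ID,{lane.sample_id}",
        f"GeneRLF,{panel.name}",
        "</Sample_Attributes>",
        "<Lane_Attributes>",
        "ID,1",
        f"FovCount,{lane.fov_attempted}",
        f"FovCounted,{lane.fov_counted}",
        f"BindingDensity,{format_float(lane.binding_density)}",
        "</Lane_Attributes>",
        "<Code_Summary>",
        "CodeClass,Name,Accession,Count",
    ]
    for p in panel.probes:
        lines.append(f"{p.code_class},{p.gene_symbol},{p.probe_id},{lane.counts[p.probe_id]}")
    lines.append("</Code_Summary>")
    for name, body in lane.extra_sections.items():
        lines.append(f"<{name}>")
        lines.extend(body)
        lines.append(f"</{name}>")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Panel definitions and sample sheets (plain CSV)


def read_panel_csv(path) -> PanelDefinition:
    df = pd.read_csv(path, dtype={"probe_id": str, "gene_symbol": str})
    probes = []
    for _, row in df.iterrows():
        conc = row.get("concentration_fM")
        conc = None if pd.isna(conc) else float(conc)
        probes.append(
            ProbeRecord(row["probe_id"], row["gene_symbol"], row["code_class"], conc)
        )
    name = df["panel"].iloc[0] if "panel" in df.columns else "panel"
    return PanelDefinition(name, tuple(probes))


def write_panel_csv(panel: PanelDefinition, path) -> None:
    rows = [
        {
            "panel": panel.name,
            "probe_id": p.probe_id,
            "gene_symbol": p.gene_symbol,
            "code_class": p.code_class,
            "concentration_fM": "" if p.concentration_fM is None
            else format_float(p.concentration_fM),
        }
        for p in panel.probes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype=str)
    return [
        SampleMeta(row["sample_id"], row["diagnosis"], row["center"])
        for _, row in df.iterrows()
    ]


def write_sample_sheet(metadata: list[SampleMeta], path) -> None:
    pd.DataFrame(
        [{"sample_id": m.sample_id, "diagnosis": m.diagnosis, "center": m.center}
         for m in metadata]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------


def assemble_matrix(
    lanes: list[LaneRecord],
    panel: PanelDefinition,
    metadata: list[SampleMeta],
) -> CountMatrix:
    """Assemble lanes into a raw CountMatrix; column order follows metadata."""
    meta_ids = [m.sample_id for m in metadata]
    if len(set(meta_ids)) != len(meta_ids):
        raise ConsistencyError("duplicate sample_id in metadata")
    by_id: dict[str, LaneRecord] = {}
    for lane in lanes:
        if lane.sample_id in by_id:
            raise ConsistencyError(f"duplicate lane for sample {lane.sample_id}")
        by_id[lane.sample_id] = lane
    unmatched = sorted(set(by_id) - set(meta_ids))
    if unmatched:
        raise ConsistencyError(f"lanes without metadata: {unmatched[:5]}")
    missing = sorted(set(meta_ids) - set(by_id))
    if missing:
        raise ConsistencyError(f"metadata without lanes: {missing[:5]}")

    values = pd.DataFrame(
        {sid: [by_id[sid].counts[pid] for pid in panel.probe_ids] for sid in meta_ids},
        index=pd.Index(panel.probe_ids, name="probe_id"),
        dtype=int,
    )
    samples = pd.DataFrame(
        {
            "diagnosis": [m.diagnosis for m in metadata],
            "center": [m.center for m in metadata],
            "fov_attempted": [by_id[s].fov_attempted for s in meta_ids],
            "fov_counted": [by_id[s].fov_counted for s in meta_ids],
            "binding_density": [by_id[s].binding_density for s in meta_ids],
        },
        index=pd.Index(meta_ids, name="sample_id"),
    )
    return CountMatrix(panel=panel, samples=samples, values=values, stage_tag="raw")
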