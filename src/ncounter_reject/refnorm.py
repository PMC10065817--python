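"""Reference-gene stability ranking (geNorm) and two-step normalization.

geNorm scores each candidate reference gene by its mean pairwise variation:
``M_j = mean over k != j of SD_samples(log2 x_j - log2 x_k)`` — a gene that
keeps a constant ratio to every other candidate is stable (low M).  The
least stable gene is eliminated and M recomputed until two remain; the last
genes standing are the best references.  Because M is built from ratios it
is invariant to rescaling any sample's column.

Normalization is two multiplicative steps, each a per-sample factor of the
form ``mean over samples of probe-set geomeans / sample geomean``: first
the positive-control (technical) factor, then the reference-gene (RNA
input) factor computed on the technically corrected counts.  After content
normalization the reference-gene geometric mean is identical across
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import geomean
from .panelio import CountMatrix, PanelDefinition
from .qc import norm_factors, technical_norm_factor

GENORM_PSEUDOCOUNT = 0.5


@dataclass
class GeNormResult:
    """Stability values, elimination trace, and the selected reference set."""

    stability_M: dict[str, float]  # gene -> M at its elimination stage
    pairwise_variation: pd.DataFrame  # V_jk = SD over samples of log2(x_j/x_k)
    elimination_order: list[str]  # first removed -> last removed
    final_pair: tuple[str, str]
    ranking: list[str]  # most stable first (final pair, then reverse eliminations)
    selected_references: list[str]
    v_by_n: dict[int, float] = field(default_factory=dict)  # geNorm V(n/n+1)
    pseudocount_applied: bool = False


def _stability_m(log_values: pd.DataFrame) -> pd.Series:
    """M for every gene of a log2 candidate block (genes x samples)."""
    arr = log_values.values
    diffs = arr[:, None, :] - arr[None, :, :]
    sds = np.std(diffs, axis=2, ddof=1)
    m = sds.sum(axis=1) / (len(arr) - 1)  # mean over k != j (diagonal SD is 0)
    return pd.Series(m, index=log_values.index)


def genorm(values: pd.DataFrame, k: int = 3) -> GeNormResult:
    """Rank candidate reference genes by geNorm stability.

    ``values`` holds positive expression values, genes in rows.  Ties in M
    are broken lexicographically by row label.  Zero counts get a 0.5
    pseudocount (applied to the whole block, flagged in the result).
    """
    if values.shape[0] < 3:
        raise ValueError("geNorm needs >=3 candidate genes")
    if (values.values < 0).any():
        raise ValueError("negative expression values")
    pseudo = bool((values.values == 0).any())
    work = values.astype(float) + (GENORM_PSEUDOCOUNT if pseudo else 0.0)
    if (work.values <= 0).any():
        raise ValueError("nonpositive values after pseudocount")
    logs = np.log2(work)

    labels = list(values.index)
    arr = logs.values
    v = np.std(arr[:, None, :] - arr[None, :, :], axis=2, ddof=1)
    pairwise = pd.DataFrame(v, index=labels, columns=labels)

    stability: dict[str, float] = {}
    order: list[str] = []
    current = logs.copy()
    while current.shape[0] > 2:
        m = _stability_m(current)
        # deterministic: among ties on M, drop the lexicographically first label
        victim = sorted(m[np.isclose(m, m.max())].index)[0]
        stability[victim] = float(m[victim])
        order.append(victim)
        current = current.drop(index=victim)
    m_final = _stability_m(current)
    pair = tuple(sorted(current.index))
    for g in pair:
        stability[g] = float(m_final[g])

    ranking = list(pair) + list(reversed(order))
    if k > len(labels):
        raise ValueError(f"cannot select {k} references from {len(labels)} candidates")

    v_by_n: dict[int, float] = {}
    for n in range(2, len(ranking)):
        nf_n = logs.loc[ranking[:n]].mean(axis=0)  # log2 geomean of top n
        nf_n1 = logs.loc[ranking[: n + 1]].mean(axis=0)
        v_by_n[n] = float(np.std(nf_n - nf_n1, ddof=1))

    return GeNormResult(
        stability_M=stability,
        pairwise_variation=pairwise,
        elimination_order=order,
        final_pair=pair,  # type: ignore[arg-type]
        ranking=ranking,
        selected_references=ranking[:k],
        v_by_n=v_by_n,
        pseudocount_applied=pseudo,
    )


def genorm_rank(matrix: CountMatrix, candidates: list[str] | None = None,
                k: int = 3) -> GeNormResult:
    """Run geNorm on a CountMatrix's reference candidates, labeled by gene symbol."""
    probe_ids = candidates or matrix.panel.ids_of("Housekeeping")
    block = matrix.values.loc[probe_ids].astype(float)
    block.index = [matrix.panel.probe(pid).gene_symbol for pid in probe_ids]
    return genorm(block, k=k)


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class NormalizedMatrix:
    """Content-normalized expression with the factors that produced it."""

    panel: PanelDefinition
    samples: pd.DataFrame
    values: pd.DataFrame
    pos_factors: pd.Series
    content_factors: pd.Series
    references_used: list[str]  # probe ids
    stage_tag: str = "content_normalized"

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def endogenous_values(self) -> pd.DataFrame:
        return self.values.loc[self.panel.ids_of("Endogenous")]

    def log_endogenous(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(normalized + pseudocount) content matrix for downstream stats."""
        return np.log2(self.endogenous_values() + pseudocount)

    def sample_ids_for(self, diagnosis: str) -> list[str]:
        return list(self.samples.index[self.samples["diagnosis"] == diagnosis])


def resolve_references(panel: PanelDefinition, references: list[str]) -> list[str]:
    """Map reference gene symbols or probe ids onto panel probe ids."""
    known = set(panel.probe_ids)
    by_symbol: dict[str, str] = {}
    for p in panel.probes:
        if p.code_class in ("Housekeeping", "Endogenous"):
            by_symbol.setdefault(p.gene_symbol, p.probe_id)
    out = []
    for ref in references:
        if ref in known:
            out.append(ref)
        elif ref in by_symbol:
            out.append(by_symbol[ref])
        else:
            raise KeyError(f"reference {ref!r} not found in panel {panel.name}")
    return out


def positive_normalize(matrix: CountMatrix) -> tuple[CountMatrix, pd.Series]:
    """Scale each sample by its positive-control technical factor."""
    factors = technical_norm_factor(matrix)
    values = matrix.values.astype(float).mul(factors, axis=1)
    out = CountMatrix(panel=matrix.panel, samples=matrix.samples.copy(),
                      values=values, stage_tag="pos_normalized")
    return out, factors


def content_normalize(
    matrix: CountMatrix,
    references: list[str],
    pos_factors: pd.Series | None = None,
) -> NormalizedMatrix:
    """Scale each sample by its reference-gene content factor.

    ``references`` may be gene symbols or probe ids.  ``pos_factors`` only
    records the factors of an earlier technical-normalization step; pass
    the pos-normalized matrix itself to chain the steps (or use
    :func:`normalize`).
    """
    ref_ids = resolve_references(matrix.panel, references)
    factors = norm_factors(matrix, ref_ids)
    values = matrix.values.astype(float).mul(factors, axis=1)
    if pos_factors is None:
        pos_factors = pd.Series(1.0, index=matrix.values.columns)
    return NormalizedMatrix(
        panel=matrix.panel,
        samples=matrix.samples.copy(),
        values=values,
        pos_factors=pos_factors,
        content_factors=factors,
        references_used=ref_ids,
    )


def normalize(matrix: CountMatrix, references: list[str],
              use_positive: bool = True) -> NormalizedMatrix:
    """Positive-control step (optional) followed by reference-gene step."""
    if use_positive:
        pos_matrix, pos_f = positive_normalize(matrix)
    else:
        pos_matrix, pos_f = matrix, pd.Series(1.0, index=matrix.values.columns)
    return content_normalize(pos_matrix, references, pos_factors=pos_f)


def reference_geomeans(norm: NormalizedMatrix) -> pd.Series:
    """Per-sample geomean of the reference genes actually used (QC check)."""
    vals = norm.values.loc[norm.references_used]
    return pd.Series({sid: geomean(vals[sid]) for sid in vals.columns})
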