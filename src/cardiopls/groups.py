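"""Electrophysiological group effects and regulatory flow export.

Beta coefficients from the fitted PLS models are aggregated into
ion-channel groupings — Depolarization, Repolarization, Net
(Depolarization minus Repolarization), Resting, Calcium handling and
Coupling — to summarise each regulator's expected influence on cardiac
electrophysiology. For the two-stage flow (Sankey) export, each gene's
coefficients are max-absolute scaled into [-1, 1] without shifting the
centre, so signs are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import GenePanel

__all__ = [
    "GroupEffectTable",
    "SankeyFlows",
    "group_mean_beta",
    "maxabs_scale_signed",
    "sankey_export",
]

GROUP_ORDER = ["Depolarization", "Repolarization", "Net", "Resting",
               "Calcium", "Coupling"]


@dataclass
class GroupEffectTable:
    """Regulator x grouping table of mean beta coefficients.

    The ``Net`` column is exactly Depolarization - Repolarization;
    ``Coupling`` is the single gap-junction gene's coefficient.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        net = self.table["Depolarization"] - self.table["Repolarization"]
        if not np.allclose(self.table["Net"], net, rtol=0, atol=0):
            raise ValueError("Net column must equal Depolarization - "
                             "Repolarization exactly")


def group_mean_beta(beta: pd.DataFrame, panel: GenePanel) -> GroupEffectTable:
    """Average beta coefficients over each ion-channel grouping.

    ``beta`` is regulators x IC genes (e.g. ``PLSResults.beta_frame``).
    Groupings come from the panel; a gene may belong to several
    groupings (SLC8A1 and CACNA1C sit in both Depolarization and
    Calcium).
    """
    missing = {
        g for genes in panel.groupings.values() for g in genes
        if g not in beta.columns
    }
    if missing:
        raise KeyError(f"beta lacks grouping genes: {sorted(missing)}")
    cols = {}
    for name, genes in panel.groupings.items():
        cols[name] = beta.loc[:, list(genes)].mean(axis=1)
    table = pd.DataFrame(cols)
    table["Net"] = table["Depolarization"] - table["Repolarization"]
    return GroupEffectTable(table.loc[:, GROUP_ORDER])


def maxabs_scale_signed(coeffs: np.ndarray) -> np.ndarray:
    """Scale a coefficient vector into [-1, 1] by its max absolute value.

    The centre is not shifted, so signs are preserved; an all-zero
    vector maps to itself.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        raise ValueError("empty coefficient vector")
    m = np.abs(coeffs).max()
    return coeffs if m == 0 else coeffs / m


@dataclass
class SankeyFlows:
    """Two-stage regulator -> TF -> ion-channel flow list.

    Each link carries the scaled coefficient magnitude as ``weight``
    (in [0, 1]) and a ``sign`` label; nodes are ordered modifiers,
    TFs, ICs.
    """

    nodes: list[dict]
    links: list[dict]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"nodes": self.nodes, "links": self.links},
                             indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SankeyFlows":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        obj = json.loads(text)
        return cls(obj["nodes"], obj["links"])


def sankey_export(beta_stage1: pd.DataFrame, beta_stage2: pd.DataFrame,
                  panel: GenePanel, prune: float = 0.01,
                  path: str | Path | None = None) -> SankeyFlows:
    """Build flow data from the two regression stages.

    ``beta_stage1`` is modifiers x TFs (acetylation modifiers
    predicting transcription factors), ``beta_stage2`` TFs x ICs. Each
    target gene's incoming coefficients are max-absolute scaled; links
    whose scaled magnitude falls below ``prune`` are omitted. Note a
    negative stage-1 link into a negative stage-2 link reads as a
    positive net input-output relationship; no product is computed —
    the diagram keeps the stages separate.
    """
    if list(beta_stage1.columns) != list(beta_stage2.index):
        raise ValueError(
            "TF set of stage 1 (columns) must match stage 2 (rows)"
        )
    scaled1 = beta_stage1.apply(
        lambda col: pd.Series(maxabs_scale_signed(col.to_numpy()),
                              index=col.index))
    scaled2 = beta_stage2.apply(
        lambda col: pd.Series(maxabs_scale_signed(col.to_numpy()),
                              index=col.index))
    node_names = (list(beta_stage1.index) + list(beta_stage2.index)
                  + list(beta_stage2.columns))
    stage_of = (["modifier"] * len(beta_stage1.index)
                + ["TF"] * len(beta_stage2.index)
                + ["IC"] * len(beta_stage2.columns))
    nodes = [{"id": i, "name": n, "stage": s}
             for i, (n, s) in enumerate(zip(node_names, stage_of))]
    index = {n: i for i, n in enumerate(node_names)}
    # TF names appear once as sources and once as node entries; modifiers
    # and ICs are unique, so the mapping above is unambiguous as long as
    # blocks are disjoint (enforced by the panel).
    links = []
    for scaled, (src_names, dst_offset) in (
        (scaled1, (list(beta_stage1.index), len(beta_stage1.index))),
        (scaled2, (list(beta_stage2.index),
                   len(beta_stage1.index) + len(beta_stage2.index))),
    ):
        dst_names = list(scaled.columns)
        for si, s in enumerate(src_names):
            for di, d in enumerate(dst_names):
                w = float(scaled.iloc[si, di])
                if abs(w) < prune:
                    continue
                links.append({
                    "source": index[s] if scaled is scaled1
                    else len(beta_stage1.index) + si,
                    "target": dst_offset + di,
                    "weight": abs(w),
                    "sign": "positive" if w > 0 else "negative",
                    "source_name": s,
                    "target_name": d,
                })
    flows = SankeyFlows(nodes, links)
    if path is not None:
        flows.to_json(path)
    return flows
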