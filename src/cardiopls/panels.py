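"""Gene panels: regulatory blocks and electrophysiological groupings.

The analysis is organised around five gene blocks — three classes of
acetylation modifiers (HDACs, sirtuins, HATs), a set of cardiac
transcription factors (TFs), and ten "rhythmonome" ion-channel /
transporter genes (ICs) — plus groupings of the IC genes by
electrophysiological role (depolarization, repolarization, resting
membrane potential, calcium handling, cell–cell coupling).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["GenePanel", "load_panel", "DEFAULT_BLOCKS", "DEFAULT_GROUPINGS"]

# Canonical block membership. HDAC/SIRT/HAT form the modifier (input) block;
# TFs the mediator block; ICs the response block.
DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    "HDAC": (
        "HDAC1", "HDAC2", "HDAC3", "HDAC4", "HDAC5", "HDAC6",
        "HDAC7", "HDAC8", "HDAC9", "HDAC10", "HDAC11",
    ),
    "SIRT": ("SIRT1", "SIRT2", "SIRT3", "SIRT4", "SIRT5", "SIRT6", "SIRT7"),
    "HAT": (
        "KAT2A", "KAT2B", "HAT1", "ATF2", "KAT5", "KAT6A", "KAT6B",
        "KAT7", "EP300", "CREBBP", "NCOA1", "NCOA3", "TAF1", "GTF3C1",
        "CLOCK",
    ),
    "TF": (
        "FOXO1", "FOXO3", "GATA4", "GATA6", "HIF1A", "KLF4", "KLF5",
        "MEF2A", "NFAT5", "NFKB1", "NKX25", "NOTCH1", "RUNX1", "SHMT2",
        "SOD1", "TBX5", "TGFB1", "TRIM28", "YY1",
    ),
    "IC": (
        "SCN5A", "CACNA1C", "KCNH2", "KCNQ1", "KCNJ2", "ATP1A1",
        "SLC8A1", "ATP2A2", "RYR2", "GJA1",
    ),
}

# IC groupings by electrophysiological role. SLC8A1 (Na/Ca exchanger) and
# CACNA1C legitimately appear in two groupings; overlap is by design.
DEFAULT_GROUPINGS: dict[str, tuple[str, ...]] = {
    "Depolarization": ("SCN5A", "CACNA1C", "SLC8A1"),
    "Repolarization": ("KCNH2", "KCNQ1", "KCNJ2", "ATP1A1"),
    "Resting": ("KCNJ2", "ATP1A1"),
    "Calcium": ("ATP2A2", "RYR2", "SLC8A1", "CACNA1C"),
    "Coupling": ("GJA1",),
}

DEFAULT_REFERENCE_GENE = "GAPDH"


class PanelConfigError(ValueError):
    """Raised when a panel configuration violates panel invariants."""


@dataclass(frozen=True)
class GenePanel:
    """Named gene blocks, ion-channel groupings and the reference gene.

    Parameters
    ----------
    blocks
        Mapping block name -> ordered gene symbols. Must contain the keys
        ``HDAC``, ``SIRT``, ``HAT``, ``TF`` and ``IC``.
    groupings
        Mapping grouping name -> gene symbols; every grouping gene must be
        a member of the IC block. Groupings may overlap.
    reference_gene
        Housekeeping gene used for sample-quality filtering (GAPDH by
        default).
    """

    blocks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BLOCKS)
    )
    groupings: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPINGS)
    )
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", {k: tuple(v) for k, v in self.blocks.items()}
        )
        object.__setattr__(
            self, "groupings", {k: tuple(v) for k, v in self.groupings.items()}
        )
        missing = {"HDAC", "SIRT", "HAT", "TF", "IC"} - set(self.blocks)
        if missing:
            raise PanelConfigError(f"panel missing blocks: {sorted(missing)}")
        for name, genes in self.blocks.items():
            if len(set(genes)) != len(genes):
                raise PanelConfigError(f"duplicate genes in block {name!r}")
        mod = set(self.modifier_genes)
        for a, b in (("modifier", "TF"), ("modifier", "IC"), ("TF", "IC")):
            left = mod if a == "modifier" else set(self.blocks[a])
            overlap = left & set(self.blocks[b])
            if overlap:
                raise PanelConfigError(
                    f"blocks {a} and {b} overlap: {sorted(overlap)}"
                )
        ic = set(self.blocks["IC"])
        for gname, genes in self.groupings.items():
            stray = set(genes) - ic
            if stray:
                raise PanelConfigError(
                    f"grouping {gname!r} lists genes outside the IC block: "
                    f"{sorted(stray)}"
                )

    @property
    def modifier_genes(self) -> tuple[str, ...]:
        """HDAC + SIRT + HAT genes, in block order."""
        return self.blocks["HDAC"] + self.blocks["SIRT"] + self.blocks["HAT"]

    @property
    def tf_genes(self) -> tuple[str, ...]:
        return self.blocks["TF"]

    @property
    def ic_genes(self) -> tuple[str, ...]:
        return self.blocks["IC"]

    @property
    def all_genes(self) -> tuple[str, ...]:
        """All panel genes in block order (reference gene excluded)."""
        return self.modifier_genes + self.tf_genes + self.ic_genes

    def block_of(self, gene: str) -> str:
        for name, genes in self.blocks.items():
            if gene in genes:
                return name
        raise KeyError(gene)

    def resolve(self, symbols: list[str] | tuple[str, ...]) -> list[str]:
        """Match symbols against panel genes, case-insensitively.

        Exact matches pass through; a case-insensitive match emits a
        warning and returns the panel's canonical capitalisation.
        """
        canon = {g.upper(): g for g in self.all_genes + (self.reference_gene,)}
        out = []
        for s in symbols:
            if s in canon.values():
                out.append(s)
            elif s.upper() in canon:
                warnings.warn(
                    f"gene symbol {s!r} matched panel gene "
                    f"{canon[s.upper()]!r} case-insensitively",
                    stacklevel=2,
                )
                out.append(canon[s.upper()])
            else:
                raise KeyError(f"gene symbol {s!r} not in panel")
        return out

    def to_dict(self) -> dict:
        return {
            "blocks": {k: list(v) for k, v in self.blocks.items()},
            "groupings": {k: list(v) for k, v in self.groupings.items()},
            "reference_gene": self.reference_gene,
        }


def load_panel(source: str | Path | dict = "default") -> GenePanel:
    """Load a :class:`GenePanel` from a YAML/JSON file or return the default.

    Parameters
    ----------
    source
        ``"default"`` for the built-in panel, a path to a YAML or JSON
        config with keys ``blocks``, ``groupings``, ``reference_gene``,
        or an already-parsed mapping with those keys.
    """
    if isinstance(source, str) and source == "default":
        return GenePanel()
    if isinstance(source, dict):
        cfg = source
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            cfg = json.loads(text)
        else:
            cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "blocks" not in cfg:
        raise PanelConfigError("panel config must define 'blocks'")
    return GenePanel(
        blocks={k: tuple(v) for k, v in cfg["blocks"].items()},
        groupings={
            k: tuple(v)
            for k, v in cfg.get("groupings", DEFAULT_GROUPINGS).items()
        },
        reference_gene=cfg.get("reference_gene", DEFAULT_REFERENCE_GENE),
    )
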