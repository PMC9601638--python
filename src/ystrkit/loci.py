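"""Locus registry for the 27-locus Yfiler Plus Y-STR panel.

The panel combines 17 standard loci with 10 rapidly mutating (RM) loci.
Two loci are multi-copy (``DYS385a/b`` and ``DYF387S1a/b``): each individual
carries two alleles that cannot be assigned to a physical copy, so they are
treated as unordered pairs and excluded from network/distance panels.  The
remaining 23 single-copy loci form the network panel, with ``DYS389II``
stored raw and adjusted (``DYS389II - DYS389I``) only where an analysis
requires independent repeat counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

__all__ = [
    "LocusDefinition",
    "PANEL",
    "PANEL_NAMES",
    "SINGLE_COPY_LOCI",
    "MULTI_COPY_PAIRS",
    "NETWORK_LOCI",
    "default_mutation_rates",
    "build_panel",
]

# Multi-copy systems: base name -> (copy-a column, copy-b column)
MULTI_COPY_PAIRS: dict[str, tuple[str, str]] = {
    "DYS385": ("DYS385a", "DYS385b"),
    "DYF387S1": ("DYF387S1a", "DYF387S1b"),
}

# 23 single-copy loci in conventional Yfiler Plus reporting order.
SINGLE_COPY_LOCI: tuple[str, ...] = (
    "DYS19",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "YGATAH4",
    "DYS449",
    "DYS460",
    "DYS481",
    "DYS518",
    "DYS533",
    "DYS570",
    "DYS576",
    "DYS627",
)

#: Network-eligible loci: the 23 single-copy loci (DYS389II adjusted downstream).
NETWORK_LOCI: tuple[str, ...] = SINGLE_COPY_LOCI


@dataclass(frozen=True)
class LocusDefinition:
    """One STR locus of the panel.

    Parameters
    ----------
    name:
        Column name, e.g. ``"DYS19"`` or ``"DYS385a"``.
    copy_class:
        ``"single"`` or ``"multi"`` (multi = one copy of a duplicated system).
    mutation_rate:
        Probability of a mutation per father-to-son transmission; must lie
        in the open interval (0, 0.05).
    in_network_panel:
        Whether the locus enters network / R_ST panels (False for multi-copy).
    """

    name: str
    copy_class: str
    mutation_rate: float
    in_network_panel: bool

    def __post_init__(self) -> None:
        if self.copy_class not in ("single", "multi"):
            raise ValueError(f"bad copy_class {self.copy_class!r}")
        if not (0.0 < self.mutation_rate < 0.05):
            raise ValueError(
                f"mutation rate for {self.name} out of (0, 0.05): {self.mutation_rate}"
            )
        if self.copy_class == "multi" and self.in_network_panel:
            raise ValueError(f"multi-copy locus {self.name} cannot be in network panel")


def default_mutation_rates() -> dict[str, float]:
    """Bundled published consensus mutation rates, per locus column."""
    text = resources.files("ystrkit.data").joinpath("mutation_rates.json").read_text()
    return dict(json.loads(text)["rates"])


def build_panel(rates: Mapping[str, float] | None = None) -> tuple[LocusDefinition, ...]:
    """Build the 27-locus panel, optionally overriding mutation rates per locus."""
    table = default_mutation_rates()
    if rates:
        unknown = set(rates) - set(table)
        if unknown:
            raise KeyError(f"unknown loci in rate override: {sorted(unknown)}")
        table.update(rates)
    defs = [
        LocusDefinition(name, "single", table[name], in_network_panel=True)
        for name in SINGLE_COPY_LOCI
    ]
    for a, b in MULTI_COPY_PAIRS.values():
        defs.append(LocusDefinition(a, "multi", table[a], in_network_panel=False))
        defs.append(LocusDefinition(b, "multi", table[b], in_network_panel=False))
    return tuple(defs)


PANEL: tuple[LocusDefinition, ...] = build_panel()
PANEL_NAMES: tuple[str, ...] = tuple(d.name for d in PANEL)

assert len(PANEL) == 27
assert sum(d.in_network_panel for d in PANEL) == 23
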