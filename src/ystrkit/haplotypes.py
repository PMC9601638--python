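"""Haplotype data model: allele calls, records, tables, and the
preprocessing rules (DYS389 adjustment, network filtering, abnormal-allele
accounting) that downstream analyses rely on.

Allele states follow forensic convention:

* ``normal`` — a single integer repeat count,
* ``microvariant`` — a single non-integer count (e.g. 17.2 = partial repeat),
* ``null`` — no amplification product (e.g. a deletion spanning DYS448),
* ``duplicated`` — more than one allele at a single-copy locus (copy-number
  variant, seen at DYS19).

Multi-copy loci (DYS385a/b, DYF387S1a/b) are unordered: the two columns are
canonicalized so that the smaller allele is stored under the ``a`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import pandas as pd

from .loci import (
    LocusDefinition,
    MULTI_COPY_PAIRS,
    NETWORK_LOCI,
    PANEL,
    PANEL_NAMES,
)

__all__ = [
    "AlleleCall",
    "Haplotype",
    "HaplotypeTable",
    "AdjustOutcome",
    "adjust_dys389",
    "adjust_dys389_table",
    "filter_for_network",
    "abnormal_allele_report",
    "format_allele",
]

REPEAT_MIN, REPEAT_MAX = 5.0, 60.0


def format_allele(v: float) -> str:
    """Render a repeat count the way a forensic table prints it (17, 17.2)."""
    if float(v).is_integer():
        return str(int(v))
    return f"{v:g}"


@dataclass(frozen=True)
class AlleleCall:
    """A called allele state at one locus column.

    ``values`` is a sorted tuple of repeat counts: empty for ``null``, one
    value for ``normal``/``microvariant``, two or more for ``duplicated``.
    """

    state: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(sorted(float(v) for v in self.values)))
        n = len(self.values)
        if self.state == "null" and n != 0:
            raise ValueError("null call must have no values")
        if self.state in ("normal", "microvariant") and n != 1:
            raise ValueError(f"{self.state} call must have exactly one value")
        if self.state == "duplicated" and n < 2:
            raise ValueError("duplicated call needs >= 2 values")
        if self.state == "microvariant" and self.values[0].is_integer():
            raise ValueError("microvariant call must have a fractional repeat count")
        if self.state == "normal" and not self.values[0].is_integer():
            raise ValueError("normal call must have an integer repeat count")
        if self.state not in ("null", "normal", "microvariant", "duplicated"):
            raise ValueError(f"unknown allele state {self.state!r}")

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "AlleleCall":
        vals = tuple(sorted(float(v) for v in values))
        if not vals:
            return cls("null", ())
        if len(vals) == 1:
            state = "normal" if vals[0].is_integer() else "microvariant"
            return cls(state, vals)
        return cls("duplicated", vals)

    @property
    def is_single_numeric(self) -> bool:
        return len(self.values) == 1

    def token(self) -> str:
        """Canonical text form: '' for null, '15,16' for a duplication."""
        return ",".join(format_allele(v) for v in self.values)


@dataclass(frozen=True)
class Haplotype:
    """One individual's allele calls across the panel, with group labels."""

    sample_id: str
    calls: dict[str, AlleleCall]
    population: str = ""
    tribe: str | None = None
    clan: str | None = None

    def key(self, panel_names: tuple[str, ...] = PANEL_NAMES) -> tuple[str, ...]:
        """Canonical haplotype identity: per-locus tokens in panel order."""
        return tuple(self.calls[name].token() for name in panel_names)

    def call(self, locus: str) -> AlleleCall:
        return self.calls[locus]


def _canonicalize_multicopy(calls: dict[str, AlleleCall]) -> dict[str, AlleleCall]:
    """Redistribute multi-copy pair values so the pair is an ascending set."""
    out = dict(calls)
    for a, b in MULTI_COPY_PAIRS.values():
        vals = sorted(calls[a].values + calls[b].values)
        if not vals:
            out[a] = out[b] = AlleleCall("null", ())
        elif len(vals) == 1:
            out[a] = AlleleCall.from_values(vals)
            out[b] = AlleleCall("null", ())
        else:
            out[a] = AlleleCall.from_values(vals[:1])
            out[b] = AlleleCall.from_values(vals[1:])
    return out


@dataclass
class HaplotypeTable:
    """Validated collection of haplotypes over a fixed panel.

    ``dys389_adjusted`` records whether DYS389II already holds the adjusted
    value (DYS389II − DYS389I); the flag prevents double subtraction.
    """

    records: list[Haplotype]
    panel: tuple[LocusDefinition, ...] = PANEL
    dys389_adjusted: bool = False

    def __post_init__(self) -> None:
        names = tuple(d.name for d in self.panel)
        seen: set[str] = set()
        canon: list[Haplotype] = []
        for h in self.records:
            if h.sample_id in seen:
                raise ValueError(f"duplicate sample_id {h.sample_id!r}")
            seen.add(h.sample_id)
            missing = set(names) - set(h.calls)
            if missing:
                raise ValueError(f"sample {h.sample_id}: missing loci {sorted(missing)}")
            extra = set(h.calls) - set(names)
            if extra:
                raise ValueError(f"sample {h.sample_id}: unknown loci {sorted(extra)}")
            canon.append(replace(h, calls=_canonicalize_multicopy(h.calls)))
        self.records = canon

    def __len__(self) -> int:
        return len(self.records)

    @property
    def panel_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.panel)

    def group_labels(self, group_by: str) -> list[str]:
        if group_by not in ("population", "tribe", "clan"):
            raise KeyError(f"unknown grouping field {group_by!r}")
        return [getattr(h, group_by) or "unknown" for h in self.records]

    def subset(self, sample_ids: Iterable[str]) -> "HaplotypeTable":
        wanted = set(sample_ids)
        return HaplotypeTable(
            [h for h in self.records if h.sample_id in wanted],
            panel=self.panel,
            dys389_adjusted=self.dys389_adjusted,
        )


class AdjustOutcome(NamedTuple):
    haplotype: Haplotype
    adjusted: bool
    warning: str | None


def adjust_dys389(h: Haplotype) -> AdjustOutcome:
    """Replace DYS389II by DYS389II − DYS389I (the repeats private to the
    distal segment), so the two loci contribute independent counts.

    The flanking DYS389II amplicon physically contains the DYS389I repeat
    stretch, so the raw count double-counts DYS389I.  Records where either
    locus is null or duplicated cannot be adjusted and are returned
    unchanged with a warning; a non-positive adjusted value is returned but
    flagged as out of range.
    """
    c1, c2 = h.calls["DYS389I"], h.calls["DYS389II"]
    if not (c1.is_single_numeric and c2.is_single_numeric):
        return AdjustOutcome(h, False, f"{h.sample_id}: DYS389I/II not both single-valued")
    adj = c2.values[0] - c1.values[0]
    calls = dict(h.calls)
    calls["DYS389II"] = AlleleCall.from_values([adj]) if adj != 0 else AlleleCall(
        "normal", (0.0,)
    )
    warning = None
    if adj < REPEAT_MIN:
        warning = f"{h.sample_id}: adjusted DYS389II = {format_allele(adj)} out of range"
    return AdjustOutcome(replace(h, calls=calls), True, warning)


def adjust_dys389_table(t: HaplotypeTable) -> tuple[HaplotypeTable, list[str]]:
    """Apply the DYS389 adjustment once across a table.

    Returns the adjusted table (flagged to prevent re-adjustment) and the
    list of warnings for records left unadjusted or out of range.
    """
    if t.dys389_adjusted:
        raise ValueError("table already DYS389-adjusted; refusing to subtract twice")
    out: list[Haplotype] = []
    warnings: list[str] = []
    for h in t.records:
        res = adjust_dys389(h)
        out.append(res.haplotype)
        if res.warning:
            warnings.append(res.warning)
        elif not res.adjusted:
            warnings.append(f"{h.sample_id}: unadjusted")
    return HaplotypeTable(out, panel=t.panel, dys389_adjusted=True), warnings


def filter_for_network(t: HaplotypeTable) -> tuple[HaplotypeTable, pd.DataFrame]:
    """Drop records unusable in the 23-locus network/distance panel.

    A record is retained only when every network-eligible locus carries
    exactly one numeric value (normal or microvariant).  Null alleles
    (e.g. DYS448 deletions) and duplications (e.g. DYS19 copy-number
    variants) at network loci exclude the record.  Multi-copy loci never
    cause exclusion — they are outside the network panel.

    Returns the retained table and an exclusion report with one row per
    excluded sample (columns ``sample_id``, ``locus``, ``reason``).
    """
    retained: list[Haplotype] = []
    rows: list[dict[str, str]] = []
    for h in t.records:
        bad: list[tuple[str, str]] = []
        for locus in NETWORK_LOCI:
            call = h.calls[locus]
            if call.state == "null":
                bad.append((locus, "null allele"))
            elif call.state == "duplicated":
                bad.append((locus, "duplicated allele"))
        if bad:
            for locus, reason in bad:
                rows.append({"sample_id": h.sample_id, "locus": locus, "reason": reason})
        else:
            retained.append(h)
    report = pd.DataFrame(rows, columns=["sample_id", "locus", "reason"])
    kept = HaplotypeTable(retained, panel=t.panel, dys389_adjusted=t.dys389_adjusted)
    return kept, report


def abnormal_allele_report(t: HaplotypeTable, group_by: str = "population") -> pd.DataFrame:
    """Count null, microvariant and duplicated calls per locus and group.

    Every abnormal call is counted exactly once; loci with no abnormal
    calls are omitted.  Returns a tidy frame with columns
    ``group``, ``locus``, ``nulls``, ``microvariants``, ``duplications``.
    """
    labels = t.group_labels(group_by)
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for h, g in zip(t.records, labels):
        for locus in t.panel_names:
            call = h.calls[locus]
            if call.state in ("null", "microvariant", "duplicated"):
                slot = counts.setdefault(
                    (g, locus), {"nulls": 0, "microvariants": 0, "duplications": 0}
                )
                kind = {
                    "null": "nulls",
                    "microvariant": "microvariants",
                    "duplicated": "duplications",
                }[call.state]
                slot[kind] += 1
    rows = [
        {"group": g, "locus": locus, **c} for (g, locus), c in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["group", "locus", "nulls", "microvariants", "duplications"]
    )
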