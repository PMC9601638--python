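"""Reading and writing wide haplotype tables.

The expected layout is the common YHRD-style wide table: one row per
individual, a ``sample_id`` column, optional ``population`` / ``tribe`` /
``clan`` label columns, and one column per locus.  Multi-copy loci may
appear either as a combined column (``DYS385`` holding ``"11-14"``) or as
split columns (``DYS385a`` / ``DYS385b``).

Token conventions (all configurable):

* null allele — empty cell or the sentinel ``"0"``,
* duplicated allele at a single-copy locus — values joined by ``","``,
* multi-copy pair in a combined column — values joined by ``"-"``,
* microvariants — decimal repeat counts such as ``17.2``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .haplotypes import (
    AlleleCall,
    Haplotype,
    HaplotypeTable,
    REPEAT_MAX,
    REPEAT_MIN,
    format_allele,
)
from .loci import MULTI_COPY_PAIRS, PANEL_NAMES

__all__ = ["read_haplotypes", "write_haplotypes"]

_LABEL_COLUMNS = ("population", "tribe", "clan")
_COMBINED_TO_PAIR = dict(MULTI_COPY_PAIRS)
_DIALECT_SEP = {"wide_tsv": "\t", "csv": ","}


def _parse_values(
    token: str, *, null_sentinels: Sequence[str], seps: Sequence[str]
) -> list[float]:
    token = token.strip()
    if token in null_sentinels:
        return []
    for sep in seps:
        if sep and sep in token:
            parts = [p.strip() for p in token.split(sep)]
            break
    else:
        parts = [token]
    values = []
    for p in parts:
        if p in null_sentinels:
            continue
        values.append(float(p))
    return values


def _check_range(values: list[float], row: str, locus: str) -> None:
    for v in values:
        if not (REPEAT_MIN <= v <= REPEAT_MAX):
            raise ValueError(
                f"sample {row}, locus {locus}: repeat count {v} outside "
                f"[{REPEAT_MIN:g}, {REPEAT_MAX:g}]"
            )


def read_haplotypes(
    path: str | Path,
    dialect: str = "wide_tsv",
    *,
    null_sentinels: Sequence[str] = ("", "0"),
    dup_sep: str = ",",
    pair_sep: str = "-",
) -> HaplotypeTable:
    """Read a wide haplotype table into a validated :class:`HaplotypeTable`.

    Raises
    ------
    ValueError
        On an unknown locus column, or on an allele token that cannot be
        parsed (the error names the offending sample and locus).
    """
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("input is missing the required 'sample_id' column")

    locus_cols: list[str] = []
    for col in df.columns:
        if col == "sample_id" or col in _LABEL_COLUMNS:
            continue
        if col in PANEL_NAMES or col in _COMBINED_TO_PAIR:
            locus_cols.append(col)
        else:
            raise ValueError(f"unknown locus column {col!r}")

    covered: set[str] = set()
    for col in locus_cols:
        covered.update(_COMBINED_TO_PAIR.get(col, (col,)))
    missing = set(PANEL_NAMES) - covered
    if missing:
        raise ValueError(f"input is missing panel loci: {sorted(missing)}")

    records: list[Haplotype] = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        calls: dict[str, AlleleCall] = {}
        for col in locus_cols:
            token = row[col]
            try:
                if col in _COMBINED_TO_PAIR:
                    vals = _parse_values(
                        token, null_sentinels=null_sentinels, seps=(pair_sep, dup_sep)
                    )
                    _check_range(vals, sid, col)
                    a, b = _COMBINED_TO_PAIR[col]
                    vals = sorted(vals)
                    calls[a] = AlleleCall.from_values(vals[:1])
                    calls[b] = AlleleCall.from_values(vals[1:])
                else:
                    vals = _parse_values(
                        token, null_sentinels=null_sentinels, seps=(dup_sep,)
                    )
                    _check_range(vals, sid, col)
                    calls[col] = AlleleCall.from_values(vals)
            except ValueError as exc:
                raise ValueError(
                    f"sample {sid}, locus {col}: cannot parse allele token "
                    f"{token!r} ({exc})"
                ) from exc
        records.append(
            Haplotype(
                sample_id=sid,
                calls=calls,
                population=row.get("population", ""),
                tribe=row.get("tribe") or None,
                clan=row.get("clan") or None,
            )
        )
    return HaplotypeTable(records)


def write_haplotypes(
    t: HaplotypeTable,
    path: str | Path,
    dialect: str = "wide_tsv",
    *,
    dup_sep: str = ",",
    pair_sep: str = "-",
) -> None:
    """Write a table in canonical wide form (combined multi-copy columns,
    empty cell for null alleles)."""
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = ["sample_id", "population", "tribe", "clan"]
    single = [n for n in t.panel_names if all(n not in pair for pair in MULTI_COPY_PAIRS.values())]
    rows = []
    for h in t.records:
        row: dict[str, str] = {
            "sample_id": h.sample_id,
            "population": h.population,
            "tribe": h.tribe or "",
            "clan": h.clan or "",
        }
        for locus in single:
            row[locus] = h.calls[locus].token().replace(",", dup_sep)
        for base, (a, b) in MULTI_COPY_PAIRS.items():
            vals = h.calls[a].values + h.calls[b].values
            row[base] = pair_sep.join(format_allele(v) for v in sorted(vals))
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols + single + list(MULTI_COPY_PAIRS))
    df.to_csv(path, sep=_DIALECT_SEP[dialect], index=False)
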