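"""Direct-count forensic statistics on Y-STR haplotypes.

Haplotype-level quantities (all computed from the observed spectrum of
distinct haplotypes):

* haplotype diversity  HD = n (1 − Σ p_i²) / (n − 1)   (Nei's unbiased form),
* haplotype match probability  HMP = Σ p_i²,
* discrimination capacity  DC = distinct / n,
* unique-haplotype fraction = singletons / n.

Per-locus parameters on allele frequencies p_a:

* gene diversity  GD = n (1 − Σ p_a²) / (n − 1),
* random match probability  RMP = Σ p_a²,
* power of discrimination  PD = 1 − RMP,
* polymorphism information content  PIC = 1 − Σ p² − (Σ p²)² + Σ p⁴.

Haplotype identity is exact equality of all 27 locus calls, including
abnormal states (a DYS448 null is a state, distinct from every numeric
allele) and sorted multi-copy pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .haplotypes import HaplotypeTable, format_allele
from .loci import MULTI_COPY_PAIRS

__all__ = [
    "HaplotypeSpectrum",
    "ForensicSummary",
    "LocusStats",
    "spectrum",
    "haplotype_diversity",
    "match_probability",
    "discrimination_capacity",
    "unique_fraction",
    "forensic_summary",
    "locus_statistics",
    "summary_report",
]


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Multiset of distinct haplotypes with observation counts."""

    counts: dict[tuple[str, ...], int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty spectrum")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all haplotype counts must be >= 1")

    @classmethod
    def from_counts(cls, counts: list[int]) -> "HaplotypeSpectrum":
        """Build an anonymous spectrum from a list of observation counts."""
        return cls({(f"h{i}",): c for i, c in enumerate(counts)})

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        return len(self.counts)

    @property
    def singletons(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)


def spectrum(t: HaplotypeTable) -> HaplotypeSpectrum:
    """Count distinct haplotypes by exact identity of all panel calls."""
    if not t.records:
        raise ValueError("cannot build a spectrum from an empty table")
    return HaplotypeSpectrum(dict(Counter(h.key(t.panel_names) for h in t.records)))


def match_probability(s: HaplotypeSpectrum) -> float:
    """HMP = Σ (count_i / n)², probability two random draws match."""
    n = s.n
    return sum((c / n) ** 2 for c in s.counts.values())


def haplotype_diversity(s: HaplotypeSpectrum) -> float:
    """HD = n (1 − Σ p_i²) / (n − 1); requires n ≥ 2."""
    n = s.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    return n * (1.0 - match_probability(s)) / (n - 1)


def discrimination_capacity(s: HaplotypeSpectrum) -> float:
    """DC = number of distinct haplotypes / sample size."""
    return s.distinct / s.n


def unique_fraction(s: HaplotypeSpectrum) -> float:
    """Fraction of individuals carrying a haplotype observed exactly once."""
    return s.singletons / s.n


@dataclass(frozen=True)
class ForensicSummary:
    """One row of a haplotype-level forensic summary table."""

    n: int
    distinct: int
    unique_fraction: float
    dc: float
    hmp: float
    hd: float | None  # None when n < 2 (undefined)

    @classmethod
    def from_spectrum(cls, s: HaplotypeSpectrum) -> "ForensicSummary":
        return cls(
            n=s.n,
            distinct=s.distinct,
            unique_fraction=unique_fraction(s),
            dc=discrimination_capacity(s),
            hmp=match_probability(s),
            hd=haplotype_diversity(s) if s.n >= 2 else None,
        )


def forensic_summary(t: HaplotypeTable) -> ForensicSummary:
    return ForensicSummary.from_spectrum(spectrum(t))


def summary_report(t: HaplotypeTable, group_by: str = "population") -> pd.DataFrame:
    """Per-group forensic summary (one row per population or tribe).

    Columns follow the conventional forensic report order: sample size,
    distinct haplotypes, unique-haplotype fraction (as a proportion),
    discrimination capacity, haplotype match probability, haplotype
    diversity.  HD is NaN for groups of size 1.
    """
    labels = t.group_labels(group_by)
    rows = []
    for group in sorted(set(labels)):
        sub = HaplotypeTable(
            [h for h, g in zip(t.records, labels) if g == group],
            panel=t.panel,
            dys389_adjusted=t.dys389_adjusted,
        )
        summ = forensic_summary(sub)
        rows.append(
            {
                "group": group,
                "n": summ.n,
                "distinct": summ.distinct,
                "unique_fraction": summ.unique_fraction,
                "dc": summ.dc,
                "hmp": summ.hmp,
                "hd": summ.hd if summ.hd is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LocusStats:
    """Per-locus forensic parameters on allele frequencies."""

    locus: str
    allele_freqs: dict[str, float]
    n: int
    n_alleles: int
    gd: float
    rmp: float
    pd: float
    pic: float


def _locus_observations(t: HaplotypeTable, locus: str, include_nulls: bool) -> list[str]:
    """One allele-state observation per individual at a locus.

    For a multi-copy system (pass the base name, e.g. ``"DYS385"``) the
    observation is the canonical unordered combination, e.g. ``"11-14"``.
    Null calls are excluded from the denominator unless ``include_nulls``.
    """
    obs: list[str] = []
    if locus in MULTI_COPY_PAIRS:
        a, b = MULTI_COPY_PAIRS[locus]
        for h in t.records:
            vals = sorted(h.calls[a].values + h.calls[b].values)
            if not vals:
                if include_nulls:
                    obs.append("null")
                continue
            obs.append("-".join(format_allele(v) for v in vals))
    else:
        if locus not in t.panel_names:
            raise KeyError(f"unknown locus {locus!r}")
        for h in t.records:
            call = h.calls[locus]
            if call.state == "null":
                if include_nulls:
                    obs.append("null")
                continue
            obs.append(call.token())
    return obs


def locus_statistics(
    t: HaplotypeTable, locus: str, *, include_nulls: bool = False
) -> LocusStats:
    """GD / RMP / PD / PIC on the allele-state frequencies of one locus.

    Duplicated calls count as one compound state (e.g. ``"15,16"``), and
    microvariants as their own decimal states, mirroring how forensic
    frequency tables list them.  With ``include_nulls`` the null state
    forms its own frequency class; by default null calls are dropped from
    the denominator.
    """
    obs = _locus_observations(t, locus, include_nulls)
    if not obs:
        raise ValueError(f"locus {locus}: no typed alleles")
    n = len(obs)
    counts = Counter(obs)
    freqs = {a: c / n for a, c in sorted(counts.items())}
    p2 = sum(f * f for f in freqs.values())
    p4 = sum(f**4 for f in freqs.values())
    gd = n * (1.0 - p2) / (n - 1) if n > 1 else 0.0
    pic = 1.0 - p2 - p2 * p2 + p4
    return LocusStats(
        locus=locus,
        allele_freqs=freqs,
        n=n,
        n_alleles=len(freqs),
        gd=gd,
        rmp=p2,
        pd=1.0 - p2,
        pic=pic,
    )


def locus_report(t: HaplotypeTable, *, include_nulls: bool = False) -> pd.DataFrame:
    """Locus-by-locus parameter table over the whole panel (multi-copy
    systems summarized once under their base name)."""
    loci = [
        n
        for n in t.panel_names
        if all(n not in pair for pair in MULTI_COPY_PAIRS.values())
    ] + list(MULTI_COPY_PAIRS)
    rows = []
    for locus in loci:
        st = locus_statistics(t, locus, include_nulls=include_nulls)
        rows.append(
            {
                "locus": st.locus,
                "n": st.n,
                "n_alleles": st.n_alleles,
                "gd": st.gd,
                "rmp": st.rmp,
                "pd": st.pd,
                "pic": st.pic,
            }
        )
    return pd.DataFrame(rows)
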