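"""Synthetic founder-effect Y-STR populations under a stepwise mutation
model (SMM).

Each tribe is modeled as a star genealogy: a fraction of its samples
(``founder_fraction``, emulating the dominant founder lineage within a
tribe) descend independently from the tribe founder haplotype over ``g``
generations, mutating at each locus per generation with the locus-specific
rate μ_l by ±1 repeat (symmetric single-step).  Under this model the
repeat count at a locus after g generations has mean equal to the founder
value and variance μ_l·g, which makes the generator analytically checkable.
Remaining samples represent unrelated background lineages and are drawn as
independent haplotypes jittered around the panel's modal alleles.

Data artifacts seen in real casework are injected after mutation:
DYS448 deletions (null alleles), DYS19 copy-number duplications (a second
allele one repeat away), and DYS458 microvariants (+0.2 partial repeats).

DYS389II is handled physically: the simulator evolves DYS389I and the
distal DYS389II segment independently and reports the raw nested count
(DYS389I + distal), so downstream adjustment recovers independent loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .haplotypes import AlleleCall, Haplotype, HaplotypeTable
from .loci import MULTI_COPY_PAIRS, PANEL_NAMES, default_mutation_rates

__all__ = [
    "TribeSpec",
    "SimulationConfig",
    "GenealogySample",
    "BASE_HAPLOTYPE",
    "simulate_tribe",
    "simulate_population",
    "fixture_karakalpakstan",
]

#: Plausible modal Yfiler Plus haplotype used as the ancestral base
#: (DYS389II given as the raw nested count).
BASE_HAPLOTYPE: dict[str, float] = {
    "DYS19": 15,
    "DYS389I": 13,
    "DYS389II": 29,
    "DYS390": 24,
    "DYS391": 10,
    "DYS392": 11,
    "DYS393": 13,
    "DYS437": 14,
    "DYS438": 10,
    "DYS439": 12,
    "DYS448": 19,
    "DYS456": 15,
    "DYS458": 17,
    "DYS635": 23,
    "YGATAH4": 12,
    "DYS449": 29,
    "DYS460": 10,
    "DYS481": 22,
    "DYS518": 38,
    "DYS533": 11,
    "DYS570": 17,
    "DYS576": 18,
    "DYS627": 20,
    "DYS385a": 11,
    "DYS385b": 14,
    "DYF387S1a": 36,
    "DYF387S1b": 38,
}

# internal evolution tracks the distal DYS389II segment, not the raw count
_EVOLVE_COLUMNS = tuple(PANEL_NAMES)


class GenealogySample(NamedTuple):
    """A simulated table plus per-sample ground truth."""

    table: HaplotypeTable
    truth: pd.DataFrame


@dataclass(frozen=True)
class TribeSpec:
    """One tribe of the simulated population.

    ``founder_fraction`` is the share of the tribe descending from the
    tribal founder lineage; the rest are unrelated background lineages.
    ``generations`` is the expansion depth of the founder star genealogy.
    """

    name: str
    proportion: float
    generations: int = 20
    founder_fraction: float = 0.7
    founder: dict[str, float] | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of a simulated multi-tribe population."""

    tribes: tuple[TribeSpec, ...] = (
        TribeSpec("Alimuly", 103 / 464, 20, 0.67),
        TribeSpec("Baiuly", 272 / 464, 20, 0.746),
        TribeSpec("Zhetiru", 89 / 464, 20, 0.258),
    )
    n: int = 464
    seed: int = 0
    split_generations: int = 60
    dys448_null_rate: float = 0.14
    dys19_dup_rate: float = 0.14
    microvariant_rate: float = 0.0065
    population: str = "Simulated"
    rates: dict[str, float] = field(default_factory=default_mutation_rates)

    def __post_init__(self) -> None:
        total = sum(t.proportion for t in self.tribes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tribe proportions must sum to 1 (got {total})")
        for r in (self.dys448_null_rate, self.dys19_dup_rate, self.microvariant_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("artifact rates must lie in [0, 1]")
        if any(t.generations < 0 for t in self.tribes) or self.split_generations < 0:
            raise ValueError("generation counts must be >= 0")


def _raw_to_internal(founder: dict[str, float]) -> dict[str, float]:
    f = dict(founder)
    f["DYS389II"] = f["DYS389II"] - f["DYS389I"]
    return f


def _internal_to_raw(values: dict[str, float]) -> dict[str, float]:
    v = dict(values)
    v["DYS389II"] = v["DYS389II"] + v["DYS389I"]
    return v


def _evolve(
    founder_internal: dict[str, float],
    g: int,
    rates: dict[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, float], int]:
    """One lineage after g generations of symmetric single-step SMM.

    Returns the internal value map and the number of mutation events.
    """
    out = dict(founder_internal)
    events = 0
    for locus in _EVOLVE_COLUMNS:
        mu = rates[locus]
        k = int(rng.binomial(g, mu)) if g > 0 else 0
        if k:
            steps = rng.choice((-1, 1), size=k).sum()
            out[locus] = out[locus] + float(steps)
            events += k
    return out, events


def _values_to_haplotype(
    values: dict[str, float],
    sample_id: str,
    population: str,
    tribe: str | None,
    clan: str | None = None,
) -> Haplotype:
    calls = {name: AlleleCall.from_values([values[name]]) for name in PANEL_NAMES}
    return Haplotype(sample_id, calls, population, tribe, clan)


def simulate_tribe(
    founder: dict[str, float],
    n: int,
    generations: int,
    rates: dict[str, float] | None = None,
    seed: int | None = None,
    *,
    tribe: str = "Tribe",
    population: str = "Simulated",
    sample_prefix: str = "S",
) -> GenealogySample:
    """Star-genealogy SMM sample: n independent lineages from one founder.

    ``founder`` maps every panel column to a repeat count (raw DYS389II).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rates = rates or default_mutation_rates()
    rng = np.random.default_rng(seed)
    internal = _raw_to_internal(founder)
    records, truth_rows = [], []
    for i in range(n):
        values, events = _evolve(internal, generations, rates, rng)
        raw = _internal_to_raw(values)
        sid = f"{sample_prefix}{i:04d}"
        records.append(_values_to_haplotype(raw, sid, population, tribe))
        truth_rows.append(
            {
                "sample_id": sid,
                "tribe": tribe,
                "founder": tribe,
                "lineage": "founder",
                "mutations": events,
            }
        )
    return GenealogySample(
        HaplotypeTable(records), pd.DataFrame(truth_rows)
    )


def _background_haplotype(
    rng: np.random.Generator, rates: dict[str, float]
) -> dict[str, float]:
    """An unrelated lineage: base alleles with two-sided geometric jitter,
    spread proportional to each locus's mutational volatility."""
    out = {}
    for locus in PANEL_NAMES:
        spread = 2 + int(rates[locus] > 0.008) * 2  # faster loci wander further
        step = int(rng.integers(-spread, spread + 1))
        out[locus] = BASE_HAPLOTYPE[locus] + step
    return out


def _inject_artifacts(
    h: Haplotype, cfg: SimulationConfig, rng: np.random.Generator
) -> Haplotype:
    calls = dict(h.calls)
    if rng.random() < cfg.dys448_null_rate:
        calls["DYS448"] = AlleleCall("null", ())
    if rng.random() < cfg.dys19_dup_rate:
        v = calls["DYS19"].values[0]
        second = v + (1.0 if rng.random() < 0.5 else -1.0)
        calls["DYS19"] = AlleleCall.from_values([v, second])
    if rng.random() < cfg.microvariant_rate:
        v = calls["DYS458"].values[0]
        calls["DYS458"] = AlleleCall.from_values([v + 0.2])
    return Haplotype(h.sample_id, calls, h.population, h.tribe, h.clan)


def simulate_population(cfg: SimulationConfig) -> GenealogySample:
    """Simulate a multi-tribe founder-effect population.

    Tribe founders descend from a shared ancestral haplotype over
    ``split_generations`` of SMM (unless a founder is given explicitly),
    creating related but distinct tribal clusters.  Within each tribe,
    ``founder_fraction`` of samples form the founder star; the rest are
    background lineages.  Artifacts are injected after mutation.
    """
    rng = np.random.default_rng(cfg.seed)
    base_internal = _raw_to_internal(BASE_HAPLOTYPE)

    founders: dict[str, dict[str, float]] = {}
    for spec in cfg.tribes:
        if spec.founder is not None:
            founders[spec.name] = _raw_to_internal(spec.founder)
        else:
            founders[spec.name], _ = _evolve(
                base_internal, cfg.split_generations, cfg.rates, rng
            )

    sizes = [int(round(spec.proportion * cfg.n)) for spec in cfg.tribes]
    sizes[-1] += cfg.n - sum(sizes)

    records, truth_rows = [], []
    idx = 0
    for spec, size in zip(cfg.tribes, sizes):
        n_founder = int(round(spec.founder_fraction * size))
        for j in range(size):
            sid = f"S{idx:04d}"
            idx += 1
            if j < n_founder:
                values, events = _evolve(
                    founders[spec.name], spec.generations, cfg.rates, rng
                )
                raw = _internal_to_raw(values)
                lineage = "founder"
            else:
                raw = _background_haplotype(rng, cfg.rates)
                events = 0
                lineage = "background"
            h = _values_to_haplotype(raw, sid, cfg.population, spec.name)
            h = _inject_artifacts(h, cfg, rng)
            records.append(h)
            truth_rows.append(
                {
                    "sample_id": sid,
                    "tribe": spec.name,
                    "founder": spec.name if lineage == "founder" else "background",
                    "lineage": lineage,
                    "mutations": events,
                }
            )
    return GenealogySample(HaplotypeTable(records), pd.DataFrame(truth_rows))


def fixture_karakalpakstan() -> HaplotypeTable:
    """Deterministic 59-record table with exactly one shared haplotype.

    Synthetic stand-in reproducing the *spectrum* of a small population
    sample in which 58 distinct haplotypes occur and exactly one of them
    is carried by two individuals (57 singletons + 1 doubleton).  The
    allele values themselves are simulated, not real data.
    """
    rates = default_mutation_rates()
    rng = np.random.default_rng(590058)
    internal = _raw_to_internal(BASE_HAPLOTYPE)
    seen: set[tuple] = set()
    records: list[Haplotype] = []
    i = 0
    while len(records) < 58:
        values, _ = _evolve(internal, 30, rates, rng)
        raw = _internal_to_raw(values)
        h = _values_to_haplotype(
            raw, f"KK{i:03d}", "Karakalpakstan Kazakh", None
        )
        key = h.key()
        if key in seen:
            continue
        seen.add(key)
        records.append(h)
        i += 1
    # duplicate the first haplotype to create the single shared pair
    twin = records[0]
    records.append(
        Haplotype("KK058", dict(twin.calls), twin.population, twin.tribe, twin.clan)
    )
    return HaplotypeTable(records)
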