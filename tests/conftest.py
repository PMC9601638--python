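import numpy as np
import pytest

from ystrkit.haplotypes import AlleleCall, Haplotype, HaplotypeTable
from ystrkit.loci import PANEL_NAMES
from ystrkit.simulate import BASE_HAPLOTYPE, fixture_karakalpakstan


def make_haplotype(
    sample_id: str,
    offsets: dict[str, float] | None = None,
    population: str = "Pop",
    tribe: str | None = None,
    **call_overrides: AlleleCall,
) -> Haplotype:
    """A base haplotype with per-locus offsets and explicit call overrides."""
    calls = {}
    for name in PANEL_NAMES:
        v = BASE_HAPLOTYPE[name] + (offsets or {}).get(name, 0)
        calls[name] = AlleleCall.from_values([v])
    calls.update(call_overrides)
    return Haplotype(sample_id, calls, population, tribe)


def random_table(rng: np.random.Generator, n: int, spread: int = 1) -> HaplotypeTable:
    """Random table over the full panel; small spread forces collisions."""
    records = []
    for i in range(n):
        offsets = {
            name: int(rng.integers(-spread, spread + 1)) for name in PANEL_NAMES
        }
        records.append(make_haplotype(f"R{i:03d}", offsets))
    return HaplotypeTable(records)


@pytest.fixture(scope="session")
def karakalpakstan_table() -> HaplotypeTable:
    return fixture_karakalpakstan()
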