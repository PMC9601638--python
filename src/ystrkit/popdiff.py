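"""Population differentiation: squared repeat-count distances, two-level
AMOVA, R_ST matrices, permutation significance, and classical MDS.

R_ST is the microsatellite analogue of F_ST: the analysis of molecular
variance is run on squared differences of repeat counts, which weights
allele pairs by their mutational distance under the stepwise model.  The
decomposition for P populations with sizes n_p (N = Σ n_p), writing
δ_ij for the squared repeat distance between individuals i and j:

    SSD_total  = (1/N) Σ_{i<j} δ_ij                (all pairs)
    SSD_within = Σ_p (1/n_p) Σ_{i<j ∈ p} δ_ij
    SSD_among  = SSD_total − SSD_within
    σ²_w = SSD_within / (N − P)
    σ²_a = (SSD_among / (P − 1) − σ²_w) / n′,  n′ = (N − Σ n_p²/N)/(P − 1)
    Φ_ST = σ²_a / (σ²_a + σ²_w)

Distances operate on the 23-locus network panel with DYS389II adjusted;
multi-copy loci are excluded.  Microvariant alleles enter through their
numeric values (a 0.2-repeat difference contributes 0.04).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable, adjust_dys389_table, filter_for_network
from .loci import NETWORK_LOCI

__all__ = [
    "AmovaResult",
    "DistanceMatrix",
    "MdsResult",
    "repeat_vectors",
    "repeat_distance",
    "amova_two_level",
    "rst_matrix",
    "permutation_test",
    "classical_mds",
]


def repeat_vectors(t: HaplotypeTable) -> np.ndarray:
    """Extract the (n, 23) matrix of repeat counts for the network panel.

    The table must already be network-filtered (exactly one numeric value
    per network locus) and DYS389-adjusted.
    """
    if not t.dys389_adjusted:
        raise ValueError("adjust DYS389II before computing repeat vectors")
    rows = []
    for h in t.records:
        vals = []
        for locus in NETWORK_LOCI:
            call = h.calls[locus]
            if not call.is_single_numeric:
                raise ValueError(
                    f"sample {h.sample_id}: {locus} is {call.state}; "
                    "apply filter_for_network first"
                )
            vals.append(call.values[0])
        rows.append(vals)
    return np.asarray(rows, dtype=float)


def repeat_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Squared repeat distance Σ_l (a_l − b_l)² between two repeat vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"panel mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(d @ d)


def _squared_distance_matrix(x: np.ndarray) -> np.ndarray:
    g = x @ x.T
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


@dataclass(frozen=True)
class AmovaResult:
    """Two-level AMOVA decomposition with raw (possibly negative) Φ_ST."""

    ssd_total: float
    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_a: float
    sigma2_w: float
    n_prime: float
    phi_st: float

    @property
    def rst(self) -> float:
        """Φ_ST clamped to [0, 1], the conventional reported R_ST."""
        return min(max(self.phi_st, 0.0), 1.0)


def amova_two_level(groups: list[np.ndarray]) -> AmovaResult:
    """Two-level AMOVA on squared repeat distances between individuals.

    ``groups`` is a list of (n_p, L) repeat-count arrays, one per
    population.  Requires at least two groups and N − P ≥ 1 within-group
    degrees of freedom.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    P = len(groups)
    if P < 2:
        raise ValueError("AMOVA needs at least two groups")
    sizes = [g.shape[0] for g in groups]
    N = sum(sizes)
    if N - P < 1:
        raise ValueError(
            "AMOVA needs at least one within-group degree of freedom (N - P >= 1)"
        )
    x = np.vstack(groups)
    d2 = _squared_distance_matrix(x)
    iu = np.triu_indices(N, k=1)
    ssd_total = d2[iu].sum() / N

    ssd_within = 0.0
    start = 0
    for n_p in sizes:
        block = d2[start : start + n_p, start : start + n_p]
        ssd_within += block[np.triu_indices(n_p, k=1)].sum() / n_p
        start += n_p
    ssd_among = ssd_total - ssd_within

    df_among = P - 1
    df_within = N - P
    sigma2_w = ssd_within / df_within
    n_prime = (N - sum(n * n for n in sizes) / N) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_w) / n_prime
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom > 0 else 0.0
    return AmovaResult(
        ssd_total=ssd_total,
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        df_among=df_among,
        df_within=df_within,
        sigma2_a=sigma2_a,
        sigma2_w=sigma2_w,
        n_prime=n_prime,
        phi_st=phi,
    )


def permutation_test(
    groups: list[np.ndarray], n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Permutation p-value for Φ_ST (individuals shuffled across groups).

    Returns ``(observed_phi, p)`` with p = (1 + #{Φ_perm ≥ Φ_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    observed = amova_two_level(groups).phi_st
    sizes = [g.shape[0] for g in groups]
    pooled = np.vstack(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        shuffled = pooled[perm]
        parts, start = [], 0
        for n_p in sizes:
            parts.append(shuffled[start : start + n_p])
            start += n_p
        if amova_two_level(parts).phi_st >= observed:
            hits += 1
    return observed, (1 + hits) / (n_perm + 1)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled distance matrix (clamped pairwise R_ST)."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "d", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))


def rst_matrix(
    t: HaplotypeTable, group_by: str = "population"
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise R_ST between groups of a haplotype table.

    Records failing the network filter are excluded (their accounting is
    returned as the second element).  DYS389 adjustment is applied here if
    the table still holds raw counts.
    """
    kept, report = filter_for_network(t)
    if not kept.dys389_adjusted:
        kept, _ = adjust_dys389_table(kept)
    labels = kept.group_labels(group_by)
    x = repeat_vectors(kept)
    names = sorted(set(labels))
    arrays = {g: x[[i for i, lab in enumerate(labels) if lab == g]] for g in names}
    names = [g for g in names if arrays[g].shape[0] > 0]
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups for R_ST")
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = amova_two_level([arrays[names[i]], arrays[names[j]]])
            d[i, j] = d[j, i] = res.rst
    return DistanceMatrix(tuple(names), d), report


@dataclass(frozen=True)
class MdsResult:
    """Classical (Torgerson) MDS embedding with Kruskal stress-1."""

    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    stress: float

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.labels), columns=cols)


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 between a target distance matrix and the Euclidean
    distances of an embedding: sqrt(Σ(d_ij − D_ij)² / Σ d_ij²)."""
    emb = _squared_distance_matrix(coords) ** 0.5
    iu = np.triu_indices(d.shape[0], k=1)
    num = float(((d[iu] - emb[iu]) ** 2).sum())
    den = float((d[iu] ** 2).sum())
    if den == 0.0:
        return 0.0
    return (num / den) ** 0.5


def classical_mds(dm: DistanceMatrix, k: int = 2) -> MdsResult:
    """Metric MDS by Torgerson double centering.

    Negative eigenvalues (non-Euclidean input) are truncated to zero; the
    embedding uses the k leading non-negative components.
    """
    n = len(dm.labels)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}]")
    d2 = dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals[:k], 0.0, None)
    coords = vecs[:, :k] * np.sqrt(pos)[None, :]
    return MdsResult(
        labels=dm.labels,
        coordinates=coords,
        eigenvalues=vals,
        stress=kruskal_stress(dm.d, coords),
    )
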