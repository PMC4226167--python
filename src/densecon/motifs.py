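"""Triplet-motif analysis of the statistical connectome.

Three neurons can be wired in 2^6 = 64 labeled configurations of directed
edges over the ordered pairs (1,2),(2,1),(1,3),(3,1),(2,3),(3,2).  Grouping
configurations that differ only by a relabeling of the three nodes (the 6
permutations of S3) leaves 16 non-redundant motif classes: 7 with all three
node pairs connected, 6 with two, 2 with one, and the empty motif.

Because the statistical connectome gives an independent Bernoulli
probability p_e for every directed edge, the probability of each labeled
configuration is the product over the six edges of p_e or (1 - p_e), and a
motif-class probability is the sum over its member configurations.  A
population-level spectrum averages these class probabilities over sampled
neuron triplets (sharing at most one neuron between any two triplets) and
is compared against the spectrum of a uniformly connected network with the
population's mean pairwise connection probability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EDGE_ORDER",
    "MotifClass",
    "MotifSpectrum",
    "enumerate_motif_classes",
    "triplet_spectrum",
    "sample_triplets",
    "population_spectrum",
    "uniform_null_comparison",
]

#: Bit order of the 6 directed edges among nodes 0, 1, 2.
EDGE_ORDER: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1),
)
_EDGE_INDEX = {e: i for i, e in enumerate(EDGE_ORDER)}
N_CONFIGURATIONS = 64


def _edges_of(config: int) -> list[tuple[int, int]]:
    return [e for i, e in enumerate(EDGE_ORDER) if config >> i & 1]


def _permute_configuration(config: int, perm: tuple[int, int, int]) -> int:
    out = 0
    for i, (a, b) in enumerate(EDGE_ORDER):
        if config >> i & 1:
            out |= 1 << _EDGE_INDEX[(perm[a], perm[b])]
    return out


def _connected_pairs(config: int) -> int:
    """Number of unordered node pairs joined by at least one edge."""
    pairs = {frozenset(e) for e in _edges_of(config)}
    return len(pairs)


@dataclass(frozen=True)
class MotifClass:
    """Isomorphism class of triplet configurations.

    ``representative`` is the lexicographically smallest member (as a 6-bit
    integer in :data:`EDGE_ORDER` bit order); ``edge_count`` counts distinct
    connected node pairs (0..3), not directed edges.
    """

    id: int
    representative: int
    members: tuple[int, ...]
    edge_count: int


def enumerate_motif_classes() -> list[MotifClass]:
    """Partition the 64 configurations under node-permutation isomorphism.

    Classes are numbered 1..16, ordered by connected-pair count descending
    (three-connected first, the empty motif last) and then by smallest
    representative.  The numbering is canonical to this package; published
    pictogram orders are graphical and may differ.
    """
    perms = list(itertools.permutations(range(3)))
    seen: set[int] = set()
    classes: list[tuple[int, tuple[int, ...]]] = []
    for config in range(N_CONFIGURATIONS):
        if config in seen:
            continue
        orbit = sorted({_permute_configuration(config, p) for p in perms})
        seen.update(orbit)
        classes.append((orbit[0], tuple(orbit)))
    classes.sort(key=lambda c: (-_connected_pairs(c[0]), c[0]))
    return [
        MotifClass(id=i + 1, representative=rep, members=members,
                   edge_count=_connected_pairs(rep))
        for i, (rep, members) in enumerate(classes)
    ]


_CLASSES = None


def _classes() -> list[MotifClass]:
    global _CLASSES
    if _CLASSES is None:
        _CLASSES = enumerate_motif_classes()
    return _CLASSES


@dataclass
class MotifSpectrum:
    """Probability of each of the 16 motif classes (sums to 1)."""

    probabilities: np.ndarray
    sds: np.ndarray | None = None
    classes: list[MotifClass] = field(default_factory=_classes)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.classes),):
            raise ValueError("spectrum length must match the class count")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"motif_id": c.id, "edge_count": c.edge_count,
             "n_members": len(c.members), "prob": p}
            for c, p in zip(self.classes, self.probabilities)
        ]
        df = pd.DataFrame(rows)
        if self.sds is not None:
            df["prob_sd"] = self.sds
        return df


def _configuration_probabilities(p: np.ndarray) -> np.ndarray:
    """Probability of each of the 64 configurations from 6 edge probabilities."""
    out = np.empty(N_CONFIGURATIONS)
    for config in range(N_CONFIGURATIONS):
        prob = 1.0
        for i in range(6):
            prob *= p[i] if config >> i & 1 else 1.0 - p[i]
        out[config] = prob
    return out


def triplet_spectrum(p) -> MotifSpectrum:
    """Motif spectrum of one triplet from its six directed-edge probabilities.

    ``p`` is ordered like :data:`EDGE_ORDER`:
    (p12, p21, p13, p31, p23, p32).
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (6,):
        raise ValueError("expected six edge probabilities")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("edge probabilities must lie in [0, 1]")
    config_probs = _configuration_probabilities(p)
    probs = np.array([
        config_probs[list(c.members)].sum() for c in _classes()
    ])
    return MotifSpectrum(probs)


# ---------------------------------------------------------------------------
# population-level spectra
# ---------------------------------------------------------------------------

def max_feasible_triplets(n: int) -> int:
    """Upper bound on triplets sharing at most one neuron pairwise: each
    triplet consumes three distinct unordered pairs."""
    return n * (n - 1) // 6


def sample_triplets(n: int, n_triplets: int, rng: np.random.Generator,
                    max_attempts_factor: int = 200) -> list[tuple[int, int, int]]:
    """Uniform triplet sample subject to <= 1 shared neuron between triplets.

    Two triplets share at most one neuron iff no unordered pair of neurons
    appears in two triplets, so sampling marks each accepted triplet's three
    pairs as used (rejection sampling with an attempt cap).
    """
    if n < 3:
        raise ValueError("population must contain at least 3 neurons")
    bound = max_feasible_triplets(n)
    if n_triplets > bound:
        raise ValueError(
            f"cannot draw {n_triplets} triplets from {n} neurons under the "
            f"one-shared-neuron constraint; at most {bound} are feasible"
        )
    used_pairs: set[frozenset] = set()
    triplets: list[tuple[int, int, int]] = []
    attempts = 0
    cap = max_attempts_factor * n_triplets
    while len(triplets) < n_triplets:
        if attempts >= cap:
            raise RuntimeError(
                f"triplet sampling stalled after {attempts} attempts with "
                f"{len(triplets)}/{n_triplets} triplets; request fewer "
                f"triplets (feasible bound: {bound})"
            )
        attempts += 1
        tri = tuple(int(v) for v in rng.choice(n, size=3, replace=False))
        pairs = [frozenset(c) for c in itertools.combinations(tri, 2)]
        if any(pr in used_pairs for pr in pairs):
            continue
        used_pairs.update(pairs)
        triplets.append(tri)
    return triplets


def _edge_probabilities(p_matrix: np.ndarray,
                        tri: tuple[int, int, int]) -> np.ndarray:
    a, b, c = tri
    return np.array([
        p_matrix[a, b], p_matrix[b, a], p_matrix[a, c],
        p_matrix[c, a], p_matrix[b, c], p_matrix[c, b],
    ])


def population_spectrum(p_matrix: np.ndarray, n_triplets: int = 2000,
                        n_repeats: int = 10, seed: int = 0) -> MotifSpectrum:
    """Motif spectrum of a population, mean +/- SD over sampling repeats.

    ``p_matrix`` is the square matrix of pairwise connection probabilities
    (diagonal ignored).  Each repeat draws ``n_triplets`` triplets under the
    one-shared-neuron constraint, averages their spectra, and the repeat
    means yield the across-repeat SD.  If the population is exactly three
    neurons the single triplet's analytic spectrum is returned.
    """
    p_matrix = np.asarray(p_matrix, dtype=float)
    if p_matrix.ndim != 2 or p_matrix.shape[0] != p_matrix.shape[1]:
        raise ValueError("p_matrix must be square")
    n = p_matrix.shape[0]
    if n == 3:
        spec = triplet_spectrum(_edge_probabilities(p_matrix, (0, 1, 2)))
        spec.sds = np.zeros(len(spec.probabilities))
        return spec
    root = np.random.SeedSequence(seed)
    repeat_means = []
    for rep_seq in root.spawn(n_repeats):
        rng = np.random.default_rng(rep_seq)
        tris = sample_triplets(n, n_triplets, rng)
        spectra = np.stack([
            triplet_spectrum(_edge_probabilities(p_matrix, tri)).probabilities
            for tri in tris
        ])
        repeat_means.append(spectra.mean(axis=0))
    repeat_means = np.stack(repeat_means)
    return MotifSpectrum(
        probabilities=repeat_means.mean(axis=0),
        sds=repeat_means.std(axis=0, ddof=1) if n_repeats > 1
        else np.zeros(repeat_means.shape[1]),
    )


def uniform_null_comparison(spectrum: MotifSpectrum,
                            p_uniform: float) -> pd.DataFrame:
    """Deviation and z-score of a spectrum against uniform connectivity.

    The null sets all six edge probabilities to ``p_uniform`` (deterministic
    closed form); deviation = (observed - null) / null and
    z = (observed - null) / across-repeat SD.  A zero-null class observed
    with positive probability is flagged with infinite deviation.
    """
    if not 0.0 <= p_uniform <= 1.0:
        raise ValueError("p_uniform must lie in [0, 1]")
    null = triplet_spectrum(np.full(6, p_uniform)).probabilities
    obs = spectrum.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        deviation = np.where(null > 0, (obs - null) / null,
                             np.where(obs > 0, np.inf, 0.0))
    sds = spectrum.sds
    if sds is None:
        z = np.full_like(obs, np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sds > 0, (obs - null) / sds, np.nan)
    df = MotifSpectrum(obs, sds).to_frame()
    df = df.rename(columns={"prob": "prob_mean"})
    df["null_prob"] = null
    df["deviation"] = deviation
    df["z"] = z
    return df
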