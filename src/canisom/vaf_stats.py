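"""VAF-distribution statistics: histograms, Jensen–Shannon divergence,
label-permutation testing, and the 6-class base-substitution spectrum.

Two binned VAF distributions are compared by JS divergence in bits,
JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m = (p + q)/2 and base-2 logs, so
identical distributions score 0 and disjoint supports score 1. Significance
comes from a permutation test: the two groups are pooled, relabeled at the
original group sizes, and the p-value is the proportion of permuted JS
divergences strictly greater than the observed one (no +1 correction; the
1/n_perm resolution floor is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import rel_entr

from .variant_io import VariantCall

_LN2 = np.log(2.0)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_PURINE_TO_PYRIMIDINE = {"G": "C", "A": "T"}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class VafDistribution:
    """A binned VAF distribution on [0, 1] with unit total mass."""

    edges: tuple[float, ...]
    masses: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges)
        masses = np.asarray(self.masses)
        if len(edges) != len(masses) + 1:
            raise ValueError("need len(edges) == len(masses) + 1")
        if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must increase strictly from 0 to 1")
        if np.any(masses < 0) or abs(masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must be >= 0 and sum to 1")

    @classmethod
    def from_values(cls, values: Sequence[float], bins: int = 20) -> "VafDistribution":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("cannot build a VAF distribution from no values")
        edges = np.linspace(0.0, 1.0, bins + 1)
        counts, _ = np.histogram(np.clip(values, 0.0, 1.0), bins=edges)
        masses = counts / counts.sum()
        return cls(tuple(edges), tuple(masses), int(values.size))


def js_divergence(p: VafDistribution, q: VafDistribution) -> float:
    """Jensen–Shannon divergence between two binned distributions, in bits."""
    if p.edges != q.edges:
        raise ValueError("distributions must share bin edges")
    return _jsd_bits(np.asarray(p.masses), np.asarray(q.masses))


def _jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    val = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / _LN2
    return float(min(max(val, 0.0), 1.0))


@dataclass(frozen=True)
class PermutationResult:
    """Observed JSD with its permutation p-value.

    ``p`` counts strictly greater permuted divergences, as defined;
    ``p_floor = 1/n_perm`` is the estimator's resolution (a reported p of 0
    means p < p_floor).
    """

    observed: float
    p: float
    n_perm: int
    n_greater: int

    @property
    def p_floor(self) -> float:
        return 1.0 / self.n_perm


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
    bins: int = 20,
) -> PermutationResult:
    """Label-permutation test of whether two VAF samples share a distribution.

    The pooled values are repeatedly split at the original group sizes and
    the JS divergence of the binned splits recomputed; permutations are
    vectorized over blocks. Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges = np.linspace(0.0, 1.0, bins + 1)
    pooled = np.concatenate([a, b])
    # bin index per pooled value; right edge closed on the last bin
    idx = np.clip(np.searchsorted(edges, pooled, side="right") - 1, 0, bins - 1)
    onehot = np.zeros((pooled.size, bins))
    onehot[np.arange(pooled.size), idx] = 1.0
    totals = onehot.sum(axis=0)

    counts_a = onehot[: a.size].sum(axis=0)
    observed = _jsd_bits(counts_a / a.size, (totals - counts_a) / b.size)

    labels = np.zeros(pooled.size)
    labels[: a.size] = 1.0
    n_greater = 0
    block = max(1, min(n_perm, 4_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        perm = rng.permuted(np.tile(labels, (k, 1)), axis=1)
        ca = perm @ onehot  # (k, bins) counts in group a
        pa = ca / a.size
        pb = (totals[None, :] - ca) / b.size
        m = 0.5 * (pa + pb)
        jsd = 0.5 * (rel_entr(pa, m).sum(axis=1) + rel_entr(pb, m).sum(axis=1)) / _LN2
        n_greater += int(np.count_nonzero(jsd > observed + 1e-12))
        done += k
    return PermutationResult(observed, n_greater / n_perm, n_perm, n_greater)


@dataclass(frozen=True)
class SpectrumCounts:
    """Counts over the 6 pyrimidine-collapsed substitution classes."""

    counts: dict[str, int]
    n_non_snv: int = 0

    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {c: 0.0 for c in SUBSTITUTION_CLASSES}
        return {c: self.counts[c] / total for c in SUBSTITUTION_CLASSES}


def collapse_substitution(ref: str, alt: str) -> str | None:
    """Collapse a single-base substitution to its pyrimidine-reference class."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if ref in _PURINE_TO_PYRIMIDINE:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{ref}>{alt}"
    return label if label in SUBSTITUTION_CLASSES else None


def spectrum(calls: Iterable[VariantCall]) -> SpectrumCounts:
    """Base-substitution spectrum of a call set; non-SNVs counted separately."""
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    non_snv = 0
    for call in calls:
        label = collapse_substitution(call.ref, call.alt)
        if label is None:
            non_snv += 1
        else:
            counts[label] += 1
    return SpectrumCounts(counts, non_snv)
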