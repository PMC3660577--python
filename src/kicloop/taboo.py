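"""Taboo-sampling bookkeeping: torsion-bin vectors, the TabooMap and the
weighted refill of the vector list, plus the native bin vector used by
torsion-restricted sampling.

A torsion bin vector is a string over {A, B, E, G, a, b, e, g}, one character
per segment residue; lowercase marks a cis peptide bond at that position.
Coverage is accounted over the 4^L phi/psi bin space, so vectors are
uppercase-normalised before being stored in the map (cis/trans variants of
the same phi/psi vector count once).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .geometry import Pose, SegmentDefinition
from .priors import BINS, Tables, bin_probability, classify_bin

ALPHABET = set("ABEGabeg")
BIN_INDEX = {b: i for i, b in enumerate(BINS)}

#: list size from the protocol: refilled whenever exhausted
DEFAULT_LIST_SIZE = 1000
#: the map is cleared when this fraction of bin space has been covered
CLEAR_THRESHOLD = 0.95
#: |omega| below this (degrees) classifies a peptide bond as cis
CIS_OMEGA_CUTOFF = 90.0

# above this many total vectors the refill switches from exact enumeration of
# the untested set to rejection sampling (4^L grows to ~17M at L=12)
_ENUMERATION_LIMIT = 4 ** 8


def validate_vector(v: str, length: int | None = None) -> str:
    if length is not None and len(v) != length:
        raise ValueError(f"bin vector {v!r} has length {len(v)}, expected {length}")
    if not set(v) <= ALPHABET:
        raise ValueError(f"bin vector {v!r} contains characters outside ABEGabeg")
    return v


@dataclass
class TabooMap:
    """History of sampled torsion-bin vectors for one segment.

    ``counts[p, b]`` is how often bin ``BINS[b]`` has been sampled at segment
    position ``p`` — these survive a clear event so that the frequency
    adjustment keeps steering away from over-sampled bins.
    """

    length: int
    threshold: float = CLEAR_THRESHOLD
    vectors: set = field(default_factory=set)
    counts: np.ndarray = None
    n_cleared: int = 0

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((self.length, len(BINS)), dtype=np.int64)

    @property
    def coverage(self) -> float:
        return len(self.vectors) / float(4 ** self.length)

    def __contains__(self, v: str) -> bool:
        return v.upper() in self.vectors

    def record(self, v: str) -> None:
        """Record a sampled vector; clears the set (counts retained) once
        coverage reaches the threshold."""
        validate_vector(v, self.length)
        self.vectors.add(v.upper())
        for p, ch in enumerate(v.upper()):
            self.counts[p, BIN_INDEX[ch]] += 1
        if self.coverage >= self.threshold:
            self.vectors.clear()
            self.n_cleared += 1


def record_vector(tmap: TabooMap, v: str) -> TabooMap:
    tmap.record(v)
    return tmap


def adjusted_bin_weights(tmap: TabooMap, aas, tables: Tables,
                         mode: str = "standard",
                         left_flank_aa: str | None = None,
                         right_flank_aa: str | None = None) -> np.ndarray:
    """(L, 4) per-position bin weights: prior probability of the bin for the
    residue type, divided by (1 + how often the bin was already sampled at
    that position), renormalised per position.

    The division is this package's concrete realisation of comparing the
    type's preferences with the sampling history: monotone-decreasing in the
    sampled count and never zero.
    """
    L = tmap.length
    w = np.zeros((L, len(BINS)))
    for p, aa in enumerate(aas):
        left = aas[p - 1] if p > 0 else left_flank_aa
        right = aas[p + 1] if p < L - 1 else right_flank_aa
        next_aa = right
        for b, bin_ in enumerate(BINS):
            prior = bin_probability(aa, bin_, tables, mode=mode,
                                    left_aa=left, right_aa=right,
                                    next_aa=next_aa)
            w[p, b] = prior / (1.0 + tmap.counts[p, b])
        w[p] /= w[p].sum()
    return w


def _vector_weight(v: str, w: np.ndarray) -> float:
    return float(np.prod([w[p, BIN_INDEX[ch]] for p, ch in enumerate(v)]))


def refill_vector_list(tmap: TabooMap, aas, tables: Tables,
                       mode: str = "standard",
                       rng: np.random.Generator | None = None,
                       size: int = DEFAULT_LIST_SIZE,
                       left_flank_aa: str | None = None,
                       right_flank_aa: str | None = None) -> list:
    """A fresh list of untested torsion-bin vectors.

    Returns ``min(size, #untested)`` distinct vectors not present in the map,
    drawn without replacement with probability proportional to the product of
    per-position adjusted bin weights.  For small 4^L the untested set is
    enumerated exactly; for long segments vectors are drawn position-wise
    (the product weight factorises) and duplicates/tested vectors rejected.
    """
    rng = rng if rng is not None else np.random.default_rng()
    L = tmap.length
    if len(aas) != L:
        raise ValueError(f"{len(aas)} residue types for segment length {L}")
    w = adjusted_bin_weights(tmap, aas, tables, mode, left_flank_aa, right_flank_aa)
    total = 4 ** L
    if total <= _ENUMERATION_LIMIT:
        untested = ["".join(t) for t in itertools.product(BINS, repeat=L)
                    if "".join(t) not in tmap.vectors]
        assert untested, "clearing invariant violated: bin space exhausted"
        weights = np.array([_vector_weight(v, w) for v in untested])
        # weighted sampling without replacement via exponential sort keys
        keys = rng.exponential(size=len(untested)) / weights
        order = np.argsort(keys)
        return [untested[i] for i in order[:min(size, len(untested))]]
    chosen: list = []
    seen = set()
    while len(chosen) < size:
        draws = np.stack([rng.choice(len(BINS), size=4 * size, p=w[p])
                          for p in range(L)], axis=1)
        for row in draws:
            v = "".join(BINS[b] for b in row)
            if v in seen or v in tmap.vectors:
                continue
            seen.add(v)
            chosen.append(v)
            if len(chosen) == size:
                break
    return chosen


def next_vector(vector_list: list, tmap: TabooMap) -> str | None:
    """Pop entries off the front of the list until one is found that is not
    already in the map; returns None if the list is exhausted (caller
    refills)."""
    while vector_list:
        v = vector_list.pop(0)
        if v not in tmap:
            return v
    return None


@dataclass
class TabooSampler:
    """Owns the TabooMap and the vector list; hands out the next untested
    vector, refilling the list whenever it runs dry."""

    aas: list
    tables: Tables
    mode: str = "standard"
    size: int = DEFAULT_LIST_SIZE
    left_flank_aa: str | None = None
    right_flank_aa: str | None = None
    tmap: TabooMap = None
    _list: list = field(default_factory=list)

    def __post_init__(self):
        if self.tmap is None:
            self.tmap = TabooMap(length=len(self.aas))

    def next_vector(self, rng: np.random.Generator) -> str:
        v = next_vector(self._list, self.tmap)
        while v is None:
            self._list = refill_vector_list(
                self.tmap, self.aas, self.tables, self.mode, rng, self.size,
                self.left_flank_aa, self.right_flank_aa)
            v = next_vector(self._list, self.tmap)
        return v

    def record(self, v: str) -> None:
        self.tmap.record(v)


def native_bin_vector(native: Pose, segment: SegmentDefinition) -> str:
    """The constant bin vector for torsion-restricted sampling: per segment
    residue the bin of the native phi/psi, lowercased where the native
    peptide bond into the residue is cis (|omega| < 90)."""
    chars = []
    for resi in segment.residues():
        i = resi - 1
        phi, psi = native.phi[i], native.psi[i]
        if not (np.isfinite(phi) and np.isfinite(psi)):
            raise ValueError(
                f"residue {resi}: undefined native phi/psi inside the segment"
            )
        ch = classify_bin(phi, psi)
        omega = native.omega[i]
        if np.isfinite(omega) and abs(omega) < CIS_OMEGA_CUTOFF:
            ch = ch.lower()
        chars.append(ch)
    return "".join(chars)
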