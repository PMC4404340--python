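"""Pairwise evolutionary distances (p, Kimura 2-parameter) and NJ trees.

Distance matrices use pairwise deletion: each pair is compared over the
columns where both sequences carry an unambiguous base. This differs
deliberately from the complete-deletion rule used for haplotype identity
and site statistics (the MEGA-vs-DnaSP split typical of barcode studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from mitopop.haplotypes import HaplotypeSet, is_transition
from mitopop.seqio import Alignment, LabeledMatrix


class SaturationError(ValueError):
    """K2P log argument non-positive: the pair is saturated."""


@dataclass(frozen=True)
class PairCounts:
    """Transition (P) and transversion (Q) difference proportions."""

    P: float
    Q: float
    sites_compared: int

    @property
    def p_dist(self) -> float:
        return self.P + self.Q


_UNAMBIG = frozenset("ACGT")


def pair_counts(seq_a: str, seq_b: str) -> PairCounts:
    """Count transition/transversion mismatch proportions for one pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    ts = tv = m = 0
    for a, b in zip(seq_a, seq_b):
        if a in _UNAMBIG and b in _UNAMBIG:
            m += 1
            if a != b:
                if is_transition(a, b):
                    ts += 1
                else:
                    tv += 1
    if m == 0:
        raise ValueError("no comparable sites between the two sequences")
    return PairCounts(P=ts / m, Q=tv / m, sites_compared=m)


def k2p(counts: PairCounts) -> float:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: P={counts.P:.4f}, Q={counts.Q:.4f}"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pair_distance(seq_a: str, seq_b: str, model: str = "k2p") -> float:
    c = pair_counts(seq_a, seq_b)
    if model == "p":
        return c.p_dist
    if model == "k2p":
        return k2p(c)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(
    data: Alignment | HaplotypeSet, model: str = "k2p"
) -> LabeledMatrix:
    """Pairwise distance matrix among sequences (or haplotypes).

    Saturated pairs under K2P are recorded as NaN rather than raising.
    """
    if isinstance(data, HaplotypeSet):
        labels = data.haplotype_ids
        seqs = data.sequences
    else:
        labels = data.ids
        seqs = data.seqs
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pair_distance(seqs[i], seqs[j], model=model)
            except SaturationError:
                d = np.nan
            m[i, j] = m[j, i] = d
    return LabeledMatrix(tuple(labels), m)


def nj_tree(m: LabeledMatrix, outgroup: str | None = None) -> str:
    """Neighbor-joining (Saitou-Nei) tree in newick, optionally rooted.

    Negative branch lengths are clamped to zero. NaN entries are rejected
    with the offending pairs listed.
    """
    if m.n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    bad = [
        (m.labels[i], m.labels[j])
        for i in range(m.n)
        for j in range(i + 1, m.n)
        if not np.isfinite(m.values[i, j])
    ]
    if bad:
        raise ValueError(f"distance matrix has NA entries for pairs: {bad}")
    dm = _SkbioDM(m.values, ids=list(m.labels))
    tree = _skbio_nj(dm)  # clamps negative branch lengths by default
    if outgroup is not None:
        if outgroup not in m.labels:
            raise ValueError(f"outgroup {outgroup!r} not among taxa")
        tree = tree.root_at(tree.find(outgroup).parent)
    return str(tree).strip()
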