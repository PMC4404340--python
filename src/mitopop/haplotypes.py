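"""Haplotype collapsing and site-level polymorphism summaries.

Individuals with identical sequences over the analysis sites share a
haplotype. Analysis sites are the alignment columns free of gaps and
ambiguity codes in every record ("complete deletion"), the DnaSP-style
convention, so haplotype identity and all site statistics share one site
universe.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from mitopop.seqio import Alignment, AlignmentError

_UNAMBIGUOUS = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T."""
    pair = {a, b}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def analysis_columns(aln: Alignment) -> np.ndarray:
    """Indices of columns with an unambiguous base (ACGT) in every record."""
    mat = aln.to_matrix()
    ok = np.isin(mat, list(_UNAMBIGUOUS)).all(axis=0)
    return np.flatnonzero(ok)


@dataclass(frozen=True)
class HaplotypeSet:
    """Distinct sequences with their frequencies and member sample ids.

    ``sequences`` are restricted to the analysis sites. Haplotype ids are
    H1..HK in order of first appearance in the source alignment.
    """

    haplotype_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    frequencies: tuple[int, ...]
    members: tuple[tuple[str, ...], ...]
    L_used: int

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("haplotype sequences differ in length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("haplotype sequences are not distinct")
        if any(f < 1 for f in self.frequencies):
            raise ValueError("haplotype frequencies must be >= 1")
        for f, mem in zip(self.frequencies, self.members):
            if mem and len(mem) != f:
                raise ValueError("member list length disagrees with frequency")

    @property
    def n(self) -> int:
        return int(sum(self.frequencies))

    @property
    def K(self) -> int:
        return len(self.haplotype_ids)

    @property
    def p(self) -> np.ndarray:
        """Relative haplotype frequencies p_i = f_i / n."""
        f = np.asarray(self.frequencies, dtype=float)
        return f / f.sum()

    @classmethod
    def from_frequencies(cls, freqs, sequences=None) -> "HaplotypeSet":
        """Build from a bare frequency spectrum (no sequences known).

        Used for published haplotype-frequency tables; sequence-dependent
        statistics are unavailable unless ``sequences`` is given.
        """
        freqs = tuple(int(f) for f in freqs)
        K = len(freqs)
        if sequences is None:
            sequences = tuple(f"?{i:06d}" for i in range(K))  # distinct placeholders
            L = 0
        else:
            sequences = tuple(sequences)
            L = len(sequences[0])
        ids = tuple(f"H{i + 1}" for i in range(K))
        return cls(ids, sequences, freqs, tuple(() for _ in range(K)), L)

    def expand(self) -> Alignment:
        """Alignment with each haplotype repeated to its frequency."""
        ids, seqs = [], []
        for hid, seq, f, mem in zip(
            self.haplotype_ids, self.sequences, self.frequencies, self.members
        ):
            names = mem if mem else tuple(f"{hid}_{k}" for k in range(f))
            for name in names:
                ids.append(name)
                seqs.append(seq)
        return Alignment(tuple(ids), tuple(seqs))


def collapse_haplotypes(aln: Alignment) -> HaplotypeSet:
    """Collapse an alignment into distinct haplotypes over analysis sites."""
    cols = analysis_columns(aln)
    if cols.size == 0:
        raise AlignmentError(
            "no analysis sites remain after complete deletion of "
            "gapped/ambiguous columns"
        )
    mat = aln.to_matrix()[:, cols]
    reduced = ["".join(row) for row in mat]
    order: dict[str, int] = {}
    members: list[list[str]] = []
    for sid, seq in zip(aln.ids, reduced):
        if seq not in order:
            order[seq] = len(order)
            members.append([])
        members[order[seq]].append(sid)
    seqs = tuple(order.keys())
    ids = tuple(f"H{i + 1}" for i in range(len(seqs)))
    freqs = tuple(len(m) for m in members)
    return HaplotypeSet(ids, seqs, freqs, tuple(tuple(m) for m in members), len(cols))


@dataclass(frozen=True)
class SiteSummary:
    """Counts of polymorphic / parsimony-informative sites and mutations."""

    S: int
    PI: int
    n_ts: int
    n_tv: int
    base_comp: dict[str, float] = field(repr=False)
    L_used: int = 0

    @property
    def n_substitutions(self) -> int:
        return self.n_ts + self.n_tv

    @property
    def at_content(self) -> float:
        return self.base_comp["A"] + self.base_comp["T"]


def site_summary(hset: HaplotypeSet) -> SiteSummary:
    """Column-wise polymorphism summary, weighted by haplotype frequency.

    A column with m observed states contributes m-1 substitutions, each
    classified transition or transversion relative to the column's
    frequency-weighted majority state. Parsimony-informative columns have
    at least two states each carried by at least two individuals.
    """
    freqs = np.asarray(hset.frequencies, dtype=float)
    n = freqs.sum()
    if hset.K == 0 or not hset.sequences[0] or hset.sequences[0].startswith("?"):
        raise ValueError("site summary requires haplotype sequences")
    L = len(hset.sequences[0])
    mat = np.frombuffer("".join(hset.sequences).encode(), dtype="S1")
    mat = mat.reshape(hset.K, L).astype("U1")

    S = PI = n_ts = n_tv = 0
    comp = Counter({b: 0.0 for b in "ACGT"})
    for j in range(L):
        col = mat[:, j]
        state_freq: Counter = Counter()
        for b, f in zip(col, freqs):
            state_freq[b] += f
            comp[b] += f
        states = sorted(state_freq)  # deterministic tie order
        if len(states) >= 2:
            S += 1
            if sum(1 for b in states if state_freq[b] >= 2) >= 2:
                PI += 1
            major = max(states, key=lambda b: (state_freq[b], b))
            for b in states:
                if b == major:
                    continue
                if is_transition(major, b):
                    n_ts += 1
                else:
                    n_tv += 1
    total = sum(comp.values())
    base_comp = {b: comp[b] / total for b in "ACGT"}
    return SiteSummary(S=S, PI=PI, n_ts=n_ts, n_tv=n_tv, base_comp=base_comp, L_used=L)
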