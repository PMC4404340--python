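"""Automatic Barcode Gap Discovery (ABGD) species delimitation.

Partitions sequences into candidate species by locating the "barcode gap"
between intra- and inter-specific pairwise distances, then splitting
recursively within each group, over a log-spaced range of prior limits P
to intraspecific divergence.

The gap criterion reconstructs the published procedure's spirit: ranked
pairwise distances are scanned above the prior P, and the first successive
gap wider than X times both the divergence at which it occurs and the
mean gap among all smaller ranked distances defines the threshold (taken
at the gap midpoint).
Behaviour is pinned by
monotonicity (group count non-increasing in P) and planted-clade recovery
rather than bit-compatibility with the original server.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitopop.seqio import LabeledMatrix


@dataclass(frozen=True)
class AbgdConfig:
    P_min: float = 0.001
    P_max: float = 0.1
    n_priors: int = 10
    X: float = 1.5
    model: str = "k2p"

    def __post_init__(self) -> None:
        if not (0.0 < self.P_min < self.P_max < 1.0):
            raise ValueError("need 0 < P_min < P_max < 1")
        if self.X <= 1.0:
            raise ValueError("gap width X must exceed 1")
        if self.n_priors < 1:
            raise ValueError("need at least one prior")

    @property
    def priors(self) -> np.ndarray:
        return np.geomspace(self.P_min, self.P_max, self.n_priors)


@dataclass(frozen=True)
class Partition:
    """Assignment of every sequence id to a group index, at one prior."""

    prior: float
    threshold: float | None
    groups: dict[str, int] = field(repr=False)

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def group_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, g in self.groups.items():
            out.setdefault(g, []).append(sid)
        return out


def distance_histogram(
    dist: LabeledMatrix, bins: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(counts, edges, ranked) for the lower-triangle pairwise distances."""
    ranked = np.sort(dist.condensed())
    counts, edges = np.histogram(ranked, bins=bins)
    return counts, edges, ranked


def find_gap(ranked: np.ndarray, P: float, X: float) -> float | None:
    """Locate the barcode-gap threshold in an ascending distance list.

    Scans successive gaps g_i = d_(i+1) - d_(i) with d_(i+1) > P; returns
    the midpoint of the first gap that (a) exceeds X times the divergence
    at which it occurs, max(d_(i), P) -- X is a *relative* gap width, so a
    jump no wider than the intraspecific divergence already accumulated
    below it is not a barcode gap -- and (b) exceeds X times the mean gap
    among the ranked distances below it. Returns None when no gap
    qualifies.
    """
    ranked = np.asarray(ranked, dtype=float)
    if ranked.size < 2:
        return None
    diffs = np.diff(ranked)
    for i, g in enumerate(diffs):
        if ranked[i + 1] <= P or g <= X * max(ranked[i], P):
            continue
        before = diffs[:i][diffs[:i] > 0]
        # baseline spacing among the distances strictly below d_(i+1)
        w = before.mean() if before.size else 0.0
        if w == 0.0:
            # all distances below the candidate are identical: a tight
            # cloud. Require at least two of them so an isolated smallest
            # distance never forces a split on its own
            if i >= 1:
                return float((ranked[i] + ranked[i + 1]) / 2.0)
            continue
        if g > X * w:
            return float((ranked[i] + ranked[i + 1]) / 2.0)
    return None


def _split(dist: np.ndarray, ids: list[int], P: float, X: float):
    """Connected components of {(i,j): d_ij < t} for the found threshold."""
    sub = dist[np.ix_(ids, ids)]
    iu = np.triu_indices(len(ids), 1)
    ranked = np.sort(sub[iu])
    t = find_gap(ranked, P, X)
    if t is None:
        return None, [ids]
    adj = sub < t
    n = len(ids)
    seen = np.zeros(n, dtype=bool)
    comps: list[list[int]] = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(ids[u])
            for v in np.flatnonzero(adj[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        comps.append(sorted(comp))
    if len(comps) == 1:
        return None, comps
    return t, comps


def abgd_partition(
    dist: LabeledMatrix, config: AbgdConfig | None = None
) -> list[Partition]:
    """One Partition per prior, each from recursive gap splitting.

    The initial split's threshold is recorded; recursion re-applies the
    gap search within every group of size >= 3 until no group splits.
    """
    config = config or AbgdConfig()
    n = dist.n
    order = np.argsort(np.array(dist.labels))  # label-order invariance
    vals = dist.values[np.ix_(order, order)]
    labels = [dist.labels[i] for i in order]

    out = []
    for P in config.priors:
        t0, comps = _split(vals, list(range(n)), float(P), config.X)
        # recursive refinement
        queue = list(comps)
        final: list[list[int]] = []
        while queue:
            grp = queue.pop(0)
            if len(grp) < 3:
                final.append(grp)
                continue
            _, sub = _split(vals, grp, float(P), config.X)
            if len(sub) == 1:
                final.append(grp)
            else:
                queue.extend(sub)
        final.sort(key=lambda g: g[0])
        groups = {labels[i]: gi for gi, grp in enumerate(final) for i in grp}
        out.append(Partition(prior=float(P), threshold=t0, groups=groups))
    return out
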