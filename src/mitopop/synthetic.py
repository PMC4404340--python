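"""Synthetic alignments and metadata with known, tunable structure.

Two generators cover the regimes the analysis pipeline assumes:

* ``simulate_star_expansion`` - star genealogies after a recent demographic
  expansion: one founder per clade placed ``divergence`` mutations from a
  random root, each sampled individual carrying Poisson(lambda) private
  mutations. Produces excess singletons and negative Tajima's D / Fu's Fs,
  and clades separated by a distance gap well above the intraclade spread
  (a planted "barcode gap").
* ``simulate_coalescent`` - a neutral Kingman coalescent with infinite-sites
  mutation, the null model against which D and Fs are calibrated
  (E[pi] = theta, E[S] = theta * a1).

Mutations follow an infinite-sites scheme with collision re-draw, so
segregating-site counting stays exact. A simulated mutation is a
transversion with probability ``tv_fraction`` (default 0.1, echoing the
transition-dominated spectrum of mitochondrial barcodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitopop.seqio import Alignment, SampleTable

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = "ACGT"


@dataclass(frozen=True)
class PopSpec:
    name: str
    n: int
    lat: float = 0.0
    lon: float = 0.0


@dataclass(frozen=True)
class CladeSpec:
    name: str
    divergence: int  # mutations from the shared root to the clade founder
    populations: tuple[PopSpec, ...]
    expansion: float = 0.5  # mean private mutations per sampled lineage


@dataclass(frozen=True)
class SynthConfig:
    L: int = 600
    clades: tuple[CladeSpec, ...] = ()
    tv_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tv_fraction <= 1.0):
            raise ValueError("tv_fraction must be in [0, 1]")
        if self.L <= 0:
            raise ValueError("L must be positive")


def _mutate(seq: list[str], site: int, rng, tv_fraction: float) -> None:
    base = seq[site]
    if rng.random() < tv_fraction:
        seq[site] = _TRANSVERSIONS[base][rng.integers(2)]
    else:
        seq[site] = _TRANSITION[base]


def _draw_sites(rng, k: int, L: int, used: set[int]) -> list[int]:
    """k distinct unused sites (infinite-sites with collision re-draw)."""
    if len(used) + k > L:
        raise ValueError(
            f"mutation load exceeds sequence length ({len(used)}+{k} > {L})"
        )
    out: list[int] = []
    while len(out) < k:
        s = int(rng.integers(L))
        if s not in used:
            used.add(s)
            out.append(s)
    return out


def simulate_star_expansion(
    config: SynthConfig,
) -> tuple[Alignment, SampleTable, dict]:
    """Star-expansion alignment + metadata + truth record.

    Every individual is its clade's founder sequence plus Poisson(lambda)
    private mutations at sites unused elsewhere, giving an exactly star
    genealogy within clades and a clean inter-clade barcode gap.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    root = [str(b) for b in rng.choice(list(_BASES), size=config.L)]
    used: set[int] = set()
    ids, seqs, rows = [], [], []
    truth: dict = {"root": "".join(root), "founders": {}, "mutations": {}}
    for clade in config.clades:
        founder = root.copy()
        for site in _draw_sites(rng, clade.divergence, config.L, used):
            _mutate(founder, site, rng, config.tv_fraction)
        truth["founders"][clade.name] = "".join(founder)
        for pop in clade.populations:
            for k in range(pop.n):
                sid = f"{pop.name}_{k + 1}"
                seq = founder.copy()
                nmut = int(rng.poisson(clade.expansion))
                sites = _draw_sites(rng, nmut, config.L, used)
                for site in sites:
                    _mutate(seq, site, rng, config.tv_fraction)
                truth["mutations"][sid] = sites
                ids.append(sid)
                seqs.append("".join(seq))
                rows.append(
                    {"sample_id": sid, "population": pop.name,
                     "country": pop.name, "group": clade.name,
                     "host_plant": "synthetic",
                     "lat": pop.lat, "lon": pop.lon}
                )
    aln = Alignment(tuple(ids), tuple(seqs))
    table = SampleTable(pd.DataFrame(rows))
    return aln, table, truth


def simulate_coalescent(
    n: int, theta: float, L: int, seed: int | None = None,
    tv_fraction: float = 0.1,
) -> Alignment:
    """Neutral Kingman coalescent sample with infinite-sites mutations.

    Coalescence times are exponential with rate C(k,2); mutations are
    Poisson(theta/2 * branch length) dropped uniformly on branches.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)

    # build the tree bottom-up; record (parent, branch_length) per node
    nodes = list(range(n))
    parent: dict[int, int] = {}
    blen: dict[int, float] = {}
    t = 0.0
    birth = {i: 0.0 for i in range(n)}
    nxt = n
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        for child in (a, b):
            parent[child] = nxt
            blen[child] = t - birth[child]
        birth[nxt] = t
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    root_node = nodes[0]

    root_seq = [str(b) for b in rng.choice(list(_BASES), size=L)]
    used: set[int] = set()
    seqs: dict[int, list[str]] = {root_node: root_seq}

    # walk the tree top-down, dropping mutations on each branch
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    stack = [root_node]
    while stack:
        p = stack.pop()
        for c in children.get(p, []):
            seq = seqs[p].copy()
            nmut = int(rng.poisson(theta / 2.0 * blen[c]))
            for site in _draw_sites(rng, nmut, L, used):
                _mutate(seq, site, rng, tv_fraction)
            seqs[c] = seq
            stack.append(c)
    ids = tuple(f"s{i + 1}" for i in range(n))
    return Alignment(ids, tuple("".join(seqs[i]) for i in range(n)))
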