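"""Distance-based AMOVA, pairwise Phi_ST, geographic distances, Mantel test.

AMOVA follows the Excoffier-Smouse-Quattro sums-of-squared-distances
decomposition. Following the Arlequin convention for molecular distance
matrices, the squared inter-individual deviation delta^2 used in the sums
is the supplied distance itself (e.g. K2P) unless ``square_distances`` is
set, in which case distances are squared first.

Permutation p-values use (b + 1)/(B + 1) throughout, with scheme:
Phi_ST - permute individuals among populations; Phi_SC - permute
individuals among populations within their group; Phi_CT - permute whole
populations among groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _all_perms
from typing import Sequence

import numpy as np

from mitopop.seqio import LabeledMatrix, SampleTable

EARTH_RADIUS_KM = 6371.0088


class DesignError(ValueError):
    """Invalid population/group design for AMOVA."""


# ------------------------------------------------------------------ AMOVA


@dataclass(frozen=True)
class AmovaResult:
    """Variance components and Phi-statistics of a hierarchical AMOVA.

    For a two-level design (no groups) ``sigma_a``, ``Phi_CT`` and
    ``Phi_SC`` are None and ``sigma_b`` holds the among-population
    component.
    """

    df: dict[str, int]
    ssd: dict[str, float]
    sigma_a: float | None  # among groups
    sigma_b: float  # among populations (within groups, if grouped)
    sigma_c: float  # within populations
    Phi_ST: float
    Phi_CT: float | None
    Phi_SC: float | None
    p_ST: float | None = None
    p_CT: float | None = None
    p_SC: float | None = None
    B: int = 0
    coefficients: dict[str, float] = field(default_factory=dict)

    @property
    def sigma_total(self) -> float:
        return (self.sigma_a or 0.0) + self.sigma_b + self.sigma_c

    @property
    def percentages(self) -> dict[str, float]:
        tot = self.sigma_total
        out = {}
        if self.sigma_a is not None:
            out["among_groups"] = 100.0 * self.sigma_a / tot
        out["among_populations"] = 100.0 * self.sigma_b / tot
        out["within_populations"] = 100.0 * self.sigma_c / tot
        return out


def _ssd(sq: np.ndarray, idx: np.ndarray) -> float:
    """Sum over i<j in idx of delta^2_ij / |idx|."""
    sub = sq[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * len(idx))


def _components(
    sq: np.ndarray,
    pop_codes: np.ndarray,
    group_of_pop: np.ndarray | None,
):
    """Variance components for one assignment. Returns an AmovaResult
    without p-values."""
    N = len(pop_codes)
    pops = np.unique(pop_codes)
    P = len(pops)
    ssd_total = _ssd(sq, np.arange(N))
    pop_idx = {p: np.flatnonzero(pop_codes == p) for p in pops}
    sizes = np.array([len(pop_idx[p]) for p in pops], dtype=float)
    ssd_wp = float(sum(_ssd(sq, pop_idx[p]) for p in pops))

    if group_of_pop is None:
        df_ap, df_wp = P - 1, N - P
        if df_ap < 1 or df_wp < 1:
            raise DesignError("AMOVA needs >=2 populations and df_within >= 1")
        ssd_ap = ssd_total - ssd_wp
        sigma_c = ssd_wp / df_wp
        n_c = (N - float(np.sum(sizes**2)) / N) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_c
        tot = sigma_b + sigma_c
        phi_st = sigma_b / tot if tot != 0 else 0.0
        return AmovaResult(
            df={"among_populations": df_ap, "within_populations": df_wp,
                "total": N - 1},
            ssd={"among_populations": ssd_ap, "within_populations": ssd_wp,
                 "total": ssd_total},
            sigma_a=None, sigma_b=sigma_b, sigma_c=sigma_c,
            Phi_ST=phi_st, Phi_CT=None, Phi_SC=None,
            coefficients={"n_c": n_c},
        )

    groups = np.unique(group_of_pop)
    G = len(groups)
    df_ag, df_apwg, df_wp = G - 1, P - G, N - P
    if df_ag < 1 or df_apwg < 1 or df_wp < 1:
        level = ("among_groups" if df_ag < 1
                 else "among_populations_within_groups" if df_apwg < 1
                 else "within_populations")
        raise DesignError(f"zero degrees of freedom at level {level!r}")
    grp_idx = {
        g: np.concatenate([pop_idx[p] for p, gg in zip(pops, group_of_pop)
                           if gg == g])
        for g in groups
    }
    ssd_ag_plus = float(sum(_ssd(sq, grp_idx[g]) for g in groups))
    ssd_apwg = ssd_ag_plus - ssd_wp
    ssd_ag = ssd_total - ssd_apwg - ssd_wp

    Ng = {g: len(grp_idx[g]) for g in groups}
    sum_np2_by_grp = {
        g: float(sum(len(pop_idx[p]) ** 2 for p, gg in zip(pops, group_of_pop)
                     if gg == g))
        for g in groups
    }
    n1 = (N - sum(sum_np2_by_grp[g] / Ng[g] for g in groups)) / df_apwg
    n2 = (sum(sum_np2_by_grp[g] / Ng[g] for g in groups)
          - float(np.sum(sizes**2)) / N) / df_ag
    n3 = (N - sum(Ng[g] ** 2 for g in groups) / N) / df_ag

    sigma_c = ssd_wp / df_wp
    sigma_b = (ssd_apwg / df_apwg - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / tot if tot != 0 else 0.0
    phi_ct = sigma_a / tot if tot != 0 else 0.0
    bc = sigma_b + sigma_c
    phi_sc = sigma_b / bc if bc != 0 else 0.0
    return AmovaResult(
        df={"among_groups": df_ag,
            "among_populations_within_groups": df_apwg,
            "within_populations": df_wp, "total": N - 1},
        ssd={"among_groups": ssd_ag,
             "among_populations_within_groups": ssd_apwg,
             "within_populations": ssd_wp, "total": ssd_total},
        sigma_a=sigma_a, sigma_b=sigma_b, sigma_c=sigma_c,
        Phi_ST=phi_st, Phi_CT=phi_ct, Phi_SC=phi_sc,
        coefficients={"n": n1, "n_prime": n2, "n_doubleprime": n3},
    )


def amova(
    dist: LabeledMatrix,
    pops: Sequence[str],
    groups: Sequence[str] | None = None,
    B: int = 1000,
    seed: int | None = None,
    square_distances: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA on a per-individual distance matrix.

    ``pops`` assigns each individual (in matrix label order) to a
    population; ``groups`` optionally assigns each individual to a group
    (must be constant within populations). ``B`` permutations per tested
    Phi-statistic; ``B=0`` skips permutation testing.
    """
    pops = list(pops)
    if len(pops) != dist.n:
        raise DesignError("pops must have one label per matrix row")
    sq = dist.values**2 if square_distances else dist.values.astype(float)
    if not np.all(np.isfinite(sq)):
        raise DesignError("distance matrix contains non-finite entries")
    _, pop_codes = np.unique(pops, return_inverse=True)
    P = pop_codes.max() + 1

    group_of_pop = None
    if groups is not None:
        groups = list(groups)
        if len(groups) != dist.n:
            raise DesignError("groups must have one label per matrix row")
        gp: dict[int, str] = {}
        for pc, g in zip(pop_codes, groups):
            if pc in gp and gp[pc] != g:
                raise DesignError(
                    "a population is assigned to more than one group"
                )
            gp[pc] = g
        _, gcodes = np.unique([gp[p] for p in range(P)], return_inverse=True)
        group_of_pop = gcodes

    obs = _components(sq, pop_codes, group_of_pop)
    if B <= 0:
        return obs

    rng = np.random.default_rng(seed)
    N = dist.n

    # Phi_ST: permute individuals among populations (whole design shuffled)
    b_st = 0
    for _ in range(B):
        perm = rng.permutation(N)
        try:
            r = _components(sq, pop_codes[perm], group_of_pop)
        except DesignError:
            continue
        if r.Phi_ST >= obs.Phi_ST:
            b_st += 1
    p_st = (b_st + 1) / (B + 1)

    p_ct = p_sc = None
    if group_of_pop is not None:
        # Phi_SC: permute individuals among populations within their group
        grp_of_ind = group_of_pop[pop_codes]
        b_sc = 0
        for _ in range(B):
            perm_codes = pop_codes.copy()
            for g in np.unique(grp_of_ind):
                idx = np.flatnonzero(grp_of_ind == g)
                perm_codes[idx] = pop_codes[idx][rng.permutation(len(idx))]
            r = _components(sq, perm_codes, group_of_pop)
            if r.Phi_SC >= obs.Phi_SC:
                b_sc += 1
        p_sc = (b_sc + 1) / (B + 1)

        # Phi_CT: permute whole populations among groups
        b_ct = 0
        for _ in range(B):
            r = _components(sq, pop_codes, rng.permutation(group_of_pop))
            if r.Phi_CT >= obs.Phi_CT:
                b_ct += 1
        p_ct = (b_ct + 1) / (B + 1)

    return AmovaResult(
        df=obs.df, ssd=obs.ssd,
        sigma_a=obs.sigma_a, sigma_b=obs.sigma_b, sigma_c=obs.sigma_c,
        Phi_ST=obs.Phi_ST, Phi_CT=obs.Phi_CT, Phi_SC=obs.Phi_SC,
        p_ST=p_st, p_CT=p_ct, p_SC=p_sc, B=B,
        coefficients=obs.coefficients,
    )


# ----------------------------------------------------------- pairwise FST


def pairwise_fst(
    dist: LabeledMatrix,
    pops: Sequence[str],
    B: int = 1000,
    seed: int | None = None,
    square_distances: bool = False,
) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Pairwise Phi_ST between populations via two-population AMOVAs.

    Returns (fst, pvalues) matrices over the population labels in order of
    first appearance. Negative Phi_ST values are preserved (they indicate
    no detectable differentiation). Populations with a single member give
    NaN rows.
    """
    pops = list(pops)
    if len(pops) != dist.n:
        raise DesignError("pops must have one label per matrix row")
    labels = list(dict.fromkeys(pops))
    if len(labels) < 2:
        raise DesignError("need at least 2 populations")
    idx = {lab: np.flatnonzero(np.asarray(pops) == lab) for lab in labels}
    K = len(labels)
    fst = np.zeros((K, K))
    pvals = np.zeros((K, K))
    rng = np.random.default_rng(seed)
    for a in range(K):
        for b in range(a + 1, K):
            ia, ib = idx[labels[a]], idx[labels[b]]
            if len(ia) < 2 or len(ib) < 2:
                fst[a, b] = fst[b, a] = np.nan
                pvals[a, b] = pvals[b, a] = np.nan
                continue
            sel = np.concatenate([ia, ib])
            sub = LabeledMatrix(
                tuple(dist.labels[i] for i in sel),
                dist.values[np.ix_(sel, sel)],
            )
            sub_pops = [pops[i] for i in sel]
            res = amova(
                sub, sub_pops, B=B,
                seed=int(rng.integers(2**31 - 1)),
                square_distances=square_distances,
            )
            fst[a, b] = fst[b, a] = res.Phi_ST
            pvals[a, b] = pvals[b, a] = res.p_ST if res.p_ST is not None else np.nan
    return (
        LabeledMatrix(tuple(labels), fst),
        LabeledMatrix(tuple(labels), pvals),
    )


# -------------------------------------------------------------- geography


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (mean Earth radius 6371.0088 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geo_distance(
    table: SampleTable | Sequence[tuple[str, float, float]],
    by: str = "population",
) -> LabeledMatrix:
    """Great-circle distance matrix (km) between labelled points.

    When given a SampleTable, points are the centroids (mean lat/lon) of
    the ``by`` column's levels. Labels with missing coordinates raise.
    """
    if isinstance(table, SampleTable):
        df = table.df
        if "lat" not in df.columns or "lon" not in df.columns:
            raise DesignError("sample table has no lat/lon columns")
        cent = df.groupby(by, sort=False)[["lat", "lon"]].mean()
        missing = sorted(cent.index[cent.isna().any(axis=1)])
        if missing:
            raise DesignError(f"missing coordinates for: {missing}")
        points = [(str(lab), float(r.lat), float(r.lon))
                  for lab, r in cent.iterrows()]
    else:
        points = [(str(l), float(a), float(b)) for l, a, b in table]
        missing = [l for l, a, b in points
                   if not (math.isfinite(a) and math.isfinite(b))]
        if missing:
            raise DesignError(f"missing coordinates for: {missing}")
    labels = tuple(p[0] for p in points)
    n = len(points)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(points[i][1], points[i][2],
                             points[j][1], points[j][2])
            m[i, j] = m[j, i] = d
    return LabeledMatrix(labels, m)


# ------------------------------------------------------------ Mantel test


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    B: int
    exact: bool = False

    @property
    def R2(self) -> float:
        return self.r**2


def _offdiag_r(m1: np.ndarray, m2: np.ndarray) -> float:
    n = m1.shape[0]
    iu = np.tril_indices(n, -1)
    return float(np.corrcoef(m1[iu], m2[iu])[0, 1])


def mantel(
    m1: LabeledMatrix,
    m2: LabeledMatrix,
    B: int = 1000,
    seed: int | None = None,
    transform1=None,
    transform2=None,
) -> MantelResult:
    """Mantel matrix-correlation test between two labelled matrices.

    r is the Pearson correlation over lower-triangle entries; the p-value
    comes from random row/column co-permutations of ``m2`` (two-sided on
    |r|, (b+1)/(B+1)). For n <= 7 all n! permutations are enumerated
    exactly. Optional elementwise transforms (e.g. np.log on distances or
    x/(1-x) on FST) are applied before correlating.
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices must share labels in the same order")
    n = m1.n
    if n < 4:
        raise ValueError("Mantel test needs n >= 4")
    a = m1.values.astype(float).copy()
    b = m2.values.astype(float).copy()
    if transform1 is not None:
        iu = ~np.eye(n, dtype=bool)
        a[iu] = transform1(a[iu])
    if transform2 is not None:
        iu = ~np.eye(n, dtype=bool)
        b[iu] = transform2(b[iu])
    r_obs = _offdiag_r(a, b)

    if n <= 7:
        count = 0
        total = 0
        for perm in _all_perms(range(n)):
            total += 1
            pm = b[np.ix_(perm, perm)]
            if abs(_offdiag_r(a, pm)) >= abs(r_obs) - 1e-12:
                count += 1
        return MantelResult(r=r_obs, p=count / total, B=total, exact=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        pm = b[np.ix_(perm, perm)]
        if abs(_offdiag_r(a, pm)) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=(count + 1) / (B + 1), B=B)
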