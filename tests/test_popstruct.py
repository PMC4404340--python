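import math
from itertools import permutations

import numpy as np
import pytest

from mitopop.popstruct import (
    DesignError,
    amova,
    geo_distance,
    haversine_km,
    mantel,
    pairwise_fst,
    EARTH_RADIUS_KM,
)
from mitopop.seqio import LabeledMatrix


def _random_design(rng, sizes, spread=1.0, shift=0.0):
    """Random symmetric non-negative distance matrix with labelled pops.

    ``shift`` adds extra distance between individuals of different pops.
    """
    n = sum(sizes)
    pops = []
    for p, s in enumerate(sizes):
        pops.extend([f"pop{p}"] * s)
    m = rng.random((n, n)) * spread
    m = (m + m.T) / 2
    for i in range(n):
        for j in range(n):
            if pops[i] != pops[j]:
                m[i, j] += shift
    np.fill_diagonal(m, 0)
    labels = tuple(f"i{k}" for k in range(n))
    return LabeledMatrix(labels, m), pops


def oracle_amova_two_level(values, pops):
    """Independent sums-of-squared-distances decomposition, plain loops."""
    n = len(pops)
    names = sorted(set(pops))
    idx = {p: [i for i, x in enumerate(pops) if x == p] for p in names}
    ssd_tot = sum(values[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ssd_wp = 0.0
    for p in names:
        ids = idx[p]
        ssd_wp += sum(
            values[i][j] for a, i in enumerate(ids) for j in ids[a + 1:]
        ) / len(ids)
    ssd_ap = ssd_tot - ssd_wp
    P = len(names)
    sigma_c = ssd_wp / (n - P)
    n_c = (n - sum(len(idx[p]) ** 2 for p in names) / n) / (P - 1)
    sigma_b = (ssd_ap / (P - 1) - sigma_c) / n_c
    phi_st = sigma_b / (sigma_b + sigma_c)
    return {"ssd_tot": ssd_tot, "ssd_wp": ssd_wp, "ssd_ap": ssd_ap,
            "sigma_b": sigma_b, "sigma_c": sigma_c, "phi_st": phi_st}


def oracle_amova_three_level(values, pops, groups):
    """Independent three-level decomposition following the classic
    mean-square equations, written with explicit loops."""
    n = len(pops)
    pop_names = sorted(set(pops))
    grp_of = {}
    for p, g in zip(pops, groups):
        grp_of[p] = g
    grp_names = sorted(set(groups))
    pidx = {p: [i for i, x in enumerate(pops) if x == p] for p in pop_names}
    gidx = {g: [i for i, x in enumerate(groups) if x == g] for g in grp_names}

    def ssd_of(ids):
        return sum(
            values[i][j] for a, i in enumerate(ids) for j in ids[a + 1:]
        ) / len(ids)

    ssd_tot = ssd_of(list(range(n)))
    ssd_wp = sum(ssd_of(pidx[p]) for p in pop_names)
    ssd_wg = sum(ssd_of(gidx[g]) for g in grp_names)
    ssd_apwg = ssd_wg - ssd_wp
    ssd_ag = ssd_tot - ssd_wg
    P, G = len(pop_names), len(grp_names)
    df_ag, df_apwg, df_wp = G - 1, P - G, n - P
    sizes = {p: len(pidx[p]) for p in pop_names}
    Ng = {g: len(gidx[g]) for g in grp_names}
    A = sum(
        sum(sizes[p] ** 2 for p in pop_names if grp_of[p] == g) / Ng[g]
        for g in grp_names
    )
    n1 = (n - A) / df_apwg
    n2 = (A - sum(sizes[p] ** 2 for p in pop_names) / n) / df_ag
    n3 = (n - sum(Ng[g] ** 2 for g in grp_names) / n) / df_ag
    sigma_c = ssd_wp / df_wp
    sigma_b = (ssd_apwg / df_apwg - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    return {"sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_c": sigma_c,
            "phi_st": (sigma_a + sigma_b) / tot, "phi_ct": sigma_a / tot,
            "phi_sc": sigma_b / (sigma_b + sigma_c)}


class TestAmova:
    def test_identical_populations_near_zero(self, rng):
        m, pops = _random_design(rng, [10, 10], spread=1.0, shift=0.0)
        r = amova(m, pops, B=0)
        assert abs(r.Phi_ST) < 0.15

    def test_distinct_fixed_haplotypes_phi_one(self):
        # no within-pop variation, all between: Phi_ST = 1
        n = 8
        m = np.zeros((n, n))
        pops = ["A"] * 4 + ["B"] * 4
        for i in range(n):
            for j in range(n):
                if pops[i] != pops[j]:
                    m[i, j] = 0.3
        r = amova(LabeledMatrix(tuple(f"i{k}" for k in range(n)), m),
                  pops, B=0)
        assert r.Phi_ST == pytest.approx(1.0, abs=1e-12)

    def test_two_level_matches_oracle(self, rng):
        m, pops = _random_design(rng, [4, 5, 3], shift=0.4)
        r = amova(m, pops, B=0)
        o = oracle_amova_two_level(m.values.tolist(), pops)
        assert r.Phi_ST == pytest.approx(o["phi_st"], abs=1e-12)
        assert r.sigma_b == pytest.approx(o["sigma_b"], abs=1e-12)
        assert r.ssd["total"] == pytest.approx(o["ssd_tot"], abs=1e-12)

    def test_three_level_matches_oracle(self, rng):
        m, pops = _random_design(rng, [4, 4, 3, 5], shift=0.5)
        groups = ["G1" if p in ("pop0", "pop1") else "G2" for p in pops]
        r = amova(m, pops, groups=groups, B=0)
        o = oracle_amova_three_level(m.values.tolist(), pops, groups)
        for got, want in [(r.Phi_ST, o["phi_st"]), (r.Phi_CT, o["phi_ct"]),
                          (r.Phi_SC, o["phi_sc"]), (r.sigma_a, o["sigma_a"])]:
            assert got == pytest.approx(want, abs=1e-12)

    def test_ssd_additivity_and_percentages(self, rng):
        m, pops = _random_design(rng, [4, 6, 5], shift=0.3)
        groups = ["G1" if p == "pop0" else "G2" for p in pops]
        r = amova(m, pops, groups=groups, B=0)
        parts = (r.ssd["among_groups"]
                 + r.ssd["among_populations_within_groups"]
                 + r.ssd["within_populations"])
        assert parts == pytest.approx(r.ssd["total"], abs=1e-9)
        assert sum(r.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_null_pvalue_not_small(self, rng):
        m, pops = _random_design(rng, [8, 8], shift=0.0)
        r = amova(m, pops, B=199, seed=11)
        assert r.p_ST > 0.05

    def test_structured_pvalue_small(self, rng):
        m, pops = _random_design(rng, [8, 8], spread=0.2, shift=1.0)
        r = amova(m, pops, B=199, seed=11)
        assert r.p_ST <= 0.01

    def test_population_in_two_groups_rejected(self, rng):
        m, pops = _random_design(rng, [4, 4])
        groups = ["G1"] * 4 + ["G2"] * 4
        groups[0] = "G2"
        with pytest.raises(DesignError):
            amova(m, pops, groups=groups, B=0)


class TestPairwiseFst:
    def test_matches_per_pair_amova(self, rng):
        m, pops = _random_design(rng, [4, 5, 3, 4], shift=0.4)
        fst, _ = pairwise_fst(m, pops, B=0)
        for a in range(fst.n):
            for b in range(a + 1, fst.n):
                pa, pb = fst.labels[a], fst.labels[b]
                sel = [i for i, p in enumerate(pops) if p in (pa, pb)]
                sub = LabeledMatrix(
                    tuple(m.labels[i] for i in sel),
                    m.values[np.ix_(sel, sel)],
                )
                r = amova(sub, [pops[i] for i in sel], B=0)
                assert fst.values[a, b] == pytest.approx(r.Phi_ST, abs=1e-12)

    def test_singleton_population_gives_na(self, rng):
        m, pops = _random_design(rng, [5, 1, 4])
        fst, pv = pairwise_fst(m, pops, B=0)
        i = fst.labels.index("pop1")
        row = np.delete(fst.values[i], i)
        assert np.isnan(row).all()

    def test_negative_values_preserved(self, rng):
        # identical composition -> Phi_ST fluctuates around 0, often below
        vals = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            m, pops = _random_design(r, [6, 6], shift=0.0)
            fst, _ = pairwise_fst(m, pops, B=0)
            vals.append(fst.values[0, 1])
        assert min(vals) < 0  # negatives are reported, not clipped


class TestGeoDistance:
    def test_identical_points_zero(self):
        m = geo_distance([("a", 10.0, 20.0), ("b", 10.0, 20.0)])
        assert m.values[0, 1] == 0.0

    def test_one_degree_arc_on_equator(self):
        m = geo_distance([("a", 0.0, 0.0), ("b", 0.0, 1.0)])
        expected = 2 * math.pi * EARTH_RADIUS_KM / 360
        assert m.values[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_antipodal_points_half_circumference(self):
        m = geo_distance([("a", 0.0, 0.0), ("b", 0.0, 180.0)])
        assert m.values[0, 1] == pytest.approx(
            math.pi * EARTH_RADIUS_KM, rel=1e-9
        )

    def test_missing_coordinates_listed(self):
        with pytest.raises(DesignError, match="pnan"):
            geo_distance([("ok", 0.0, 0.0), ("pnan", float("nan"), 1.0)])

    def test_haversine_symmetry(self):
        assert haversine_km(10, 20, -30, 140) == pytest.approx(
            haversine_km(-30, 140, 10, 20)
        )


class TestMantel:
    def _labeled(self, vals, labels=None):
        n = vals.shape[0]
        labels = labels or tuple(f"x{i}" for i in range(n))
        return LabeledMatrix(tuple(labels), vals)

    def test_self_correlation_is_one(self, rng):
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        lm = self._labeled(m)
        r = mantel(lm, lm, B=99, seed=1)
        assert r.r == pytest.approx(1.0)
        assert r.R2 == pytest.approx(1.0)

    def test_exact_mode_matches_manual_enumeration(self, rng):
        a = rng.random((4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((4, 4))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        la, lb = self._labeled(a), self._labeled(b)
        res = mantel(la, lb, seed=0)
        assert res.exact and res.B == 24

        def corr(m1, m2):
            iu = np.tril_indices(4, -1)
            return np.corrcoef(m1[iu], m2[iu])[0, 1]

        r_obs = corr(a, b)
        count = sum(
            abs(corr(a, b[np.ix_(p, p)])) >= abs(r_obs) - 1e-12
            for p in permutations(range(4))
        )
        assert res.p == pytest.approx(count / 24)
        assert res.r == pytest.approx(r_obs)

    def test_label_mismatch_rejected(self, rng):
        a = np.zeros((4, 4))
        la = self._labeled(a, ("a", "b", "c", "d"))
        lb = self._labeled(a, ("a", "b", "d", "c"))
        with pytest.raises(ValueError, match="labels"):
            mantel(la, lb, B=9, seed=0)
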