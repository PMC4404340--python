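"""End-to-end orchestration: haplotypes -> diversity -> FST/AMOVA -> Mantel
-> ABGD -> network, from a single YAML-able configuration.

Every stage writes TSV (tables), newick (trees) or edge-list TSV/GraphML
(networks) into the output directory, plus one machine-readable JSON
summary and a log of the seeds and option flags in force. Reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from mitopop import seqio
from mitopop.abgd import AbgdConfig, abgd_partition, distance_histogram
from mitopop.distances import distance_matrix, nj_tree
from mitopop.diversity import diversity_summary
from mitopop.haplotypes import collapse_haplotypes, site_summary
from mitopop.mjnetwork import annotate_network, build_mjn
from mitopop.popstruct import amova, geo_distance, mantel, pairwise_fst

log = logging.getLogger("mitopop")


@dataclass
class RunConfig:
    alignment: str | None = None
    samples: str | None = None
    fst_matrix: str | None = None  # fixtures-only mode
    km_matrix: str | None = None
    outdir: str = "mitopop_out"
    seed: int = 0
    model: str = "k2p"
    B: int = 1000
    group_column: str = "group"
    epsilon: float = 10.0
    tv_weight: float = 3.0
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    square_distances: bool = False
    mantel_log_distance: bool = False
    mantel_fst_linearized: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        abgd_raw = raw.pop("abgd", {})
        cfg = cls(**raw)
        if abgd_raw:
            cfg.abgd = AbgdConfig(**abgd_raw)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        return cfg


def _mantel_transforms(cfg: RunConfig):
    t1 = (lambda x: x / (1.0 - x)) if cfg.mantel_fst_linearized else None
    t2 = np.log if cfg.mantel_log_distance else None
    return t1, t2


def _na(x, fmt="%.6g"):
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) else fmt % x


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the JSON-serialisable summary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config": {
        "model": cfg.model, "B": cfg.B, "epsilon": cfg.epsilon,
        "tv_weight": cfg.tv_weight, "square_distances": cfg.square_distances,
        "mantel_log_distance": cfg.mantel_log_distance,
        "mantel_fst_linearized": cfg.mantel_fst_linearized,
        "abgd": {"P_min": cfg.abgd.P_min, "P_max": cfg.abgd.P_max,
                 "n_priors": cfg.abgd.n_priors, "X": cfg.abgd.X},
    }}
    rng = np.random.default_rng(cfg.seed)

    if cfg.alignment is None:
        return _run_fixtures_only(cfg, out, summary, rng)

    aln = seqio.read_alignment(cfg.alignment)
    samples = seqio.read_samples(cfg.samples) if cfg.samples else None
    log.info("alignment: %d records x %d sites", aln.n, aln.length)

    # --- haplotypes -------------------------------------------------------
    hset = collapse_haplotypes(aln)
    ss = site_summary(hset)
    with open(out / "haplotypes.tsv", "w") as fh:
        fh.write("haplotype\tfrequency\tmembers\n")
        for hid, f, mem in zip(hset.haplotype_ids, hset.frequencies,
                               hset.members):
            fh.write(f"{hid}\t{f}\t{','.join(mem)}\n")
    with open(out / "site_summary.tsv", "w") as fh:
        fh.write("S\tPI\tn_ts\tn_tv\tA\tC\tG\tT\tL_used\n")
        fh.write(
            f"{ss.S}\t{ss.PI}\t{ss.n_ts}\t{ss.n_tv}\t"
            + "\t".join("%.5f" % ss.base_comp[b] for b in "ACGT")
            + f"\t{ss.L_used}\n"
        )
    summary["haplotypes"] = {"n": hset.n, "K": hset.K, "S": ss.S,
                             "PI": ss.PI, "n_ts": ss.n_ts, "n_tv": ss.n_tv}

    # --- diversity by grouping -------------------------------------------
    div_rows = []
    strata = {"all": {None: list(aln.ids)}}
    if samples is not None:
        for col in ("population", "country", cfg.group_column):
            if col in samples.df.columns:
                labels = samples.labels_for(aln.ids, column=col)
                by: dict = {}
                for sid, lab in zip(aln.ids, labels):
                    by.setdefault(lab, []).append(sid)
                strata[col] = by
    for level, groups in strata.items():
        for name, ids in sorted(groups.items(), key=lambda kv: str(kv[0])):
            sub = seqio.Alignment(
                tuple(ids), tuple(aln.seqs[aln.ids.index(i)] for i in ids)
            )
            if sub.n < 2:
                continue
            d = diversity_summary(collapse_haplotypes(sub))
            div_rows.append(
                {"level": level, "name": name or "all", "n": d.n, "K": d.K,
                 "h": d.h, "pi": d.pi, "S": d.S, "D": d.D, "Fs": d.Fs}
            )
    with open(out / "diversity.tsv", "w") as fh:
        fh.write("level\tname\tn\tK\th\tpi\tS\tD\tFs\n")
        for r in div_rows:
            fh.write(
                f"{r['level']}\t{r['name']}\t{r['n']}\t{r['K']}\t"
                f"{_na(r['h'])}\t{_na(r['pi'])}\t{r['S']}\t"
                f"{_na(r['D'])}\t{_na(r['Fs'])}\n"
            )
    overall = next(r for r in div_rows if r["level"] == "all")
    summary["diversity"] = {k: overall[k] for k in ("n", "K", "h", "pi",
                                                    "S", "D", "Fs")}

    # --- distances and NJ tree -------------------------------------------
    dm_ind = distance_matrix(aln, model=cfg.model)
    dm_hap = distance_matrix(hset, model=cfg.model)
    seqio.write_labeled_matrix(dm_hap, out / "haplotype_distances.tsv")
    if dm_hap.n >= 3 and np.all(np.isfinite(dm_hap.values)):
        (out / "nj_tree.nwk").write_text(nj_tree(dm_hap) + "\n")

    # --- population structure --------------------------------------------
    if samples is not None:
        pops = samples.labels_for(aln.ids, column="population")
        seed_fst = int(rng.integers(2**31 - 1))
        fst, pvals = pairwise_fst(
            dm_ind, pops, B=cfg.B, seed=seed_fst,
            square_distances=cfg.square_distances,
        )
        seqio.write_labeled_matrix(fst, out / "pairwise_fst.tsv")
        seqio.write_labeled_matrix(pvals, out / "pairwise_fst_pvalues.tsv")

        groups = None
        if cfg.group_column in samples.df.columns:
            groups = samples.labels_for(aln.ids, column=cfg.group_column)
        am = amova(dm_ind, pops, groups=groups, B=cfg.B,
                   seed=int(rng.integers(2**31 - 1)),
                   square_distances=cfg.square_distances)
        with open(out / "amova.tsv", "w") as fh:
            fh.write("level\tdf\tSSD\tvariance\tpercent\tphi\tp\n")
            pct = am.percentages
            rows = []
            if am.sigma_a is not None:
                rows.append(("among_groups", am.df["among_groups"],
                             am.ssd["among_groups"], am.sigma_a,
                             pct["among_groups"], am.Phi_CT, am.p_CT))
                rows.append((
                    "among_populations_within_groups",
                    am.df["among_populations_within_groups"],
                    am.ssd["among_populations_within_groups"], am.sigma_b,
                    pct["among_populations"], am.Phi_SC, am.p_SC))
            else:
                rows.append(("among_populations", am.df["among_populations"],
                             am.ssd["among_populations"], am.sigma_b,
                             pct["among_populations"], am.Phi_ST, am.p_ST))
            rows.append(("within_populations", am.df["within_populations"],
                         am.ssd["within_populations"], am.sigma_c,
                         pct["within_populations"], am.Phi_ST, am.p_ST))
            for name, df_, ssd_, var, pc, phi, p in rows:
                fh.write(f"{name}\t{df_}\t{_na(ssd_)}\t{_na(var)}\t"
                         f"{_na(pc, '%.2f')}\t{_na(phi)}\t{_na(p)}\n")
        summary["amova"] = {
            "Phi_ST": am.Phi_ST, "Phi_CT": am.Phi_CT, "Phi_SC": am.Phi_SC,
            "p_ST": am.p_ST, "p_CT": am.p_CT, "p_SC": am.p_SC,
            "percentages": am.percentages,
        }

        # Mantel isolation-by-distance, when coordinates are available
        if {"lat", "lon"} <= set(samples.df.columns) and \
                samples.df[["lat", "lon"]].notna().all(axis=None):
            km = geo_distance(samples, by="population")
            km_o = km.submatrix(fst.labels)
            if fst.n >= 4:
                t1, t2 = _mantel_transforms(cfg)
                mr = mantel(fst, km_o, B=cfg.B,
                            seed=int(rng.integers(2**31 - 1)),
                            transform1=t1, transform2=t2)
                summary["mantel"] = {"r": mr.r, "R2": mr.R2, "p": mr.p,
                                     "B": mr.B, "exact": mr.exact}
            seqio.write_labeled_matrix(fst, out / "fst_km_merged.tsv",
                                       upper=km_o)

    # --- ABGD -------------------------------------------------------------
    parts = abgd_partition(dm_hap, cfg.abgd)
    counts, edges, ranked = distance_histogram(dm_hap)
    np.savetxt(out / "abgd_ranked_distances.tsv", ranked, fmt="%.6g")
    with open(out / "abgd_partitions.tsv", "w") as fh:
        fh.write("prior\tthreshold\tn_groups\tassignment\n")
        for p in parts:
            assign = ";".join(f"{k}:{v}" for k, v in sorted(p.groups.items()))
            fh.write(f"{p.prior:.6g}\t{_na(p.threshold)}\t{p.n_groups}\t"
                     f"{assign}\n")
    summary["abgd"] = {"n_groups_per_prior": [p.n_groups for p in parts],
                       "priors": [p.prior for p in parts]}

    # --- median-joining network ------------------------------------------
    if hset.K >= 2:
        net = build_mjn(hset, epsilon=cfg.epsilon, tv_weight=cfg.tv_weight)
        nx.write_graphml(
            _stringify_attrs(net.graph), out / "network.graphml"
        )
        with open(out / "network_edges.tsv", "w") as fh:
            fh.write("u\tv\tweight\tsites\n")
            for u, v, d in sorted(net.graph.edges(data=True)):
                sites = ",".join(map(str, d.get("sites", ())))
                fh.write(f"{u}\t{v}\t{d['weight']:.6g}\t{sites}\n")
        summary["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_medians": net.n_medians,
            "total_cost": net.total_cost,
        }
        if samples is not None:
            comp, founders = annotate_network(net, hset, samples,
                                              by="population")
            comp.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
            summary["network"]["founders"] = founders

    _finalise(out, summary)
    return summary


def _run_fixtures_only(cfg: RunConfig, out: Path, summary: dict, rng) -> dict:
    """No alignment: Mantel on supplied FST/km matrices only."""
    if cfg.fst_matrix is None or cfg.km_matrix is None:
        raise ValueError(
            "fixtures-only mode needs fst_matrix and km_matrix paths"
        )
    fst = seqio.read_labeled_matrix(cfg.fst_matrix, triangle="lower")
    km = seqio.read_labeled_matrix(cfg.km_matrix, triangle="upper")
    t1, t2 = _mantel_transforms(cfg)
    mr = mantel(fst, km, B=cfg.B, seed=int(rng.integers(2**31 - 1)),
                transform1=t1, transform2=t2)
    summary["mantel"] = {"r": mr.r, "R2": mr.R2, "p": mr.p, "B": mr.B,
                         "exact": mr.exact}
    seqio.write_labeled_matrix(fst, out / "fst_km_merged.tsv", upper=km)
    _finalise(out, summary)
    return summary


def _stringify_attrs(g: nx.Graph) -> nx.Graph:
    """GraphML cannot hold tuples; stringify edge site lists."""
    g2 = g.copy()
    for _, _, d in g2.edges(data=True):
        if "sites" in d:
            d["sites"] = ",".join(map(str, d["sites"]))
    return g2


def _finalise(out: Path, summary: dict) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
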