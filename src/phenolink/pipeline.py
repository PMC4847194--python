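"""End-to-end pipeline: one structured config file in, a report directory out.

Stages run in a fixed order; a stage whose config block is absent is skipped
with a logged notice. Every stage draws its seed from the master seed through
a documented counter scheme (``stage_seed = (master * 10007 + index) mod
2^31``), so a rerun with the same config and seed reproduces every artifact
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (PHENOTYPES, SimConfig, simulate_cohort, read_otu_table,
               read_metadata, write_otu_table, write_metadata,
               filter_prevalence, clr_transform, within_subject_split,
               stars_select_eta, fit_spls, bootstrap_significance,
               cluster_scores, transition_diagram, stars_network,
               write_network, count_orbits, graphlet_correlation_matrix, gcd,
               embed_networks, attack_curve, summary_stats, top_keystones,
               fit_age_model, maz_scores, classify_disease, homa_ir,
               homa_elevated)

log = logging.getLogger(__name__)

STAGES = ("data", "filter", "clr", "decompose", "spls", "cluster", "networks",
          "topology", "maz", "classify", "homa")


def stage_seed(master: int, stage: str) -> int:
    return (int(master) * 10007 + STAGES.index(stage)) % (2 ** 31)


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute the configured stages; returns the report directory."""
    cfg = load_config(config_path) if not isinstance(config_path, dict) else config_path
    master = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "phenolink_run"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": master, "stages": []}

    def done(name, **info):
        report["stages"].append(name)
        report[name] = info
        log.info("stage %s done: %s", name, info)

    def skipped(name):
        log.info("stage %s skipped: no config block", name)

    try:
        # ---- data -------------------------------------------------------
        truth = None
        if "simulate" in cfg:
            sc = SimConfig(**{**cfg["simulate"], "seed": stage_seed(master, "data")})
            table, meta, truth = simulate_cohort(sc)
            write_otu_table(table, out / "otu_table.tsv")
            write_metadata(meta, out / "metadata.tsv")
            with open(out / "truth.json", "w") as fh:
                json.dump({"assoc_otus": truth.assoc_otus.tolist(),
                           "age_taxa": {str(k): v for k, v in
                                        truth.true_age_taxa.items()},
                           "coefficients": truth.true_coefficients.tolist()}, fh)
            done("data", n_samples=table.n_samples, n_otus=table.n_otus,
                 simulated=True)
        elif "input" in cfg:
            table = read_otu_table(cfg["input"]["otu_table"],
                                   cfg["input"].get("format", "tsv"))
            meta = read_metadata(cfg["input"]["metadata"]).aligned_to(table)
            done("data", n_samples=table.n_samples, n_otus=table.n_otus,
                 simulated=False)
        else:
            raise ValueError("config needs a 'simulate' or 'input' block")

        # ---- filter -----------------------------------------------------
        if "filter" in cfg:
            table = filter_prevalence(table, cfg["filter"].get("min_fraction", 0.10))
            write_otu_table(table, out / "otu_filtered.tsv")
            done("filter", n_otus=table.n_otus)
        else:
            skipped("filter")

        # ---- clr --------------------------------------------------------
        if "clr" in cfg:
            clr = clr_transform(table, cfg["clr"].get("pseudocount", 1.0))
            pd.DataFrame(clr.values, index=clr.sample_ids,
                         columns=clr.otu_ids).to_csv(out / "clr.tsv", sep="\t")
            done("clr", pseudocount=clr.pseudocount)
        else:
            skipped("clr")
            clr = None

        # ---- decompose ---------------------------------------------------
        assoc = scores = None
        if "decompose" in cfg and clr is not None:
            pheno_cols = [c for c in PHENOTYPES if c in meta.frame.columns]
            Y = meta.phenotype_matrix(pheno_cols).to_numpy()
            dec_x = within_subject_split(clr.values, meta.subjects,
                                         meta.frame["diet"].to_numpy())
            dec_y = within_subject_split(Y, meta.subjects,
                                         meta.frame["diet"].to_numpy())
            pd.DataFrame(dec_x.within, index=clr.sample_ids,
                         columns=clr.otu_ids).to_csv(out / "within_X.tsv", sep="\t")
            pd.DataFrame(dec_y.within, index=clr.sample_ids,
                         columns=pheno_cols).to_csv(out / "within_Y.tsv", sep="\t")
            done("decompose", phenotypes=pheno_cols)
        else:
            skipped("decompose")
            dec_x = dec_y = None

        # ---- spls -------------------------------------------------------
        if "spls" in cfg and dec_x is not None:
            sp = cfg["spls"]
            seed = stage_seed(master, "spls")
            prof = stars_select_eta(dec_x.within, dec_y.within, meta.subjects,
                                    n_subsets=sp.get("n_subsets", 50),
                                    threshold=sp.get("threshold", 0.001),
                                    K=sp.get("K", 7), seed=seed)
            model = fit_spls(dec_x.within, dec_y.within, eta=prof.eta_selected,
                             K=sp.get("K", 7))
            assoc = bootstrap_significance(
                dec_x.within, dec_y.within, meta.subjects, model.support,
                B_boot=sp.get("b_boot", 2000), B_null=sp.get("b_null", None),
                alpha=sp.get("alpha", 0.01), seed=seed + 1)
            scores = model.T
            pd.DataFrame({"eta": prof.eta_grid, "D": prof.D,
                          "D_monotone": prof.D_monotone}).to_csv(
                out / "stability.tsv", sep="\t", index=False)
            rows = []
            for o in np.where(model.support)[0]:
                for r, ph in enumerate(pheno_cols):
                    rows.append({"otu": table.otu_ids[o], "phenotype": ph,
                                 "coefficient": assoc.coefficients[o, r],
                                 "p": assoc.p_values[o, r],
                                 "significant": bool(assoc.significant[o, r])})
            pd.DataFrame(rows).to_csv(out / "associations.tsv", sep="\t",
                                      index=False)
            with open(out / "spls_model.json", "w") as fh:
                json.dump({"eta": model.eta, "K": model.K,
                           "support": [table.otu_ids[o] for o in
                                       np.where(model.support)[0]],
                           "W": model.W.tolist(), "B": model.B.tolist()}, fh)
            done("spls", eta=prof.eta_selected, n_support=int(model.support.sum()),
                 n_significant=int(assoc.significant.sum()))
        else:
            skipped("spls")

        # ---- cluster ----------------------------------------------------
        clusters = None
        if "cluster" in cfg and scores is not None:
            cl = cfg["cluster"]
            fit = cluster_scores(scores, range(1, cl.get("k_max", 9) + 1),
                                 seed=stage_seed(master, "cluster"))
            clusters = fit.assignment
            pd.DataFrame({"sample": table.sample_ids, "cluster": clusters}
                         ).to_csv(out / "clusters.tsv", sep="\t", index=False)
            fit.bic_table.to_csv(out / "bic.tsv", sep="\t")
            moves, loops = transition_diagram(clusters, meta.subjects, meta.weeks,
                                              cl.get("min_count", 6))
            moves.to_csv(out / "transitions.tsv", sep="\t", index=False)
            loops.to_csv(out / "self_loops.tsv", sep="\t", index=False)
            done("cluster", k=fit.k, family=fit.model_family)
        else:
            skipped("cluster")

        # ---- networks ---------------------------------------------------
        nets = {}
        if "networks" in cfg and clusters is not None:
            nw = cfg["networks"]
            min_n = nw.get("min_samples", 15)
            phylum = dict(zip(table.otu_ids, table.phylum_labels()))
            for k in sorted(set(clusters)):
                idx = clusters == k
                if idx.sum() < min_n:
                    log.info("cluster %d has %d samples (< %d); no network",
                             k, int(idx.sum()), min_n)
                    continue
                sub = table.select_samples(idx)
                # composition is cluster-local: clr recomputed on the subset
                sub_clr = clr_transform(sub).values
                nets[k] = stars_network(sub_clr, sub.otu_ids,
                                        n_subsets=nw.get("n_subsets", 50),
                                        threshold=nw.get("threshold", 0.0005),
                                        seed=stage_seed(master, "networks") + k,
                                        phylum=phylum)
                write_network(nets[k].graph, out / f"network_c{k}.tsv")
            done("networks", clusters=sorted(nets),
                 edges={int(k): n.n_edges for k, n in nets.items()})
        else:
            skipped("networks")

        # ---- topology ---------------------------------------------------
        if "topology" in cfg and nets:
            tp = cfg["topology"]
            gcms, summaries = {}, {}
            for k, net in nets.items():
                sig = count_orbits(net.graph)
                gcms[k] = graphlet_correlation_matrix(sig)
                summaries[k] = {**summary_stats(net),
                                "keystones": top_keystones(net, 2)}
                curves = {s: attack_curve(net.graph, s,
                                          n_rep=tp.get("n_rep", 50),
                                          seed=stage_seed(master, "topology"))
                          for s in ("random", "degree", "betweenness")}
                pd.DataFrame({"fraction": curves["random"].fraction_removed,
                              **{s: c.connectivity for s, c in curves.items()}}
                             ).to_csv(out / f"attack_c{k}.tsv", sep="\t",
                                      index=False)
            ks = sorted(gcms)
            D = np.zeros((len(ks), len(ks)))
            for a in range(len(ks)):
                for b in range(a + 1, len(ks)):
                    D[a, b] = D[b, a] = gcd(gcms[ks[a]], gcms[ks[b]])
            pd.DataFrame(D, index=ks, columns=ks).to_csv(out / "gcd.tsv", sep="\t")
            if len(ks) >= 2:
                coords = embed_networks(D)
                pd.DataFrame(coords, index=ks, columns=["mds1", "mds2"]
                             ).to_csv(out / "mds.tsv", sep="\t")
            with open(out / "topology.json", "w") as fh:
                json.dump({str(k): v for k, v in summaries.items()}, fh,
                          default=float)
            done("topology", networks=ks)
        else:
            skipped("topology")

        # ---- maz --------------------------------------------------------
        if "maz" in cfg:
            mz = cfg["maz"]
            ctrl = meta.frame["treatment"].to_numpy() == "control"
            model = fit_age_model(table.counts[ctrl], meta.weeks[ctrl],
                                  n_trees=mz.get("n_trees", 1000),
                                  seed=stage_seed(master, "maz"))
            res = maz_scores(model, table.counts, meta.weeks, ctrl)
            res.to_frame(table.sample_ids).to_csv(out / "maz.tsv", sep="\t")
            done("maz", mean_maz=float(np.nanmean(res.maz)))
        else:
            skipped("maz")

        # ---- classify ---------------------------------------------------
        if "classify" in cfg:
            cd = cfg["classify"]
            homa = homa_ir(meta.frame["glucose"].to_numpy(),
                           meta.frame["insulin"].to_numpy())
            disease_sample = homa_elevated(homa)
            if "NAFLD" in meta.frame.columns:
                disease_sample |= meta.frame["NAFLD"].to_numpy() > 5
            # label is per subject: any diseased observation marks the animal
            by_subj = pd.Series(disease_sample, index=meta.subjects
                                ).groupby(level=0).any()
            labels = by_subj[meta.subjects].to_numpy()
            rep = classify_disease(table, labels, meta.weeks,
                                   n_trees=cd.get("n_trees", 1000),
                                   depth=cd.get("depth", 1000),
                                   n_trials=cd.get("n_trials", 10),
                                   seed=stage_seed(master, "classify"),
                                   importance=cd.get("importance", True))
            rep.errors.to_csv(out / "rf_errors.tsv", sep="\t", index=False)
            rep.importance.to_csv(out / "rf_importance.tsv", sep="\t")
            done("classify", mean_error={str(k): float(v) for k, v in
                                         rep.mean_error.items()})
        else:
            skipped("classify")

        # ---- homa -------------------------------------------------------
        if "homa" in cfg and {"glucose", "insulin"} <= set(meta.frame.columns):
            score = homa_ir(meta.frame["glucose"].to_numpy(),
                            meta.frame["insulin"].to_numpy())
            pd.DataFrame({"sample": meta.sample_ids, "homa_ir": score,
                          "homa_elevated": homa_elevated(score)}
                         ).to_csv(out / "homa.tsv", sep="\t", index=False)
            done("homa", n_elevated=int(homa_elevated(score).sum()))
        else:
            skipped("homa")
    except Exception as exc:
        ran = set(report["stages"])
        failed = next((s for s in STAGES if s in cfg or (s == "data") if s not in ran),
                      "?")
        log.error("pipeline halted in stage %r: %s", failed, exc)
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return out
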