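"""End-to-end orchestration of the subtyping analysis on one cohort.

Stages run in dependency order — simulate → preprocess → discover → score →
regulons → classify → deconvolve → trajectory → survival → ihc — each
writing its artifacts under the output directory and recording wall-clock,
seeds and output checksums in a run manifest. Stages can be toggled off;
requesting a stage whose upstream artifact is missing raises a dependency
error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import clinical as clin
from . import deconvolve as dcv
from . import io as sio
from . import nmf
from . import regulons as rg
from . import signatures as sig
from . import synthetic as syn
from . import trajectory as traj
from .matrix import GeneSetCollection, ValidationError
from .preprocess import counts_to_log_tpm, filter_variable_genes, tpm_from_log

log = logging.getLogger("sclc_taxonomy.pipeline")

STAGES = [
    "simulate", "preprocess", "discover", "score", "regulons",
    "classify", "deconvolve", "trajectory", "survival", "ihc",
]

DEFAULT_CONFIG = {
    "out_dir": "run",
    "seed": 7,
    "stages": {s: True for s in STAGES},
    "cohort": {},                      # CohortConfig overrides
    "timecourse": {},                  # TimeCourseConfig overrides
    "n_variable_genes": 1000,
    "k_min": 2,
    "k_max": 8,
    "n_subsamples": 30,
    "n_perm": 20,
    "null_subsamples": 8,
    "drop_threshold": 0.02,
    "ssgsea_alpha": 0.25,
    "regulon_n_perm": 200,
    "regulon_fdr_q": 0.05,
    "metagene_n_top": 100,
    "classifier_genes": 100,
    "cd8_cutoff": "median",
    "n_pcs": 3,
}


class DependencyError(RuntimeError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(path: str, stage: str, upstream: str) -> str:
    if not os.path.exists(path):
        raise DependencyError(
            f"stage {stage!r} requires {path} produced by stage {upstream!r}"
        )
    return path


def load_config(path=None, overrides=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        cfg[k] = v
    return cfg


def annotate_clusters(log_expr, labels, programs: GeneSetCollection, regulators: dict) -> dict:
    """Map discovered cluster ids to subtype names.

    Each cluster is scored for the three phenotype programs (EMT → SCLC-M,
    immune → SCLC-I, hypoxia → SCLC-H) and the three regulator genes
    (→ SCLC-A/-P/-N); cluster/name pairs are assigned greedily by
    standardised score so every cluster gets a unique annotation.
    """
    anno_scores = {}
    score_defs = {
        "SCLC-M": ("set", programs["EMT"]),
        "SCLC-I": ("set", programs["IMMUNE"]),
        "SCLC-H": ("set", programs["HYPOXIA"]),
        "SCLC-A": ("gene", regulators["SCLC-A"]),
        "SCLC-P": ("gene", regulators["SCLC-P"]),
        "SCLC-N": ("gene", regulators["SCLC-N"]),
    }
    df = log_expr.to_frame()
    labels = np.asarray(labels)
    for name, (kind, ref) in score_defs.items():
        if kind == "set":
            present = [g for g in ref if g in df.index]
            vals = df.loc[present].mean(axis=0).to_numpy()
        else:
            vals = df.loc[ref].to_numpy() if ref in df.index else np.zeros(df.shape[1])
        per_cluster = np.array([vals[labels == c].mean() for c in np.unique(labels)])
        z = (per_cluster - per_cluster.mean()) / (per_cluster.std() or 1.0)
        anno_scores[name] = z
    clusters = list(np.unique(labels))
    pairs = sorted(
        ((anno_scores[n][i], n, c) for n in anno_scores for i, c in enumerate(clusters)),
        reverse=True,
    )
    mapping, used = {}, set()
    for score, name, c in pairs:
        if c not in mapping and name not in used:
            mapping[c] = name
            used.add(name)
    for c in clusters:  # more clusters than names: keep raw id
        mapping.setdefault(c, f"NMF{c + 1}")
    return mapping


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = config["out_dir"]
    os.makedirs(out, exist_ok=True)
    stages = config["stages"]
    ss = np.random.SeedSequence(config["seed"])
    seeds = {s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGES, ss.spawn(len(STAGES)))}
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config["seed"],
        "stage_seeds": seeds,
        "stages": {},
    }

    def record(stage, t0, paths):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {p: _sha256(p) for p in paths},
        }

    p = {
        "counts": f"{out}/counts.tsv",
        "lengths": f"{out}/gene_lengths.tsv",
        "truth": f"{out}/truth.json",
        "signature": f"{out}/celltype_signature.tsv",
        "clinical": f"{out}/clinical.csv",
        "logtpm": f"{out}/log2tpm.tsv",
        "rho": f"{out}/cophenetic.tsv",
        "labels": f"{out}/labels.csv",
        "metagenes": f"{out}/metagenes.gmt",
        "scores": f"{out}/signature_scores.tsv",
        "enrich": f"{out}/regulon_enrichment.tsv",
        "model": f"{out}/nsc_model.json",
        "calls": f"{out}/classifier_calls.csv",
        "fractions": f"{out}/fractions.csv",
        "mi_scores": f"{out}/mi_scores.csv",
        "pseudotime": f"{out}/pseudotime.csv",
        "concordance": f"{out}/concordance.tsv",
        "survival": f"{out}/logrank.json",
        "km": f"{out}/km_curves.tsv",
        "ihc": f"{out}/ihc_calls.csv",
        "manifest": f"{out}/manifest.json",
    }

    if stages.get("simulate"):
        t0 = time.time()
        cohort_cfg = syn.CohortConfig(**{"seed": seeds["simulate"], **config["cohort"]})
        counts, lengths, truth, clinical = syn.generate_cohort(cohort_cfg)
        sio.write_expression_tsv(counts, p["counts"])
        sio.write_gene_lengths_tsv(lengths, p["lengths"])
        sio.write_clinical_csv(clinical, p["clinical"])
        truth.celltype_signature.rename_axis("gene_id").to_csv(p["signature"], sep="\t")
        with open(p["truth"], "w") as fh:
            json.dump(
                {
                    "subtype_labels": truth.subtype_labels,
                    "ne_position": truth.ne_position.tolist(),
                    "fractions": truth.fractions.to_dict(orient="index"),
                    "programs": {k: sorted(truth.programs[k]) for k in truth.programs.names()},
                    "regulators": truth.regulators,
                },
                fh,
            )
        record(
            "simulate", t0,
            [p["counts"], p["lengths"], p["truth"], p["clinical"], p["signature"]],
        )

    if stages.get("preprocess"):
        t0 = time.time()
        counts = sio.read_expression_tsv(_need(p["counts"], "preprocess", "simulate"), "counts")
        lengths = sio.read_gene_lengths_tsv(p["lengths"])
        logtpm = counts_to_log_tpm(counts, lengths)
        logtpm = filter_variable_genes(logtpm, min(config["n_variable_genes"], logtpm.n_genes))
        sio.write_expression_tsv(logtpm, p["logtpm"])
        record("preprocess", t0, [p["logtpm"]])

    if stages.get("discover"):
        t0 = time.time()
        logtpm = sio.read_expression_tsv(_need(p["logtpm"], "discover", "preprocess"), "log2TPM")
        res = nmf.run_rank_scan(
            logtpm,
            k_min=config["k_min"], k_max=config["k_max"],
            n_subsamples=config["n_subsamples"], n_perm=config["n_perm"],
            null_subsamples=config["null_subsamples"],
            drop_threshold=config["drop_threshold"], seed=seeds["discover"],
        )
        pd.DataFrame(
            {
                "K": list(res.cophenetic),
                "rho": [res.cophenetic[k] for k in res.cophenetic],
                "null_p5": [res.band[k][0] for k in res.cophenetic],
                "null_p95": [res.band[k][1] for k in res.cophenetic],
            }
        ).to_csv(p["rho"], sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": logtpm.sample_ids, "cluster": res.labels}
        ).to_csv(p["labels"], index=False)
        metasets = {
            f"metagene_{k+1}": set(
                nmf.extract_metagene_genes(res.factors.W, k, config["metagene_n_top"], logtpm.gene_ids)
            )
            for k in range(res.selected_rank)
        }
        sio.write_gmt(GeneSetCollection(metasets), p["metagenes"])
        with open(f"{out}/rank_selection.json", "w") as fh:
            json.dump(res.selection, fh)
        record("discover", t0, [p["rho"], p["labels"], p["metagenes"]])

    truth_data = None
    if os.path.exists(p["truth"]):
        with open(p["truth"]) as fh:
            truth_data = json.load(fh)

    if stages.get("score"):
        t0 = time.time()
        logtpm = sio.read_expression_tsv(_need(p["logtpm"], "score", "preprocess"), "log2TPM")
        if truth_data is None:
            raise DependencyError("stage 'score' requires truth.json (program gene sets)")
        sets = GeneSetCollection(
            {k: set(v) for k, v in truth_data["programs"].items() if k in ("EMT", "IMMUNE", "HYPOXIA")}
        )
        table = sig.score_table(logtpm, sets, method="ssgsea", alpha=config["ssgsea_alpha"])
        table.to_csv(p["scores"], sep="\t")
        record("score", t0, [p["scores"]])

    if stages.get("regulons"):
        t0 = time.time()
        logtpm = sio.read_expression_tsv(_need(p["logtpm"], "regulons", "preprocess"), "log2TPM")
        meta = sio.read_gmt(_need(p["metagenes"], "regulons", "discover"))
        regulators = [r for r in truth_data["regulators"].values() if r in logtpm.gene_ids]
        edges = rg.build_network(
            logtpm, regulators, n_perm=config["regulon_n_perm"],
            seed=seeds["regulons"], fdr_q=config["regulon_fdr_q"],
        )
        edges = rg.dpi_prune(edges)
        table = rg.enrichment_table(
            {name: meta[name] for name in meta.names()},
            rg.edges_to_regulons(edges),
            logtpm.gene_ids,
        )
        table.to_csv(p["enrich"], sep="\t", index=False)
        record("regulons", t0, [p["enrich"]])

    if stages.get("classify"):
        t0 = time.time()
        logtpm = sio.read_expression_tsv(_need(p["logtpm"], "classify", "preprocess"), "log2TPM")
        labels_df = pd.read_csv(_need(p["labels"], "classify", "discover"))
        model = clf.train(
            logtpm, labels_df["cluster"].astype(str), seed=seeds["classify"]
        )
        model.to_json(p["model"])
        calls, probs = clf.predict(model, logtpm)
        pd.DataFrame({"sample_id": logtpm.sample_ids, "call": calls}).join(
            probs.reset_index(drop=True)
        ).to_csv(p["calls"], index=False)
        record("classify", t0, [p["model"], p["calls"]])

    annotation = None
    if stages.get("deconvolve") or stages.get("trajectory") or stages.get("survival"):
        logtpm = sio.read_expression_tsv(_need(p["logtpm"], "deconvolve", "preprocess"), "log2TPM")
        labels_df = pd.read_csv(_need(p["labels"], "deconvolve", "discover"))
        if truth_data is not None:
            annotation = annotate_clusters(
                logtpm, labels_df["cluster"].to_numpy(),
                GeneSetCollection({k: set(v) for k, v in truth_data["programs"].items()}),
                truth_data["regulators"],
            )
            subtype_calls = labels_df["cluster"].map(annotation)
        else:
            subtype_calls = labels_df["cluster"].astype(str)
        subtype_calls.index = labels_df["sample_id"]

    epi_log_path = f"{out}/epithelial_log2.tsv"
    if stages.get("deconvolve"):
        t0 = time.time()
        counts_full = sio.read_expression_tsv(p["counts"], "counts")
        lengths = sio.read_gene_lengths_tsv(p["lengths"])
        full_tpm = tpm_from_log(counts_to_log_tpm(counts_full, lengths))
        sig_mtx = pd.read_csv(
            _need(p["signature"], "deconvolve", "simulate"), sep="\t", index_col="gene_id"
        )
        fr = dcv.fractions_table(full_tpm, sig_mtx)
        fr.to_csv(p["fractions"])
        groups = subtype_calls.reindex(full_tpm.sample_ids)
        profiles = {}
        for grp in groups.unique():
            members = [s for s in full_tpm.sample_ids if groups[s] == grp]
            if len(members) >= 8:
                profiles[grp] = dcv.groupwise_expression(
                    full_tpm.subset_samples(members), fr.loc[members]
                )
        pooled = dcv.groupwise_expression(full_tpm, fr)
        group_of = {s: (groups[s] if groups[s] in profiles else "__pooled__")
                    for s in full_tpm.sample_ids}
        profiles["__pooled__"] = pooled
        epi, flags = dcv.epithelial_per_sample(full_tpm, fr, profiles, pd.Series(group_of))
        epi_log = np.log2(epi + 1.0)
        epi_log.insert(0, "gene_id", epi_log.index)
        epi_log.to_csv(epi_log_path, sep="\t", index=False)
        m_like = [s for s in full_tpm.sample_ids if groups[s] == "SCLC-M"]
        i_like = [s for s in full_tpm.sample_ids if groups[s] == "SCLC-I"]
        outputs = [p["fractions"], epi_log_path]
        if len(m_like) >= 3 and len(i_like) >= 3:
            epi_log_df = np.log2(epi + 1.0)
            de = dcv.epithelial_de(
                epi_log_df[m_like], epi_log_df[i_like], config["classifier_genes"]
            )
            scores = dcv.mi_intrinsic_scores(logtpm, de.up_in_a, de.up_in_b)
            scores.to_csv(p["mi_scores"])
            outputs.append(p["mi_scores"])
        record("deconvolve", t0, outputs)

    if stages.get("trajectory"):
        t0 = time.time()
        epi_log_df = pd.read_csv(
            _need(epi_log_path, "trajectory", "deconvolve"), sep="\t", index_col="gene_id"
        )
        programs = GeneSetCollection({k: set(v) for k, v in truth_data["programs"].items()})
        ne_groups = subtype_calls.reindex(epi_log_df.columns)
        ne_like = ne_groups.isin(["SCLC-A", "SCLC-N"])
        nonne_like = ne_groups.isin(["SCLC-M", "SCLC-P"])
        sig_genes = sorted((programs["NE"] | programs["NONNE"]) & set(epi_log_df.index))
        if ne_like.sum() >= 2 and nonne_like.sum() >= 2:
            proto_ne = epi_log_df.loc[sig_genes, ne_like.to_numpy()].mean(axis=1)
            proto_nonne = epi_log_df.loc[sig_genes, nonne_like.to_numpy()].mean(axis=1)
            ne_scores = pd.Series(
                [
                    sig.ne_score(epi_log_df[s], proto_ne, proto_nonne, sig_genes)
                    for s in epi_log_df.columns
                ],
                index=epi_log_df.columns,
            )
        else:
            ne_scores = pd.Series(0.0, index=epi_log_df.columns)
        res = traj.infer_pseudotime(epi_log_df, ne_scores, n_pcs=config["n_pcs"])
        df = pd.DataFrame(
            {
                "sample_id": epi_log_df.columns,
                "pseudotime": res.pseudotime.to_numpy(),
                "ne_score": ne_scores.to_numpy(),
                "subtype": subtype_calls.reindex(epi_log_df.columns).to_numpy(),
            }
        )
        df.to_csv(p["pseudotime"], index=False)
        record("trajectory", t0, [p["pseudotime"]])

    if stages.get("survival"):
        t0 = time.time()
        clin_df = sio.read_clinical_csv(_need(p["clinical"], "survival", "simulate"))
        groups = subtype_calls.reindex(clin_df["sample_id"]).fillna("NA").to_numpy()
        chi2, df_, pval = clin.logrank_test(clin_df["os_time"], clin_df["os_event"], groups)
        with open(p["survival"], "w") as fh:
            json.dump({"chi2": chi2, "df": df_, "p": pval}, fh)
        km_rows = []
        for grp in pd.unique(groups):
            m = groups == grp
            km = clin.km_estimate(clin_df["os_time"][m], clin_df["os_event"][m])
            km.insert(0, "group", grp)
            km_rows.append(km)
        pd.concat(km_rows).to_csv(p["km"], sep="\t", index=False)
        record("survival", t0, [p["survival"], p["km"]])

    if stages.get("ihc"):
        t0 = time.time()
        clin_df = sio.read_clinical_csv(_need(p["clinical"], "ihc", "simulate"))
        calls = clin.ihc_classify(clin_df, config["cd8_cutoff"])
        calls.to_csv(p["ihc"], index=False)
        record("ihc", t0, [p["ihc"]])

    with open(p["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
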