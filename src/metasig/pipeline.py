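"""Config-driven pipeline: ingest -> catalog -> signatures -> clusters -> screens.

Every stage writes plain-text artifacts (TSV/JSON) into the run directory and
registers them, with content hashes, in a run manifest. Reruns with identical
config and inputs reproduce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog96, consensus_cluster, genomic_screen, io_cohort, nmf_signatures, survstats
from .errors import ConfigError, MetasigError

DEFAULT_CONFIG = {
    "inputs": {"maf": None, "clinical": None, "cnv": None, "ici": None},
    "catalog": {"min_sample_frac": 0.01, "panel_mb": 1.14},
    "nmf": {"k_range": [2, 6], "n_runs": 10, "seed": 17, "max_iter": 400, "tol": 1e-6, "k": None},
    "binarize": {"threshold": 0.25},
    "cluster": {
        "k_max": 8,
        "reps": 1000,
        "p_item": 0.8,
        "seed": 23,
        "sd_min": 0.1,
        "min_consensus": 0.9,
        "elbow": 0.1,
        "k": None,
    },
    "screens": {
        "recurrent_min_frac": 0.05,
        "fdr": 0.1,
        "alpha": 0.05,
        "adjust": ["age", "sex", "tumor_type"],
        "min_carriers": 5,
        "ici_gene": None,
    },
    "reference_signatures": None,  # TSV path; packaged example used when null
    "output_dir": "metasig_run",
}

_VALID_TOP = set(DEFAULT_CONFIG)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    bad = [k for k in user if k not in _VALID_TOP]
    if bad:
        raise ConfigError(f"unknown config keys: {bad}", keys=bad)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            unknown = [k for k in val if k not in cfg[key]]
            if unknown:
                raise ConfigError(f"unknown keys under {key!r}: {unknown}", keys=unknown)
            cfg[key].update(val)
        else:
            cfg[key] = val
    if not cfg["inputs"].get("maf") or not cfg["inputs"].get("clinical"):
        missing = [k for k in ("maf", "clinical") if not cfg["inputs"].get(k)]
        raise ConfigError(f"inputs.{missing} must be set", keys=missing)
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}
    stage_seconds: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def register(self, name: str, path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def note(self, message: str) -> None:
        self.log.append(message)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "input_hashes": self.input_hashes,
                    "outputs": self.outputs,
                    "stage_seconds": self.stage_seconds,
                    "log": self.log,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def run_pipeline(config_path) -> RunManifest:
    cfg = load_config(config_path)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.stage_seconds[stage] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and isinstance(exc, MetasigError):
                    raise MetasigError(f"stage {stage!r} failed: {exc}") from exc

        return _T()

    # --- ingest -----------------------------------------------------------
    with timed("ingest"):
        records = io_cohort.read_maf(cfg["inputs"]["maf"])
        manifest.input_hashes["maf"] = _sha256(cfg["inputs"]["maf"])
        clinical_records = io_cohort.read_clinical(cfg["inputs"]["clinical"])
        manifest.input_hashes["clinical"] = _sha256(cfg["inputs"]["clinical"])
        cnv_records = []
        if cfg["inputs"].get("cnv"):
            cnv_records = io_cohort.read_cnv(cfg["inputs"]["cnv"])
            manifest.input_hashes["cnv"] = _sha256(cfg["inputs"]["cnv"])
        ici_records = []
        if cfg["inputs"].get("ici"):
            ici_records = io_cohort.read_ici(cfg["inputs"]["ici"])
            manifest.input_hashes["ici"] = _sha256(cfg["inputs"]["ici"])
        manifest.note(f"ingest: {len(records)} mutation records")
        nonsyn = io_cohort.filter_nonsynonymous(records)
        manifest.note(f"nonsynonymous filter: {len(records)} -> {len(nonsyn)} records")
        clinical = io_cohort.clinical_frame(clinical_records)
        samples = list(clinical.index)

    # --- catalog ----------------------------------------------------------
    with timed("catalog"):
        snvs = [r for r in nonsyn if r.variant_type == "SNP"]
        catalog = catalog96.build_catalog(
            snvs, samples, min_sample_frac=cfg["catalog"]["min_sample_frac"]
        )
        catalog.to_tsv(out / "catalog96.tsv")
        manifest.register("catalog96", out / "catalog96.tsv")
        by_sample: dict[str, list] = {s: [] for s in samples}
        for r in nonsyn:
            if r.sample_id in by_sample:
                by_sample[r.sample_id].append(r)
        tmb = {
            s: catalog96.compute_tmb(rs, panel_mb=cfg["catalog"]["panel_mb"])
            for s, rs in by_sample.items()
        }
        tcw_rows = []
        for s, rs in by_sample.items():
            snv_rs = [r for r in rs if r.variant_type == "SNP"]
            summ = catalog96.compute_tcw(snv_rs, sample_id=s)
            tcw_rows.append(
                {"sample_id": s, "tmb": round(tmb[s], 4), "tcw_count": summ.tcw_count, "total_c_mut": summ.total_c_mut}
            )
        pd.DataFrame(tcw_rows).to_csv(out / "burden.tsv", sep="\t", index=False)
        manifest.register("burden", out / "burden.tsv")
        if clinical["tmb"].isna().all():
            clinical = clinical.assign(tmb=[tmb[s] for s in samples])

    # --- signatures -------------------------------------------------------
    with timed("signatures"):
        ncfg = cfg["nmf"]
        k_lo, k_hi = ncfg["k_range"]
        rank = nmf_signatures.estimate_rank(
            catalog.counts,
            range(int(k_lo), int(k_hi) + 1),
            n_runs=int(ncfg["n_runs"]),
            seed=int(ncfg["seed"]),
            max_iter=int(ncfg["max_iter"]),
        )
        k = int(ncfg["k"]) if ncfg.get("k") else rank.chosen_k
        sigs, expo, kl = nmf_signatures.nmf_factorize(
            catalog.counts,
            k,
            seed=int(ncfg["seed"]),
            max_iter=int(ncfg["max_iter"]),
            tol=float(ncfg["tol"]),
            samples=samples,
        )
        ref_path = cfg.get("reference_signatures")
        if ref_path is None:
            from importlib.resources import files

            ref_path = files("metasig.data") / "reference_signatures_example.tsv"
        ref = nmf_signatures.ReferenceSignatures.from_tsv(ref_path)
        matches, sim = nmf_signatures.match_reference(sigs, ref)
        present = nmf_signatures.binarize_activity(expo, threshold=float(cfg["binarize"]["threshold"]))
        sigs.to_frame(catalog.channels).to_csv(out / "signatures.tsv", sep="\t")
        expo.rel_frame().round(6).to_csv(out / "exposures_rel.tsv", sep="\t")
        pd.DataFrame(
            present, index=pd.Index(samples, name="sample_id"), columns=sigs.names
        ).astype(int).to_csv(out / "signature_presence.tsv", sep="\t")
        with open(out / "rank_selection.json", "w") as fh:
            json.dump(
                {
                    "k_range": rank.k_range,
                    "cophenetic": {str(kk): rank.cophenetic[kk] for kk in rank.k_range},
                    "reconstruction_error": {str(kk): rank.reconstruction_error[kk] for kk in rank.k_range},
                    "chosen_k": rank.chosen_k,
                    "used_k": k,
                    "kl_divergence": kl,
                    "reference_matches": matches,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        for name in ("signatures.tsv", "exposures_rel.tsv", "signature_presence.tsv", "rank_selection.json"):
            manifest.register(name.split(".")[0], out / name)
        manifest.note(f"signatures: chosen_k={rank.chosen_k}, used k={k}")

    # --- clustering -------------------------------------------------------
    with timed("cluster"):
        ccfg = cfg["cluster"]
        try:
            X, keep = consensus_cluster.filter_low_variance(expo.H_rel, sd_min=float(ccfg["sd_min"]))
            result = consensus_cluster.consensus_cluster(
                X,
                k_max=int(ccfg["k_max"]),
                reps=int(ccfg["reps"]),
                p_item=float(ccfg["p_item"]),
                seed=int(ccfg["seed"]),
            )
            result = consensus_cluster.finalize_subtypes(
                result,
                k=int(ccfg["k"]) if ccfg.get("k") else None,
                min_cluster_consensus=float(ccfg["min_consensus"]),
                elbow=float(ccfg["elbow"]),
            )
            labels = pd.DataFrame({"sample_id": samples, "cluster": result.labels})
            labels.to_csv(out / "clusters.tsv", sep="\t", index=False)
            manifest.register("clusters", out / "clusters.tsv")
            with open(out / "cluster_quality.json", "w") as fh:
                json.dump(
                    {
                        "chosen_k": result.chosen_k,
                        "area": {str(kk): result.area[kk] for kk in result.k_values},
                        "delta_area": {str(kk): result.delta_area[kk] for kk in result.k_values},
                        "cluster_consensus": {str(c): v for c, v in result.cluster_consensus.items()},
                        "unstable_clusters": result.unstable_clusters,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            manifest.register("cluster_quality", out / "cluster_quality.json")
            cluster_labels = pd.Series(result.labels, index=clinical.index, name="cluster")
            manifest.note(f"cluster: k={result.chosen_k}")
        except MetasigError as exc:
            cluster_labels = None
            manifest.note(f"cluster: skipped ({exc})")

    # --- survival ---------------------------------------------------------
    with timed("survival"):
        surv_df = clinical.dropna(subset=["os_months", "os_event"])
        km = survstats.km_fit(surv_df["os_months"], surv_df["os_event"].astype(int))
        summary: dict = {
            "km_median": km.median,
            "km_median_ci": list(km.median_ci),
            "n": int(len(surv_df)),
        }
        instability_cols = [c for c in ("tmb", "fga", "msi") if surv_df[c].notna().any()]
        if instability_cols:
            try:
                fit = survstats.coxph_fit(surv_df, "os_months", "os_event", instability_cols)
                summary["instability_cox"] = json.loads(fit.summary.round(6).to_json(orient="index"))
            except MetasigError as exc:
                manifest.note(f"survival: instability Cox skipped ({exc})")
        adjust = [c for c in cfg["screens"]["adjust"] if surv_df[c].notna().any()]
        sig_cox = {}
        for j, name in enumerate(sigs.names):
            ind = pd.Series(present[:, j].astype(float), index=clinical.index, name="sig_present")
            df = surv_df.join(ind)
            try:
                fit = survstats.coxph_fit(df, "os_months", "os_event", ["sig_present", *adjust], ph_check=True)
                row = fit.summary.loc["sig_present"]
                sig_cox[name] = {
                    "hr": round(float(row["hr"]), 6),
                    "ci_low": round(float(row["ci_low"]), 6),
                    "ci_high": round(float(row["ci_high"]), 6),
                    "p": round(float(row["p"]), 8),
                    "ph_global_p": round(float(fit.ph_global_p), 8),
                }
            except MetasigError as exc:
                sig_cox[name] = {"error": str(exc)}
        summary["signature_cox"] = sig_cox
        if cluster_labels is not None:
            df = surv_df.join(cluster_labels.astype(str))
            groups = [g for _, g in df.groupby("cluster")]
            if len(groups) >= 2:
                kw = survstats.kruskal_wallis([g["tmb"].dropna() for g in groups]) if df["tmb"].notna().any() else None
                summary["cluster_tmb_test"] = None if kw is None else {"stat": kw.statistic, "p": kw.p}
        with open(out / "survival_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest.register("survival_summary", out / "survival_summary.json")

    # --- screens ----------------------------------------------------------
    with timed("screens"):
        scfg = cfg["screens"]
        M = genomic_screen.gene_mutation_matrix(nonsyn, samples)
        rec = genomic_screen.recurrent_genes(M, min_frac=float(scfg["recurrent_min_frac"]))
        gene_screen = genomic_screen.prognostic_gene_screen(
            M,
            surv_df,
            adjust=adjust,
            alpha=float(scfg["alpha"]),
            genes=rec,
            min_carriers=int(scfg["min_carriers"]),
        )
        gene_screen.round(6).to_csv(out / "gene_screen.tsv", sep="\t", index=False)
        manifest.register("gene_screen", out / "gene_screen.tsv")
        prognostic = list(gene_screen.loc[gene_screen.get("significant", pd.Series(dtype=bool)) == True, "gene"])
        network_genes = prognostic if len(prognostic) >= 2 else rec[: min(len(rec), 25)]
        if len(network_genes) >= 2:
            assocs, degree = genomic_screen.cooccurrence_network(M, genes=network_genes, fdr=float(scfg["fdr"]))
            genomic_screen.pair_table(assocs).round(6).to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
            degree.to_csv(out / "interaction_degree.tsv", sep="\t")
            manifest.register("cooccurrence", out / "cooccurrence.tsv")
            manifest.register("interaction_degree", out / "interaction_degree.tsv")
        if cnv_records:
            cnv_screen = genomic_screen.cnv_survival_screen(
                cnv_records, surv_df, call="deletion", adjust=adjust, min_carriers=int(scfg["min_carriers"])
            )
            cnv_screen.round(6).to_csv(out / "cnv_screen.tsv", sep="\t", index=False)
            manifest.register("cnv_screen", out / "cnv_screen.tsv")
        if ici_records and scfg.get("ici_gene"):
            mutants = set(M.index[M[scfg["ici_gene"]]]) if scfg["ici_gene"] in M.columns else set()
            ici_mut = {r.sample_id for r in ici_records if r.sample_id in mutants}
            # ICI cohorts are usually disjoint samples; fall back to suffix convention
            if not ici_mut:
                ici_mut = {r.sample_id for r in ici_records if r.sample_id.endswith("_MUT")}
            try:
                test, rates = genomic_screen.ici_response_assoc(ici_records, ici_mut)
                with open(out / "ici_response.json", "w") as fh:
                    json.dump({"p": test.p, "odds_ratio": test.effect, **rates}, fh, indent=2, sort_keys=True)
                manifest.register("ici_response", out / "ici_response.json")
            except MetasigError as exc:
                manifest.note(f"screens: ICI association skipped ({exc})")

    manifest.save(out / "manifest.json")
    return manifest


def report(manifest: RunManifest) -> dict:
    """Collect the run's headline numbers into a single JSON-able summary."""
    out: dict = {"stages": manifest.stage_seconds, "outputs": sorted(manifest.outputs)}
    base = None
    for entry in manifest.outputs.values():
        base = Path(entry["path"]).parent
        break
    if base is None:
        return out
    for name in ("rank_selection", "cluster_quality", "survival_summary", "ici_response"):
        p = base / f"{name}.json"
        if p.exists():
            with open(p) as fh:
                out[name] = json.load(fh)
    for name in ("gene_screen", "cnv_screen"):
        p = base / f"{name}.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            if "significant" in df.columns:
                out[name] = df[df["significant"]].to_dict("records")
    return out
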