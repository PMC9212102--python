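"""End-to-end pipeline: cohort -> connectomes -> harmonization -> graphs ->
classifier CV -> saliency -> topology -> clinical correlations.

Every stage writes plain-text artifacts under a run directory together with
a manifest (config hash, seed, package version), and the report files are
byte-reproducible for a fixed config + seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (
    devectorize_upper,
    fisher_z,
    pearson_connectivity,
    stack_edges,
)
from .evaluate import CVReport, CVScheme, cross_validate
from .gcn import GCNClassifier, aggregate_saliency
from .graphs import build_cohort_graphs
from .harmonize import (
    AnalysisError,
    CombatHarmonizer,
    bh_fdr,
    design_from_records,
    site_effect_scan,
)
from .svm import NestedLinearSVM, region_weights
from .synth import (
    SynthConfig,
    generate_cohort,
    inject_site_effects,
    subjects_to_frame,
    write_atlas,
)
from .topology import (
    cohort_nodal_metrics,
    correlate_symptoms,
    permutation_group_test,
    pomp,
)

log = logging.getLogger("connectogcn")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},
    "graph": {"k": 10, "weighting": "gaussian"},
    "harmonize": {"enabled": True, "within_folds": False},
    "model": "gcn",
    "gcn": {},
    "svm": {},
    "cv": {"kind": "stratified_kfold", "n_folds": 10, "n_repeats": 1},
    "saliency": {"top_k": 10},
    "topology": {"sparsity": 0.20, "n_perm": 10000, "q": 0.05},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _synth_config(cfg: dict) -> SynthConfig:
    kw = dict(cfg.get("synth", {}))
    if "site_sizes" in kw:
        kw["site_sizes"] = tuple(tuple(x) for x in kw["site_sizes"])
        kw.setdefault("n_sites", len(kw["site_sizes"]))
    if "signal_nodes" in kw:
        kw["signal_nodes"] = tuple(kw["signal_nodes"])
    kw.setdefault("seed", cfg["seed"])
    return SynthConfig(**kw)


class _FoldwiseHarmonizedModel:
    """Fit ComBat on the training fold only, apply it to the test fold.

    Operates on subject indices into cohort-level arrays so CV code never
    sees site metadata. Methodologically stricter than pooled-first
    harmonization (no information flows from test to train).
    """

    def __init__(self, edges, sites, covariates, n_regions, make_inner):
        self.edges = edges
        self.sites = sites
        self.covariates = covariates
        self.n_regions = n_regions
        self.make_inner = make_inner

    def _featurize(self, harmonized_edges, inner):
        if isinstance(inner, GCNClassifier):
            return np.stack(
                [devectorize_upper(e, self.n_regions) for e in harmonized_edges]
            )
        return harmonized_edges

    def fit(self, idx, y):
        idx = np.asarray(idx)
        self.combat_ = CombatHarmonizer()
        harmonized = self.combat_.fit_transform(
            self.edges[idx], sites=self.sites[idx], covariates=self.covariates[idx]
        )
        self.inner_ = self.make_inner()
        self.inner_.fit(self._featurize(harmonized, self.inner_), y)
        self.classes_ = self.inner_.classes_
        return self

    def _transform(self, idx):
        idx = np.asarray(idx)
        harmonized = self.combat_.transform(
            self.edges[idx], sites=self.sites[idx], covariates=self.covariates[idx]
        )
        return self._featurize(harmonized, self.inner_)

    def predict(self, idx):
        return self.inner_.predict(self._transform(idx))

    def predict_proba(self, idx):
        return self.inner_.predict_proba(self._transform(idx))

    def decision_function(self, idx):
        return self.inner_.decision_function(self._transform(idx))


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute all stages; returns in-memory results and writes artifacts."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    results: dict = {"config": cfg}
    try:
        _run_stages(cfg, out, results)
    except Exception as exc:  # partial outputs stay on disk for inspection
        stage = results.get("stage", "?")
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return results


def _run_stages(cfg: dict, out: Path, results: dict) -> None:
    seed = int(cfg["seed"])

    results["stage"] = "synth"
    scfg = _synth_config(cfg)
    records, series = generate_cohort(scfg)
    subjects = subjects_to_frame(records)
    subjects.to_csv(out / "subjects.csv", index=False, float_format="%.10g")
    write_atlas(scfg.region_labels, out / "atlas.tsv")
    log.info("synth: %d subjects, %d sites", len(records), scfg.n_sites)

    results["stage"] = "connectome"
    matrices = [
        fisher_z(
            pearson_connectivity(
                ts.values, subject_id=ts.subject_id, region_labels=scfg.region_labels
            )
        )
        for ts in series
    ]
    edge_df = stack_edges(matrices)
    site_ids = np.array([r.site_id for r in records])
    diagnosis = np.array([r.diagnosis for r in records])
    edges_raw, site_params = inject_site_effects(
        edge_df.to_numpy(), list(site_ids), scfg
    )
    pd.DataFrame(edges_raw, index=edge_df.index, columns=edge_df.columns).to_csv(
        out / "edges_raw.csv", float_format="%.8g"
    )
    log.info("connectome: %d edges per subject", edge_df.shape[1])

    results["stage"] = "harmonize"
    covariates = design_from_records(records)
    controls = diagnosis == "control"
    scan_group = controls if controls.sum() >= 4 else np.ones(len(records), bool)

    def _scan(edges):
        try:
            return site_effect_scan(
                edges[scan_group],
                site_ids[scan_group],
                q=cfg["topology"]["q"],
                group="control",
            ).summary()
        except AnalysisError as exc:
            log.info("site-effect scan skipped: %s", exc)
            return None

    pre = _scan(edges_raw)
    harm_cfg = cfg["harmonize"]
    if harm_cfg["enabled"] and not harm_cfg["within_folds"]:
        edges_model = CombatHarmonizer().fit_transform(
            edges_raw, sites=site_ids, covariates=covariates
        )
        scan = {"pre": pre, "post": _scan(edges_model)}
    else:
        edges_model = edges_raw
        scan = {"pre": pre}
    with open(out / "site_scan.json", "w") as fhj:
        json.dump(scan, fhj, indent=2, sort_keys=True)
    results["site_scan"] = scan
    log.info("harmonize: %s", scan)

    results["stage"] = "graphs"
    n_regions = scfg.n_regions
    z_stack = np.stack([devectorize_upper(e, n_regions) for e in edges_model])
    gk = cfg["graph"]

    results["stage"] = "model_cv"
    cvc = cfg["cv"]
    scheme = CVScheme(
        kind=cvc["kind"],
        n_folds=cvc.get("n_folds", 10),
        n_repeats=cvc.get("n_repeats", 1),
        seed=seed,
    )
    model_kind = cfg["model"]
    harm_state = "after" if harm_cfg["enabled"] else "before"

    def make_gcn(fold_seed):
        return GCNClassifier(
            k=gk["k"], weighting=gk["weighting"], seed=fold_seed, **cfg["gcn"]
        )

    def make_svm(fold_seed):
        return NestedLinearSVM(seed=fold_seed, **cfg["svm"])

    if harm_cfg["enabled"] and harm_cfg["within_folds"]:
        maker = make_gcn if model_kind == "gcn" else make_svm
        X_cv = np.arange(len(records))

        def make_model(fold_seed):
            return _FoldwiseHarmonizedModel(
                edges_raw,
                site_ids,
                covariates,
                n_regions,
                lambda: maker(fold_seed),
            )

    else:
        X_cv = z_stack if model_kind == "gcn" else edges_model
        make_model = make_gcn if model_kind == "gcn" else make_svm

    report: CVReport = cross_validate(
        make_model,
        X_cv,
        diagnosis,
        scheme,
        site_ids=site_ids,
        model_kind=model_kind,
        harmonization=harm_state,
    )
    report.to_csv(out / f"cv_report_{model_kind}.csv")
    report.to_json(out / f"cv_report_{model_kind}.json")
    results["cv_report"] = report
    log.info("model_cv: %s", report.summary["balanced_accuracy"])

    results["stage"] = "saliency"
    top_k = cfg["saliency"]["top_k"]
    if model_kind == "gcn":
        final = make_gcn(seed)
        final.fit(z_stack, diagnosis)
        cam = final.cam_scores(z_stack, target_class="patient")
        saliency = aggregate_saliency(
            cam, top_k=top_k, region_labels=scfg.region_labels
        )
        saliency.to_frame().to_csv(
            out / "saliency_gcn.csv", index=False, float_format="%.6f"
        )
        top_regions = saliency.top_regions.tolist()
        results["saliency"] = saliency
    else:
        final = make_svm(seed)
        final.fit(edges_model, diagnosis)
        rw = region_weights(
            final.coef_, n_regions, top_k=top_k, region_labels=scfg.region_labels
        )
        rw.to_csv(out / "saliency_svm.csv", index=False, float_format="%.6f")
        top_regions = rw["region_index"].to_numpy()[:top_k].tolist()
        results["saliency"] = rw
    results["top_regions"] = top_regions
    log.info("saliency: top regions %s", top_regions)

    results["stage"] = "topology"
    tcfg = cfg["topology"]
    metrics = cohort_nodal_metrics(
        list(z_stack),
        subjects["subject_id"].tolist(),
        sparsity=tcfg["sparsity"],
        regions=top_regions,
        region_labels=scfg.region_labels,
    )
    metrics.to_csv(out / "nodal_metrics.csv", index=False, float_format="%.8g")
    wide = metrics.pivot_table(
        index="subject_id", columns=["region_index", "metric"], values="value",
        sort=False,
    ).reindex(subjects["subject_id"])
    names = [f"region_{r:03d}:{m}" for r, m in wide.columns]
    tests = permutation_group_test(
        wide.to_numpy(),
        diagnosis,
        n_perm=tcfg["n_perm"],
        seed=seed,
        q=tcfg["q"],
        names=names,
    )
    tests.to_csv(out / "topology_tests.csv", index=False, float_format="%.8g")
    results["topology_tests"] = tests

    results["stage"] = "clinical"
    pat = diagnosis == "patient"
    corr = None
    if pat.sum() >= 4:
        frames = []
        for dim in ("symptom_negative", "symptom_positive"):
            raw = subjects.loc[pat, dim].to_numpy(dtype=float)
            ok = np.isfinite(raw)
            scores = np.full(raw.size, np.nan)
            if ok.any():
                scores[ok] = pomp(
                    raw[ok],
                    float(subjects.loc[pat, "scale_min"].iloc[0]),
                    float(subjects.loc[pat, "scale_max"].iloc[0]),
                )
            sub = correlate_symptoms(
                wide.to_numpy()[pat],
                scores,
                q=tcfg["q"],
                names=[f"{n}:{dim}" for n in names],
            )
            frames.append(sub)
        corr = pd.concat(frames, ignore_index=True)
        # FDR over the full regions x metrics x symptom-dimension family
        corr["fdr_significant"] = bh_fdr(corr["p"].to_numpy(), tcfg["q"])
        corr.to_csv(out / "symptom_correlations.csv", index=False, float_format="%.8g")
    results["symptom_correlations"] = corr

    results["stage"] = "manifest"
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "n_subjects": len(records),
        "n_regions": n_regions,
        "model": model_kind,
        "harmonization": harm_state,
    }
    with open(out / "manifest.json", "w") as fhj:
        json.dump(manifest, fhj, indent=2, sort_keys=True)
    results["manifest"] = manifest
    results["stage"] = "done"
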