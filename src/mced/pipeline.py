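"""End-to-end orchestration: QC -> split -> marker discovery (train only) ->
featurization -> single-feature training -> ensemble training -> prediction ->
evaluation, with artifact writing, a provenance manifest and a train/test
leakage audit."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import classifiers, copynumber, ensemble, fragmentome, methylome
from .io import Manifest, audit_no_leakage, qc_gate, read_bed
from .simcohort import CANCER_TYPES, TISSUE_TYPES, SimConfig, simulate_cohort, simulate_tissue_panel

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    # methylome
    min_cov: float = 3.0
    coverage_agg: str = "mean"
    pct: float = 10.0
    beta_cut: float = 0.5
    min_cpg: int = 3
    fdr: float = 0.05
    blacklist_path: str | None = None
    max_fallback_regions: int = 200
    # copy number
    alpha_pct: float = 5.0
    beta_pct: float = 20.0
    k_sigma: float = 2.0
    include_losses: bool = True
    # fragmentome
    fsd_lo: int = 80
    fsd_hi: int = 220
    fsd_width: int = 5
    # classifiers
    candidates: tuple = classifiers.DEFAULT_CANDIDATES
    folds: int = 4
    # ensemble
    target_specificity: float = 0.95
    too_delta: float = 0.07
    logit_eps: float = 1e-6
    uniform_too_weights: bool = False
    healthy_min_age: float = 50.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        cfg = cls(sim=sim, **d)
        if isinstance(cfg.candidates, list):
            cfg.candidates = tuple(cfg.candidates)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidates"] = list(self.candidates)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(raw)
    if cfg.blacklist_path and not Path(cfg.blacklist_path).exists():
        raise FileNotFoundError(f"blacklist file not found: {cfg.blacklist_path}")
    return cfg


@dataclass
class PipelineResult:
    sheet: pd.DataFrame
    truth: object
    regions: list
    amf: pd.DataFrame
    csd_markers: pd.DataFrame
    too_markers: pd.DataFrame
    marker_fallback: bool
    cnv_ratios: object
    cnv_calls: pd.DataFrame
    cnv_markers: object
    cnv_scores: pd.Series
    frag_features: dict
    bundles: dict
    feature_scores: pd.DataFrame  # all samples x (amf, cnv, fsr, fsd)
    too_weights: dict
    model: ensemble.EnsembleModel
    predictions: pd.DataFrame
    metrics: pd.DataFrame
    training_provenance: dict


def _train_ids(sheet: pd.DataFrame, label=None, min_age: float | None = None) -> list[str]:
    m = sheet["split"] == "train"
    if label is not None:
        m &= sheet["label"] == label if isinstance(label, str) else sheet["label"].isin(label)
    if min_age is not None:
        m &= sheet["age"] >= min_age
    return sheet.loc[m, "sample_id"].tolist()


def build_markers(cpg, sheet, tissue_sheet, tissue_cpg, cfg: PipelineConfig):
    """Marker discovery on the training split.

    Per cancer type: cfDNA (train cancer vs train healthy) markers, filtered
    for directional concordance with tumor-vs-adjacent tissue markers where
    matched tissue exists. CSD markers are the union over types; TOO markers
    come from one-vs-rest (type vs other cancers) comparisons.
    """
    healthy_train = _train_ids(sheet, "healthy")
    blacklist = read_bed(cfg.blacklist_path) if cfg.blacklist_path else None
    filtered = methylome.filter_sites(cpg, healthy_train, cfg.min_cov, blacklist,
                                      coverage_agg=cfg.coverage_agg)
    status = methylome.classify_cpg_status(filtered, healthy_train, cfg.pct, cfg.beta_cut)
    regions = methylome.build_regions(status, filtered.sites, cfg.min_cpg)
    amf = methylome.compute_amf(filtered, regions)

    tissue_amf = None
    if tissue_cpg is not None:
        # tissue shares the cohort site grid; apply the same filtering mask
        key = set(zip(filtered.sites["chrom"], filtered.sites["pos0"]))
        mask = [(c, p) in key for c, p in zip(tissue_cpg.sites["chrom"], tissue_cpg.sites["pos0"])]
        tissue_amf = methylome.compute_amf(tissue_cpg.subset_sites(np.asarray(mask)), regions)

    csd_parts, too_parts = [], []
    for ctype in CANCER_TYPES:
        cancer_train = _train_ids(sheet, ctype)
        cfdna, _ = methylome.select_dmrs(
            amf, cancer_train, healthy_train, cfg.fdr,
            comparison="cfdna-cancer-vs-healthy", target=ctype)
        if tissue_amf is not None and ctype in TISSUE_TYPES:
            tum = tissue_sheet.query("target == @ctype and role == 'tumor'")["sample_id"].tolist()
            adj = tissue_sheet.query("target == @ctype and role == 'adjacent_normal'")["sample_id"].tolist()
            tissue, _ = methylome.select_dmrs(
                tissue_amf, tum, adj, cfg.fdr,
                comparison="tumor-vs-adjacent", target=ctype)
            final = methylome.concordance_filter(tissue, cfdna)
            final["concordance_checked"] = True
        else:
            final = cfdna.copy()
            final["concordance_checked"] = False
        csd_parts.append(final)

        others = _train_ids(sheet, [t for t in CANCER_TYPES if t != ctype])
        ovr, _ = methylome.select_dmrs(
            amf, cancer_train, others, cfg.fdr,
            comparison="cancer-vs-other-cancers", target=ctype)
        too_parts.append(ovr)

    csd_markers = pd.concat(csd_parts, ignore_index=True)
    too_markers = pd.concat(too_parts, ignore_index=True)
    return filtered, regions, amf, csd_markers, too_markers, healthy_train


def _amf_feature_columns(amf, csd_markers, too_markers, sheet, cfg: PipelineConfig):
    """Marker-region AMF columns; falls back to the highest-variance regions
    on the training split when no marker survives (null cohorts)."""
    cols = sorted(set(csd_markers["region_id"]) | set(too_markers["region_id"]))
    if cols:
        return cols, False
    train = amf.loc[_train_ids(sheet)]
    var = train.var(axis=0, skipna=True).sort_values(ascending=False)
    return list(var.index[:cfg.max_fallback_regions]), True


def _impute_train_mean(features: pd.DataFrame, train_ids: list[str]) -> pd.DataFrame:
    means = features.loc[features.index.intersection(train_ids)].mean(axis=0)
    return features.fillna(means).fillna(0.0)


def _oof_cnv_rescore(cnv_scores, bins, labels, healthy_train, train_all,
                     cfg: PipelineConfig, folds: int = 4) -> pd.Series:
    """Rescore training-healthy samples with reference statistics and markers
    built without them (fold-wise), mirroring classifier stacking."""
    healthy_train = list(healthy_train)
    if len(healthy_train) < folds + 3:
        return cnv_scores
    out = cnv_scores.copy()
    fold_of = np.arange(len(healthy_train)) % folds
    for k in range(folds):
        held = [s for s, f in zip(healthy_train, fold_of) if f == k]
        ref = [s for s in healthy_train if s not in held]
        marker_train = [s for s in train_all if s not in held]
        ratios = copynumber.normalize_bins(bins, ref)
        calls = copynumber.call_alterations(ratios, cfg.k_sigma)
        markers = copynumber.select_cnv_markers(
            calls.loc[marker_train], labels, cfg.alpha_pct, cfg.beta_pct,
            cfg.include_losses, cfg.k_sigma)
        if len(markers) > 0:
            out.loc[held] = copynumber.cnv_csd_scores(calls.loc[held], markers)
        else:
            out.loc[held] = (calls.loc[held] != 0).mean(axis=1)
    return out


def run_pipeline(cfg: PipelineConfig, outdir=None, inputs=None) -> PipelineResult:
    """Run every stage on a simulated (default) or caller-provided cohort.

    ``inputs``, when given, is a dict with keys ``sheet``, ``cpg``, ``bins``,
    ``frags`` and optionally ``truth``, ``tissue_sheet``, ``tissue_cpg``.
    """
    manifest = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = Manifest(outdir, seed=cfg.seed, config=cfg.to_dict())

    # ---- stage 1: cohort -------------------------------------------------
    if inputs is None:
        sheet, cpg, bins, frags, truth = simulate_cohort(cfg.sim)
        tissue_sheet, tissue_cpg = simulate_tissue_panel(cfg.sim, truth)
    else:
        sheet, cpg, bins, frags = (inputs["sheet"], inputs["cpg"],
                                   inputs["bins"], inputs["frags"])
        truth = inputs.get("truth")
        tissue_sheet = inputs.get("tissue_sheet")
        tissue_cpg = inputs.get("tissue_cpg")
    if outdir is not None:
        sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        cpg.to_tsv(outdir / "cpg_counts.tsv")
        bins.rename_axis("sample_id").to_csv(outdir / "bin_counts.tsv", sep="\t")
        frags.to_tsv(outdir / "fragment_hists.tsv")
        if truth is not None:
            truth.to_json(outdir / "ground_truth.json")
        if tissue_sheet is not None:
            tissue_sheet.to_csv(outdir / "tissue_sheet.tsv", sep="\t", index=False)
            tissue_cpg.to_tsv(outdir / "tissue_counts.tsv")
        manifest.record_stage("cohort", ["sample_sheet.tsv", "cpg_counts.tsv",
                                         "bin_counts.tsv", "fragment_hists.tsv"],
                              n_samples=len(sheet))

    # ---- stage 2: QC gate ------------------------------------------------
    qc_cols = ["mapping_rate", "duplication_rate", "conversion_efficiency"]
    if all(c in sheet.columns for c in qc_cols):
        qc = qc_gate(sheet[["sample_id"] + qc_cols])
        passed = set(qc.loc[qc["qc_pass"], "sample_id"])
        sheet = sheet[sheet["sample_id"].isin(passed)].reset_index(drop=True)
        ids = sheet["sample_id"].tolist()
        cpg = cpg.subset_samples(ids)
        bins = bins.loc[ids]
        keep = [frags.samples.index(s) for s in ids]
        frags = fragmentome.FragmentHistogramSet(
            frags.counts[keep], frags.lengths, ids, frags.windows)
        if outdir is not None:
            qc.to_csv(outdir / "qc_gate.tsv", sep="\t", index=False)
            manifest.record_stage("qc", ["qc_gate.tsv"], n_pass=len(passed))

    if "split" not in sheet.columns:
        raise ValueError("sample sheet must carry a split column before modeling")
    train_all = _train_ids(sheet)
    sheet_idx = sheet.set_index("sample_id")

    # ---- stage 3: methylation markers (train only) -----------------------
    filtered, regions, amf, csd_markers, too_markers, healthy_train = build_markers(
        cpg, sheet, tissue_sheet, tissue_cpg, cfg)
    amf_cols, marker_fallback = _amf_feature_columns(amf, csd_markers, too_markers, sheet, cfg)
    amf_features = _impute_train_mean(amf[amf_cols], train_all)
    if outdir is not None:
        with open(outdir / "regions.bed", "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t+\n")
        amf.to_csv(outdir / "amf_matrix.tsv", sep="\t")
        amf_features.rename_axis("sample_id").to_csv(outdir / "features_amf.tsv", sep="\t")
        csd_markers.to_csv(outdir / "markers_csd.tsv", sep="\t", index=False)
        too_markers.to_csv(outdir / "markers_too.tsv", sep="\t", index=False)
        manifest.record_stage("markers", ["regions.bed", "amf_matrix.tsv",
                                          "markers_csd.tsv", "markers_too.tsv"],
                              n_regions=len(regions), n_csd=len(csd_markers),
                              n_too=len(too_markers), fallback=marker_fallback)

    # ---- stage 4: CNV features (reference from train healthy) ------------
    cnv_ratios = copynumber.normalize_bins(bins, healthy_train)
    cnv_calls = copynumber.call_alterations(cnv_ratios, cfg.k_sigma)
    labels_series = sheet_idx["label"]
    train_calls = cnv_calls.loc[train_all]
    cnv_markers = copynumber.select_cnv_markers(
        train_calls, labels_series, cfg.alpha_pct, cfg.beta_pct,
        cfg.include_losses, cfg.k_sigma)
    if len(cnv_markers) > 0:
        cnv_scores = copynumber.cnv_csd_scores(cnv_calls, cnv_markers)
        cnv_fallback = False
    else:
        # null cohorts: no prevalence-rule marker survives; fall back to the
        # overall alteration fraction so the ensemble still has a CNV score
        cnv_scores = (cnv_calls != 0).mean(axis=1)
        cnv_fallback = True
    # training healthy are inside both the reference panel and the marker
    # healthy-frequency rule, which biases their scores low and would place
    # the calibrated threshold too low; rescore them out-of-fold
    cnv_scores = _oof_cnv_rescore(cnv_scores, bins, labels_series, healthy_train,
                                  train_all, cfg)
    if outdir is not None:
        cnv_ratios.ratios.rename_axis("sample_id").to_csv(outdir / "copy_ratios.tsv", sep="\t")
        cnv_calls.rename_axis("sample_id").to_csv(outdir / "features_cnv.tsv", sep="\t")
        cnv_markers.markers.to_csv(outdir / "cnv_markers.tsv", sep="\t", index=False)
        cnv_scores.rename("cnv_csd_score").rename_axis("sample_id").to_csv(
            outdir / "cnv_scores.tsv", sep="\t")
        manifest.record_stage("cnv", ["copy_ratios.tsv", "cnv_markers.tsv", "cnv_scores.tsv"],
                              n_markers=len(cnv_markers), fallback=cnv_fallback)

    # ---- stage 5: fragment features (standardized on train) --------------
    fsr_raw = fragmentome.compute_fsr(frags)
    fsd_raw = fragmentome.compute_fsd(frags, cfg.fsd_lo, cfg.fsd_hi, cfg.fsd_width)
    fsr_raw = _impute_train_mean(fsr_raw, train_all)
    frag_features, scalers = {}, {}
    for name, raw in [("fsr", fsr_raw), ("fsd", fsd_raw)]:
        scaled, scaler = fragmentome.standardize(raw.loc[train_all], raw)
        frag_features[name] = scaled
        scalers[name] = scaler
    if outdir is not None:
        for name in ("fsr", "fsd"):
            frag_features[name].rename_axis("sample_id").to_csv(
                outdir / f"features_{name}.tsv", sep="\t")
        manifest.record_stage("fragments", ["features_fsr.tsv", "features_fsd.tsv"])

    # ---- stage 6: single-feature nine-class models -----------------------
    # classifier training uses train cancers plus train healthy aged >= 50
    clf_train = (_train_ids(sheet, "healthy", min_age=cfg.healthy_min_age)
                 + _train_ids(sheet, list(CANCER_TYPES)))
    cnv_call_features = pd.DataFrame(
        cnv_calls.to_numpy(dtype=float), index=cnv_calls.index,
        columns=[f"cnv:{c}" for c in cnv_calls.columns])
    namespaces = {
        "amf": amf_features,
        "cnv": cnv_call_features,
        "fsr": frag_features["fsr"],
        "fsd": frag_features["fsd"],
    }
    bundles, oof = {}, {}
    y_train = sheet_idx.loc[clf_train, "label"]
    for ns, feats in namespaces.items():
        bundle = classifiers.select_best_model(
            feats.loc[clf_train], y_train, cfg.candidates, cfg.folds,
            seed=cfg.seed, namespace=ns)
        bundles[ns] = bundle
        oof[ns] = classifiers.oof_proba(bundle, feats.loc[clf_train], y_train)
    if outdir is not None:
        (outdir / "models").mkdir(exist_ok=True)
        meta = {}
        for ns, b in bundles.items():
            joblib.dump(b.model, outdir / "models" / f"{ns}.joblib")
            meta[ns] = {"algorithm": b.algorithm, "mean_auc": b.mean_auc,
                        "candidate_aucs": b.candidate_aucs}
        pd.DataFrame(meta).T.rename_axis("namespace").to_csv(
            outdir / "models" / "selection.tsv", sep="\t")
        manifest.record_stage("train", ["models/selection.tsv"],
                              chosen={ns: b.algorithm for ns, b in bundles.items()})

    # ---- stage 7: per-sample feature scores ------------------------------
    # train rows use out-of-fold probabilities (stacking without leakage);
    # the CNV CSD score is marker-frequency based, not a classifier output
    all_ids = sheet["sample_id"].tolist()
    scores = pd.DataFrame(index=all_ids, columns=list(ensemble.FEATURES), dtype=float)
    cond_test: dict[str, pd.DataFrame] = {}
    test_ids = sheet.loc[sheet["split"] == "test", "sample_id"].tolist()
    for ns in ("amf", "fsr", "fsd", "cnv"):
        feats = namespaces[ns]
        proba_test = classifiers.predict_proba(bundles[ns], feats.loc[test_ids])
        if ns == "cnv":
            scores.loc[:, "cnv"] = cnv_scores.reindex(all_ids)
        else:
            scores.loc[clf_train, ns] = classifiers.feature_csd_score(oof[ns])
            scores.loc[test_ids, ns] = classifiers.feature_csd_score(proba_test)
            rest = [s for s in all_ids if s not in set(clf_train) | set(test_ids)]
            if rest:
                proba_rest = classifiers.predict_proba(bundles[ns], feats.loc[rest])
                scores.loc[rest, ns] = classifiers.feature_csd_score(proba_rest)
        cond_test[ns], _ = classifiers.conditional_too_proba(proba_test)

    # ---- stage 8: TOO weights from out-of-fold top-1 accuracy ------------
    cancer_train = [s for s in clf_train if sheet_idx.loc[s, "label"] != "healthy"]
    if cfg.uniform_too_weights:
        too_weights = {f: 0.25 for f in ensemble.FEATURES}
    else:
        accs = {}
        for ns in ensemble.FEATURES:
            cond, _ = classifiers.conditional_too_proba(oof[ns].loc[cancer_train])
            top1 = cond.idxmax(axis=1)
            accs[ns] = float((top1 == sheet_idx.loc[cancer_train, "label"]).mean())
        total = sum(accs.values())
        too_weights = ({k: v / total for k, v in accs.items()} if total > 0
                       else {f: 0.25 for f in ensemble.FEATURES})

    if outdir is not None:
        scores.rename_axis("sample_id").to_csv(outdir / "feature_scores.tsv", sep="\t")
        for ns, cond in cond_test.items():
            cond.rename_axis("sample_id").to_csv(outdir / f"cond_test_{ns}.tsv", sep="\t")
        with open(outdir / "too_weights.json", "w") as fh:
            import json as _json
            _json.dump(too_weights, fh, indent=1)
        manifest.record_stage("featurize", ["features_amf.tsv", "features_cnv.tsv",
                                            "feature_scores.tsv", "too_weights.json"])

    # ---- stage 9: ensemble -----------------------------------------------
    ens_train = clf_train
    y_bin = (sheet_idx.loc[ens_train, "label"] != "healthy").astype(int)
    sex_num = (sheet_idx["sex"] == "M").astype(int)
    model = ensemble.fit_cse_csd(
        scores.loc[ens_train], sheet_idx.loc[ens_train, "age"], sex_num.loc[ens_train],
        y_bin, cfg.target_specificity, seed=cfg.seed, eps=cfg.logit_eps,
        too_weights=too_weights, delta=cfg.too_delta)

    score, call = ensemble.predict_csd(
        model, scores.loc[test_ids], sheet_idx.loc[test_ids, "age"], sex_num.loc[test_ids])
    too = ensemble.predict_too(too_weights, cond_test, cfg.too_delta)
    predictions = pd.DataFrame({"sample_id": test_ids}).set_index("sample_id")
    predictions["csd_score"] = score
    predictions["csd_call"] = call
    for ns in ensemble.FEATURES:
        predictions[f"score_{ns}"] = scores.loc[test_ids, ns]
    predictions = predictions.join(too)
    predictions = predictions.reset_index()

    metrics = ensemble.evaluate(predictions,
                                sheet[["sample_id", "label", "stage"]])

    provenance = {
        "markers": healthy_train + _train_ids(sheet, list(CANCER_TYPES)),
        "cnv_reference": cnv_ratios.reference_ids,
        "cnv_markers": list(train_calls.index),
        "scaler_fsr": train_all,
        "scaler_fsd": train_all,
        **{f"bundle_{ns}": b.training_ids for ns, b in bundles.items()},
        "ensemble": model.training_ids,
    }
    audit_no_leakage(provenance, sheet)

    if outdir is not None:
        model.to_json(outdir / "ensemble.json")
        predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        metrics.to_json(outdir / "metrics.json", orient="records", indent=1)
        manifest.record_stage("ensemble", ["ensemble.json"], too_weights=too_weights)
        manifest.record_stage("predict", ["predictions.tsv"])
        manifest.record_stage("evaluate", ["metrics.tsv", "metrics.json"])

    return PipelineResult(
        sheet=sheet, truth=truth, regions=regions, amf=amf,
        csd_markers=csd_markers, too_markers=too_markers, marker_fallback=marker_fallback,
        cnv_ratios=cnv_ratios, cnv_calls=cnv_calls, cnv_markers=cnv_markers,
        cnv_scores=cnv_scores, frag_features=frag_features, bundles=bundles,
        feature_scores=scores, too_weights=too_weights, model=model,
        predictions=predictions, metrics=metrics, training_provenance=provenance,
    )
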