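"""End-to-end orchestration: generate -> preprocess -> extract -> select -> classify.

The pipeline mirrors the published experimental flow: thermograms are decoded
to temperatures, floored at 18 °C, split into feet and angiosomes, and reduced
to the 188-feature vector; subjects with any null angiosome are dropped; the
table is SMOTE-balanced (whole-table, as published, or leakage-safe in-fold);
highly correlated features are pruned; four approaches rank the survivors;
their top-10 subsets — plus the min-rank consensus set and any fixed list —
feed standard and randomized-search-optimized RBF SVMs evaluated by stratified
5-fold CV. Everything is seeded through one root seed, so a rerun with the
same config reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import balance, features, preprocess, selection, synthetic

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("id", "image_path", "mask_path", "t_min", "t_max", "label")


@dataclass
class RunConfig:
    mode: str = "synthetic"                     # or "external-manifest"
    manifest_path: str | None = None
    out_dir: str = "thermofoot_run"
    seed: int = 0
    floor: float = 18.0
    heel_fraction: float = 0.30
    smote_placement: str = "pre"                # "pre" (as published), "fold", "off"
    smote_k: int = 5
    phantom: synthetic.PhantomConfig = field(default_factory=synthetic.PhantomConfig)
    selector: selection.SelectorConfig = field(default_factory=selection.SelectorConfig)
    svm: balance.SvmConfig = field(default_factory=balance.SvmConfig)
    feature_config: features.FeatureConfig = field(default_factory=features.FeatureConfig)
    fixed_feature_list: list[str] | None = None
    run_optimized_svm: bool = True


def load_external_manifest(path: str | Path) -> pd.DataFrame:
    """Validate and load a dataset manifest CSV.

    Required columns: id, image_path, mask_path, t_min, t_max, label.
    """
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    if len(manifest) == 0:
        raise ValueError(f"empty dataset: manifest {path} has no rows")
    for col in ("image_path", "mask_path"):
        for p in manifest[col]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return manifest


def _subject_records_from_manifest(manifest: pd.DataFrame):
    for _, row in manifest.iterrows():
        gray = np.asarray(Image.open(row["image_path"]).convert("L"))
        mask = np.asarray(Image.open(row["mask_path"]).convert("L")) > 0
        yield str(row["id"]), gray, mask, float(row["t_min"]), float(row["t_max"]), int(row["label"])


def _subject_records_from_phantoms(subjects: list[synthetic.PhantomSubject]):
    for s in subjects:
        yield s.subject_id, s.gray_image, s.foot_mask, s.t_range[0], s.t_range[1], s.label


def preprocess_subject(
    gray: np.ndarray,
    mask: np.ndarray,
    t_min: float,
    t_max: float,
    floor: float = 18.0,
    heel_fraction: float = 0.30,
) -> tuple[preprocess.TemperatureMap, preprocess.AngiosomeSet, preprocess.QCResult]:
    """Decode, floor, split feet, partition angiosomes and run QC for one subject."""
    tmap = preprocess.decode_temperature(gray, t_min, t_max, foot_mask=mask)
    tmap = preprocess.apply_floor(tmap, floor=floor)
    angios = preprocess.build_angiosome_set(mask, heel_fraction=heel_fraction)
    qc = preprocess.subject_qc(angios, tmap)
    return tmap, angios, qc


def extract_feature_table(records, config: RunConfig) -> tuple[pd.DataFrame, list[str]]:
    """Feature table over all QC-passing subjects; returns (table, dropped ids)."""
    registry = features.build_default_registry(config.feature_config.ntr_classes)
    kept, dropped = [], []
    for sid, gray, mask, t_min, t_max, label in records:
        try:
            tmap, angios, qc = preprocess_subject(
                gray, mask, t_min, t_max,
                floor=config.floor, heel_fraction=config.heel_fraction,
            )
        except preprocess.SingleFootError as err:
            logger.warning("subject %s unusable: %s", sid, err)
            dropped.append(sid)
            continue
        if not qc.keep:
            logger.info("subject %s dropped by QC: %s", sid, "; ".join(qc.reasons))
            dropped.append(sid)
            continue
        kept.append((sid, tmap, angios, label))
    if not kept:
        raise ValueError("no subject passed preprocessing and QC")
    table = features.extract_table(kept, registry=registry, config=config.feature_config)
    return table, dropped


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns the run manifest (stage-by-stage counts plus artifact paths).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: data
    if config.mode == "synthetic":
        phantom_cfg = config.phantom
        subjects, _ = synthetic.generate_phantom_dataset(phantom_cfg)
        records = _subject_records_from_phantoms(subjects)
        n_input = len(subjects)
    elif config.mode == "external-manifest":
        if not config.manifest_path:
            raise ValueError("external-manifest mode needs manifest_path")
        manifest = load_external_manifest(config.manifest_path)
        records = _subject_records_from_manifest(manifest)
        n_input = len(manifest)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # --- stage 2+3: preprocess, QC, features
    table, dropped = extract_feature_table(records, config)
    table.to_csv(out / "features.csv", index_label="id")
    y = table["label"].to_numpy()
    X = table.drop(columns="label")

    # --- stage 4: class balance (published placement: whole table, before CV)
    counts_before = dict(zip(*np.unique(y, return_counts=True)))
    if config.smote_placement == "pre":
        X, y = balance.smote(X, y, k_neighbors=config.smote_k, random_state=config.seed)
    counts_after = dict(zip(*np.unique(y, return_counts=True)))

    # --- stage 5: correlation pruning
    corr = selection.CorrelationFilter(threshold=config.selector.corr_threshold).fit(X)
    X_red = corr.transform(X)

    # --- stage 6: rank by the four approaches
    rankers = selection.make_rankers(config.selector)
    ranking_rows, rankings = [], {}
    for name, ranker in rankers.items():
        ranker.fit(X_red, y)
        rankings[name] = ranker.ranked_features_
        for rank, feat in enumerate(ranker.ranked_features_, start=1):
            j = list(X_red.columns).index(feat)
            ranking_rows.append({
                "approach": name, "feature": feat, "rank": rank,
                "mean_score": ranker.scores_[j],
                **{f"fold{k}_score": ranker.fold_scores_[k, j]
                   for k in range(ranker.fold_scores_.shape[0])},
            })
    pd.DataFrame(ranking_rows).to_csv(out / "rankings.csv", index=False)

    # --- stage 7: consensus
    cons = selection.consensus(rankings, cutoffs=config.selector.consensus_cutoffs)
    cons.table.to_csv(out / "consensus.csv", index=False)
    (out / "consensus.txt").write_text(selection.format_consensus_report(cons))

    # --- stage 8: SVM evaluation
    subsets: dict[str, list[str]] = {
        name: rankers[name].top_k(config.selector.top_k) for name in rankers
    }
    if len(cons.table):
        subsets["consensus"] = cons.table["feature"].head(config.selector.top_k).tolist()
    if config.fixed_feature_list:
        missing = [f for f in config.fixed_feature_list if f not in X_red.columns]
        usable = [f for f in config.fixed_feature_list if f in X_red.columns]
        if missing:
            logger.warning("fixed-list features not in pruned table: %s", missing)
        if usable:
            subsets["fixed_list"] = usable

    smote_in_fold = config.smote_placement == "fold"
    reports = []
    for name, subset in subsets.items():
        std_cfg = balance.SvmConfig(mode="standard", gamma=0.1, C=1.0, seed=config.seed)
        reports.append(balance.fit_eval_svm(
            X_red, y, feature_subset=subset, config=std_cfg, approach=name,
            smote_in_fold=smote_in_fold, smote_k=config.smote_k,
        ))
        if config.run_optimized_svm:
            search_base = balance.SvmConfig(
                mode="optimized", seed=config.seed,
                search_iterations=config.svm.search_iterations,
                gamma_range=config.svm.gamma_range, C_range=config.svm.C_range,
            )
            best = balance.randomized_search_svm(X_red, y, feature_subset=subset,
                                                 config=search_base)
            reports.append(balance.fit_eval_svm(
                X_red, y, feature_subset=subset, config=best, approach=name,
                smote_in_fold=smote_in_fold, smote_k=config.smote_k,
            ))
    eval_df = pd.DataFrame([r.to_row() for r in reports])
    eval_df.to_csv(out / "evaluation.csv", index=False)
    (out / "evaluation.txt").write_text(balance.format_report_table(reports))

    run_manifest = {
        "config": _config_dict(config),
        "counts": {
            "subjects_input": int(n_input),
            "subjects_dropped": len(dropped),
            "subjects_kept": int(len(table)),
            "features_extracted": int(X.shape[1]),
            "features_after_pruning": int(X_red.shape[1]),
            "class_counts_before_smote": {str(k): int(v) for k, v in counts_before.items()},
            "class_counts_after_smote": {str(k): int(v) for k, v in counts_after.items()},
        },
        "dropped_subjects": dropped,
        "artifacts": sorted({p.name for p in out.iterdir()} | {"run_manifest.json"}),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return run_manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))
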