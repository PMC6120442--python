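"""End-to-end orchestration: composite -> mask -> select -> train -> classify -> evaluate.

The pipeline mirrors the processing chain of an early-season crop-mapping
study: half-month composites are built from raw observations, sparse
composite columns are discarded, non-vegetation pixels are masked on the
seasonal NIR maximum, features are ranked by JM separability and
random-forest Gini importance, an IAIN antibody network is trained on the
complete-case training pixels of the selected features, validation pixels
(missing values allowed) are classified through sub-antibodies, and a
confusion matrix with OA / kappa / per-class PA & UA is reported.

A single run seed fans out to per-stage child seeds by a fixed derivation,
so each stage is individually reproducible.  Masked pixels carry the
reserved label code 0 ("masked"), unclassifiable pixels 255.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composites import FeatureCube, build_cube, drop_sparse_composites
from .evaluation import (
    class_accuracies,
    confusion,
    kappa,
    length_sweep,
    overall_accuracy,
    saturation_point,
    sweep_table,
)
from .feature_select import (
    FeatureSelectConfig,
    gini_importance,
    pairwise_jm,
    rank_and_select,
)
from .iain import IainConfig, classify_cube, train_cube
from .vegmask import MaskConfig, seasonal_max, apply_mask

logger = logging.getLogger("iainmap")

MASKED_LABEL = "masked"
UNCLASSIFIABLE_LABEL = "unclassifiable"
#: reserved integer codes for raster-style label outputs
LABEL_CODES = {MASKED_LABEL: 0, UNCLASSIFIABLE_LABEL: 255}


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage child seeds (< 2**31) from one run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


@dataclass
class RunConfig:
    """Everything a full run needs besides the data itself."""

    seed: int = 0
    max_missing_fraction: float = 0.5
    mask: MaskConfig = field(default_factory=MaskConfig)
    features: FeatureSelectConfig = field(
        default_factory=lambda: FeatureSelectConfig(ntree=300, top_k=10)
    )
    iain: IainConfig = field(default_factory=IainConfig)
    sweep: bool = False
    sweep_bands: tuple[str, ...] = ("NIR", "NDVI")
    saturation_level: float = 95.0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_bands"] = list(self.sweep_bands)
        return d


def default_feature_plan(
    cube: FeatureCube, bands: tuple[str, ...] = ("NIR", "NDVI")
) -> list[tuple[str, list[str]]]:
    """Cumulative per-period feature plan over the given bands.

    One sweep step per composite period present in the cube, gaining that
    period's features of the requested bands — the synthetic analogue of
    the 'gained features' tables of an early-season evaluation.
    """
    periods = sorted({per for _, per in cube.features})
    labels = set(cube.feature_labels())
    plan = []
    for per in periods:
        gained = [f"{b}_{per.label}" for b in bands if f"{b}_{per.label}" in labels]
        if gained:
            plan.append((per.label, gained))
    return plan


def run_pipeline(
    observations: pd.DataFrame,
    samples: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """Execute the full chain and return a JSON-serializable run report.

    ``observations`` is the long table (pixel_id, date, band, value[,
    valid]); ``samples`` holds pixel_id, label and role ("train" or
    "validation").  When ``config.out_dir`` is set, the model, label table,
    confusion matrix, sweep table and report are written there.
    """
    config = config or RunConfig()
    seeds = stage_seeds(config.seed, 4)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    required = {"pixel_id", "label", "role"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    bad_roles = set(samples["role"]) - {"train", "validation"}
    if bad_roles:
        raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
    if not (samples["role"] == "train").any():
        raise ValueError("stage=samples: no training samples provided")

    # -- stage 1: compositing -----------------------------------------
    try:
        cube = build_cube(observations)
        cube, dropped = drop_sparse_composites(cube, config.max_missing_fraction)
    except Exception as exc:
        raise RuntimeError(f"stage=composite failed: {exc}") from exc
    report["stages"]["composite"] = {
        "n_pixels": cube.n_pixels,
        "n_features": cube.n_features,
        "dropped_sparse": [f"{b}_{p.label}" for b, p in dropped],
    }
    logger.info("composited %d pixels x %d features", cube.n_pixels, cube.n_features)

    # -- stage 2: vegetation mask -------------------------------------
    try:
        veg = apply_mask(seasonal_max(cube, "NIR"), config.mask)
    except Exception as exc:
        raise RuntimeError(f"stage=vegmask failed: {exc}") from exc
    report["stages"]["vegmask"] = {
        "threshold": config.mask.threshold,
        "n_vegetation": int(veg.sum()),
        "n_masked": int((~veg).sum()),
    }

    pid_to_row = {pid: i for i, pid in enumerate(cube.pixel_ids)}
    train_tab = samples[samples["role"] == "train"]
    valid_tab = samples[samples["role"] == "validation"]
    train_rows = np.array([pid_to_row[p] for p in train_tab["pixel_id"]])
    train_rows_veg = train_rows[veg[train_rows]]
    train_labels = train_tab["label"].to_numpy(dtype=object)[veg[train_rows]]

    # -- stage 3: feature selection -----------------------------------
    try:
        fs = dataclasses.replace(config.features, seed=seeds[0])
        tr_cube = cube.select_pixels(train_rows_veg)
        X = np.where(tr_cube.missing, np.nan, tr_cube.values)
        names = tr_cube.feature_labels()
        jm = pairwise_jm(X, train_labels, feature_names=names, ridge=fs.ridge)
        gini = gini_importance(X, train_labels, config=fs, feature_names=names)
        selected = rank_and_select(jm, gini, config=fs)
        if fs.top_k is not None:
            selected = selected[: fs.top_k]
    except Exception as exc:
        raise RuntimeError(f"stage=feature_select failed: {exc}") from exc
    report["stages"]["feature_select"] = {
        "n_candidates": len(names),
        "selected": selected,
    }
    logger.info("selected %d/%d features", len(selected), len(names))
    if not selected:
        raise RuntimeError("stage=feature_select failed: no feature selected")

    sel_idx = [names.index(s) for s in selected]

    # -- stage 4: IAIN training ---------------------------------------
    try:
        icfg = dataclasses.replace(config.iain, seed=seeds[1])
        tr_sel = tr_cube.select_features(sel_idx)
        complete = ~tr_sel.missing.any(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            network = train_cube(tr_sel, train_labels, config=icfg)
    except Exception as exc:
        raise RuntimeError(f"stage=train failed: {exc}") from exc
    report["stages"]["train"] = {
        "n_train_pixels": int(len(train_labels)),
        "n_complete_used": int(complete.sum()),
        "n_rejected_incomplete": int((~complete).sum()),
        "n_antibodies": len(network.antibodies),
    }
    logger.info(
        "trained %d antibodies from %d complete pixels",
        len(network.antibodies),
        int(complete.sum()),
    )

    # -- stage 5: classification --------------------------------------
    try:
        full_sel = cube.select_features(
            [cube.feature_labels().index(s) for s in selected]
        )
        pred_all, bad = classify_cube(network, full_sel)
    except Exception as exc:
        raise RuntimeError(f"stage=classify failed: {exc}") from exc
    final = np.array(
        [
            MASKED_LABEL
            if not veg[i]
            else (UNCLASSIFIABLE_LABEL if bad[i] else pred_all[i])
            for i in range(cube.n_pixels)
        ],
        dtype=object,
    )
    report["stages"]["classify"] = {
        "n_classified": int((~bad & veg).sum()),
        "n_unclassifiable": int((bad & veg).sum()),
        "n_masked": int((~veg).sum()),
    }

    # -- stage 6: evaluation ------------------------------------------
    try:
        vrows = np.array([pid_to_row[p] for p in valid_tab["pixel_id"]])
        vlabels = valid_tab["label"].to_numpy(dtype=object)
        usable = veg[vrows] & ~bad[vrows]
        classes = sorted(set(network.classes_) | set(vlabels), key=str)
        cm = confusion(final[vrows[usable]], vlabels[usable], classes)
        metrics = {
            "oa": overall_accuracy(cm),
            "kappa": kappa(cm),
            "per_class": {
                c: dict(zip(("pa", "ua"), class_accuracies(cm, c))) for c in classes
            },
            "n_validation_used": int(usable.sum()),
            "n_validation_excluded": int((~usable).sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"stage=evaluate failed: {exc}") from exc
    report["metrics"] = metrics
    logger.info("validation OA %.2f%%, kappa %.4f", metrics["oa"], metrics["kappa"])

    # -- stage 7: optional length sweep -------------------------------
    sweep_results = None
    if config.sweep:
        try:
            plan = default_feature_plan(cube, config.sweep_bands)
            vrows_veg = vrows[veg[vrows]]
            sweep_results = length_sweep(
                cube.select_pixels(train_rows_veg),
                train_labels,
                cube.select_pixels(vrows_veg),
                vlabels[veg[vrows]],
                plan,
                config=dataclasses.replace(config.iain, seed=seeds[2]),
            )
        except Exception as exc:
            raise RuntimeError(f"stage=sweep failed: {exc}") from exc
        report["sweep"] = {
            "saturation": {
                c: saturation_point(sweep_results, c, config.saturation_level)
                for c in classes
            },
            "table": sweep_table(sweep_results).to_dict(orient="records"),
        }

    # -- outputs -------------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        network.save(out / "model.json")
        pd.DataFrame({"pixel_id": cube.pixel_ids, "label": final}).to_csv(
            out / "labels.csv", index=False
        )
        cm.to_frame().to_csv(out / "confusion_matrix.csv")
        if sweep_results is not None:
            sweep_table(sweep_results).to_csv(out / "sweep.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report
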