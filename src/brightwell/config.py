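"""Run configuration and the end-to-end pipeline.

One YAML config (and one seed) determines every stage: plate simulation,
augmentation, feature extraction, head training, prediction, per-series
IC50 fitting, and evaluation.  ``run_pipeline`` writes every intermediate
artifact plus a manifest recording the config hash, the seed, and a SHA-256
digest of each output file, so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentationPolicy
from .hill import DoseResponseParams, ic50_per_series, summarize_ic50
from .model import (
    TrainConfig,
    get_extractor,
    predict_viability,
    save_model,
    split_dataset,
    train_head,
)
from .evaluate import cross_evaluate, embed_features, series_from_predictions
from .simulate import (
    BUILTIN_PROFILES,
    CellLineProfile,
    NoiseSpec,
    PlateDesign,
    read_plate_csv,
    simulate_plate,
    write_plate_csv,
)

logger = logging.getLogger("brightwell")

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "run"
    cell_lines: tuple[str, ...] = ("lineA", "lineB", "lineC")
    design: PlateDesign = field(default_factory=PlateDesign)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    extractor: str = "tilestats16"
    train: TrainConfig = field(default_factory=TrainConfig)
    test_series: int = 6
    validation_fraction: float = 0.2
    profiles: dict[str, CellLineProfile] = field(
        default_factory=lambda: dict(BUILTIN_PROFILES)
    )


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(data: dict) -> RunConfig:
    import copy

    d = copy.deepcopy(data)
    profiles = {}
    for name, p in d.pop("profiles", {}).items():
        p = dict(p)
        dr = p.pop("dose_response")
        profiles[name] = CellLineProfile(
            dose_response=DoseResponseParams(**dr), **p
        )
    design = d.pop("design", {})
    if "concentrations_um" in design:
        design["concentrations_um"] = tuple(design["concentrations_um"])
    policy = d.pop("policy", {})
    for key in (
        "rotations", "brightness_delta_range", "saturation_factor_range",
        "contrast_factor_range", "hue_delta_range",
    ):
        if key in policy:
            policy[key] = tuple(policy[key])
    cfg = RunConfig(
        design=PlateDesign(**design),
        noise=NoiseSpec(**d.pop("noise", {})),
        policy=AugmentationPolicy(**policy),
        train=TrainConfig(**d.pop("train", {})),
        profiles=profiles or dict(BUILTIN_PROFILES),
        **{**d, "cell_lines": tuple(d.get("cell_lines", ("lineA", "lineB", "lineC")))},
    )
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute simulate -> split -> train -> predict -> IC50 -> evaluate.

    Per cell line: simulate a plate, hold out whole test series, train the
    head on augmented training views, predict on the test wells, and fit
    per-series IC50s.  With multiple lines, every model is additionally
    evaluated on every other line's test wells (the autologous/allogenic
    cross matrix).  Returns the artifact directory; all outputs are listed
    in ``manifest.json`` with SHA-256 digests.
    """
    if cfg.extractor not in _known_extractors():
        raise ValueError(f"unknown extractor {cfg.extractor!r}")
    for line in cfg.cell_lines:
        if line not in cfg.profiles:
            raise ValueError(f"no profile for cell line {line!r}")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    extractor = get_extractor(cfg.extractor)
    written: list[Path] = []

    save_config(cfg, out / "config.yaml")
    written.append(out / "config.yaml")

    records_by_line = {}
    splits = {}
    models = {}
    test_records = {}
    line_seed = {line: cfg.seed + 1000 * i for i, line in enumerate(cfg.cell_lines)}

    for line in cfg.cell_lines:
        logger.info("simulating plate for %s", line)
        recs = simulate_plate(
            cfg.profiles[line], cfg.design, out / "images" / line,
            seed=line_seed[line], noise=cfg.noise,
        )
        records_by_line[line] = recs
        plate_csv = out / f"plate_{line}.csv"
        write_plate_csv(recs, plate_csv)
        written.append(plate_csv)

        split = split_dataset(
            recs, test_series=cfg.test_series,
            validation_fraction=cfg.validation_fraction, seed=line_seed[line],
        )
        splits[line] = split
        index = {r.well_id: r for r in recs}
        test_records[line] = [index[i] for i in split.test_ids]

        logger.info("training head for %s", line)
        model = train_head(
            recs, split, extractor, cfg.policy,
            config=cfg.train, seed=line_seed[line],
        )
        models[line] = model
        model_path = out / f"model_{line}.npz"
        save_model(model, model_path)
        written.append(model_path)

    predictions_by_pair = {}
    for train_line in cfg.cell_lines:
        for eval_line in cfg.cell_lines:
            preds = predict_viability(
                models[train_line], test_records[eval_line], extractor
            )
            predictions_by_pair[(train_line, eval_line)] = preds
            pred_csv = out / f"predictions_{train_line}_on_{eval_line}.csv"
            preds.to_csv(pred_csv, index=False)
            written.append(pred_csv)

    # per-line IC50 tables from autologous predictions
    summary_rows = []
    for line in cfg.cell_lines:
        preds = predictions_by_pair[(line, line)]
        pred_tab = ic50_per_series(series_from_predictions(preds))
        meas_tab = ic50_per_series(
            series_from_predictions(
                preds, value_column="measured_viability", source="measured"
            )
        )
        ic50_csv = out / f"ic50_{line}.csv"
        merged = meas_tab.merge(pred_tab, on="series_id", suffixes=("_meas", "_pred"))
        merged.to_csv(ic50_csv, index=False)
        written.append(ic50_csv)
        s_pred = summarize_ic50(pred_tab)
        s_meas = summarize_ic50(meas_tab)
        summary_rows.append(
            {
                "cell_line": line,
                "true_ic50_um": cfg.profiles[line].dose_response.ic50,
                "ic50_meas_mean": s_meas["mean_ic50_um"],
                "ic50_meas_sd": s_meas["sd_ic50_um"],
                "ic50_pred_mean": s_pred["mean_ic50_um"],
                "ic50_pred_sd": s_pred["sd_ic50_um"],
            }
        )

    matrix = cross_evaluate(predictions_by_pair)
    report_rows = []
    for (t, e), entry in sorted(matrix.entries.items()):
        a = entry.agreement
        report_rows.append(
            {
                "train_line": t, "eval_line": e,
                "autologous": entry.autologous,
                "r_squared": a.r_squared, "slope": a.slope,
                "intercept": a.intercept,
                "mean_difference": a.mean_difference,
                "sd_difference": a.sd_difference, "n": a.n,
                "p_unpaired": entry.unpaired.p_value if entry.unpaired else np.nan,
                "p_paired": entry.paired.p_value if entry.paired else np.nan,
            }
        )
    report = pd.DataFrame(report_rows)
    report.to_csv(out / "evaluation_report.csv", index=False)
    written.append(out / "evaluation_report.csv")

    pd.DataFrame(summary_rows).to_csv(out / "ic50_summary.csv", index=False)
    written.append(out / "ic50_summary.csv")

    # t-SNE embedding of autologous test features, labeled by Hill region
    for line in cfg.cell_lines:
        preds = predictions_by_pair[(line, line)]
        feats = []
        from .augment import center_crop
        from .simulate import load_image

        for _, row in preds.iterrows():
            rec = next(r for r in test_records[line] if r.well_id == row["well_id"])
            img = center_crop(load_image(rec.image_path), cfg.policy.crop_fraction)
            feats.append(extractor(img))
        if len(feats) > 10:
            emb = embed_features(
                np.asarray(feats), preds["concentration_um"].to_numpy(),
                cfg.profiles[line].dose_response, seed=cfg.seed,
            )
            emb_df = pd.DataFrame(
                {
                    "well_id": preds["well_id"],
                    "tsne_1": emb.coordinates[:, 0],
                    "tsne_2": emb.coordinates[:, 1],
                    "region": emb.region_labels,
                }
            )
            emb_csv = out / f"embedding_{line}.csv"
            emb_df.to_csv(emb_csv, index=False)
            written.append(emb_csv)

    cfg_digest = hashlib.sha256(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "seed": cfg.seed,
        "config_sha256": cfg_digest,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out


def _known_extractors() -> set[str]:
    return {"tilestats8", "tilestats16", "tilestats32"}
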