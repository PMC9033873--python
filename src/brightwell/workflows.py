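"""Canned study workflows: autologous replication and cross-line matrix.

These wrap the full simulate -> split -> train -> predict -> IC50 chain into
the two experiment designs the package is built to replicate:

* :func:`autologous_study` -- one cell line, whole-series holdout, measuring
  measured-vs-predicted agreement and per-series IC50 recovery on the six
  held-out dose ladders.
* :func:`cross_study` -- several cell lines, every model evaluated on every
  line's test wells (autologous diagonal vs allogenic off-diagonals).

Images are rendered in memory by default: statistically identical to the
disk path (pixels are quantized to 8-bit either way) without the PNG I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy
from .evaluate import LinearAgreement, linear_agreement, series_from_predictions, t_test
from .hill import ic50_per_series
from .model import (
    FeatureExtractor,
    RegressionModel,
    TrainConfig,
    builtin_extractor,
    predict_viability,
    split_dataset,
    train_head,
)
from .simulate import (
    BUILTIN_PROFILES,
    CellLineProfile,
    NoiseSpec,
    PlateDesign,
    simulate_plate,
)

__all__ = ["AutologousResult", "autologous_study", "cross_study"]


@dataclass
class AutologousResult:
    """Test-set outcome of one autologous train/evaluate run."""

    agreement: LinearAgreement
    ic50_measured: pd.DataFrame
    ic50_predicted: pd.DataFrame
    p_unpaired: float
    p_paired: float
    predictions: pd.DataFrame
    model: RegressionModel
    true_ic50_um: float


def _run_line(
    profile: CellLineProfile,
    design: PlateDesign,
    seed: int,
    extractor: FeatureExtractor,
    policy: AugmentationPolicy,
    train_cfg: TrainConfig,
    test_series: int,
    validation_fraction: float,
    noise: NoiseSpec,
):
    store: dict = {}
    records = simulate_plate(
        profile, design, "unwritten", seed=seed, noise=noise,
        write_images=False, image_store=store,
    )
    split = split_dataset(
        records, test_series=test_series,
        validation_fraction=validation_fraction, seed=seed,
    )
    model = train_head(
        records, split, extractor, policy,
        config=train_cfg, seed=seed, images=store,
    )
    index = {r.well_id: r for r in records}
    test_records = [index[i] for i in split.test_ids]
    return model, test_records, store


def autologous_study(
    line: str = "lineA",
    seed: int = 0,
    design: PlateDesign | None = None,
    extractor: FeatureExtractor | None = None,
    policy: AugmentationPolicy | None = None,
    train_cfg: TrainConfig | None = None,
    test_series: int = 6,
    validation_fraction: float = 0.2,
    noise: NoiseSpec | None = None,
) -> AutologousResult:
    """Simulate one line, train its model, evaluate on six held-out series.

    Returns the measured-vs-predicted linear agreement over the test wells
    plus per-series IC50 tables for measured labels and predictions, and the
    unpaired/paired Student t-test p-values between the two IC50 samples.
    """
    design = design or PlateDesign()
    extractor = extractor or builtin_extractor()
    policy = policy or AugmentationPolicy()
    train_cfg = train_cfg or TrainConfig()
    noise = noise or NoiseSpec()
    profile = BUILTIN_PROFILES[line]

    model, test_records, store = _run_line(
        profile, design, seed, extractor, policy, train_cfg,
        test_series, validation_fraction, noise,
    )
    preds = predict_viability(model, test_records, extractor, images=store)
    agreement = linear_agreement(
        preds["measured_viability"].to_numpy(),
        preds["predicted_viability"].to_numpy(),
    )
    tab_meas = ic50_per_series(
        series_from_predictions(preds, value_column="measured_viability",
                                source="measured")
    )
    tab_pred = ic50_per_series(series_from_predictions(preds))
    ok_m = tab_meas[tab_meas["converged"]]["ic50_um"]
    ok_p = tab_pred[tab_pred["converged"]]["ic50_um"]
    p_unpaired = p_paired = float("nan")
    if len(ok_m) >= 2 and len(ok_p) >= 2:
        p_unpaired = t_test(ok_m, ok_p, paired=False).p_value
        if len(ok_m) == len(ok_p):
            merged = tab_meas.merge(tab_pred, on="series_id",
                                    suffixes=("_m", "_p"))
            both = merged[merged["converged_m"] & merged["converged_p"]]
            if len(both) >= 2:
                p_paired = t_test(both["ic50_um_m"], both["ic50_um_p"],
                                  paired=True).p_value
    return AutologousResult(
        agreement=agreement,
        ic50_measured=tab_meas,
        ic50_predicted=tab_pred,
        p_unpaired=p_unpaired,
        p_paired=p_paired,
        predictions=preds,
        model=model,
        true_ic50_um=profile.dose_response.ic50,
    )


def cross_study(
    lines: tuple[str, ...] = ("lineA", "lineB", "lineC"),
    seed: int = 0,
    design: PlateDesign | None = None,
    extractor: FeatureExtractor | None = None,
    policy: AugmentationPolicy | None = None,
    train_cfg: TrainConfig | None = None,
    test_series: int = 6,
    validation_fraction: float = 0.2,
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Train one model per line; evaluate every model on every line.

    Returns the r² matrix as a DataFrame indexed by training line with one
    column per evaluated line.  Per-line seeds are derived from ``seed`` so
    plates are independent across lines.
    """
    design = design or PlateDesign()
    extractor = extractor or builtin_extractor()
    policy = policy or AugmentationPolicy()
    train_cfg = train_cfg or TrainConfig()
    noise = noise or NoiseSpec()

    models, tests, stores = {}, {}, {}
    for i, line in enumerate(lines):
        line_seed = seed + 1000 * i
        model, test_records, store = _run_line(
            BUILTIN_PROFILES[line], design, line_seed, extractor, policy,
            train_cfg, test_series, validation_fraction, noise,
        )
        models[line] = model
        tests[line] = test_records
        stores[line] = store

    r2 = pd.DataFrame(index=list(lines), columns=list(lines), dtype=float)
    for t in lines:
        for e in lines:
            preds = predict_viability(models[t], tests[e], extractor,
                                      images=stores[e])
            r2.loc[t, e] = linear_agreement(
                preds["measured_viability"].to_numpy(),
                preds["predicted_viability"].to_numpy(),
            ).r_squared
    return r2
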