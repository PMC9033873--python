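"""Agreement statistics, t-tests, cross-line evaluation, and t-SNE embedding.

Covers the standard evaluation battery for measured-vs-predicted viability:
ordinary least-squares agreement (r², slope, intercept, mean ± SD of the
differences), paired and unpaired Student t-tests on IC50 distributions, an
autologous/allogenic cross matrix (each line's model evaluated on every
line's test wells), and a 2D t-SNE embedding of feature vectors labeled by
Hill-curve region (top plateau / slope / bottom plateau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hill import DoseResponseParams, HillFitResult, SeriesResponse, fit_hill, hill_response

__all__ = [
    "LinearAgreement",
    "TTestResult",
    "CrossMatrix",
    "EmbeddingResult",
    "linear_agreement",
    "t_test",
    "cross_evaluate",
    "embed_features",
    "series_from_predictions",
    "hill_region_labels",
]


@dataclass(frozen=True)
class LinearAgreement:
    """OLS of predicted on measured: the Table-1-style statistics."""

    r_squared: float
    slope: float
    intercept: float
    mean_difference: float  # predicted - measured
    sd_difference: float
    n: int
    degenerate: bool = False  # zero variance in measured


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    df: float
    paired: bool
    zero_variance: bool = False


def linear_agreement(measured: Sequence[float], predicted: Sequence[float]) -> LinearAgreement:
    """Least-squares line predicted = slope * measured + intercept, plus r².

    r² is the squared Pearson correlation; differences are predicted -
    measured.  Zero variance in the measured values leaves the slope
    undefined and flags the result instead of fabricating numbers.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and predicted must be equal-length 1-D")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    diff = y - x
    n = len(x)
    if np.var(x) == 0:
        return LinearAgreement(
            r_squared=math.nan, slope=math.nan, intercept=math.nan,
            mean_difference=float(diff.mean()),
            sd_difference=float(diff.std(ddof=1)), n=n, degenerate=True,
        )
    res = stats.linregress(x, y)
    return LinearAgreement(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        mean_difference=float(diff.mean()),
        sd_difference=float(diff.std(ddof=1)),
        n=n,
    )


def t_test(
    a: Sequence[float], b: Sequence[float], paired: bool = False,
    equal_var: bool = True,
) -> TTestResult:
    """Two-tailed Student t-test between two samples.

    Unpaired uses the pooled equal-variance form by default (``equal_var
    =False`` switches to Welch); paired tests the differences.  Zero
    variance (identical differences, or both groups constant) flags the
    result with an undefined p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired test requires equal lengths")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")

    if paired:
        d = a - b
        if np.var(d, ddof=1) == 0:
            if np.all(d == 0):  # a == b exactly: t = 0, p = 1 is well-defined
                return TTestResult(0.0, 1.0, len(a) - 1, True)
            return TTestResult(math.nan, math.nan, len(a) - 1, True, zero_variance=True)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.pvalue), float(res.df), True)

    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, len(a) + len(b) - 2, False)
        return TTestResult(
            math.nan, math.nan, len(a) + len(b) - 2, False, zero_variance=True
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df), False)


# ---------------------------------------------------------------------------
# series assembly and cross-line evaluation


def series_from_predictions(
    predictions: pd.DataFrame,
    value_column: str = "predicted_viability",
    group_by: tuple[str, ...] = ("set", "replicate"),
    source: str = "predicted",
) -> list[SeriesResponse]:
    """Group a predictions table into dose-response series for IC50 fitting.

    The default grouping key (experiment set, replicate) yields one series
    per full dose ladder.
    """
    out = []
    for key, grp in predictions.groupby(list(group_by), sort=True):
        grp = grp.sort_values("concentration_um")
        key_t = key if isinstance(key, tuple) else (key,)
        sid = "_".join(f"{c}{v}" for c, v in zip(group_by, key_t))
        out.append(
            SeriesResponse(
                series_id=sid,
                concentrations_um=grp["concentration_um"].to_numpy(),
                responses=grp[value_column].to_numpy(),
                source=source,
            )
        )
    return out


@dataclass
class CrossEntry:
    """One (training line, evaluated line) cell of the cross matrix."""

    train_line: str
    eval_line: str
    agreement: LinearAgreement
    ic50_measured: pd.DataFrame
    ic50_predicted: pd.DataFrame
    unpaired: TTestResult | None
    paired: TTestResult | None

    @property
    def autologous(self) -> bool:
        return self.train_line == self.eval_line


@dataclass
class CrossMatrix:
    """Full autologous/allogenic evaluation matrix."""

    entries: dict[tuple[str, str], CrossEntry]

    def best_trainer(self, eval_line: str) -> str:
        """Training line whose model gives the highest r² on this line."""
        cands = {
            k[0]: e.agreement.r_squared
            for k, e in self.entries.items()
            if k[1] == eval_line and math.isfinite(e.agreement.r_squared)
        }
        if not cands:
            raise ValueError(f"no entries for evaluated line {eval_line!r}")
        return max(cands, key=cands.get)

    def r2_table(self) -> pd.DataFrame:
        lines_t = sorted({k[0] for k in self.entries})
        lines_e = sorted({k[1] for k in self.entries})
        data = [
            [
                self.entries[(t, e)].agreement.r_squared
                if (t, e) in self.entries else math.nan
                for e in lines_e
            ]
            for t in lines_t
        ]
        return pd.DataFrame(data, index=lines_t, columns=lines_e)


def cross_evaluate(
    predictions_by_pair: dict[tuple[str, str], pd.DataFrame],
) -> CrossMatrix:
    """Build the cross matrix from per-(trainer, evaluated) prediction tables.

    Each table must carry measured and predicted viability per well plus the
    set/replicate grouping columns.  Per cell the matrix records the linear
    agreement and the per-series IC50 comparison: unpaired and paired
    Student t-tests between measured-label IC50s and predicted IC50s over
    the test series.
    """
    from .hill import ic50_per_series

    entries: dict[tuple[str, str], CrossEntry] = {}
    for (train_line, eval_line), preds in predictions_by_pair.items():
        if "error" in preds.columns:
            ok = preds[preds["error"].fillna("") == ""]
        else:
            ok = preds
        agreement = linear_agreement(
            ok["measured_viability"].to_numpy(),
            ok["predicted_viability"].to_numpy(),
        )
        meas_series = series_from_predictions(
            ok, value_column="measured_viability", source="measured"
        )
        pred_series = series_from_predictions(
            ok, value_column="predicted_viability", source="predicted"
        )
        ic50_m = ic50_per_series(meas_series)
        ic50_p = ic50_per_series(pred_series)
        merged = ic50_m.merge(ic50_p, on="series_id", suffixes=("_meas", "_pred"))
        both = merged[merged["converged_meas"] & merged["converged_pred"]]
        unpaired = paired = None
        if len(both) >= 2:
            unpaired = t_test(
                both["ic50_um_meas"], both["ic50_um_pred"], paired=False
            )
            paired = t_test(
                both["ic50_um_meas"], both["ic50_um_pred"], paired=True
            )
        entries[(train_line, eval_line)] = CrossEntry(
            train_line=train_line, eval_line=eval_line, agreement=agreement,
            ic50_measured=ic50_m, ic50_predicted=ic50_p,
            unpaired=unpaired, paired=paired,
        )
    return CrossMatrix(entries)


# ---------------------------------------------------------------------------
# t-SNE feature embedding with Hill-region labels


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n, 2)
    region_labels: list[str]  # top | slope | bottom


def hill_region_labels(
    concentrations_um: Sequence[float],
    params: DoseResponseParams | HillFitResult,
    threshold: float = 0.1,
) -> list[str]:
    """Label each dose by its position on the fitted Hill curve.

    ``top`` where the curve sits within ``threshold`` of the dynamic range
    below Max, ``bottom`` within ``threshold`` above Min, else ``slope``.
    """
    if isinstance(params, HillFitResult):
        if not params.converged or params.params is None:
            raise ValueError("cannot label regions from a non-converged fit")
        params = params.params
    span = params.max_response - params.min_response
    labels = []
    for c in concentrations_um:
        y = hill_response(params, float(c))
        if y > params.max_response - threshold * span:
            labels.append("top")
        elif y < params.min_response + threshold * span:
            labels.append("bottom")
        else:
            labels.append("slope")
    return labels


def embed_features(
    features: np.ndarray,
    concentrations_um: Sequence[float],
    params: DoseResponseParams | HillFitResult,
    perplexity: float = 10.0,
    seed: int = 0,
    n_iter: int = 1000,
    region_threshold: float = 0.1,
) -> EmbeddingResult:
    """2D t-SNE of feature vectors with per-well Hill-region labels.

    Requires at least 10 vectors and more vectors than the perplexity
    allows.  A fixed seed gives identical coordinates across runs.
    """
    from sklearn.manifold import TSNE

    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or len(x) < 10:
        raise ValueError("need a 2-D feature matrix with >= 10 rows")
    if len(x) <= perplexity:
        raise ValueError(
            f"{len(x)} points cannot support perplexity {perplexity}"
        )
    if len(x) != len(concentrations_um):
        raise ValueError("one concentration per feature vector required")
    # exact gradients: datasets here are hundreds of points, and the
    # Barnes-Hut approximation needlessly breaks duplicate-point symmetry
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed,
        max_iter=n_iter, init="pca", method="exact",
    )
    coords = tsne.fit_transform(x)
    labels = hill_region_labels(concentrations_um, params, region_threshold)
    return EmbeddingResult(coordinates=coords, region_labels=labels)
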