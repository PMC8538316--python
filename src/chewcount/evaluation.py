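"""Agreement evaluation: AE / MAPE / RMSE, Bland-Altman, and ICC.

Counting accuracy is judged against an annotator gold standard:

    AE   = |actual - measured|
    MAPE = (1/n) * sum(AE_i / actual_i) * 100%
    RMSE = sqrt((1/n) * sum((actual_i - measured_i)^2))

Method-vs-gold agreement uses the Bland-Altman construction (bias and
limits of agreement at bias +/- 1.96 SD of the paired differences), and
annotator reliability uses the intraclass correlation coefficient, by
default ICC(2,1) — two-way random effects, absolute agreement, single
rater — since annotators are treated as interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError, UndefinedMetricError

__all__ = [
    "CountPair",
    "BlandAltman",
    "AgreementReport",
    "absolute_error",
    "mape",
    "rmse",
    "bland_altman",
    "icc",
    "evaluate_counts",
    "gold_standard_counts",
]


@dataclass(frozen=True)
class CountPair:
    """Gold-standard vs algorithm chew count for one clip."""

    actual: float
    measured: float
    clip_id: str = ""
    speed: str = ""


@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    fraction_within: float
    diffs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in ("bias", "sd", "loa_low", "loa_high", "fraction_within")}


@dataclass
class AgreementReport:
    ae_mean: float
    ae_sd: float
    mape_percent: float
    rmse: float
    n: int
    bland_altman: BlandAltman | None = None
    icc: float | None = None

    def to_dict(self) -> dict:
        out = {"ae_mean": self.ae_mean, "ae_sd": self.ae_sd,
               "mape_percent": self.mape_percent, "rmse": self.rmse, "n": self.n}
        if self.bland_altman is not None:
            out["bland_altman"] = self.bland_altman.to_dict()
        if self.icc is not None:
            out["icc"] = self.icc
        return out


def _as_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    pairs = list(pairs)
    if not pairs:
        raise InvalidInputError("empty pair list")
    a = np.array([p.actual for p in pairs], float)
    m = np.array([p.measured for p in pairs], float)
    return a, m


def absolute_error(pair: CountPair) -> float:
    """AE of a single clip."""
    return abs(pair.actual - pair.measured)


def mape(pairs) -> float:
    """Mean absolute percentage error, in percent of the gold-standard count."""
    a, m = _as_arrays(pairs)
    if (a <= 0).any():
        raise UndefinedMetricError("MAPE undefined for non-positive gold-standard counts")
    return float(np.mean(np.abs(a - m) / a) * 100.0)


def rmse(pairs) -> float:
    """Root mean squared count error."""
    a, m = _as_arrays(pairs)
    return float(np.sqrt(np.mean((a - m) ** 2)))


def bland_altman(a, b, ddof: int = 1) -> BlandAltman:
    """Bland-Altman agreement of two paired measurement series.

    Differences are ``a - b``; limits of agreement are bias +/- 1.96 SD
    (sample SD, ``ddof=1`` by default).  ``fraction_within`` is the share of
    points inside the limits.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise InvalidInputError("paired series must have equal length")
    if a.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least two pairs")
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=ddof))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((diffs >= lo) & (diffs <= hi)))
    return BlandAltman(bias=bias, sd=sd, loa_low=lo, loa_high=hi,
                       fraction_within=within, diffs=diffs, means=means)


def icc(ratings: np.ndarray, form: str = "icc2") -> float:
    """Intraclass correlation from a (subjects x raters) matrix, no missing cells.

    ``icc2`` is ICC(2,1): two-way random effects, absolute agreement, single
    rater.  ``icc3`` (two-way mixed, consistency) is also available.  A
    constant matrix has zero between-subject variance and no defined ICC.
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidInputError("need at least 2 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise InvalidInputError("missing cells are not supported")
    n, k = x.shape
    if np.allclose(x, x.flat[0]):
        raise UndefinedMetricError("ICC undefined for a constant rating matrix")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise InvalidInputError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise UndefinedMetricError("ICC undefined: zero variance")
    return float((msr - mse) / denom)


def gold_standard_counts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Mean annotator count per clip (kept fractional, not rounded).

    ``annotations`` columns: clip_id, speed, annotator_id, count.
    """
    required = {"clip_id", "speed", "annotator_id", "count"}
    if not required.issubset(annotations.columns):
        raise InvalidInputError(f"annotation table needs columns {sorted(required)}")
    return (annotations.groupby(["clip_id", "speed"], as_index=False)["count"]
            .mean().rename(columns={"count": "actual"}))


def evaluate_counts(results: pd.DataFrame, annotations: pd.DataFrame) -> dict:
    """Full evaluation of algorithm counts against annotator gold standard.

    ``results`` columns: clip_id, speed, method, count.  Returns a nested
    report per (method, speed) plus overall, with AE/MAPE/RMSE and
    Bland-Altman summaries, and per-speed annotator ICC where at least two
    annotators rated at least two clips.
    """
    gold = gold_standard_counts(annotations)
    merged = results.merge(gold, on=["clip_id", "speed"], how="inner")
    if merged.empty:
        raise InvalidInputError("no overlapping clips between results and annotations")
    report: dict = {"per_method_speed": {}, "annotator_icc": {}}
    for (method, speed), grp in merged.groupby(["method", "speed"]):
        pairs = [CountPair(r.actual, r.count, r.clip_id, speed) for r in grp.itertuples()]
        ae = np.array([absolute_error(p) for p in pairs])
        rep = AgreementReport(
            ae_mean=float(ae.mean()), ae_sd=float(ae.std(ddof=1)) if len(ae) > 1 else 0.0,
            mape_percent=mape(pairs), rmse=rmse(pairs), n=len(pairs),
            bland_altman=bland_altman(grp["count"].to_numpy(), grp["actual"].to_numpy())
            if len(grp) >= 2 else None,
        )
        report["per_method_speed"][f"{method}/{speed}"] = rep.to_dict()
    for speed, grp in annotations.groupby("speed"):
        pivot = grp.pivot_table(index="clip_id", columns="annotator_id", values="count")
        if pivot.shape[0] >= 2 and pivot.shape[1] >= 2 and pivot.notna().all().all():
            try:
                report["annotator_icc"][speed] = icc(pivot.to_numpy())
            except UndefinedMetricError:
                report["annotator_icc"][speed] = None
    return report


def bland_altman_plot(ba: BlandAltman, path, title: str = "") -> None:
    """Write a Bland-Altman scatter with bias and limit lines to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.7)
    for yv, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods (chews)")
    ax.set_ylabel("difference (chews)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
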