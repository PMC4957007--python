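"""Manual-vs-automated method-comparison statistics.

Manual counts (the mean of four operators) and automated counts both carry
error, so agreement is assessed with Major Axis regression — the model-II line
along the first principal axis of the 2×2 covariance matrix, which minimizes
perpendicular rather than vertical distances.  With centered sums of squares
``Sxx``, ``Syy`` and cross-products ``Sxy``:

    slope = (Syy − Sxx + sqrt((Syy − Sxx)² + 4·Sxy²)) / (2·Sxy)
    intercept = ȳ − slope·x̄

with the automated estimate on the y-axis.  Goodness of fit is the squared
Pearson correlation; significance is assessed by permutation of the pairing
(the correlation's null distribution), since both axes carry error.

The module also computes the pooled summaries of a 40-image validation table:
reconstruction rate, per-station mean area fraction, and the pooled
count/object interest fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from acqua.errors import ValidationError

TABLE_COLUMNS = ["station", "image_no", "manual_count", "manual_count_sd",
                 "manual_tl_um", "manual_tl_sd_um", "a_count", "a_tl_um",
                 "rec_joined", "rec_events", "fil_obj", "afil_aobj_pct"]

NON_NEMI_STATIONS = ("Ronciglione", "Caprarola", "Albano")


@dataclass
class MajorAxisFit:
    slope: float
    intercept: float
    r2: float
    n: int
    p_value: float = float("nan")


def load_validation_table(path=None) -> pd.DataFrame:
    """Load a validation table CSV (default: the packaged 40-image table)."""
    if path is None:
        with resources.files("acqua").joinpath("data/validation_table.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"validation table missing columns: {sorted(missing)}")
    return df


def major_axis_fit(x, y, n_permutations: int = 0, seed: int = 0) -> MajorAxisFit:
    """Major Axis (model II) regression of y (automated) on x (manual).

    Requires n ≥ 3, positive variance on both axes and nonzero covariance.
    When ``n_permutations`` > 0, a two-sided permutation p-value for the
    Pearson correlation is computed with a seeded generator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValidationError("major_axis_fit needs n >= 3 paired observations")
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx, syy, sxy = float(dx @ dx), float(dy @ dy), float(dx @ dy)
    if sxx <= 0 or syy <= 0:
        raise ValidationError("zero variance on an axis; slope undefined")
    if sxy == 0:
        raise ValidationError("zero covariance; major-axis slope undefined")
    slope = (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)) / (2.0 * sxy)
    intercept = ym - slope * xm
    r = sxy / math.sqrt(sxx * syy)
    p_value = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perm_r = np.empty(n_permutations)
        for i in range(n_permutations):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_value = (1 + np.count_nonzero(np.abs(perm_r) >= abs(r))) / (n_permutations + 1)
    return MajorAxisFit(slope=slope, intercept=intercept, r2=r * r, n=n, p_value=p_value)


class MajorAxisRegression:
    """Major Axis regression with a scikit-learn estimator surface.

    Parameters
    ----------
    n_permutations : permutations for the correlation p-value (0 disables).
    seed : seed for the permutation generator.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_, r2_, n_, p_value_
    """

    def __init__(self, n_permutations: int = 0, seed: int = 0):
        self.n_permutations = n_permutations
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_permutations": self.n_permutations, "seed": self.seed}

    def set_params(self, **params) -> "MajorAxisRegression":
        for k, v in params.items():
            if k not in ("n_permutations", "seed"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "MajorAxisRegression":
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValidationError("MajorAxisRegression expects a single feature")
            X = X[:, 0]
        res = major_axis_fit(X, y, n_permutations=self.n_permutations, seed=self.seed)
        self.slope_, self.intercept_ = res.slope, res.intercept
        self.r2_, self.n_, self.p_value_ = res.r2, res.n, res.p_value
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.slope_ * X + self.intercept_

    def score(self, X, y) -> float:  # pragma: no cover - sklearn compatibility
        return float(self.r2_)


def pooled_summaries(table: pd.DataFrame) -> dict:
    """Pooled reconstruction rate and per-station area/interest summaries.

    Returns ``reconstruction_pct`` (100·Σjoined/Σevents over all rows),
    ``mean_afil_aobj_pct`` (arithmetic mean of each station's per-image area
    fractions) and ``pooled_interest_fraction_pct`` (100·Σ automated count /
    Σ filamentous objects per station).  Zero denominators give NaN.
    """
    events = table["rec_events"].sum()
    rec = 100.0 * table["rec_joined"].sum() / events if events > 0 else float("nan")
    mean_af = {}
    pooled_int = {}
    for station, grp in table.groupby("station", sort=False):
        mean_af[station] = float(grp["afil_aobj_pct"].mean())
        fo = grp["fil_obj"].sum()
        pooled_int[station] = 100.0 * grp["a_count"].sum() / fo if fo > 0 else float("nan")
    return {
        "reconstruction_pct": rec,
        "mean_afil_aobj_pct": mean_af,
        "pooled_interest_fraction_pct": pooled_int,
    }


def station_fit_suite(table: pd.DataFrame, n_permutations: int = 0, seed: int = 0) -> dict:
    """Major-axis fits per station for abundance and total length.

    Returns every per-station fit plus the min/max slope and min r² across the
    six fits of the three low-noise stations (abundance and total length for
    Ronciglione, Caprarola and Albano), the standard linearity summary.
    """
    fits: dict[tuple[str, str], MajorAxisFit] = {}
    for station, grp in table.groupby("station", sort=False):
        fits[(station, "abundance")] = major_axis_fit(
            grp["manual_count"], grp["a_count"], n_permutations, seed)
        fits[(station, "total_length")] = major_axis_fit(
            grp["manual_tl_um"], grp["a_tl_um"], n_permutations, seed)
    six = [fits[(s, m)] for s in NON_NEMI_STATIONS for m in ("abundance", "total_length")
           if (s, m) in fits]
    summary = {}
    if six:
        summary = {
            "min_slope": min(f.slope for f in six),
            "max_slope": max(f.slope for f in six),
            "min_r2": min(f.r2 for f in six),
        }
    return {"fits": fits, "non_nemi_summary": summary}
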