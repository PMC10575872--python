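"""Image-based accuracy assessment: random points and the error matrix.

For each site, a handful of years is drawn at random, a fixed number of
random points is placed on each year's inundation map (valid pixels only),
the map's label is extracted at each point, and a reference label (truth or
photo-interpretation) is attached.  The predicted-vs-reference counts form
a 2x2 error matrix from which the standard thematic-map accuracies follow:

* overall accuracy   = 100 * trace / total points
* producer's accuracy (per class) = 100 * diagonal / reference-column total
* user's accuracy     (per class) = 100 * diagonal / predicted-row total

Rows of the matrix are the predicted class, columns the reference class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from swirmap.classifier import InundationMap

__all__ = [
    "CLASS_NAMES",
    "ErrorMatrix",
    "sample_validation_points",
    "extract_predicted_labels",
    "build_error_matrix",
]

CLASS_NAMES = ("dry", "wet")

DEFAULT_N_YEARS = 5
DEFAULT_N_POINTS_PER_YEAR = 50

POINT_COLUMNS = ["site_id", "year", "row", "col"]


@dataclass(frozen=True)
class ErrorMatrix:
    """2x2 predicted-vs-reference counts and derived accuracies (percent).

    ``counts[i, j]`` is the number of points predicted class ``i`` with
    reference class ``j`` (0 = dry, 1 = wet).  A class absent from the
    reference (zero column total) has an undefined producer's accuracy,
    reported as NaN -- never as 0; likewise for user's accuracy on an
    empty predicted row.
    """

    counts: np.ndarray
    n_total: int
    overall_accuracy: float
    producers_accuracy: Mapping[str, float]
    users_accuracy: Mapping[str, float]

    def transposed(self) -> "ErrorMatrix":
        """The matrix with predicted and reference roles swapped."""
        return _matrix_from_counts(self.counts.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"predicted_{c}" for c in CLASS_NAMES],
            columns=[f"reference_{c}" for c in CLASS_NAMES],
        )

    def to_dict(self) -> dict:
        return {
            "counts_rows_predicted_cols_reference": self.counts.tolist(),
            "n_total": self.n_total,
            "overall_accuracy": self.overall_accuracy,
            "producers_accuracy": dict(self.producers_accuracy),
            "users_accuracy": dict(self.users_accuracy),
        }


def sample_validation_points(
    maps: Sequence[InundationMap],
    n_years: int = DEFAULT_N_YEARS,
    n_points_per_year: int = DEFAULT_N_POINTS_PER_YEAR,
    seed: int = 0,
    site_id: str = "site",
) -> pd.DataFrame:
    """Draw the validation sample: random years, random valid pixels.

    ``n_years`` map years are chosen uniformly without replacement, then
    ``n_points_per_year`` positions are drawn uniformly over each chosen
    map's valid (non-nodata) pixels, so every point carries a usable
    predicted label.  Fully seeded: the same seed reproduces the same
    points.  The defaults give the conventional 5 x 50 = 250 points per
    site.
    """
    if not maps:
        raise ValueError("no inundation maps to sample from")
    by_year = {m.year: m for m in maps}
    if len(by_year) < n_years:
        raise ValueError(
            f"need {n_years} available years, only {len(by_year)} maps given"
        )
    rng = np.random.default_rng(seed)
    years = np.sort(
        rng.choice(np.sort(np.array(list(by_year))), size=n_years, replace=False)
    )
    rows: list[dict] = []
    for year in years:
        m = by_year[int(year)]
        valid_idx = np.flatnonzero(m.valid_mask.ravel())
        if valid_idx.size == 0:
            raise ValueError(f"year {year}: map has no valid pixels to sample")
        replace = valid_idx.size < n_points_per_year
        chosen = rng.choice(valid_idx, size=n_points_per_year, replace=replace)
        r, c = np.unravel_index(chosen, m.shape)
        for rr, cc in zip(r, c):
            rows.append(
                {"site_id": site_id, "year": int(year), "row": int(rr), "col": int(cc)}
            )
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


def extract_predicted_labels(
    maps: Sequence[InundationMap], points: pd.DataFrame
) -> pd.DataFrame:
    """Fill each point's ``predicted`` column from its year's map."""
    by_year = {m.year: m for m in maps}
    out = points.copy()
    predicted = np.empty(len(out), dtype=np.int64)
    for i, (_, pt) in enumerate(out.iterrows()):
        year = int(pt["year"])
        if year not in by_year:
            raise ValueError(f"no inundation map for year {year}")
        label = int(by_year[year].labels[int(pt["row"]), int(pt["col"])])
        if label not in (0, 1):
            raise ValueError(
                f"point ({pt['row']}, {pt['col']}) in year {year} is nodata"
            )
        predicted[i] = label
    out["predicted"] = predicted
    return out


def _matrix_from_counts(counts: np.ndarray) -> ErrorMatrix:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (2, 2):
        raise ValueError("error matrix must be 2x2")
    n_total = int(counts.sum())
    if n_total == 0:
        raise ValueError("error matrix has no points")
    overall = 100.0 * np.trace(counts) / n_total
    producers = {}
    users = {}
    for k, name in enumerate(CLASS_NAMES):
        col = counts[:, k].sum()
        row = counts[k, :].sum()
        producers[name] = 100.0 * counts[k, k] / col if col else float("nan")
        users[name] = 100.0 * counts[k, k] / row if row else float("nan")
    return ErrorMatrix(
        counts=counts,
        n_total=n_total,
        overall_accuracy=float(overall),
        producers_accuracy=producers,
        users_accuracy=users,
    )


def build_error_matrix(points: pd.DataFrame) -> ErrorMatrix:
    """Tally predicted-vs-reference labels into the 2x2 error matrix."""
    if len(points) == 0:
        raise ValueError("no validation points")
    for col in ("predicted", "reference"):
        if col not in points.columns or points[col].isna().any():
            raise ValueError(f"every point needs a {col} label")
        vals = set(points[col].astype(int))
        if not vals <= {0, 1}:
            raise ValueError(f"{col} labels must be binary 0/1, got {sorted(vals)}")
    pred = points["predicted"].to_numpy(dtype=np.int64)
    ref = points["reference"].to_numpy(dtype=np.int64)
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (pred, ref), 1)
    return _matrix_from_counts(counts)
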