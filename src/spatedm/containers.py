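"""In-memory containers for survey and environmental data.

The survey grid is biquarterly: only the first and third quarters (Q1, Q3)
of each year are sampled.  ``quarter_step`` is a 0-based consecutive index
over the interleaved Q1/Q3 sequence (first surveyed year's Q1 = 0, its
Q3 = 1, ...); all lags elsewhere in the package are counted in these steps.
Derived series are stored on the full step grid with NaN marking quarters
that were never surveyed or were removed by filtering, so that lagged
embeddings can account for the gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SurveyTable", "EnvSeries", "QuarterSeries", "quarter_step_grid"]

RECORD_COLUMNS = ["quarter_step", "year", "quarter", "subarea", "class_id", "cpue"]

ENV_KINDS = (
    "spatial_mean_temperature",
    "spatial_cv_temperature",
    "climate_index",
    "fishing_mortality_yearly",
)


def quarter_step_grid(year_min: int, year_max: int) -> pd.DataFrame:
    """Full consecutive (quarter_step, year, quarter) grid for a year span."""
    years = np.repeat(np.arange(year_min, year_max + 1), 2)
    quarters = np.tile([1, 3], year_max - year_min + 1)
    return pd.DataFrame(
        {"quarter_step": np.arange(years.size), "year": years, "quarter": quarters}
    )


@dataclass
class SurveyTable:
    """Long-format CPUE records: one row per (quarter_step, subarea, class).

    ``class_kind`` says whether ``class_id`` indexes age classes (integers
    >= 0) or length classes.  ``grid`` is the full biquarterly step grid of
    the survey period, including quarters with no records.
    """

    records: pd.DataFrame
    class_kind: str  # "age" | "length"
    grid: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.class_kind not in ("age", "length"):
            raise ValidationError(f"class_kind must be age|length, got {self.class_kind!r}")
        df = self.records
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"records missing columns {missing}")
        df = df[RECORD_COLUMNS].reset_index(drop=True)
        if len(df):
            bad = df.index[df["cpue"] < 0]
            if len(bad):
                raise ValidationError(f"negative cpue at record row {bad[0]}")
            if not df["quarter"].isin([1, 3]).all():
                raise ValidationError("quarter labels must be 1 (Q1) or 3 (Q3)")
            dup = df.duplicated(["quarter_step", "subarea", "class_id"])
            if dup.any():
                raise ValidationError(
                    f"duplicate (quarter_step, subarea, class) at row {int(np.nonzero(dup.values)[0][0])}"
                )
        if self.grid is None:
            if not len(df):
                raise ValidationError("empty table needs an explicit grid")
            self.grid = quarter_step_grid(int(df["year"].min()), int(df["year"].max()))
        expected = self.grid.set_index("quarter_step")
        if len(df):
            step_year = df.drop_duplicates("quarter_step").set_index("quarter_step")
            joined = step_year.join(expected, rsuffix="_grid", how="left")
            if (
                joined["year_grid"].isna().any()
                or (joined["year"] != joined["year_grid"]).any()
                or (joined["quarter"] != joined["quarter_grid"]).any()
            ):
                raise ValidationError("quarter_step inconsistent with (year, quarter) grid")
        self.records = df

    @classmethod
    def from_records(cls, df: pd.DataFrame, class_kind: str) -> "SurveyTable":
        """Assign quarter steps from (year, quarter) and validate."""
        df = df.copy()
        grid = quarter_step_grid(int(df["year"].min()), int(df["year"].max()))
        key = grid.set_index(["year", "quarter"])["quarter_step"]
        df["quarter_step"] = key.loc[
            pd.MultiIndex.from_frame(df[["year", "quarter"]])
        ].to_numpy()
        return cls(records=df, class_kind=class_kind, grid=grid)

    @property
    def n_steps(self) -> int:
        return len(self.grid)

    @property
    def surveyed_steps(self) -> np.ndarray:
        return np.sort(self.records["quarter_step"].unique())

    @property
    def subareas(self) -> list[str]:
        return sorted(self.records["subarea"].unique())

    def totals_by_subarea(self) -> pd.DataFrame:
        """Sum CPUE over classes: one row per (quarter_step, subarea)."""
        return (
            self.records.groupby(["quarter_step", "subarea"], as_index=False)["cpue"]
            .sum()
        )

    def replace_records(self, df: pd.DataFrame) -> "SurveyTable":
        return SurveyTable(records=df.reset_index(drop=True), class_kind=self.class_kind, grid=self.grid)

    def equals(self, other: "SurveyTable") -> bool:
        a = self.records.sort_values(["quarter_step", "subarea", "class_id"]).reset_index(drop=True)
        b = other.records.sort_values(["quarter_step", "subarea", "class_id"]).reset_index(drop=True)
        return a.equals(b) and self.class_kind == other.class_kind


@dataclass
class QuarterSeries:
    """A scalar series on the biquarterly (or yearly) grid with provenance.

    ``values[i]`` sits at ``years[i]``/``quarters[i]`` (``quarters`` is None
    on a yearly grid); NaN marks excluded or unobserved steps.  ``mu`` and
    ``sigma`` hold the per-step spatial moments where the series is a
    spatial statistic.
    """

    name: str
    values: np.ndarray
    years: np.ndarray
    quarters: np.ndarray | None = None
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    normalized: bool = False
    detrended: bool = False
    detrend_slope: float | None = None
    detrend_pvalue: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.shape != self.years.shape:
            raise ValidationError("values and years must be aligned")
        if self.quarters is not None:
            self.quarters = np.asarray(self.quarters, dtype=int)
            if self.quarters.shape != self.values.shape:
                raise ValidationError("values and quarters must be aligned")

    @property
    def grid(self) -> str:
        return "biquarterly" if self.quarters is not None else "yearly"

    @property
    def n_finite(self) -> int:
        return int(np.isfinite(self.values).sum())

    def with_values(self, values: np.ndarray, **prov) -> "QuarterSeries":
        return replace(self, values=np.asarray(values, float), **prov)

    def same_grid(self, other: "QuarterSeries") -> bool:
        if self.grid != other.grid or self.values.size != other.values.size:
            return False
        if not np.array_equal(self.years, other.years):
            return False
        if self.quarters is not None and not np.array_equal(self.quarters, other.quarters):
            return False
        return True


@dataclass
class EnvSeries:
    """An environmental or fishing-pressure driver on the survey grid."""

    name: str
    values: np.ndarray
    kind: str
    years: np.ndarray
    quarters: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ENV_KINDS:
            raise ValidationError(f"unknown EnvSeries kind {self.kind!r}")
        if self.kind == "fishing_mortality_yearly" and self.quarters is not None:
            raise ValidationError("fishing mortality lives on the yearly grid")

    def to_quarter_series(self) -> QuarterSeries:
        return QuarterSeries(
            name=self.name,
            values=np.asarray(self.values, float),
            years=np.asarray(self.years, int),
            quarters=None if self.quarters is None else np.asarray(self.quarters, int),
        )
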