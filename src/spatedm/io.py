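"""Reading and writing the tabular formats the pipeline touches.

All files are comma-separated UTF-8 with a header row; column names of
survey exports vary between sources, so :func:`read_survey_table` accepts
a column-name mapping.  Every row dropped on ingest is logged with a
reason code.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import ENV_KINDS, EnvSeries, SurveyTable
from .errors import FormatError, ValidationError

__all__ = [
    "read_survey_table",
    "write_survey_table",
    "read_env_series",
    "write_env_series",
    "write_results_tables",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "year": "year",
    "quarter": "quarter",
    "subarea": "subarea",
    "class": "class",
    "cpue": "cpue",
}


def read_survey_table(
    path, class_kind: str, columns: dict[str, str] | None = None
) -> SurveyTable:
    """Read a long-format CPUE CSV into a validated :class:`SurveyTable`.

    ``columns`` maps the canonical names (year, quarter, subarea, class,
    cpue) to the header names in the file.  Rows outside quarters 1 and 3
    are dropped with a logged count (the survey only samples Q1/Q3);
    negative CPUE is a validation error naming the row.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    df = df[["year", "quarter", "subarea", "class", "cpue"]].rename(
        columns={"class": "class_id"}
    )
    bad_q = ~df["quarter"].isin([1, 3])
    if bad_q.any():
        logger.warning(
            "read_survey_table[off_quarter]: dropped %d rows outside Q1/Q3", int(bad_q.sum())
        )
        df = df[~bad_q]
    neg = df.index[df["cpue"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative cpue at input row {int(neg[0])}")
    df["subarea"] = df["subarea"].astype(str)
    return SurveyTable.from_records(df.reset_index(drop=True), class_kind)


def write_survey_table(table: SurveyTable, path) -> None:
    out = table.records.rename(columns={"class_id": "class"})
    # %.17g makes the write/read round-trip exact for float64 CPUE
    out[["year", "quarter", "subarea", "class", "cpue"]].to_csv(
        path, index=False, float_format="%.17g"
    )


def read_env_series(path, name: str, kind: str) -> EnvSeries:
    """Read a driver series CSV: columns year[, quarter], value."""
    if kind not in ENV_KINDS:
        raise FormatError(f"unknown series kind {kind!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "year" not in df.columns or "value" not in df.columns:
        raise FormatError(f"{path}: needs columns year[, quarter], value")
    quarterly = "quarter" in df.columns and kind != "fishing_mortality_yearly"
    if quarterly:
        df = df.sort_values(["year", "quarter"])
        return EnvSeries(
            name=name,
            values=df["value"].to_numpy(float),
            kind=kind,
            years=df["year"].to_numpy(int),
            quarters=df["quarter"].to_numpy(int),
        )
    df = df.sort_values("year")
    return EnvSeries(
        name=name,
        values=df["value"].to_numpy(float),
        kind=kind,
        years=df["year"].to_numpy(int),
        quarters=None,
    )


def write_env_series(series: EnvSeries, path) -> None:
    cols = {"year": series.years}
    if series.quarters is not None:
        cols["quarter"] = series.quarters
    cols["value"] = series.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

TABLE1_COLUMNS = [
    "species", "E_star", "variable", "lag", "rho", "pass_fraction", "significant",
]
TABLE2_COLUMNS = ["species", "theta", "rho", "p_value", "variable", "mean_influence"]
COEF_COLUMNS = ["species", "quarter_step", "variable", "coefficient"]
SENSITIVITY_COLUMNS = [
    "species", "model", "causes", "theta", "rho", "p_value", "significant",
    "variable", "mean_influence",
]
TAYLOR_COLUMNS = ["species", "a", "b", "r_squared", "n_points", "cv_direction"]


def write_results_tables(
    ccm_scans: dict[str, list],
    attributions: dict[str, object],
    taylor_fits: dict[str, object],
    outdir,
) -> dict[str, Path]:
    """Emit the summary CSVs of a pipeline run.

    ``table1.csv``: per species and examined variable, the cross-map skill
    at the full library, best lag, and significance verdict ("n.s." rows
    keep rho empty).  ``table2.csv``: per species with a significant S-map
    reconstruction, theta, rho, p and the mean influence of each embedded
    cause.  ``coefficients.csv``: the full per-time-step coefficient
    series.  ``sensitivity.csv``: one row per alternative-embedding model
    and influenced variable.  ``taylor.csv``: the Taylor's-law fits.
    Empty inputs produce header-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .metrics import cv_abundance_direction  # deferred: io stays science-free

    t1_rows = []
    for species, scans in ccm_scans.items():
        for scan in scans:
            best = scan.best
            t1_rows.append(
                dict(
                    species=species,
                    E_star=scan.results[0].E_star_library if scan.results else "",
                    variable=scan.cause_name,
                    lag=best.lag if best else "n.s.",
                    rho=best.rho_Lmax if best else "",
                    pass_fraction=best.pass_fraction if best else "",
                    significant=scan.significant,
                )
            )
    t2_rows, coef_rows, sens_rows = [], [], []
    for species, att in attributions.items():
        if att is None:
            continue
        for k, alt in enumerate(att.alternates):
            if alt.model is None:
                continue
            base = dict(
                species=species, model=k,
                causes="+".join(alt.cause_names),
                theta=alt.model.theta, rho=alt.model.rho,
                p_value=alt.model.p_value, significant=alt.significant,
            )
            if alt.mean_influence:
                for var, infl in alt.mean_influence.items():
                    sens_rows.append(dict(base, variable=var, mean_influence=infl))
            else:
                sens_rows.append(dict(base, variable="", mean_influence=""))
        if att.model is None or not att.significant:
            continue
        for var, infl in att.mean_influence.items():
            t2_rows.append(
                dict(
                    species=species,
                    theta=att.model.theta,
                    rho=att.model.rho,
                    p_value=att.model.p_value,
                    variable=var,
                    mean_influence=infl,
                )
            )
        for j, (var, _lag) in enumerate(att.embedding.variables):
            for k, step in enumerate(att.model.steps):
                coef_rows.append(
                    dict(
                        species=species,
                        quarter_step=int(step),
                        variable=var,
                        coefficient=att.model.coefficients[k, 1 + j],
                    )
                )
    taylor_rows = [
        dict(
            species=species,
            a=fit.a,
            b=fit.b,
            r_squared=fit.r_squared,
            n_points=fit.n_points,
            cv_direction=cv_abundance_direction(fit),
        )
        for species, fit in taylor_fits.items()
    ]

    paths = {}
    for name, rows, cols in [
        ("table1", t1_rows, TABLE1_COLUMNS),
        ("table2", t2_rows, TABLE2_COLUMNS),
        ("coefficients", coef_rows, COEF_COLUMNS),
        ("sensitivity", sens_rows, SENSITIVITY_COLUMNS),
        ("taylor", taylor_rows, TAYLOR_COLUMNS),
    ]:
        p = outdir / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(p, index=False)
        paths[name] = p
    return paths
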