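"""Life-table readers and writers: CSV and the HMD 1x1 text dialect.

The Human Mortality Database publishes deaths and exposures as
whitespace-aligned text with a description line, a blank line, then
columns ``Year  Age  Female  Male  Total``; ages run 0..109 plus a
terminal open interval labelled ``110+``, and missing values are printed
as ``.``.  The reader takes a Deaths file and an Exposures file in this
layout and returns a :class:`~ggfrailty.likelihood.LifeTable` for one
year, one sex, restricted to ages at or above ``min_age`` (re-indexed so
the model age offset 0 corresponds to ``min_age``).

The CSV dialect is a plain ``age,deaths,exposure`` table with a header.
Deaths may be fractional in both dialects.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import LifeTable

__all__ = [
    "read_hmd_table",
    "write_hmd_pair",
    "read_csv_table",
    "write_csv_table",
]

SEXES = ("Female", "Male", "Total")
OPEN_AGE = 110


def _read_hmd_file(path) -> pd.DataFrame:
    """Parse one HMD 1x1 file into a Year/Age-indexed frame of the 3 sexes."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = next(
        (i for i, ln in enumerate(lines) if ln.split()[:2] == ["Year", "Age"]),
        None,
    )
    if header_idx is None:
        raise ValueError(f"{path}: no 'Year Age ...' header line found")
    df = pd.read_csv(
        io.StringIO("\n".join(lines[header_idx:])),
        sep=r"\s+",
        dtype={"Year": int, "Age": str},
        na_values=["."],
    )
    missing = [c for c in ("Year", "Age", *SEXES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[list(SEXES)].isna().any().any():
        warnings.warn(f"{path}: missing values ('.') treated as 0", stacklevel=3)
        df[list(SEXES)] = df[list(SEXES)].fillna(0.0)
    df["Age"] = df["Age"].str.rstrip("+").astype(int)
    return df


def read_hmd_table(
    deaths_path,
    exposures_path,
    year: int,
    sex: str = "Female",
    min_age: int = 70,
) -> LifeTable:
    """Read one year/sex life table above ``min_age`` from an HMD file pair.

    The ``110+`` row is kept as the final (open) interval.  Ages at the top
    of the table that have deaths recorded against zero exposure are
    zeroed out with a warning (the Poisson likelihood cannot accommodate
    them).
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    out = []
    for path in (deaths_path, exposures_path):
        df = _read_hmd_file(path)
        sel = df[df["Year"] == year]
        if sel.empty:
            raise ValueError(f"{path}: year {year} not present")
        sel = sel[sel["Age"] >= min_age].sort_values("Age")
        out.append(sel.set_index("Age")[sex])
    deaths, exposures = out
    ages = deaths.index.to_numpy()
    if not np.array_equal(ages, exposures.index.to_numpy()):
        raise ValueError("Deaths and Exposures files disagree on the age range")
    if not np.array_equal(np.diff(ages), np.ones(len(ages) - 1, dtype=ages.dtype)):
        raise ValueError("ages must be consecutive one-year intervals")
    D = deaths.to_numpy(dtype=float)
    E = exposures.to_numpy(dtype=float)
    bad = (E == 0) & (D > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} age(s) have deaths but zero exposure; "
            "both set to 0 for the likelihood",
            stacklevel=2,
        )
        D = np.where(bad, 0.0, D)
    return LifeTable(D=D, E=E, start_age=int(ages[0]))


def _format_hmd(df_rows, title: str) -> str:
    body = [title, "", f"{'Year':>6} {'Age':>5} {'Female':>14} {'Male':>14} {'Total':>14}"]
    for year, age, female, male, total in df_rows:
        age_s = f"{age}+" if age == OPEN_AGE else str(age)
        body.append(
            f"{year:>6} {age_s:>5} {female:>14.6f} {male:>14.6f} {total:>14.6f}"
        )
    return "\n".join(body) + "\n"


def write_hmd_pair(
    lt: LifeTable,
    deaths_path,
    exposures_path,
    year: int = 2000,
    sex: str = "Female",
) -> None:
    """Write a life table as an HMD-dialect Deaths/Exposures file pair.

    The selected sex column carries the data; the other columns are 0.
    The final age is labelled as the open interval when it reaches 110.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    ages = lt.start_age + np.arange(len(lt))
    for path, vals, title in (
        (deaths_path, lt.D, "Deaths (synthetic), 1x1"),
        (exposures_path, lt.E, "Exposure to risk (synthetic), 1x1"),
    ):
        rows = []
        for age, v in zip(ages, vals):
            cells = {s: 0.0 for s in SEXES}
            cells[sex] = float(v)
            cells["Total"] = float(v) if sex != "Total" else float(v)
            rows.append((year, int(age), cells["Female"], cells["Male"], cells["Total"]))
        Path(path).write_text(_format_hmd(rows, title))


def read_csv_table(path) -> LifeTable:
    """Read an ``age,deaths,exposure`` CSV into a LifeTable."""
    df = pd.read_csv(path)
    missing = [c for c in ("age", "deaths", "exposure") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.sort_values("age")
    ages = df["age"].to_numpy()
    if not np.array_equal(np.diff(ages), np.ones(len(ages) - 1, dtype=ages.dtype)):
        raise ValueError("ages must be consecutive one-year intervals")
    return LifeTable(
        D=df["deaths"].to_numpy(dtype=float),
        E=df["exposure"].to_numpy(dtype=float),
        start_age=int(ages[0]),
    )


def write_csv_table(lt: LifeTable, path) -> None:
    """Write a LifeTable as an ``age,deaths,exposure`` CSV."""
    ages = lt.start_age + np.arange(len(lt))
    df = pd.DataFrame({"age": ages, "deaths": lt.D, "exposure": lt.E})
    # %.17g round-trips IEEE doubles exactly, keeping the dialect lossless
    df.to_csv(path, index=False, float_format="%.17g")
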