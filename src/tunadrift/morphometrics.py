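"""Specimen-table analysis: length-length and length-weight regressions,
allometry test and growth-curve age estimation.

Input is a CSV with columns ``species, TL_cm, FL_cm, W_g`` (header
required), one row per fish.  The length-length conversion FL = m*TL + c is
an ordinary least-squares fit; the length-weight relation W = a*FL^b is fit
in log-log space — the standard fisheries practice, which also gives the
standard error of b needed for the allometry t-test t = (b - 3) / SE(b)
with df = n - 2 (b > 3 and p < 0.05 means positive allometric growth:
weight increasing faster than the cube of length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import GrowthModel, age_at_length, default_registry

REQUIRED_COLUMNS = ["species", "TL_cm", "FL_cm", "W_g"]


class SpecimenFormatError(ValueError):
    """A specimen table violates the documented CSV schema."""


def read_specimens(path) -> pd.DataFrame:
    """Read and validate a specimen CSV."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SpecimenFormatError(f"unreadable specimen CSV {path}: {exc}") from exc
    return validate_specimens(df)


def validate_specimens(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SpecimenFormatError(f"specimen table missing columns: {missing}")
    for col in ("TL_cm", "FL_cm", "W_g"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise SpecimenFormatError(f"column {col} must be positive numbers")
    if (df["FL_cm"] > df["TL_cm"] + 1e-9).any():
        raise SpecimenFormatError("fork length exceeds total length in some rows")
    return df


@dataclass(frozen=True)
class RegressionResult:
    """Fit summary for either the length-length or length-weight relation.

    For the length-length fit ``slope``/``intercept`` are the line
    coefficients.  For the length-weight fit ``slope`` is the allometric
    exponent b and ``intercept`` the back-transformed coefficient a.
    """

    species: str
    kind: str                  # "length_length" | "length_weight"
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r: float
    n: int

    @property
    def a(self) -> float:
        return self.intercept

    @property
    def b(self) -> float:
        return self.slope


def fit_length_length(df: pd.DataFrame, species: str | None = None
                      ) -> RegressionResult:
    """OLS fit of FL on TL for one species."""
    sub = _one_species(df, species)
    tl = sub["TL_cm"].to_numpy(dtype=float)
    fl = sub["FL_cm"].to_numpy(dtype=float)
    if np.ptp(tl) == 0:
        raise ValueError("total length is constant; cannot fit a line")
    res = stats.linregress(tl, fl)
    return RegressionResult(
        species=str(sub["species"].iloc[0]), kind="length_length",
        slope=res.slope, intercept=res.intercept,
        se_slope=res.stderr, se_intercept=res.intercept_stderr,
        r=res.rvalue, n=tl.size,
    )


def fit_length_weight(df: pd.DataFrame, species: str | None = None
                      ) -> RegressionResult:
    """Power-law fit W = a * FL**b via OLS on log W vs log FL."""
    sub = _one_species(df, species)
    fl = sub["FL_cm"].to_numpy(dtype=float)
    w = sub["W_g"].to_numpy(dtype=float)
    if np.any(fl <= 0) or np.any(w <= 0):
        raise ValueError("length-weight fit needs positive FL and W")
    if np.ptp(fl) == 0:
        raise ValueError("fork length is constant; cannot fit a power law")
    res = stats.linregress(np.log(fl), np.log(w))
    return RegressionResult(
        species=str(sub["species"].iloc[0]), kind="length_weight",
        slope=res.slope, intercept=float(np.exp(res.intercept)),
        se_slope=res.stderr, se_intercept=res.intercept_stderr,
        r=res.rvalue, n=fl.size,
    )


def _one_species(df: pd.DataFrame, species: str | None) -> pd.DataFrame:
    if species is not None:
        df = df[df["species"] == species]
    if df.empty:
        raise ValueError(f"no records for species {species!r}")
    if df["species"].nunique() != 1:
        raise ValueError("pass a single-species table or the species argument")
    if len(df) < 3:
        raise ValueError("need at least 3 records to fit")
    return df


@dataclass(frozen=True)
class AllometryTest:
    """t-test of the length-weight exponent b against isometry (b = 3)."""

    species: str
    b: float
    se_b: float
    t: float
    df: int
    p: float
    t_vs_zero: float  # companion statistic b / SE(b), for comparison
    verdict: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.species}: b={self.b:.4f} t={self.t:.1f} "
                f"df={self.df} p={self.p:.3g} ({self.verdict})")


def allometry_test(result: RegressionResult) -> AllometryTest:
    """Two-sided t-test of b = 3 with df = n - 2.

    Also reports b / SE(b) (the test of b against zero) because published
    tables sometimes print that statistic instead.

    A perfect (zero-residual) fit has SE(b) = 0; the test is then
    degenerate and reported as t = 0 (if b = 3 to numerical precision) or
    +/- infinity.
    """
    if result.kind != "length_weight":
        raise ValueError("allometry test applies to a length-weight fit")
    if result.se_slope < 0:
        raise ValueError("SE(b) must be >= 0")
    dof = result.n - 2
    if result.se_slope == 0:
        if abs(result.b - 3.0) < 1e-9:
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(result.b - 3.0) * np.inf, 0.0
    else:
        t = (result.b - 3.0) / result.se_slope
        p = 2.0 * stats.t.sf(abs(t), dof)
    if p < 0.05:
        verdict = "positive allometric" if result.b > 3 else "negative allometric"
    else:
        verdict = "isometric"
    t0 = (result.b / result.se_slope if result.se_slope > 0
          else np.sign(result.b) * np.inf)
    return AllometryTest(species=result.species, b=result.b,
                         se_b=result.se_slope, t=float(t), df=dof, p=float(p),
                         t_vs_zero=float(t0), verdict=verdict)


# -- ageing ----------------------------------------------------------------

def estimate_ages(df: pd.DataFrame,
                  registry: dict[str, GrowthModel] | None = None
                  ) -> pd.DataFrame:
    """Append an ``age_days`` column by inverting each species' growth curve.

    Order-invariant: ages depend only on species and fork length.
    """
    registry = registry if registry is not None else default_registry()
    df = validate_specimens(df).copy()
    unknown = sorted(set(df["species"]) - set(registry))
    if unknown:
        raise ValueError(f"no growth model registered for species: {unknown}")
    ages = np.empty(len(df))
    for sp, sub in df.groupby("species"):
        ages[df.index.get_indexer(sub.index)] = age_at_length(
            registry[sp], sub["FL_cm"].to_numpy(dtype=float))
    df["age_days"] = ages
    return df


def cohort_summary(df_aged: pd.DataFrame) -> pd.DataFrame:
    """Per-species and overall age statistics (sample SD, n - 1).

    SD is reported as NaN for groups of one.  Also includes mean fork
    length per group.
    """
    def stats_block(sub: pd.DataFrame, label: str) -> dict:
        a = sub["age_days"].to_numpy(dtype=float)
        return {
            "group": label,
            "n": a.size,
            "mean_age_days": float(a.mean()),
            "sd_age_days": float(a.std(ddof=1)) if a.size > 1 else np.nan,
            "min_age_days": float(a.min()),
            "max_age_days": float(a.max()),
            "mean_fl_cm": float(sub["FL_cm"].mean()),
        }

    rows = [stats_block(sub, sp) for sp, sub in df_aged.groupby("species")]
    rows.append(stats_block(df_aged, "all"))
    return pd.DataFrame(rows)


def age_frequency(df_aged: pd.DataFrame, bin_days: float = 1.0) -> pd.DataFrame:
    """Age-frequency histogram with 1-day bins (per species and overall)."""
    bins = np.floor(df_aged["age_days"].to_numpy(dtype=float) / bin_days).astype(int)
    out = (pd.DataFrame({"age_day_bin": bins, "species": df_aged["species"]})
           .groupby(["age_day_bin", "species"]).size()
           .reset_index(name="count")
           .sort_values(["age_day_bin", "species"], ignore_index=True))
    return out


def species_report(df: pd.DataFrame,
                   registry: dict[str, GrowthModel] | None = None
                   ) -> pd.DataFrame:
    """Per-species regression/allometry table plus age summary columns."""
    rows = []
    for sp in sorted(df["species"].unique()):
        ll = fit_length_length(df, sp)
        lw = fit_length_weight(df, sp)
        al = allometry_test(lw)
        rows.append({
            "species": sp, "n": ll.n,
            "ll_slope": ll.slope, "ll_intercept": ll.intercept, "ll_r": ll.r,
            "lw_a": lw.a, "lw_b": lw.b, "lw_se_b": lw.se_slope, "lw_r": lw.r,
            "allometry_t": al.t, "allometry_df": al.df, "allometry_p": al.p,
            "allometry_t_vs_zero": al.t_vs_zero, "allometry": al.verdict,
        })
    report = pd.DataFrame(rows)
    aged = estimate_ages(df, registry)
    summary = cohort_summary(aged).set_index("group")
    return report.merge(summary.drop(columns=["n"]), left_on="species",
                        right_index=True, how="left")
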