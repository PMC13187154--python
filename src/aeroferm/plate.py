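"""Extracellular acidification rate (ECAR) from microplate absorbance kinetics.

The assay follows cells in phenol-red medium in a 96-well plate: absorbance at
560 nm is read every few minutes, converted to pH through an affine standard
curve, and the acidification rate (pH/h) is the ordinary least-squares slope of
pH against time.  The dextrose-dependent ECAR of a strain is the difference
between the rate of its carbon (2% dextrose) well and its paired water-control
well; rapid fermenters acidify fast and therefore have strongly negative ECAR
(around -0.03 pH/h), while respiratory species sit near zero or drift slightly
basic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("carbon", "control")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Affine map pH = slope * A560 + intercept fitted over a calibration range."""

    slope: float
    intercept: float
    r_squared: float
    calib_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard curve slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
        lo, hi = self.calib_range
        if not lo < hi:
            raise ValueError("calibration range must have min < max")

    def ph(self, a560: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(a560, dtype=float) + self.intercept


@dataclass
class WellSeries:
    """One well's absorbance kinetics."""

    well_id: str
    strain: str
    condition: str
    replicate: int
    time_min: np.ndarray
    a560: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.a560 = np.asarray(self.a560, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"well {self.well_id}: condition {self.condition!r} not in {CONDITIONS}"
            )
        if len(self.time_min) != len(self.a560):
            raise ValueError(f"well {self.well_id}: time and absorbance lengths differ")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"well {self.well_id}: time_min must be strictly increasing")


@dataclass(frozen=True)
class EcarResult:
    """Paired carbon/control slopes (pH/h) and their difference, per replicate."""

    strain: str
    replicate: int
    slope_carbon: float
    slope_control: float
    fit_r2_carbon: float
    fit_r2_control: float

    @property
    def ecar(self) -> float:
        return self.slope_carbon - self.slope_control


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_standard_curve(calib: pd.DataFrame) -> StandardCurve:
    """OLS fit of pH as a function of A560 from a calibration table.

    Parameters
    ----------
    calib
        Table with columns ``ph`` and ``a560`` (one row per buffer standard,
        typically spanning pH 6.5-7.5).

    The fit direction (pH on absorbance) is deliberate: downstream we need pH
    from measured absorbance, so no fitted slope is ever divided through.
    """
    if not {"ph", "a560"}.issubset(calib.columns):
        raise ValueError("calibration table needs columns 'ph' and 'a560'")
    ph = np.asarray(calib["ph"], dtype=float)
    a = np.asarray(calib["a560"], dtype=float)
    if len(ph) < 2:
        raise ValueError(f"calibration table has {len(ph)} points; need at least 2")
    if len(np.unique(ph)) != len(ph):
        raise ValueError("calibration table has duplicate pH values")
    if not np.all(np.isfinite(a)) or np.any(a < 0):
        raise ValueError("calibration absorbances must be finite and >= 0")
    if np.ptp(a) == 0:
        raise ValueError("degenerate calibration table: all absorbances identical")
    slope, intercept = np.polyfit(a, ph, 1)
    fitted = slope * a + intercept
    ss_res = float(np.sum((ph - fitted) ** 2))
    ss_tot = float(np.sum((ph - ph.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return StandardCurve(float(slope), float(intercept), r2, (float(a.min()), float(a.max())))


def absorbance_to_ph(
    series: WellSeries, curve: StandardCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a well's absorbance trace to pH.

    Returns ``(ph, extrapolated)`` where ``extrapolated`` flags timepoints whose
    absorbance fell outside the standard curve's calibration range.  Values are
    never clipped; extrapolation is a warning condition only.
    """
    ph = curve.ph(series.a560)
    lo, hi = curve.calib_range
    extrapolated = (series.a560 < lo) | (series.a560 > hi)
    if np.any(extrapolated):
        logger.warning(
            "well %s: %d/%d timepoints outside calibration range [%g, %g]",
            series.well_id, int(extrapolated.sum()), len(ph), lo, hi,
        )
    return ph, extrapolated


def acidification_slope(
    ph: Sequence[float],
    time_min: Sequence[float],
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """OLS slope of pH against time, in pH per hour, with the fit's R^2.

    Non-finite pH values are dropped pairwise with their timepoints.  ``window``
    restricts the fit to ``t_start <= t <= t_end`` (minutes); the default uses
    the full measurement window.
    """
    ph = np.asarray(ph, dtype=float)
    t = np.asarray(time_min, dtype=float)
    if len(ph) != len(t):
        raise ValueError("ph and time_min lengths differ")
    keep = np.isfinite(ph) & np.isfinite(t)
    if window is not None:
        t0, t1 = window
        keep &= (t >= t0) & (t <= t1)
    ph, t = ph[keep], t[keep]
    if len(t) < 3:
        raise ValueError(f"need >= 3 finite timepoints to fit a slope, got {len(t)}")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance: cannot fit a slope")
    t_h = t / 60.0
    slope, intercept = np.polyfit(t_h, ph, 1)
    fitted = slope * t_h + intercept
    ss_res = float(np.sum((ph - fitted) ** 2))
    ss_tot = float(np.sum((ph - ph.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return float(slope), r2


def dextrose_dependent_ecar(
    carbon: WellSeries,
    control: WellSeries,
    curve: StandardCurve,
    window: tuple[float, float] | None = None,
) -> EcarResult:
    """ECAR of one replicate: carbon-well slope minus paired control-well slope."""
    if carbon.condition != "carbon":
        raise ValueError(f"well {carbon.well_id} is not a carbon well")
    if control.condition != "control":
        raise ValueError(f"well {control.well_id} is not a control well")
    if (carbon.strain, carbon.replicate) != (control.strain, control.replicate):
        raise ValueError(
            f"wells {carbon.well_id} ({carbon.strain} rep {carbon.replicate}) and "
            f"{control.well_id} ({control.strain} rep {control.replicate}) are not a pair"
        )
    ph_c, _ = absorbance_to_ph(carbon, curve)
    ph_w, _ = absorbance_to_ph(control, curve)
    s_c, r2_c = acidification_slope(ph_c, carbon.time_min, window)
    s_w, r2_w = acidification_slope(ph_w, control.time_min, window)
    return EcarResult(carbon.strain, carbon.replicate, s_c, s_w, r2_c, r2_w)


def aggregate_replicates(
    results: Iterable[EcarResult], min_n: int = 1
) -> pd.DataFrame:
    """Per-species trait table: mean ECAR, sample SD, replicate count.

    Species with fewer than ``min_n`` replicates are kept but flagged in the
    ``low_n`` column.  SD is reported as NaN for a single replicate.
    """
    rows = [
        {"strain": r.strain, "replicate": r.replicate, "ecar": r.ecar}
        for r in results
    ]
    if not rows:
        raise ValueError("no ECAR results to aggregate")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("strain")["ecar"]
        .agg(mean_ecar="mean", sd_ecar=lambda s: s.std(ddof=1), n_replicates="count")
        .reset_index()
    )
    out["low_n"] = out["n_replicates"] < min_n
    return out


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab from the header line
    return pd.read_csv(path, sep=None, engine="python")


def read_calibration(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"ph", "a560"}.issubset(df.columns):
        raise ValueError(f"{path}: calibration table needs columns ph, a560")
    return df[["ph", "a560"]]


def read_layout(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    need = {"well", "strain", "condition", "replicate"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: layout table needs columns {sorted(need)}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"{path}: unknown conditions {sorted(bad)}")
    return df


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read plate kinetics in long (well, time_min, a560) or wide dialect.

    The wide dialect has one row per well and one column per timepoint, with
    numeric column headers giving the time in minutes; it is detected from the
    header and melted to long form.
    """
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    lower = [c.lower() for c in df.columns]
    if {"well", "time_min", "a560"}.issubset(lower):
        df.columns = lower
        return df[["well", "time_min", "a560"]].astype({"time_min": float, "a560": float})
    # wide: first column is the well id, remaining headers must parse as times
    well_col = df.columns[0]
    try:
        times = [float(c) for c in df.columns[1:]]
    except ValueError as err:
        raise ValueError(
            f"{path}: not long format (missing well/time_min/a560) and wide-format "
            f"headers are not numeric times"
        ) from err
    long = df.melt(id_vars=[well_col], var_name="time_min", value_name="a560")
    long = long.rename(columns={well_col: "well"})
    long["time_min"] = long["time_min"].astype(float)
    long["a560"] = long["a560"].astype(float)
    _ = times
    return long.sort_values(["well", "time_min"], kind="stable").reset_index(drop=True)


def wells_from_tables(plate: pd.DataFrame, layout: pd.DataFrame) -> list[WellSeries]:
    """Join kinetics with the plate layout into per-well series.

    Wells present in the kinetics but absent from the layout (or vice versa)
    are logged and skipped.
    """
    meta = layout.set_index("well")
    series: list[WellSeries] = []
    seen = set()
    for well, grp in plate.groupby("well", sort=True):
        seen.add(well)
        if well not in meta.index:
            logger.warning("well %s has kinetics but no layout entry; skipped", well)
            continue
        row = meta.loc[well]
        grp = grp.sort_values("time_min", kind="stable")
        series.append(
            WellSeries(
                well_id=str(well),
                strain=str(row["strain"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                time_min=grp["time_min"].to_numpy(),
                a560=grp["a560"].to_numpy(),
            )
        )
    for well in meta.index.difference(seen):
        logger.warning("well %s is in the layout but has no kinetics; skipped", well)
    return series


def process_plate(
    plate: pd.DataFrame,
    layout: pd.DataFrame,
    calibration: pd.DataFrame,
    window: tuple[float, float] | None = None,
    min_replicates: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: calibration fit, per-replicate ECAR, species trait table.

    Returns ``(ecar_table, trait_table)``.  Unpaired wells are reported and
    skipped rather than failing the run.
    """
    curve = fit_standard_curve(calibration)
    wells = wells_from_tables(plate, layout)
    by_key: dict[tuple[str, int, str], WellSeries] = {}
    for w in wells:
        key = (w.strain, w.replicate, w.condition)
        if key in by_key:
            raise ValueError(f"duplicate well for {key}: {by_key[key].well_id}, {w.well_id}")
        by_key[key] = w
    results: list[EcarResult] = []
    pairs = sorted({(s, r) for (s, r, _c) in by_key})
    for strain, rep in pairs:
        carbon = by_key.get((strain, rep, "carbon"))
        control = by_key.get((strain, rep, "control"))
        if carbon is None or control is None:
            missing = "carbon" if carbon is None else "control"
            logger.warning("%s replicate %d lacks a %s well; pair skipped", strain, rep, missing)
            continue
        results.append(dextrose_dependent_ecar(carbon, control, curve, window))
    ecar_df = pd.DataFrame(
        {
            "strain": [r.strain for r in results],
            "replicate": [r.replicate for r in results],
            "slope_carbon": [r.slope_carbon for r in results],
            "slope_control": [r.slope_control for r in results],
            "ecar": [r.ecar for r in results],
            "fit_r2_carbon": [r.fit_r2_carbon for r in results],
            "fit_r2_control": [r.fit_r2_control for r in results],
        }
    )
    trait_df = aggregate_replicates(results, min_n=min_replicates)
    return ecar_df, trait_df


def write_itol_color_strip(
    trait: pd.DataFrame,
    path: str | Path,
    dataset_label: str = "mean ECAR (pH/h)",
) -> None:
    """Export a species -> color annotation strip (iTOL COLORSTRIP dialect).

    Mean ECAR is mapped linearly onto a green gradient: the most negative
    (fastest-acidifying) species is brightest.
    """
    vals = trait["mean_ecar"].to_numpy(dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    span = hi - lo if hi > lo else 1.0
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#00a000",
        "DATA",
    ]
    for _, row in trait.iterrows():
        frac = (hi - float(row["mean_ecar"])) / span  # 1 = most rapid ECAR
        g = int(round(120 + 135 * frac))
        lines.append(f"{row['strain']}\t#{40:02x}{g:02x}{40:02x}")
    Path(path).write_text("\n".join(lines) + "\n")
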