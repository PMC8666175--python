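"""Assay figures of merit: LLOD, LLOQ, linearity, and CV components.

Characterizes a targeted assay per CPTAC-style validation practice:

* **LLOD** — back-calculated concentration at the blank mean + 3 SD signal
  threshold (n >= 3 blank matrix runs); when the blanks show no signal the
  threshold falls back to 3 SD of the lowest spiked level's signal.
* **LLOQ** — the lowest spiked concentration at which the replicate CV of
  the measured ratio is below 20%, requiring all higher levels to qualify
  as well so a noise dip cannot define a spurious LLOQ.
* **Linearity** — ordinary least squares of the mean measured ratio
  against nominal concentration; protein-level linearity first averages
  the ratios of the protein's peptides at each level.
* **CV components** — from the days x replicates design: intra-assay CV is
  the average over days of the within-day replicate CV; inter-assay CV is
  the average over injection index of that injection's across-day CV;
  total CV = sqrt(intra^2 + inter^2).  All CVs are SD/mean on the ratio
  scale, in percent.

Peptides are accepted when intra-, inter-, and total CV are all below the
threshold (default 20%) at every level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .srm_data import AssayReport, ValidationError
from .quantify import compute_ratios

__all__ = [
    "InsufficientDataError",
    "DegenerateCalibrationError",
    "LinearFit",
    "compute_llod",
    "compute_lloq",
    "fit_linearity",
    "compute_cv_components",
    "cv_components",
    "accept_peptides",
    "build_assay_report",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested figure of merit."""


class DegenerateCalibrationError(ValueError):
    """Calibration response cannot be inverted (non-positive slope)."""


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def inverse(self, signal: float) -> float:
        """Concentration at which the fitted line reaches ``signal``."""
        return (signal - self.intercept) / self.slope


def _cv_percent(x: np.ndarray) -> float:
    """Sample CV (SD/mean, ddof=1) in percent."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0:
        return np.nan
    return float(100.0 * x.std(ddof=1) / m)


def compute_llod(
    blank_areas,
    lowest_spike_areas,
    calibration: LinearFit,
) -> float:
    """Lower limit of detection in fmol.

    The signal threshold is mean(blank) + 3*SD(blank) over >= 3 blank
    matrix runs.  If no blank shows signal (all missing or zero), the
    threshold falls back to 3*SD of the lowest spiked level's signal (no
    mean term).  The threshold is mapped to concentration through the
    inverse of the calibration line and floored at 0.
    """
    blanks = np.asarray(pd.Series(blank_areas).dropna(), dtype=float)
    if len(blanks) < 3:
        raise InsufficientDataError(
            f"need >= 3 blank runs, got {len(blanks)}")
    if calibration.slope <= 0:
        raise DegenerateCalibrationError(
            f"calibration slope must be > 0, got {calibration.slope}")
    if np.all(blanks == 0):
        low = np.asarray(pd.Series(lowest_spike_areas).dropna(), dtype=float)
        if len(low) < 2:
            raise InsufficientDataError(
                "blank fallback needs >= 2 lowest-spike measurements")
        threshold = 3.0 * low.std(ddof=1)
    else:
        threshold = blanks.mean() + 3.0 * blanks.std(ddof=1)
    return max(0.0, calibration.inverse(threshold))


def compute_lloq(
    series: dict[float, "np.ndarray | list[float]"],
    threshold_percent: float = 20.0,
) -> float:
    """Lower limit of quantification in fmol.

    Returns the lowest level whose replicate CV is below the threshold
    *and* whose every higher level also qualifies; NaN when no level
    qualifies (not quantifiable).
    """
    levels = sorted(series)
    cvs = {}
    for lvl in levels:
        x = np.asarray(pd.Series(series[lvl]).dropna(), dtype=float)
        if len(x) < 2:
            raise InsufficientDataError(
                f"level {lvl:g}: need >= 2 replicates to compute a CV")
        cvs[lvl] = _cv_percent(x)
    lloq = np.nan
    for lvl in reversed(levels):
        if np.isnan(cvs[lvl]) or cvs[lvl] >= threshold_percent:
            break
        lloq = lvl
    return lloq


def fit_linearity(series: dict, scope: str = "peptide",
                  weighting: str | None = None) -> LinearFit:
    """Least-squares fit of measured response against nominal concentration.

    ``series`` maps level (fmol) to the replicate measurements at that
    level (peptide scope), or to a mapping peptide -> measurements
    (protein scope, which averages the peptides' mean ratios per level
    before fitting).  Needs >= 3 distinct levels.

    ``weighting="inverse_square"`` applies 1/x^2 weights — the standard
    choice for calibration curves whose noise is proportional to signal,
    where an unweighted fit lets the top levels swing the intercept.  R^2
    is always reported on the unweighted scale.
    """
    if scope not in ("peptide", "protein"):
        raise ValidationError(f"unknown scope {scope!r}")
    levels = sorted(series)
    if len(levels) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct levels, got {len(levels)}")
    y = []
    for lvl in levels:
        v = series[lvl]
        if scope == "protein" and isinstance(v, dict):
            means = [float(np.nanmean(np.asarray(x, dtype=float)))
                     for x in v.values()]
            y.append(float(np.nanmean(means)))
        else:
            y.append(float(np.nanmean(np.asarray(v, dtype=float))))
    x = np.asarray(levels, dtype=float)
    y = np.asarray(y, dtype=float)
    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "inverse_square":
        w = 1.0 / x ** 2
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return LinearFit(float(slope), float(intercept), float(r2))


def cv_components(values: np.ndarray) -> tuple[float, float, float]:
    """CV components from a days x replicates array of measurements.

    intra = mean over days of the within-day replicate CV; inter = mean
    over replicate index of that injection's across-day CV; total =
    sqrt(intra^2 + inter^2).  Missing cells (NaN) are tolerated as long as
    each retained axis slice keeps >= 2 values and >= 2 slices survive per
    axis.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValidationError("expected a 2-D days x replicates array")
    day_cvs = [_cv_percent(row[~np.isnan(row)])
               for row in v if (~np.isnan(row)).sum() >= 2]
    rep_cvs = [_cv_percent(col[~np.isnan(col)])
               for col in v.T if (~np.isnan(col)).sum() >= 2]
    if len(day_cvs) < 2:
        raise InsufficientDataError("fewer than 2 usable days")
    if len(rep_cvs) < 2:
        raise InsufficientDataError("fewer than 2 usable replicate series")
    intra = float(np.mean(day_cvs))
    inter = float(np.mean(rep_cvs))
    total = float(np.sqrt(intra ** 2 + inter ** 2))
    return intra, inter, total


def compute_cv_components(
    design_table: pd.DataFrame,
    level: float,
) -> tuple[float, float, float]:
    """CV components at one spike level of a replicate-design ratio table.

    ``design_table`` needs columns day_index, replicate_index, value and a
    spike_fmol column to select the level.
    """
    sub = design_table[design_table["spike_fmol"] == level]
    if sub.empty:
        raise InsufficientDataError(f"no measurements at level {level:g}")
    grid = sub.pivot_table(index="day_index", columns="replicate_index",
                           values="value", aggfunc="first", observed=True)
    return cv_components(grid.values)


def accept_peptides(
    report: AssayReport,
    threshold_percent: float = 20.0,
) -> set[str]:
    """Peptides whose intra-, inter-, and total CV are all below the
    threshold at every measured level.  Missing CVs disqualify."""
    accepted = set()
    cv_cols = [c for c in report.peptides.columns
               if c.startswith(("intra_cv_", "inter_cv_", "total_cv_"))]
    for _, row in report.peptides.iterrows():
        vals = row[cv_cols].astype(float)
        if len(vals) and vals.notna().all() and (vals < threshold_percent).all():
            accepted.add(row["peptide"])
    return accepted


def build_assay_report(
    calibration_table: pd.DataFrame,
    calibration_meta: pd.DataFrame,
    replicate_table: pd.DataFrame,
    replicate_meta: pd.DataFrame,
    peptide_to_protein: dict[str, str] | None = None,
    cv_threshold_percent: float = 20.0,
    excluded: pd.DataFrame | None = None,
) -> AssayReport:
    """Full per-peptide and per-protein assay characterization.

    Calibration runs titrate the heavy standard against a fixed light
    counterpart, so ratios are oriented heavy/light there; the response
    curve for LLOD inversion is the summed heavy area against nominal
    fmol.  Replicate-design CVs are computed on the heavy/light ratio.
    Protein figures: R^2 of the level-wise average of peptide ratios, and
    per-level total CV averaged over the protein's accepted peptides.
    """
    cal = compute_ratios(calibration_table, excluded=excluded,
                         orientation="heavy_over_light")
    cal = cal.merge(calibration_meta[["run_id", "run_type", "spike_fmol"]],
                    on="run_id")
    rep = compute_ratios(replicate_table, excluded=excluded,
                         orientation="heavy_over_light")
    rep = rep.merge(
        replicate_meta[["run_id", "spike_fmol", "day_index", "replicate_index"]],
        on="run_id")

    if peptide_to_protein is None:
        peptide_to_protein = dict(
            calibration_table[["peptide", "protein"]].drop_duplicates().values)

    cal_spiked = cal[cal["run_type"] == "calibration"]
    cal_blank = cal[cal["run_type"] == "blank"]
    levels = sorted(cal_spiked["spike_fmol"].unique())
    rep_levels = sorted(rep["spike_fmol"].unique())

    pep_rows = []
    pep_series: dict[str, dict[float, np.ndarray]] = {}
    for pep in sorted(peptide_to_protein):
        prot = peptide_to_protein[pep]
        mine = cal_spiked[cal_spiked["peptide"] == pep]
        # response curve: summed heavy area vs nominal fmol
        area_series = {lvl: mine.loc[mine["spike_fmol"] == lvl, "heavy_sum"].values
                       for lvl in levels}
        response = fit_linearity(area_series, weighting="inverse_square")
        blanks = cal_blank.loc[cal_blank["peptide"] == pep, "heavy_sum"]
        lowest = area_series[levels[0]]
        try:
            llod = compute_llod(blanks, lowest, response)
        except (InsufficientDataError, DegenerateCalibrationError):
            llod = np.nan
        ratio_series = {lvl: mine.loc[mine["spike_fmol"] == lvl, "ratio"].values
                        for lvl in levels}
        pep_series[pep] = ratio_series
        try:
            lloq = compute_lloq(ratio_series, cv_threshold_percent)
        except InsufficientDataError:
            lloq = np.nan
        linfit = fit_linearity(ratio_series)

        row = dict(protein=prot, peptide=pep, llod_fmol=llod, lloq_fmol=lloq,
                   r_squared=linfit.r_squared,
                   lloq_below_llod=bool(np.isfinite(lloq) and np.isfinite(llod)
                                        and lloq < llod))
        mine_rep = rep[rep["peptide"] == pep].rename(columns={"ratio": "value"})
        for lvl in rep_levels:
            try:
                intra, inter, total = compute_cv_components(mine_rep, lvl)
            except InsufficientDataError:
                intra = inter = total = np.nan
            row[f"intra_cv_{lvl:g}"] = intra
            row[f"inter_cv_{lvl:g}"] = inter
            row[f"total_cv_{lvl:g}"] = total
        pep_rows.append(row)

    peptides = pd.DataFrame(pep_rows)
    report = AssayReport(peptides=peptides, proteins=pd.DataFrame())
    accepted = accept_peptides(report, cv_threshold_percent)
    peptides["accepted"] = peptides["peptide"].isin(accepted)

    prot_rows = []
    for prot in sorted(set(peptide_to_protein.values())):
        peps = [p for p, pr in peptide_to_protein.items() if pr == prot]
        series = {lvl: {p: pep_series[p][lvl] for p in peps if p in pep_series}
                  for lvl in levels}
        try:
            pr2 = fit_linearity(series, scope="protein").r_squared
        except InsufficientDataError:
            pr2 = np.nan
        row = dict(protein=prot, protein_r_squared=pr2)
        acc = peptides[(peptides["protein"] == prot) & peptides["accepted"]]
        for lvl in rep_levels:
            col = f"total_cv_{lvl:g}"
            row[f"protein_total_cv_{lvl:g}"] = (
                float(acc[col].mean()) if len(acc) and acc[col].notna().any()
                else np.nan)
        prot_rows.append(row)

    report.proteins = pd.DataFrame(prot_rows)
    return report
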