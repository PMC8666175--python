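"""Ratio computation, interference exclusion, normalization, and rollup.

The quantitative signal of a targeted assay is the ratio of the light
(endogenous or synthetic unlabeled) to the heavy (stable-isotope-labeled
internal standard) peak area, summed over a peptide's usable transitions.
Because every transition of a peptide measures the same molecule, a
transition whose light/heavy ratio deviates sharply from its siblings is
carrying interfering signal and is excluded.

Downstream, log2 ratios are normalized for run-level technical effects
estimated from the heavy internal standards (spiked at constant amount, so
any run-to-run movement of their areas is technical), and peptide
abundances are aggregated into protein estimators by weighted sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .srm_data import ValidationError

__all__ = [
    "flag_interference",
    "compute_ratios",
    "normalize",
    "rollup",
]


def flag_interference(
    table: pd.DataFrame,
    fold_tolerance: float = 2.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Flag transitions whose light/heavy ratio disagrees with siblings.

    For each (run, peptide), the per-fragment light/heavy ratio is compared
    with the within-peptide median ratio; a fragment deviating by more than
    ``fold_tolerance`` in either direction is excluded.  At least one
    transition is always retained.  Peptides measured with a single
    transition have nothing to compare against and are returned unflagged
    with a warning.

    Returns
    -------
    (excluded, warnings)
        ``excluded`` has columns run_id, peptide, fragment, reason.
    """
    if fold_tolerance <= 1:
        raise ValidationError("fold_tolerance must be > 1")
    records = []
    warn: list[str] = []
    wide = table.pivot_table(
        index=["run_id", "peptide", "fragment"], columns="label",
        values="area", aggfunc="first", observed=True,
    )
    for (run, pep), grp in wide.groupby(level=["run_id", "peptide"], observed=True):
        frags = grp.index.get_level_values("fragment")
        if len(frags) < 2:
            warn.append(f"{run}/{pep}: single transition, interference check skipped")
            continue
        light = grp.get("light", pd.Series(index=grp.index, dtype=float))
        heavy = grp.get("heavy", pd.Series(index=grp.index, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.asarray(light, dtype=float) / np.asarray(heavy, dtype=float)
        ok = np.isfinite(ratio) & (ratio > 0)
        if ok.sum() < 2:
            continue
        med = float(np.median(ratio[ok]))
        dev = np.where(ok, np.maximum(ratio / med, med / ratio), np.nan)
        flag = ok & (dev > fold_tolerance)
        if flag.sum() >= ok.sum():  # never exclude every usable transition
            keep = int(np.nanargmin(dev))
            flag[keep] = False
        for f, fl in zip(frags, flag):
            if fl:
                records.append(dict(run_id=run, peptide=pep, fragment=f,
                                    reason="interference"))
    excluded = pd.DataFrame(records, columns=["run_id", "peptide", "fragment", "reason"])
    return excluded, warn


def compute_ratios(
    table: pd.DataFrame,
    excluded: pd.DataFrame | None = None,
    orientation: str = "light_over_heavy",
) -> pd.DataFrame:
    """Summed-transition peptide ratios per run.

    The peptide ratio is sum(light areas over used transitions) /
    sum(heavy areas over used transitions) — area-weighted, so strong
    transitions dominate and weak-transition noise is damped.  Calibration
    experiments, where the heavy standard is the titrated analyte, may set
    ``orientation="heavy_over_light"``.

    A fragment is *used* when both labels have a non-missing area and it is
    not listed in ``excluded``.  A zero (or absent) denominator yields a
    missing ratio with a reason code rather than an error.

    Returns a DataFrame with one row per (run_id, peptide): protein,
    light_sum, heavy_sum, ratio, log2_ratio, transitions_used, n_excluded,
    reason.
    """
    if orientation not in ("light_over_heavy", "heavy_over_light"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    excl_keys: set[tuple] = set()
    if excluded is not None and len(excluded):
        excl_keys = set(zip(excluded["run_id"], excluded["peptide"],
                            excluded["fragment"]))

    wide = table.pivot_table(
        index=["run_id", "protein", "peptide", "fragment"], columns="label",
        values="area", aggfunc="first", observed=True,
    ).reset_index()
    for col in ("light", "heavy"):
        if col not in wide.columns:
            wide[col] = np.nan

    rows = []
    for (run, prot, pep), grp in wide.groupby(
            ["run_id", "protein", "peptide"], observed=True, sort=True):
        n_total = len(grp)
        keys = list(zip([run] * n_total, [pep] * n_total, grp["fragment"]))
        is_excl = np.array([k in excl_keys for k in keys])
        both = grp["light"].notna().values & grp["heavy"].notna().values
        used = both & ~is_excl
        n_used = int(used.sum())
        light_sum = float(grp.loc[used, "light"].sum()) if n_used else np.nan
        heavy_sum = float(grp.loc[used, "heavy"].sum()) if n_used else np.nan
        reason = ""
        if n_used == 0:
            ratio = np.nan
            if not grp["light"].notna().any():
                reason = "no_light_signal"
            elif not grp["heavy"].notna().any():
                reason = "no_heavy_signal"
            else:
                reason = "no_usable_transitions"
        else:
            num, den = (light_sum, heavy_sum)
            if orientation == "heavy_over_light":
                num, den = den, num
            if den == 0:
                ratio = np.nan
                reason = ("zero_heavy_sum" if orientation == "light_over_heavy"
                          else "zero_light_sum")
            else:
                ratio = num / den
        log2_ratio = np.log2(ratio) if (np.isfinite(ratio) and ratio > 0) else np.nan
        rows.append(dict(run_id=run, protein=prot, peptide=pep,
                         light_sum=light_sum, heavy_sum=heavy_sum,
                         ratio=ratio, log2_ratio=log2_ratio,
                         transitions_used=n_used,
                         n_excluded=n_total - n_used,
                         reason=reason))
    out = pd.DataFrame(rows)
    return out


@dataclass
class NormalizationResult:
    """Normalized log2 peptide abundances plus the per-run technical
    factors that were removed."""

    values: pd.DataFrame        # runs x peptides, normalized log2 ratios
    run_factors: pd.Series      # log2 technical factor per run
    warnings: list[str]


def normalize(
    ratio_table: pd.DataFrame,
    method: str = "median",
    min_peptides: int = 3,
) -> NormalizationResult:
    """Remove run-level technical effects using the heavy standards.

    The heavy peptides are spiked at a constant amount, so the run factor
    t_r is estimated from their areas: the median over peptides of
    (log2 heavy area in run r − that peptide's across-run mean log2 heavy
    area).  Each run's log2 ratios are shifted by −t_r, which levels the
    heavy standards across runs.  ``method="linear_model"`` replaces the
    median with the least-squares two-way (run + peptide) fit of the log2
    heavy areas, whose run coefficients equal per-run means of the same
    residuals.

    Runs with fewer than ``min_peptides`` heavy observations keep a factor
    of 0 and are reported in the warnings.
    """
    if method not in ("median", "linear_model"):
        raise ValidationError(f"unknown normalization method {method!r}")
    heavy = ratio_table.pivot_table(index="run_id", columns="peptide",
                                    values="heavy_sum", aggfunc="first",
                                    observed=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_heavy = np.log2(heavy.where(heavy > 0))
    centered = log_heavy - log_heavy.mean(axis=0)
    warn: list[str] = []
    factors = {}
    for run in centered.index:
        row = centered.loc[run].dropna()
        if len(row) < min_peptides:
            warn.append(f"run {run}: only {len(row)} heavy observations, "
                        f"factor set to 0")
            factors[run] = 0.0
        elif method == "median":
            factors[run] = float(row.median())
        else:
            factors[run] = float(row.mean())
    run_factors = pd.Series(factors, name="run_factor")

    ratios = ratio_table.pivot_table(index="run_id", columns="peptide",
                                     values="log2_ratio", aggfunc="first",
                                     observed=True)
    normalized = ratios.sub(run_factors.reindex(ratios.index).fillna(0.0), axis=0)
    return NormalizationResult(values=normalized, run_factors=run_factors,
                               warnings=warn)


def rollup(
    peptide_values: pd.DataFrame,
    peptide_to_protein: dict[str, str],
    scheme: str = "inverse_variance",
) -> "ProteinAbundanceMatrix":
    """Aggregate peptide log2 abundances into protein estimators.

    Protein value per sample = sum of w_p * peptide_p over the protein's
    non-missing peptides, with weights renormalized to sum to 1 in every
    sample (so adding a constant to all of a protein's peptides adds the
    same constant to the protein).  ``inverse_variance`` weights each
    peptide by 1/var of its centered values across samples — the
    minimum-variance linear combination when peptide errors are
    independent; ``equal`` weights uniformly.  A protein with no
    non-missing peptide in a sample yields a missing cell.
    """
    from .srm_data import ProteinAbundanceMatrix

    if scheme not in ("inverse_variance", "equal"):
        raise ValidationError(f"unknown rollup scheme {scheme!r}")
    missing = [p for p in peptide_values.columns if p not in peptide_to_protein]
    if missing:
        raise ValidationError(f"peptides without protein mapping: {missing[:5]}")

    proteins: dict[str, list[str]] = {}
    for pep in peptide_values.columns:
        proteins.setdefault(peptide_to_protein[pep], []).append(pep)

    out = {}
    provenance: dict[str, dict[str, float]] = {}
    for prot, peps in proteins.items():
        sub = peptide_values[peps]
        if scheme == "equal" or len(peps) == 1:
            w = np.ones(len(peps))
        else:
            # variance of the peptide's centered trajectory across samples
            var = sub.sub(sub.mean(axis=0), axis=1).var(axis=0, ddof=1).values
            var = np.where((var > 0) & np.isfinite(var), var, np.nan)
            if np.isnan(var).all():
                w = np.ones(len(peps))
            else:
                fill = np.nanmax(var)
                w = 1.0 / np.where(np.isnan(var), fill, var)
        w = w / w.sum()
        provenance[prot] = {p: float(x) for p, x in zip(peps, w)}
        wmat = np.tile(w, (len(sub), 1))
        wmat = np.where(sub.notna().values, wmat, 0.0)
        wsum = wmat.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.nansum(wmat * sub.values, axis=1) / wsum
        vals[wsum == 0] = np.nan
        out[prot] = vals
    values = pd.DataFrame(out, index=peptide_values.index)
    values.index.name = "sample_id"
    return ProteinAbundanceMatrix(values=values, provenance=provenance)
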