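"""Synthetic SRM/MRM experiment generator with known ground truth.

Emulates the three experiment classes of a CPTAC-style assay
characterization and its clinical application, so every downstream stage
can be tested against known truth:

* a calibration (dilution) series — heavy stable-isotope-labeled (SIL)
  peptides spiked at 0.5–1000 fmol with the light counterpart fixed at
  100 fmol, plus blank matrix runs;
* a repeatability design — 3 injection replicates x 5 days at 5/50/500 fmol
  heavy with 30 fmol fixed light, carrying separate within-day and
  between-day variance components;
* a clinical cohort — 28 control / 15 cirrhosis / 19 hepatocellular
  carcinoma (HCC) samples in which two disjoint protein clusters move in
  opposite directions, with cirrhosis as an intermediate state.

Noise model: peak areas are multiplicative-lognormal around the expected
response (concentration-dependent CV, inflating toward the detection
limit) plus a zero-mean additive residual; blank signal is drawn from a
background distribution truncated at zero.  Spiked-run areas are treated
as background-subtracted (Skyline-style), so the blank distribution enters
blank runs only.  The lognormal is a stand-in: the distributional form of
real SRM measurement noise is not identified by the experiments emulated
here.

All generators take an explicit seed; there is no global random state.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .srm_data import TRANSITION_COLUMNS, METADATA_COLUMNS, ValidationError

__all__ = [
    "GroundTruth",
    "CohortDesign",
    "PANEL_PROTEINS",
    "default_ground_truth",
    "default_cohort_design",
    "generate_calibration",
    "generate_replicate_design",
    "generate_cohort",
]

# The 13 one-carbon-metabolism enzymes monitored by the assay.
PANEL_PROTEINS = [
    "GNMT", "AHCY", "CBS", "CGL", "DHFR", "MAT1A", "MAT2A",
    "MAT2B", "MTAP", "BHMT", "SHMT1", "SHMT2", "METH",
]

# Proteins enriched in normal liver (cluster 1) vs ubiquitously expressed
# enzymes upregulated in HCC (cluster 2).
CLUSTER1 = ["GNMT", "CBS", "CGL", "MAT1A", "BHMT", "SHMT1", "SHMT2"]
CLUSTER2 = ["AHCY", "DHFR", "MAT2A", "MAT2B", "MTAP", "METH"]

DEFAULT_LEVELS = (0.5, 1.0, 4.0, 10.0, 50.0, 100.0, 500.0, 1000.0)

_PANEL_SEED = 19731211  # fixes the synthetic peptide panel itself


def _synthetic_peptides() -> dict[str, str]:
    """Deterministic synthetic tryptic peptide panel: 40 peptides over the
    13 proteins (4 for GNMT, 3 each for the rest), 8-25 residues, ending in
    K/R as a tryptic peptide would."""
    rng = np.random.default_rng(_PANEL_SEED)
    interior = list("ACDEFGHILNQSTVY")  # no K/R/P interior, no M/W
    peptide_to_protein: dict[str, str] = {}
    for protein in PANEL_PROTEINS:
        n_pep = 4 if protein == "GNMT" else 3
        for _ in range(n_pep):
            while True:
                length = int(rng.integers(8, 18))
                body = "".join(rng.choice(interior, size=length - 1))
                pep = body + ("K" if rng.random() < 0.5 else "R")
                if pep not in peptide_to_protein:
                    break
            peptide_to_protein[pep] = protein
    return peptide_to_protein


@dataclass
class GroundTruth:
    """Simulated counterparts of every measured quantity.

    Attributes
    ----------
    peptide_to_protein : mapping peptide -> protein (each peptide unique to
        one protein, as a proteotypic surrogate must be).
    slope : per-peptide response, area units per fmol (> 0).
    transition_fractions : per peptide, fragment-ion label -> fraction of
        the peptide signal carried by that transition (fractions sum to 1).
    background_mean, background_sd : blank-signal distribution, area units.
    spiked_residual_sd : SD of the zero-mean additive residual on
        background-subtracted spiked-run areas.
    cv_at_level : spike concentration (fmol) -> multiplicative noise CV.
    intra_cv, inter_cv : within-day and between-day variance components of
        the replicate design, as fractions.
    protein_baseline : clinical-cohort log2 baseline abundance per protein.
    condition_effects : protein -> {"cirrhosis": d1, "HCC": d2} log2
        fold-changes vs control.
    peptide_offset_sd : SD of per-peptide log2 offsets around the protein
        baseline (ionization-efficiency spread).
    cohort_noise_sd : residual log2 measurement noise per clinical sample.
    """

    peptide_to_protein: dict[str, str]
    slope: dict[str, float]
    transition_fractions: dict[str, dict[str, float]]
    background_mean: float = 1000.0
    background_sd: float = 900.0
    spiked_residual_sd: float = 50.0
    cv_at_level: dict[float, float] = field(default_factory=dict)
    intra_cv: float = 0.05
    inter_cv: float = 0.08
    protein_baseline: dict[str, float] = field(default_factory=dict)
    condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    peptide_offset_sd: float = 0.3
    cohort_noise_sd: float = 0.5

    def __post_init__(self):
        for pep, s in self.slope.items():
            if s <= 0:
                raise ValidationError(f"slope for {pep} must be > 0")
        for lvl, cv in self.cv_at_level.items():
            if cv < 0:
                raise ValidationError(f"cv_at_level[{lvl}] must be >= 0")
        proteins = set(self.peptide_to_protein.values())
        for prot in self.condition_effects:
            if prot not in proteins:
                raise ValidationError(f"condition effect for unknown protein {prot}")

    @property
    def peptides(self) -> list[str]:
        return list(self.peptide_to_protein)

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for prot in self.peptide_to_protein.values():
            seen.setdefault(prot)
        return list(seen)

    def cv_for_level(self, level: float) -> float:
        """CV at a spike level, log-linearly interpolated between the
        configured anchor levels (constant extrapolation outside)."""
        if not self.cv_at_level:
            return 0.0
        if level in self.cv_at_level:
            return self.cv_at_level[level]
        lv = np.array(sorted(self.cv_at_level))
        cv = np.array([self.cv_at_level[x] for x in lv])
        return float(np.interp(np.log(level), np.log(lv), cv))

    def to_dict(self) -> dict:
        return {
            "peptide_to_protein": dict(self.peptide_to_protein),
            "slope": {k: float(v) for k, v in self.slope.items()},
            "transition_fractions": {
                p: {f: float(x) for f, x in d.items()}
                for p, d in self.transition_fractions.items()
            },
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "spiked_residual_sd": self.spiked_residual_sd,
            "cv_at_level": {float(k): float(v) for k, v in self.cv_at_level.items()},
            "intra_cv": self.intra_cv,
            "inter_cv": self.inter_cv,
            "protein_baseline": dict(self.protein_baseline),
            "condition_effects": {k: dict(v) for k, v in self.condition_effects.items()},
            "peptide_offset_sd": self.peptide_offset_sd,
            "cohort_noise_sd": self.cohort_noise_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        d = dict(d)
        d["cv_at_level"] = {float(k): float(v) for k, v in d.get("cv_at_level", {}).items()}
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortDesign:
    """Clinical cohort layout: class sizes and the two protein clusters
    with opposite regulation."""

    n_control: int = 28
    n_cirrhosis: int = 15
    n_hcc: int = 19
    cluster1: tuple[str, ...] = tuple(CLUSTER1)
    cluster2: tuple[str, ...] = tuple(CLUSTER2)

    def __post_init__(self):
        if min(self.n_control, self.n_cirrhosis, self.n_hcc) < 2:
            raise ValidationError("each condition needs at least 2 samples")
        if set(self.cluster1) & set(self.cluster2):
            raise ValidationError("protein clusters must be disjoint")

    def to_dict(self) -> dict:
        return {
            "n_control": self.n_control,
            "n_cirrhosis": self.n_cirrhosis,
            "n_hcc": self.n_hcc,
            "cluster1": list(self.cluster1),
            "cluster2": list(self.cluster2),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortDesign":
        d = dict(d)
        d["cluster1"] = tuple(d.get("cluster1", CLUSTER1))
        d["cluster2"] = tuple(d.get("cluster2", CLUSTER2))
        return cls(**d)


def default_ground_truth(
    hcc_effect: float = 1.0,
    cirrhosis_fraction: float = 0.5,
    cohort_noise_sd: float = 0.5,
) -> GroundTruth:
    """Ground truth for the default 13-protein / 40-peptide panel.

    Response slopes are spread lognormally around 2000 area units/fmol;
    multiplicative CV grows toward low concentrations; the blank background
    is set so the blank mean + 3 SD threshold back-calculates to roughly
    0.5–4 fmol across peptides.  Cluster-1 proteins go down and cluster-2
    proteins up in HCC by ``hcc_effect`` log2 units, with cirrhosis at
    ``cirrhosis_fraction`` of the way (an intermediate, pre-tumoral state).
    """
    rng = np.random.default_rng(_PANEL_SEED + 1)
    peptide_to_protein = _synthetic_peptides()
    slope = {p: float(2000.0 * rng.lognormal(0.0, 0.35))
             for p in peptide_to_protein}
    fragments = ["y5", "y6", "y7"]
    transition_fractions = {}
    for p in peptide_to_protein:
        w = rng.dirichlet([6.0, 4.0, 2.0])
        transition_fractions[p] = {f: float(x) for f, x in zip(fragments, w)}
    cv_at_level = {0.5: 0.10, 1.0: 0.08, 4.0: 0.06, 10.0: 0.05,
                   50.0: 0.04, 100.0: 0.04, 500.0: 0.03, 1000.0: 0.03}
    protein_baseline = {prot: float(rng.normal(10.0, 1.5)) for prot in PANEL_PROTEINS}
    condition_effects = {}
    for prot in PANEL_PROTEINS:
        if prot in CLUSTER1:
            d = -hcc_effect
        elif prot in CLUSTER2:
            d = +hcc_effect
        else:
            d = 0.0
        condition_effects[prot] = {"cirrhosis": d * cirrhosis_fraction, "HCC": d}
    return GroundTruth(
        peptide_to_protein=peptide_to_protein,
        slope=slope,
        transition_fractions=transition_fractions,
        cv_at_level=cv_at_level,
        protein_baseline=protein_baseline,
        condition_effects=condition_effects,
        cohort_noise_sd=cohort_noise_sd,
    )


def default_cohort_design() -> CohortDesign:
    return CohortDesign()


def _truncated_background(rng, mean, sd, size):
    """Draws from Normal(mean, sd) truncated at 0 (rejection sampling)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    n = int(np.prod(size)) if np.ndim(size) else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[draw >= 0]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out.reshape(size)


def _retention_time(pep: str) -> float:
    """Stable pseudo retention time (minutes) from the peptide string."""
    return 10.0 + 40.0 * (zlib.crc32(pep.encode()) % 1000) / 1000.0


def _sigma_log(cv: float) -> float:
    """Log-scale SD giving a lognormal with the requested CV."""
    return float(np.sqrt(np.log1p(cv ** 2)))


def generate_calibration(
    truth: GroundTruth,
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_blanks: int = 3,
    n_replicates: int = 3,
    counterpart_fmol: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the dilution series plus blank matrix runs.

    Heavy (SIL) peptides are spiked at each level with ``n_replicates``
    replicate runs per level; light counterparts sit at a fixed
    ``counterpart_fmol`` (100 fmol by default).  The multiplicative
    lognormal noise draw is shared across a peptide's transitions within a
    run (injection/ionization noise acts at the precursor level), with a
    small independent additive residual per transition.  Blank runs carry
    background signal only.

    Returns (transition table, run metadata); identical seed, identical
    output.
    """
    levels = [float(x) for x in levels]
    if any(x <= 0 for x in levels) or sorted(levels) != levels:
        raise ValidationError("levels must be positive and sorted ascending")
    if n_blanks < 3:
        raise ValidationError("need at least 3 blank runs")
    rng = np.random.default_rng(seed)
    rows = []
    meta = []
    for level in levels:
        for rep in range(1, n_replicates + 1):
            run_id = f"cal_{level:g}fmol_r{rep}"
            meta.append(dict(run_id=run_id, run_type="calibration",
                             spike_fmol=level, counterpart_fmol=counterpart_fmol,
                             replicate_index=rep, day_index=np.nan,
                             sample_id=np.nan, condition=np.nan))
            for pep, prot in truth.peptide_to_protein.items():
                rt = _retention_time(pep)
                for label, amount in (("heavy", level), ("light", counterpart_fmol)):
                    cv = truth.cv_for_level(amount)
                    noise = rng.lognormal(-0.5 * _sigma_log(cv) ** 2, _sigma_log(cv))
                    for frag, fracw in truth.transition_fractions[pep].items():
                        expected = truth.slope[pep] * fracw * amount
                        area = expected * noise + rng.normal(0, truth.spiked_residual_sd)
                        rows.append((run_id, prot, pep, 2, frag, label, rt,
                                     max(area, 0.0)))
    for b in range(1, n_blanks + 1):
        run_id = f"blank_{b}"
        meta.append(dict(run_id=run_id, run_type="blank", spike_fmol=0.0,
                         counterpart_fmol=0.0, replicate_index=b,
                         day_index=np.nan, sample_id=np.nan, condition=np.nan))
        for pep, prot in truth.peptide_to_protein.items():
            rt = _retention_time(pep)
            for label in ("heavy", "light"):
                fracs = truth.transition_fractions[pep]
                bg = _truncated_background(rng, truth.background_mean,
                                           truth.background_sd, len(fracs))
                for (frag, fracw), s in zip(fracs.items(), bg):
                    rows.append((run_id, prot, pep, 2, frag, label, rt,
                                 float(s * fracw)))
    table = pd.DataFrame(rows, columns=TRANSITION_COLUMNS)
    metadata = pd.DataFrame(meta, columns=METADATA_COLUMNS)
    return table, metadata


def generate_replicate_design(
    truth: GroundTruth,
    levels: Sequence[float] = (5.0, 50.0, 500.0),
    light_fmol: float = 30.0,
    days: int = 5,
    reps_per_day: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the repeatability design: ``reps_per_day`` injections on
    each of ``days`` days at each heavy spike level, light fixed.

    The heavy area decomposes as expected x exp(day effect) x exp(replicate
    noise) with the day effect ~ Normal(0, sigma(inter_cv)) per (peptide,
    level, day) and replicate noise ~ Normal(0, sigma(intra_cv)) per
    injection, both on the log scale.  Light areas are noise-free so the
    heavy/light ratio carries exactly the two configured variance
    components.
    """
    if days < 2 or reps_per_day < 2:
        raise ValidationError("need at least 2 days and 2 replicates per day")
    levels = [float(x) for x in levels]
    if any(x <= 0 for x in levels):
        raise ValidationError("levels must be positive")
    rng = np.random.default_rng(seed)
    s_intra = _sigma_log(truth.intra_cv)
    s_inter = _sigma_log(truth.inter_cv)
    rows = []
    meta = []
    peps = truth.peptides
    for level in levels:
        day_eff = rng.normal(0.0, s_inter, size=(len(peps), days))
        rep_eff = rng.normal(0.0, s_intra, size=(len(peps), days, reps_per_day))
        for d in range(days):
            for r in range(reps_per_day):
                run_id = f"rep_{level:g}fmol_d{d + 1}_r{r + 1}"
                meta.append(dict(run_id=run_id, run_type="replicate_design",
                                 spike_fmol=level, counterpart_fmol=light_fmol,
                                 replicate_index=r + 1, day_index=d + 1,
                                 sample_id=np.nan, condition=np.nan))
                for i, pep in enumerate(peps):
                    prot = truth.peptide_to_protein[pep]
                    rt = _retention_time(pep)
                    mult = float(np.exp(day_eff[i, d] + rep_eff[i, d, r]))
                    for frag, fracw in truth.transition_fractions[pep].items():
                        heavy = truth.slope[pep] * fracw * level * mult
                        light = truth.slope[pep] * fracw * light_fmol
                        rows.append((run_id, prot, pep, 2, frag, "heavy", rt, heavy))
                        rows.append((run_id, prot, pep, 2, frag, "light", rt, light))
    table = pd.DataFrame(rows, columns=TRANSITION_COLUMNS)
    # keep metadata grouped by run in generation order
    metadata = pd.DataFrame(meta, columns=METADATA_COLUMNS)
    return table, metadata


def generate_cohort(
    design: CohortDesign,
    truth: GroundTruth,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate normalized log2 peptide abundances for the clinical cohort.

    Each sample/peptide cell is protein baseline + condition effect +
    peptide offset + Normal(0, cohort_noise_sd).  Peptides inherit their
    protein's condition effect exactly (a proteotypic peptide is a pure
    surrogate of its protein).

    Returns (samples x peptides DataFrame of log2 abundances, run
    metadata with one clinical run per sample).
    """
    proteins = set(truth.proteins)
    for prot in tuple(design.cluster1) + tuple(design.cluster2):
        if prot not in proteins:
            raise ValidationError(f"cluster protein {prot} not in ground truth")
    for prot in proteins:
        if prot not in truth.condition_effects:
            raise ValidationError(f"no condition effects configured for {prot}")
    rng = np.random.default_rng(seed)
    samples = (
        [(f"ctrl_{i + 1:02d}", "control") for i in range(design.n_control)]
        + [(f"cirr_{i + 1:02d}", "cirrhosis") for i in range(design.n_cirrhosis)]
        + [(f"hcc_{i + 1:02d}", "HCC") for i in range(design.n_hcc)]
    )
    peps = truth.peptides
    offsets = rng.normal(0.0, truth.peptide_offset_sd, size=len(peps))
    values = np.empty((len(samples), len(peps)))
    for j, pep in enumerate(peps):
        prot = truth.peptide_to_protein[pep]
        base = truth.protein_baseline.get(prot, 10.0) + offsets[j]
        for i, (_, cond) in enumerate(samples):
            eff = 0.0 if cond == "control" else truth.condition_effects[prot][cond]
            values[i, j] = base + eff
    values += rng.normal(0.0, truth.cohort_noise_sd, size=values.shape)
    table = pd.DataFrame(values, index=[s for s, _ in samples], columns=peps)
    table.index.name = "sample_id"
    meta = pd.DataFrame(
        dict(
            run_id=[f"clin_{s}" for s, _ in samples],
            run_type="clinical",
            spike_fmol=np.nan,
            counterpart_fmol=np.nan,
            replicate_index=np.nan,
            day_index=np.nan,
            sample_id=[s for s, _ in samples],
            condition=[c for _, c in samples],
        ),
        columns=METADATA_COLUMNS,
    )
    return table, meta
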