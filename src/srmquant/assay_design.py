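"""In-silico tryptic digestion and proteotypic-peptide candidate selection.

A targeted SRM/MRM assay monitors a handful of *proteotypic* peptides per
protein: peptides that are observed reliably by MS and unique to one
protein.  Candidates come from two kinds of evidence — in-house shotgun
experiments (with a search-engine score) and public repositories — and are
filtered and ranked by a fixed rule set:

1. at most 4 peptides per protein;
2. candidates supported by both experimental and database evidence are
   preferred;
3. experimental candidates require a search-engine (Mascot-type) score
   above a threshold (default 28);
4. database-only candidates are admitted only when the protein has no
   MS-detected peptide at all;
5. length 8–25 residues;
6. no missed cleavages;
7. peptides containing easily modified residues (Met, Trp by default) are
   avoided when alternatives exist.

Cleavage follows the standard trypsin convention: after K or R, but not
when the next residue is P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .srm_data import AMINO_ACIDS, ValidationError

__all__ = [
    "PeptideCandidate",
    "SelectionConfig",
    "digest_trypsin",
    "select_candidates",
]


@dataclass(frozen=True)
class PeptideCandidate:
    """One candidate peptide for one protein.

    ``source`` records the evidence class: ``experimental`` (seen in-house
    by MS, must carry a score), ``database`` (public repositories only), or
    ``both``.
    """

    peptide: str
    protein: str
    source: str  # experimental | database | both
    evidence_score: float | None = None
    missed_cleavages: int = 0

    def __post_init__(self):
        if self.missed_cleavages < 0:
            raise ValidationError("missed_cleavages must be >= 0")
        if self.source not in ("experimental", "database", "both"):
            raise ValidationError(f"unknown evidence source {self.source!r}")
        if self.source == "experimental" and self.evidence_score is None:
            raise ValidationError("experimental candidate needs an evidence score")


@dataclass
class SelectionConfig:
    """Tunable knobs of the candidate filter.

    ``modifiable_residues`` implements the "avoid residues that might be
    modified" rule as a blacklist; Met and Trp (oxidation-prone) are the
    default.  N-terminal Gln/Glu cyclization is not modeled.
    """

    max_per_protein: int = 4
    min_length: int = 8
    max_length: int = 25
    min_score: float = 28.0
    max_missed_cleavages: int = 0
    modifiable_residues: frozenset[str] = frozenset("MW")


def digest_trypsin(sequence: str, max_missed: int = 0) -> list[tuple[str, int]]:
    """Digest a protein sequence with trypsin specificity.

    Cleaves C-terminal to K/R except when followed by P.  Returns
    ``(peptide, n_missed_cleavages)`` pairs for every missed-cleavage count
    up to ``max_missed``; a peptide with k missed cleavages is the
    concatenation of k+1 adjacent fully cleaved fragments.

    Raises
    ------
    ValidationError
        Naming the position of the first invalid residue.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    for i, res in enumerate(sequence):
        if res not in AMINO_ACIDS:
            raise ValidationError(f"invalid residue {res!r} at position {i + 1}")
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")

    fragments: list[str] = []
    start = 0
    for i, res in enumerate(sequence):
        if res in "KR" and i + 1 < len(sequence) and sequence[i + 1] != "P":
            fragments.append(sequence[start:i + 1])
            start = i + 1
    fragments.append(sequence[start:])

    out: list[tuple[str, int]] = []
    for k in range(max_missed + 1):
        for j in range(len(fragments) - k):
            out.append(("".join(fragments[j:j + k + 1]), k))
    return out


def _passes_hard_filters(c: PeptideCandidate, cfg: SelectionConfig) -> bool:
    if not (cfg.min_length <= len(c.peptide) <= cfg.max_length):
        return False
    if c.missed_cleavages > cfg.max_missed_cleavages:
        return False
    if c.source in ("experimental", "both") and (
        c.evidence_score is None or c.evidence_score <= cfg.min_score
    ):
        return False
    return True


_SOURCE_RANK = {"both": 0, "experimental": 1, "database": 2}


def select_candidates(
    candidates: Iterable[PeptideCandidate],
    config: SelectionConfig | None = None,
) -> dict[str, list[PeptideCandidate]]:
    """Apply the proteotypic selection rules per protein.

    Filter order: length window, missed cleavages, score threshold for
    MS-detected candidates; database-only candidates are admitted only for
    proteins with no surviving MS-detected peptide; peptides containing
    blacklisted residues are dropped when clean alternatives remain.
    Ranking prefers dual-evidence candidates, then higher scores, then the
    lexicographically smaller peptide (a deterministic total order), and
    truncates to the per-protein maximum.

    Returns a mapping protein -> ranked accepted candidates (an empty list
    is a legal outcome).
    """
    cfg = config or SelectionConfig()
    by_protein: dict[str, list[PeptideCandidate]] = {}
    for c in candidates:
        by_protein.setdefault(c.protein, []).append(c)

    selected: dict[str, list[PeptideCandidate]] = {}
    for protein in sorted(by_protein):
        raw = by_protein[protein]
        pool = [c for c in raw if _passes_hard_filters(c, cfg)]
        if any(c.source in ("experimental", "both") for c in raw):
            # database-only candidates admitted only when MS detected nothing
            pool = [c for c in pool if c.source != "database"]
        clean = [c for c in pool
                 if not (set(c.peptide) & cfg.modifiable_residues)]
        if clean:
            pool = clean  # modifiable residues avoided when alternatives exist
        pool.sort(key=lambda c: (
            _SOURCE_RANK[c.source],
            -(c.evidence_score if c.evidence_score is not None else float("-inf")),
            c.peptide,
        ))
        selected[protein] = pool[: cfg.max_per_protein]
    return selected
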