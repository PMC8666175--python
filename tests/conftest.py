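import numpy as np
import pytest

from srmquant import synthetic


def make_truth(
    n_proteins=2,
    peptides_per_protein=2,
    n_transitions=3,
    cv_at_level=None,
    background_mean=1000.0,
    background_sd=900.0,
    spiked_residual_sd=50.0,
    intra_cv=0.05,
    inter_cv=0.08,
    slope=2000.0,
    **kw,
):
    """Small hand-sized ground truth for fast tests."""
    rng = np.random.default_rng(7)
    frags = [f"y{5 + i}" for i in range(n_transitions)]
    pep_map, slopes, fracs = {}, {}, {}
    for i in range(n_proteins):
        prot = f"P{i + 1}"
        for j in range(peptides_per_protein):
            pep = "".join(rng.choice(list("ACDEFGHILNQSTVY"), size=9)) + "K"
            pep_map[pep] = prot
            slopes[pep] = float(slope * rng.lognormal(0, 0.2))
            w = np.full(n_transitions, 1.0 / n_transitions)
            fracs[pep] = {f: float(x) for f, x in zip(frags, w)}
    return synthetic.GroundTruth(
        peptide_to_protein=pep_map,
        slope=slopes,
        transition_fractions=fracs,
        background_mean=background_mean,
        background_sd=background_sd,
        spiked_residual_sd=spiked_residual_sd,
        cv_at_level=cv_at_level or {},
        intra_cv=intra_cv,
        inter_cv=inter_cv,
        protein_baseline={f"P{i + 1}": 10.0 for i in range(n_proteins)},
        condition_effects={f"P{i + 1}": {"cirrhosis": 0.0, "HCC": 0.0}
                           for i in range(n_proteins)},
        **kw,
    )


@pytest.fixture(scope="session")
def default_truth():
    return synthetic.default_ground_truth()


@pytest.fixture(scope="session")
def noise_free_truth():
    """Full 13-protein/40-peptide panel with all noise switched off."""
    t = synthetic.default_ground_truth()
    t.cv_at_level = {}
    t.spiked_residual_sd = 0.0
    t.background_sd = 0.0
    t.intra_cv = 0.0
    t.inter_cv = 0.0
    t.cohort_noise_sd = 0.0
    t.peptide_offset_sd = 0.0
    return t
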