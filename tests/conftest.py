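import numpy as np
import pytest

import beready as br


@pytest.fixture(scope="session")
def md_config():
    """Default development-cohort simulation configuration (72 genes,
    n = 18/18/17/10 across the four cycle phases)."""
    return br.default_md_like_config()


@pytest.fixture(scope="session")
def md_counts(md_config):
    """One simulated development cohort (fixed seed)."""
    m, truth = br.simulate_counts(md_config, seed=11)
    return m, truth


@pytest.fixture(scope="session")
def md_model(md_config, md_counts):
    """Reference model fitted on the simulated development cohort."""
    m, _ = md_counts
    return br.fit_reference(m, md_config.panel.housekeeper_ids, seed=12)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_panel():
    """Small panel (20-nt targets) including the genes named in the assay,
    two of them housekeepers."""
    rng = np.random.default_rng(402)
    genes = [("SDHA", True), ("TBP", True), ("OGT", False), ("TPM2", False),
             ("LEFTY1", False), ("CAMK2D", False)]
    return br.ProbePanel(
        [br.ProbeTarget(g, _random_seq(rng, 20), hk) for g, hk in genes]
    )


@pytest.fixture(scope="session")
def toy_layout(toy_panel):
    return br.ReadLayout.for_panel(toy_panel)


def make_read(panel, gene, umi1="ACGT", umi2="TTTT", mutate_at=()):
    """Build a [UMI][target][UMI] read, optionally mutating target bases
    at the given 0-based target positions (cyclic base substitution)."""
    seq = list(panel[gene].target_seq)
    for pos in mutate_at:
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return umi1 + "".join(seq) + umi2
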