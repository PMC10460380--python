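"""Phase-structured synthetic data with known ground truth.

No public count matrix or read set exists for this assay, so every other
module is exercised on simulated data whose truth is known by
construction.  The generator emulates the structure of the real study:

* a 72-gene panel — 4 housekeepers (SDHA, CYC1, TBP, HMBS), 11 named
  window-of-implantation genes, and 57 placeholder receptivity
  biomarkers standing in for the published biomarker set, whose gene
  symbols are not part of this package;
* four cycle-phase groups (PE, ESE, MSE, LSE) whose biomarker means
  follow a low-rank latent trajectory (3 factors), while housekeeper
  means are phase-constant so housekeeper normalization is the correct
  de-noising;
* negative-binomial molecule counts with a log-normal per-sample
  library-size factor;
* optionally, UMI-tagged reads per molecule with geometric PCR
  duplication and uniform per-base substitution errors, so the counting
  module can be checked against the simulated truth read-by-read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .panel_io import (
    PHASE_TO_CLASS,
    PHASES,
    CountMatrix,
    ProbePanel,
    ProbeTarget,
    ReadLayout,
)

HOUSEKEEPERS = ("SDHA", "CYC1", "TBP", "HMBS")
WOI_GENES = ("CAMK2D", "CAAP1", "FOXN2", "GGNBP2", "ICA1L", "LEFTY1",
             "OGT", "PPIP5K2", "RIC3", "TPM2", "YARS2")
N_PLACEHOLDER_BIOMARKERS = 57

#: Internal seed fixing the default panel sequences and latent structure,
#: independent of the simulation seed (the panel is a fixed artifact).
_PANEL_SEED = 20230826

#: Latent factor scores per phase (rows: PE, ESE, MSE, LSE).  Factor 1
#: tracks cycle progression; factors 2-3 add curvature so the phases are
#: separable but not collinear.
_PHASE_FACTORS = np.array(
    [
        [-1.5, 0.7, 0.3],
        [-0.7, -0.5, -0.3],
        [0.6, -0.6, 0.4],
        [1.6, 0.8, -0.4],
    ]
)


@dataclass
class ReadSimConfig:
    """Read-level noise model for FASTQ simulation."""

    mean_reads_per_molecule: float = 5.0
    per_base_error_rate: float = 0.0
    umi_len_each: int = 4
    umi_count: int = 2

    def __post_init__(self) -> None:
        if self.mean_reads_per_molecule < 1:
            raise ValueError("mean_reads_per_molecule must be >= 1")
        if not (0 <= self.per_base_error_rate < 1):
            raise ValueError("per_base_error_rate must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Everything needed to simulate a cohort."""

    panel: ProbePanel
    n_per_phase: dict[str, int]
    phase_means: pd.DataFrame          # genes x phases, expected molecule counts
    dispersion: pd.Series              # per-gene NB size parameter
    libsize_sigma: float = 0.15
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)

    def __post_init__(self) -> None:
        genes = self.panel.target_ids
        if list(self.phase_means.index) != genes:
            raise ValueError("phase_means rows must match panel target order")
        if set(self.phase_means.columns) != set(PHASES):
            raise ValueError(f"phase_means columns must be {PHASES}")
        hk = self.phase_means.loc[list(self.panel.housekeeper_ids)]
        if (hk.to_numpy() <= 0).any():
            raise ValueError("housekeeper means must be positive")
        if (self.dispersion.to_numpy() <= 0).any():
            raise ValueError("dispersion (NB size) must be positive")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_phase.values())


@dataclass
class GroundTruth:
    """Per-sample truth emitted alongside simulated data."""

    phase: pd.Series                   # sample -> PE/ESE/MSE/LSE
    reference_class: pd.Series         # sample -> reference class value
    libsize: pd.Series                 # sample -> library-size factor
    true_counts: pd.DataFrame          # samples x genes molecule counts

    def to_dict(self) -> dict:
        return {
            "phase": self.phase.to_dict(),
            "reference_class": self.reference_class.to_dict(),
            "libsize": self.libsize.to_dict(),
        }


def _random_panel(rng: np.random.Generator, seq_len: int = 50) -> ProbePanel:
    gene_ids = (
        list(HOUSEKEEPERS)
        + list(WOI_GENES)
        + [f"RB{i:02d}" for i in range(1, N_PLACEHOLDER_BIOMARKERS + 1)]
    )
    targets = []
    for gid in gene_ids:
        seq = "".join(rng.choice(list("ACGT"), size=seq_len))
        targets.append(ProbeTarget(gid, seq, gid in HOUSEKEEPERS))
    return ProbePanel(targets)


def default_md_like_config() -> SimulationConfig:
    """Default cohort configuration mirroring the development-set design:
    n = 18 (PE), 18 (ESE), 17 (MSE), 10 (LSE); 72-gene panel; biomarker
    phase means on a 3-factor latent trajectory with phase separation of
    at least 4 pooled standard deviations; housekeepers phase-constant.

    The panel sequences and latent loadings are fixed (internal seed), so
    the configuration is a constant artifact; only count/read sampling
    consumes the user's seed.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    panel = _random_panel(rng)
    genes = panel.target_ids
    n_genes = len(genes)
    is_hk = np.array([panel[g].is_housekeeper for g in genes])

    base = np.where(is_hk, 500.0, np.exp(rng.normal(np.log(150.0), 0.4, n_genes)))
    loadings = np.zeros((n_genes, 3))
    loadings[~is_hk, 0] = rng.normal(0.0, 0.55, (~is_hk).sum())
    loadings[~is_hk, 1] = rng.normal(0.0, 0.35, (~is_hk).sum())
    loadings[~is_hk, 2] = rng.normal(0.0, 0.25, (~is_hk).sum())
    log_shift = loadings @ _PHASE_FACTORS.T          # genes x phases
    means = base[:, None] * np.exp(log_shift)
    phase_means = pd.DataFrame(means, index=genes, columns=list(PHASES))
    dispersion = pd.Series(25.0, index=genes)
    return SimulationConfig(
        panel=panel,
        n_per_phase={"PE": 18, "ESE": 18, "MSE": 17, "LSE": 10},
        phase_means=phase_means,
        dispersion=dispersion,
        libsize_sigma=0.15,
        read_sim=ReadSimConfig(),
    )


def simulate_counts(cfg: SimulationConfig, seed: int | np.random.Generator | None = None,
                    cohort: str = "synthetic",
                    sample_prefix: str = "S") -> tuple[CountMatrix, GroundTruth]:
    """Draw a cohort of negative-binomial molecule counts.

    count[s, g] ~ NB(mean = L_s * phase_means[g, phase(s)], size =
    dispersion[g]) with L_s ~ LogNormal(0, libsize_sigma).  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    rows, phases, libs, ids = [], [], [], []
    i = 0
    for phase in PHASES:
        for _ in range(cfg.n_per_phase.get(phase, 0)):
            i += 1
            sid = f"{sample_prefix}{i:03d}"
            L = float(np.exp(rng.normal(0.0, cfg.libsize_sigma))) \
                if cfg.libsize_sigma > 0 else 1.0
            mu = L * cfg.phase_means[phase].to_numpy()
            size = cfg.dispersion.to_numpy()
            p = size / (size + mu)
            rows.append(rng.negative_binomial(size, p))
            phases.append(phase)
            libs.append(L)
            ids.append(sid)
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                          columns=cfg.panel.target_ids)
    meta = pd.DataFrame({"phase": phases, "cohort": cohort}, index=counts.index)
    truth = GroundTruth(
        phase=pd.Series(phases, index=counts.index),
        reference_class=pd.Series(
            [PHASE_TO_CLASS[p].value for p in phases], index=counts.index
        ),
        libsize=pd.Series(libs, index=counts.index),
        true_counts=counts.copy(),
    )
    return CountMatrix(counts, meta), truth


def simulate_reads(gene_counts, panel: ProbePanel, read_sim: ReadSimConfig,
                   seed: int | np.random.Generator | None = None,
                   sample_id: str = "sample",
                   out: IO[str] | str | Path | None = None,
                   ) -> list[tuple[str, str]]:
    """Emit UMI-tagged reads for one sample's molecule counts.

    For each true molecule a UMI is drawn uniformly, a PCR duplicate
    count from a geometric law with the configured mean, and each read is
    ``[UMI][target][UMI]`` with independent per-base substitution errors
    over the target region.  UMI bases are emitted error-free: the
    counter defines molecules by exact UMI identity (no 1-edit merging),
    so corrupted UMIs would mint phantom molecules rather than test the
    mismatch tolerance.  Read names carry ground-truth tags
    ``gene|molecule|umi`` for oracle tests.  Returns the (name, sequence)
    list and, if ``out`` is given, writes FASTQ text.
    """
    rng = np.random.default_rng(seed)
    gene_counts = pd.Series(gene_counts)
    umi_space = 4 ** (read_sim.umi_len_each * read_sim.umi_count)
    total_mol = int(gene_counts.sum())
    per_gene_max = int(gene_counts.max()) if total_mol else 0
    if per_gene_max > 1 and 1 - math.exp(
        -per_gene_max * (per_gene_max - 1) / (2 * umi_space)
    ) > 0.01:
        import logging

        logging.getLogger(__name__).warning(
            "UMI collision probability exceeds 1%% for %d molecules over %d "
            "UMIs (birthday bound)", per_gene_max, umi_space,
        )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p_geom = 1.0 / read_sim.mean_reads_per_molecule
    reads: list[tuple[str, str]] = []
    for gid, n_mol in gene_counts.items():
        if gid not in panel:
            raise KeyError(f"gene {gid!r} not in panel")
        target = np.frombuffer(panel[gid].target_seq.encode(), dtype=np.uint8)
        for mol in range(int(n_mol)):
            umi_bits = rng.integers(0, 4, read_sim.umi_len_each * read_sim.umi_count)
            umi1 = bases[umi_bits[: read_sim.umi_len_each]]
            umi2 = bases[umi_bits[read_sim.umi_len_each:]]
            n_reads = int(rng.geometric(p_geom))
            for r in range(n_reads):
                body = target
                if read_sim.per_base_error_rate > 0:
                    err = rng.random(len(target)) < read_sim.per_base_error_rate
                    if err.any():
                        body = target.copy()
                        shift = rng.integers(1, 4, int(err.sum()))
                        idx = np.flatnonzero(err)
                        cur = np.searchsorted(bases, body[idx])
                        body[idx] = bases[(cur + shift) % 4]
                if read_sim.umi_count == 2:
                    seq = np.concatenate([umi1, body, umi2])
                else:
                    seq = np.concatenate([umi1, body])
                umi_str = (umi1.tobytes() + umi2.tobytes()).decode()
                name = f"{sample_id}:{gid}|{mol}|{umi_str}:{r}"
                reads.append((name, seq.tobytes().decode()))
    if out is not None:
        close = False
        if isinstance(out, (str, Path)):
            out = open(out, "w")
            close = True
        try:
            for name, seq in reads:
                out.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
        finally:
            if close:
                out.close()
    return reads


def layout_for(cfg: SimulationConfig) -> ReadLayout:
    """Read layout matching the simulated read structure."""
    return ReadLayout.for_panel(
        cfg.panel, cfg.read_sim.umi_len_each, cfg.read_sim.umi_count
    )
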