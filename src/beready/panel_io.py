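"""Data model and file I/O for the targeted receptivity panel.

This module defines the panel of ligation-probe targets, the read layout
(where the UMIs and the ligated target region sit inside a read), the
sample x gene molecule-count matrix, and the five ordered receptivity
classes.  All on-disk formats are plain text: TSV for panels, counts and
sample metadata, versioned JSON for fitted reference models.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Menstrual-cycle phase vocabulary used for training labels.
PHASES = ("PE", "ESE", "MSE", "LSE")

#: Cohort tags carried in sample metadata.
COHORTS = ("MD", "MV", "RIF", "synthetic", "unknown")

_DNA = set("ACGT")


class PanelError(ValueError):
    """Raised for invalid panel definitions or malformed input files."""


class ReceptivityClass(str, Enum):
    """The five ordered receptivity classes.

    ``PRE``, ``RECEPTIVE`` and ``POST`` are *reference* classes (training
    centroids exist for them); ``EARLY`` and ``LATE`` are transitionary
    classes assigned to samples that sit between two adjacent reference
    groups and are never used as training labels.
    """

    PRE = "pre-receptive"
    EARLY = "early-receptive"
    RECEPTIVE = "receptive"
    LATE = "late-receptive"
    POST = "post-receptive"

    @property
    def order(self) -> int:
        return list(ReceptivityClass).index(self)

    def __lt__(self, other: "ReceptivityClass") -> bool:  # temporal order
        return self.order < other.order


#: Reference (training) classes in temporal order.
REFERENCE_CLASSES = (
    ReceptivityClass.PRE,
    ReceptivityClass.RECEPTIVE,
    ReceptivityClass.POST,
)

#: Transitionary class sitting between each adjacent reference pair.
TRANSITION_BETWEEN = {
    (ReceptivityClass.PRE, ReceptivityClass.RECEPTIVE): ReceptivityClass.EARLY,
    (ReceptivityClass.RECEPTIVE, ReceptivityClass.POST): ReceptivityClass.LATE,
}

#: Default mapping from cycle-phase label to reference class: proliferative
#: and early-secretory samples are pre-receptive, mid-secretory samples are
#: receptive (the expected window of implantation), late-secretory samples
#: are post-receptive.
PHASE_TO_CLASS = {
    "PE": ReceptivityClass.PRE,
    "ESE": ReceptivityClass.PRE,
    "MSE": ReceptivityClass.RECEPTIVE,
    "LSE": ReceptivityClass.POST,
}


@dataclass(frozen=True)
class ProbeTarget:
    """A single ligation-probe target: gene symbol, captured sequence,
    and whether the gene is a housekeeper used for normalization."""

    target_id: str
    target_seq: str
    is_housekeeper: bool = False

    def __post_init__(self) -> None:
        if not self.target_id:
            raise PanelError("empty target_id")
        if not self.target_seq:
            raise PanelError(f"target {self.target_id!r}: empty target_seq")
        bad = set(self.target_seq.upper()) - _DNA
        if bad:
            raise PanelError(
                f"target {self.target_id!r}: non-ACGT characters {sorted(bad)}"
            )
        object.__setattr__(self, "target_seq", self.target_seq.upper())


class ProbePanel:
    """An ordered collection of :class:`ProbeTarget` with unique IDs and a
    common target-sequence length."""

    def __init__(self, targets: Iterable[ProbeTarget]):
        targets = list(targets)
        if not targets:
            raise PanelError("panel contains zero targets")
        seen: dict[str, int] = {}
        for t in targets:
            if t.target_id in seen:
                raise PanelError(f"duplicate target_id {t.target_id!r}")
            seen[t.target_id] = 1
        lengths = {len(t.target_seq) for t in targets}
        if len(lengths) != 1:
            ragged = sorted(
                (t.target_id, len(t.target_seq)) for t in targets
            )
            raise PanelError(
                f"target sequences must all share one length; got lengths "
                f"{sorted(lengths)} (first few: {ragged[:4]})"
            )
        self.targets: list[ProbeTarget] = targets
        self._by_id = {t.target_id: t for t in targets}

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.targets)

    def __contains__(self, target_id: str) -> bool:
        return target_id in self._by_id

    def __getitem__(self, target_id: str) -> ProbeTarget:
        return self._by_id[target_id]

    @property
    def target_ids(self) -> list[str]:
        return [t.target_id for t in self.targets]

    @property
    def housekeeper_ids(self) -> list[str]:
        return [t.target_id for t in self.targets if t.is_housekeeper]

    @property
    def biomarker_ids(self) -> list[str]:
        return [t.target_id for t in self.targets if not t.is_housekeeper]

    @property
    def seq_len(self) -> int:
        return len(self.targets[0].target_seq)


@dataclass(frozen=True)
class ReadLayout:
    """Positions of UMIs and target region within each read.

    The default mirrors the assay design of one 4-nt UMI on each side of
    the ligated target: ``[UMI-4][target][UMI-4]``.  ``target_region`` is
    0-based half-open; the UMI key is the concatenation of both 4-mers.
    """

    umi_len_each: int = 4
    umi_count: int = 2
    target_region: tuple[int, int] = (4, 54)

    def __post_init__(self) -> None:
        if self.umi_len_each < 1:
            raise ValueError("umi_len_each must be >= 1")
        if self.umi_count not in (1, 2):
            raise ValueError("umi_count must be 1 or 2")
        s, e = self.target_region
        if not (0 <= s < e):
            raise ValueError(f"invalid target_region {self.target_region}")

    @classmethod
    def for_panel(cls, panel: ProbePanel, umi_len_each: int = 4,
                  umi_count: int = 2) -> "ReadLayout":
        """Layout with the target region sized to the panel, UMIs flanking."""
        start = umi_len_each
        return cls(umi_len_each, umi_count, (start, start + panel.seq_len))

    @property
    def umi_len_total(self) -> int:
        return self.umi_len_each * self.umi_count

    @property
    def read_len(self) -> int:
        """Minimum read length covering target region and trailing UMI."""
        end = self.target_region[1]
        if self.umi_count == 2:
            end += self.umi_len_each
        return end

    def extract_umi(self, read_seq: str) -> str:
        parts = [read_seq[: self.umi_len_each]]
        if self.umi_count == 2:
            e = self.target_region[1]
            parts.append(read_seq[e: e + self.umi_len_each])
        return "".join(parts)


class CountMatrix:
    """Samples x genes UMI-corrected molecule counts plus per-sample
    metadata (cycle phase and cohort tag).

    ``counts`` is an integer DataFrame indexed by sample, ``meta`` a
    DataFrame with columns ``phase`` and ``cohort`` on the same index.
    The raw matrix is never mutated by downstream normalization.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame | None = None):
        counts = counts.copy()
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(arr.astype(float))):
                bad = np.argwhere(frac != 0)
                s, g = bad[0] if len(bad) else (0, 0)
                raise ValueError(
                    f"non-integer count at sample {counts.index[s]!r}, "
                    f"gene {counts.columns[g]!r}"
                )
            counts = counts.astype(np.int64)
        if arr.size and (counts.to_numpy() < 0).any():
            s, g = np.argwhere(counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[s]!r}, "
                f"gene {counts.columns[g]!r}"
            )
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate gene_ids")
        self.counts = counts.astype(np.int64)
        if meta is None:
            meta = pd.DataFrame(index=counts.index)
        meta = meta.reindex(counts.index)
        if "phase" not in meta:
            meta["phase"] = "unknown"
        if "cohort" not in meta:
            meta["cohort"] = "unknown"
        meta["phase"] = meta["phase"].fillna("unknown")
        meta["cohort"] = meta["cohort"].fillna("unknown")
        bad_phase = set(meta["phase"]) - set(PHASES) - {"unknown"}
        if bad_phase:
            log.warning(
                "unknown phase label(s) %s stored as 'unknown'", sorted(bad_phase)
            )
            meta.loc[meta["phase"].isin(bad_phase), "phase"] = "unknown"
        self.meta = meta[["phase", "cohort"]]

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def phases(self) -> pd.Series:
        return self.meta["phase"]

    def reference_labels(self) -> pd.Series:
        """Map phase labels to reference classes (PE/ESE -> pre-receptive,
        MSE -> receptive, LSE -> post-receptive); unknown phases -> NaN."""
        return self.phases.map(lambda p: PHASE_TO_CLASS.get(p, np.nan))

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(sample_ids)],
                           self.meta.loc[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.meta.equals(other.meta)
        )


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> ProbePanel:
    """Read a panel TSV with columns target_id, target_seq, is_housekeeper."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"target_id", "target_seq", "is_housekeeper"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file {path}: missing columns {sorted(missing)}")
    dup = df["target_id"][df["target_id"].duplicated()].tolist()
    if dup:
        raise PanelError(f"panel file {path}: duplicate target_id(s) {dup}")
    targets = [
        ProbeTarget(
            target_id=row.target_id,
            target_seq=row.target_seq,
            is_housekeeper=str(row.is_housekeeper).strip().lower()
            in ("1", "true", "yes"),
        )
        for row in df.itertuples()
    ]
    return ProbePanel(targets)


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "target_id": panel.target_ids,
            "target_seq": [t.target_seq for t in panel.targets],
            "is_housekeeper": [int(t.is_housekeeper) for t in panel.targets],
        }
    ).to_csv(path, sep="\t", index=False)


def panel_from_fasta(path: str | Path, housekeeper_token: str = "housekeeper") -> ProbePanel:
    """Convenience importer: FASTA records become targets; a record whose
    header contains *housekeeper_token* is flagged as a housekeeper."""
    from Bio import SeqIO

    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        targets.append(
            ProbeTarget(rec.id, str(rec.seq), housekeeper_token in rec.description)
        )
    return ProbePanel(targets)


def _meta_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.tsv") if p.suffix != ".tsv" \
        else p.with_name(p.stem + ".meta.tsv")


def read_counts(path: str | Path, meta_path: str | Path | None = None) -> CountMatrix:
    """Read a count TSV (first column sample_id, rest integer gene counts),
    optionally joining a companion metadata TSV (sample_id, phase, cohort).

    Samples missing from the metadata get phase/cohort ``unknown`` with a
    logged warning, so classification-only runs need no labels.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = None
    mp = Path(meta_path) if meta_path is not None else _meta_path(path)
    if mp.exists():
        meta = pd.read_csv(mp, sep="\t", index_col=0)
        missing = set(df.index) - set(meta.index)
        if missing:
            log.warning(
                "metadata missing for sample(s) %s; phase set to 'unknown'",
                sorted(missing),
            )
    try:
        return CountMatrix(df, meta)
    except ValueError as e:
        raise ValueError(f"count file {path}: {e}") from e


def write_counts(m: CountMatrix, path: str | Path,
                 meta_path: str | Path | None = None) -> None:
    m.counts.to_csv(path, sep="\t", index_label="sample_id")
    mp = Path(meta_path) if meta_path is not None else _meta_path(path)
    m.meta.to_csv(mp, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Model serialization (thin wrappers; format lives with ReferenceModel)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a fitted ReferenceModel to versioned JSON."""
    model.save(path)


def load_model(path: str | Path):
    """Load a ReferenceModel saved by :func:`save_model`."""
    from .beready_model import ReferenceModel

    return ReferenceModel.load(path)
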