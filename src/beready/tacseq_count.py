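"""UMI-corrected molecule counting from targeted ligation-probe reads.

Each read carries a fixed-length ligated target region flanked by UMI
bases.  A read is assigned to the unique panel target at minimal Hamming
distance from its target region, provided that distance does not exceed
``max_mismatches`` (default 5, inclusive).  Reads sharing a (target, UMI)
pair are PCR duplicates of one original molecule; the molecule count of a
target is the number of distinct UMIs supported by at least
``umi_read_threshold`` reads.

Ambiguity is handled conservatively: a tie between two targets at the
minimal distance leaves the read unassigned (reason ``ambiguous``), and
ambiguous bases (N) always count as mismatches.  No 1-edit UMI merging is
performed: exact UMI identity defines a molecule.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .panel_io import CountMatrix, ProbePanel, ReadLayout

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of matching one read against the panel."""

    read_id: str
    target_id: str | None
    mismatches: int
    umi: str
    reason: str | None = None  # None if assigned; "short"|"ambiguous"|"distant"

    @property
    def assigned(self) -> bool:
        return self.target_id is not None


class _Matcher:
    """Vectorized Hamming matcher over the panel's target sequences."""

    def __init__(self, panel: ProbePanel, layout: ReadLayout):
        s, e = layout.target_region
        if e - s != panel.seq_len:
            raise ValueError(
                f"layout target_region length {e - s} != panel sequence "
                f"length {panel.seq_len}"
            )
        self.panel = panel
        self.layout = layout
        self.ids = panel.target_ids
        # byte matrix: n_targets x seq_len
        self._mat = np.frombuffer(
            "".join(t.target_seq for t in panel.targets).encode(), dtype=np.uint8
        ).reshape(len(panel), panel.seq_len)

    def __call__(self, read_id: str, read_seq: str, max_mismatches: int) -> ReadAssignment:
        layout = self.layout
        read_seq = read_seq.upper()
        if len(read_seq) < layout.read_len:
            return ReadAssignment(read_id, None, -1, "", reason="short")
        umi = layout.extract_umi(read_seq)
        s, e = layout.target_region
        region = np.frombuffer(read_seq[s:e].encode(), dtype=np.uint8)
        dists = (self._mat != region).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatches:
            return ReadAssignment(read_id, None, best, umi, reason="distant")
        hits = np.flatnonzero(dists == best)
        if len(hits) > 1:
            log.debug("read %s ambiguous between %s at distance %d",
                      read_id, [self.ids[i] for i in hits], best)
            return ReadAssignment(read_id, None, best, umi, reason="ambiguous")
        return ReadAssignment(read_id, self.ids[int(hits[0])], best, umi)


def assign_read(read_seq: str, panel: ProbePanel, layout: ReadLayout | None = None,
                max_mismatches: int = 5, read_id: str = "read") -> ReadAssignment:
    """Assign one read to its panel target (or leave unassigned).

    The minimal-Hamming-distance target wins if unique and within
    ``max_mismatches`` (inclusive).  For bulk counting use
    :func:`count_reads`, which reuses the matcher across reads.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if layout is None:
        layout = ReadLayout.for_panel(panel)
    return _Matcher(panel, layout)(read_id, read_seq, max_mismatches)


def _iter_fastq(fastq) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ path (plain or gzip) or an
    iterable of (read_id, sequence) pairs."""
    if isinstance(fastq, (str, Path)):
        import pysam

        try:
            with pysam.FastxFile(str(fastq)) as fh:
                for i, rec in enumerate(fh):
                    if not rec.sequence:
                        raise ValueError(f"malformed FASTQ record #{i} ({rec.name})")
                    yield rec.name, rec.sequence
        except OSError as e:
            raise ValueError(f"cannot parse FASTQ {fastq}: {e}") from e
    else:
        for item in fastq:
            yield item


@dataclass
class QCSummary:
    """Read-level quality summary for one counted sample."""

    total_reads: int = 0
    assigned_reads: int = 0
    unassigned: dict[str, int] = field(default_factory=dict)
    molecules: int = 0
    umis_per_target: dict[str, int] = field(default_factory=dict)

    @property
    def assigned_fraction(self) -> float:
        return self.assigned_reads / self.total_reads if self.total_reads else 0.0

    @property
    def duplication_rate(self) -> float:
        """Mean supporting reads per distinct (target, UMI) molecule."""
        return self.assigned_reads / self.molecules if self.molecules else 0.0

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "assigned_reads": self.assigned_reads,
            "assigned_fraction": self.assigned_fraction,
            "duplication_rate": self.duplication_rate,
            "unassigned": dict(self.unassigned),
            "molecules": self.molecules,
            "umis_per_target": dict(self.umis_per_target),
        }


def umi_table(fastq, panel: ProbePanel, layout: ReadLayout | None = None,
              max_mismatches: int = 5) -> tuple[dict[str, Counter], QCSummary]:
    """Tabulate UMI support: target_id -> Counter(umi -> read count)."""
    if layout is None:
        layout = ReadLayout.for_panel(panel)
    matcher = _Matcher(panel, layout)
    table: dict[str, Counter] = defaultdict(Counter)
    qc = QCSummary()
    unassigned: Counter = Counter()
    for read_id, seq in _iter_fastq(fastq):
        qc.total_reads += 1
        a = matcher(read_id, seq, max_mismatches)
        if a.assigned:
            qc.assigned_reads += 1
            table[a.target_id][a.umi] += 1
        else:
            unassigned[a.reason] += 1
    qc.unassigned = dict(unassigned)
    return table, qc


def count_reads(fastq, panel: ProbePanel, layout: ReadLayout | None = None,
                max_mismatches: int = 5, umi_read_threshold: int = 1,
                sample_id: str = "sample") -> tuple[CountMatrix, QCSummary]:
    """Count molecules for one sample from a FASTQ stream.

    The molecule count of a target is the number of distinct UMIs whose
    supporting-read count is at least ``umi_read_threshold``.  An empty
    input yields an all-zero row (with a warning), not an error.
    """
    if umi_read_threshold < 1:
        raise ValueError("umi_read_threshold must be >= 1")
    table, qc = umi_table(fastq, panel, layout, max_mismatches)
    if qc.total_reads == 0:
        log.warning("empty FASTQ input for sample %s; zero counts", sample_id)
    counts = {}
    for tid in panel.target_ids:
        umis = table.get(tid, {})
        n = sum(1 for c in umis.values() if c >= umi_read_threshold)
        counts[tid] = n
        if n:
            qc.umis_per_target[tid] = n
    qc.molecules = sum(counts.values())
    df = pd.DataFrame([counts], index=pd.Index([sample_id], name="sample_id"))
    return CountMatrix(df[panel.target_ids]), qc
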