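"""Cleavage-end counting from aligned RNA fragments.

RiboMeth-seq reads out alkaline hydrolysis: every cut between nucleotide i and
i+1 leaves a fragment 3' end at nucleotide i and a fragment 5' end at i+1.  The
5'-end count is therefore shifted one position upstream and combined with the
3'-end count, giving a per-bond cleavage count n_i for bonds i = 1..L-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .refdata import ReferenceRNA


@dataclass(frozen=True)
class Fragment:
    """One hydrolysis fragment: outermost coordinates of a properly paired read
    pair, 1-based closed."""

    rna_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad fragment interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EndCountTrack:
    """Per-position raw 5'/3' end counts and the combined per-bond track.

    Arrays are 1-based: index p holds the count for nucleotide position p
    (index 0 is unused).  ``combined[i] = three_ends[i] + five_ends[i+1]`` for
    interior bonds i = 1..L-1; cuts at the molecule termini fall off the track.
    """

    rna_id: str
    length: int
    five_ends: np.ndarray
    three_ends: np.ndarray
    n_fragments: int = 0

    @classmethod
    def empty(cls, rna_id: str, length: int) -> "EndCountTrack":
        return cls(rna_id, length, np.zeros(length + 2, dtype=np.int64),
                   np.zeros(length + 2, dtype=np.int64))

    @property
    def combined(self) -> np.ndarray:
        """Combined cleavage counts; entry i (1..L-1) is bond i, others zero."""
        n = np.zeros(self.length + 1, dtype=np.int64)
        n[1:self.length] = self.three_ends[1:self.length] + self.five_ends[2:self.length + 1]
        return n

    def to_dataframe(self) -> pd.DataFrame:
        comb = self.combined
        return pd.DataFrame({
            "rna_id": self.rna_id,
            "bond_position": np.arange(1, self.length),
            "five_count": self.five_ends[2:self.length + 1],
            "three_count": self.three_ends[1:self.length],
            "combined": comb[1:self.length],
        })


@dataclass(frozen=True)
class CoverageStats:
    rna_id: str
    n_fragments: int
    length: int

    @property
    def aec(self) -> float:
        return self.n_fragments / self.length


# ---------------------------------------------------------------------------


def extract_fragments(
    source: str | Path,
    references: Sequence[ReferenceRNA],
    min_mapq: int = 0,
) -> tuple[list[Fragment], dict]:
    """Extract fragments from a SAM/BAM file or a BED-like TSV.

    SAM/BAM: one fragment per properly paired pair (outermost mate
    coordinates, taken from read 1 of each primary pair).  TSV: columns
    rna_id, start, end with a '#'-prefixed header.  Returns the fragments and
    a summary of dropped records.
    """
    path = Path(source)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        return _extract_from_alignments(path, references, min_mapq)
    return _extract_from_tsv(path, references)


def _extract_from_alignments(path: Path, references, min_mapq):
    import pysam

    known = {r.id: r.length for r in references}
    dropped = {"not_proper_pair": 0, "secondary_or_supplementary": 0,
               "low_mapq": 0, "not_read1": 0}
    fragments: list[Fragment] = []
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                dropped["secondary_or_supplementary"] += int(not read.is_unmapped)
                if read.is_unmapped:
                    dropped["not_proper_pair"] += 1
                continue
            if not read.is_proper_pair:
                dropped["not_proper_pair"] += 1
                continue
            if not read.is_read1:
                dropped["not_read1"] += 1  # counted once per pair via read 1
                continue
            if read.mapping_quality < min_mapq:
                dropped["low_mapq"] += 1
                continue
            rna = read.reference_name
            if rna not in known:
                raise ValueError(f"{path}: alignment reference {rna!r} not loaded")
            tlen = read.template_length
            if tlen > 0:
                start = read.reference_start + 1
                end = read.reference_start + tlen
            else:
                end = read.reference_end
                start = end + tlen + 1
            start, end = max(1, start), min(known[rna], end)
            fragments.append(Fragment(rna, start, end))
    return fragments, dropped


def _extract_from_tsv(path: Path, references):
    from .refdata import _read_tsv

    known = {r.id: r.length for r in references}
    df = _read_tsv(path)
    fragments = []
    for row in df.itertuples(index=False):
        if row.rna_id not in known:
            raise ValueError(f"{path}: fragment reference {row.rna_id!r} not loaded")
        fragments.append(Fragment(row.rna_id, int(row.start), int(row.end)))
    return fragments, {}


def write_fragments_tsv(fragments: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#rna_id\tstart\tend\n")
        for f in fragments:
            fh.write(f"{f.rna_id}\t{f.start}\t{f.end}\n")


def count_ends(
    fragments: Iterable[Fragment],
    rna: ReferenceRNA | str,
    length: Optional[int] = None,
) -> EndCountTrack:
    """Count fragment 5'/3' ends on one RNA and build the combined track."""
    if isinstance(rna, ReferenceRNA):
        rna_id, length = rna.id, rna.length
    else:
        rna_id = rna
        if length is None:
            raise ValueError("length required when rna is given by id")
    starts, ends = [], []
    for f in fragments:
        if f.rna_id != rna_id:
            raise ValueError(f"fragment on {f.rna_id} passed to track for {rna_id}")
        if f.end > length:
            raise ValueError(f"fragment [{f.start},{f.end}] outside 1..{length}")
        starts.append(f.start)
        ends.append(f.end)
    track = EndCountTrack.empty(rna_id, length)
    if starts:
        track.five_ends[:] = np.bincount(starts, minlength=length + 2)
        track.three_ends[:] = np.bincount(ends, minlength=length + 2)
        track.n_fragments = len(starts)
    return track


def count_ends_arrays(
    rna_id: str, length: int, starts: np.ndarray, ends: np.ndarray
) -> EndCountTrack:
    """Vectorized variant of :func:`count_ends` for simulation-scale input."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size and (starts.min() < 1 or ends.max() > length):
        raise ValueError("fragment outside reference bounds")
    track = EndCountTrack.empty(rna_id, length)
    if starts.size:
        track.five_ends[:] = np.bincount(starts, minlength=length + 2)
        track.three_ends[:] = np.bincount(ends, minlength=length + 2)
        track.n_fragments = int(starts.size)
    return track


def aec(track: EndCountTrack) -> CoverageStats:
    """Average end count: mapped fragments (read pairs) divided by RNA length."""
    if track.length == 0:
        raise ValueError("zero-length RNA")
    return CoverageStats(track.rna_id, track.n_fragments, track.length)


def pool_tracks(tracks: Sequence[EndCountTrack]) -> EndCountTrack:
    """Element-wise sum of end-count tracks from multiple datasets."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    pooled = EndCountTrack.empty(first.rna_id, first.length)
    for t in tracks:
        if (t.rna_id, t.length) != (first.rna_id, first.length):
            raise ValueError(
                f"cannot pool {t.rna_id}({t.length}) with {first.rna_id}({first.length})"
            )
        pooled.five_ends += t.five_ends
        pooled.three_ends += t.three_ends
        pooled.n_fragments += t.n_fragments
    return pooled


def write_track_tsv(track: EndCountTrack, path: str | Path) -> None:
    df = track.to_dataframe()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
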