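"""Box C/D snoRNA guide assignment for 2'-O-methylation sites.

A box C/D snoRNA carries box C (RUGAUGA) near its 5' end, box D (CUGA) near
its 3' end, and internal C'/D' copies (D' is often degenerate, here required
only to end in an exact GA, i.e. NNGA).  The spacer immediately upstream of
box D or D' is the antisense guide: it forms an ungapped antiparallel duplex
with the substrate, and the substrate nucleotide paired with the fifth guide
position upstream of the box is the one methylated (the D+5 rule).

The search enumerates exact ungapped antisense matches directly (no alignment
heuristics): Watson-Crick-only duplex cores of at least ``seed_min`` pairs are
found first, then extended outward through G:U wobble pairs.  Primary duplexes
must place the methylation site at guide position 5 and carry at least 2
substrate pairs 5' and 3 pairs 3' of the site.  Extra (secondary) duplexes of
7-15 bp elsewhere on the snoRNA are reported when they do not substantially
overlap box motifs or the primary pair.  Guides upstream of box D' can act
non-canonically on a second site at guide position 6 or 7, which is detected
as a tandem pattern downstream of a D'-guided site.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .refdata import (
    BOX_C_MOTIF,
    BOX_D_MOTIF,
    Interval,
    NmSite,
    ReferenceRNA,
    SnoRNA,
    motif_matches,
)

logger = logging.getLogger(__name__)

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def is_gu(a: str, b: str) -> bool:
    return (a, b) in GU_PAIRS


# ---------------------------------------------------------------------------
# Box motif location


@dataclass
class BoxAnnotation:
    """Located box motifs for one snoRNA (intervals 1-based closed)."""

    snorna: str
    boxC: Optional[Interval] = None
    boxD: Optional[Interval] = None
    boxCprime: Optional[Interval] = None
    boxDprime_candidates: list[Interval] = field(default_factory=list)
    provenance: str = "motif_search"


@dataclass(frozen=True)
class BoxSearchConfig:
    """Degeneracy and placement windows for box motif search."""

    boxD_terminal_window: int = 10  # box D must end within this many nt of 3' end
    boxC_window: tuple[int, int] = (2, 12)  # box C searched within these nt
    min_guide_room: int = 7  # nt upstream required for a D' candidate's guide


def find_boxes(
    snorna: SnoRNA, config: BoxSearchConfig = BoxSearchConfig()
) -> BoxAnnotation:
    """Locate box C, D, C' and D' candidates on a C/D snoRNA.

    Catalog-annotated coordinates override motif search.  Box D is the
    3'-most CUGA inside the terminal window; box C the 5'-most RUGAUGA inside
    nt 2-12.  Every internal NNGA whose GA dinucleotide is exact is kept as a
    box D' candidate for guide search.  A snoRNA without any box D candidate
    is excluded from D-guide search (boxD None, logged).
    """
    if snorna.klass != "CD":
        raise ValueError(f"{snorna.name}: box search requires a C/D snoRNA")
    seq, L = snorna.sequence, snorna.length
    ann = BoxAnnotation(snorna.name)
    from_catalog = []

    if snorna.boxD is not None:
        ann.boxD = snorna.boxD
        from_catalog.append("D")
    else:
        lo = max(1, L - config.boxD_terminal_window + 1)
        hits = [j for j in range(lo, L - 2)
                if motif_matches(BOX_D_MOTIF, seq[j - 1:j + 3])]
        ann.boxD = (hits[-1], hits[-1] + 3) if hits else None
        if ann.boxD is None:
            logger.info("%s: no box D candidate in 3'-terminal %d nt",
                        snorna.name, config.boxD_terminal_window)

    if snorna.boxC is not None:
        ann.boxC = snorna.boxC
        from_catalog.append("C")
    else:
        lo, hi = config.boxC_window
        hits = [j for j in range(lo, hi - 5)
                if motif_matches(BOX_C_MOTIF, seq[j - 1:j + 6])]
        ann.boxC = (hits[0], hits[0] + 6) if hits else None

    interior_lo = (ann.boxC[1] + 1) if ann.boxC else config.boxC_window[1] + 1
    interior_hi = (ann.boxD[0] - 1) if ann.boxD else L

    if snorna.boxCprime is not None:
        ann.boxCprime = snorna.boxCprime
    else:
        hits = [j for j in range(interior_lo, interior_hi - 5)
                if motif_matches(BOX_C_MOTIF, seq[j - 1:j + 6])]
        ann.boxCprime = (hits[0], hits[0] + 6) if hits else None

    if snorna.boxDprime is not None:
        ann.boxDprime_candidates = [snorna.boxDprime]
        from_catalog.append("Dprime")
    else:
        ann.boxDprime_candidates = [
            (j, j + 3)
            for j in range(max(interior_lo, config.min_guide_room + 1), interior_hi - 2)
            if seq[j + 1:j + 3] == "GA"
        ]
    ann.provenance = "catalog" if from_catalog else "motif_search"
    return ann


# ---------------------------------------------------------------------------
# Duplex records


@dataclass
class DuplexRecord:
    """An ungapped antiparallel guide-substrate duplex.

    ``pairs`` holds (substrate_pos, sno_pos, pairtype) triples with pairtype
    'WC', 'GU' or 'MM' (relaxed mode only), sorted by substrate position;
    consecutive substrate positions pair with consecutive snoRNA positions in
    reverse.  For primary records ``nm_offset`` is the guide position (counted
    upstream of the box, 1 = adjacent) paired with the methylation site: 5 is
    canonical, 6/7 non-canonical.
    """

    snorna: str
    kind: str  # "primary" | "extra"
    substrate_rna: str
    substrate_interval: Interval
    sno_interval: Interval
    pairs: list[tuple[int, int, str]]
    box_used: Optional[str] = None  # "D" | "Dprime"
    box_interval: Optional[Interval] = None
    nm_position: Optional[int] = None
    nm_offset: Optional[int] = None
    noncanonical: bool = False
    relaxed: bool = False
    note: str = ""
    side: Optional[str] = None  # extra pairs: 5prime/3prime of primary on substrate
    dist_substrate: Optional[int] = None
    dist_sno: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def n_gu(self) -> int:
        return sum(1 for _, _, t in self.pairs if t == "GU")

    @property
    def guide_interval(self) -> Optional[Interval]:
        """Box-relative guide coordinates (1 = adjacent upstream of the box)."""
        if self.box_interval is None:
            return None
        bs = self.box_interval[0]
        return (bs - self.sno_interval[1], bs - self.sno_interval[0])

    def pair_string(self) -> str:
        """Dot-bracket-like summary: '(' WC, 'o' GU, 'x' mismatch."""
        return "".join(
            {"WC": "(", "GU": "o", "MM": "x"}[t] for _, _, t in self.pairs
        )

    def revalidate(self, target: ReferenceRNA, snorna: SnoRNA) -> None:
        """Assert every pair against the two sequences (guards stale coords)."""
        prev = None
        for p, s, t in self.pairs:
            a, b = target.base(p), snorna.sequence[s - 1]
            ok = is_wc(a, b) if t == "WC" else is_gu(a, b) if t == "GU" else True
            if not ok:
                raise ValueError(f"{self.snorna}: pair ({p},{s}) is not {t}")
            if prev is not None and (p != prev[0] + 1 or s != prev[1] - 1):
                raise ValueError(f"{self.snorna}: pairs not ungapped antiparallel")
            prev = (p, s)


def _maximal_wc_run(
    tseq: str, sseq: str, p_anchor: int, s_anchor: int,
    p_bounds: Interval, s_bounds: Interval,
) -> Optional[Interval]:
    """Maximal contiguous WC run through the anchored pair, on the diagonal
    p + s = const.  Returns the substrate interval or None if the anchor
    itself is not WC."""
    if not is_wc(tseq[p_anchor - 1], sseq[s_anchor - 1]):
        return None
    diag = p_anchor + s_anchor
    p_lo = p_anchor
    while (p_lo - 1 >= p_bounds[0] and diag - (p_lo - 1) <= s_bounds[1]
           and is_wc(tseq[p_lo - 2], sseq[diag - p_lo])):
        p_lo -= 1
    p_hi = p_anchor
    while (p_hi + 1 <= p_bounds[1] and diag - (p_hi + 1) >= s_bounds[0]
           and is_wc(tseq[p_hi], sseq[diag - p_hi - 2])):
        p_hi += 1
    return (p_lo, p_hi)


def search_primary(
    nm: NmSite,
    target: ReferenceRNA,
    snorna: SnoRNA,
    boxes: BoxAnnotation,
    seed_min: int = 7,
    flank_window: int = 100,
) -> list[DuplexRecord]:
    """Find canonical (D+5) primary duplexes for one site against one snoRNA.

    For each box D / D' candidate the site is anchored to guide position 5;
    the maximal Watson-Crick run through the anchor is kept when it has at
    least ``seed_min`` pairs, at least 2 pairs 5' and 3 pairs 3' of the site
    on the substrate, and stays within the +/-``flank_window`` substrate
    window (clipped at sequence ends, never wrapped).
    """
    if target.base(nm.position) != nm.base:
        raise ValueError(f"{nm.label}: base mismatch with reference")
    w_lo = max(1, nm.position - flank_window)
    w_hi = min(target.length, nm.position + flank_window)
    candidates: list[tuple[str, Interval]] = []
    if boxes.boxD is not None:
        candidates.append(("D", boxes.boxD))
    candidates.extend(("Dprime", iv) for iv in boxes.boxDprime_candidates)

    records: list[DuplexRecord] = []
    seen: set[tuple] = set()
    for box_used, box_iv in candidates:
        bs = box_iv[0]
        s_anchor = bs - 5
        if s_anchor < 1:
            continue
        run = _maximal_wc_run(
            target.sequence, snorna.sequence, nm.position, s_anchor,
            (w_lo, w_hi), (1, bs - 1),
        )
        if run is None:
            continue
        p_lo, p_hi = run
        if (p_hi - p_lo + 1) < seed_min:
            continue
        if nm.position - p_lo < 2 or p_hi - nm.position < 3:
            continue
        diag = nm.position + s_anchor
        pairs = [(p, diag - p, "WC") for p in range(p_lo, p_hi + 1)]
        key = (p_lo, p_hi, diag - p_hi, box_used, box_iv)
        if key in seen:
            continue
        seen.add(key)
        records.append(DuplexRecord(
            snorna=snorna.name, kind="primary", substrate_rna=target.id,
            substrate_interval=(p_lo, p_hi),
            sno_interval=(diag - p_hi, diag - p_lo),
            pairs=pairs, box_used=box_used, box_interval=box_iv,
            nm_position=nm.position, nm_offset=5,
        ))
    return records


def extend_gu(
    duplex: DuplexRecord, target: ReferenceRNA, snorna: SnoRNA
) -> DuplexRecord:
    """Extend a duplex stepwise at both ends through WC or G:U wobble pairs.

    Extension stops at the first non-pair, at sequence bounds, and (for
    box-anchored records) at the box: box nucleotides are never paired.
    """
    pairs = sorted(duplex.pairs)
    diag = pairs[0][0] + pairs[0][1]
    s_max = duplex.box_interval[0] - 1 if duplex.box_interval else snorna.length

    p = pairs[-1][0] + 1  # 3' on substrate, 5' on snoRNA guide
    while p <= target.length and diag - p >= 1:
        a, b = target.base(p), snorna.sequence[diag - p - 1]
        if is_wc(a, b) or is_gu(a, b):
            pairs.append((p, diag - p, "WC" if is_wc(a, b) else "GU"))
            p += 1
        else:
            break
    p = pairs[0][0] - 1
    head: list[tuple[int, int, str]] = []
    while p >= 1 and diag - p <= s_max:
        a, b = target.base(p), snorna.sequence[diag - p - 1]
        if is_wc(a, b) or is_gu(a, b):
            head.append((p, diag - p, "WC" if is_wc(a, b) else "GU"))
            p -= 1
        else:
            break
    pairs = list(reversed(head)) + pairs
    return replace(
        duplex,
        pairs=pairs,
        substrate_interval=(pairs[0][0], pairs[-1][0]),
        sno_interval=(pairs[-1][1], pairs[0][1]),
    )


def _overlap(a: Optional[Interval], b: Optional[Interval]) -> int:
    if a is None or b is None:
        return 0
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def search_extra(
    primary: DuplexRecord,
    target: ReferenceRNA,
    snorna: SnoRNA,
    boxes: BoxAnnotation,
    seed_min: int = 7,
    len_range: tuple[int, int] = (7, 15),
    max_box_overlap: int = 2,
    flank_window: int = 100,
) -> list[DuplexRecord]:
    """Find extra (secondary) duplexes supporting an accepted primary pair.

    All ungapped antiparallel duplexes with a WC core of at least ``seed_min``
    pairs between the substrate window and the snoRNA are enumerated and
    GU-extended; candidates overlapping box C/D/C'/D' motifs or the primary
    pair (either molecule) by more than ``max_box_overlap`` nt, or falling
    outside ``len_range``, are discarded.  Records are annotated with their
    side and distance relative to the primary pair on both molecules.
    """
    nm_pos = primary.nm_position
    w_lo = max(1, nm_pos - flank_window)
    w_hi = min(target.length, nm_pos + flank_window)
    tseq, sseq = target.sequence, snorna.sequence
    excluded = [boxes.boxC, boxes.boxD, boxes.boxCprime,
                primary.box_interval, primary.sno_interval]

    found: dict[tuple, DuplexRecord] = {}
    for diag in range(w_lo + 1, w_hi + snorna.length + 1):
        p = max(w_lo, diag - snorna.length)
        p_end = min(w_hi, diag - 1)
        run_start = None
        p_cursor = p
        while p_cursor <= p_end + 1:
            good = (p_cursor <= p_end
                    and is_wc(tseq[p_cursor - 1], sseq[diag - p_cursor - 1]))
            if good and run_start is None:
                run_start = p_cursor
            elif not good and run_start is not None:
                run = (run_start, p_cursor - 1)
                run_start = None
                if run[1] - run[0] + 1 >= seed_min:
                    rec = DuplexRecord(
                        snorna=snorna.name, kind="extra", substrate_rna=target.id,
                        substrate_interval=run,
                        sno_interval=(diag - run[1], diag - run[0]),
                        pairs=[(q, diag - q, "WC") for q in range(run[0], run[1] + 1)],
                        nm_position=nm_pos,
                    )
                    rec = extend_gu(rec, target, snorna)
                    if not len_range[0] <= rec.length <= len_range[1]:
                        p_cursor += 1
                        continue
                    if any(_overlap(rec.sno_interval, iv) > max_box_overlap
                           for iv in excluded):
                        p_cursor += 1
                        continue
                    if _overlap(rec.substrate_interval, primary.substrate_interval) \
                            > max_box_overlap:
                        p_cursor += 1
                        continue
                    _annotate_relative(rec, primary)
                    found.setdefault(
                        (rec.substrate_interval, rec.sno_interval), rec
                    )
            p_cursor += 1
    return sorted(found.values(), key=lambda r: r.substrate_interval)


def _annotate_relative(extra: DuplexRecord, primary: DuplexRecord) -> None:
    es, ee = extra.substrate_interval
    ps, pe = primary.substrate_interval
    if es > pe:
        extra.side = "3prime"
        extra.dist_substrate = es - pe - 1
    elif ee < ps:
        extra.side = "5prime"
        extra.dist_substrate = ps - ee - 1
    else:
        extra.side = "overlap"
        extra.dist_substrate = 0
    qs, qe = extra.sno_interval
    rs, re_ = primary.sno_interval
    if qs > re_:
        extra.dist_sno = qs - re_ - 1
    elif qe < rs:
        extra.dist_sno = rs - qe - 1
    else:
        extra.dist_sno = 0


# ---------------------------------------------------------------------------
# Relaxed mode (mismatch-tolerant rescue for otherwise unassigned sites)


def search_primary_relaxed(
    nm: NmSite,
    target: ReferenceRNA,
    snorna: SnoRNA,
    boxes: BoxAnnotation,
    min_len: int = 12,
    flank_window: int = 100,
) -> list[DuplexRecord]:
    """Mismatch-tolerant D+5 search: one internal mismatch allowed, longer
    minimum duplex.  Results are labeled ``relaxed`` and are off by default in
    :func:`assign_all`."""
    base = search_primary(nm, target, snorna, boxes, seed_min=4,
                          flank_window=flank_window)
    out = []
    for rec in base:
        rec = _bridge_one_mismatch(rec, target, snorna, flank_window)
        if rec.length >= min_len and sum(t == "MM" for *_, t in rec.pairs) <= 1:
            out.append(replace(rec, relaxed=True, note="relaxed: 1 mismatch allowed"))
    return out


def _bridge_one_mismatch(
    rec: DuplexRecord, target: ReferenceRNA, snorna: SnoRNA, flank_window: int
) -> DuplexRecord:
    """Try to grow a WC core across a single internal mismatch, preferring the
    side that yields the longer duplex."""
    best = rec
    diag = rec.pairs[0][0] + rec.pairs[0][1]
    w_lo = max(1, rec.nm_position - flank_window)
    w_hi = min(target.length, rec.nm_position + flank_window)
    s_max = rec.box_interval[0] - 1 if rec.box_interval else snorna.length
    for direction in (+1, -1):
        pairs = sorted(rec.pairs)
        edge = pairs[-1][0] if direction == 1 else pairs[0][0]
        mm = edge + direction
        s_mm = diag - mm
        if not (w_lo <= mm <= w_hi and 1 <= s_mm <= s_max):
            continue
        ext: list[tuple[int, int, str]] = [(mm, s_mm, "MM")]
        p = mm + direction
        while (w_lo <= p <= w_hi and 1 <= diag - p <= s_max
               and is_wc(target.base(p), snorna.sequence[diag - p - 1])):
            ext.append((p, diag - p, "WC"))
            p += direction
        if len(ext) < 3:  # a mismatch must buy at least 2 further WC pairs
            continue
        new_pairs = sorted(pairs + ext)
        cand = replace(
            rec, pairs=new_pairs,
            substrate_interval=(new_pairs[0][0], new_pairs[-1][0]),
            sno_interval=(new_pairs[-1][1], new_pairs[0][1]),
        )
        if cand.length > best.length:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Whole-catalog assignment


@dataclass(frozen=True)
class AssignConfig:
    seed_min: int = 7
    flank_window: int = 100
    extra_len_range: tuple[int, int] = (7, 15)
    max_box_overlap: int = 2
    relaxed: bool = False
    relaxed_min_len: int = 12
    expressed_only: bool = False
    search_extras: bool = True


@dataclass
class SiteAssignment:
    site: NmSite
    primaries: list[DuplexRecord] = field(default_factory=list)
    extras: list[DuplexRecord] = field(default_factory=list)

    @property
    def unassigned(self) -> bool:
        return not self.primaries

    @property
    def guide_names(self) -> list[str]:
        return sorted({r.snorna for r in self.primaries})


@dataclass
class AssignmentReport:
    """Per-site guide assignments plus recomputable aggregate statistics."""

    assignments: dict[tuple[str, int], SiteAssignment]
    catalog: list[SnoRNA] = field(default_factory=list)

    def __getitem__(self, key: tuple[str, int]) -> SiteAssignment:
        return self.assignments[key]

    @property
    def sites(self) -> list[SiteAssignment]:
        return list(self.assignments.values())

    def stats(self) -> dict:
        gene_of = {s.name: s.gene for s in self.catalog}
        n_assigned = sum(not a.unassigned for a in self.sites)
        best_lengths = [max(r.length for r in a.primaries)
                        for a in self.sites if not a.unassigned]
        multi = sum(
            len({gene_of.get(r.snorna, r.snorna) for r in a.primaries}) >= 2
            for a in self.sites
        )
        extras = [r for a in self.sites for r in a.extras]
        sub_dists = [r.dist_substrate for r in extras if r.dist_substrate is not None]
        sno_dists = [r.dist_sno for r in extras if r.dist_sno is not None]
        return {
            "n_sites": len(self.sites),
            "n_assigned": n_assigned,
            "n_unassigned": len(self.sites) - n_assigned,
            "n_noncanonical": sum(
                any(r.noncanonical for r in a.primaries) for a in self.sites
            ),
            "n_multi_guide": multi,
            "n_ge9bp": sum(l >= 9 for l in best_lengths),
            "n_with_extra": sum(bool(a.extras) for a in self.sites),
            "primary_length_hist": dict(sorted(Counter(best_lengths).items())),
            "extra_length_hist": dict(sorted(Counter(r.length for r in extras).items())),
            "extra_side_counts": dict(Counter(r.side for r in extras)),
            "median_extra_dist_substrate": float(np.median(sub_dists)) if sub_dists else None,
            "median_extra_dist_sno": float(np.median(sno_dists)) if sno_dists else None,
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a in self.sites:
            records = a.primaries + a.extras
            if not records:
                rows.append((a.site.rna_id, a.site.position, a.site.base,
                             "", "", "", "", "", "", ""))
            for r in records:
                rows.append((
                    a.site.rna_id, a.site.position, a.site.base, r.snorna,
                    r.kind, r.box_used or "", r.nm_offset or "",
                    f"{r.substrate_interval[0]}-{r.substrate_interval[1]}",
                    f"{r.sno_interval[0]}-{r.sno_interval[1]}",
                    r.pair_string(),
                ))
        return pd.DataFrame(rows, columns=[
            "rna_id", "position", "base", "snorna", "kind", "box_used",
            "nm_offset", "substrate_interval", "sno_interval", "pairs",
        ])


def detect_noncanonical(
    report: AssignmentReport,
    nm_sites: Sequence[NmSite],
    targets: Sequence[ReferenceRNA],
    snornas: Sequence[SnoRNA],
) -> AssignmentReport:
    """Add non-canonical (guide position 6/7) records for tandem D'-guided sites.

    An unassigned site 1 nt (offset 6) or 2 nt (offset 7) 3' of a site already
    assigned through a D' guide inherits that guide; offset 6 follows the
    validated tandem pattern, offset 7 is flagged as predicted.
    """
    for key, a in report.assignments.items():
        if not a.unassigned:
            continue
        rna_id, pos = key
        for delta, note in ((1, "tandem D'+5/+6"), (2, "predicted D'+5/+7")):
            upstream = report.assignments.get((rna_id, pos - delta))
            if upstream is None:
                continue
            donors = [r for r in upstream.primaries
                      if r.box_used == "Dprime" and not r.noncanonical]
            for r in donors:
                a.primaries.append(replace(
                    r, nm_position=pos, nm_offset=5 + delta,
                    noncanonical=True, note=note,
                ))
            if donors:
                break
    return report


def assign_all(
    nm_sites: Sequence[NmSite],
    targets: Sequence[ReferenceRNA],
    catalog: Sequence[SnoRNA],
    config: AssignConfig = AssignConfig(),
) -> AssignmentReport:
    """Run the full guide-assignment pipeline over all sites and snoRNAs.

    Pipeline: box location -> D+5 primary search -> GU extension -> extra-pair
    search -> non-canonical tandem detection -> optional relaxed rescue of
    still-unassigned sites.
    """
    by_id = {t.id: t for t in targets}
    cds = [s for s in catalog
           if s.klass == "CD" and (s.expressed or not config.expressed_only)]
    boxes = {s.name: find_boxes(s) for s in cds}
    report = AssignmentReport(
        {(s.rna_id, s.position): SiteAssignment(s) for s in nm_sites},
        catalog=list(catalog),
    )
    for site in nm_sites:
        target = by_id.get(site.rna_id)
        if target is None:
            raise ValueError(f"{site.label}: reference {site.rna_id!r} not loaded")
        a = report[(site.rna_id, site.position)]
        for sno in cds:
            prims = search_primary(site, target, sno, boxes[sno.name],
                                   config.seed_min, config.flank_window)
            prims = [extend_gu(p, target, sno) for p in prims]
            a.primaries.extend(prims)
            if config.search_extras:
                for p in prims:
                    a.extras.extend(search_extra(
                        p, target, sno, boxes[sno.name], config.seed_min,
                        config.extra_len_range, config.max_box_overlap,
                        config.flank_window,
                    ))
    detect_noncanonical(report, nm_sites, targets, cds)
    if config.relaxed:
        for site in nm_sites:
            a = report[(site.rna_id, site.position)]
            if not a.unassigned:
                continue
            for sno in cds:
                a.primaries.extend(search_primary_relaxed(
                    site, by_id[site.rna_id], sno, boxes[sno.name],
                    config.relaxed_min_len, config.flank_window,
                ))
    return report


# ---------------------------------------------------------------------------
# Cross-species conservation


def conservation_intersect(
    site_lists: Mapping[str, Sequence[NmSite]],
    alignment_maps: Optional[Mapping[str, Mapping[tuple[str, int], tuple[str, int]]]] = None,
) -> tuple[dict[str, list[tuple[NmSite, frozenset]]], dict[frozenset, int]]:
    """Label sites with the species sharing their (mapped) position.

    ``alignment_maps[species]`` translates that species' (rna_id, position)
    into common reference coordinates; a missing map means identity and an
    unmapped position counts as species-specific (logged).  Returns per-site
    labels and Venn region counts over common coordinates.
    """
    alignment_maps = alignment_maps or {}
    coord_sets: dict[str, set] = {}
    mapped: dict[str, list] = {}
    for species, sites in site_lists.items():
        amap = alignment_maps.get(species)
        coords = []
        for s in sites:
            key = (s.rna_id, s.position)
            if amap is None:
                coords.append(key)
            elif key in amap:
                coords.append(amap[key])
            else:
                logger.info("%s %s: unmapped, treated as species-specific",
                            species, s.label)
                coords.append(("__unmapped__" + species, s.position, s.rna_id))
        mapped[species] = coords
        coord_sets[species] = set(coords)

    labels: dict[str, list] = {}
    for species, sites in site_lists.items():
        labels[species] = [
            (s, frozenset(sp for sp, cs in coord_sets.items() if c in cs))
            for s, c in zip(sites, mapped[species])
        ]
    venn: dict[frozenset, int] = {}
    all_coords = set().union(*coord_sets.values()) if coord_sets else set()
    for c in all_coords:
        region = frozenset(sp for sp, cs in coord_sets.items() if c in cs)
        venn[region] = venn.get(region, 0) + 1
    return labels, venn
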