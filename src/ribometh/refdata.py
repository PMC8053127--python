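"""Reference RNAs, snoRNA catalogs and Nm annotation tables.

All user-facing coordinates are 1-based and intervals are fully closed, matching
the nucleotide nomenclature used for rRNA sites (e.g. 25S_G2620).  DNA input is
transliterated to RNA (T -> U) on load; the transliteration is logged, not an
error, so genomic FASTA can be used directly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

COMPARTMENTS = ("cytoplasmic", "chloroplast", "mitochondrial", "snRNA", "other")

#: IUPAC degeneracy used for box motifs. R = purine.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "N": "ACGU",
}

BOX_C_MOTIF = "RUGAUGA"
BOX_D_MOTIF = "CUGA"


def motif_matches(motif: str, seq: str) -> bool:
    """True if ``seq`` matches an IUPAC-degenerate ``motif`` exactly."""
    if len(motif) != len(seq):
        return False
    return all(s in IUPAC[m] for m, s in zip(motif, seq))


def _clean_sequence(raw: str, name: str) -> str:
    seq = str(raw).upper()
    if "T" in seq:
        logger.info("record %s: transliterating DNA (T) to RNA (U)", name)
        seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"record {name!r} contains non-RNA characters: {sorted(bad)}"
        )
    if not seq:
        raise ValueError(f"record {name!r} has an empty sequence")
    return seq


@dataclass(frozen=True)
class ReferenceRNA:
    """A reference RNA species (rRNA, snRNA, ...) against which fragments map."""

    id: str
    sequence: str
    compartment: str = "other"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]


Interval = tuple[int, int]


@dataclass
class SnoRNA:
    """A small nucleolar RNA with optional box C/D annotation.

    ``variant_of`` collapses gene variants (U24.1, U24.2 -> U24); ``None`` means
    the record is its own gene.  Box intervals are 1-based closed and optional:
    when absent, :func:`ribometh.guidemap.find_boxes` locates them by motif.
    """

    name: str
    sequence: str
    klass: str = "CD"  # "CD" or "HACA"
    variant_of: Optional[str] = None
    boxC: Optional[Interval] = None
    boxD: Optional[Interval] = None
    boxCprime: Optional[Interval] = None
    boxDprime: Optional[Interval] = None
    expressed: bool = True

    def __post_init__(self) -> None:
        if self.klass not in ("CD", "HACA"):
            raise ValueError(f"unknown snoRNA class {self.klass!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gene(self) -> str:
        return self.variant_of or self.name

    def subseq(self, interval: Interval) -> str:
        a, b = interval
        return self.sequence[a - 1:b]

    def validate_boxes(self) -> None:
        """Check annotated box motifs against the canonical patterns."""
        for iv, motif, label in (
            (self.boxC, BOX_C_MOTIF, "boxC"),
            (self.boxD, BOX_D_MOTIF, "boxD"),
        ):
            if iv is None:
                continue
            a, b = iv
            if not (1 <= a <= b <= self.length):
                raise ValueError(f"{self.name}: {label} interval {iv} outside sequence")
            if not motif_matches(motif, self.subseq(iv)):
                raise ValueError(
                    f"{self.name}: {label} {self.subseq(iv)!r} does not match {motif}"
                )
        order = [iv for iv in (self.boxC, self.boxDprime, self.boxD) if iv]
        if [iv[0] for iv in order] != sorted(iv[0] for iv in order):
            raise ValueError(f"{self.name}: boxes out of 5'->3' order C, D', D")


@dataclass
class NmSite:
    """An annotated 2'-O-methylated nucleotide."""

    rna_id: str
    position: int
    base: str
    assigned_guides: list[str] = field(default_factory=list)
    noncanonical: bool = False
    conservation: frozenset[str] = frozenset()

    @property
    def label(self) -> str:
        return f"{self.rna_id}_{self.base}{self.position}"


# ---------------------------------------------------------------------------
# FASTA / TSV loading


def load_fasta(path: str | Path, compartment: str = "other") -> list[ReferenceRNA]:
    """Load reference RNAs from FASTA; DNA is transliterated, ids must be unique."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    rnas: list[ReferenceRNA] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        rnas.append(ReferenceRNA(rec.id, _clean_sequence(rec.seq, rec.id), compartment))
    return rnas


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a '#'-headed TSV; the first line names the columns."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#'-prefixed header line")
        columns = header.lstrip("#").rstrip("\n").split("\t")
        df = pd.read_csv(
            fh, sep="\t", names=columns, dtype=str, keep_default_na=False
        )
    return df


def load_nm_table(
    path: str | Path,
    references: Optional[Sequence[ReferenceRNA]] = None,
) -> list[NmSite]:
    """Load an Nm annotation table (rna_id, position, base, guides, noncanonical).

    When ``references`` are given, each site's position and base are validated
    against the reference sequence.
    """
    df = _read_tsv(path)
    required = {"rna_id", "position", "base"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    by_id = {r.id: r for r in references} if references else {}
    sites: list[NmSite] = []
    for row in df.itertuples(index=False):
        pos = int(row.position)
        base = row.base.upper().replace("T", "U")
        guides = [g for g in getattr(row, "guides", "").split(";") if g]
        noncanon = getattr(row, "noncanonical", "0") in ("1", "true", "True")
        cons_raw = getattr(row, "conservation", "")
        cons = frozenset(c for c in cons_raw.split(";") if c)
        site = NmSite(row.rna_id, pos, base, guides, noncanon, cons)
        ref = by_id.get(row.rna_id)
        if ref is not None:
            if not 1 <= pos <= ref.length:
                raise ValueError(f"{site.label}: position outside 1..{ref.length}")
            if ref.base(pos) != base:
                raise ValueError(
                    f"{site.label}: annotated base {base} != reference {ref.base(pos)}"
                )
        sites.append(site)
    return sites


def write_nm_table(sites: Iterable[NmSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#rna_id\tposition\tbase\tguides\tnoncanonical\tconservation\n")
        for s in sites:
            fh.write(
                f"{s.rna_id}\t{s.position}\t{s.base}\t{';'.join(s.assigned_guides)}\t"
                f"{int(s.noncanonical)}\t{';'.join(sorted(s.conservation))}\n"
            )


# ---------------------------------------------------------------------------
# snoRNA catalogs


def _parse_interval(text: str) -> Optional[Interval]:
    if not text:
        return None
    m = re.match(r"^(\d+)-(\d+)$", text)
    if not m:
        raise ValueError(f"bad interval {text!r}; expected 'start-end' (1-based closed)")
    return int(m.group(1)), int(m.group(2))


def load_catalog(
    fasta_path: str | Path,
    meta_path: Optional[str | Path] = None,
    validate: bool = False,
) -> list[SnoRNA]:
    """Load a snoRNA catalog from FASTA plus an optional metadata TSV.

    The metadata columns are name, variant_of, klass, expressed and the four
    optional box intervals written as 'start-end'.
    """
    seqs = {r.id: _clean_sequence(r.seq, r.id) for r in SeqIO.parse(str(fasta_path), "fasta")}
    meta: dict[str, dict] = {}
    if meta_path is not None:
        df = _read_tsv(meta_path)
        for row in df.itertuples(index=False):
            meta[row.name] = {
                "variant_of": getattr(row, "variant_of", "") or None,
                "klass": getattr(row, "klass", "CD") or "CD",
                "expressed": getattr(row, "expressed", "1") in ("1", "true", "True"),
                "boxC": _parse_interval(getattr(row, "boxC", "")),
                "boxD": _parse_interval(getattr(row, "boxD", "")),
                "boxCprime": _parse_interval(getattr(row, "boxCprime", "")),
                "boxDprime": _parse_interval(getattr(row, "boxDprime", "")),
            }
    catalog = [SnoRNA(name=name, sequence=seq, **meta.get(name, {})) for name, seq in seqs.items()]
    if validate:
        for sno in catalog:
            sno.validate_boxes()
    return catalog


def catalog_stats(catalog: Sequence[SnoRNA]) -> dict:
    """Distinct gene and gene-variant counts per class, split by expression.

    Variants are collapsed onto ``variant_of`` (a record with none is its own
    gene); a ``variant_of`` that names no catalog gene and no record is an error.
    """
    names = {s.name for s in catalog}
    for s in catalog:
        if s.variant_of is None or s.variant_of in names:
            continue
        # a gene label is fine as long as some other record shares it
        if not any(o is not s and o.gene == s.variant_of for o in catalog):
            raise ValueError(f"{s.name}: dangling variant_of {s.variant_of!r}")
    out: dict = {}
    for klass in ("CD", "HACA"):
        members = [s for s in catalog if s.klass == klass]
        expressed = [s for s in members if s.expressed]
        out[klass] = {
            "genes": len({s.gene for s in members}),
            "variants": len(members),
            "expressed_genes": len({s.gene for s in expressed}),
            "expressed_variants": len(expressed),
        }
    return out


# ---------------------------------------------------------------------------
# Packaged annotation fixtures (printed tables, bundled as TSV)


def _packaged(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("ribometh").joinpath("data", name)))


def cytoplasmic_nm_sites() -> list[NmSite]:
    """The 111 Nm annotated in Arabidopsis cytoplasmic rRNAs (18S/25S/5.8S)."""
    return load_nm_table(_packaged("arabidopsis_cytoplasmic_nm.tsv"))


def organellar_nm_sites() -> list[NmSite]:
    """Nm annotated in Arabidopsis chloroplast (Pt_*) and mitochondrial (Mt_*) rRNAs."""
    return load_nm_table(_packaged("arabidopsis_organellar_nm.tsv"))


def snrna_nm_sites() -> list[NmSite]:
    """The 19 Nm annotated in Arabidopsis spliceosomal snRNAs."""
    return load_nm_table(_packaged("arabidopsis_snrna_nm.tsv"))
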