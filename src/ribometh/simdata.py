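"""Synthetic RiboMeth-seq scenes with machine-readable ground truth.

A scene holds random reference RNAs, planted 2'-O-methylation sites with
per-site stoichiometry f, and box C/D snoRNAs constructed with correct box
architecture whose guide elements are exact antisense complements of the
substrate windows (placing each site at the planted guide offset).

Fragmentation follows the alkaline-hydrolysis model: each molecule draws its
methylation state per site as Bernoulli(f) — stoichiometry is a property of
the molecule population, not of individual bonds — and every unprotected bond
is cleaved independently with probability p0.  A methylated nucleotide fully
protects the bond 3' of it.  Fragments between consecutive cuts (and the
molecule termini) are kept when their length falls inside the insert-size
selection window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .refdata import NmSite, ReferenceRNA, SnoRNA

RNA_BASES = np.array(list("ACGU"))
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class NmTruth:
    """A planted methylation site."""

    rna_id: str
    position: int
    stoichiometry: float
    guide_snorna: Optional[str] = None
    nm_offset_planted: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.stoichiometry <= 1:
            raise ValueError("stoichiometry must be in [0, 1]")
        if self.nm_offset_planted not in (5, 6, 7):
            raise ValueError("planted offset must be 5, 6 or 7")


@dataclass(frozen=True)
class SiteSpec:
    """Requested placement of one planted site (input to make_scene)."""

    rna_index: int = 0
    position: Optional[int] = None  # None -> random placement
    f: float = 1.0
    guided: bool = True
    box: str = "D"  # guide slot used: "D" or "Dprime"
    offset: int = 5  # 6/7 sites attach to the offset-5 site (offset-5) nt 5'
    extra_pair: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for scene generation and fragmentation.

    ``p0`` is the per-bond cleavage probability per molecule under mild
    alkaline hydrolysis; ``insert_range`` is the retained fragment-length
    window (the library's gel cut minus adaptors).  ``n_fragments_target`` is
    the number of retained fragments per RNA.
    """

    seed: int = 0
    n_rnas: int = 1
    rna_length: int = 2000
    gc_content: float = 0.5
    p0: float = 0.02
    n_fragments_target: int = 50_000
    insert_range: tuple[int, int] = (20, 200)
    n_molecules_max: int = 2_000_000
    mutation_rate: float = 0.0
    n_sites: int = 20
    stoichiometry: float = 1.0
    guide_len_range: tuple[int, int] = (10, 12)
    site_margin: int = 110  # min distance of planted sites from RNA ends
    site_min_separation: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        if self.insert_range[0] < 1 or self.insert_range[0] > self.insert_range[1]:
            raise ValueError("bad insert_range")


@dataclass
class Scene:
    references: list[ReferenceRNA]
    snornas: list[SnoRNA]
    truth: list[NmTruth]
    config: SimulationConfig

    def reference(self, rna_id: str) -> ReferenceRNA:
        return next(r for r in self.references if r.id == rna_id)

    def truth_sites(self) -> list[NmSite]:
        """Planted truth as NmSite annotations (guides filled from truth)."""
        out = []
        for t in self.truth:
            ref = self.reference(t.rna_id)
            guides = [t.guide_snorna] if t.guide_snorna else []
            out.append(NmSite(t.rna_id, t.position, ref.base(t.position), guides,
                              noncanonical=t.nm_offset_planted != 5))
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "references.fasta", "w") as fh:
            for r in self.references:
                fh.write(f">{r.id}\n{r.sequence}\n")
        with open(outdir / "snornas.fasta", "w") as fh:
            for s in self.snornas:
                fh.write(f">{s.name}\n{s.sequence}\n")
        with open(outdir / "snorna_catalog.tsv", "w") as fh:
            fh.write("#name\tvariant_of\tklass\texpressed\tboxC\tboxD\tboxCprime\tboxDprime\n")
            for s in self.snornas:
                ivs = ["%d-%d" % iv if iv else "" for iv in
                       (s.boxC, s.boxD, s.boxCprime, s.boxDprime)]
                fh.write(f"{s.name}\t{s.variant_of or ''}\t{s.klass}\t"
                         f"{int(s.expressed)}\t" + "\t".join(ivs) + "\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("#rna_id\tposition\tstoichiometry\tguide_snorna\tnm_offset\n")
            for t in self.truth:
                fh.write(f"{t.rna_id}\t{t.position}\t{t.stoichiometry}\t"
                         f"{t.guide_snorna or ''}\t{t.nm_offset_planted}\n")
        with open(outdir / "scene_config.json", "w") as fh:
            json.dump({k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(self.config).items()}, fh, indent=1)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(RNA_BASES, size=length, p=probs))


def _place_positions(
    rng: np.random.Generator, length: int, n: int, margin: int, min_sep: int
) -> list[int]:
    lo, hi = margin, length - margin
    span = hi - lo - (n - 1) * min_sep
    if n > 0 and span < 0:
        raise ValueError(f"cannot place {n} sites with separation {min_sep} "
                         f"on an RNA of length {length}")
    if n == 0:
        return []
    # sorted draws in the compressed span, then re-inflate the gaps
    base = np.sort(rng.integers(0, span + 1, size=n))
    pos = base + lo + np.arange(n) * min_sep
    return [int(p) for p in pos]


def make_scene(
    config: SimulationConfig,
    site_specs: Optional[Sequence[SiteSpec]] = None,
    scramble_guides: Sequence[str] = (),
) -> Scene:
    """Build a fully specified scene from the configuration.

    When ``site_specs`` is omitted, ``n_sites`` canonically guided (D box,
    offset 5) sites at ``stoichiometry`` are placed at random positions.
    ``scramble_guides`` shuffles the guide element of the named snoRNAs after
    construction (for guide-degradation experiments); ``mutation_rate``
    applies random point substitutions to every guide element instead.
    """
    rng = np.random.default_rng(config.seed)
    lengths = [config.rna_length] * config.n_rnas
    references = [
        ReferenceRNA(f"rna{i}", _random_seq(rng, L, config.gc_content))
        for i, L in enumerate(lengths)
    ]

    if site_specs is None:
        per_rna = np.array_split(np.arange(config.n_sites), config.n_rnas)
        site_specs = []
        for i, chunk in enumerate(per_rna):
            for _ in chunk:
                site_specs.append(SiteSpec(rna_index=i, f=config.stoichiometry))
    site_specs = list(site_specs)

    # resolve positions per RNA
    resolved: list[SiteSpec] = []
    for i, ref in enumerate(references):
        specs_here = [s for s in site_specs if s.rna_index == i]
        free = [s for s in specs_here if s.position is None]
        taken = [s.position for s in specs_here if s.position is not None]
        auto = _place_positions(rng, ref.length, len(free),
                                config.site_margin, config.site_min_separation) \
            if free else []
        it = iter(auto)
        for s in specs_here:
            pos = s.position if s.position is not None else next(it)
            gmax = config.guide_len_range[1]
            if pos - 4 < 1 or pos + gmax - 4 > ref.length:
                raise ValueError(
                    f"site at {ref.id}:{pos} too close to the RNA end for a "
                    f"guide window")
            resolved.append(replace(s, position=pos))
        if len({s.position for s in resolved if s.rna_index == i}) != len(specs_here):
            raise ValueError(f"duplicate site positions on {ref.id}")
    site_specs = resolved

    # offset-6/7 specs attach to the offset-5 spec (offset-5) nt upstream,
    # which must use the D' guide slot
    anchors: dict[tuple[int, int], SiteSpec] = {
        (s.rna_index, s.position): s for s in site_specs if s.offset == 5
    }
    for s in site_specs:
        if s.offset in (6, 7):
            key = (s.rna_index, s.position - (s.offset - 5))
            if key not in anchors:
                raise ValueError(
                    f"offset-{s.offset} site at rna{s.rna_index}:{s.position} "
                    f"needs an offset-5 anchor at {key[1]}")
            if anchors[key].box != "Dprime":
                raise ValueError("non-canonical anchors must use the D' guide slot")

    snornas: list[SnoRNA] = []
    truth: list[NmTruth] = []
    guide_name: dict[tuple[int, int], str] = {}
    for s in site_specs:
        ref = references[s.rna_index]
        if s.offset == 5 and s.guided:
            sno = _build_snorna(rng, ref, s, len(snornas), config)
            snornas.append(sno)
            guide_name[(s.rna_index, s.position)] = sno.name
    for s in site_specs:
        ref = references[s.rna_index]
        if s.offset in (6, 7):
            guide = guide_name.get((s.rna_index, s.position - (s.offset - 5)))
        else:
            guide = guide_name.get((s.rna_index, s.position)) if s.guided else None
        truth.append(NmTruth(ref.id, s.position, s.f, guide, s.offset))

    if config.mutation_rate > 0 or scramble_guides:
        snornas = [_degrade_guide(rng, sno, config.mutation_rate,
                                  sno.name in set(scramble_guides))
                   for sno in snornas]
    return Scene(references, snornas, sorted(truth, key=lambda t: (t.rna_id, t.position)), config)


def _build_snorna(
    rng: np.random.Generator, ref: ReferenceRNA, spec: SiteSpec,
    index: int, config: SimulationConfig,
) -> SnoRNA:
    """Assemble pad-C-spacer-[D' guide]-NNGA-spacer-[D guide]-CUGA-pad."""
    glen = int(rng.integers(config.guide_len_range[0], config.guide_len_range[1] + 1))
    nm = spec.position
    # substrate positions nm-4 .. nm+glen-5 pair guide positions 1..glen;
    # the guide element is their reverse complement
    guide = revcomp(ref.sequence[nm - 5: nm + glen - 5])
    filler = lambda n: _random_seq(rng, n, 0.5)  # noqa: E731

    pad5 = filler(5)
    boxC = rng.choice(["A", "G"]) + "UGAUGA"
    if spec.extra_pair and spec.box == "D":
        # an 8-nt element complementary to the flank just 3' of the primary
        # substrate interval, planted inside the first spacer
        flank = ref.sequence[nm + glen - 5: nm + glen + 3]
        spacer1 = filler(2) + revcomp(flank)
    else:
        spacer1 = filler(10)
    dprime_slot = guide if spec.box == "Dprime" else filler(10)
    boxDp = filler(2) + "GA"
    spacer2 = filler(8)
    d_slot = guide if spec.box == "D" else filler(10)
    boxD = "CUGA"
    pad3 = filler(3)

    parts = [pad5, boxC, spacer1, dprime_slot, boxDp, spacer2, d_slot, boxD, pad3]
    seq = "".join(parts)
    offs = np.cumsum([0] + [len(p) for p in parts])
    iv = lambda k: (int(offs[k]) + 1, int(offs[k + 1]))  # noqa: E731
    return SnoRNA(
        name=f"sno{index}", sequence=seq, klass="CD",
        boxC=iv(1), boxDprime=iv(4), boxD=iv(7), expressed=True,
    )


def _degrade_guide(
    rng: np.random.Generator, sno: SnoRNA, rate: float, scramble: bool
) -> SnoRNA:
    """Point-mutate or shuffle the guide elements of a synthetic snoRNA."""
    seq = list(sno.sequence)
    for iv_box in (sno.boxD, sno.boxDprime):
        if iv_box is None:
            continue
        lo = max(0, iv_box[0] - 1 - 12)
        hi = iv_box[0] - 1
        if scramble:
            segment = [seq[k] for k in range(lo, hi)]
            rng.shuffle(segment)
            seq[lo:hi] = segment
        elif rate > 0:
            for k in range(lo, hi):
                if rng.random() < rate:
                    seq[k] = str(rng.choice([b for b in "ACGU" if b != seq[k]]))
    return replace(sno, sequence="".join(seq))


# ---------------------------------------------------------------------------
# Fragmentation


@dataclass
class FragmentSet:
    """Simulated retained fragments per RNA (1-based closed intervals)."""

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    n_molecules: dict[str, int]
    seed: int

    def n_fragments(self, rna_id: str) -> int:
        return int(self.starts[rna_id].size)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#rna_id\tstart\tend\n")
            for rna_id in self.starts:
                for a, b in zip(self.starts[rna_id], self.ends[rna_id]):
                    fh.write(f"{rna_id}\t{a}\t{b}\n")


def simulate_fragments(
    references: Sequence[ReferenceRNA],
    truth: Sequence[NmTruth],
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> FragmentSet:
    """Simulate alkaline fragmentation with methylation protection.

    Molecules are generated until ``n_fragments_target`` retained fragments
    per RNA or ``n_molecules_max`` molecules; falling short is an error that
    reports the achieved count.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    n_mol: dict[str, int] = {}
    lmin, lmax = config.insert_range
    for ref in references:
        L = ref.length
        sites = [(t.position, t.stoichiometry) for t in truth if t.rna_id == ref.id]
        acc_s: list[np.ndarray] = []
        acc_e: list[np.ndarray] = []
        n_ret, molecules = 0, 0
        # roughly one cut per 1/p0 nt -> ~L*p0 fragments per molecule
        batch = max(64, int(config.n_fragments_target / max(1.0, (L - 1) * config.p0)) + 1)
        while n_ret < config.n_fragments_target and molecules < config.n_molecules_max:
            m = min(batch, config.n_molecules_max - molecules)
            cuts = rng.random((m, L - 1)) < config.p0
            for pos, f in sites:
                # bond `pos` is protected in the methylated fraction of molecules
                methylated = rng.random(m) < f
                cuts[methylated, pos - 1] = False
            s_arr, e_arr = _fragments_from_cuts(cuts, L, lmin, lmax)
            acc_s.append(s_arr)
            acc_e.append(e_arr)
            n_ret += s_arr.size
            molecules += m
        if n_ret < config.n_fragments_target:
            raise RuntimeError(
                f"{ref.id}: only {n_ret}/{config.n_fragments_target} fragments "
                f"after {molecules} molecules")
        s_all = np.concatenate(acc_s)[:config.n_fragments_target]
        e_all = np.concatenate(acc_e)[:config.n_fragments_target]
        starts[ref.id], ends[ref.id] = s_all, e_all
        n_mol[ref.id] = molecules
    return FragmentSet(starts, ends, n_mol, seed)


def _fragments_from_cuts(
    cuts: np.ndarray, L: int, lmin: int, lmax: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized conversion of per-molecule cut matrices to retained fragments."""
    m = cuts.shape[0]
    mol_idx, bond_idx = np.nonzero(cuts)  # row-major: sorted by molecule, bond
    cut_pos = bond_idx + 1  # a cut after nucleotide cut_pos
    counts = cuts.sum(axis=1)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1]) + m  # fragments = cuts + 1 per molecule
    frag_starts = np.empty(total, dtype=np.int64)
    frag_ends = np.empty(total, dtype=np.int64)
    out = 0
    for i in range(m):
        cp = cut_pos[offsets[i]:offsets[i + 1]]
        k = cp.size + 1
        frag_ends[out:out + k - 1] = cp
        frag_ends[out + k - 1] = L
        frag_starts[out] = 1
        frag_starts[out + 1:out + k] = cp + 1
        out += k
    lengths = frag_ends - frag_starts + 1
    keep = (lengths >= lmin) & (lengths <= lmax)
    return frag_starts[keep], frag_ends[keep]


# ---------------------------------------------------------------------------
# Condition pairs (wild type vs mutant)


@dataclass(frozen=True)
class KnockdownSpec:
    """Planted perturbation: scale snoRNA copy numbers and/or site stoichiometries.

    ``snorna_factors`` maps snoRNA names to abundance scale factors;
    ``class_factor`` applies one factor to a whole class ("CD"/"HACA").
    ``site_f`` overrides stoichiometries outright; with ``couple_sites`` the
    stoichiometry of each guided site is instead scaled by its guide's
    abundance factor (methylation tracks snoRNP availability).
    """

    snorna_factors: Mapping[str, float] = field(default_factory=dict)
    class_factor: Optional[tuple[str, float]] = None
    site_f: Mapping[tuple[str, int], float] = field(default_factory=dict)
    couple_sites: bool = False


@dataclass
class ConditionPair:
    wt_fragments: FragmentSet
    mut_fragments: FragmentSet
    wt_counts: dict[str, int]
    mut_counts: dict[str, int]
    lengths: dict[str, int]
    truth_wt: list[NmTruth]
    truth_mut: list[NmTruth]
    factors: dict[str, float]


def make_condition_pair(
    scene: Scene,
    spec: KnockdownSpec,
    seed: Optional[int] = None,
    reference_id: str = "18S",
    reference_reads: int = 40_000,
    snorna_copies: tuple[int, int] = (20_000, 100_000),
    reads_per_copy_kb: float = 0.02,
) -> ConditionPair:
    """Simulate a wild-type / mutant pair with planted abundance deltas.

    snoRNA read counts are Poisson draws proportional to copy number x length;
    a stable reference RNA (default id "18S") anchors the normalization.
    Mutant stoichiometries follow ``spec``.
    """
    seed = scene.config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    factors: dict[str, float] = {}
    for sno in scene.snornas:
        f = 1.0
        if spec.class_factor and sno.klass == spec.class_factor[0]:
            f = spec.class_factor[1]
        f = spec.snorna_factors.get(sno.name, f)
        factors[sno.name] = f
    unknown = set(spec.snorna_factors) - {s.name for s in scene.snornas}
    if unknown:
        raise ValueError(f"unknown snoRNAs in knockdown spec: {sorted(unknown)}")

    truth_mut = []
    for t in scene.truth:
        f = t.stoichiometry
        if (t.rna_id, t.position) in spec.site_f:
            f = spec.site_f[(t.rna_id, t.position)]
        elif spec.couple_sites and t.guide_snorna is not None:
            f = f * factors[t.guide_snorna]
        truth_mut.append(replace(t, stoichiometry=f))

    wt_frags = simulate_fragments(scene.references, scene.truth, scene.config,
                                  seed=int(rng.integers(2**31)))
    mut_frags = simulate_fragments(scene.references, truth_mut, scene.config,
                                   seed=int(rng.integers(2**31)))

    lengths = {reference_id: 1800}
    copies = {}
    wt_counts = {reference_id: int(rng.poisson(reference_reads))}
    mut_counts = {reference_id: int(rng.poisson(reference_reads))}
    for sno in scene.snornas:
        lengths[sno.name] = sno.length
        copies[sno.name] = int(rng.integers(*snorna_copies))
        lam = copies[sno.name] * sno.length / 1000 * reads_per_copy_kb
        wt_counts[sno.name] = int(rng.poisson(lam))
        mut_counts[sno.name] = int(rng.poisson(lam * factors[sno.name]))
    return ConditionPair(wt_frags, mut_frags, wt_counts, mut_counts, lengths,
                         list(scene.truth), truth_mut, factors)
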