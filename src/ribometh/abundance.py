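"""RNA abundance quantification normalized to 18S rRNA.

Reads mapped to an RNA (fragments, i.e. read pairs) are divided by the RNA
length in kilobases (RPK); dividing each RPK by the 18S RPK and scaling by
1e6 gives a normalized TPM: the number of molecules per million 18S rRNA
molecules.  Cytoplasmic rRNA is a stable internal standard across samples,
which makes normalized TPM comparable between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AbundanceRecord:
    rna_id: str
    mapped_reads: int
    length_kb: float
    rpk: float
    norm_tpm: float


def quantify(
    read_counts: Mapping[str, int],
    lengths: Mapping[str, int],
    reference_id: str = "18S",
) -> dict[str, AbundanceRecord]:
    """Compute RPK and 18S-normalized TPM for every RNA.

    The reference RNA reports norm_tpm = 1e6 by construction; a missing or
    zero-count reference is an error.
    """
    if reference_id not in read_counts or read_counts[reference_id] <= 0:
        raise ValueError(f"reference RNA {reference_id!r} missing or has zero reads")
    ref_rpk = read_counts[reference_id] / (lengths[reference_id] / 1000)
    out = {}
    for rna_id, reads in read_counts.items():
        if rna_id not in lengths:
            raise ValueError(f"no length for {rna_id!r}")
        length_kb = lengths[rna_id] / 1000
        rpk = reads / length_kb
        out[rna_id] = AbundanceRecord(
            rna_id, int(reads), length_kb, rpk, rpk / ref_rpk * 1e6
        )
    return out


@dataclass
class FractionChange:
    """Per-RNA and aggregate abundance fraction changes between conditions.

    ``change`` = (TPM_wt - TPM_mut) / TPM_wt: 1 means complete loss, 0 no
    change, negative means accumulation.  The aggregate over a class is
    computed both as the change of summed TPM and as the mean of per-RNA
    changes; the two differ when abundances are heterogeneous.
    """

    per_rna: pd.DataFrame
    aggregate_summed: Optional[float]
    aggregate_mean: Optional[float]
    excluded: list[str]


def fraction_change(
    wt: Mapping[str, AbundanceRecord],
    mut: Mapping[str, AbundanceRecord],
    members: Optional[Sequence[str]] = None,
) -> FractionChange:
    """Fraction change of normalized TPM from wt to mutant.

    ``members`` restricts the aggregate to a class of RNAs (e.g. all C/D
    snoRNAs); RNAs with zero wt TPM are excluded from per-RNA changes.
    """
    ids = list(members) if members is not None else sorted(set(wt) & set(mut))
    rows, excluded = [], []
    for rna_id in ids:
        if rna_id not in wt or rna_id not in mut:
            excluded.append(rna_id)
            continue
        tw, tm = wt[rna_id].norm_tpm, mut[rna_id].norm_tpm
        if tw == 0:
            excluded.append(rna_id)
            continue
        rows.append((rna_id, tw, tm, (tw - tm) / tw))
    df = pd.DataFrame(rows, columns=["rna_id", "tpm_wt", "tpm_mut", "change"])
    total_wt = df["tpm_wt"].sum()
    agg_sum = float((total_wt - df["tpm_mut"].sum()) / total_wt) if total_wt > 0 else None
    agg_mean = float(df["change"].mean()) if len(df) else None
    return FractionChange(df, agg_sum, agg_mean, excluded)


def cumulative_guide_change(
    guide_names: Sequence[str],
    wt: Mapping[str, AbundanceRecord],
    mut: Mapping[str, AbundanceRecord],
) -> Optional[float]:
    """Fraction change of the summed abundance of all guides of one site.

    All assigned guide variants are summed per condition before the change is
    taken.  Returns None when no guide is quantified in both conditions or
    the wt sum is zero.
    """
    quantified = [g for g in guide_names if g in wt and g in mut]
    if not quantified:
        return None
    tw = sum(wt[g].norm_tpm for g in quantified)
    tm = sum(mut[g].norm_tpm for g in quantified)
    if tw == 0:
        return None
    return (tw - tm) / tw


def guide_change_score_correlation(
    deltas: Sequence[float], guide_changes: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between per-site MethScore changes and cumulative
    guide abundance changes (r, p)."""
    if len(deltas) != len(guide_changes) or len(deltas) < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = stats.pearsonr(np.asarray(deltas), np.asarray(guide_changes))
    return float(r), float(p)


def abundance_table(records: Mapping[str, AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.rna_id, r.mapped_reads, r.rpk, r.norm_tpm)
         for r in sorted(records.values(), key=lambda r: r.rna_id)],
        columns=["rna_id", "reads", "rpk", "norm_tpm"],
    )
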