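"""Pool-differentiating variants: fixed vs polymorphic, synonymous vs
non-synonymous, with the derived allele's frequency in the wild pool.

A column is *fixed* between two pools when each pool is monomorphic over its
non-missing calls (with at least ``min_called`` called samples, guarding
against fixation declared from one or two sequences) and the two alleles
differ.  Coding effect is determined by translating the codon containing the
column under each observed allele with the standard genetic code; columns
with gap alleles are reported structurally as indels and never classified
synonymous/non-synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import INGROUP_POOLS, LocusAlignment

__all__ = [
    "VariantCall",
    "call_pool_variants",
    "classify_coding_effect",
    "screen_selected_loci",
    "variant_table",
]

DEFAULT_MIN_CALLED = 4


@dataclass(frozen=True)
class VariantCall:
    locus_id: str
    column: int                       # 0-based alignment position
    alleles: dict                     # pool -> {allele(str): count} over non-missing calls
    fixed_between: tuple[tuple[str, str], ...]
    coding_effect: str                # synonymous | nonsynonymous | noncoding | indel
    wild_freq_derived: float          # NaN when undefined


def _cds_position_map(aln: LocusAlignment) -> dict[int, int]:
    """Alignment column -> index in the concatenated CDS."""
    mapping: dict[int, int] = {}
    pos = 0
    for start, end in aln.cds_intervals:
        for c in range(start, end):
            mapping[c] = pos
            pos += 1
    return mapping


def classify_coding_effect(
    aln: LocusAlignment, column: int, alleles: list[str]
) -> str:
    """Effect of substituting ``alleles`` at ``column``.

    Gap alleles -> ``indel``; columns outside the CDS (or in an incomplete
    codon) -> ``noncoding``; otherwise the codon containing the column is
    translated under each allele, with the remaining codon positions taken
    from the majority base: any amino-acid change -> ``nonsynonymous``.
    """
    if "-" in alleles:
        return "indel"
    cds_map = _cds_position_map(aln)
    if not cds_map:
        return "noncoding"
    total = len(cds_map)
    if (total - aln.frame) % 3 != 0:
        raise ValueError(
            f"locus {aln.locus_id}: CDS length {total} minus frame {aln.frame} "
            "is not a multiple of 3"
        )
    if column not in cds_map:
        return "noncoding"
    cds_pos = cds_map[column]
    if cds_pos < aln.frame:
        return "noncoding"
    codon_idx = (cds_pos - aln.frame) // 3
    codon_cds = [aln.frame + 3 * codon_idx + o for o in range(3)]
    inv = {v: k for k, v in cds_map.items()}
    codon_cols = [inv[p] for p in codon_cds]
    offset = cds_pos - codon_cds[0]
    context = [_majority_base(aln, c) for c in codon_cols]
    if any(b is None for b in context):
        return "noncoding"
    aas = set()
    for allele in alleles:
        codon = context.copy()
        codon[offset] = allele
        aas.add(str(Seq("".join(codon)).translate()))
    return "synonymous" if len(aas) == 1 else "nonsynonymous"


def _majority_base(aln: LocusAlignment, column: int) -> str | None:
    col = aln.residues[:, column]
    ok = (col != b"N") & (col != b"-")
    if not ok.any():
        return None
    vals, counts = np.unique(col[ok], return_counts=True)
    return vals[np.argmax(counts)].decode("ascii")


def call_pool_variants(
    aln: LocusAlignment, min_called: int = DEFAULT_MIN_CALLED
) -> list[VariantCall]:
    """Emit every column polymorphic or pool-differentiating among the
    ingroup pools, with per-pool allele counts over non-missing calls."""
    pools_present = [p for p in INGROUP_POOLS if p in aln.pools]
    if len(pools_present) < 2:
        raise ValueError(f"locus {aln.locus_id}: need >= 2 ingroup pools")
    rows_by_pool = {p: aln.pool_members(p) for p in pools_present}
    calls: list[VariantCall] = []
    for col in range(aln.alignment_length):
        column = aln.residues[:, col]
        counts: dict[str, dict[str, int]] = {}
        observed: set[str] = set()
        for pool, rows in rows_by_pool.items():
            sub = column[rows]
            sub = sub[sub != b"N"]
            vals, cnt = np.unique(sub, return_counts=True)
            counts[pool] = {v.decode("ascii"): int(c) for v, c in zip(vals, cnt)}
            observed.update(counts[pool])
        if len(observed) < 2:
            continue
        fixed_allele = {
            pool: next(iter(c)) for pool, c in counts.items()
            if len(c) == 1 and sum(c.values()) >= min_called
        }
        fixed_between = tuple(
            (p1, p2)
            for p1, p2 in combinations(pools_present, 2)
            if p1 in fixed_allele and p2 in fixed_allele
            and fixed_allele[p1] != fixed_allele[p2]
        )
        wild_freq = float("nan")
        if "improved" in fixed_allele and "wild" in counts and counts["wild"]:
            cultivated = fixed_allele["improved"]
            n_wild = sum(counts["wild"].values())
            wild_freq = counts["wild"].get(cultivated, 0) / n_wild
        effect = classify_coding_effect(aln, col, sorted(observed))
        calls.append(
            VariantCall(
                locus_id=aln.locus_id, column=col, alleles=counts,
                fixed_between=fixed_between, coding_effect=effect,
                wild_freq_derived=wild_freq,
            )
        )
    return calls


def screen_selected_loci(
    scan_table: pd.DataFrame,
    calls_by_locus: dict[str, list[VariantCall]],
    wild_freq_cutoff: float = 0.20,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """For each FDR-significant locus, list fixed non-synonymous differences
    involving the cultivated pools and flag those whose cultivated allele is
    at low frequency (< cutoff) in the wild."""
    sig = (
        scan_table.dropna(subset=["q_value"])
        .groupby("locus")["q_value"].min()
        .pipe(lambda s: set(s[s < fdr_alpha].index))
    )
    rows = []
    for locus in sorted(sig):
        for call in calls_by_locus.get(locus, []):
            if call.coding_effect != "nonsynonymous":
                continue
            pairs = [
                pair for pair in call.fixed_between
                if "wild" in pair or ("landrace" in pair and "improved" in pair)
            ]
            if not pairs:
                continue
            low = (
                call.wild_freq_derived < wild_freq_cutoff
                if np.isfinite(call.wild_freq_derived)
                else False
            )
            rows.append(
                dict(
                    locus=locus, column=call.column,
                    fixed_between=";".join("-".join(p) for p in pairs),
                    wild_freq_derived=call.wild_freq_derived,
                    low_wild_freq=low,
                )
            )
    return pd.DataFrame(rows, columns=["locus", "column", "fixed_between", "wild_freq_derived", "low_wild_freq"])


def variant_table(calls: list[VariantCall]) -> pd.DataFrame:
    """VCF-like flat table: one row per variant column."""
    rows = []
    for c in calls:
        rows.append(
            dict(
                locus=c.locus_id, position=c.column,
                alleles=";".join(
                    f"{pool}:" + ",".join(f"{a}={n}" for a, n in sorted(cnt.items()))
                    for pool, cnt in c.alleles.items()
                ),
                fixed_between=";".join("-".join(p) for p in c.fixed_between),
                effect=c.coding_effect,
                wild_freq=c.wild_freq_derived,
            )
        )
    return pd.DataFrame(rows, columns=["locus", "position", "alleles", "fixed_between", "effect", "wild_freq"])
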