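"""Per-locus diversity statistics: S, π, θ_W, haplotype count and divergence.

All statistics are computed after *complete deletion*: every alignment column
containing a gap or missing base (N) in any sequence of the analysis set is
excluded before counting.  Divergence to the single outgroup sequence is the
raw mean Hamming distance on retained columns (no multiple-hit correction by
default; a Jukes–Cantor correction is available behind ``jc_correction``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import INGROUP_POOLS, LocusAlignment, pool_slice

__all__ = [
    "DiversityStats",
    "DivergenceStats",
    "complete_deletion",
    "segregating_sites",
    "watterson_theta",
    "nucleotide_diversity",
    "haplotype_count",
    "outgroup_divergence",
    "harmonic_number",
    "pool_diversity",
    "diversity_table",
]


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson normalizer for n sequences."""
    if n < 2:
        raise ValueError("harmonic_number requires n >= 2")
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass(frozen=True)
class DiversityStats:
    locus_id: str
    pool: str
    n: int
    L_net: int
    S: int
    pi: float
    theta_w: float
    n_hap: int
    a_n: float


@dataclass(frozen=True)
class DivergenceStats:
    locus_id: str
    pool: str
    D: float          # exact mean Hamming distance to the outgroup
    D_rounded: int    # nearest-integer count fed to the Poisson likelihood
    L_net: int
    d_per_site: float


def complete_deletion(aln: LocusAlignment) -> np.ndarray:
    """Indices of columns free of '-' and 'N' in every sequence of ``aln``."""
    bad = (aln.residues == b"-") | (aln.residues == b"N")
    return np.flatnonzero(~bad.any(axis=0))


def segregating_sites(aln: LocusAlignment, retained: np.ndarray) -> int:
    """Number of retained columns with more than one allele in the sample."""
    if aln.n < 2:
        raise ValueError("segregating_sites requires n >= 2 sequences")
    if len(retained) == 0:
        return 0
    cols = aln.residues[:, retained]
    return int((cols != cols[0]).any(axis=0).sum())


def watterson_theta(S: int, n: int, L_net: int) -> float:
    """Watterson's θ per site: S / (a_n · L_net)."""
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    if L_net == 0:
        return float("nan")
    return S / (harmonic_number(n) * L_net)


def nucleotide_diversity(aln: LocusAlignment, retained: np.ndarray) -> float:
    """π per site: mean pairwise Hamming distance on retained columns / L_net."""
    if aln.n < 2:
        raise ValueError("nucleotide_diversity requires n >= 2")
    L_net = len(retained)
    if L_net == 0:
        return float("nan")
    cols = aln.residues[:, retained]
    n = aln.n
    total = 0
    for i in range(n - 1):
        total += int((cols[i + 1 :] != cols[i]).sum())
    n_pairs = n * (n - 1) // 2
    return total / n_pairs / L_net


def haplotype_count(aln: LocusAlignment, retained: np.ndarray) -> int:
    """Number of distinct residue strings restricted to retained columns."""
    if len(retained) == 0:
        return 1 if aln.n >= 1 else 0
    cols = aln.residues[:, retained]
    return len({cols[i].tobytes() for i in range(aln.n)})


def outgroup_divergence(
    aln: LocusAlignment, pool: str, jc_correction: bool = False
) -> DivergenceStats:
    """Mean Hamming distance from each ingroup sequence to the single outgroup.

    Retained columns are taken jointly over the ingroup pool *and* the
    outgroup, so S and D of one HKA test share a site set.
    """
    out_idx = aln.pool_members("outgroup")
    if len(out_idx) != 1:
        raise ValueError(
            f"locus {aln.locus_id}: need exactly one outgroup sequence, found {len(out_idx)}"
        )
    in_idx = aln.pool_members(pool)
    if not in_idx:
        raise ValueError(f"locus {aln.locus_id}: pool {pool!r} empty")
    sub = aln.residues[in_idx + out_idx]
    bad = (sub == b"-") | (sub == b"N")
    retained = np.flatnonzero(~bad.any(axis=0))
    L_net = len(retained)
    if L_net == 0:
        return DivergenceStats(aln.locus_id, pool, float("nan"), 0, 0, float("nan"))
    cols = sub[:, retained]
    diffs = (cols[:-1] != cols[-1]).sum(axis=1)
    D = float(diffs.mean())
    d = D / L_net
    if jc_correction:
        d = -0.75 * np.log1p(-4.0 * d / 3.0)
        D = d * L_net
    return DivergenceStats(aln.locus_id, pool, D, int(round(D)), L_net, d)


def pool_diversity(aln: LocusAlignment, pool: str) -> DiversityStats:
    """Polymorphism statistics for one ingroup pool after complete deletion
    within that pool (the per-pool DnaSP-style summary)."""
    sub = pool_slice(aln, pool)
    if sub.n < 2:
        raise ValueError(f"locus {aln.locus_id}: pool {pool!r} has n < 2")
    retained = complete_deletion(sub)
    L_net = len(retained)
    S = segregating_sites(sub, retained)
    return DiversityStats(
        locus_id=aln.locus_id,
        pool=pool,
        n=sub.n,
        L_net=L_net,
        S=S,
        pi=nucleotide_diversity(sub, retained),
        theta_w=watterson_theta(S, sub.n, L_net),
        n_hap=haplotype_count(sub, retained),
        a_n=harmonic_number(sub.n),
    )


def diversity_table(alignments, pools=INGROUP_POOLS):
    """Table-style summary: one row per locus × pool with divergence attached.

    Returns a pandas DataFrame with columns locus, pool, n, L_net, S, pi,
    theta_w, n_hap, D.
    """
    import pandas as pd

    rows = []
    for aln in alignments:
        has_out = "outgroup" in aln.pools
        for pool in pools:
            if pool not in aln.pools:
                continue
            st = pool_diversity(aln, pool)
            D = outgroup_divergence(aln, pool).D if has_out else float("nan")
            rows.append(
                dict(
                    locus=st.locus_id, pool=pool, n=st.n, L_net=st.L_net, S=st.S,
                    pi=st.pi, theta_w=st.theta_w, n_hap=st.n_hap, D=D,
                )
            )
    return pd.DataFrame(rows)
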