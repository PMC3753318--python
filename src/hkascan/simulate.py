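"""Synthetic study generator: coalescent sequence data and Poisson count data
shaped like a candidate-gene domestication scan.

The default configuration emulates the study design the package targets:
7 putatively neutral loci plus 13 domestication-candidate and 14
improvement-candidate loci of ~700 aligned bp, sampled from 8 wild, 6
landrace and 6 improved accessions plus a single outgroup.  Derived pools
carry a genome-wide bottleneck (diversity scaling < 1 applied to every
locus), and selected loci additionally carry a sweep factor k << 1 in the
pools where selection acted: domestication loci in landrace + improved,
improvement loci in improved only.

Two generators are provided:

* :func:`simulate_counts` draws (S, D) directly from the Poisson HKA model —
  the exact generative twin of the likelihood fitted by :mod:`hkascan.hka`,
  used for calibration and recovery experiments.
* :func:`simulate_alignment` / :func:`simulate_study` build full sequence
  alignments under a standard n-coalescent with infinite-sites mutation:
  within-pool genealogies are scaled by (bottleneck × k); divergence accrues
  along stem and outgroup branches at the locus's ancestral (wild-scale)
  rate, so E[D] = θ·(T + 1)·L for every pool.  Conventions: θ is 4Nμ per
  site; time is measured in units of 2N generations.

Every source of randomness flows from ``SimConfig.seed`` through
``numpy.random.SeedSequence`` spawns, so outputs are bit-identical across
runs and platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import harmonic_number
from .io import (
    INGROUP_POOLS,
    LocusAlignment,
    SampleSheet,
    write_cds_table,
    write_locus_alignment,
    write_sample_sheet,
)

__all__ = ["SimConfig", "SimTruth", "StudyData", "simulate_counts",
           "simulate_alignment", "simulate_study", "locus_sweep_pools"]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

ROLE_NEUTRAL = "neutral"
ROLE_DOM = "domestication-candidate"
ROLE_IMP = "improvement-candidate"


@dataclass(frozen=True)
class SimConfig:
    """Generative description of one synthetic study."""

    seed: int
    n_neutral: int = 7
    n_dom: int = 13
    n_imp: int = 14
    pool_sizes: dict = field(
        default_factory=lambda: {"wild": 8, "landrace": 6, "improved": 6, "outgroup": 1}
    )
    L: int = 700
    theta_site: float = 0.01
    T: float = 8.0
    bottleneck: dict = field(
        default_factory=lambda: {"wild": 1.0, "landrace": 0.6, "improved": 0.5}
    )
    sweep_k: float = 0.05
    sweeps_enabled: bool = True
    # CDS annotation and planted fixed non-synonymous differences
    cds_interval: tuple[int, int] = (100, 400)
    n_plant_nonsyn: int = 0
    plant_wild_carriers: int = 1

    def __post_init__(self) -> None:
        for pool, s in self.bottleneck.items():
            if not (0.0 < s <= 1.0):
                raise ValueError(f"bottleneck scaling for {pool} must be in (0, 1]")
        if not (0.0 < self.sweep_k <= 1.0):
            raise ValueError("sweep_k must be in (0, 1]")
        for pool, n in self.pool_sizes.items():
            if n < 1:
                raise ValueError(f"pool size for {pool} must be >= 1")
        if self.cds_interval[1] > self.L:
            # keep the default annotation usable at small L: middle half,
            # trimmed to whole codons
            start = self.L // 4
            length = 3 * ((self.L // 2) // 3)
            object.__setattr__(self, "cds_interval", (start, start + length))

    def locus_roles(self) -> list[tuple[str, str]]:
        loci = [(f"neu{i+1:02d}", ROLE_NEUTRAL) for i in range(self.n_neutral)]
        loci += [(f"dom{i+1:02d}", ROLE_DOM) for i in range(self.n_dom)]
        loci += [(f"imp{i+1:02d}", ROLE_IMP) for i in range(self.n_imp)]
        return loci


def locus_sweep_pools(role: str, cfg: SimConfig) -> tuple[str, ...]:
    """Pools in which a locus of the given role carries a sweep."""
    if not cfg.sweeps_enabled:
        return ()
    if role == ROLE_DOM:
        return ("landrace", "improved")
    if role == ROLE_IMP:
        return ("improved",)
    return ()


@dataclass
class SimTruth:
    """Ground truth for recovery tests: one row per locus × pool plus planted
    non-synonymous fixed differences."""

    table: pd.DataFrame           # locus, role, pool, true_theta, true_k, n_mutations
    mutation_columns: dict        # (locus, pool) -> sorted tuple of segregating columns
    planted_nonsyn: pd.DataFrame  # locus, column, ancestral_codon, derived_codon, wild_freq


def _true_k(role: str, pool: str, cfg: SimConfig) -> float:
    return cfg.sweep_k if pool in locus_sweep_pools(role, cfg) else 1.0


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw (S, D) count data directly from the Poisson HKA model.

    S ~ Poisson(k·θ_pool·a_n) and D ~ Poisson(θ_pool·(T + (1+k)/2)) with
    θ_pool = theta_site · L · bottleneck[pool]; one row per locus × pool.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    rows, truth_rows = [], []
    for locus, role in cfg.locus_roles():
        for pool in INGROUP_POOLS:
            n = cfg.pool_sizes[pool]
            theta = cfg.theta_site * cfg.L * cfg.bottleneck[pool]
            k = _true_k(role, pool, cfg)
            a_n = harmonic_number(n)
            S = int(rng.poisson(k * theta * a_n))
            D = int(rng.poisson(theta * (cfg.T + (1.0 + k) / 2.0)))
            rows.append(dict(locus=locus, pool=pool, role=role, S=S, D=D, L=cfg.L, n=n))
            truth_rows.append(
                dict(locus=locus, role=role, pool=pool, true_theta=theta, true_k=k, n_mutations=S)
            )
    truth = SimTruth(
        table=pd.DataFrame(truth_rows),
        mutation_columns={},
        planted_nonsyn=pd.DataFrame(columns=["locus", "column", "ancestral_codon", "derived_codon", "wild_freq"]),
    )
    return pd.DataFrame(rows), truth


# -- sequence-level simulation --------------------------------------------


def _coalescent_intervals(n: int, scale: float, rng: np.random.Generator):
    """Simulate a standard n-coalescent scaled by ``scale``.

    Yields per-lineage mutation opportunities as a list of
    (tip_set, branch_length) pairs, plus the tree height.
    """
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    birth = {fs: 0.0 for fs in lineages}
    t = 0.0
    branches: list[tuple[frozenset, float]] = []
    while len(lineages) > 1:
        j = len(lineages)
        t += rng.exponential(scale * 2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = lineages[int(i1)], lineages[int(i2)]
        branches.append((a, t - birth[a]))
        branches.append((b, t - birth[b]))
        merged = a | b
        lineages = [l for m, l in enumerate(lineages) if m not in (int(i1), int(i2))]
        lineages.append(merged)
        birth[merged] = t
        del birth[a], birth[b]
    return branches, t


class ColumnPool:
    """Free-column bookkeeping for infinite-sites mutation placement."""

    def __init__(self, L: int, rng: np.random.Generator):
        self._free = list(rng.permutation(L))
        self.L = L

    def reserve(self, columns: Sequence[int]) -> None:
        taken = set(columns)
        self._free = [c for c in self._free if c not in taken]

    def take(self, count: int, locus: str) -> list[int]:
        if count > len(self._free):
            raise RuntimeError(
                f"locus {locus}: {count} mutations requested but only "
                f"{len(self._free)} free columns remain; increase L"
            )
        out, self._free = self._free[:count], self._free[count:]
        return [int(c) for c in out]


def _apply_mutation(residues: np.ndarray, rows: Sequence[int], col: int,
                    ancestral: np.ndarray, rng: np.random.Generator) -> None:
    anc = ancestral[col]
    alts = _BASES[_BASES != anc]
    derived = alts[rng.integers(len(alts))]
    residues[list(rows), col] = derived


def simulate_alignment(
    cfg: SimConfig,
    locus_id: str,
    role: str = ROLE_NEUTRAL,
    seed_seq: np.random.SeedSequence | None = None,
    sheet: SampleSheet | None = None,
    plant_nonsyn: bool = False,
) -> tuple[LocusAlignment, SimTruth]:
    """Simulate one locus alignment across all pools plus the outgroup.

    Per ingroup pool an independent coalescent genealogy is drawn with branch
    lengths scaled by bottleneck[pool] × k; mutations fall on branches at
    rate θ_site·L/2 per unit time onto distinct uniformly chosen columns
    (infinite sites).  Above the pool MRCAs the pools share a single
    ancestral lineage (short pool-specific stems join a common ancestor at
    the height of the deepest pool root), which meets the outgroup lineage
    at height T + Exp(1): divergence therefore accrues mostly on branches
    common to all pools, E[D] = θ_site·L·(T + 1) per pool, and fixed
    differences *between* ingroup pools stay rare.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(seed_seq)
    if sheet is None:
        sheet = default_sample_sheet(cfg)
    sample_ids = sheet.sample_ids
    pools = tuple(sheet.pool_of(s) for s in sample_ids)
    n_total, L = len(sample_ids), cfg.L
    ancestral = _BASES[rng.integers(4, size=L)]
    residues = np.tile(ancestral, (n_total, 1))
    colpool = ColumnPool(L, rng)
    r = cfg.theta_site * L / 2.0  # mutation rate per lineage per 2N-unit time

    cds = (cfg.cds_interval,) if (plant_nonsyn or cfg.n_plant_nonsyn) else ()
    planted_rows = []
    if plant_nonsyn:
        planted_rows.append(_plant_nonsyn(cfg, residues, ancestral, pools, colpool, rng, locus_id))

    # within-pool genealogies first; their mutations segregate within pools
    pool_rows: dict[str, list[int]] = {}
    pool_trees: dict[str, tuple[list, float]] = {}
    truth_rows = []
    mutation_columns: dict[tuple[str, str], tuple[int, ...]] = {}
    for pool in INGROUP_POOLS:
        rows = [i for i, p in enumerate(pools) if p == pool]
        if not rows:
            continue
        k = _true_k(role, pool, cfg)
        scale = cfg.bottleneck[pool] * k
        pool_rows[pool] = rows
        pool_trees[pool] = _coalescent_intervals(len(rows), scale, rng)
        branches, _height = pool_trees[pool]
        seg_cols = []
        for tip_set, blen in branches:
            n_mut = int(rng.poisson(r * blen))
            if n_mut == 0:
                continue
            cols = colpool.take(n_mut, locus_id)
            targets = [rows[t] for t in tip_set]
            for col in cols:
                _apply_mutation(residues, targets, col, ancestral, rng)
            if 0 < len(tip_set) < len(rows):
                seg_cols.extend(cols)
        mutation_columns[(locus_id, pool)] = tuple(sorted(seg_cols))
        truth_rows.append(
            dict(locus=locus_id, role=role, pool=pool,
                 true_theta=cfg.theta_site * L * cfg.bottleneck[pool],
                 true_k=k, n_mutations=len(seg_cols))
        )

    # shared ancestry above the pool MRCAs: pool stems join a common
    # ancestor at the deepest pool root, then one lineage runs up to the
    # junction with the outgroup at height T + Exp(1)
    H_anc = max((h for _, h in pool_trees.values()), default=0.0)
    H_junction = max(cfg.T + rng.exponential(1.0), H_anc)
    all_ingroup = [i for rows in pool_rows.values() for i in rows]
    for pool, rows in pool_rows.items():
        stem = H_anc - pool_trees[pool][1]
        for col in colpool.take(int(rng.poisson(r * stem)), locus_id):
            _apply_mutation(residues, rows, col, ancestral, rng)
    for col in colpool.take(int(rng.poisson(r * (H_junction - H_anc))), locus_id):
        _apply_mutation(residues, all_ingroup, col, ancestral, rng)

    # outgroup branch from the junction down to the present
    out_rows = [i for i, p in enumerate(pools) if p == "outgroup"]
    for col in colpool.take(int(rng.poisson(r * H_junction)), locus_id):
        _apply_mutation(residues, out_rows, col, ancestral, rng)

    aln = LocusAlignment(
        locus_id=locus_id, sample_ids=sample_ids, pools=pools,
        residues=residues, cds_intervals=cds, frame=0,
    )
    truth = SimTruth(
        table=pd.DataFrame(truth_rows),
        mutation_columns=mutation_columns,
        planted_nonsyn=pd.DataFrame(
            planted_rows or None,
            columns=["locus", "column", "ancestral_codon", "derived_codon", "wild_freq"],
        ),
    )
    return aln, truth


def _plant_nonsyn(cfg, residues, ancestral, pools, colpool, rng, locus_id) -> dict:
    """Plant one fixed non-synonymous difference in the improved pool at low
    frequency in the wild (AAA Lys → AGA Arg at a reserved codon)."""
    start, end = cfg.cds_interval
    codon0 = start + 3 * int((end - start) // 6)  # a codon near the CDS middle
    cols = [codon0, codon0 + 1, codon0 + 2]
    colpool.reserve(cols)
    ancestral[cols] = np.array([b"A", b"A", b"A"], dtype="S1")
    residues[:, cols] = np.array([b"A", b"A", b"A"], dtype="S1")
    imp_rows = [i for i, p in enumerate(pools) if p == "improved"]
    wild_rows = [i for i, p in enumerate(pools) if p == "wild"]
    residues[imp_rows, codon0 + 1] = b"G"
    carriers = rng.choice(len(wild_rows), size=min(cfg.plant_wild_carriers, len(wild_rows)), replace=False)
    for c in carriers:
        residues[wild_rows[int(c)], codon0 + 1] = b"G"
    return dict(
        locus=locus_id, column=codon0 + 1, ancestral_codon="AAA", derived_codon="AGA",
        wild_freq=len(carriers) / len(wild_rows),
    )


def default_sample_sheet(cfg: SimConfig) -> SampleSheet:
    prefix = {"wild": "w", "landrace": "l", "improved": "i", "outgroup": "out"}
    rows = []
    for pool in ("wild", "landrace", "improved", "outgroup"):
        for j in range(cfg.pool_sizes[pool]):
            rows.append((f"{prefix[pool]}{j+1}", pool))
    return SampleSheet(samples=tuple(rows))


@dataclass
class StudyData:
    """A complete runnable synthetic study."""

    config: SimConfig
    sheet: SampleSheet
    alignments: list[LocusAlignment]
    roles: pd.DataFrame          # locus, role
    truth: SimTruth
    outdir: Path | None = None


def simulate_study(cfg: SimConfig, outdir: str | Path | None = None) -> StudyData:
    """Simulate the full study: all loci, all pools, with sweeps planted by
    role (domestication loci swept in landrace + improved, improvement loci
    in improved only).  When ``outdir`` is given, writes FASTA per locus, the
    sample sheet, a roles table, CDS intervals and the ground-truth table —
    exactly the input formats the pipeline reads."""
    sheet = default_sample_sheet(cfg)
    loci = cfg.locus_roles()
    children = np.random.SeedSequence(cfg.seed).spawn(len(loci))
    imp_loci = [l for l, role in loci if role == ROLE_IMP]
    plant_set = set(imp_loci[: cfg.n_plant_nonsyn])

    alignments, truth_tables, mut_cols, planted = [], [], {}, []
    for (locus, role), child in zip(loci, children):
        aln, truth = simulate_alignment(
            cfg, locus, role, seed_seq=child, sheet=sheet, plant_nonsyn=locus in plant_set
        )
        alignments.append(aln)
        truth_tables.append(truth.table)
        mut_cols.update(truth.mutation_columns)
        if len(truth.planted_nonsyn):
            planted.append(truth.planted_nonsyn)
    truth = SimTruth(
        table=pd.concat(truth_tables, ignore_index=True),
        mutation_columns=mut_cols,
        planted_nonsyn=(
            pd.concat(planted, ignore_index=True) if planted
            else pd.DataFrame(columns=["locus", "column", "ancestral_codon", "derived_codon", "wild_freq"])
        ),
    )
    roles = pd.DataFrame([{"locus": l, "role": r} for l, r in loci])
    study = StudyData(config=cfg, sheet=sheet, alignments=alignments, roles=roles, truth=truth)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "loci").mkdir(parents=True, exist_ok=True)
        write_sample_sheet(sheet, outdir / "samples.tsv")
        roles.to_csv(outdir / "roles.tsv", sep="\t", index=False)
        for aln in alignments:
            write_locus_alignment(aln, outdir / "loci" / f"{aln.locus_id}.fasta")
        cds = {a.locus_id: (a.cds_intervals, a.frame) for a in alignments if a.cds_intervals}
        if cds:
            write_cds_table(cds, outdir / "cds.tsv")
        truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if len(truth.planted_nonsyn):
            truth.planted_nonsyn.to_csv(outdir / "planted_nonsyn.tsv", sep="\t", index=False)
        study.outdir = outdir
    return study
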