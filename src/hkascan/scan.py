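"""Staged selection scan: neutral-panel validation, candidate tests per gene
pool, FDR correction and timing classification.

The scan mirrors a two-stage design: each putatively neutral locus is first
tested leave-one-out against the rest of the panel (the panel passes when no
locus rejects neutrality); every candidate is then tested against the full
neutral panel, separately in the wild, landrace and improved pools.  Running
the pools separately dates the selection: loss of diversity in landrace and
improved pools indicates selection during domestication, loss confined to
the improved pool indicates selection during improvement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import harmonic_number
from .fdr import storey_qvalues
from .hka import HkaLocusData, HkaTestResult, hka_test, locus_data_from_frame
from .io import INGROUP_POOLS, LocusAlignment, pool_slice
from .diversity import complete_deletion, segregating_sites

logger = logging.getLogger(__name__)

__all__ = [
    "PanelValidation",
    "ScanResult",
    "counts_from_alignments",
    "validate_neutral_panel",
    "scan_candidates",
    "classify_timing",
]

TIMING_NONE = "none"
TIMING_DOM = "domestication"
TIMING_IMP = "improvement"
TIMING_WILD = "wild-flagged"


def counts_from_alignments(alignments, roles: dict[str, str]) -> pd.DataFrame:
    """Build the HKA count table (locus, pool, role, S, D, L, n) from
    alignments.

    For each locus × pool, columns are retained by complete deletion over the
    pool's sequences *plus* the outgroup, so polymorphism and divergence of
    one test share a site set; S counts segregating retained columns within
    the pool, D is the mean Hamming distance to the outgroup.  Pools with
    fewer than two sequences or no retained columns are dropped with a
    logged reason.
    """
    rows = []
    for aln in alignments:
        out_idx = aln.pool_members("outgroup")
        if len(out_idx) != 1:
            logger.warning("locus %s: no single outgroup; skipped", aln.locus_id)
            continue
        for pool in INGROUP_POOLS:
            idx = aln.pool_members(pool)
            if len(idx) < 2:
                logger.warning("locus %s pool %s: n < 2; dropped from scan", aln.locus_id, pool)
                continue
            sub = aln.residues[idx + out_idx]
            bad = (sub == b"-") | (sub == b"N")
            retained = np.flatnonzero(~bad.any(axis=0))
            if len(retained) == 0:
                logger.warning("locus %s pool %s: L_net = 0; dropped from scan", aln.locus_id, pool)
                continue
            cols = sub[:, retained]
            ingroup = cols[:-1]
            S = int((ingroup != ingroup[0]).any(axis=0).sum())
            D = float((ingroup != cols[-1]).sum(axis=1).mean())
            rows.append(
                dict(
                    locus=aln.locus_id, pool=pool,
                    role=roles.get(aln.locus_id, "neutral"),
                    S=S, D=D, L=int(len(retained)), n=len(idx),
                )
            )
    return pd.DataFrame(rows)


@dataclass
class PanelValidation:
    """Leave-one-out neutrality check of the control-locus panel."""

    pool: str
    results: list[HkaTestResult]
    errors: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def passed(self) -> bool:
        return all(r.p_value >= self.alpha for r in self.results)


def validate_neutral_panel(
    panel: list[HkaLocusData],
    pool: str = "",
    alpha: float = 0.05,
    lrt_df: int = 2,
    seed: int = 0,
    n_starts: int = 8,
) -> PanelValidation:
    """Test each panel locus leave-one-out against the remaining panel loci.

    Per-locus fit failures are recorded, never raised, so one bad locus does
    not abort the panel.
    """
    if len(panel) < 3:
        raise ValueError("neutral panel needs at least 3 loci")
    results, errors = [], {}
    for focal in panel:
        try:
            res = hka_test(panel, focal.locus_id, df=lrt_df, seed=seed,
                           n_starts=n_starts, pool=pool)
            results.append(res)
        except Exception as exc:  # noqa: BLE001 - propagate per locus, not panel
            errors[focal.locus_id] = str(exc)
    return PanelValidation(pool=pool, results=results, errors=errors, alpha=alpha)


def classify_timing(
    p_wild: float | None,
    p_landrace: float | None,
    p_improved: float | None,
    alpha: float = 0.05,
) -> str:
    """Date the selection event from per-pool significance.

    Landrace AND improved significant -> domestication; improved only ->
    improvement; wild significant (without a cultivated signal) is an anomaly
    flagged rather than suppressed, since selection is tested relative to
    wild ancestry.  Missing p-values count as non-significant.
    """

    def sig(p):
        return p is not None and np.isfinite(p) and p < alpha

    if sig(p_landrace) and sig(p_improved):
        return TIMING_DOM
    if sig(p_improved):
        return TIMING_IMP
    if sig(p_wild):
        return TIMING_WILD
    return TIMING_NONE


@dataclass
class ScanResult:
    """Per-locus, per-pool scan outcomes (the study's summary-table analogue)."""

    table: pd.DataFrame
    panel: dict[str, PanelValidation]
    pi0: float | None
    alpha: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _theta_w_row(row) -> float:
    return row.S / (harmonic_number(int(row.n)) * int(row.L))


def scan_candidates(
    counts: pd.DataFrame,
    pools=INGROUP_POOLS,
    alpha: float = 0.05,
    lrt_df: int = 2,
    seed: int = 0,
    n_starts: int = 8,
    validate_panel: bool = True,
    strict_panel: bool = False,
    fdr_scope: str = "joint",
    timing_from: str = "p_value",
    timing_requires_deficit: bool = True,
) -> ScanResult:
    """Run the full candidate scan on a count table.

    Each candidate × pool test fits the neutral panel plus the focal
    candidate; q-values are attached across all candidate tests (``joint``)
    or within each pool (``per-pool``).  Timing classes use raw p-values by
    default (``timing_from='q_value'`` switches to FDR-based classification).
    Because timing dates *positive* selection, a pool only contributes to the
    timing class when its fitted k̂ < 1 (diversity deficit); significant
    excess diversity (k̂ > 1) stays visible in the table but does not date a
    sweep (disable via ``timing_requires_deficit=False``).  Per-locus fit
    failures yield not-available rows rather than aborting.
    """
    if fdr_scope not in ("joint", "per-pool"):
        raise ValueError("fdr_scope must be 'joint' or 'per-pool'")
    panel_checks: dict[str, PanelValidation] = {}
    rows = []
    for pool in pools:
        data = locus_data_from_frame(counts, pool)
        panel = [d for d in data if d.role == "neutral"]
        cands = [d for d in data if d.role != "neutral"]
        if len(panel) < 2:
            raise ValueError(f"pool {pool}: need at least 2 neutral panel loci")
        if validate_panel and len(panel) >= 3:
            check = validate_neutral_panel(panel, pool=pool, alpha=alpha,
                                           lrt_df=lrt_df, seed=seed, n_starts=n_starts)
            panel_checks[pool] = check
            if not check.passed:
                msg = f"neutral panel failed validation in pool {pool}"
                if strict_panel:
                    raise RuntimeError(msg)
                warnings.warn(msg, RuntimeWarning)
            for res in check.results:
                rows.append(_row(counts, res.locus_id, pool, res.p_value, res.k_hat))
        for cand in cands:
            dataset = panel + [cand]
            try:
                res = hka_test(dataset, cand.locus_id, df=lrt_df, seed=seed,
                               n_starts=n_starts, pool=pool)
                rows.append(_row(counts, cand.locus_id, pool, res.p_value, res.k_hat))
            except Exception as exc:  # noqa: BLE001
                logger.warning("scan failed for %s/%s: %s", cand.locus_id, pool, exc)
                rows.append(_row(counts, cand.locus_id, pool, float("nan"), float("nan")))
    table = pd.DataFrame(rows)

    # q-values across candidate tests only
    table["q_value"] = np.nan
    pi0 = None
    cand_mask = (table["role"] != "neutral") & table["p_value"].notna()
    if cand_mask.any():
        if fdr_scope == "joint":
            qres = storey_qvalues(table.loc[cand_mask, "p_value"].to_numpy())
            table.loc[cand_mask, "q_value"] = qres.q_values
            pi0 = qres.pi0
        else:
            for pool in pools:
                m = cand_mask & (table["pool"] == pool)
                if m.any():
                    qres = storey_qvalues(table.loc[m, "p_value"].to_numpy())
                    table.loc[m, "q_value"] = qres.q_values
                    pi0 = qres.pi0

    table["significant_05"] = table["p_value"] < alpha
    table["marginal_10"] = (table["p_value"] >= alpha) & (table["p_value"] <= 0.10)

    stat = "q_value" if timing_from == "q_value" else "p_value"
    timing = {}
    for locus, grp in table[table["role"] != "neutral"].groupby("locus"):
        by_pool = {}
        for r in grp.itertuples(index=False):
            p = getattr(r, stat)
            if timing_requires_deficit and np.isfinite(r.k_hat) and r.k_hat >= 1.0:
                p = 1.0
            by_pool[r.pool] = p
        timing[locus] = classify_timing(
            by_pool.get("wild"), by_pool.get("landrace"), by_pool.get("improved"),
            alpha=alpha,
        )
    table["timing_class"] = table["locus"].map(timing).fillna(TIMING_NONE)
    order = {p: i for i, p in enumerate(pools)}
    table = table.sort_values(["role", "locus", "pool"], key=lambda s: s.map(order) if s.name == "pool" else s)
    return ScanResult(table=table.reset_index(drop=True), panel=panel_checks, pi0=pi0, alpha=alpha)


def _row(counts: pd.DataFrame, locus: str, pool: str, p: float, k_hat: float) -> dict:
    rec = counts[(counts["locus"] == locus) & (counts["pool"] == pool)].iloc[0]
    return dict(
        locus=locus, role=rec.role, pool=pool,
        theta_w=_theta_w_row(rec), p_value=p, k_hat=k_hat,
    )
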