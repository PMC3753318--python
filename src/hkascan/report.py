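"""Group summaries, the end-to-end pipeline, and the markdown report.

``summarize_diversity`` reproduces the headline arithmetic of a candidate
scan: unweighted mean θ_W per locus class × pool and the percent diversity
loss of each derived pool relative to the same class's wild mean, reported
both exactly and rounded to the nearest 5% for prose-style comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import read_cds_table, read_locus_alignment, read_sample_sheet
from .diversity import diversity_table
from .hka import read_count_table
from .scan import ScanResult, counts_from_alignments, scan_candidates
from .variants import call_pool_variants, screen_selected_loci, variant_table

logger = logging.getLogger(__name__)

__all__ = ["summarize_diversity", "render_report", "run_pipeline", "plot_diversity",
           "PipelineConfig", "PipelineOutput"]

ROLE_ORDER = ["neutral", "domestication-candidate", "improvement-candidate"]
POOL_ORDER = ["wild", "landrace", "improved"]


def _round5(x: float) -> float:
    return float(5 * round(x / 5))


def summarize_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Mean θ_W per role × pool with percent loss relative to wild.

    ``table`` needs columns locus, role, pool, theta_w (one row per locus ×
    pool).  Loss is 100·(1 − mean_pool / mean_wild) within each role; the
    wild column's loss is 0 by definition and losses are undefined (NaN)
    when the wild mean is missing.
    """
    rows = []
    for role, grp in table.groupby("role"):
        means = grp.groupby("pool")["theta_w"].mean()
        wild_mean = means.get("wild", np.nan)
        for pool in POOL_ORDER:
            if pool not in means.index:
                continue
            if np.isfinite(wild_mean) and wild_mean > 0:
                loss = 100.0 * (1.0 - means[pool] / wild_mean)
            else:
                loss = np.nan
            rows.append(
                dict(role=role, pool=pool, mean_theta_w=means[pool],
                     loss_vs_wild=loss,
                     loss_rounded5=_round5(loss) if np.isfinite(loss) else np.nan)
            )
    out = pd.DataFrame(rows)
    out["role"] = pd.Categorical(out["role"], [r for r in ROLE_ORDER if r in set(out["role"])] +
                                 sorted(set(out["role"]) - set(ROLE_ORDER)), ordered=True)
    return out.sort_values(["role", "pool"], key=lambda s: s.map({p: i for i, p in enumerate(POOL_ORDER)}) if s.name == "pool" else s).reset_index(drop=True)


def plot_diversity(summary: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of mean θ_W per role × pool."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roles = summary["role"].unique()
    x = np.arange(len(roles))
    width = 0.25
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, pool in enumerate(POOL_ORDER):
        sub = summary[summary["pool"] == pool].set_index("role")
        vals = [sub["mean_theta_w"].get(r, np.nan) for r in roles]
        ax.bar(x + (i - 1) * width, vals, width, label=pool)
    ax.set_xticks(x)
    ax.set_xticklabels([str(r).replace("-candidate", "") for r in roles])
    ax.set_ylabel("mean Watterson's θ per site")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(
    scan: ScanResult,
    summary: pd.DataFrame,
    screen: pd.DataFrame | None = None,
    title: str = "Selection scan report",
) -> str:
    """Markdown report rendered from the result tables (single source of
    truth: every number comes from the TSV-backed frames)."""
    lines = [f"# {title}", ""]
    lines.append("## Neutral panel validation")
    if scan.panel:
        for pool, check in scan.panel.items():
            verdict = "pass" if check.passed else "FAIL"
            worst = min((r.p_value for r in check.results), default=float("nan"))
            lines.append(f"- {pool}: {verdict} (smallest leave-one-out p = {worst:.4f})")
    else:
        lines.append("- not run")
    lines.append("")
    lines.append("## Diversity by locus class")
    lines.append("")
    lines.append("| role | pool | mean θ_W | loss vs wild (%) | rounded |")
    lines.append("|---|---|---|---|---|")
    for r in summary.itertuples(index=False):
        loss = f"{r.loss_vs_wild:.1f}" if np.isfinite(r.loss_vs_wild) else "n/a"
        r5 = f"{r.loss_rounded5:.0f}" if np.isfinite(r.loss_rounded5) else "n/a"
        lines.append(f"| {r.role} | {r.pool} | {r.mean_theta_w:.4f} | {loss} | {r5} |")
    lines.append("")
    cand = scan.table[scan.table["role"] != "neutral"]
    sig = cand.dropna(subset=["q_value"]).groupby("locus")["q_value"].min()
    fdr_loci = sorted(sig[sig < 0.05].index)
    lines.append("## Candidate tests")
    lines.append("")
    n_raw = cand[cand["significant_05"]]["locus"].nunique()
    lines.append(f"- candidates with raw p < {scan.alpha} in some pool: {n_raw}")
    lines.append(f"- FDR < 0.05 loci ({len(fdr_loci)}): {', '.join(fdr_loci) if fdr_loci else 'none'}")
    if scan.pi0 is not None:
        lines.append(f"- estimated null proportion pi0: {scan.pi0:.3f}")
    lines.append("")
    lines.append("| locus | role | pool | θ_W | p | q | timing |")
    lines.append("|---|---|---|---|---|---|---|")
    for r in cand.itertuples(index=False):
        q = f"{r.q_value:.4f}" if np.isfinite(r.q_value) else "n/a"
        p = f"{r.p_value:.4f}" if np.isfinite(r.p_value) else "n/a"
        lines.append(f"| {r.locus} | {r.role} | {r.pool} | {r.theta_w:.4f} | {p} | {q} | {r.timing_class} |")
    lines.append("")
    if screen is not None:
        lines.append("## Fixed non-synonymous differences at FDR-significant loci")
        lines.append("")
        if len(screen):
            lines.append("| locus | column | fixed between | wild freq | low (<20%) |")
            lines.append("|---|---|---|---|---|")
            for r in screen.itertuples(index=False):
                wf = f"{r.wild_freq_derived:.3f}" if np.isfinite(r.wild_freq_derived) else "n/a"
                lines.append(f"| {r.locus} | {r.column} | {r.fixed_between} | {wf} | {r.low_wild_freq} |")
        else:
            lines.append("none found")
        lines.append("")
    return "\n".join(lines)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed)."""

    seed: int
    output_dir: Path
    sample_sheet: Path | None = None
    loci_dir: Path | None = None
    roles: Path | None = None
    cds: Path | None = None
    count_table: Path | None = None
    alpha: float = 0.05
    lrt_df: int = 2
    fdr_scope: str = "joint"
    timing_from: str = "p_value"
    wild_freq_cutoff: float = 0.20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        errors = []
        if "seed" not in raw:
            errors.append("seed: required")
        if "output_dir" not in raw:
            errors.append("output_dir: required")
        inputs = raw.get("inputs", {})
        has_aln = "sample_sheet" in inputs and "loci_dir" in inputs and "roles" in inputs
        has_counts = "count_table" in inputs
        if not (has_aln or has_counts):
            errors.append("inputs: need either (sample_sheet, loci_dir, roles) or count_table")
        if errors:
            raise ValueError("config schema violations: " + "; ".join(errors))
        base = Path(path).parent

        def p(key):
            return (base / inputs[key]).resolve() if key in inputs else None

        cfg = cls(
            seed=int(raw["seed"]),
            output_dir=(base / raw["output_dir"]).resolve(),
            sample_sheet=p("sample_sheet"), loci_dir=p("loci_dir"),
            roles=p("roles"), cds=p("cds"), count_table=p("count_table"),
            alpha=float(raw.get("alpha", 0.05)), lrt_df=int(raw.get("lrt_df", 2)),
            fdr_scope=str(raw.get("fdr_scope", "joint")),
            timing_from=str(raw.get("timing_from", "p_value")),
            wild_freq_cutoff=float(raw.get("wild_freq_cutoff", 0.20)),
        )
        for name in ("sample_sheet", "loci_dir", "roles", "cds", "count_table"):
            val = getattr(cfg, name)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"inputs.{name}: {val} does not exist")
        return cfg


@dataclass
class PipelineOutput:
    scan: ScanResult
    summary: pd.DataFrame
    diversity: pd.DataFrame | None
    screen: pd.DataFrame | None
    report_path: Path


def run_pipeline(config: PipelineConfig | str | Path) -> PipelineOutput:
    """End-to-end scan: read inputs, compute diversity, validate the panel,
    test candidates, correct for FDR, classify timing, screen variants and
    write the report.  Count-table-only configs skip the alignment-based
    diversity and variant stages."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    diversity = screen = None
    if config.count_table is not None:
        counts = read_count_table(config.count_table)
        alignments = None
    else:
        sheet = read_sample_sheet(config.sample_sheet)
        roles_df = pd.read_csv(config.roles, sep="\t")
        roles = dict(zip(roles_df["locus"], roles_df["role"]))
        cds = read_cds_table(config.cds) if config.cds else {}
        alignments = []
        for fa in sorted(Path(config.loci_dir).glob("*.fasta")):
            intervals, frame = cds.get(fa.stem, ((), 0))
            alignments.append(read_locus_alignment(fa, sheet, cds_intervals=intervals, frame=frame))
        if not alignments:
            raise FileNotFoundError(f"no *.fasta files under {config.loci_dir}")
        counts = counts_from_alignments(alignments, roles)
        diversity = diversity_table(alignments)
        diversity.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.6g")

    counts.to_csv(out / "counts.tsv", sep="\t", index=False, float_format="%.6g")
    scan = scan_candidates(
        counts, alpha=config.alpha, lrt_df=config.lrt_df, seed=config.seed,
        fdr_scope=config.fdr_scope, timing_from=config.timing_from,
    )
    for r in scan.table.itertuples(index=False):
        logger.info("scan %s/%s: theta_w=%.4g p=%.4g k_hat=%.4g", r.locus, r.pool,
                    r.theta_w, r.p_value, r.k_hat)
    scan.to_tsv(out / "scan.tsv")
    theta_tbl = scan.table[["locus", "role", "pool", "theta_w"]].drop_duplicates()
    summary = summarize_diversity(theta_tbl)
    summary.to_csv(out / "group_summary.tsv", sep="\t", index=False, float_format="%.6g")

    if alignments is not None:
        calls = {a.locus_id: call_pool_variants(a) for a in alignments}
        all_calls = [c for lst in calls.values() for c in lst]
        variant_table(all_calls).to_csv(out / "variants.tsv", sep="\t", index=False, float_format="%.6g")
        screen = screen_selected_loci(scan.table, calls, wild_freq_cutoff=config.wild_freq_cutoff)
        screen.to_csv(out / "screen.tsv", sep="\t", index=False, float_format="%.6g")

    report = render_report(scan, summary, screen)
    report_path = out / "report.md"
    report_path.write_text(report)
    plot_diversity(summary, out / "diversity.png")
    return PipelineOutput(scan=scan, summary=summary, diversity=diversity,
                          screen=screen, report_path=report_path)
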