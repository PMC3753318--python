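"""Bundled reference data.

``load_sunflower_scan`` returns the published per-locus summary of a
candidate-gene survey of sunflower domestication: Watterson's θ and ML-HKA
P-values in the wild, landrace and improved gene pools for 7 neutral control
loci, 13 domestication candidates and 14 improvement candidates (34 loci in
all).  P-values printed as 0.0000 were truncated at four decimals in the
source and are floored at 1e-5 on request, since a likelihood-ratio χ²
p-value cannot be exactly zero.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_sunflower_scan", "scan_pvalue_matrix", "P_FLOOR"]

P_FLOOR = 1e-5

_POOL_COLS = {"wild": "p_wild", "landrace": "p_landrace", "improved": "p_improved"}


def load_sunflower_scan(floor_zero_p: bool = True) -> pd.DataFrame:
    """The bundled 34-locus diversity/P-value table.

    Columns: role, locus, product, theta_{wild,landrace,improved},
    p_{wild,landrace,improved}.
    """
    with resources.files("hkascan.data").joinpath("sunflower_candidate_scan.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if floor_zero_p:
        for col in _POOL_COLS.values():
            df[col] = df[col].clip(lower=P_FLOOR)
    return df


def scan_pvalue_matrix(df: pd.DataFrame | None = None, candidates_only: bool = True) -> pd.DataFrame:
    """Long-format P-values (locus, role, pool, p_value) for FDR analysis."""
    if df is None:
        df = load_sunflower_scan()
    if candidates_only:
        df = df[df["role"] != "neutral"]
    rows = []
    for rec in df.itertuples(index=False):
        for pool, col in _POOL_COLS.items():
            rows.append(dict(locus=rec.locus, role=rec.role, pool=pool,
                             p_value=getattr(rec, col)))
    return pd.DataFrame(rows)
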