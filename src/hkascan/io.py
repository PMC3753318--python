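"""Input/output for per-locus alignments and the study sample sheet.

The analysis unit is a pre-aligned FASTA file per locus whose record ids are
sample ids listed in a tab-separated sample sheet assigning each sample to one
of four pools: ``wild``, ``landrace``, ``improved`` or ``outgroup``.  Each
FASTA record is one haplotype (samples were sequenced directly; phasing is out
of scope).  Coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

POOLS = ("wild", "landrace", "improved", "outgroup")
INGROUP_POOLS = ("wild", "landrace", "improved")

_VALID_RESIDUES = frozenset(b"ACGT-N")
# IUPAC nucleotide ambiguity codes (other than N) collapse to missing.
_AMBIGUITY = frozenset(b"RYSWKMBDHV")


@dataclass(frozen=True)
class SampleSheet:
    """Assignment of sample ids to gene pools.

    Invariants: sample ids are unique and exactly one sample belongs to the
    outgroup pool.
    """

    samples: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.samples]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id(s) in sample sheet: {sorted(dupes)}")
        bad = {p for _, p in self.samples if p not in POOLS}
        if bad:
            raise ValueError(f"unknown pool token(s): {sorted(bad)}; expected one of {POOLS}")
        n_out = sum(1 for _, p in self.samples if p == "outgroup")
        if n_out != 1:
            raise ValueError(f"sample sheet must contain exactly one outgroup sample, found {n_out}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.samples)

    def pool_of(self, sample_id: str) -> str:
        for s, p in self.samples:
            if s == sample_id:
                return p
        raise KeyError(sample_id)

    def pool_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in POOLS}
        for _, p in self.samples:
            counts[p] += 1
        return counts

    def ids_in_pool(self, pool: str) -> tuple[str, ...]:
        return tuple(s for s, p in self.samples if p == pool)


@dataclass(frozen=True)
class LocusAlignment:
    """Aligned sequences for one locus with per-sequence pool labels.

    ``residues`` is an (n, L) byte matrix over {A, C, G, T, -, N}.  CDS
    intervals, when present, are sorted non-overlapping 0-based half-open
    intervals with a reading-frame offset (number of bases to skip before the
    first complete codon of the concatenated CDS).
    """

    locus_id: str
    sample_ids: tuple[str, ...]
    pools: tuple[str, ...]
    residues: np.ndarray
    cds_intervals: tuple[tuple[int, int], ...] = ()
    frame: int = 0
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        res = np.asarray(self.residues, dtype="S1")
        object.__setattr__(self, "residues", res)
        if res.ndim != 2:
            raise ValueError("residues must be a 2-D (n, L) matrix")
        if res.shape[0] != len(self.sample_ids) or len(self.sample_ids) != len(self.pools):
            raise ValueError("sample_ids, pools and residue rows must agree in length")
        if res.shape[1] < 1:
            raise ValueError("alignment_length must be >= 1")
        bad = set(np.unique(res).tolist()) - {c.to_bytes(1, "big") for c in _VALID_RESIDUES}
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}; expected A/C/G/T/-/N")
        prev_end = 0
        for start, end in self.cds_intervals:
            if not (0 <= start < end <= res.shape[1]):
                raise ValueError(f"CDS interval [{start}, {end}) outside alignment")
            if start < prev_end:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def n(self) -> int:
        return self.residues.shape[0]

    @property
    def alignment_length(self) -> int:
        return self.residues.shape[1]

    def sequence(self, i: int) -> str:
        return self.residues[i].tobytes().decode("ascii")

    def pool_members(self, pool: str) -> list[int]:
        return [i for i, p in enumerate(self.pools) if p == pool]

    def present_pools(self) -> tuple[str, ...]:
        return tuple(p for p in POOLS if p in self.pools)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet with header columns ``sample_id`` and ``pool``.

    Pool tokens are case-insensitive and stored lower-case.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_id = header.index("sample_id")
            i_pool = header.index("pool")
        except ValueError as exc:
            raise ValueError(f"{path}: header must contain 'sample_id' and 'pool' columns") from exc
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            rows.append((parts[i_id].strip(), parts[i_pool].strip().lower()))
    return SampleSheet(samples=tuple(rows))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tpool\n")
        for s, p in sheet.samples:
            fh.write(f"{s}\t{p}\n")


def _clean_residues(seq: str) -> tuple[bytes, int]:
    """Upper-case a sequence and collapse non-N ambiguity codes to N."""
    raw = seq.upper().encode("ascii")
    arr = np.frombuffer(raw, dtype="S1").copy()
    amb = np.isin(arr, [c.to_bytes(1, "big") for c in _AMBIGUITY])
    n_amb = int(amb.sum())
    arr[amb] = b"N"
    return arr.tobytes(), n_amb


def read_locus_alignment(
    path: str | Path,
    sheet: SampleSheet,
    cds_intervals: Sequence[tuple[int, int]] = (),
    frame: int = 0,
    locus_id: str | None = None,
) -> LocusAlignment:
    """Read one pre-aligned FASTA file keyed to the sample sheet.

    All records must have identical length; headers must be sample ids present
    in the sheet.  Residues are upper-cased and IUPAC ambiguity codes other
    than N are converted to N (a warning with the count is logged).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    known = set(sheet.sample_ids)
    offenders = [r.id for r in records if r.id not in known]
    if offenders:
        raise ValueError(f"{path}: FASTA headers absent from sample sheet: {offenders}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal sequence lengths {sorted(lengths)}; input must be pre-aligned")
    rows = []
    n_amb_total = 0
    for r in records:
        cleaned, n_amb = _clean_residues(str(r.seq))
        n_amb_total += n_amb
        rows.append(np.frombuffer(cleaned, dtype="S1"))
    if n_amb_total:
        logger.warning("%s: converted %d ambiguity residues to N", path, n_amb_total)
    return LocusAlignment(
        locus_id=locus_id or path.stem,
        sample_ids=tuple(r.id for r in records),
        pools=tuple(sheet.pool_of(r.id) for r in records),
        residues=np.vstack(rows),
        cds_intervals=tuple(tuple(iv) for iv in cds_intervals),
        frame=frame,
        n_ambiguous=n_amb_total,
    )


def write_locus_alignment(aln: LocusAlignment, path: str | Path) -> None:
    """Write canonical FASTA: upper-case residues, 60-column wrap."""
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.sample_ids[i], description="")
        for i in range(aln.n)
    ]
    SeqIO.write(records, str(path), "fasta")


def pool_slice(aln: LocusAlignment, pool: str) -> LocusAlignment:
    """Restrict an alignment to one pool, preserving order of appearance."""
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}")
    idx = aln.pool_members(pool)
    if not idx:
        raise ValueError(f"locus {aln.locus_id}: no sequences in pool {pool!r}")
    return replace(
        aln,
        sample_ids=tuple(aln.sample_ids[i] for i in idx),
        pools=tuple(aln.pools[i] for i in idx),
        residues=aln.residues[idx],
    )


def read_cds_table(path: str | Path) -> dict[str, tuple[tuple[tuple[int, int], ...], int]]:
    """Read BED-like CDS intervals: columns locus_id, start, end, frame.

    Returns ``{locus_id: (intervals, frame)}``; intervals sorted per locus.
    The frame must be consistent across rows of one locus.
    """
    out: dict[str, tuple[list[tuple[int, int]], int]] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            locus = parts[cols["locus_id"]]
            iv = (int(parts[cols["start"]]), int(parts[cols["end"]]))
            frame = int(parts[cols["frame"]])
            if locus in out and out[locus][1] != frame:
                raise ValueError(f"{path}: inconsistent frame for locus {locus}")
            out.setdefault(locus, ([], frame))[0].append(iv)
    return {k: (tuple(sorted(v[0])), v[1]) for k, v in out.items()}


def write_cds_table(
    cds: dict[str, tuple[Iterable[tuple[int, int]], int]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("locus_id\tstart\tend\tframe\n")
        for locus, (intervals, frame) in cds.items():
            for start, end in intervals:
                fh.write(f"{locus}\t{start}\t{end}\t{frame}\n")
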