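"""Genomic interval algebra on 0-based half-open coordinates.

This is the coordinate backbone of the package: a ``GenomeInterval`` value
type, a sorted ``IntervalSet`` container backed by a pandas DataFrame, and
the three primitives every downstream statistic is built from —

* :func:`merge_intervals` — transitive merging of intervals whose gaps do
  not exceed a threshold (the smoothing primitive);
* :func:`intersect_length` — exact overlapping-base counts between two sets
  (the interval-intersection primitive behind every overlap percentage);
* :func:`coverage_fraction` — fraction of a query interval covered by a
  disjoint target set.

All coordinates are BED-native: 0-based, half-open ``[start, end)``.  GFF3
input is converted on read (start − 1).  A *gap* between two intervals is
the number of bases strictly between them, ``start(next) − end(prev)``; a
gap exactly equal to the merge threshold is merged ("did not exceed").
Strand is carried on intervals but ignored by the algebra here; only the
TSS-profile code consults it.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class CoordinateError(ValueError):
    """An interval violates coordinate invariants or chromosome bounds."""


class ParameterError(ValueError):
    """A caller-supplied parameter is out of its valid range."""


class InputFormatError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclasses.dataclass(frozen=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclasses.dataclass
class ChromosomeSpace:
    """Chromosome name -> length map with a designated target chromosome.

    The *target* plays the "chromosome 4" role: enrichment statistics compare
    per-domain coverage on the target against the rest-of-genome chromosomes.
    """

    sizes: dict[str, int]
    target: str

    def __post_init__(self) -> None:
        for name, size in self.sizes.items():
            if size <= 0:
                raise CoordinateError(f"chromosome {name!r} has non-positive length {size}")
        if self.target not in self.sizes:
            raise CoordinateError(f"target chromosome {self.target!r} not in space")

    @property
    def rest(self) -> list[str]:
        return [c for c in self.sizes if c != self.target]

    def check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.sizes:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.sizes[chrom]:
            raise CoordinateError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"[0, {self.sizes[chrom]})"
            )

    @classmethod
    def read_tsv(cls, path, target: str) -> "ChromosomeSpace":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise InputFormatError(f"{path}:{lineno}: expected two columns")
                try:
                    sizes[parts[0]] = int(parts[1])
                except ValueError as exc:
                    raise InputFormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
        return cls(sizes, target)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, size in self.sizes.items():
                fh.write(f"{name}\t{size}\n")


def _as_frame(obj) -> pd.DataFrame:
    """Coerce intervals-as-anything to a (chrom, start, end[, ...]) frame."""
    if isinstance(obj, IntervalSet):
        return obj.df
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, GenomeInterval):
        return pd.DataFrame(
            {"chrom": [obj.chrom], "start": [obj.start], "end": [obj.end], "strand": [obj.strand]}
        )
    rows = list(obj)
    if rows and isinstance(rows[0], GenomeInterval):
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in rows],
                "start": [r.start for r in rows],
                "end": [r.end for r in rows],
                "strand": [r.strand for r in rows],
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _merge_arrays(starts: np.ndarray, ends: np.ndarray, max_gap: int):
    """Merge sorted interval arrays transitively; gap <= max_gap merges."""
    if starts.size == 0:
        return starts, ends
    # new run begins where the gap to the running maximum end exceeds max_gap
    run_end = np.maximum.accumulate(ends)
    new_run = np.empty(starts.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] - run_end[:-1] > max_gap
    run_id = np.cumsum(new_run) - 1
    n = run_id[-1] + 1
    out_starts = starts[new_run]
    out_ends = np.zeros(n, dtype=ends.dtype)
    np.maximum.at(out_ends, run_id, ends)
    return out_starts, out_ends


def _covered_length(qs, qe, ts, te) -> np.ndarray:
    """Bases of each query [qs, qe) covered by disjoint sorted targets."""
    qs = np.asarray(qs, dtype=np.int64)
    qe = np.asarray(qe, dtype=np.int64)
    ts = np.asarray(ts, dtype=np.int64)
    te = np.asarray(te, dtype=np.int64)
    if ts.size == 0 or qs.size == 0:
        return np.zeros(qs.size, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(te - ts)])
    i = np.searchsorted(te, qs, side="right")  # first target ending after query start
    j = np.searchsorted(ts, qe, side="left")   # first target starting at/after query end
    out = np.zeros(qs.size, dtype=np.int64)
    hit = i < j
    ii, jj = i[hit], j[hit]
    full = cum[jj] - cum[ii]
    left_clip = np.maximum(0, qs[hit] - ts[ii])
    right_clip = np.maximum(0, te[jj - 1] - qe[hit])
    out[hit] = full - left_clip - right_clip
    return out


class IntervalSet:
    """A sorted collection of intervals, optionally known-disjoint.

    Thin wrapper around a DataFrame with at least ``chrom``, ``start``,
    ``end`` columns, kept sorted by (chrom, start, end).  Extra columns
    (name, strand, value, ...) ride along untouched.
    """

    def __init__(self, df: pd.DataFrame, disjoint: bool = False) -> None:
        df = _as_frame(df)
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ParameterError("IntervalSet needs chrom/start/end columns")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            row = df.loc[bad[0]]
            raise CoordinateError(
                f"invalid interval {row['chrom']}:{row['start']}-{row['end']} (record {bad[0]})"
            )
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.disjoint = bool(disjoint)
        if disjoint:
            g = self.df.groupby("chrom", sort=False)
            overlap = (g["start"].shift(-1) < self.df["end"]) & (
                g["chrom"].shift(-1) == self.df["chrom"]
            )
            if overlap.fillna(False).any():
                k = int(np.flatnonzero(overlap.fillna(False).to_numpy())[0])
                raise CoordinateError(
                    f"set flagged disjoint but records {k} and {k + 1} overlap"
                )

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomeInterval], disjoint: bool = False):
        return cls(_as_frame(list(intervals)), disjoint=disjoint)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomeInterval]:
        has_strand = "strand" in self.df.columns
        for row in self.df.itertuples(index=False):
            strand = getattr(row, "strand", ".") if has_strand else "."
            yield GenomeInterval(row.chrom, int(row.start), int(row.end), strand if strand in STRANDS else ".")

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def validate_against(self, space: ChromosomeSpace) -> None:
        for row in self.df.itertuples():
            space.check(row.chrom, int(row.start), int(row.end))

    def merge(self, max_gap: int = 0) -> "IntervalSet":
        return merge_intervals(self, max_gap)

    def _per_chrom(self):
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)


def merge_intervals(s, max_gap: int = 0) -> IntervalSet:
    """Transitively merge intervals separated by <= ``max_gap`` bases.

    ``max_gap=0`` merges touching/overlapping intervals only.  The output is
    disjoint and sorted; total span never decreases.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be non-negative, got {max_gap}")
    s = s if isinstance(s, IntervalSet) else IntervalSet(s)
    parts = []
    for chrom, starts, ends in s._per_chrom():
        ms, me = _merge_arrays(starts, ends, max_gap)
        parts.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    if not parts:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), disjoint=True)
    return IntervalSet(pd.concat(parts, ignore_index=True), disjoint=True)


def intersect_length(a, b, space: ChromosomeSpace | None = None):
    """Exact count of bases covered by both sets.

    Returns ``(total, per_chrom)``.  Symmetric in its arguments.  Also
    counts, per chromosome, the number of records of *a* overlapping any
    record of *b* (exposed because published intersection tools report
    either bases or records); see :func:`intersect_records`.
    """
    a = a if isinstance(a, IntervalSet) else IntervalSet(a)
    b = b if isinstance(b, IntervalSet) else IntervalSet(b)
    if space is not None:
        a.validate_against(space)
        b.validate_against(space)
    am = merge_intervals(a, 0)
    bm = merge_intervals(b, 0)
    per_chrom: dict[str, int] = {}
    bmap = {chrom: (ts, te) for chrom, ts, te in bm._per_chrom()}
    for chrom, qs, qe in am._per_chrom():
        if chrom not in bmap:
            continue
        ts, te = bmap[chrom]
        n = int(_covered_length(qs, qe, ts, te).sum())
        if n:
            per_chrom[chrom] = n
    return sum(per_chrom.values()), per_chrom


def intersect_records(a, b) -> int:
    """Number of records of *a* overlapping at least one record of *b*."""
    a = a if isinstance(a, IntervalSet) else IntervalSet(a)
    b = b if isinstance(b, IntervalSet) else IntervalSet(b)
    bm = merge_intervals(b, 0)
    bmap = {chrom: (ts, te) for chrom, ts, te in bm._per_chrom()}
    count = 0
    for chrom, qs, qe in a._per_chrom():
        if chrom not in bmap:
            continue
        ts, te = bmap[chrom]
        count += int((_covered_length(qs, qe, ts, te) > 0).sum())
    return count


def covered_length(queries, targets) -> np.ndarray:
    """Per-query covered bases against a target set (merged internally)."""
    q = queries if isinstance(queries, IntervalSet) else IntervalSet(queries)
    tm = merge_intervals(targets, 0)
    tmap = {chrom: (ts, te) for chrom, ts, te in tm._per_chrom()}
    out = np.zeros(len(q), dtype=np.int64)
    df = q.df
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in tmap:
            continue
        ts, te = tmap[chrom]
        out[sub.index.to_numpy()] = _covered_length(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64), ts, te
        )
    return out


def coverage_fraction(query: GenomeInterval, targets) -> float:
    """Fraction of *query* covered by *targets* (merged first)."""
    qdf = pd.DataFrame({"chrom": [query.chrom], "start": [query.start], "end": [query.end]})
    cov = int(covered_length(IntervalSet(qdf), targets)[0])
    return cov / query.length


# ---------------------------------------------------------------------------
# BED reader/writer (tab-separated, 0-based half-open)

def read_bed(path, space: ChromosomeSpace | None = None, strict: bool = True,
             logger=None) -> IntervalSet:
    """Read BED3/BED4/BED6 into an IntervalSet.

    In strict mode malformed lines raise :class:`InputFormatError` with the
    line number; in lenient mode they are skipped and counted via *logger*
    (a callable taking a message).
    """
    rows = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 3:
                    raise ValueError("fewer than 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if not 0 <= start < end:
                    raise ValueError(f"bad coordinates {start}-{end}")
                name = parts[3] if len(parts) > 3 else "."
                score = parts[4] if len(parts) > 4 else "."
                strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
                if space is not None:
                    space.check(chrom, start, end)
            except (ValueError, CoordinateError) as exc:
                if strict:
                    raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
                skipped += 1
                if logger:
                    logger(f"{path}:{lineno}: skipped ({exc})")
                continue
            rows.append((chrom, start, end, name, score, strand))
    if skipped and logger:
        logger(f"{path}: skipped {skipped} malformed line(s)")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return IntervalSet(df)


def write_bed(obj, path, columns: int = 3) -> None:
    """Write an IntervalSet/DataFrame as BED with the requested column count."""
    df = _as_frame(obj).copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    cols = ["chrom", "start", "end", "name", "score", "strand"][:columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
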