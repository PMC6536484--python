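"""Four-state chromatin track: reading, smoothing, composition.

The input track classifies fixed-width genomic fragments (200 bp at model
resolution) into one of four chromatin types — *aquamarine* (open,
interband-like), *lazurite* and *malachite* (intermediate, gray-band-like),
and *ruby* (dense, black-band-like) — plus *gap* where the classifier
returned no call.  Smoothing combines fragments of identical state whose
intervening gap does not exceed ``max_gap`` (default 400 bp) into domains;
fragments of different states are never merged, regardless of gap size.

Tracks and domains are plain DataFrames with columns ``chrom, start, end,
state`` (domains additionally carry ``n_fragments`` and ``absorbed_gap_bp``),
so every interval primitive from :mod:`polyband.intervals` applies directly.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import (
    GenomeInterval,
    InputFormatError,
    IntervalSet,
    ParameterError,
    _covered_length,
    merge_intervals,
)

STATES = ("aquamarine", "lazurite", "malachite", "ruby")
GAP = "gap"
ALL_STATES = STATES + (GAP,)

#: states that form bands (everything except the interband state)
BAND_STATES = ("lazurite", "malachite", "ruby")
INTERBAND_STATE = "aquamarine"

DEFAULT_GRID = 200
DEFAULT_MAX_GAP = 400

TRACK_COLUMNS = ["chrom", "start", "end", "state"]
DOMAIN_COLUMNS = TRACK_COLUMNS + ["n_fragments", "absorbed_gap_bp"]


@dataclasses.dataclass
class CompositionProfile:
    """Per-state base fractions of a region (gap/unassigned included)."""

    fractions: dict[str, float]
    bases: dict[str, int]
    total_length: int

    def __getitem__(self, state: str) -> float:
        return self.fractions.get(state, 0.0)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": list(self.fractions),
                "bases": [self.bases[s] for s in self.fractions],
                "fraction": [self.fractions[s] for s in self.fractions],
            }
        )


def read_state_track(path, grid: int = DEFAULT_GRID, aliases: Mapping[str, str] | None = None,
                     strict: bool = True, logger=None) -> pd.DataFrame:
    """Read a BED4 chromatin-state track into a validated fragment frame.

    The BED name column must be one of the four state names or ``gap``
    (case-insensitive; extendable with an alias map).  Fragments must be
    non-overlapping; their lengths must be positive multiples of *grid*
    (error in strict mode, warning otherwise).
    """
    alias = {s: s for s in ALL_STATES}
    if aliases:
        alias.update({k.lower(): v for k, v in aliases.items()})
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputFormatError(f"{path}:{lineno}: state track needs 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            state = alias.get(name.lower())
            if state is None:
                raise InputFormatError(
                    f"{path}:{lineno}: unknown state label {name!r} "
                    f"(expected one of {ALL_STATES})"
                )
            if not 0 <= start < end:
                raise InputFormatError(f"{path}:{lineno}: bad coordinates {start}-{end}")
            if (end - start) % grid or start % grid:
                msg = f"{path}:{lineno}: fragment {chrom}:{start}-{end} off the {grid}-bp grid"
                if strict:
                    raise InputFormatError(msg)
                if logger:
                    logger(msg)
            rows.append((chrom, start, end, state, lineno))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS + ["_line"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1] if len(df) > 1 else np.array([], bool)
    overlap = same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])
    if overlap.any():
        k = int(np.flatnonzero(overlap)[0])
        raise InputFormatError(
            f"{path}: overlapping fragments at lines {int(df['_line'][k])} and "
            f"{int(df['_line'][k + 1])}"
        )
    return df.drop(columns="_line")


def write_state_track(fragments: pd.DataFrame, path) -> None:
    """Write fragments or domains as BED4 (name = state)."""
    fragments[TRACK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def smooth(fragments: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Merge same-state fragments whose intervening gap is <= ``max_gap``.

    Gap-labeled fragments count as empty space: two aquamarine fragments
    separated by a 400-bp gap call become one aquamarine domain spanning it,
    with the bridged bases tallied in ``absorbed_gap_bp``.  A fragment of a
    *different* state between two same-state fragments always breaks the
    run.  Returns the domain frame sorted by (chrom, start).
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be non-negative, got {max_gap}")
    df = fragments[fragments["state"] != GAP]
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if df.empty:
        return pd.DataFrame(columns=DOMAIN_COLUMNS)
    chrom = df["chrom"].to_numpy()
    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    state = df["state"].to_numpy()
    new_run = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        same = (chrom[1:] == chrom[:-1]) & (state[1:] == state[:-1])
        close = (start[1:] - end[:-1]) <= max_gap
        new_run[1:] = ~(same & close)
    run_id = np.cumsum(new_run) - 1
    n = run_id[-1] + 1
    out = pd.DataFrame(
        {
            "chrom": chrom[new_run],
            "start": start[new_run],
            "end": np.zeros(n, np.int64),
            "state": state[new_run],
            "n_fragments": np.bincount(run_id, minlength=n),
            "absorbed_gap_bp": np.zeros(n, np.int64),
        }
    )
    ends = np.zeros(n, np.int64)
    np.maximum.at(ends, run_id, end)
    out["end"] = ends
    frag_bases = np.bincount(run_id, weights=(end - start), minlength=n).astype(np.int64)
    out["absorbed_gap_bp"] = (out["end"] - out["start"]) - frag_bases
    return out


def state_composition(region, track: pd.DataFrame, warn_empty: bool = True) -> CompositionProfile:
    """Per-state covered-base fractions of a region.

    *track* may be a fragment frame (raw composition: absorbed gaps counted
    as gap) or a smoothed-domain frame (absorbed gap bases attributed to the
    merged domain's state).  The remainder of the region not covered by any
    state-labeled interval is reported under ``gap`` together with explicit
    gap calls; fractions sum to 1.
    """
    if isinstance(region, GenomeInterval):
        qdf = pd.DataFrame({"chrom": [region.chrom], "start": [region.start], "end": [region.end]})
    else:
        qdf = region.df if isinstance(region, IntervalSet) else pd.DataFrame(region)
    total = int((qdf["end"] - qdf["start"]).sum())
    if total == 0:
        if warn_empty:
            warnings.warn("state_composition called on an empty region", stacklevel=2)
        return CompositionProfile({s: 0.0 for s in ALL_STATES}, {s: 0 for s in ALL_STATES}, 0)
    queries = IntervalSet(qdf)
    bases: dict[str, int] = {}
    for s in STATES:
        sub = track[track["state"] == s]
        if sub.empty:
            bases[s] = 0
            continue
        tm = merge_intervals(IntervalSet(sub[["chrom", "start", "end"]]), 0)
        tmap = {c: (ts, te) for c, ts, te in tm._per_chrom()}
        n = 0
        for c, g in queries.df.groupby("chrom", sort=False):
            if c in tmap:
                n += int(_covered_length(g["start"].to_numpy(), g["end"].to_numpy(), *tmap[c]).sum())
        bases[s] = n
    bases[GAP] = total - sum(bases[s] for s in STATES)
    fractions = {s: bases[s] / total for s in ALL_STATES}
    return CompositionProfile(fractions, bases, total)
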