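"""Feature statistics over chromatin domains and morphological structures.

Implements the statistics used to characterise band/interband organisation:

* point-feature **density** in pcs/kb per named region set (e.g. insertion
  sites per chromatin type or per structure);
* **overlap percentage** — % of a region set's length covered by an
  interval feature (ChIP domains, TE remnants);
* the **TSS-anchored binned profile**: 200-bp bins laid out from each
  in-scope gene's 5' start towards the intergenic spacer (s1..s5) and into
  the gene body (g1..g5), counts normalised by the gene's transcript
  number; head-to-head gene pairs each receive features in their shared
  spacer;
* **rank-sum enrichment**: per (feature, chromatin state), the two-sided
  unpaired Wilcoxon test comparing per-domain coverage proportions on the
  target chromosome against the rest of the genome;
* **expression-breadth comparison** of genes grouped by the structure
  class holding their 5' start;
* per-region **signal medians** — the median of per-domain maxima of a
  step (bedGraph) signal.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .intervals import ChromosomeSpace, IntervalSet, covered_length, merge_intervals
from .state_track import STATES
from .stats import rank_sum_p, rank_sum_verdict
from .structures import KLASSES, GeneModel, MorphStructure

DEFAULT_BIN = 200
DEFAULT_N_BINS = 5
DEFAULT_ALPHA = 0.001


def _region_df(obj) -> pd.DataFrame:
    if isinstance(obj, IntervalSet):
        return obj.df
    if isinstance(obj, pd.DataFrame):
        return obj
    return IntervalSet(obj).df


# ---------------------------------------------------------------------------
# Density and overlap

def density(points: pd.DataFrame, region_sets: dict[str, object]) -> pd.DataFrame:
    """Point-feature density in pcs/kb per named region set.

    *points* needs ``chrom`` and ``pos`` columns.  Regions within a set are
    merged before measuring.  A zero-length set yields a null density.
    """
    rows = []
    for name, regions in region_sets.items():
        merged = merge_intervals(IntervalSet(_region_df(regions)), 0)
        total = merged.total_length()
        count = _count_points_in(points, merged)
        if total == 0:
            warnings.warn(f"region set {name!r} has zero length; density undefined",
                          stacklevel=2)
            rows.append({"set": name, "n_points": count, "length_bp": 0, "density_per_kb": None})
        else:
            rows.append({"set": name, "n_points": count, "length_bp": total,
                         "density_per_kb": count / (total / 1000.0)})
    return pd.DataFrame(rows)


def _count_points_in(points: pd.DataFrame, merged: IntervalSet) -> int:
    count = 0
    tmap = {c: (ts, te) for c, ts, te in merged._per_chrom()}
    for chrom, sub in points.groupby("chrom", sort=False):
        if chrom not in tmap:
            continue
        ts, te = tmap[chrom]
        pos = np.sort(sub["pos"].to_numpy(np.int64))
        i = np.searchsorted(pos, ts, side="left")
        j = np.searchsorted(pos, te, side="left")
        count += int((j - i).sum())
    return count


def overlap_percent(features, region_sets: dict[str, object]) -> pd.DataFrame:
    """% of each named set's length covered by the (merged) feature intervals."""
    fmerged = merge_intervals(IntervalSet(_region_df(features)), 0)
    rows = []
    for name, regions in region_sets.items():
        merged = merge_intervals(IntervalSet(_region_df(regions)), 0)
        total = merged.total_length()
        if total == 0:
            warnings.warn(f"region set {name!r} has zero length; overlap undefined",
                          stacklevel=2)
            rows.append({"set": name, "length_bp": 0, "covered_bp": 0, "percent": None})
            continue
        cov = int(covered_length(merged, fmerged).sum())
        rows.append({"set": name, "length_bp": total, "covered_bp": cov,
                     "percent": 100.0 * cov / total})
    return pd.DataFrame(rows)


def structure_region_sets(structures: list[MorphStructure]) -> dict[str, pd.DataFrame]:
    """Named region sets for the three structure classes plus all bands."""
    out: dict[str, list] = {k: [] for k in KLASSES}
    for s in structures:
        out[s.klass].append({"chrom": s.chrom, "start": s.start, "end": s.end})
    sets = {k: pd.DataFrame(v, columns=["chrom", "start", "end"]) for k, v in out.items()}
    sets["all_bands"] = pd.concat([sets["gray_band"], sets["black_band"]], ignore_index=True)
    return sets


def state_region_sets(domains: pd.DataFrame, chrom: str | None = None) -> dict[str, pd.DataFrame]:
    """Named region sets, one per chromatin state, optionally one chromosome."""
    d = domains if chrom is None else domains[domains["chrom"] == chrom]
    return {s: d[d["state"] == s][["chrom", "start", "end"]] for s in STATES}


# ---------------------------------------------------------------------------
# TSS-anchored binned profile

@dataclasses.dataclass
class TSSProfile:
    """Transcript-normalised feature counts in bins around gene 5' starts."""

    labels: list[str]
    values: np.ndarray
    n_genes: int
    bin: int = DEFAULT_BIN

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.labels)

    @property
    def max_bin(self) -> str:
        return self.labels[int(np.argmax(self.values))]

    def top_bins(self, k: int = 2) -> set[str]:
        order = np.argsort(self.values)[::-1]
        return {self.labels[i] for i in order[:k]}


def profile_labels(n_bins: int = DEFAULT_N_BINS) -> list[str]:
    return [f"s{i}" for i in range(n_bins, 0, -1)] + [f"g{i}" for i in range(1, n_bins + 1)]


def tss_profile(features: pd.DataFrame, genes: list[GeneModel], scope,
                bin: int = DEFAULT_BIN, n_bins: int = DEFAULT_N_BINS,
                interval_mode: str = "midpoint") -> TSSProfile:
    """Binned feature profile around the 5' starts of in-scope genes.

    A gene is in scope when its 5' start lies inside *scope* (e.g. the
    interband intervals).  For each such gene, ``n_bins`` bins of ``bin`` bp
    extend from the 5' start away from the gene (s1 nearest the start) and
    into the gene body (g1 first); orientation follows the strand.  Each
    feature in a bin adds ``1 / n_transcripts`` of that gene.  A feature
    lying in the shared spacer of two head-to-head genes falls into s-bins
    of both and is credited to both.

    Interval features are assigned by midpoint (``interval_mode="midpoint"``)
    or to every bin they overlap (``"any_overlap"``).
    """
    scope_set = merge_intervals(IntervalSet(_region_df(scope)), 0)
    smap = {c: (ts, te) for c, ts, te in scope_set._per_chrom()}

    is_points = "pos" in features.columns
    if is_points:
        feat = features[["chrom", "pos"]].copy()
        feat["_lo"] = feat["pos"]
        feat["_hi"] = feat["pos"] + 1
    else:
        feat = features[["chrom", "start", "end"]].copy()
        if interval_mode == "midpoint":
            mid = (feat["start"] + feat["end"]) // 2
            feat["_lo"] = mid
            feat["_hi"] = mid + 1
        elif interval_mode == "any_overlap":
            feat["_lo"] = feat["start"]
            feat["_hi"] = feat["end"]
        else:
            raise ValueError(f"unknown interval_mode {interval_mode!r}")
    # lo and hi are sorted independently: counting features intersecting a
    # bin needs #(lo < bin_end) - #(hi <= bin_start), each on its own order
    by_chrom = {
        c: (np.sort(sub["_lo"].to_numpy(np.int64)), np.sort(sub["_hi"].to_numpy(np.int64)))
        for c, sub in feat.groupby("chrom", sort=False)
    }

    labels = profile_labels(n_bins)
    values = np.zeros(2 * n_bins)
    n_used = 0
    for g in genes:
        if g.chrom not in smap:
            continue
        ts, te = smap[g.chrom]
        p = g.five_prime_start
        k = np.searchsorted(te, p, side="right")
        if k >= len(ts) or not (ts[k] <= p < te[k]):
            continue
        n_used += 1
        if g.chrom not in by_chrom:
            continue
        lo, hi = by_chrom[g.chrom]
        boundary = p if g.strand == "+" else p + 1
        # bin edges from s{n}..s1,g1..g{n} in genomic coordinates
        if g.strand == "+":
            edges = boundary + bin * np.arange(-n_bins, n_bins + 1)
            order = np.arange(2 * n_bins)
        else:
            edges = boundary + bin * np.arange(-n_bins, n_bins + 1)
            order = np.arange(2 * n_bins)[::-1]  # genomic left-to-right = g{n}..s{n}
        # features whose [lo, hi) intersects each bin [edges[i], edges[i+1])
        i = np.searchsorted(hi, edges[:-1], side="right")
        j = np.searchsorted(lo, edges[1:], side="left")
        counts = np.maximum(0, j - i)
        values[order] += counts / g.n_transcripts
    return TSSProfile(labels, values, n_used, bin)


# ---------------------------------------------------------------------------
# Rank-sum coverage enrichment

def domain_coverage_fractions(domains: pd.DataFrame, feature) -> np.ndarray:
    """Per-domain fraction of bases covered by the (merged) feature set."""
    if domains.empty:
        return np.zeros(0)
    dset = IntervalSet(domains[["chrom", "start", "end"]])
    cov = covered_length(dset, IntervalSet(_region_df(feature)))
    lengths = (dset.df["end"] - dset.df["start"]).to_numpy()
    return cov / lengths


def _expand_to_fragments(domains: pd.DataFrame, grid: int) -> pd.DataFrame:
    rows = []
    for r in domains.itertuples(index=False):
        starts = np.arange(r.start, r.end, grid, dtype=np.int64)
        rows.append(pd.DataFrame({
            "chrom": r.chrom, "start": starts,
            "end": np.minimum(starts + grid, r.end), "state": r.state,
        }))
    return pd.concat(rows, ignore_index=True) if rows else domains

def wilcoxon_enrichment(features: dict[str, pd.DataFrame], domains: pd.DataFrame,
                        space: ChromosomeSpace, alpha: float = DEFAULT_ALPHA,
                        unit: str = "domain", grid: int = 200) -> pd.DataFrame:
    """Enrichment/depletion of each feature in each chromatin state.

    For every (feature, state) pair, sample A holds the coverage proportion
    of each state domain on the target chromosome and sample B the same on
    all remaining chromosomes; the two are compared with a two-sided
    unpaired rank-sum test.  ``unit="fragment"`` measures per grid fragment
    instead of per smoothed domain.  Rows with fewer than two observations
    in either sample are emitted with verdict ``ns`` and flagged.
    """
    if unit == "fragment":
        domains = _expand_to_fragments(domains, grid)
    elif unit != "domain":
        raise ValueError(f"unknown unit {unit!r}")
    rows = []
    for label, feat in features.items():
        fset = merge_intervals(IntervalSet(_region_df(feat)), 0)
        for state in STATES:
            sub = domains[domains["state"] == state]
            a_dom = sub[sub["chrom"] == space.target]
            b_dom = sub[sub["chrom"] != space.target]
            a = domain_coverage_fractions(a_dom, fset)
            b = domain_coverage_fractions(b_dom, fset)
            row = {
                "feature": label, "state": state,
                "n_target": len(a), "n_rest": len(b),
                "median_target": float(np.median(a)) if len(a) else np.nan,
                "median_rest": float(np.median(b)) if len(b) else np.nan,
                "p_value": np.nan, "verdict": "ns", "flag": "",
            }
            if len(a) < 2 or len(b) < 2:
                row["flag"] = "insufficient_sample"
            else:
                p, verdict = rank_sum_verdict(a, b, alpha)
                row["p_value"] = p
                row["verdict"] = verdict
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression breadth

def expression_breadth_compare(genes: list[GeneModel], structures: list[MorphStructure]):
    """Breadth distributions of genes grouped by the class of the structure
    containing their 5' start, with pairwise two-sided rank-sum tests."""
    structures = sorted(structures, key=lambda s: (s.chrom, s.start))
    groups: dict[str, list[int]] = {k: [] for k in KLASSES}
    missing = 0
    for g in genes:
        if g.expression_breadth is None:
            missing += 1
            continue
        for s in structures:
            if s.chrom == g.chrom and s.start <= g.five_prime_start < s.end:
                groups[s.klass].append(g.expression_breadth)
                break
    if missing:
        warnings.warn(f"{missing} gene(s) lacking expression breadth excluded", stacklevel=2)
    summary = pd.DataFrame(
        [
            {
                "group": k,
                "n": len(v),
                "median": float(np.median(v)) if v else np.nan,
                "mean": float(np.mean(v)) if v else np.nan,
            }
            for k, v in groups.items()
        ]
    )
    pairs = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            p = rank_sum_p(a, b) if len(a) >= 1 and len(b) >= 1 else np.nan
            pairs.append({"group_a": names[i], "group_b": names[j], "p_value": p})
    return summary, pd.DataFrame(pairs)


# ---------------------------------------------------------------------------
# Step-signal medians

def domain_signal_median(signal: pd.DataFrame, region_sets: dict[str, object],
                         length_weighted: bool = False) -> pd.DataFrame:
    """Median of per-region signal maxima for each named region set.

    The per-region value is the maximum bedGraph step value overlapping the
    region (0 when none).  With ``length_weighted=True`` the median over a
    set is weighted by region length, so the value reported for a structure
    class reflects the signal level of the typical *base*, not the typical
    domain — a band whose enriched state is a minority of its length then
    reports a low value even though its maximum is high.
    """
    sig = signal.sort_values(["chrom", "start"], kind="mergesort")
    smap = {
        c: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64),
            g["value"].to_numpy(float))
        for c, g in sig.groupby("chrom", sort=False)
    }
    rows = []
    for name, regions in region_sets.items():
        df = _region_df(regions)
        peaks, lengths = [], []
        for r in df.itertuples(index=False):
            peak = 0.0
            if r.chrom in smap:
                ts, te, tv = smap[r.chrom]
                i = int(np.searchsorted(te, r.start, side="right"))
                j = int(np.searchsorted(ts, r.end, side="left"))
                if i < j:
                    peak = float(tv[i:j].max())
            peaks.append(peak)
            lengths.append(int(r.end) - int(r.start))
        med = _median(np.asarray(peaks, float),
                      np.asarray(lengths, float) if length_weighted else None)
        rows.append({"set": name, "n_regions": len(peaks), "median_peak": med})
    return pd.DataFrame(rows)


def _median(values: np.ndarray, weights: np.ndarray | None) -> float:
    if values.size == 0:
        return float("nan")
    if weights is None:
        return float(np.median(values))
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, cum[-1] / 2.0)])
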