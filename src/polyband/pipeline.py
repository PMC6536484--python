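"""End-to-end pipeline: smooth -> segment -> compose -> gene content ->
density / overlap / profiles / enrichment, with a machine- and
human-readable run report."""

from __future__ import annotations

import dataclasses
import json
import os
import warnings

import numpy as np
import pandas as pd

from . import feature_stats as fs
from .intervals import ChromosomeSpace, write_bed
from .state_track import DEFAULT_GRID, DEFAULT_MAX_GAP, state_composition, smooth
from .structures import (
    DEFAULT_INCLUSION_MAX,
    DEFAULT_INTERBAND_MIN_LEN,
    DEFAULT_RUBY_MIN,
    INTERBAND,
    MorphStructure,
    apply_anchors,
    apply_overrides,
    classify_gene_content,
    find_inclusions,
    inclusions_to_frame,
    segment,
    structures_to_frame,
)


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters; defaults match the published analysis settings."""

    grid: int = DEFAULT_GRID
    max_gap: int = DEFAULT_MAX_GAP
    interband_min_len: int = DEFAULT_INTERBAND_MIN_LEN
    inclusion_max: int = DEFAULT_INCLUSION_MAX
    ruby_min: int = DEFAULT_RUBY_MIN
    bin: int = fs.DEFAULT_BIN
    n_bins: int = fs.DEFAULT_N_BINS
    alpha: float = fs.DEFAULT_ALPHA
    seed: int = 0
    outdir: str | None = None


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


@dataclasses.dataclass
class RunReport:
    """Per-stage records plus the pipeline's summary tables."""

    config: dict
    stages: list = dataclasses.field(default_factory=list)
    tables: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)
    complete: bool = False

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "complete": self.complete,
            "stages": self.stages,
            "warnings": self.warnings,
            "tables": {
                k: json.loads(v.to_json(orient="records")) if isinstance(v, pd.DataFrame) else v
                for k, v in self.tables.items()
            },
        }
        return json.dumps(payload, indent=2, default=_round6)

    def to_markdown(self) -> str:
        lines = ["# polyband run report", ""]
        for st in self.stages:
            lines.append(f"- **{st['stage']}**: " + ", ".join(
                f"{k}={_round6(v)}" for k, v in st.items() if k != "stage"))
        for name, table in self.tables.items():
            lines += ["", f"## {name}", ""]
            if isinstance(table, pd.DataFrame):
                lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
            else:
                lines.append(json.dumps(table, default=_round6))
        return "\n".join(lines) + "\n"


def run_pipeline(fragments: pd.DataFrame, space: ChromosomeSpace, config: RunConfig,
                 genes=None, points: dict | None = None, intervals: dict | None = None,
                 signals: dict | None = None, anchors: pd.DataFrame | None = None,
                 overrides: dict | None = None):
    """Run every stage on in-memory inputs; returns (report, results dict).

    *fragments* is the state track; *genes* a list of GeneModel; *points*,
    *intervals* and *signals* are label->DataFrame feature maps.  Stage
    outputs are returned in the results dict and, when ``config.outdir`` is
    set, written as TSV/BED files.
    """
    report = RunReport(config=dataclasses.asdict(config))
    results: dict = {}
    points = points or {}
    intervals = intervals or {}
    signals = signals or {}
    target = space.target

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        domains = smooth(fragments, max_gap=config.max_gap)
        results["domains"] = domains
        report.add_stage("smooth", n_fragments=len(fragments), n_domains=len(domains),
                         max_gap=config.max_gap)

        structures: list[MorphStructure] = segment(
            domains[domains["chrom"] == target],
            interband_min_len=config.interband_min_len,
            inclusion_max=config.inclusion_max,
            ruby_min=config.ruby_min,
        )
        if anchors is not None:
            structures = apply_anchors(structures, anchors[anchors["chrom"] == target])
        if overrides:
            structures = apply_overrides(structures, overrides, ruby_min=config.ruby_min)
        results["structures"] = structures
        n_ib = sum(1 for s in structures if s.klass == INTERBAND)
        report.add_stage("segment", n_structures=len(structures),
                         n_bands=len(structures) - n_ib, n_interbands=n_ib)
        struct_table = structures_to_frame(structures)
        report.tables["structure_census"] = _structure_census(structures, space)
        results["structure_table"] = struct_table

        inclusion_records, inclusion_summary = find_inclusions(structures)
        results["inclusions"] = inclusion_records
        report.tables["inclusion_summary"] = inclusion_summary

        target_region = pd.DataFrame(
            {"chrom": [target], "start": [0], "end": [space.sizes[target]]})
        comp_smoothed = state_composition(target_region, domains, warn_empty=False)
        comp_raw = state_composition(target_region, fragments, warn_empty=False)
        report.tables["composition"] = pd.DataFrame(
            {
                "state": list(comp_smoothed.fractions),
                "fraction_smoothed": list(comp_smoothed.fractions.values()),
                "fraction_raw": [comp_raw.fractions[s] for s in comp_smoothed.fractions],
            }
        )
        report.add_stage("compose", total_bp=comp_smoothed.total_length)

        struct_sets = fs.structure_region_sets(structures)
        state_sets = fs.state_region_sets(domains, chrom=target)

        if genes:
            content_table, content_summary = classify_gene_content(structures, genes)
            results["gene_content"] = content_table
            report.tables["gene_content_summary"] = content_summary
            breadth_summary, breadth_pairs = fs.expression_breadth_compare(genes, structures)
            report.tables["expression_breadth"] = breadth_summary
            report.tables["expression_breadth_tests"] = breadth_pairs
            report.add_stage("gene_content", n_genes=len(genes))

        interband_scope = struct_sets[INTERBAND]
        for label, pts in points.items():
            report.tables[f"density_{label}_structures"] = fs.density(pts, struct_sets)
            report.tables[f"density_{label}_states"] = fs.density(pts, state_sets)
            if genes is not None and len(interband_scope):
                prof = fs.tss_profile(pts, genes, interband_scope,
                                      bin=config.bin, n_bins=config.n_bins)
                results[f"profile_{label}"] = prof
                report.tables[f"profile_{label}"] = prof.as_series().to_frame("value").reset_index(
                    names="bin")
        for label, ivs in intervals.items():
            report.tables[f"overlap_{label}_structures"] = fs.overlap_percent(ivs, struct_sets)
            report.tables[f"overlap_{label}_states"] = fs.overlap_percent(ivs, state_sets)
            if genes is not None and len(interband_scope):
                prof = fs.tss_profile(ivs, genes, interband_scope,
                                      bin=config.bin, n_bins=config.n_bins)
                results[f"profile_{label}"] = prof
        if intervals:
            enrich = fs.wilcoxon_enrichment(intervals, domains, space, alpha=config.alpha)
            results["enrichment"] = enrich
            report.tables["enrichment"] = enrich
            report.add_stage("enrich", n_rows=len(enrich), alpha=config.alpha)
        else:
            report.tables["enrichment"] = "empty"
        if not points and not intervals:
            report.tables["density"] = "empty"

        for label, sig in signals.items():
            sets = dict(state_sets)
            # structure-class sets measured over member domains, length-weighted
            member_sets = {
                k: pd.concat([s.member_domains for s in structures if s.klass == k],
                             ignore_index=True)[["chrom", "start", "end"]]
                for k in ("interband", "gray_band", "black_band")
                if any(s.klass == k for s in structures)
            }
            report.tables[f"signal_{label}_states"] = fs.domain_signal_median(sig, sets)
            report.tables[f"signal_{label}_structures"] = fs.domain_signal_median(
                sig, member_sets, length_weighted=True)

        report.warnings = [str(w.message) for w in caught]

    report.complete = True
    if config.outdir:
        _write_outputs(config.outdir, report, results, domains)
    return report, results


def _structure_census(structures: list[MorphStructure], space: ChromosomeSpace) -> pd.DataFrame:
    total = space.sizes[space.target]
    rows = []
    for klass in ("interband", "gray_band", "black_band"):
        sub = [s for s in structures if s.klass == klass]
        length = sum(s.length for s in sub)
        sizes = [s.length for s in sub]
        rows.append(
            {
                "klass": klass,
                "count": len(sub),
                "total_bp": length,
                "pct_of_chromosome": 100.0 * length / total,
                "min_kb": min(sizes) / 1000 if sizes else np.nan,
                "max_kb": max(sizes) / 1000 if sizes else np.nan,
                "mean_kb": float(np.mean(sizes)) / 1000 if sizes else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(outdir: str, report: RunReport, results: dict, domains: pd.DataFrame) -> None:
    os.makedirs(outdir, exist_ok=True)
    domains.to_csv(os.path.join(outdir, "domains.tsv"), sep="\t", index=False)
    if "structure_table" in results:
        results["structure_table"].to_csv(
            os.path.join(outdir, "structures.tsv"), sep="\t", index=False)
        bed = results["structure_table"].rename(columns={"name": "name"})
        bed["score"] = bed["klass"].map({"interband": 0, "gray_band": 1, "black_band": 2})
        write_bed(bed[["chrom", "start", "end", "name", "score"]].assign(strand="."),
                  os.path.join(outdir, "structures.bed"), columns=6)
    if "inclusions" in results:
        inclusions_to_frame(results["inclusions"]).to_csv(
            os.path.join(outdir, "inclusions.tsv"), sep="\t", index=False)
    if "gene_content" in results:
        results["gene_content"].to_csv(
            os.path.join(outdir, "gene_content.tsv"), sep="\t", index=False)
    for name, table in report.tables.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write(report.to_markdown())
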