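"""Synthetic polytene-chromosome generator with ground truth.

Generates complete pipeline inputs — a four-state fragment track, gene
models, point/interval features and a step signal — for a target ("dot")
chromosome plus a rest-of-genome chromosome, with bookkeeping that makes
every planted quantity recoverable by the pipeline's own measurements.

The default plan mirrors the organisation of the Drosophila fourth
chromosome's polytenized arm: 11 black bands (ruby cores with lazurite
edges, 35.8-89 kb), 16 gray bands (lazurite/malachite, 6.6-56.8 kb) and
the 26 interbands between them (aquamarine, ~4-12.3 kb); housekeeping
genes start in interbands, often head-to-head; open-chromatin features
(insertion sites, DHS, replication-origin sites) concentrate within a few
hundred bp of those gene starts; HP1a/POF-like coverage is elevated on the
target chromosome's aquamarine and lazurite only; TE remnants sit in band
states; a repressive signal is elevated on ruby.

Structure sizes are drawn from scaled Beta distributions over the printed
ranges whose means match the printed averages (a plain uniform draw over
the ranges is available but its expected total exceeds the arm length);
class totals are rescaled to fit the chromosome when necessary.  All
randomness flows from one seed through fixed per-component streams, so
adding a feature never perturbs the genome draw.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd

from .intervals import ChromosomeSpace, ParameterError
from .io import write_bedgraph, write_genes_gff3, write_points_bed
from .state_track import GAP, STATES, smooth, write_state_track
from .structures import BLACK, GRAY, INTERBAND, GeneModel

# canonical band order of the modelled arm (black = ruby-cored)
CANONICAL_BANDS = [
    ("101E1-2", BLACK), ("101F1", GRAY), ("102A1-2", GRAY), ("102A4-5", GRAY),
    ("102A6", GRAY), ("102A6'", GRAY), ("102A6''", GRAY), ("102B1-2", BLACK),
    ("102B3-4", GRAY), ("102B5-6", BLACK), ("102B7", GRAY), ("102B8-9", GRAY),
    ("102C1-2", BLACK), ("102C3", GRAY), ("102C4-5", GRAY), ("102C6-7", GRAY),
    ("102C8", GRAY), ("102D1-2", BLACK), ("102D4-5", BLACK), ("102D6-7", BLACK),
    ("102D8", GRAY), ("102E1-2", BLACK), ("102E3", GRAY), ("102E4-5", BLACK),
    ("102F1-2", BLACK), ("102F3", GRAY), ("102F4-5", BLACK),
]


class InfeasiblePlanError(ParameterError):
    """The structure plan cannot fit in the configured chromosome length."""


@dataclasses.dataclass
class SimConfig:
    """Generator parameters; defaults emulate the dot-chromosome arm."""

    seed: int = 0
    target_chrom: str = "chr4"
    target_length: int = 1_250_000
    rest_chrom: str = "chrR"
    rest_length: int = 10_000_000
    grid: int = 200

    # structure plan
    n_black: int = 11
    n_gray: int = 16
    black_size_range: tuple[int, int] = (35_800, 89_000)
    black_size_mean: float = 61_040.0
    gray_size_range: tuple[int, int] = (6_600, 56_800)
    gray_size_mean: float = 22_860.0
    interband_size_range: tuple[int, int] = (4_000, 12_300)
    interband_size_mean: float = 6_600.0
    size_distribution: str = "mean_matched"  # or "uniform"
    margin: int = 2_000
    boundary_gap_prob: float = 0.4
    boundary_gap_max: int = 1_200

    # within-structure state composition (fractions of the drawn size)
    black_fracs: tuple[float, float, float, float] = (0.37, 0.28, 0.17, 0.18)  # ruby, laz, mal, gap
    gray_fracs: tuple[float, float, float] = (0.54, 0.22, 0.24)  # laz, mal, gap
    interband_gap_frac: float = 0.06  # short (<= 400 bp) model-gap punches

    # inclusion plan (target chromosome; rest scales with length)
    n_band_aqua_inclusions: int = 21
    band_inclusion_sizes: tuple[int, int, int] = (400, 600, 2_600)  # triangular lo/mode/hi
    band_inclusion_edge_margin: int = 5_000  # keep inclusions un-bridgeable from band edges
    n_black_host_bands: int = 8
    n_gray_host_bands: int = 5
    n_interband_lazurite_inclusions: int = 7
    interband_lazurite_sizes: tuple[int, int] = (2_800, 4_800)
    n_interband_malachite_inclusions: int = 2
    interband_malachite_sizes: tuple[int, int] = (1_600, 1_800)

    # gene plan
    head_to_head_prob: float = 0.5
    n_whole_gene_interbands: int = 6
    n_band_start_genes: int = 16
    gene_length_range: tuple[int, int] = (3_000, 30_000)
    whole_gene_length_range: tuple[int, int] = (800, 3_000)
    band_gene_length_range: tuple[int, int] = (2_000, 10_000)
    transcript_count_weights: tuple[float, ...] = (0.5, 0.25, 0.15, 0.1)
    breadth_means: dict = dataclasses.field(
        default_factory=lambda: {INTERBAND: 18.0, GRAY: 9.0, BLACK: 3.0}
    )
    breadth_sds: dict = dataclasses.field(
        default_factory=lambda: {INTERBAND: 4.0, GRAY: 3.0, BLACK: 2.0}
    )
    breadth_max: int = 25

    # feature plan
    n_p_elements: int = 107
    p_element_tss_frac: float = 0.7
    tss_window: int = 400
    n_dhs: int = 250
    dhs_upstream_window: int = 200
    dhs_background_frac: float = 0.15
    n_orc2: int = 250
    orc2_center_sd: float = 180.0
    orc2_center_max: int = 400
    orc2_width_range: tuple[int, int] = (200, 600)
    orc2_background_frac: float = 0.15
    n_te_remnants: int = 55
    te_size_range: tuple[int, int] = (400, 1_400)
    coverage_base: dict = dataclasses.field(
        default_factory=lambda: {
            "aquamarine": 0.25, "lazurite": 0.25, "malachite": 0.20, "ruby": 0.05
        }
    )
    hp1a_multiplier: float = 2.0
    pof_multiplier: float = 2.0
    coverage_concentration: float = 30.0
    signal_step: int = 400
    signal_ruby_mean: float = 2.5
    signal_base_mean: float = 0.0
    signal_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.grid <= 0 or self.target_length <= 0 or self.rest_length <= 0:
            raise ParameterError("lengths and grid must be positive")
        if self.n_black < 1 or self.n_gray < 1:
            raise ParameterError("need at least one band of each class")
        for name in ("black_size_range", "gray_size_range", "interband_size_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ParameterError(f"{name} must satisfy 0 < lo < hi")


# ---------------------------------------------------------------------------
# Internal building blocks

@dataclasses.dataclass
class _Block:
    state: str       # one of STATES or GAP
    length: int
    inclusion: bool = False
    start: int = -1  # filled at placement

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclasses.dataclass
class _Structure:
    klass: str
    name: str
    blocks: list  # of _Block

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def _round_grid(x: float, grid: int) -> int:
    return max(grid, int(round(float(x) / grid)) * grid)


def _draw_sizes(rng, n, lo, hi, mean, mode, grid, conc: float = 8.0) -> np.ndarray:
    if mode == "uniform":
        vals = rng.uniform(lo, hi, n)
    elif mode == "mean_matched":
        m = (mean - lo) / (hi - lo)
        if not 0 < m < 1:
            raise ParameterError(f"size mean {mean} outside range ({lo}, {hi})")
        vals = lo + (hi - lo) * rng.beta(conc * m, conc * (1 - m), n)
    else:
        raise ParameterError(f"unknown size_distribution {mode!r}")
    return np.array([_round_grid(v, grid) for v in vals])


def _split_by_fracs(total: int, fracs, grid: int) -> list[int]:
    """Split *total* (a grid multiple) by fractions, preserving the sum."""
    units = total // grid
    raw = np.asarray(fracs) * units
    base = np.floor(raw).astype(int)
    rem = units - base.sum()
    order = np.argsort(-(raw - base))
    for k in range(rem):
        base[order[k % len(base)]] += 1
    base = np.maximum(base, 1)
    # re-balance if the >=1 floor overshot
    while base.sum() > units:
        base[np.argmax(base)] -= 1
    return [int(b) * grid for b in base]


def _split_parts(rng, total: int, k: int, grid: int) -> list[int]:
    """Split a grid-multiple total into k grid-multiple parts >= grid."""
    units = total // grid
    if units < k:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, units), size=k - 1, replace=False)) if k > 1 else np.array([], int)
    bounds = np.concatenate([[0], cuts, [units]])
    return [int(b) * grid for b in np.diff(bounds)]


def _gap_chunks(rng, total: int, grid: int, max_chunk: int) -> list[int]:
    chunks = []
    rem = total
    while rem > 0:
        c = min(rem, int(rng.integers(1, max(max_chunk // grid, 1) + 1)) * grid)
        chunks.append(c)
        rem -= c
    return chunks


def _black_band_blocks(rng, size: int, cfg: SimConfig) -> list[_Block]:
    ruby_t, laz_t, mal_t, gap_t = _split_by_fracs(size, cfg.black_fracs, cfg.grid)
    laz_l, laz_r = _split_parts(rng, laz_t, 2, cfg.grid) if laz_t >= 2 * cfg.grid else (laz_t, 0)
    mal_l, mal_r = _split_parts(rng, mal_t, 2, cfg.grid) if mal_t >= 2 * cfg.grid else (mal_t, 0)
    core = [("lazurite", laz_l), ("malachite", mal_l), ("ruby", ruby_t),
            ("malachite", mal_r), ("lazurite", laz_r)]
    blocks = [_Block(s, ln) for s, ln in core if ln > 0]
    for c in _gap_chunks(rng, gap_t, cfg.grid, 1_600):
        pos = int(rng.integers(1, len(blocks)))  # interior boundaries only
        blocks.insert(pos, _Block(GAP, c))
    return blocks


def _gray_band_blocks(rng, size: int, cfg: SimConfig) -> list[_Block]:
    laz_t, mal_t, gap_t = _split_by_fracs(size, cfg.gray_fracs, cfg.grid)
    laz_l, laz_r = _split_parts(rng, laz_t, 2, cfg.grid) if laz_t >= 2 * cfg.grid else (laz_t, 0)
    core = [("lazurite", laz_l), ("malachite", mal_t), ("lazurite", laz_r)]
    blocks = [_Block(s, ln) for s, ln in core if ln > 0]
    if len(blocks) > 1:  # gap runs sit strictly inside the band
        for c in _gap_chunks(rng, gap_t, cfg.grid, 1_600):
            blocks.insert(int(rng.integers(1, len(blocks))), _Block(GAP, c))
    return blocks


def _interband_blocks(rng, size: int, cfg: SimConfig) -> list[_Block]:
    # model-gap punches come out of the drawn span, but the aquamarine core
    # never drops below the interband size minimum (it must stay detectable)
    gap_t = 0
    if cfg.interband_gap_frac > 0:
        gap_t = min(_round_grid(cfg.interband_gap_frac * size, cfg.grid),
                    max(0, size - cfg.interband_size_range[0]))
    blocks = [_Block("aquamarine", size - gap_t)]
    rem = gap_t
    while rem > 0:
        c = min(rem, int(rng.integers(1, 3)) * cfg.grid)  # 200 or 400: absorbed on smoothing
        if not _punch(rng, blocks, _Block(GAP, c), "aquamarine", cfg.grid):
            break
        rem -= c
    return blocks


def _punch(rng, blocks: list, insert: _Block, host_state: str, grid: int,
           edge_margin: int = 0) -> bool:
    """Split a random host-state block and insert *insert* between the halves.

    ``edge_margin`` keeps the insertion at least that far from both ends of
    the block list and from previously planted inclusions of the same
    state, so nearby planted fragments can never be bridged into one
    apparent structure.
    """
    offsets = np.concatenate([[0], np.cumsum([b.length for b in blocks])])
    total = int(offsets[-1])
    forbidden = [
        (int(offsets[i]) - edge_margin, int(offsets[i + 1]) + edge_margin)
        for i, b in enumerate(blocks) if b.inclusion and b.state == insert.state
    ]
    candidates = []
    for i, b in enumerate(blocks):
        if b.state != host_state or b.inclusion or b.length < 2 * grid:
            continue
        lo = max(grid, edge_margin - int(offsets[i]))
        hi = min(b.length - grid, total - edge_margin - int(offsets[i]))
        if lo > hi:
            continue
        pos = np.arange(lo, hi + 1, grid) + int(offsets[i])  # absolute insert points
        for f0, f1 in forbidden:
            pos = pos[(pos + insert.length <= f0) | (pos >= f1)]
        if pos.size:
            candidates.append((i, pos))
    if not candidates:
        return False
    i, pos = candidates[int(rng.integers(len(candidates)))]
    host = blocks[i]
    cut = int(pos[int(rng.integers(pos.size))]) - int(offsets[i])
    blocks[i:i + 1] = [_Block(host.state, cut), insert, _Block(host.state, host.length - cut)]
    return True


# ---------------------------------------------------------------------------
# Genome simulation

@dataclasses.dataclass
class GroundTruth:
    structures: pd.DataFrame       # name, klass, chrom, start, end
    inclusions: pd.DataFrame       # host, host_klass, state, chrom, start, end
    composition: dict              # chrom -> {state: bases} incl. gap + unlabeled
    gene_classes: dict             # gene_id -> structure klass of its 5' start


@dataclasses.dataclass
class SimResult:
    config: SimConfig
    space: ChromosomeSpace
    fragments: pd.DataFrame        # chrom, start, end, state (incl. gap rows)
    genes: list
    anchors: pd.DataFrame
    truth: GroundTruth
    _structures: dict = dataclasses.field(default_factory=dict)  # chrom -> list[_Structure]

    def domains(self, max_gap: int = 400) -> pd.DataFrame:
        return smooth(self.fragments, max_gap=max_gap)

    def interband_genes(self, chrom: str | None = None) -> list:
        chrom = chrom or self.config.target_chrom
        return [g for g in self.genes
                if g.chrom == chrom and self.truth.gene_classes[g.gene_id] == INTERBAND]

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        truth_dir = os.path.join(outdir, "truth")
        os.makedirs(truth_dir, exist_ok=True)
        write_state_track(self.fragments, os.path.join(outdir, "state_track.bed"))
        write_genes_gff3(self.genes, os.path.join(outdir, "genes.gff3"))
        self.space.write_tsv(os.path.join(outdir, "chrom_sizes.tsv"))
        with open(os.path.join(outdir, "breadth.tsv"), "w") as fh:
            fh.write("gene_id\tn_tissues\n")
            for g in self.genes:
                if g.expression_breadth is not None:
                    fh.write(f"{g.gene_id}\t{g.expression_breadth}\n")
        self.anchors.to_csv(os.path.join(outdir, "anchors.tsv"), sep="\t", index=False)
        self.truth.structures.to_csv(os.path.join(truth_dir, "structures.tsv"), sep="\t", index=False)
        self.truth.inclusions.to_csv(os.path.join(truth_dir, "inclusions.tsv"), sep="\t", index=False)


def _plan_chromosome(rng, chrom: str, length: int, n_black: int, n_gray: int,
                     cfg: SimConfig, canonical: bool) -> list[_Structure]:
    """Draw the alternating band/interband plan and fit it to the chromosome."""
    if canonical and (n_black, n_gray) == (11, 16):
        band_plan = list(CANONICAL_BANDS)
    else:
        klasses = [BLACK] * n_black + [GRAY] * n_gray
        rng.shuffle(klasses)
        band_plan = [(None, k) for k in klasses]
    n_bands = len(band_plan)
    n_inter = n_bands - 1

    mode = cfg.size_distribution
    black_sizes = _draw_sizes(rng, n_black, *cfg.black_size_range, cfg.black_size_mean, mode, cfg.grid)
    gray_sizes = _draw_sizes(rng, n_gray, *cfg.gray_size_range, cfg.gray_size_mean, mode, cfg.grid)
    inter_sizes = _draw_sizes(rng, n_inter, *cfg.interband_size_range, cfg.interband_size_mean, mode, cfg.grid)

    # inclusion sizes are drawn up front: they extend their host structures,
    # so they belong in the length budget
    scale = n_bands / (cfg.n_black + cfg.n_gray)
    n_binc = max(1, round(cfg.n_band_aqua_inclusions * scale))
    lo_t, mode_t, hi_t = cfg.band_inclusion_sizes
    band_inc_sizes = [_round_grid(rng.triangular(lo_t, mode_t, hi_t), cfg.grid)
                      for _ in range(n_binc)]
    inter_inc_plan = []
    for n_inc, state, (ilo, ihi) in (
        (max(1, round(cfg.n_interband_lazurite_inclusions * scale)), "lazurite",
         cfg.interband_lazurite_sizes),
        (max(1, round(cfg.n_interband_malachite_inclusions * scale)), "malachite",
         cfg.interband_malachite_sizes),
    ):
        for _ in range(n_inc):
            inter_inc_plan.append((state, _round_grid(rng.uniform(ilo, ihi), cfg.grid)))

    boundary_gaps = np.where(
        rng.random(n_inter * 2) < cfg.boundary_gap_prob,
        rng.integers(2, cfg.boundary_gap_max // cfg.grid + 1, n_inter * 2) * cfg.grid,
        0,
    )
    overhead = (int(boundary_gaps.sum()) + 2 * cfg.margin
                + sum(band_inc_sizes) + sum(sz for _, sz in inter_inc_plan))
    total = int(black_sizes.sum() + gray_sizes.sum() + inter_sizes.sum())
    budget = length - overhead
    if budget < (n_bands + n_inter) * 2 * cfg.grid:
        raise InfeasiblePlanError(
            f"{chrom}: {n_bands} bands + {n_inter} interbands cannot fit in {length} bp"
        )
    if total > budget:
        f = budget / total
        if f < 0.5:
            raise InfeasiblePlanError(
                f"{chrom}: planned structures ({total} bp) exceed chromosome budget "
                f"({budget} bp) by more than 2x"
            )
        # shrink bands proportionally; interbands never drop below their range
        # minimum (they must stay detectable as interbands)
        black_sizes = np.array([_round_grid(s * f, cfg.grid) for s in black_sizes])
        gray_sizes = np.array([max(cfg.gray_size_range[0] // cfg.grid * cfg.grid,
                                   _round_grid(s * f, cfg.grid)) for s in gray_sizes])
        inter_sizes = np.array([max(cfg.interband_size_range[0],
                                    _round_grid(s * f, cfg.grid)) for s in inter_sizes])
        overshoot = int(black_sizes.sum() + gray_sizes.sum() + inter_sizes.sum()) - budget
        while overshoot > 0:  # shave grid steps off the largest band of either class
            bi, gi_ = int(np.argmax(black_sizes)), int(np.argmax(gray_sizes))
            arr, i = ((black_sizes, bi) if black_sizes[bi] >= gray_sizes[gi_]
                      else (gray_sizes, gi_))
            if arr[i] <= cfg.gray_size_range[0]:
                raise InfeasiblePlanError(f"{chrom}: cannot fit structure plan")
            arr[i] -= cfg.grid
            overshoot -= cfg.grid

    structures: list[_Structure] = []
    ib, ig = 0, 0
    for k, (name, klass) in enumerate(band_plan):
        if klass == BLACK:
            size, ib = int(black_sizes[ib]), ib + 1
            blocks = _black_band_blocks(rng, size, cfg)
        else:
            size, ig = int(gray_sizes[ig]), ig + 1
            blocks = _gray_band_blocks(rng, size, cfg)
        structures.append(_Structure(klass, name or "", blocks))
        if k < n_inter:
            structures.append(
                _Structure(INTERBAND, "", _interband_blocks(rng, int(inter_sizes[k]), cfg))
            )

    # plant the pre-drawn inclusions
    bands = [s for s in structures if s.klass != INTERBAND]
    inters = [s for s in structures if s.klass == INTERBAND]
    blacks = [s for s in bands if s.klass == BLACK]
    grays = [s for s in bands if s.klass == GRAY]
    margin_b = cfg.band_inclusion_edge_margin
    big_enough = lambda s: sum(b.length for b in s.blocks) >= 2 * margin_b + 3 * cfg.grid
    blacks_ok = [s for s in blacks if big_enough(s)]
    grays_ok = [s for s in grays if big_enough(s)]
    n_bh = min(len(blacks_ok), max(1, round(cfg.n_black_host_bands * scale)))
    n_gh = min(len(grays_ok), max(0, round(cfg.n_gray_host_bands * scale)))
    hosts = [blacks_ok[i] for i in rng.choice(len(blacks_ok), n_bh, replace=False)]
    if n_gh:
        hosts += [grays_ok[i] for i in rng.choice(len(grays_ok), n_gh, replace=False)]
    for k, size in enumerate(band_inc_sizes):
        host = hosts[k % len(hosts)]
        ok = _punch(rng, host.blocks, _Block("aquamarine", size, inclusion=True),
                    rng.choice(["lazurite", "malachite"]), cfg.grid, edge_margin=margin_b)
        if not ok:
            for alt in ("lazurite", "malachite"):
                if _punch(rng, host.blocks, _Block("aquamarine", size, inclusion=True),
                          alt, cfg.grid, edge_margin=margin_b):
                    break
    host_order = rng.permutation(len(inters))
    for k, (state, size) in enumerate(inter_inc_plan):
        i = int(host_order[k % len(inters)])
        _punch(rng, inters[i].blocks, _Block(state, size, inclusion=True),
               "aquamarine", cfg.grid)

    # place along the chromosome
    pos = cfg.margin
    gi = 0
    for k, s in enumerate(structures):
        if k > 0:
            pos += int(boundary_gaps[gi])
            gi += 1
        for b in s.blocks:
            b.start = pos
            pos += b.length
    if pos + cfg.margin > length:
        raise InfeasiblePlanError(f"{chrom}: placed structures overrun the chromosome")
    return structures


def _name_structures(structures: list[_Structure]) -> None:
    nb = ni = 0
    prev_band = None
    for s in structures:
        if s.klass == INTERBAND:
            ni += 1
            s.name = s.name or f"I{ni:03d}"
        else:
            nb += 1
            s.name = s.name or f"B{nb:03d}"
    # interbands between named bands get "left/right" style names
    for k, s in enumerate(structures):
        if s.klass == INTERBAND and 0 < k < len(structures) - 1:
            s.name = f"{structures[k - 1].name}/{structures[k + 1].name}"


def simulate_genome(config: SimConfig) -> SimResult:
    """Generate the state track, genes, anchors and ground truth."""
    rng = _rng(config, 0)
    per_chrom: dict[str, list[_Structure]] = {}
    per_chrom[config.target_chrom] = _plan_chromosome(
        rng, config.target_chrom, config.target_length, config.n_black, config.n_gray,
        config, canonical=True,
    )
    scale = config.rest_length / config.target_length
    per_chrom[config.rest_chrom] = _plan_chromosome(
        rng, config.rest_chrom, config.rest_length,
        max(1, round(config.n_black * scale)), max(2, round(config.n_gray * scale)),
        config, canonical=False,
    )
    for structures in per_chrom.values():
        _name_structures(structures)

    frag_rows, struct_rows, inc_rows = [], [], []
    composition: dict[str, dict[str, int]] = {}
    for chrom, structures in per_chrom.items():
        comp = {s: 0 for s in STATES + (GAP,)}
        length = config.target_length if chrom == config.target_chrom else config.rest_length
        for s in structures:
            for b in s.blocks:
                frag_rows.append((chrom, b.start, b.end, b.state))
                comp[b.state] += b.length
                if b.inclusion:
                    inc_rows.append((s.name, s.klass, b.state, chrom, b.start, b.end))
            struct_rows.append((s.name, s.klass, chrom, s.start, s.end))
        comp[GAP] += length - sum(comp.values())  # unlabeled space counts as gap
        composition[chrom] = comp

    fragments = pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "state"])
    fragments = fragments.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    structures_df = pd.DataFrame(struct_rows, columns=["name", "klass", "chrom", "start", "end"])
    inclusions_df = pd.DataFrame(
        inc_rows, columns=["host", "host_klass", "state", "chrom", "start", "end"])
    space = ChromosomeSpace(
        {config.target_chrom: config.target_length, config.rest_chrom: config.rest_length},
        config.target_chrom,
    )

    genes, gene_classes = _simulate_genes(config, per_chrom)
    anchors = pd.DataFrame(
        {
            "chrom": structures_df["chrom"],
            "pos": (structures_df["start"] + structures_df["end"]) // 2,
            "name": structures_df["name"],
        }
    )
    truth = GroundTruth(structures_df, inclusions_df, composition, gene_classes)
    return SimResult(config, space, fragments, genes, anchors, truth, per_chrom)


def _simulate_genes(config: SimConfig, per_chrom) -> tuple[list, dict]:
    rng = _rng(config, 1)
    genes: list[GeneModel] = []
    gene_classes: dict[str, str] = {}
    tw = np.asarray(config.transcript_count_weights)
    tw = tw / tw.sum()

    def n_tx() -> int:
        return int(rng.choice(np.arange(1, len(tw) + 1), p=tw))

    def breadth(klass: str) -> int:
        mu, sd = config.breadth_means[klass], config.breadth_sds[klass]
        return int(np.clip(round(rng.normal(mu, sd)), 0, config.breadth_max))

    def add(gid, chrom, start, end, strand, klass, length_cap):
        start, end = max(0, start), min(length_cap, end)
        g = GeneModel(gid, chrom, start, end, strand, n_tx(), breadth(klass))
        genes.append(g)
        gene_classes[gid] = klass

    gid_counter = 0
    for chrom, structures in per_chrom.items():
        length = (config.target_length if chrom == config.target_chrom
                  else config.rest_length)
        inters = [s for s in structures if s.klass == INTERBAND]
        whole_hosts = set(
            rng.choice(len(inters), min(config.n_whole_gene_interbands, len(inters)),
                       replace=False).tolist()
        ) if inters else set()
        for idx, s in enumerate(inters):
            aqua = [b for b in s.blocks if b.state == "aquamarine" and not b.inclusion]
            spots = [int(b.start + rng.integers(0, b.length)) for b in aqua for _ in (0, 1)]
            rng.shuffle(spots)
            glo, ghi = config.gene_length_range
            if rng.random() < config.head_to_head_prob and len(spots) >= 2:
                t1, t2 = sorted(spots[:2])
                if t2 - t1 < 2:
                    t2 = t1 + 2
                gid_counter += 1
                add(f"g{gid_counter:04d}", chrom, t1 + 1 - int(rng.integers(glo, ghi)),
                    t1 + 1, "-", INTERBAND, length)
                gid_counter += 1
                add(f"g{gid_counter:04d}", chrom, t2, t2 + int(rng.integers(glo, ghi)),
                    "+", INTERBAND, length)
            else:
                t = spots[0]
                gid_counter += 1
                if rng.random() < 0.5:
                    add(f"g{gid_counter:04d}", chrom, t, t + int(rng.integers(glo, ghi)),
                        "+", INTERBAND, length)
                else:
                    add(f"g{gid_counter:04d}", chrom, t + 1 - int(rng.integers(glo, ghi)),
                        t + 1, "-", INTERBAND, length)
            if idx in whole_hosts:
                big = max(aqua, key=lambda b: b.length)
                wlo, whi = config.whole_gene_length_range
                glen = min(int(rng.integers(wlo, whi)), big.length - 2)
                if glen >= 200:
                    off = int(rng.integers(0, big.length - glen))
                    gid_counter += 1
                    add(f"g{gid_counter:04d}", chrom, big.start + off, big.start + off + glen,
                        rng.choice(["+", "-"]), INTERBAND, length)
        # genes starting inside band aquamarine inclusions
        incl = [(s, b) for s in structures if s.klass != INTERBAND
                for b in s.blocks if b.inclusion and b.state == "aquamarine"]
        scale = len(structures) / (2 * (config.n_black + config.n_gray) - 1)
        want = max(1, round(config.n_band_start_genes * scale))
        if incl:
            picks = rng.choice(len(incl), min(want, len(incl)), replace=False)
            blo, bhi = config.band_gene_length_range
            for i in picks:
                s, b = incl[int(i)]
                t = int(b.start + rng.integers(0, b.length))
                gid_counter += 1
                strand = rng.choice(["+", "-"])
                glen = int(rng.integers(blo, bhi))
                if strand == "+":
                    add(f"g{gid_counter:04d}", chrom, t, t + glen, "+", s.klass, length)
                else:
                    add(f"g{gid_counter:04d}", chrom, t + 1 - glen, t + 1, "-", s.klass, length)
    return sorted(genes, key=lambda g: (g.chrom, g.start)), gene_classes


# ---------------------------------------------------------------------------
# Feature simulation

@dataclasses.dataclass
class FeatureResult:
    points: dict[str, pd.DataFrame]     # label -> chrom/pos
    intervals: dict[str, pd.DataFrame]  # label -> chrom/start/end
    signals: dict[str, pd.DataFrame]    # label -> chrom/start/end/value

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for label, df in self.points.items():
            write_points_bed(df, os.path.join(outdir, f"{label}.bed"))
        for label, df in self.intervals.items():
            df[["chrom", "start", "end"]].to_csv(
                os.path.join(outdir, f"{label}.bed"), sep="\t", header=False, index=False)
        for label, df in self.signals.items():
            write_bedgraph(df, os.path.join(outdir, f"{label}.bedgraph"))


def _tss_boundary(g: GeneModel) -> int:
    """Coordinate of the transcription-start boundary (bin origin)."""
    return g.start if g.strand == "+" else g.end


def simulate_features(config: SimConfig, genome: SimResult) -> FeatureResult:
    """Generate point/interval features and the step signal for *genome*."""
    tchrom, tlen = config.target_chrom, config.target_length
    tss_genes = genome.interband_genes(tchrom)
    if not tss_genes:
        raise ParameterError("genome has no interband-start genes on the target chromosome")

    points: dict[str, pd.DataFrame] = {}
    intervals: dict[str, pd.DataFrame] = {}

    # P-element-like insertion sites: TSS-window placement + uniform background
    rng = _rng(config, 2)
    pos = []
    for _ in range(config.n_p_elements):
        if rng.random() < config.p_element_tss_frac:
            g = tss_genes[int(rng.integers(len(tss_genes)))]
            p = _tss_boundary(g) + int(rng.integers(-config.tss_window, config.tss_window))
        else:
            p = int(rng.integers(0, tlen))
        pos.append(int(np.clip(p, 0, tlen - 1)))
    points["p_element"] = pd.DataFrame({"chrom": tchrom, "pos": sorted(pos)})

    # DHS-like sites: within the upstream window of interband gene starts
    rng = _rng(config, 3)
    pos = []
    for _ in range(config.n_dhs):
        if rng.random() < config.dhs_background_frac:
            p = int(rng.integers(0, tlen))
        else:
            g = tss_genes[int(rng.integers(len(tss_genes)))]
            off = int(rng.integers(1, config.dhs_upstream_window + 1))
            b = _tss_boundary(g)
            p = b - off if g.strand == "+" else b + off - 1
        pos.append(int(np.clip(p, 0, tlen - 1)))
    points["dhs"] = pd.DataFrame({"chrom": tchrom, "pos": sorted(pos)})

    # ORC2-like sites: intervals centred near gene starts
    rng = _rng(config, 4)
    rows = []
    for _ in range(config.n_orc2):
        w = int(rng.integers(*config.orc2_width_range))
        if rng.random() < config.orc2_background_frac:
            c = int(rng.integers(w, tlen - w))
        else:
            g = tss_genes[int(rng.integers(len(tss_genes)))]
            off = np.clip(rng.normal(0, config.orc2_center_sd),
                          -config.orc2_center_max, config.orc2_center_max)
            c = _tss_boundary(g) + int(round(off))
        s = max(0, c - w // 2)
        rows.append((tchrom, s, min(tlen, s + w)))
    intervals["orc2"] = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    # TE remnants: confined to band states on the target chromosome
    rng = _rng(config, 5)
    band_blocks = [
        b for s in genome._structures[tchrom] if s.klass != INTERBAND
        for b in s.blocks if b.state in ("lazurite", "malachite", "ruby")
    ]
    weights = np.array([b.length for b in band_blocks], float)
    weights /= weights.sum()
    rows, used = [], []
    attempts = 0
    while len(rows) < config.n_te_remnants and attempts < config.n_te_remnants * 20:
        attempts += 1
        b = band_blocks[int(rng.choice(len(band_blocks), p=weights))]
        size = int(rng.integers(*config.te_size_range))
        if b.length <= size:
            continue
        s = b.start + int(rng.integers(0, b.length - size))
        if any(s < e0 and s + size > s0 for s0, e0 in used):
            continue
        used.append((s, s + size))
        rows.append((tchrom, s, s + size))
    intervals["te_1360"] = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    # HP1a/POF-like coverage: per-block planted coverage fractions
    for stream, label, mult in ((6, "hp1a", config.hp1a_multiplier),
                                (7, "pof", config.pof_multiplier)):
        rng = _rng(config, stream)
        rows = []
        conc = config.coverage_concentration
        for chrom, structures in genome._structures.items():
            for s in structures:
                for b in s.blocks:
                    if b.state == GAP:
                        continue
                    p = config.coverage_base[b.state]
                    if chrom == tchrom and b.state in ("aquamarine", "lazurite"):
                        p = min(p * mult, 0.95)
                    frac = rng.beta(p * conc, (1 - p) * conc)
                    cov = int(round(frac * b.length))
                    if cov < 10:
                        continue
                    k = 1 if b.length < 2_000 or cov < 100 else int(rng.integers(1, 4))
                    seg = np.maximum(1, rng.multinomial(cov - k, np.ones(k) / k) + 1)
                    free = b.length - cov
                    gaps = rng.multinomial(free, np.ones(k + 1) / (k + 1))
                    cursor = b.start
                    for kk in range(k):
                        cursor += int(gaps[kk])
                        rows.append((chrom, cursor, cursor + int(seg[kk])))
                        cursor += int(seg[kk])
        intervals[label] = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start"]).reset_index(drop=True)

    # repressive step signal elevated on ruby
    rng = _rng(config, 8)
    sig_rows = []
    step = config.signal_step
    for chrom, structures in genome._structures.items():
        for s in structures:
            for b in s.blocks:
                if b.state == GAP:
                    continue
                mu = config.signal_ruby_mean if b.state == "ruby" else config.signal_base_mean
                edges = np.arange(b.start, b.end, step)
                vals = rng.normal(mu, config.signal_sd, len(edges))
                for e, v in zip(edges, vals):
                    sig_rows.append((chrom, int(e), int(min(e + step, b.end)), float(v)))
    signals = {
        "h3k27me3": pd.DataFrame(sig_rows, columns=["chrom", "start", "end", "value"])
        .sort_values(["chrom", "start"]).reset_index(drop=True)
    }
    return FeatureResult(points, intervals, signals)
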