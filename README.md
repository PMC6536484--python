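# polyband

Band/interband annotation and genomic-feature statistics for polytene
chromosomes, built around a four-state chromatin track.

## The problem

The polytene chromosomes of *Drosophila* show a reproducible pattern of
alternating structures: decondensed, transcription-associated **interbands**,
moderately compact **gray bands**, and dense **black bands**.  A
four-chromatin-state model classifies the genome at 200-bp resolution into
*aquamarine* (open, interband-like), *lazurite* and *malachite*
(intermediate, gray-band-like) and *ruby* (dense, black-band-like) states,
with *gaps* where no call is made.  Projecting that track onto morphological
structures makes it possible to ask, in genomic coordinates, what bands and
interbands actually contain: gene 5′ ends, replication-origin (ORC2) sites,
DNase I hypersensitive sites, transposon insertions, HP1a/POF binding,
repressive histone marks.

`polyband` is a reusable implementation of that analysis chain for anyone
studying chromosome-scale chromatin organisation:

1. **smooth** — merge same-state fragments across model gaps of ≤ 400 bp
   into chromatin domains;
2. **segment** — partition domains into strictly alternating interbands
   (aquamarine runs ≥ 4 kb, allowed to bridge sub-5-kb foreign inclusions)
   and bands (black when they carry ≥ 5 kb of ruby, else gray);
3. **measure** — state composition, inclusion census, gene content,
   feature densities in pcs/kb, overlap percentages, TSS-anchored 200-bp
   binned profiles normalised by transcript count, per-domain signal
   medians, and per-state coverage enrichment via the two-sided unpaired
   Wilcoxon (Mann–Whitney) test of a target chromosome against the rest of
   the genome (α = 0.001).

A first-class synthetic-genome generator (`polyband.simulate`) produces
complete inputs — state track, GFF3 genes, feature BEDs, bedGraph signal —
with ground truth, emulating the organisation of the *Drosophila* dot
(fourth) chromosome arm: 11 black + 16 gray bands with the 26 interbands
between them, housekeeping genes starting in interbands (often
head-to-head), open-chromatin features clustered within a few hundred bp of
those gene starts, HP1a/POF-like coverage doubled on the target chromosome's
aquamarine+lazurite only, and TE remnants confined to band states.

## The statistics at the core

For a feature *F* and chromatin state *k*, the enrichment test compares the
samples of per-domain coverage proportions

&nbsp;&nbsp;&nbsp;&nbsp;A = { |F ∩ d| / |d| : d a state-*k* domain on the target chromosome },&nbsp;
B = { same on all other chromosomes }

with the two-sided unpaired rank-sum test (exact enumeration when both
n ≤ 10, tie-corrected normal approximation otherwise); a row is *enriched*
when p < α and median(A) > median(B).

The TSS profile lays out bins of 200 bp from each in-scope gene's 5′ start:
s1…s5 away from the gene (s1 adjacent to the start) and g1…g5 into the
body, mirrored on the − strand.  Each feature in a bin contributes
1/(number of transcripts of that gene); a feature in the shared spacer of
two head-to-head genes is credited to both.

## Worked example

```python
import polyband as pb
from polyband import feature_stats as fs

cfg = pb.SimConfig(seed=1)
genome = pb.simulate_genome(cfg)
features = pb.simulate_features(cfg, genome)

domains = genome.domains()                      # 400-bp gap smoothing
target = domains[domains.chrom == "chr4"].reset_index(drop=True)
structures = pb.segment(target)                 # bands + interbands

enrich = fs.wilcoxon_enrichment({"hp1a": features.intervals["hp1a"]},
                                domains, genome.space)
print(enrich[["state", "median_target", "median_rest", "p_value", "verdict"]]
      .to_string(index=False))
```

prints

```
     state  median_target  median_rest      p_value  verdict
aquamarine       0.491161     0.237903 2.645086e-32 enriched
  lazurite       0.501207     0.243633 3.373487e-38 enriched
 malachite       0.184000     0.195000 8.615928e-01       ns
      ruby       0.061031     0.050330 8.893114e-01       ns
```

— the HP1a-like coverage planted at twice the baseline on the target
chromosome's aquamarine and lazurite is recovered in exactly those two
states (median coverage ≈ 0.49 vs ≈ 0.24 genome-wide) and nowhere else.
Segmenting this genome yields 11 black bands, 16 gray bands and 26
interbands at exactly the planted boundaries, and the DHS-like profile over
interband gene starts peaks in bin s1 (151.8 transcript-normalised counts
vs ≤ 29.2 in every other bin), the upstream window where those sites were
planted.

The same stages are available from a shell:

```sh
polyband simulate --seed 1 --out sim/
polyband run --track sim/state_track.bed --chrom-sizes sim/chrom_sizes.tsv \
    --target chr4 --genes sim/genes.gff3 --anchors sim/anchors.tsv \
    --interval-bed sim/features/hp1a.bed --signal sim/features/h3k27me3.bedgraph \
    --out run/
```

which writes per-stage TSVs plus `report.json` / `report.md`.

## Layout

| module | contents |
| --- | --- |
| `polyband.intervals` | 0-based half-open interval algebra, BED I/O, chromosome space |
| `polyband.state_track` | four-state track reading, gap smoothing, composition |
| `polyband.structures` | band/interband segmentation, inclusions, gene content, anchors |
| `polyband.feature_stats` | densities, overlaps, TSS profiles, rank-sum enrichment, signal medians |
| `polyband.stats` | exact + asymptotic two-sided rank-sum test |
| `polyband.simulate` | synthetic genome/feature generator with ground truth |
| `polyband.pipeline`, `polyband.cli` | end-to-end runner, report, `polyband` command |

See `docs/methods.md` for the model, parameter defaults and design notes.
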