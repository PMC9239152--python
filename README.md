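# multihic

Analytics for the organization of multipartite bacterial genomes: Hi-C
contact-map construction and iterative normalization, region-based
interreplicon interaction quantification with background subtraction,
ChIP/input enrichment tracks, and single-cell origin-focus statistics —
plus a synthetic-data generator so the whole pipeline can be exercised and
validated without external datasets.

The coordinate system models a four-replicon genome (circular Ch1,
2,841 kb; linear Ch2, 2,076 kb; plasmids pAt, 542 kb and pTi, 216 kb) at
10-kb bins, with Ch1 rotated so that position 1,400,001 becomes bin 1 and
its replication origin sits near the centre of its bin range.

## Library overview

| module | contents |
| --- | --- |
| `multihic.genome_model` | replicon specs, global 1-based binning, Ch1 rotation |
| `multihic.synthetic_data` | contact maps / contact records / ChIP tracks / focus tables |
| `multihic.hic_pipeline` | pair filtering, binning, iterative matrix balancing |
| `multihic.interaction_quant` | origin-origin rectangle and chromosome-alignment parallelogram scores, background-subtracted percentages |
| `multihic.chip_quant` | ChIP/input enrichment, binning, above-baseline peak scores |
| `multihic.foci_analysis` | colocalization (< 6 px, strict), pole distances, focus-count tables |
| `multihic.cli_io` | matrix / bedGraph / pair / focus-table / layout IO, end-to-end synthetic workflow |

Key conventions:

* coordinates and bins are 1-based, bins inclusive of a partial final bin;
* contact matrices are symmetric; each contact adds 1 to both `m[i,j]` and
  `m[j,i]` (2 on the diagonal);
* balancing repeats `m_ij <- m_ij * T / (R_i * R_j)` per sweep until the
  maximum relative marginal error is below 1e-5, then rescales so rows and
  columns sum to 1; zero-marginal bins are masked;
* region scores are doubled to count the mirrored region across the main
  diagonal; mutant percentages are `100 * (S - S_bg) / (S_wt - S_bg)`;
* bedGraph files are 0-based half-open externally and converted once at the
  IO boundary.

## Command line

```sh
multihic simulate map   --seed 1 --noise-pairs 500000 --out wt.mat
multihic simulate pairs --seed 1 --n-pairs 100000 --out pairs.tsv
multihic simulate chip  --seed 1 --peak Ch2:965000:200:500 \
    --out-chip chip.bg --out-input input.bg
multihic simulate foci  --seed 1 --n-cells 1000 --out foci.tsv

multihic hic pairs.tsv --out norm.mat            # bin + balance
multihic quantify wt.mat bg.mat mutant.mat        # percent of WT
multihic chip chip.bg input.bg --bin-size 1000 --window Ch2:960000:970000
multihic foci foci.tsv --threshold 6
multihic reproduce-synthetic --seed 1             # full check report
```

A custom genome is supplied with `--layout layout.yaml`:

```yaml
bin_size: 10000
ch1_start_offset: 1400000
replicons:
  - {name: Ch1, length: 2841000, topology: circular, origin: 2825000}
  - {name: Ch2, length: 2076000, topology: linear,   origin: 965000}
  - {name: pAt, length: 542000,  topology: circular, origin: 271000}
  - {name: pTi, length: 216000,  topology: circular, origin: 108000}
```

## Preparing real focus tables

Focus tables are consumed as TSV (`cell_id, pole_ax, pole_ay, pole_bx,
pole_by, length_px, width_px, channel, focus_x, focus_y`, one focus per
row). Cell outlines and spots are expected from external segmentation
software such as Oufti (cellDetection + spotDetection). Settings used for
data of this kind: pre-Gaussian wavelet scale 0, low pass 2, spot radius 2,
intensity threshold 0.4, min region size 4, fit radius 2; post-Gaussian
minHeight 0, minWidth 1.9, maxWidth 10, adjusted squared error 0; followed
by manual inspection of meshes. All distances in the tables are pixels.

## Scope notes

Read alignment, restriction-fragment ligation classification (beyond a
simplified same-fragment filter), peak calling, and cell segmentation are
out of scope; the pipeline starts from contact records / coverage tracks /
focus tables.
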