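# erclust

Bin-based enrichment-region calling and clustering for ChIP-seq, with
ranking, evaluation, bivalent-domain integration and CRISPR-screen gene
prioritization — exercised end-to-end on a bundled read simulator, so no
external data is needed.

## Method sketch

Mapped reads are strand-shifted (the shift is estimated by maximizing the
proportion of short inter-read gaps) and every gap between neighboring
shifted reads becomes a **bin**, the atomic unit of the caller:

1. **ERs (enriched regions)** — a 20-bin window slides along each
   chromosome, is shrunk from the 5' side into 3'-anchored step windows,
   and step windows containing an over-long bin are excluded.  The most
   significant step window (upper-tail Poisson against
   `max(d_genome*l, R_control*SF)`) is the final window; final-window
   p-values are Benjamini–Yekutieli adjusted genome-wide and significant
   windows are merged into ERs.  The bin-length ceiling is trained on
   chr1–chr5 by sweeping `0.2*shift .. 2*shift` until 80% of merged windows
   are longer than `2*shift`.
2. **SERs (short-ER clusters)** — triggered when FR-D (fraction of
   neighboring ER pairs whose gap is below half of either ER's length)
   exceeds 1%.  Candidate connecting lengths come from percentiles of
   neighbor gaps of coordinate-shuffled ERs (PDNP, 1st–10th, < 10 kb);
   each candidate re-runs the window caller with `x =
   min(max(floor(l*d*5), 20), 500)` bins and merged windows are trimmed to
   the shortest region covering their member ERs.  The first candidate
   bringing FR-D below 1% wins.
3. **LERs (long-ER clusters / broad signals)** — triggered when FR-RE
   (fraction of neighboring-ER covering regions with reads enrichment
   RE > 1.5) exceeds 1%; candidates are the 5th–50th PDNP percentiles
   (< 100 kb) and the largest candidate keeping the member-gap FR-RE at or
   above 99% wins.  A matched mode picks instead the LER set whose length
   distribution is closest (CDF-area distance) to a reference set.

On top of the callers: rank-sum ranking of ERs (q-value + summit height),
SERs (read count) and LERs (fold-change + length); reliability curves of
ranked ERs against motif hits with area-ratio verdicts; gene association
rules (1 kb for SERs, 80% coverage for LERs, 10 kb for TF clusters); the
bivalent candidate-gene filter; and rank-shift gene scoring of
negative-selection CRISPR screens against a non-targeting control pool,
with one-sided KS enrichment.

## CLI

```sh
# make a synthetic dataset with known truth (5 x 2 Mb chromosomes)
erclust simulate --out-dir sim --seed 1 --n-peaks 300 --case-reads 400000

# full pipeline: shift estimation, ERs, SERs, LERs
erclust call --case sim/case.bed --control sim/control.bed \
    --genome sim/genome.chrom.sizes --seed 1 --out-dir out

# individual stages / diagnostics
erclust shift --case sim/case.bed --genome sim/genome.chrom.sizes
erclust call-ers ... ; erclust call-sers ... ; erclust call-lers ...
erclust diagnose ...          # FR-D / FR-RE vs connecting-length tables
erclust rank --ers-bed out/ers.bed ...
erclust evaluate --ranked ranked.tsv --motifs motifs.bed
erclust integrate --h3k4me3-sers ... --h3k27me3-lers ... \
    --nanog-lers ... --oct4-lers ... --genes genes.bed
erclust screen-rank --counts sgrna_counts.tsv --candidates genes.txt
```

Outputs are BED6+ tables (ERs with summit offset, p/q/fold-change; SER/LER
with member lists and the clustering statistic) plus a JSON manifest.

## Layout

- `src/erclust/reads_io.py` — reads, shifting, bins, short-bin statistic
- `src/erclust/window_engine.py` — windows, Poisson testing, ER calling
- `src/erclust/cluster_ser.py` / `cluster_ler.py` — SER/LER clustering
- `src/erclust/rank_integrate.py` — ranking, evaluation, integration
- `src/erclust/screen_prioritize.py` — CRISPR screen gene ranking
- `src/erclust/synthetic_data.py` — seeded simulator with truth intervals
- `src/erclust/cli.py` — `erclust` command-line entry points
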