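# inlinebc

Toolkit for **dual in-line barcoded amplicon sequencing**: demultiplexing,
barcode-recovery statistics, diversity metrics and data-driven selection
of an optimal 96-pair barcode panel.

In an in-line design every read carries its sample tag inside the
sequence itself — a 5-bp leader (`GCATC`), an 8-bp barcode, then the
16S-binding primer and the amplicon, on both mates (forward barcode on
read 1, reverse on read 2). Samples are labelled by *pairs* of barcodes,
so `f` forward and `r` reverse barcoded primers distinguish `f × r`
samples: a full 96-well plate needs only 8 + 12 = 20 unique primers.
This package is for groups running or evaluating such workflows — it
answers, with ground-truth simulations where real data is not needed:
how many reads survive demultiplexing at each error tolerance, whether
any barcode biases recovery or measured community structure, and which
plate grid of barcode pairs behaves most consistently.

## What it computes

* **Demultiplexing** — anchored exact leader match, then nearest-barcode
  assignment under a substitution budget (Hamming) or separate
  substitution/indel budgets (bounded unit-cost alignment); distance
  ties are called `unknown`, never guessed. Stringency modes `0err`,
  `1err`, `1err+indel`, `2err`, `2err+indel`.
* **Recovery** — observed read shares per barcode/pair vs the uniform
  expectation 1/N (8.33% per reverse barcode of 12; 1/136 per bacterial
  pair), unknowns included in the denominator; mean ± SD across samples.
* **Diversity** — Hill numbers `D_q = (Σ pᵢ^q)^{1/(1−q)}` for
  q = 0, 1, 2 (richness, exp Shannon, inverse Simpson), Pielou's
  `J = H/ln S`, Hill evenness `Eq = D_q/D_0`, seeded rarefaction,
  Bray-Curtis `Σ|x−y|/Σ(x+y)` and classical PCoA.
* **Panel selection** — per-sample z-score → PCA (≥90% variance, ≤3
  axes) → k-means (k = 2); co-clustering frequencies across samples;
  average-linkage metaclustering of `1 − frequency`; exact search for
  the plate grid `F′ × R′` maximizing membership in the best
  metacluster while minimizing unique primers.
* **Simulation** — paired reads with the exact construct layout, per-base
  substitution/indel errors, tag jumping, and planted good/bad
  performance structure, all seed-deterministic with truth tables.

## Worked example

Simulate a 4 × 4 catalogue at realistic error rates (1% substitutions,
0.1% indels on every base of the construct), demultiplex under the full
stringency ladder, and plan a 96-sample plate:

```python
from inlinebc import simulate as sim, demux as dm
from inlinebc.catalogue import min_primer_count

cat = sim.random_catalogue(4, 4, seed=7)
plan = sim.SimulationPlan(
    catalogue=cat, reads_per_pair=2000, seed=7,
    tag_rates=sim.ErrorRates(substitution=0.01, insertion=0.001, deletion=0.001),
)
r1, r2, truth = sim.generate_reads(plan)
reads = [dm.ReadPair(a[0], a[1], a[2], b[1], b[2]) for a, b in zip(r1, r2)]
modes = ["0err", "1err", "1err+indel", "2err", "2err+indel"]
for rep in dm.run_mode_panel(reads, cat, [dm.config_for_mode(m) for m in modes]):
    print(f"{rep.mode:>10}: {rep.assigned_fraction:7.2%} of {rep.total} read pairs assigned")

f, r, total = min_primer_count(96, max_f=8, max_r=17)
print(f"96 samples: {f} forward x {r} reverse = {total} unique primers")
```

prints

```
      0err:  73.04% of 32000 read pairs assigned
      1err:  85.89% of 32000 read pairs assigned
1err+indel:  88.36% of 32000 read pairs assigned
      2err:  86.88% of 32000 read pairs assigned
2err+indel:  88.68% of 32000 read pairs assigned
96 samples: 8 forward x 12 reverse = 20 unique primers
```

Reading it: with errors across a ~33-bp construct, exact matching loses
a quarter of the reads; one tolerated barcode substitution recovers most
of them, and indel tolerance a little more. (`1err+indel` can exceed
`2err` — an indel-carrying read is assignable only by the former; the
guaranteed monotone chains are the nested-budget ones.)

Selecting a 96-pair panel from a 13 × 12 catalogue whose metrics hide a
planted 25% of misbehaving pairs:

```python
from inlinebc.selection import pair_id, select_barcode_panel

big = sim.random_catalogue(13, 12, seed=12)
pids = [pair_id(a, b) for a, b in big.enumerate_pairs()]
tables, labels = sim.planted_metrics(pids, bad_fraction=0.25, effect_size_sd=3.0, seed=1)
res = select_barcode_panel(tables, big, panel_size=96, seed=0)
print(f"selected grid: {len(res.forward_ids)} x {len(res.reverse_ids)} "
      f"({res.n_primers} unique primers)")
print(f"fraction of grid in the best metacluster: {res.score:.3f}")
```

prints

```
selected grid: 12 x 8 (20 unique primers)
fraction of grid in the best metacluster: 0.833
```

— a 12 × 8 grid, again 20 primers; with bad pairs scattered at random no
pure grid can avoid them entirely, and the selector provably maximizes
the well-behaved fraction (here 16 planted bad pairs remain out of 96,
the exhaustive optimum for this instance).

The same steps are available from the shell:

```bash
inlinebc catalogue plan --samples 96
inlinebc simulate reads --reads-per-pair 2000 --sub-rate 0.01 --seed 7 --out-dir sim/
inlinebc demux --r1 sim/reads_R1.fastq.gz --r2 sim/reads_R2.fastq.gz \
    --catalogue sim/catalogue.tsv --modes 0err,1err,1err+indel --out-dir demux/
inlinebc select --metrics s1.tsv s2.tsv s3.tsv --catalogue cat.tsv \
    --panel-size 96 --seed 0 --out-dir panel/
```

## Layout

```
src/inlinebc/
  catalogue.py   barcoded-primer constructs, I/O, separation, primer arithmetic
  demux.py       paired-end demultiplexer, stringency modes, reports, FASTQ I/O
  recovery.py    observed-vs-theoretical recovery summaries
  diversity.py   Hill numbers, evenness, rarefaction, Bray-Curtis, PCoA
  selection.py   co-clustering consensus and plate-grid panel selection
  simulate.py    synthetic reads, mock communities, planted metric tables
  cli.py         the `inlinebc` command-line interface
docs/methods.md  models, defaults and numerical conventions
```
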