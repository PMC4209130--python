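# introndelay

Simulation and analysis of **intron delay** during early *Drosophila*
embryogenesis.

The early fly embryo runs 13 extremely fast synchronous nuclear divisions
(~9 min each at first, lengthening to ~17 min, then a ~60 min 14th-cycle
interphase). At every mitosis, engaged RNA polymerases are stripped from the
condensing chromosomes and their incomplete nascent transcripts are degraded.
A zygotic gene can therefore only make full-length mRNA if its **primary
transcript** (introns included) fits within one interphase: with elongation
rate *v* and interphase duration *T*, the maximum completable length is
*v·T*. Long genes — long mostly because of their introns — are silenced or
rate-capped until the cell cycle slows, while maternally deposited mRNA is
unaffected. This package is for researchers studying zygotic genome
activation and gene-structure evolution who want a tested, reproducible
implementation of the analyses that detect this mechanism, together with a
mechanistic simulator that generates data with known ground truth.

## What it provides

* **`synthetic_data`** — a stochastic simulator of abortive transcription
  under a timed cell-cycle schedule (`simulate_timecourse`), a genome/
  annotation generator (`make_genome`), a strand-aware read sampler for
  poly-A and total-RNA libraries (`sample_reads`, 6-column BED output), and a
  multi-species orthologous-intron evolver (`evolve_orthologous_introns`).
* **`quantify`** — gene-level union-rule read counting (a read counts only if
  it overlaps exactly one gene), RPKM = count / (library/10⁶ × exonic kb),
  and the RPKM > 5 / ≥100-reads filters.
* **`delay_analysis`** — short/long classes at 5 kb, data-driven threshold
  selection, median expression trajectories with bootstrap CIs and OLS fits,
  an ANCOVA-style interaction test for the narrowing long/short gap, and
  2×2 chi-square enrichments (intronless × origin, stability × length).
* **`coverage_analysis`** — 5′→3′ fractional coverage in ten 500-bp windows
  over the first 5 kb of each transcript (exonic bases only), per-class
  median-profile slopes, slope-difference trends over the timecourse, and
  5′:3′ 1-kb RPKM ratios.
* **`conservation_analysis`** — cross-species variability of orthologous
  intron lengths via the corrected coefficient of variation
  **CV\* = (1 + 1/(4n)) × sd/mean**, expression-quartile gene categories, and
  permuted Kruskal–Wallis category comparisons with Bonferroni correction
  (plus the <150-bp mean-length sensitivity re-analysis).
* **`stats_core`** — bootstrap-normal CIs (10,000 resamples), permuted
  Kruskal–Wallis (10,000 permutations, add-one p), 2×2 chi-square, OLS.

See `docs/methods.md` for the model, parameter defaults, and design choices.

## Worked example

Simulate 600 genes (maternal and zygotic, mixed lengths) through the default
syncytial schedule, then ask whether long zygotic genes activate late:

```python
import pandas as pd
from introndelay import (
    make_genome, simulate_timecourse, pools_to_expression,
    assign_length_class, median_trajectory, ancova_interaction,
)
from introndelay.models import CellCycleSchedule, SimulationConfig

genes, classes = make_genome(600, seed=7)
schedule = CellCycleSchedule.drosophila_default()
pools = simulate_timecourse(genes, schedule, SimulationConfig(), seed=8)
expr = pools_to_expression(pools)  # genes x 6 sample times (mRNA counts)

lengths = pd.Series({g.gene_id: g.primary_length for g in genes})
cls = classes.set_index("gene_id").join(
    assign_length_class(lengths)[["length_class"]]
)
traj = median_trajectory(expr, cls, n_boot=2000, seed=9)
for key, fit in sorted(traj.fits.items()):
    print(f"{key[0]:8s} {key[1]:5s} slope={fit.slope:+.3f}  R2={fit.r_squared:.3f}")

med = traj.medians
zyg = med[med.origin == "zygotic"]
short = zyg[zyg.length_class == "short"].sort_values("t_index")["median"].values
long_ = zyg[zyg.length_class == "long"].sort_values("t_index")["median"].values
anc = ancova_interaction(short, long_)
print(f"ANCOVA interaction: F={anc.f_interaction:.1f}, p={anc.p_interaction:.2e}")
```

Output:

```
maternal long  slope=-0.142  R2=0.964
maternal short slope=-0.123  R2=0.998
zygotic  long  slope=+0.814  R2=0.988
zygotic  short slope=+0.378  R2=0.994
ANCOVA interaction: F=153.1, p=2.45e-04
```

Read: median log2 expression of maternal genes declines slowly (deposited
mRNA decaying), both zygotic classes rise, but the long class rises more than
twice as fast as the short class — its expression is released only as
interphases lengthen — and the interaction test confirms the long/short gap
changes over development. That is the intron-delay signature.

There is also a thin CLI over the same functions:

```bash
introndelay simulate --outdir sim --n-genes 300 --seed 1
introndelay quantify --gtf sim/annotation.gtf --beds sim/reads_t0.bed ... --out quant
introndelay delay --matrix quant/rpkm.tsv --classes sim/classes.tsv \
    --lengths sim/lengths.tsv --out delay_out
introndelay coverage --gtf sim/annotation.gtf --beds ... --classes sim/classes.tsv --out cov
introndelay conserve --introns sim/introns.tsv --matrix quant/rpkm.tsv \
    --classes sim/classes.tsv --out cons
```

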