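# tracerflux

Partitioning soil CO₂ efflux among **lignin**, **bulk litter**, and **soil
organic carbon (SOC)** using a position-specific ¹³C tracer, for sealed-jar
incubations and field litterbags.

## The problem

Whether lignin limits litter and soil carbon decomposition is hard to test
because lignin cannot be measured directly in a decomposing soil/litter
mixture. A clean solution is a synthetic lignin labeled with 99 atom% ¹³C at
the Cβ position of each C₉ unit — the propyl-sidechain carbon whose cleavage
is the rate-limiting depolymerization step. Mixing this tracer (with
natural-abundance C₄-grass litter) into mineral soils and following the CO₂
and its δ¹³C lets each carbon source be quantified separately.

`tracerflux` implements that analysis as a tested, reusable pipeline:

1. **isotopes** — exact δ¹³C ↔ atom-fraction conversion and two-source
   mixing, valid from natural abundance to 99 atom% (all mixing is done in
   atom-fraction space, F = ¹³C/(¹²C+¹³C), the linear coordinate);
2. **lab** — sealed-jar headspace CO₂ (ppm, δ¹³C) → interval CO₂-C fluxes by
   the ideal gas law, then per-interval partitioning with the three-treatment
   design (soil-only control; soil+litter+unlabeled lignin;
   soil+litter+¹³Cβ-labeled lignin):
   * f_litter = (F_t2 − F_control)/(F_litter − F_control)
   * Cβ-C = total_t3 · (F_t3 − F_t2)/(F_label − F_t2)

   and accumulation to percent of initial pool C (41.9 mg litter C and
   264 µg Cβ per 1 g soil; 250:25:1 soil:litter:lignin);
3. **field** — litterbag endpoint C and δ¹³C → lignin-Cβ remaining, using
   site-level unlabeled bags as the reference with a new-carbon correction;
4. **ancillary** — net N mineralization, amplicon-table count filters
   (≤900-sequence samples, <10-count ASVs), Chao1-residual richness,
   Hellinger transform;
5. **simulate** — a synthetic-data generator that emulates the full
   experiment with known ground truth, so every stage is validated by
   parameter recovery;
6. **pipeline / cli** — the end-to-end runner, tidy CSV schemas with
   metadata headers, and the recovery report.

## Worked example

Simulate a small noise-free experiment and partition it:

```python
from tracerflux import SimulationConfig, simulate_experiment, lab
from tracerflux.simulate import noise_free

cfg = noise_free(SimulationConfig(seed=11))
headspace, manifest, truth = simulate_experiment(cfg, n_sites=2, n_points=2)
parts = lab.partition_intervals(lab.interval_fluxes(headspace), manifest)
cum = lab.accumulate(parts)
final = cum[cum["checkpoint_day"] == 571]
print(final[["site_id", "point_id", "depth",
             "pct_lignin_cbeta", "pct_litter", "pct_soc"]]
      .round(2).to_string(index=False))
```

```
site_id  point_id depth  pct_lignin_cbeta  pct_litter  pct_soc
    S01         1  0-15             13.79       21.51    83.63
    S01         1 15-30             15.75       18.92    88.97
    S01         3  0-15             10.70       21.44    91.15
    S01         3 15-30             13.58       24.63    84.77
    S02         1  0-15              5.01        4.19     6.64
    S02         1 15-30              3.42        5.02     7.32
    S02         3  0-15              3.16        4.92     7.83
    S02         3 15-30              4.37        5.36     9.17
```

Each row is one soil sample (site × point × depth): the cumulative CO₂-C
attributed to the Cβ tracer, the litter, and the native SOC after 571 days,
as a percent of each pool's initial carbon. With noise switched off these
recover the simulator's ground truth to better than 0.01 percentage points;
at instrument noise (0.2 ‰ on δ¹³C, 1% on CO₂) the estimates stay unbiased.

The same stages are available from the shell:

```sh
tracerflux run-all --seed 7 --out out/            # simulate + analyze + score
tracerflux lab   --headspace out/headspace.csv --manifest out/manifest.csv \
                 --out out/partitions.csv
tracerflux field --bags out/field_bags.csv --manifest out/field_manifest.csv \
                 --out out/field_loss.csv
tracerflux asv-filter --counts out/asv_counts.tsv --out out/filtered.tsv
```

Every output CSV begins with `#`-prefixed metadata (version, seed, R_VPDB,
config hash); `out/recovery_report.csv` scores estimated against true
cumulative percentages per pool and stage.

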