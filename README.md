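# tubeqc

Quality evaluation of citrate anticoagulant evacuated blood-collection
tubes on a purified-water model — for medical laboratories that want
direct insight into the tubes entering their coagulation workflow, and
for producers controlling their filling process.

Citrate concentration in a specimen affects coagulation results, yet
the end user normally has no way to check a tube's anticoagulant
amount, its residual liquid volume (which shrinks on the shelf by
evaporation), or the concentration an actual draw would see. `tubeqc`
implements the desk side of a low-cost UV-spectrometric methodology
that recovers all three from two complementary determinations on
purified water:

* **amount per tube** from a composite extraction of N tubes into a
  flask of volume V_f: `n_ac = c_comp · V_f / N` (μmol);
* **residual anticoagulant volume** from a single tube filled with
  water in the nominal draw volume V_draw, closing the mass balance
  `n_ac = c · (V_draw + V_ac)`, i.e. `V_ac = (n_ac − V_draw·c)/c`;
* **concentration at the nominal total volume**
  `c = n_ac / (V_draw + V_ac_nom)`, compared with the declaration as a
  relative bias against a 10 % tolerance.

Around that core: ordinary-least-squares calibration with the standard
uncertainty of interpolation
`s_x0 = (s_yx/a)·√(1/m + 1/n + (y0−ȳ)²/(a²·Sxx))` combined with the
dilution uncertainty; a standard-additions estimator; water-loss
detection by one-way ANOVA with Fisher's LSD
`t_{1−α/2, h(n−1)}·s·√(2/n)` and a compact-letter display; draw-volume
tolerance checks; and a fully seeded synthetic campaign generator with
known ground truth.

## Worked example

The package bundles the tables of a reference evaluation campaign of
nine tube types from three producers (A, B, C; labels carry the
nominal draw volume in mL and the expiration date). Reproducing the
campaign's verdict table:

```python
from tubeqc import datasets as ds, qc
from tubeqc.io import verdicts_frame

verdicts = qc.qc_report(
    ds.tube_specs(), ds.composite_determinations(), ds.per_tube_determinations()
)
print(verdicts_frame(verdicts)[[
    "label", "amount_per_tube_rounded", "expected_amount_rounded",
    "amount_bias_pct_rounded", "ac_volume_rounded",
    "ac_volume_bias_pct_rounded", "conc_bias_pct_rounded",
    "compliant_amount", "compliant_conc",
]].to_string(index=False))
```

```
       label  amount_per_tube_rounded  expected_amount_rounded  amount_bias_pct_rounded  ac_volume_rounded  ac_volume_bias_pct_rounded  conc_bias_pct_rounded  compliant_amount  compliant_conc
  A_1.8_9.4.                     26.3                     21.8                     20.6              0.134                       -33.1                   24.8             False           False
  A_1.8_9.7.                     26.8                     21.8                     22.9              0.156                       -21.9                   25.7             False           False
 B_1.8_31.7.                     23.6                     21.8                      8.3              0.015                       -92.3                   19.3              True           False
 C_1.8_31.3.                     26.8                     21.8                     22.9              0.011                       -94.6                   35.8             False           False
 C_2.7_31.5.                     38.4                     32.7                     17.4              0.166                       -44.8                   22.9             False           False
 B_3.6_31.8.                     56.3                     51.6                      9.1              0.337                       -15.7                   10.9              True           False
 C_4.5_31.7.                     55.0                     52.5                      4.8              0.045                       -90.9                   15.2              True           False
C_4.5_31.12.                     56.1                     52.5                      6.9              0.136                       -72.7                   15.2              True           False
 C_4.5_30.6.                     66.6                     64.5                      3.3              0.223                       -55.3                    9.3              True            True
```

Reading the first row: type A_1.8_9.4. was dosed with 26.3 μmol of
citrate against a declared 21.8 μmol (bias +20.6 %, over tolerance);
at examination only 0.134 mL of the nominal 0.2 mL of solution remained
(−33.1 %, evaporation); and the concentration a nominal draw would see
exceeds the declaration by 24.8 %. Only C_4.5_30.6. is compliant in
both amount and concentration. (Derived values recomputed from inputs
reported at printed precision can differ from the campaign's own
unrounded intermediates in the last digit, e.g. 9.1 vs 9.0.)

Water-loss testing on the bundled weighing summaries:

```python
from tubeqc import stability as st
groups = [st.GroupSummary(r.date, r.count, r.sum, r.mean, r.variance)
          for r in ds.mass_summaries().query("tube_type == 'B_1.8_31.7.'").itertuples()]
res = st.anova_from_summaries(groups)
print(f"F = {res.f_statistic:.2f} (crit {res.f_critical:.2f}), LSD = {res.lsd:.5f} g")
print(res.letters)
```

```
F = 50.93 (crit 2.39), LSD = 0.01916 g
{'25.02.': 'a', '11.03.': 'b', '06.04.': 'b', '5.05.': 'c', '16.06.': 'd', '7.07.': 'd'}
```

Time is a highly significant factor (the tube type loses water);
weighing dates sharing a letter do not differ by more than the LSD.

## Command line

```sh
tubeqc simulate --seed 7 --out-dir demo/      # synthetic campaign + ground truth
tubeqc calibrate --in demo/calibration_points.csv --out fit.json
tubeqc quantify  --fit fit.json --in absorbances.csv --out conc.csv
tubeqc qc        --meta demo/tubes_meta.csv --det demo/determinations.csv --out report.csv
tubeqc stability --masses demo/masses.csv --out stability.json
tubeqc drawvol   --in demo/draw_volumes.csv --meta demo/tubes_meta.csv
```

All tables are comma-separated, dot-decimal, UTF-8 with ISO 8601
dates. Exit codes: 0 success, 2 validation error, 3 computation
degeneracy.

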