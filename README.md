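# letdamage

Analytical LET-dependent DNA damage yield models for fully stripped light
ions (H, He, Li, Be, B, C, N, O, Ne), acting as a fast surrogate for
detailed track-structure simulations. The package ships:

- **Parameter database** (`letdamage.params`): 135 fitted parameter sets —
  one per (ion, damage class, effect channel) — for five damage classes
  (strand breakage SB, single-strand breaks SSB, double-strand breaks DSB,
  DSB clusters, DSB sites) and three channels (total, direct, indirect),
  with CSV/JSON serialization and structural validation (completeness,
  universal low-LET yields, positivity).
- **Yield models** (`letdamage.models`): the two analytical forms
  (decreasing power law with a log-Gaussian dip for SB/SSB; increasing
  power law with a logistic overkill denominator for the DSB family),
  low-LET limits, peak finding, yield tables, RBE against a low-LET
  hydrogen reference, and per-cell damage counts (6.6 Gbp genome).
- **Mixed fields** (`letdamage.mixed`): dose-weighted yield and RBE for
  arbitrary (ion, LET, dose) compositions, with an additivity warning
  above 100 Gy.
- **Fitting** (`letdamage.fitting`): the constrained protocol that produced
  the database — p1 fixed and universal, p2…p5 fitted per ion by relative
  least squares with seeded multistart — plus a grid-scan surrogate for the
  universal-p1 adjustment, nested-model term selection, and a synthetic
  noisy-yield generator for parameter-recovery studies.
- **Break classification** (`letdamage.breaks`): direct/indirect break
  induction probabilities (linear 5–37.5 eV ramp; 0.65 per ·OH attack),
  a Bernoulli break sampler, and the SSB/DSB/cluster/site classifier
  (opposite strands within 10 bp → DSB; DSB within 25 bp → cluster) with a
  clustered-pattern generator for testing.

Units are fixed throughout: LET in keV/µm, yields in Gy⁻¹ Gbp⁻¹, dose in Gy.
The models interpolate the fitted LET ranges; evaluations outside a
per-ion validity window are flagged, not rejected, and the low-energy
"hook" region below ~1 MeV/u is deliberately not modelled.

## Library quick start

```python
import letdamage as ld

db = ld.load_params()                      # built-in table, 135 entries
p = db.get("C", "DSB_SITE", "TOTAL")
ld.evaluate(p, 150.0).value                # 14.61 Gy^-1 Gbp^-1
ld.rbe(db, ld.make_spec("C", "DSB"), 150)  # 2.29 vs low-LET hydrogen
ld.peak_yield(p, ld.ValidityWindow(1, 300))
ld.per_cell_yield(6.8, dose_gy=1.0)        # 44.88 DSB per cell

field = [ld.MixedFieldComponent(ld.get_ion("H"), 10, 1.0),
         ld.MixedFieldComponent(ld.get_ion("C"), 150, 1.0)]
ld.mixed_yield(db, field, "DSB")
```

## CLI

`letdamage` exposes one entry point with subcommands:

```sh
letdamage evaluate --ion H --class dsb --channel total --let 10   # 8.589
letdamage rbe --ion C --class dsb --let 150                       # 2.291
letdamage table --lets 0.3:600:log:50 --classes dsb,dsb_cluster --out table.tsv
letdamage mixedfield --in field.csv --classes dsb,dsb_site --out result.tsv
letdamage fit --in data.tsv --class dsb --fix-p1 6.8 --out params.csv
letdamage simulate-yields --ion H --class dsb --lets 0.3:40:log:11 --cv 0.015 --seed 1 --out data.tsv
letdamage simulate-breaks --tracks 50 --scale 2 --seed 3 --out breaks.tsv
letdamage classify --in breaks.tsv --dsb-bp 10 --cluster-bp 25
letdamage validate-db --params my_params.csv
```

Exit codes: 0 success, 2 usage, 3 I/O, 4 validation, 5 non-convergence.
Tabular outputs carry `#` header comments with version, seed and parameter
provenance; identical arguments and seed give byte-identical files.

### File schemas

- Parameters (CSV): `damage_class,ion,channel,p1,p2,p3,p4,p5`; omitted
  terms as the literal `NA` (never 0). JSON: array of objects, same keys.
- Yield data (TSV): `ion, let_kev_um, yield_per_gy_gbp[, cv]`.
- Mixed field (CSV): `ion, let_kev_um, dose_gy`.
- Break lists (TSV): `position_bp, strand, mechanism`.

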