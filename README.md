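# fermpipe

Constraint-based simulation of single- and serial two-step fermentations.

Organism metabolic models (SBML level 3 + FBC, or a small tabular TSV
dialect) are wrapped in a five-chamber envelope — **Media**, **Internal**,
**Growth**, **Product**, **Waste** — connected only by generated,
unidirectional transporter reactions. The wrapped system is evaluated with
FBA (maximal growth) and FVA (min/max product flux at the growth optimum)
to predict product yields as percent of input media mass. Media is dosed on
a 1 gDW·gDW⁻¹·h⁻¹ basis: each feed flux is fixed to the molar equivalent of
a compound's mass fraction (mg per gDW of media).

On top of the core simulator sit:

* **serial two-step runs** — organism 1 ferments the feedstock; residual
  media plus transferable secreted by-products (product harvested,
  volatiles dropped) feed organism 2; yields are accounted against the
  original input mass,
* **media sensitivity analysis** — relative yield after nullifying each
  media compound's feed,
* **media gradient analysis** — finite-difference yield change per +1 mg
  of each compound,
* **knockout screening** — exhaustive (choice-in-organism-1,
  choice-in-organism-2) single-reaction knockout scans, reported in % of
  wild type,
* **campaign planning** — (single pipes + ordered distinct organism pairs)
  × media × targets × oxygen conditions,
* **a local resumable task runner** — deterministic task ids, checkpointed
  restarts, byte-identical output regardless of worker count.

LPs are solved with scipy's HiGHS backend behind a single solve-LP
contract; the test suite cross-checks every optimum against an
independently formulated cobrapy/GLPK solve.

## CLI

A toy suite (two mass-balanced organisms, media, registries) ships with the
package and exercises every feature without any download:

```bash
fermpipe fixtures --dir fixtures/
echo '{"etoh": 46, "co2": 44, "glc": 180, "xyl": 150}' > fixtures/weights.json

# single-step fermentation of 1 g glucose to ethanol
fermpipe simulate --model fixtures/TOY-A.tsv --registry fixtures/registry_TOY-A.csv \
    --media fixtures/m1.csv --target etoh --oxygen anaerobic \
    --weights fixtures/weights.json

# serial two-step run, then an exhaustive knockout scan on 4 workers
fermpipe two-step --model fixtures/TOY-A.tsv --model fixtures/TOY-B.tsv \
    --registry fixtures/registry_TOY-A.csv --registry fixtures/registry_TOY-B.csv \
    --media fixtures/m2.csv --target etoh --weights fixtures/weights.json
fermpipe --workers 4 knockout-scan --model fixtures/TOY-A.tsv --model fixtures/TOY-B.tsv \
    --registry fixtures/registry_TOY-A.csv --registry fixtures/registry_TOY-B.csv \
    --media fixtures/m2.csv --target etoh --weights fixtures/weights.json

# sensitivity / gradient analyses and campaign dry-run planning
fermpipe sensitivity --model fixtures/TOY-A.tsv --registry fixtures/registry_TOY-A.csv \
    --media fixtures/m1.csv --target etoh --weights fixtures/weights.json
fermpipe gradient --model fixtures/TOY-A.tsv --registry fixtures/registry_TOY-A.csv \
    --media fixtures/m1.csv --target etoh --weights fixtures/weights.json
fermpipe plan --media 3 --targets 5 --organisms 4 --conditions 2
```

All outputs are CSV; `--out-dir`, `--workers`, `--seed` and `--log-level`
are global options.

## File formats

* **Tabular models** — TSV with `reaction_id`, `equation`
  (e.g. `1 glc -> 2 etoh + 2 co2`; fractions like `5/3` allowed), `lb`,
  `ub`; header directives `#growth=<reaction_id>` and optional
  `#excretable=<met,met,...>`. Missing bounds default to ±1000.
* **Media CSV** — `compound_id, mass_mg_per_gDW,
  molecular_weight_g_per_mol, transferable`.
* **Registry CSV** — `canonical_id, model_id, model_metabolite_id`; maps
  canonical media/product compounds onto each model's metabolite namespace.
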