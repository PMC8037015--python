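# hbttc

One Health screening thresholds for organic chemicals in freshwater.

The package derives a single water concentration protective of both
ecological receptors and humans who drink water abstracted from the same
body, by running two branches and taking their minimum:

- **Ecological branch** — aquatic toxicity endpoints (algae, invertebrates,
  fish; acute and chronic) are aggregated into per-cell geometric means, an
  assessment factor (10–10 000) is selected from the data availability
  pattern, and a PNEC is derived. Per mode-of-action class (Verhaar 1–5),
  the class threshold is the 5th percentile of the log10 PNEC distribution,
  estimated empirically and by fitted normal and logistic distributions,
  with the lowest back-transformed candidate selected.
- **Human branch** — drinking-water quality standards from
  `QS = 0.1 · TL · bw / wu`, where TL is a Cramer-class TTC dose, an
  ADI/TDI/RfD/BMD used directly, or NOAEL/100. Carcinogens (oral slope
  factor present) instead use `QS = (risk / SF) · bw / wu` at a 10⁻⁶ risk
  level, or a supplied risk-level concentration.
- **Combiner** — generic thresholds for the 15 (Verhaar × Cramer) pairs, or
  compound-specific thresholds `min(PNEC, QS)` per chemical, each labelled
  with the limiting branch.

A synthetic-data module generates chemicals, endpoint designs and PNEC
populations with known ground truth, so the whole pipeline is testable
offline.

## CLI

All commands read/write comma-separated UTF-8 tables with a header row.

```sh
# quality standard for a Cramer class (prints 105 µg/L)
hbttc derive-qs --cramer-class 1 --bw 70

# the 15 generic combined thresholds from the shipped reference constants
hbttc derive-hbttc generic --builtin-tables

# synthetic batch through the full ecological branch
hbttc simulate --seed 1 --n-chemicals 50 -o endpoints.csv
hbttc derive-pnec endpoints.csv -o pnecs.csv
hbttc derive-ecottc pnec_table.csv -o ecottc.csv   # needs verhaar_class column

# compound-specific thresholds
hbttc derive-qs --input hazard_table.csv -o qs.csv
hbttc derive-hbttc compound --pnec-table pnec_table.csv --hazard-table hazard_table.csv
```

Options such as body weight (`--bw`), the assessment factor for the
data-rich chronic rule (`--rich-chronic-af`, in [1, 5]) and the TL
selection mode (`--tl-mode conservative|precedence`) can also be set in a
YAML config passed via `--config`. Row-level input errors are reported to
stderr with line numbers and signalled by exit status 3.

Reference constants (published candidate triples, Cramer TTC doses, the
assessment-factor ladder, literature comparison values) ship as a versioned
data file, `src/hbttc/data/builtin_tables.json`.

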