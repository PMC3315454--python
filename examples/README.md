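# Example configs

- `sweep.csv` — parameter sets for `genesurf substitution-rate --config sweep.csv --route mc --reps 500 --seed 1 --out phi.csv` (the sublinear phi(N) table).
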