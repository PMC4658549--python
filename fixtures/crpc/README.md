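# CRPC network transcription slot

This directory is reserved for a transcription of the curated
castration-resistant prostate cancer network and its 91 update
equations, which are distributed only as a journal supplement and are
therefore not bundled here.

To analyze that model, place two files in this directory and point the
CLI at them:

* `crpc_network.tsv` — the signed interaction table in the package's
  TSV dialect (`source<TAB>effect<TAB>target[<TAB>and_group]`, effect
  `activate`/`inhibit`).
* `crpc_rules.txt` — the 91 update equations, one
  `target, expression` line each (`&`, `|`, `!`, parentheses, 0/1).
* optionally `crpc_expression_levels.csv` — `gene,level` with the known
  ON/OFF annotations, for consistency scoring.

Then, from the repository root:

    net-suite run-all --rules fixtures/crpc/crpc_rules.txt --out-dir run/crpc

No guessed or reconstructed content is shipped: everything in the test
suite runs on synthetic data generated by `logicnet.synth`.
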