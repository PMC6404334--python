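# Bundled synthetic study

All files here are **synthetic**, generated by `gsepd.simulate.golden_spec()`
(negative-binomial counts, fixed seed 20240):

- `counts.tsv` — 60 genes x 16 samples of raw counts.
- `samples.tsv` — 6 samples in condition `A`, 6 in `B`, 4 `nontested`
  samples whose expression interpolates the two groups.
- `gene_sets.tsv` / `term_names.tsv` — five 10-gene sets; `GO:0000001`
  carries a log2 effect of 4 in group B, the other four are decoys.
- `truth.tsv` — which terms carry the simulated effect.

Regenerate with:

```python
from gsepd.simulate import golden_spec, simulate_study
cm, samples, sets, truth = simulate_study(golden_spec())
```
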