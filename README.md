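# virtres — virtual resections on individual structural brain networks

`virtres` is a toolkit for planning *virtual resections* on structural
brain connectomes, for researchers studying epilepsy surgery with network
models.  Seizure propagation from a hypothesized epileptogenic zone (EZ)
is simulated as a discrete-time SIR process on the patient's binarized
DTI network; the drop in eigenvector centrality (EC) of the EZ serves as
a fast surrogate for the reduction in propagation; and simulated
annealing searches, per resection size, for the set of EZ-to-rest
connections whose removal maximizes that drop.  The *optimal* resection
is the smallest one retaining 90% of the effect of a full disconnection —
typically sparing a quarter of the connections the actual surgery would
sever.

## Model

On the binary adjacency `A`, each region is susceptible (S), ictally
active (I), or refractory (R).  Per synchronous step, a susceptible node
with `m` active neighbors activates with probability `1 − (1 − β)^m`, and
an active node becomes refractory with probability `γ = 0.03`.  Severity
is read out as `I(t₀)`, the mean active fraction at `t₀ = 10` over 10,000
runs; `β` is calibrated per network by raising it in steps of 0.001 until
on average 98% of nodes end refractory.  Spreading is epidemic when
`λ = β/γ > λ_c = 1/λ_max(A)`.

A resection removing edge set `E'` from the candidates (all edges from EZ
nodes to the rest) is scored by

    ΔEC(E')   = mean_EZ EC(A) − mean_EZ EC(A − E'),   normalized by ΔEC(full),

and its dynamical effect by the normalized drop in `I(t₀)`.  Since real
tractography cannot be redistributed, `virtres` ships a synthetic cohort
generator (degree-corrected hierarchical block model with a shared
cohort template) reproducing the network properties the method depends
on; see `docs/methods.md`.

## Worked example

```bash
resect simulate --subjects 1 --nodes 92 --density 0.11 --seed 1 --out cohort/
resect optimize --matrix cohort/subject00.csv --ez 46,49,52,81,89 --density 0.11 \
    --fraction 0.9 --seed 42
```

prints (abridged):

```json
{
  "K": 51,
  "k_star": 31,
  "spared_fraction": 0.3921568627450981,
  "normalized_effect_at_k_star": 0.9067783329205769,
  "removed_edges": [[46, 33], [46, 48], ...]
}
```

Read: this subject's five-region EZ has 51 candidate connections;
removing the 31 annealed ones already achieves 90.7% of the EC reduction
of cutting all 51, sparing 39% of the connections.  The library
equivalents are `generate_cohort`, `effect_curve`, `compare_strategies`,
`validate_surrogate`, and `run_pipeline` (YAML-configured end-to-end run
writing TSV/JSON tables and a reproducibility manifest); see the
docstrings.

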