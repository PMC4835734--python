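# sirthresh

Predicting the epidemic threshold of the SIR model on a network is a central
problem in network epidemiology, and three classical theories give three
different answers.  `sirthresh` implements all three predictors, a stochastic
simulator that measures the *actual* (size-dependent) threshold, and the
comparison machinery to decide — per network — which theory to trust.  It is
aimed at researchers in network science and computational epidemiology who
want reproducible threshold estimates on real or synthetic contact networks.

## The science

For SIR dynamics with per-contact transmission probability β and recovery
probability γ (effective spreading rate λ = β/γ), the three theoretical
thresholds are:

* **MFL** (mean-field-like / heterogeneous mean-field): uses only the degree
  distribution,
  λ_c^MFL = ⟨k⟩ / (⟨k²⟩ − ⟨k⟩).
* **QMF** (quenched mean-field): uses the full adjacency matrix A,
  λ_c^QMF = 1 / Λ_A, with Λ_A the leading eigenvalue of A.
* **DMP** (dynamical message passing): uses the non-backtracking operator,
  λ_c^DMP = 1 / Λ_M, with Λ_M the leading eigenvalue of the 2N×2N block
  matrix M = [[A, I−D], [I, 0]] (D the degree diagonal), whose non-trivial
  spectrum equals that of the 2E×2E directed-edge non-backtracking matrix.

The numerical ("accurate") threshold comes from simulation: for each λ on a
grid an ensemble of final epidemic sizes r is generated and the relative
variance χ = (⟨r²⟩ − ⟨r⟩²)/⟨r⟩² is evaluated; its peak over λ marks the
transition.  Diagnostics include the inverse participation ratio
IPR = Σᵢvᵢ⁴ of the principal eigenvectors (localization), the LHN/LKN
classification (Λ_A closer to √k_max — hub localization — or to ⟨k²⟩/⟨k⟩ —
k-core localization), and error curves stratified by assortativity r,
clustering c, and modularity Q.

Two exact relationships anchor the validation: λ_c^QMF ≤ λ_c^DMP on every
cyclic connected graph, and MFL ≡ DMP on uncorrelated configuration networks
(where Λ_M → ⟨k²⟩/⟨k⟩ − 1).

## Worked example

Generate an uncorrelated power-law configuration network (ν_D = 3.5,
k_min = 3, structural cutoff k_max = ⌊√N⌋), predict, and measure:

```bash
$ sirthresh -q generate --N 10000 --nu 3.5 --seed 42 --out net.edges
$ sirthresh -q predict --net net.edges
lc_mfl=0.17681955
lc_qmf=0.098415345
lc_dmp=0.17937186
$ sirthresh -q spectral --net net.edges
lambda_A=10.161017
ipr_A=0.16598192
lambda_M=5.5750105
ipr_M=0.0015968158
localization=LHN
tie_flag=False
$ sirthresh -q find-threshold --net net.edges --n 2000 --seed 7
lambda_c=0.17681955
```

Reading: the MFL and DMP predictions nearly coincide (0.1768 vs 0.1794) —
the configuration model at the structural cutoff has no degree correlations,
so the degree distribution carries all the information the message-passing
theory uses.  The QMF prediction (0.0984) is almost a factor of two below
them: the adjacency eigenvector is localized on the hubs (ipr_A ≈ 0.17,
class LHN), dragging Λ_A up and the threshold down.  The simulated threshold
(λ_c = 0.1768 from the χ peak over a 25-point grid, 2000 realizations per
point) lands on the MFL/DMP value: on this network the simpler theories are
right and QMF is off by ~44%.

The same pipeline is available as a library (`sirthresh.analyze_network`
returns the complete per-network record) and scales to corpora of edge lists
via `sirthresh compare --nets DIR --out results/`.

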