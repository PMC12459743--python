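# eegconn

Directed, band-limited cortical connectivity for response-inhibition EEG —
from sensor epochs to a small set of source nodes, and from node time
courses to **linear (LC)** and **nonlinear (NC)** directed connectivity with
surrogate-based significance.

## Who this is for

Researchers studying inhibitory control (Simon Go/Nogo-style paradigms) who
want to ask *which cortical region drives which*, in the theta (4–7 Hz) and
alpha (8–12 Hz) bands, and whether that influence is linear or nonlinear —
and anyone who needs a fully synthetic, ground-truth-validated testbed for
such a pipeline.  Every stage can be exercised without any external data:
the built-in generators produce task designs, behavior, coupled oscillatory
sources, sensor mixtures, and artifacts with known answers.

## The model at the core

Node signals x(n) ∈ R^M follow a nonlinear multivariate autoregressive
(nMVAR) model of order p:

    x(n) = f(x_p) + σ(n),    x_p = [x₁(n−1), …, x_M(n−1), …, x_M(n−p)]ᵀ

f is fit by a one-hidden-layer tanh perceptron (10 units) trained with
incremental backpropagation (momentum, adaptive learning rate, early
stopping, 10-fold permuted 80/10/10 cross-validation).  The fit is then
split as f = f_lin + f_nonlin via the network Jacobian J(x): with
J₀ = J(0) = W_o·diag(1 − tanh²(b_h))·W_h,

    LC[i→j] = (1/p) Σ_k |J₀[j,(i,k)]|            (input-independent slope)
    NC[i→j] = ⟨(1/p) Σ_k |J(x)[j,(i,k)] − J₀[j,(i,k)]|⟩_x   (curvature)

Significance comes from time-shifted surrogates: each channel is circularly
shifted by an independent random offset, preserving its dynamics while
destroying cross-channel alignment; empirical one-sided p-values use the +1
rank correction.

Upstream, sensor epochs become node time courses via LCMV beamforming
(unit-gain minimum-variance spatial filters), neural-activity-index
thresholding (top 2% of labeled voxels), and DBSCAN clustering
(eps = 1.5 × voxel edge, ≥ 2 voxels), with the cluster-mean time course as
the node signal.  See `docs/methods.md` for assumptions, defaults, and
known limitations.

## Worked example

A small end-to-end run (120 trials, alpha band, 20 surrogates, 5 folds):

```bash
cat > demo.yaml <<'YAML'
simulate:
  n_trials: 120
  n_blocks: 2
ncreann:
  surrogates: 20
  folds: 5
YAML
eegconn run --config demo.yaml --seed 7 --out demo_out
```

prints

```
Simon Nogo effect: +0.111
alpha/nogo_congruent: LC strength 0.2008  NC strength 0.0610
alpha/nogo_incongruent: LC strength 0.2339  NC strength 0.0701
outputs in demo_out
```

Reading the numbers: the *Simon Nogo effect* is accuracy(Nogo congruent) −
accuracy(Nogo incongruent); with only 18 Nogo trials per cell its sign is
dominated by sampling noise (+0.111 here — at the default 720-trial design
the simulated effect is reliably negative, the usual inversion).  *LC/NC
strength* is the mean off-diagonal connectivity among the source clusters
found for each condition — the network-strength summary used for
condition and group comparisons.  `demo_out/` contains the full bundle:
`connectivity.csv` (per-edge LC, NC and surrogate p-values),
`clusters.csv` (node labels, sizes, centroids), `accuracy.csv`,
`behavior.csv`, `rejection_report.csv` (which trials the 200 μV / flatline
rules removed and why), Figure-style SVG graphs (arrow labels are values
× 100; solid = significant, dashed = not), `summary.json` with provenance
(config hash, seed, version), and `run.h5` with epochs, grid, and model
weights.  Rerunning with the same config and seed reproduces every file
exactly.

Library use mirrors the CLI:

```python
from eegconn.syndata import benchmark_b1, simulate_nmvar
from eegconn.ncreann import NCREANNConfig, estimate_connectivity

sources, edges = simulate_nmvar(benchmark_b1(), 8000, seed=1)
result = estimate_connectivity(sources, order=10,
                               config=NCREANNConfig(seed=1),
                               window_ms=None, n_surrogates=50)
print(result.lc.round(3))      # linear edge 0->1 dominates
print(result.nc.round(3))      # nonlinear edge 0->2 dominates
print(result.p_lc.round(3), result.p_nc.round(3))
```

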