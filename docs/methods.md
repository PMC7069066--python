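# Methods

This document records the model, its parameters, and the numerical
choices, so that every number the package produces can be traced to a
stated rule.

## 1. Synthetic circuit

The circuit is a cartoon cortical column: a cylinder of radius 230 µm
with two layers ("upper": depth 0–400 µm, "lower": 400–1000 µm) and
four m-types (upper/lower pyramidal cells, EXC; upper/lower basket
cells, INH) with fixed fractions.  `default_circuit_spec` freezes these
numbers; nothing in the package depends on them beyond the spec object,
so other columns can be described by constructing a `CircuitSpec`
directly.

Somata are placed uniformly in the lateral disc (radius via √u
sampling) and uniformly in the m-type's layer interval.  Per-m-type
counts follow largest-remainder rounding of the fractions, so they are
deterministic given `n_neurons`.

### Density clouds

Each m-type carries two 2-D density clouds (axonal and dendritic) in
(lateral offset r, depth y) coordinates, each a mixture of axis-aligned
Gaussian components with a weight interpreted as total bouton/spine
mass.  Clouds are rendered on a shared square lattice (default bin
2 µm) over an extent covering ±5σ of every component; rendering
normalizes each component to its weight so that discretization does not
change the mass.

### Morphological jitter (η)

Neuron *i*'s morphology is the type cloud displaced by δᵢ ~ N(0, η²)
(per axis) and scaled by sᵢ = exp(N(0, (η/50)²)), a log-normal size
factor.  The instance overlap then factorizes as

  Oᵢⱼ = sᵢ sⱼ F_type(Δᵢⱼ + δᵢ − δⱼ)

where F_type is the type-level convolution field.  At η = 0 this
reduces exactly (bitwise, not approximately) to the cloud overlap,
which the tests exploit: the reference and cloud wiring then sample the
same per-block distributions.

## 2. Wiring

### Overlap fields

For an ordered m-type pair (pre, post) the overlap field is the 2-D
cross-correlation of the presynaptic axon cloud with the postsynaptic
dendrite cloud, computed by FFT convolution (`scipy.signal.fftconvolve`)
on the shared lattice; `F.at(r, Δy)` is a nearest-bin lookup.  The mass
identity ∫F = (axon mass)·(dendrite mass) (Fubini) is tested.

### Reference connectome

For every ordered m-type pair the target edge count comes from
`default_targets` (the mean_degree × n edge budget split across pairs
proportionally to summed squared type-level overlap, largest-remainder
rounded).  Candidate weights are the squared jittered instance overlaps
Oᵢⱼ² over all (pre, post) soma pairs of the block; the required
number of distinct edges is drawn by sequential weighted
sampling *without replacement* (pick proportionally, set the picked
weight to zero, renormalize, repeat).  Two implementations are
provided — the literal sequential procedure and an equivalent Gumbel
top-k sampler — and their marginal inclusion probabilities are verified
against exact enumeration of the sequential process (acceptance
criterion 3).

### Cloud connectome

The cloud wiring replaces Oᵢⱼ by the *type-average* overlap at the
soma offset, transfers it with Õ = O² (exponent configurable), and
draws **exactly the same number of connections per m-type pair** as the
reference.  First-order structure is therefore conserved by
construction; the acceptance script reports the max-abs difference of
the macroconnectome (always 0).

### Transplant and loss accounting

Physiological attributes (synapse counts, path lengths) exist only for
reference connections.  The transplant keeps the inhibitory subgraph of
the reference bitwise unchanged and places each excitatory cloud edge
into an attribute "slot" taken from the reference connections of the
same (postsynaptic neuron, presynaptic m-type) group; when a group
needs more slots than the reference provides, slots are reused
(`duplicated`) up to a bound, beyond which edges are dropped (`lost`).
The `LossReport` satisfies required = placed + lost per pair, exactly.

### Controls

- `matched_removal` deletes from the reference exactly the per-pair
  `lost` counts of the loss report (uniformly at random within pair).
- `shuffle_path_length` permutes path lengths within each
  (postsynaptic neuron, presynaptic m-type) group, preserving the
  multiset exactly and touching nothing else.

## 3. Topology

Directed simplices are cliques with a linear order: (v₀,…,vₙ) with an
edge vᵢ→vⱼ for all i<j.  Enumeration uses numba-compiled uint64-bitset
kernels (iterative DFS over intersected out-neighbor sets, graphs up to
64·48 nodes in principle, depth cap 48).  A simplex is **maximal** iff
no vertex can be *inserted at any position* — not merely appended — to
give a larger simplex; maximality is always decided against the full
graph even when enumeration is capped at `max_dim`.  Isolated vertices
are maximal 0-simplices.  All kernels are verified exactly against a
brute-force permutation oracle on random digraphs (criterion 1).

Other statistics: ND-in-degree (number of N-simplices a neuron sinks),
connection participation (per-edge counts of being the source/sink edge
of an N-simplex, with polarity (n_src−n_snk)/(n_src+n_snk)), triad
census (networkx), Fagiolo directed clustering, characteristic path
length (exact BFS below `exact_limit` nodes, seeded source sampling
above), small-worldness against a G(n,m) ER reference, Euler
characteristic from simplex counts, and GF(2) Betti numbers from
boundary-matrix ranks (guarded to ≤64 nodes; connectome-scale homology
needs specialized software and is out of scope).

## 4. Simulation

A discrete-time (1 ms) GLM/hazard network: each neuron's hazard is
exp(bias + synaptic input) with exponential synaptic kernels
(τ = 5 ms), conduction delays from connection path lengths at
300 µm/ms, an absolute refractory period of 3 ms, and an optional
thalamic stimulus (fibers innervating all neurons within a lateral
radius, frozen Poisson or pulsed-envelope spike trains shared across
trials).  The calcium-like knob γ scales excitatory weights by γ^1.7
and inhibitory weights by γ, mimicking the steeper calcium dependence
of excitatory release; γ > 1 moves the network from an asynchronous
toward a synchronous regime.

## 5. Activity statistics

- **Spike-time reliability**: spike trains on a 0.5 ms
  signal grid are convolved with a Gaussian (σ = 5 ms); r_spike is the
  mean cosine similarity over trial pairs.  For two single-spike trains
  Δ apart this equals exp(−Δ²/(4σ²)) analytically, tested at Δ = 5 ms
  (≈ 0.7788).
- **Trial correlations**: Pearson correlations of trial
  PSTHs; K trials → K(K−1)/2 pairs within a model (30 → **435**) and
  K(K+1)/2 cross-model pairs including equal-index pairs (30 → **465**).
- **Pairwise correlation matrix**: Pearson correlation of per-neuron
  PSTHs built over *concatenated* stimulus trials at Δt = 20 ms;
  neurons with no spikes (zero variance) are excluded, not zero-filled.
- **Simplex-position profiles**: for each maximal simplex dimension,
  the mean pairwise correlation of neuron pairs occupying positions
  (0,1) (source pair) … (n−1,n) (sink pair).
- **Distance dependence**: nonlinear least squares of
  r = a·exp(−d/λ) + c (`scipy.optimize.curve_fit`), recovery verified
  on synthetic data.

## 6. Numerical and scale choices

- All randomness flows from user seeds through
  `numpy.random.default_rng(SeedSequence([seed, salt]))`; stage seeds
  in the pipeline are sha256-derived and < 2³¹.
- Package-level problem sizes are desk scale by choice: the default
  pipeline runs ~800–2000 neurons.  Headline numbers of 31k-neuron
  reconstructions (σ_out = 152, tens of millions of simplices) are
  properties of that scale and are not reproduced; the acceptance tests
  check the *qualitative* reference-vs-cloud contrasts instead.
- The evoked simplex-correlation study
  (`io.run_simplex_correlation_study`) uses n = 500, mean degree 30,
  η = 20 µm, γ = 1.15, 20 trials × 2 s, a 25-fiber pulsed stimulus,
  maximal simplices to dimension 5, and summarizes dimensions with
  ≥ 20 pair observations by the least-squares slope of mean correlation
  vs dimension and count-weighted pooled sink/source means.  The regime
  (γ slightly above 1, evoked) is where recurrent structure, not noise,
  shapes correlations; at γ = 1 spontaneous activity the profile is
  flat within estimator noise.

## 7. Known limitations

- Two layers / four m-types is a deliberate cartoon; realism lives in
  the mechanism (clouds, jitter, transfer), not the taxonomy.
- Betti numbers are exact but limited to small graphs.
- The GLM simulator is a statistical stand-in for conductance-based
  simulation; rates and correlations are in biologically plausible
  ranges but are not fits to data.
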