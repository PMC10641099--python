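# Methods

## Contact-network model

A structure is reduced to one representative point per standard
amino-acid residue. Three representations are supported:

- **ca** — the Cα atom (default). Residues without a Cα are skipped.
- **cb** — the Cβ atom, falling back to Cα for glycine or when Cβ is
  missing; this shifts the point toward the side chain and slightly
  favours side-chain packing contacts.
- **centroid** — the unweighted mean of the residue's heavy atoms.
  Hydrogens are excluded because their presence in deposited PDB files is
  inconsistent; including them would make the network depend on the
  refinement protocol rather than the structure. The centroid is
  all-heavy-atom (backbone included); a side-chain-only centroid is a
  conceivable variant but is not implemented.

Two residues i, j are connected when

    d_min <= ||x_i − x_j|| <= d_max   (both ends inclusive)

with defaults d_min = 4.0 Å and d_max = 8.0 Å, the classical PCN window:
the lower bound removes covalently constrained neighbours (consecutive
Cαs sit at ≈3.8 Å), the upper bound keeps genuine non-covalent contacts.
Inclusivity is fixed on both ends so that bit-exact tests are possible.
An optional `min_seq_sep` parameter (default 0 = off) additionally
suppresses same-chain pairs closer than that many sequence positions;
inter-chain pairs are never suppressed.

Parsing keeps only model 1 of multi-model files (NMR-ensemble iteration
is the caller's loop), keeps alt-locs ' ' and 'A' only (a deterministic
single-conformer graph), excludes waters, HETATM records and non-standard
residues (including MSE), preserves author numbering and insertion codes,
and orders nodes by (chain, res_seq, i_code). Each atom record retains
its raw source line, which is what lets the B-factor annotation writer
guarantee that every column other than columns 61–66 is byte-identical
to the input. Annotated values are formatted `%6.2f` and clamped to
[−99.99, 999.99], the widest range the fixed-width field can carry.

### Adjacency-file dialect

Precomputed matrices are exchanged as plain text: an optional
`# labels: …` header (space-separated node labels), then N rows of N
space-separated 0/1 entries. Matrices must be square, symmetric, binary
and zero-diagonal; weighted matrices are rejected rather than silently
binarized, on the principle that coercion hides upstream errors.

### The helix fixture

`generate_helix_fixture(n)` emits a CA-only ideal α-helix: residue i at
(r cos iθ, r sin iθ, i·h) with r = 2.3 Å, θ = 100°, h = 1.5 Å. Its
contact structure under the default window is known in closed form
(separations 2, 3, 4 are inside the window at 5.43/5.05/6.20 Å;
separations 1 and 5 fall outside at 3.83/8.66 Å), which makes it a
complete analytic oracle for the build step. It emulates the local
geometry of real secondary structure but none of the tertiary contacts,
chain breaks, alt-locs or missing atoms of experimental files — passing
on it validates geometry and plumbing, not robustness to messy PDBs
(which is exercised separately with malformed-input tests).

## Centrality

Degree, betweenness and closeness follow the standard definitions;
betweenness uses Brandes' algorithm with each unordered pair counted
once (raw), normalized by (N−1)(N−2)/2. Closeness is computed per
connected component, raw = (n_c−1)/Σd, with the Wasserman–Faust factor
(n_c−1)/(N−1) applied in the normalized value so that nodes in small
fragments are discounted rather than crashing multi-chain or broken
structures. Eigenvector centrality is a power iteration started from the
all-ones vector — a deterministic choice that also keeps every iterate
nonnegative, fixing the sign convention for free; convergence is
declared at max-norm change < 1e−10 (default) within 1000 iterations,
otherwise an error reports the residual. Both raw and normalized values
are always emitted; annotation uses the normalized one.

## Partitioning

Spectral clustering takes the k eigenvectors of smallest eigenvalue of
the chosen Laplacian; for the symmetric variant rows are unit-normalized
first (Ng–Jordan–Weiss). Random-walk eigenvectors are recovered from the
symmetric ones as D^(−1/2) v (the two matrices are similar, so their
spectra coincide and one symmetric eigensolve serves both). Isolated
nodes use the 0-diagonal convention in the normalized Laplacians and so
contribute an extra zero eigenvalue, preserving the identity
"multiplicity of 0 = number of components".

The Laplacian eigenmap uses eigenvectors 2..d+1 of L (the constant
eigenvector carries no information), hence d ≤ N−1; the HOPE/Katz
embedding supports d ≤ N. Numerical note: on disconnected graphs the
zero eigenspace of L is degenerate and a plain symmetric eigensolve
returns an arbitrary basis for it; the implementation therefore shifts
the constant direction above the spectrum (by 2·max-degree + 1, a
Gershgorin bound) before solving, so the returned coordinates are always
orthogonal to the constant vector and component indicators come out as
sign-opposite values. Eigenvector and SVD column signs are fixed by
making each column's largest-magnitude entry nonnegative.

The Katz decay defaults to β = 0.05, safe for typical PCN spectral radii
(dense contact graphs reach ρ(A) ≈ 10–15); β ≥ 1/ρ(A) is rejected
because the Katz series diverges there.

All k-means steps share one contract: k-means++ initialization, 10
restarts, fixed seed, best inertia kept. Partition labels are renumbered
by first node occurrence, so identical cluster structures always produce
identical label vectors regardless of method-internal numbering.

Community extraction wraps seeded Louvain (resolution 1.0 by default),
Clauset–Newman–Moore greedy modularity and seeded asynchronous label
propagation; Girvan–Newman is an explicit loop that removes the edge of
maximum edge betweenness until the requested number of components is
reached, breaking ties deterministically by lowest (i, j) edge index.
Modularity Q is evaluated directly from Q = Σ_s [e_s/m − (d_s/2m)²].

The algorithm roster is deliberately fixed at ten — three spectral
variants, two embeddings feeding one clusterer, four community methods,
plus k-means itself — chosen to span all four analysis families.

### Planted-partition fixture

`generate_planted_partition(blocks, size, p_in, p_out, seed)` draws a
stochastic block model: within-block edges with probability p_in,
between-block with p_out < p_in. The recovery benchmark uses 4 blocks of
15 nodes with p_in = 0.9 and p_out = 0.05 — a strongly assortative,
clearly recoverable regime in which a correct implementation should
reach adjusted Rand index ≥ 0.9 against the planted labels in ≳95% of
seeds; failures at these settings indicate implementation defects, not
statistical hardness. The SBM emulates modular connectivity only; it has
none of the spatial banding of real contact maps.

## Node roles

Participation and intramodular z follow the network-cartography
formulas given in the README. Degenerate cases are mapped to 0 rather
than NaN — isolated nodes (k = 0) get P = 0, and clusters with zero
within-degree spread (σ = 0, including singletons) get z = 0 — keeping
downstream tables and plots total. The z-score uses the **population**
(divide-by-n) standard deviation; with it, every cluster with σ > 0
standardizes exactly to mean 0 and sd 1, an identity the tests assert to
1e−9. Role-zone classification (the R1–R7 hub taxonomy) is out of scope;
only P and z are reported.

## Orchestration

Each CLI run resolves exactly one input source (PDB file, adjacency
file, or `helix:N` fixture), builds the network if coordinates are
available, executes one analysis, writes TSVs (floats printed with
`%.10g`, so outputs are byte-reproducible under a fixed seed) and
appends a JSON-lines record — inputs, build parameters, method, seed,
output paths, toolkit version, timestamp — to `pcn_journal.jsonl` in the
output directory. Record ids are sequential within a journal. A
`key=value` config file may override the built-in defaults; explicit
command-line flags override the file. PDB download by id is available
behind an injectable fetcher but is exercised only with stubs offline.

## Problem sizes

The test-suite and acceptance-script workloads — 200 random graphs of at
most 7 nodes against the brute-force enumerator, 100 random graphs for
the spectrum/component identity, 100 stochastic-block-model seeds at 60
nodes, and 30-residue helix fixtures — were chosen so that each check
has clear statistical force while the whole suite completes in seconds;
all of them are ordinary desktop-scale computations.

## Known limitations

- No mmCIF input, occupancy weighting or biological-assembly expansion.
- Contacts are binary: no distance-weighted or atom-level graphs.
- Betweenness/closeness assume unweighted shortest paths.
- Node-role values are partition-dependent; P and z from different
  clustering methods are not directly comparable.
- The helix and SBM generators are idealized fixtures; conclusions about
  real proteins require real structures.
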