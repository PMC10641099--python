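# pcnkit — protein contact networks, GUI-free

`pcnkit` builds and analyzes **protein contact networks (PCNs)**: graph
representations of 3D protein structures in which each residue is a node
(located at its Cα atom, Cβ atom, or heavy-atom centroid) and an edge
connects every residue pair whose Euclidean distance lies in an inclusive
window [d_min, d_max] (default 4–8 Å — the lower cutoff excludes covalent
backbone neighbours, the upper bounds significant non-covalent contacts).
The resulting binary adjacency matrix **A** is the substrate for the four
analysis families the toolkit provides:

1. **Centrality** — degree `k_i = Σ_j A_ij`, betweenness (Brandes
   shortest-path mediation), closeness (inverse farness with
   Wasserman–Faust scaling across components) and eigenvector centrality
   (principal eigenvector of A by power iteration).
2. **Spectral clustering** — k-means on the eigenvectors of the smallest
   eigenvalues of the graph Laplacian L = D − A, or of its symmetric
   (L_sym = I − D^(−1/2) A D^(−1/2)) or random-walk (L_rw = I − D^(−1)A)
   normalizations.
3. **Embedded clustering** — k-means on explicit node embeddings: the
   Laplacian eigenmap, or a HOPE-style truncated SVD of the Katz
   similarity S = (I − βA)^(−1) βA.
4. **Community extraction** — Louvain, Clauset–Newman–Moore greedy
   modularity, asynchronous label propagation and Girvan–Newman
   edge-betweenness removal, scored by Newman modularity
   Q = Σ_s [e_s/m − (d_s/2m)²].

For any partition, per-node roles follow the Guimerà–Amaral cartography:
the **participation coefficient** P_i = 1 − Σ_s (κ_is/k_i)² and the
**intramodular connectivity z-score** z_i = (κ_i − ⟨κ⟩_{s_i})/σ_{κ,s_i},
where κ_is counts the edges node i sends into cluster s.

It is aimed at structural bioinformaticians who want scriptable,
reproducible PCN analyses: every run is seeded, results are plain TSV
tables, per-residue scores can be written back into the B-factor column of
the source PDB for colouring in any molecular viewer, and each run is
journalled to a JSON-lines file.

## Worked example

Compute betweenness centrality on the built-in ideal α-helix fixture
(30 CA-only residues on the canonical helix geometry: radius 2.3 Å,
100°/residue, 1.5 Å rise):

```
$ pcn centrality --metric betweenness --fixture helix:30 -o out/
{"build_params": {"chains": null, "d_max": 8.0, "d_min": 4.0, "min_seq_sep": 0,
 "mode": "ca"}, "input": "fixture:helix:30", "method": "centrality:betweenness",
 "outputs": ["out/pcn_centrality_betweenness.tsv"], ... "record_id": "run-000001"}

$ head -4 out/pcn_centrality_betweenness.tsv
node_index  chain  res_seq  res_name  raw           normalized
0           A      1        ALA       0.5833333333  0.001436781609
1           A      2        ALA       0.5           0.001231527094
2           A      3        ALA       2.596969697   0.006396477086
```

Under the 4–8 Å window the helix network contains exactly the pairs at
sequence separation |i−j| ∈ {2, 3, 4} (81 edges for n = 30): consecutive
CAs sit at ≈3.83 Å (below d_min) and |i−j| = 5 pairs at ≈8.66 Å (above
d_max). The `raw` column counts shortest-path pair dependencies; terminal
residues mediate few paths, mid-helix residues many.

A typical pipeline on a real structure:

```
pcn build      --pdb 1abc.pdb --mode ca -o out/          # adjacency + edge list
pcn cluster    --method spectral --k 4 --variant sym --seed 1 --pdb 1abc.pdb -o out/
pcn roles      --partition out/pcn_partition.tsv --pdb 1abc.pdb -o out/
pcn centrality --metric degree --pdb 1abc.pdb --annotate -o out/   # B-factor PDB
```

`pcn cluster`/`pcn community` write a partition TSV (and the Laplacian
spectrum for spectral runs); `pcn roles` writes the long-format z–P table
(`structure_label, node_index, chain, res_seq, cluster, k, kappa, P, z`).
Precomputed adjacency matrices are accepted with `--matrix FILE` in the
plain-text dialect documented in `docs/methods.md`.

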