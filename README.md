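# sigreach

Exact signal-reachability probabilities in probabilistic directed networks,
with the downstream analyses used to characterise transcription regulatory
networks (TRNs): reachability profiles, node-removal centrality and
perturbation stability.

## The problem

Regulatory and signalling interactions are uncertain: databases attach a
confidence value to each interaction. Modelling a network as a directed
graph `G = (V, E, P)` whose edges exist **independently** with probability
`P(e) ∈ (0, 1]` raises the natural question: *what is the probability that a
signal starting at a source gene `s` can reach a target gene `t`?* A
network with `n` probabilistic edges represents `2^n` deterministic
topologies, and two-terminal reachability over that ensemble is
#P-complete, so naive enumeration dies beyond a few tens of edges.

`sigreach` computes this probability **exactly** by divide and conquer over
*good node separators*. An s-t node separator is a node set `K` whose
removal disconnects `t` from `s`; it is *good* if it induces no backward
edges (no edge from the far side back into the near side). Along a sequence
`K_0 = {s}, K_1, …, K_{c+1} = {t}` of good separators the method maintains a
collapsed polynomial `Σ_S β_S z_S`, where `z_S` encodes the event that
exactly the subset `S ⊆ K_i` is reachable from the source and
`β_S = p({s}, S, K_i)` its probability. Each stage multiplies in the edge
polynomials `p_j x_j + q_j y_j` of the edges between `K_i` and `K_{i+1}`,
and a collapsing operator replaces every term whose outcome at `K_{i+1}` is
already determined by `γ·z_T`, summing coefficients. The final polynomial
has two terms, `γ_{t} z_{t} + γ_∅ z_∅`, and `γ_{t}` is the s-t reachability
probability — exact, for any separator sequence.

On top of the single-pair computation the package provides

- **reachability profiles** `R[i, j] = p(s_i, t_j)` over source/target lists,
- **gene centrality** `Σ_s Σ_t [p(s,t) − p_ḡ(s,t)]` (profile drop when gene
  `g` is deleted),
- **network stability** — mean `|p^δ(s,t) − p(s,t)|` when every edge
  probability is uniformly perturbed within `±δ` (clipped to `[0, 1]`),
- two exponential **oracles** (configuration enumeration and
  inclusion–exclusion over simple paths) used to certify the method,
- a **scale-free network generator** (preferential attachment, edge count
  fixed at twice the node count) and small named fixture networks.

## Worked example

```python
from sigreach import fixture, reachability_probability, brute_force_reachability

net = fixture("bridge5")          # s→a, s→b, a→b, a→t, b→t, all p = 0.5
print(reachability_probability(net, "s", "t"))   # 0.46875
print(brute_force_reachability(net, "s", "t"))   # 0.46875  (15 of 32 configs)
```

The directed bridge has 32 configurations, 15 of which connect `s` to `t`,
hence 15/32 = 0.46875. The same computation from the shell:

```bash
sigreach fixture --name bridge5 --out bridge5.tsv
sigreach reach --network bridge5.tsv --source s --target t
# 0.468750000000
sigreach separators --network bridge5.tsv --source s --target t
# K_0: s
# K_1: a,b
# K_2: t
# stage 1: 3 edges
# stage 2: 2 edges
```

A profile over explicit source/target lists, written as CSV:

```bash
sigreach simulate --nodes 50 --seed 1 --out ba50.tsv
printf 'n0\nn1\n' > sources.txt
printf 'n5\nn9\n' > targets.txt
sigreach profile --network ba50.tsv --sources sources.txt --targets targets.txt --out profile.csv
sigreach centrality --network ba50.tsv --sources sources.txt --targets targets.txt --all --out centrality.csv
sigreach stability --network ba50.tsv --sources sources.txt --targets targets.txt \
    --delta 0.3 --replicates 20 --seed 1 --out stability.csv
```

Edge lists are plain text (`source target probability`, `#` comments);
node lists are one identifier per line.

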