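# collmove

Agent-based simulation of collective movement decisions on weighted social
networks, for behavioural ecologists studying how a group's social structure
shapes its consensus decisions — who initiates a group departure, who is
followed, and how quickly the rest of the group joins.

## The model

A group of `N` individuals (default `N = 10`, a typical primate group size)
rests in one area and must collectively move to another. The group's social
structure is a directed, weighted affiliation matrix `r(i,k)`: each
individual distributes a fixed unit budget of social interaction over its
group mates (`Σ_k r(i,k) = 1`, zero diagonal). A one-parameter family of
networks spans the organisational continuum: in the **star** network every
non-central individual `c` gives its entire budget to a single central
individual `C` (`r(c,C) = 1`, extreme centralization, the despotic limit),
while in the **equal** network every dyad carries `1/(N-1)` (extreme
decentralization, the egalitarian limit). Chain (path) and connected
Erdős–Rényi topologies complete the canonical set.

Time advances in 1-second steps. Every resting individual departs
independently with intrinsic probability `λ` per second, so the collective
initiation probability is

```
ψ01 = N·λ                      (λ = 0.00007 /s  ⇒  ψ01 = 0.0007 /s)
```

Once `j` individuals are moving, a resting individual `i` is amplified
mimetically by its affiliation toward the movers, `S_i = Σ_{k moving} r(i,k)`:

```
ψ_i = λ + M · f(j, N) · S_i     (M = 0.002 per unit affiliation per second)
```

with a kernel `f`: `f = 1` (K1, the literal mimetic term),
`f = N - j` (K2) or `f = j·(N - j)` (K3, the parabolic-rate variant).
Because the written form of the joining rule underdetermines `f`, the
reference kernel is *calibrated* against the canonical star-network
summaries; K3 wins decisively (see `docs/methods.md`). A movement ends when
everyone has departed or when 300 s pass without a departure.

Group structure is quantified by eigenvector centrality on *received*
affiliation (closed form on the continuum: score ratio `C:c = (N-1)·r(c,C)`)
and by the **centrality index** — the central individual's score minus the
mean score of the others, 0 for the equal network rising to ~0.85 for the
star. Batches of 10,000 replicates are reduced to three decision variables
(number of joiners, first-joiner latency ΔT₁,₂, joining duration ΔT₁,₁₀),
split by initiator class (central vs non-central), and the
centrality-response relationship is fitted with linear / exponential /
logarithmic curve estimation.

## Worked example

```python
import collmove as cm

star = cm.build_continuum_network(10, 1.0)
scores = cm.eigenvector_centrality(star)
exact, table = cm.centrality_index(scores, "C")
print(f"central score  : {scores['C']:.4f}")
print(f"peer score     : {scores['c1']:.4f}")
print(f"centrality idx : {exact:.4f} (exact), {table:.2f} (rounded scores)")

cfg = cm.SimulationConfig(kernel=cm.REFERENCE_KERNEL, replicates=2000, seed=1)
records = cm.run_batch(star, cfg)
summary = cm.summarize(records, central="C")
ci, nc = summary.classes["central_init"], summary.classes["noncentral_init"]
print(f"C-initiated  : n={ci.n:4d}  joiners={ci.mean_joiners:.2f}  "
      f"first-joiner latency={ci.mean_first_latency:.1f} s")
print(f"c-initiated  : n={nc.n:4d}  joiners={nc.mean_joiners:.2f}  "
      f"first-joiner latency={nc.mean_first_latency:.1f} s")
print(f"|C - c| joiners: {summary.diffs['joiners']:.2f}")
```

prints

```
central score  : 0.9487
peer score     : 0.1054
centrality idx : 0.8433 (exact), 0.84 (rounded scores)
C-initiated  : n= 208  joiners=9.98  first-joiner latency=6.7 s
c-initiated  : n=1792  joiners=5.78  first-joiner latency=127.4 s
|C - c| joiners: 4.20
```

Read: the central individual of a star network is ~9× more central than its
peers; when it initiates, essentially the whole group follows within
seconds, but when a peripheral individual initiates, the movement recruits
barely half the group and the first follower takes two minutes — an
unshared consensus. On the equal network the same statistics are
indistinguishable between initiator classes (a shared consensus).

The same pipeline is available from the shell:

```
collmove centrality --generator star
collmove simulate --generator star --kernel K3 --replicates 10000 --seed 1 --out star.tsv
collmove summarize --batch star.tsv --central C
collmove reproduce --out report/ --replicates 10000 --seed 1
```

`collmove reproduce` writes, for each canonical network, the centrality
table, the replicate batch, the class-conditional summary and the
rank-latency profile, plus cross-network curve fits of the three decision
variables (and their C-vs-c differences) against the centrality index and
the Spearman correlation matrix of rank-latency profiles.

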