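# nflevo

**Why do signaling pathways put their negative feedback where they put
it?**  Immune cascades are damped both *upstream* (regulators that shut
down the receptor, reducing input) and *downstream* (regulators that
shut down the output protein directly).  `nflevo` is an evolutionary
simulator for asking under which conditions each kind of negative
feedback loop (NFL) evolves: it coevolves a population of hosts carrying
a five-protein immune signaling network (receptor R, activator A, immune
effector I, upstream regulator U, downstream regulator D) against a
population of pathogens P, and reports which of the network's potential
interactions stabilize as activatory or inhibitory.

It is aimed at evolutionary systems biologists who want a tested,
reproducible, desk-scale implementation of this class of model:
bit-string genotypes, ODE signaling dynamics within each host, selection
on lifetime infection burden and immune expenditure, and sequence-style
rate-of-evolution estimates.

## The model in brief

Every protein has three L-bit domains (receiver, neutral, sender).  The
interaction strength of j → i is set by the Hamming distance H between
j's sender and i's receiver domains:

    mu_ij = 1 − 2H/L ∈ [−1, 1]   (+ activation, − inhibition, 0 at H = L/2)

Within an infected host (lifetime T = 1000, forward Euler, states
clamped to [0,1]):

    dyP/dt = −|mu_PI| · yI · yP + pi · yP(1 − yP)
    dyi/dt = −phi_i · yi + Σ_j mu_ij · yj · (1 − yi)   [mu_ij > 0]
                         + Σ_j mu_ij · yj · yi         [mu_ij < 0]

Host fitness is exp(−(alpha·P̄ + beta·Ī)) from the lifetime averages of
pathogen burden and immune activity (uninfected hosts score 1); pathogen
fitness is P̄.  Hosts reproduce sexually with one recombination per
protein; pathogens asexually; both mutate by rare single-bit flips.
Every 5 generations consensus sequences yield per-domain divergences
ks (neutral) and ka (functional) and the rate ratio omega = ka/ks.
See `docs/methods.md` for the full account, all parameters, and the
rationale for the defaults.

## Worked example

Run two desk-scale replicates of the *stable receptor* regime (all
intracellular proteins degrade, the receptor does not, and receptor
recognition of the pathogen is pinned at mu = 1), then classify the
evolved architectures:

```bash
nflevo simulate --preset stable_receptor --replicates 2 --seed 7 \
        --scale 0.2 --out runs/demo        # n = 400, 4000 generations
nflevo classify --records runs/demo
```

which prints:

```json
{"architectures": {"downstream_NFL": 2}, "flags": {"downstream_NFL_A": 0,
 "downstream_NFL_D": 2, "functional_pathway": 0, "upstream_NFL": 1}, "n": 2}
```

Both replicates evolved the downstream NFL (A → D activatory and D → I
inhibitory: the output protein is shut down three signaling steps after
the receptor fires), and one of the two held the upstream NFL (A → U
activatory, U → R inhibitory) through the final window — the feedback
architecture this regime is designed to elicit, with replicate-to-
replicate noise expected at this reduced scale (`functional_pathway` is
0 here because the costly A → I coupling settles at the smallest
positive interaction quantum, +0.2, below the ±0.25 call threshold; see
`docs/methods.md`).  Per-replicate detail is written next to the records
as `*_architecture.json`.  Averaging the rate-of-evolution streams,

```bash
nflevo rates --records runs/demo --protein D --domain sender
```

starts at `sample_index 1  mean 1.0002  sd 0.0035` — the sender domain
of D diverging at the neutral rate before selection engages — and ends
around `mean 1.55  sd 0.20`, an omega above 1 reflecting the directional
sweeps and continued turnover at the feedback regulator's sender domain
while the architecture evolves.

In the `baseline` regime (no protein degradation) the same pipeline
yields downstream NFLs only — the upstream loop does not evolve there.

## Layout

| path | contents |
|---|---|
| `src/nflevo/genotypes.py` | bit-string genotypes, mu coefficients, recombination, mutation, consensus |
| `src/nflevo/dynamics.py` (+ `_kernels.py`) | within-host ODE integration, scalar reference + numba batch |
| `src/nflevo/evolution.py` | infection, fitness, selection, the generational loop |
| `src/nflevo/rates.py` | focal/temporal consensus tracking, ks/ka/omega streams |
| `src/nflevo/classify.py` | per-edge architecture calls and NFL flags |
| `src/nflevo/config.py`, `io.py`, `cli.py`, `fixtures.py` | presets, validation, plain-text I/O, CLI, test genotypes |
| `docs/methods.md` | model, assumptions, parameter rationale, limitations |
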