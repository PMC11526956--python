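# Methods

## The model

`nflevo` simulates the coevolution of a minimal immune signaling network
and a pathogen.  A host carries five proteins — receptor R, central
activator A, immune effector I, upstream regulator U and downstream
regulator D — and each pathogen carries a single protein P.  Every
protein is encoded by three bit domains of length L = 10: a *receiver*
domain through which the protein is regulated, a *sender* domain through
which it acts, and a *neutral* domain that participates in no
interaction and serves as the benchmark for the neutral rate of
evolution.

The signed strength of a directed interaction j → i is determined by the
Hamming distance H between the sender domain of j and the receiver
domain of i:

    mu_{i,j} = 1 − 2 H / L            (mu in [−1, 1], quantized in 2/L steps)

Identical domains interact at full activation (+1), complementary
domains at full inhibition (−1); exactly L/2 mismatches mean no
interaction.  The potential wiring is fixed: P → R, R → A, A → {I, U, D},
U → R, D → I, and I → P.  Which of these interactions *evolve* — and
with which sign — is the object of study.

### Within-host dynamics

During one host lifetime (T = 1000 time units) concentrations
y ∈ [0, 1]⁶ follow

    dyP/dt = −|mu_{P,I}| · yI · yP + pi · yP · (1 − yP)
    dyi/dt = −phi_i · yi + Σ_j  mu_{i,j} · yj · (1 − yi)   if mu_{i,j} > 0
                           Σ_j  mu_{i,j} · yj · yi         if mu_{i,j} < 0

Interaction terms saturate on the side they push toward, which keeps
every concentration in [0, 1].  Contributions of multiple regulators of
one target (P and U into R; A and D into I) are summed, each with its
own sign-dependent saturation factor.  An infected host starts at
yP = P0 = 1 with all host proteins at 0; an uninfected host has the
identically-zero trajectory (no constitutive investment in immunity).

Two readings of the immunity→pathogen term are implemented.  The default
(`force_inhibitory_IP = True`) forces that single interaction to be
inhibitory by using |mu_{P,I}|: immunity can at worst be evaded
(mu → 0), never recruited by the pathogen.  The literal signed term is
available as a switch, but under it the coevolutionary race settles in a
degenerate equilibrium: the pathogen's receiver evolves mu_{P,I} < 0, at
which point host immunity actively feeds the infection, hosts respond by
silencing the pathway, and no feedback architecture can evolve in any
parameter regime we probed.  The forced-inhibitory reading is the one
under which the model produces functional immune networks, and is
therefore the default.

### Integration scheme

Forward Euler with dt = 1 over T/dt = 1000 steps, each state clamped to
[0, 1] after every step.  The saturating interaction terms bound the
continuous-time flow, but Euler overshoot is possible, hence the clamp.
The lifetime averages P̄ and Ī that enter fitness are arithmetic means
over the stored grid of T/dt + 1 points including t = 0.  dt is
configurable; the logistic limit of the pathogen equation (all mu = 0)
agrees with a dt/100 reference integration to < 0.02 in the test suite.
A pure-Python per-individual integrator is kept as the reference path;
the population-scale integrator is a numba kernel that must agree with
it to 1e−12 per state per step (tested), and uses strict IEEE double
arithmetic so runs are bit-reproducible.

### Generations

Each generation: every host randomly encounters one pathogen (a random
permutation pairs the populations one-to-one) and the encounter becomes
an infection with probability theta.  Infected hosts are integrated;
host fitness is exp(−(alpha·P̄ + beta·Ī)) — the exponential-decay reading
of the fitness law, since fitness must fall from 1 toward 0 as the
averages grow — and uninfected hosts have fitness exactly 1.  A pathogen
that infected a host has fitness P̄; one that failed to infect has
fitness 0.  Parents are drawn fitness-proportionally with replacement.
Hosts reproduce sexually: each offspring draws two distinct parents, and
within each protein one domain recombines at a cut site k drawn
uniformly from 1..L−1 (sites left of k from the first parent, k and
rightward from the second) while the other two domains are inherited
whole from a uniformly chosen parent.  Pathogens reproduce asexually.
Each offspring mutates with probability MH = 0.001 (hosts) or
MP = 2·MH (pathogens) by flipping exactly one uniformly chosen bit —
the neutral domain included, as it is the neutral-rate benchmark.  Both
populations are replaced wholesale (non-overlapping generations), so n
is conserved.

Degenerate edge case: when theta is so low that a generation realizes no
infection at all, every pathogen has fitness 0; the pathogen population
then reproduces by uniform resampling (pure drift) rather than aborting
the run.  Host fitness is strictly positive always (exponential), so the
host population can never degenerate.

### Rate of evolution (ka/ks)

Every 5 generations the per-site frequency of 1s (consensus) is recorded
per protein and domain.  The first sample is the focal consensus FO;
later samples are temporal consensuses TE.  Divergence is

    k = (1/L) Σ_l [ FO_l (1 − TE_l) + TE_l (1 − FO_l) ]

— the per-site probability of a 1→0 plus a 0→1 change.  An
unnormalized over-sites sum would be incompatible with a 0.5 saturation
threshold (it can reach L), so the per-site form is used.  Applied to the neutral domain the
divergence is ks; to sender/receiver it is ka; omega = ka/ks.  When ks
exceeds 0.5 the neutral domain has saturated: the focal consensus of all
three domains of that protein is reset to the current consensus (so ka
and ks always share a focal epoch) and no omega is recorded.  omega is
recorded only when ks lies strictly inside (0, 0.5); at ks = 0 the ratio
is undefined and stored as missing rather than ±inf, to avoid
fabricating selection signals in invariant windows.  Replicate summaries
report the pointwise mean and sample standard deviation (ddof = 1)
across replicates, aligned by sample index, skipping missing values.

Note that k compares consensus *frequencies*, so an unchanged but
polymorphic population scores k = 2x(1−x) > 0, and a freshly
initialized population (site frequencies ≈ 0.5) sits near the 0.5
saturation threshold; resets are therefore frequent early in a run and
under neutrality, which is the intended behaviour of the estimator.

### Architecture classification

Evolved networks of this kind are often classified by visual inspection
of the mu trajectories; automation needs a deterministic rule.  An edge is
called from the mean of its population-mean mu over the final 10% of
generations: activatory above +0.25, inhibitory below −0.25, otherwise
not evolved.  Both knobs are exposed.  The pathogen-facing edges (P → R
and I → P) oscillate under coevolution, so they additionally report the
window amplitude and are labelled *coevolving* instead of not-evolved
when the swing exceeds 0.5.  Derived flags: functional pathway (R → A
and A → I activatory), downstream NFL via D (A → D activatory, D → I
inhibitory; three steps to shut the output down), downstream NFL via A
(D → I activatory, A → I inhibitory; two steps), and upstream NFL
(A → U activatory, U → R inhibitory).  The two downstream variants are
mutually exclusive by construction.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| L | bits per domain | 10 | sites |
| n | hosts = pathogens per generation | 2000 | individuals |
| generations | run length | 20000 | generations |
| theta | infection probability per encounter | 1.0 | — |
| pi | pathogen logistic replication rate | *no default*; presets use 0.05 | 1/time |
| P0 | initial pathogen concentration | 1.0 | — |
| phi | host protein degradation rate | 0 or 0.15 per regime | 1/time |
| T, dt | host lifetime, Euler step | 1000, 1 | time |
| alpha, beta | fitness costs of infection / response | 2, 1 | — |
| MH, MP | host / pathogen mutation probability per offspring | 0.001, 2·MH | — |
| sample_interval | consensus sampling cadence | 5 | generations |

**Why pi = 0.05.**  pi is a free parameter of the model with no natural
default, so the library refuses to default it; the presets must still
pick a number.  Because mu is quantized in steps of 2/L = 0.2, the smallest
nonzero immune clearance pressure is ≈ 0.2·yI·yP.  If pi is at or above
that quantum, a pathogen that evolves within one bit of perfect evasion
regrows as fast as minimal immunity can clear it, evasion wins the
within-host race outright, and the costly signaling pathway can never
pay for itself — no feedback architecture evolves in any regime.  For
the model to operate in the regime its study questions presuppose (a
functional immune pathway can evolve and NFLs then temper its cost), pi
must sit below 2/L; we fix pi = 0.05 in every preset.  Larger values up
to ~0.1 behave similarly but noisier; pi ≥ 0.2 is degenerate as
described.

**Preset regimes.**  `baseline` (phi = 0, alpha = 2, beta = 1,
theta = 1): the downstream NFL evolves, the upstream one does not.
`costly_response` (beta = 2): polymorphic downstream regulation — either
D or A evolves as the output inhibitor.  `degrading_proteins`
(phi = 0.15 everywhere, mu_{R,P} pinned to 1): upstream NFL becomes
possible.  `stable_receptor` (as before but phi_R = 0): the regime most
favourable to the upstream NFL.  `low_infection` / `low_infection_large`
(theta = 0.7 at n = 2000 / 5000) and `costly_stable_receptor` (beta = 2)
probe its sensitivity; `frozen_pathogen` (MP = 0, no receptor pin) removes
pathogen coevolution entirely.

## What the simulations do and do not show

The populations are synthetic by construction — uniform random bits —
so every result is a statement about the model, not about any organism:
there is no genetic architecture beyond 30 bits per protein, no linkage
map, no diploidy, no gene expression noise, no spatial or age structure,
and a single pathogen per host per generation.  The ka/ks estimator
operates on consensus frequencies of an evolving population, not on
fixed substitutions of a codon alignment, so its omega is only an
analogue of sequence-based dN/dS.  Passing tests demonstrate internal
consistency (bounds, conservation laws, neutral expectations,
reproducibility) and that the qualitative architecture outcomes are
recovered at reduced scale; they do not validate the model against
empirical data.

## Numerical and design choices

* Forward Euler + clamping rather than an adaptive integrator: the model
  needs 10⁶–10⁷ short, smooth, bounded integrations per run; the clamp
  makes boundedness unconditional and the fixed grid matches the
  lifetime-average definition.
* Initial bits are i.i.d. Bernoulli(0.5) for hosts and pathogens
  (maximum-entropy reading of "randomly created").
* Mutation acts on offspring only (no standing mutation of parents), and
  pathogens never recombine (asexual reproduction).
* Two distinct parents are required per sexual offspring; if fewer than
  two individuals have positive fitness the run aborts with a
  degenerate-population error rather than self-mating (unreachable for
  hosts, whose fitness is strictly positive).
* Population-mean mu per edge, the quantity plotted over generations, is
  averaged over all hosts for host-internal edges and over realized
  host–pathogen pairings for the two pathogen-facing edges (NaN in a
  generation with no infections).
* Trajectory-mean records, omega streams and snapshots are written with
  a fixed float format so repeated runs are byte-identical; per-replicate
  seeds derive from (master seed, replicate index) via numpy's
  SeedSequence spawn keys.
* Desk-scale problem sizes used by the test suite and the acceptance
  script — n = 500 with 3000–4000 generations and 5–10 replicates, vs
  n = 2000 with 20000 generations and 10 replicates at full scale — were
  chosen as the package's reduced verification scale; architecture
  frequencies at this scale are noisier than at full scale, which is why
  the qualitative checks are majority checks.

## Known limitations

* The architecture classifier's fixed threshold (±0.25 over the final
  10%) can disagree with visual classification near the boundary.  Two
  model features make this systematic for *activation* edges: mu is
  quantized in steps of 2/L = 0.2, and costly or saturating activations
  are optimized toward the smallest positive quantum, so their
  population mean often settles near +0.2 — just below the threshold —
  while inhibition edges, whose strength is monotonically beneficial,
  fix hard near −1 and are classified unambiguously.
* Architecture frequencies are population-size sensitive.  At reduced
  scale (n ≈ 500) both feedback loops assemble early in essentially
  every replicate, but the pathogen wins the immune-evasion race more
  often than in large populations, the pathway's payoff shrinks, and the
  upstream loop partially erodes over thousands of generations; counts
  of "upstream NFL present at the end" are therefore lower at desk scale
  than at full scale (n = 2000, 20000 generations).  This mirrors the
  model's own prediction that larger populations, where drift is weaker,
  evolve upstream feedback more reliably.
* Under the literal signed immunity term the model is degenerate (see
  above); the switch is retained for study of that regime, not as an
  equivalent alternative.
* ks compares frequency vectors, so omega is undefined (missing) in
  fully frozen windows and noisy when ks hovers near the saturation
  threshold; consumers should aggregate over many samples, as
  `summarize_omega` does.
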