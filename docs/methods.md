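# Methods

## Model

`ribotraffic` simulates the elongation stage of eukaryotic translation as a
collection of one-dimensional exclusion processes (one lattice per mRNA
copy) coupled through shared, finite pools of transfer RNAs.

**Lattice dynamics.** Each mRNA species *r* is a sequence of L_r codons,
each mapped to one of S tRNA species (1-based positions, left to right).
A ribosome covers `w` consecutive codons but decodes only the rightmost
covered codon, its *reader*. The dynamics are a continuous-time Markov
chain with four event classes:

* **Initiation** at rate α places a new reader at codon 1 (the footprint
  overhangs off-lattice to the left), enabled only while no reader sits at
  a position ≤ w. Each lattice behaves as if an initiation-competent
  ribosome is always waiting at the entry.
* **Elongation** of the ribosome reading codon j (tRNA species i = s(j))
  at rate κ·a_i(t), where a_i is the current number of charged
  (aminoacylated) tRNAs of species i; enabled only if the reader ahead
  leaves a gap of at least w codons. The hop consumes one charged tRNA:
  a_i → a_i − 1, b_i → b_i + 1 (b_i = bare count). Linearity in a_i
  encodes the assumption that decoding is limited by aa-tRNA arrival.
* **Termination** out of the last codon at rate β, assumed non-limiting
  (β larger than every hopping rate; validated at construction). By
  default the terminal hop also consumes one charged tRNA of the last
  codon's species, so every codon of the ORF is decoded exactly once per
  completed protein; `termination_consumes_trna=False` switches this off
  (the difference is a single tRNA per protein and is negligible in every
  quantity we report).
* **Recharging** of species i as one aggregated Michaelis–Menten channel
  at rate V_i·b_i/(K_i + b_i), equivalent to independent per-molecule
  recharging with enzyme saturation. Amino-acid availability is assumed
  non-limiting.

Totals T_i = a_i + b_i are conserved; there is no ribosome-pool feedback,
drop-off, wobble decoding, or internal ribosome state structure.

**Observables** are time-weighted averages over a measurement window that
follows a discarded burn-in: the current J_r (terminations per mRNA copy
per second, equal to the protein production rate and, by flux
conservation, to the hop rate past any site), reader density profiles
ρ_r(j) (fraction of time a reader occupies j), coverage profiles
ρ_cov,r(j) = Σ_{k=j}^{min(j+w−1,L)} ρ_r(k) (any part of a ribosome on j),
charging levels c_i = ⟨a_i⟩/T_i, bound ribosomes per ORF codon, and
per-site fluxes. The measurement window is split into equal blocks
(default 5) whose spread gives standard errors.

## Analytic layer

For a uniform (one-codon-species) mRNA with hopping rate k, the
low-density (LD) phase of the extended-particle exclusion process has

    J(α)  = α(k − α) / (k + (w − 1)α)
    ρ(α)  = α / (k + (w − 1)α),      ρ_cov = wρ

up to the maximal-current boundary α = k/(1 + √w), where J saturates at
k/(1 + √w)². These forms are exact in the dilute limit and agree with
exact CTMC enumeration of small lattices to ≲0.1% over the LD domain
(test suite).

**Supply, demand and the bottleneck prediction.** With σ_i = T_i/T_tot
(supply), f_i = Σ_r m_r n_{i,r} / N (demand; n_{i,r} species-i codons on
mRNA r, N total codons) and Q_i = f_i/σ_i, the LD use rate of species i is
U_i(α) = J(α)·N·f_i, evaluated with the position-averaged hopping rate
⟨k⟩ = κ T_tot Σ_i f_i σ_i (arithmetic mean over codon positions; a
harmonic-mean switch exists for sensitivity checks). Species i is
depleted once U_i reaches its maximum recharging rate V_i; inverting the
LD current gives the per-species critical initiation rate α_c,i, with
α_c = min_i α_c,i and the argmin the predicted bottleneck species.
Species whose demand can never reach V_i inside the LD phase are reported
as non-bottlenecks (α_c,i = ∞). To first order α_c,i ≈ V_i/(N f_i), which
is ∝ 1/Q_i when enzyme counts scale with tRNA counts — the species with
the largest demand/supply ratio queues first. For a mono-codon system the
same inversion with f = 1 gives the limited-resources onset α*.

**Fixed-rate bottleneck (QP).** A single slow codon of rate q in a bulk
of rate k causes a sharp queueing transition once the LD current exceeds
the slow site's carrying capacity. We model the capacity by a renewal
argument — each passage costs the service time 1/q plus a headway time
((1+√w)² − 1)/k for the follower to close the w-codon gap:

    J_cap(q, k, w) = 1 / (1/q + ((1+√w)² − 1)/k)

The headway constant is fixed by requiring that q = k recover the uniform
maximal current k/(1+√w)²; the q → 0 limit (capacity → q) is exact.
Exact enumeration of single-defect lattices shows the form is 10–20%
conservative at intermediate q/k — adequate for regime classification,
and the classifier's decisions are validated against direct simulation.
α_QP is the LD-inverse of J_cap; q > k returns ∞ (no bottleneck).

**Designer-mRNA regimes.** For the two-codon designer mRNA (uniform bulk
species 1, one central codon of species 2), whichever threshold is
smallest determines the route: α_c,2 → smooth depletion-induced queueing
of the central species (LR1); α_QP → sharp fixed-rate queueing with full
charging (QP); α_c,1 → depletion of the bulk species with **no** queueing,
because the slow codons then make up the bulk of the mRNA including its
start (LR2).

**Codon usage indices.** RSCU_j = X_j / mean(X over the synonymous
family) from the codon counts X of a designated highly-expressed
reference set; CAI is the geometric mean over an ORF of X_j/X_max within
each family (single-codon families excluded, zero counts replaced by a
0.5 pseudocount, logged). The queueing likelihood index
QLI = geometric mean over codon positions of Q_{s(j)} plays the analogous
role with tRNA availability folded in: high-CAI genes use
high-supply codons and so have low QLI, hence the negative correlation
between the two indices. QLI uses Q itself (not 1/Q); zero-Q codons
(species absent from the demand reference) are floored at half the
smallest positive Q and logged.

## Parameters

All defaults live in `src/ribotraffic/data/defaults.yaml`; nothing is
hard-coded in logic.

| parameter | default | rationale |
|---|---|---|
| ribosome width w | 9 codons | ~30 nt protected footprint |
| mean hopping rate | 10 codons/s | standard yeast elongation estimate |
| termination rate β | 50 s⁻¹ | non-limiting (≫ max k_i ≈ 24 s⁻¹) |
| cell codons / tRNAs | 1.3×10⁷ / 2.9×10⁶ | typical yeast totals; only the ratio ≈ 0.223 enters |
| cell volume | 42 fL | typical haploid yeast cell |
| synthetase k_cat | 10 s⁻¹ | average over measured synthetases |
| synthetase K_M | 0.3 µM | same; uniform-enzyme assumption |
| enzymes per tRNA | 0.18 | proteome-census estimate of synthetase:tRNA ratio |

**Cell-to-simulation scaling.** A simulation of N codons keeps the
cellular tRNA-per-codon ratio (T_tot = 0.223·N, largest-remainder
allocation over species proportional to gene copy numbers, minimum one
molecule each), sets enzyme counts E_i = round(0.18·T_i) (minimum 1,
V_i = k_cat·E_i), and converts K_M to molecules via the *effective
volume* v_eff = (cell volume)·N/(cell codons). Doubling N doubles every
extensive quantity and leaves κT_i, V_i/T_i and all intensive predictions
unchanged (tested). κ is calibrated so that the unweighted mean over tRNA
species of the fully-charged hopping rate κT_i equals the 10 codons/s
target; a codon-usage-weighted mean is available behind a switch, since
the choice of weighting is a genuine modelling degree of freedom.

One consequence of these constants worth knowing: K_M in molecules is
≈ 5.8×10⁻⁴·N while a rare tRNA species holds ≈ 8×10⁻⁴·N molecules, so for
the rarest species the Michaelis constant is comparable to the pool size
and its charging level sits measurably below 1 even well inside the LD
phase. This is a property of the measured constants, not an artifact.

**Time units.** Schedules are specified in simulated seconds of the CTMC
clock, the physically meaningful unit. For comparison with
Monte-Carlo-step bookkeeping, one MCS corresponds to N_codons + T_tot
attempted events.

## Simulation algorithm

Exact (Gillespie) continuous-time sampling: waiting times are exponential
in the total rate and events are chosen exactly proportionally to their
current rates. The numba kernel makes two identical passes over all
channels per event (total, then selection), so sampling is exact
regardless of data layout; the pure-Python reference layer
(`init_state`/`enabled_events`/`step`) implements the same semantics and
is cross-validated against the kernel and against exact enumeration
(below). Identical seeds give bit-identical trajectories. Per-site
occupancies are accumulated by a flush-on-move scheme (dwell time added
when a ribosome leaves a site), charging levels by piecewise-constant
integration between pool changes — both exact time integrals, not event
averages.

## Validation strategy

* **Exact micro-oracles.** `make_oracle_instance` enumerates the full
  CTMC state space of catalogued tiny systems (breadth-first from the
  empty, fully charged state) and solves πQ = 0 directly. Simulated
  currents, density profiles, charging levels and time-weighted state
  occupancies match within 3 SE / total variation 0.02.
* **Closed-form limits.** LD formulas against high-statistics runs (5%)
  and exact enumeration (≲0.1%); depletion onset against the α*
  prediction (±25% band, observed within ~5%); infinite-recharge runs
  against the fixed-rate extended-particle model (two independent code
  paths agree within sampling error).
* **Conservation laws.** a_i + b_i = T_i after every event, reader gaps
  ≥ w, flux equality along each lattice.

## Synthetic data

The generator module creates every input class used by tests and demos;
no external data are required.

* **Packaged ORF fixtures** (`data/synthetic_orfs.fasta`) are *synthetic*
  stand-ins for the four studied yeast ORFs, with the authentic codon
  lengths (110/480/87/560) and engineered supply/demand structure: the
  110-codon "mRNA A" uses no intrinsically slow codons but carries 24
  codons (f ≈ 0.22) of one averagely-abundant species (Glu2, GAA;
  Q ≈ 4.2) with two clusters around positions 70–79, so depletion-induced
  queueing appears behind the clusters; the 480-codon "mRNA B" instead
  scatters intrinsically slow rare-tRNA codons (Arg2, CGG) at ~40-codon
  spacing. They are regenerated deterministically by
  `synthetic.packaged_orf_records()` and the packaged file is asserted to
  match.
* **The tRNA table** (`data/trna_sc.tsv`) lists 41 species with
  approximate S. cerevisiae gene copy numbers (total 270) labelled
  alphabetically (Ala1 … Val3); the codon map assigns each of the 61
  sense codons to exactly one species (Watson–Crick match first,
  otherwise the standard wobble reader) — wobble kinetics themselves are
  deliberately not modelled.
* **The cell-cycle mixture** emulates a 70-species transcriptome in two
  abundance states: ten genes (authentic lengths) swap High/Low copy
  numbers between G1 and G2 (seven High in G1, three in G2); the seven
  G1-High genes share a strong demand (25% of codons) for one low-supply
  tRNA (Ile2/ATA), concentrating demand in G1; sixty background genes in
  three abundance tiers keep fixed copies and near-supply-proportional
  usage (bias 0.9), as expected of typical transcripts. The same tRNA
  pool (sized from the mean of the two phase totals) serves both phases.
  Desk-scale runs use ~7×10⁴ codons — roughly an order of magnitude below
  the cell-scale systems the design emulates — with a 2500 s burn-in
  chosen to pass the first/second-half stationarity check (queue filling
  is the slow mode, ~10³ s).
* **Random gene sets** interpolate log-linearly between uniform codon
  usage (bias 0) and supply-proportional usage (bias 1), giving a
  controlled gradient of codon adaptation for the QLI–CAI analysis.

What the generators do *not* emulate: real yeast codon order and amino
acid composition, UTR/initiation-context effects, wobble rate penalties,
nonuniform synthetase kinetics, and transcriptome-wide demand (the
packaged fixtures sample a few genes, so absolute demand fractions are
larger than genome-wide values). Passing tests therefore demonstrate the
model's internal consistency and the predictive power of the
supply/demand theory under controlled conditions, not genome-scale
quantitative agreement.

## Numerical choices and degenerate inputs

* Largest-remainder rounding everywhere an integer allocation must hit an
  exact total (tRNA counts, mixture copy numbers); ties broken by species
  order; allocation floors at one molecule/copy and errors when the total
  cannot support that.
* α_c inversion is closed-form (the LD current is a quadratic in α); the
  smaller root is taken and demands above the LD maximum give ∞.
* Zero-rate channels (empty pools, starved codons, blocked ribosomes) are
  simply absent from the event catalogue; a total rate of zero (e.g.
  α = 0 from an empty start) advances the clock to the end of the window.
* Stop codons are not lattice sites: terminal stops are trimmed at
  parse time; internal stops error by default (truncation is opt-in).
* Reported seeds are masked to 31 bits before reaching the kernel RNG.

## Known limitations

* The LD-based α_c systematically ignores congestion corrections near the
  maximal-current boundary and the soft depletion caused by K_M ≈ T_i for
  rare species; it is a first-order design tool, which is how it is used.
* The bottleneck-capacity form is 10–20% conservative at intermediate
  q/k (see above).
* Block standard errors assume blocks longer than the slowest
  autocorrelation time; the CLI's stationarity check (first vs second
  half within 2 SE) guards the burn-in choice but long queue-filling
  transients require explicitly generous burn-ins.
* Single-CPU event loop; replicas parallelise only as separate processes
  (independent seeds).
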