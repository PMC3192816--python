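# ribotraffic

Stochastic simulation and analysis of mRNA translation elongation with
**finite, dynamically recharged tRNA pools**.

## The problem

Ribosomes translate mRNAs codon by codon, and the speed of each step
depends on the availability of the matching aminoacylated (charged) tRNA.
Classic traffic models of translation — exclusion processes with fixed,
abundance-derived hopping rates — assume the charged pools never move.
But every elongation step *consumes* a charged tRNA, and synthetases
recharge bare tRNAs at a finite, enzyme-limited rate. When the total
demand for one tRNA species approaches its maximum recharging rate, that
species' charging level collapses, its codons become slow, and ribosome
queues form — even behind codons of an *abundant* tRNA, if demand for it
is high enough. Which codons throttle protein production is therefore set
by the interplay of **supply** (tRNA abundance) and **demand** (codon
usage weighted by mRNA abundance), and mRNAs sharing a tRNA pool compete:
changing the abundance of one transcript class can reshape the production
rates of all the others.

`ribotraffic` is for modellers of translation, codon usage and synthetic
gene design who want (i) an exact kinetic Monte Carlo simulator of this
coupled multi-lattice system and (ii) the closed-form layer that predicts
its bottlenecks without simulation.

## The model in brief

Per mRNA copy, an exclusion process of extended ribosomes (footprint `w`
codons, reader at the rightmost covered codon): initiation at rate α onto
codon 1 when the first `w` codons are clear; elongation out of a
species-`i` codon at rate κ·a_i(t) (a_i = charged count), consuming one
charged tRNA; termination at non-limiting rate β. Per tRNA species, a
Michaelis–Menten recharging channel at rate V_i·b_i/(K_i+b_i). In the
low-density phase of a uniform mRNA,

    J(α) = α(k−α)/(k+(w−1)α),   ρ(α) = α/(k+(w−1)α),

and species `i` is predicted to deplete at the initiation rate α_c,i
where its use rate J(α)·N·f_i meets V_i (N = total codons, f_i = codon
usage fraction). With supply σ_i = T_i/T_tot and demand f_i, the ratio
**Q_i = f_i/σ_i** ranks species by queueing propensity (α_c,i ∝ 1/Q_i to
first order). The per-gene geometric mean of Q is the **queueing
likelihood index (QLI)**, a codon-usage index that anticorrelates with
the classic CAI. Full derivations, parameter defaults and validation
strategy: [docs/methods.md](docs/methods.md).

## Worked example

Forty-five copies of the packaged 110-codon ribosomal-protein-like ORF
(a synthetic stand-in; see `docs/methods.md`), yeast-proportioned tRNA
pools, initiation pushed well above the predicted critical rate:

```python
import ribotraffic as rt
from ribotraffic.analytics import critical_alphas
from ribotraffic.io import packaged_path

code  = rt.load_packaged_codon_map()
table = rt.load_packaged_trna_table()
orfs  = rt.read_orf_fasta(packaged_path("synthetic_orfs.fasta"), code)
seq   = next(s for s in orfs if s.name == "YDR382W_synthetic")

mrnas  = [seq.to_mrna(45)]                       # ~5,000 codons in total
cfg    = rt.SystemConfig.from_defaults(45 * seq.length)
system = rt.build_system(table, mrnas, cfg, alpha=1.0)

ana = critical_alphas(system)
print(f"bottleneck {ana.bottleneck_label}, alpha_c = "
      f"{ana.alpha_c[ana.bottleneck_index]:.3f}, Q = {ana.Q.max():.2f}")

obs = rt.run(system, rt.Schedule(burn_in=300, measure=600), seed=1)
print(f"J = {obs.J[0]:.3f} proteins/mRNA/s")
print(f"ribosomes per codon = {obs.ribosomes_per_codon:.3f}")
print(f"charging of {ana.bottleneck_label} = "
      f"{obs.c[ana.bottleneck_index]:.3f}")
```

Output:

```
bottleneck Glu2, alpha_c = 0.097, Q = 4.23
J = 0.088 proteins/mRNA/s
ribosomes per codon = 0.073
charging of Glu2 = 0.034
```

Reading: the theory picks Glu2 (highest demand/supply ratio, Q ≈ 4.2) as
the species to deplete first, at α_c ≈ 0.1 s⁻¹. At α = 1 s⁻¹ the
simulation confirms it — Glu2 charging has collapsed to 3%, its codons
have become slow, and a queue behind the Glu2 clusters (around codon
70–79) loads the mRNA with ≈ 0.073 ribosomes per codon, an order of
magnitude above the free-flowing value. Re-running with
`infinite_recharge=True` (fixed hopping rates, the classic model) removes
the queue entirely: the depletion dynamics, not the static rates, create
the bottleneck.

## Command line

```bash
ribotraffic fixtures --preset yeast_orfs --out demo/     # inputs + run.yaml
ribotraffic simulate --config demo/run.yaml --seed 1 --out demo/run1/
ribotraffic scan     --config demo/run.yaml --alphas 0.02,0.05,0.1,0.2,0.5 --out demo/scan/
ribotraffic analyze  --fasta demo/orfs.fasta --out demo/ana/
```

Every run directory gets a `manifest.yaml` (resolved config, seed, input
digests) sufficient to reproduce it bit-for-bit.

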