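# tspopet

Biomathematical prediction of in vivo TSPO PET radioligand performance with
multiple binding sites.

The 18 kDa translocator protein (TSPO) is the standard PET target for
neuroinflammation, but the rs6971 polymorphism (Ala147Thr) splits people into
high-, mixed- and low-affinity binders (HABs/MABs/LABs), so the specific
signal of a "2nd-generation" TSPO tracer depends on who is being scanned.
`tspopet` predicts a candidate radioligand's in vivo behaviour *before
radiolabelling* — from in silico and in vitro inputs only — and propagates it
through simulated PET experiments to answer the questions tracer developers
and trialists actually ask:

* What K1, k2 and per-class BP_ND will this ligand show in vivo?
* How reproducible is its BP_ND estimate (%COV under realistic TAC noise)?
* How many subjects does a longitudinal or case–control study need, for a
  given ethnic mix of binding classes, with or without genotyping?

## The model in brief

Brain entry: `log10 P = −0.121(clogD−2.2982)² − 2.544·log10(Vx^⅓) − 2.525`,
`K1 = 3.43·f(1−e^{−PS/f})`, `k2 = (V_aq_P/V_aq_T)·K1·f_ND/f_P`.  Binding, per
class: `BP_ND = f_ND·Bmax_H/Ki_H` (HAB), the two-site sum for MABs, and
`f_ND·Bmax_L/Ki_L` (LAB).  Time-activity curves follow the one-tissue
compartment model `C_T = (1−V_B)K1 e^{−k2 t/(1+BP_ND)} ⊛ C_P + V_B C_B`
(analytic convolution, exact frame averaging), get decayed, noised with
per-frame variance ∝ raw activity / frame duration, and are re-fitted to
recover `BP_ND = V_T/V_ND − 1`.  Sample sizes come from noncentral-t power
(paired or Welch, 90% power, α = 0.05), with a Pitman-A.R.E. Mann–Whitney
correction for mixed-class cohorts.  See `docs/methods.md` for assumptions
and defaults.

## Worked example

```python
import tspopet as tp
from tspopet import BindingClass as BC

records = {r.name: r for r in tp.builtin_ligands()}   # packaged 4-ligand table
kp = tp.predict_kinetics(records["11C-PBR28"])
print(f"K1={kp.k1:.2f}  k2={kp.k2:.2f}  "
      + "  ".join(f"BP_{c.value}={kp.bp_nd[c]:.2f}" for c in BC))

# identifiability of BP_ND for a high-affinity binder under TAC noise
res = tp.cov_bpnd(records["11C-PBR28"], BC.HAB, n=1000, seed=1)
print(f"%COV[BP_ND] = {res.cov_pct:.1f}%")

# longitudinal study: subjects needed to see a 50% TSPO increase
pop = tp.simulate_class_population(records["11C-PBR28"], BC.HAB,
                                   multipliers=(1.0, 1.5), n=1000, seed=1)
r = tp.within_subject_result(pop, 1.5)
print(f"mean dBP={r.mean_effect:.2f}  sd={r.sd_delta:.2f}  n={r.n_required}")
```

prints

```
K1=0.53  k2=0.25  BP_HAB=3.97  BP_MAB=1.95  BP_LAB=0.04
%COV[BP_ND] = 0.8%
mean dBP=2.00  sd=0.49  n=3
```

PBR28 enters the brain well (K1 0.53 vs 0.10 for the reference ligand
(R)-PK11195), gives a strong, highly reproducible specific signal in HABs
(BP_ND ≈ 4, %COV under 1% vs ~36% for PK11195), and a 50% TSPO change is
detectable longitudinally with 3–4 HAB subjects — but its near-zero LAB
signal (BP_ND 0.04) is why genotyping matters for study design.

The same computations are exposed as a CLI that writes one CSV per analysis:

```sh
tspopet --seed 7 --out out predict
tspopet --seed 7 --out out identifiability
tspopet --seed 7 --out out power --design between --unknown-class --ethnicity Caucasian
tspopet --seed 7 --out out tacs --ligand 18F-PBR111 --binding-class MAB
```

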