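# reg1dyn

Dynamical models of stimulus-induced **Regnase-1** regulation, for
systems biologists studying post-transcriptional control of
inflammation. Regnase-1 is an endoribonuclease that destroys
inflammatory mRNAs (*Il6*, its own *Zc3h12a* transcript); inflammatory
signalling both degrades the protein and, via phosphorylation, hands it
to the adaptor 14-3-3. Whether the 14-3-3-bound protein still degrades
its targets is the question this package's analysis machinery decides.

Two four-variable ODE models share the state
(x1, x2, x3, x4) = (*Il6* mRNA, *Zc3h12a* mRNA, free Regnase-1,
14-3-3-bound Regnase-1) and a pulse stimulation signal s(t):

    dx1/dt = k1·s − d1·x1·x3 [− d1′·x1·x4] − d4·x1
    dx2/dt = k2·s − d2·x2·x3 [− d2′·x2·x4] − d5·x2
    dx3/dt = k3·x2 − (d3 + d6·s + d7·s)·x3 + d9·x4
    dx4/dt = d7·s·x3 − (d8 + d9)·x4

Model 1 omits the bracketed terms (bound Regnase-1 inactive); Model 2
keeps them (bound Regnase-1 active). The S513A knock-in genotype, which
cannot bind 14-3-3, is modelled by d7 = d8 = d9 = 0.

The package provides:

* closed-form equilibria for both models and genotypes (a single
  quadratic per branch, governed by the composite constant
  K = (d3 + d6·s + d7·s − d7·d9·s/(d8+d9))/k3, with K ≥ 0 guaranteeing
  existence and uniqueness of the nonnegative fixed point), plus an
  independent numeric root oracle;
* stiff-safe time integration from the resting (basal-equilibrium)
  state under ramp–plateau stimulation;
* the **matched-free-protein discrimination**: imposing the observed
  equality of free Regnase-1 across genotypes, Model 1 predicts
  identical target-mRNA levels while Model 2 forces WT strictly below
  S513A — so the observation "no mRNA difference" rejects Model 2;
* a synthetic-data generator emulating the immunoblot/RT-qPCR design
  (two genotypes × {0, 0.5, 2, 4} h × five observables × replicates,
  mean-1 lognormal noise), and log-least-squares parameter fitting.

## Worked example

```python
from reg1dyn import ModelKind, discriminate
from reg1dyn.defaults import default_parameters

for kind in ModelKind:
    v = discriminate(default_parameters(kind), s_input=1.0, matched_X3=0.4)
    print(kind.value, v.relation_x1.value, v.consistent_with_no_difference)
```

prints

```
model1 equal True
model2 wt_less False
```

With free Regnase-1 pinned to 0.4 in both genotypes, Model 1 predicts
*Il6* mRNA 1.1111 in both (EQUAL → consistent with the observed lack of
difference), while Model 2 predicts 1.0092 in WT vs 1.1111 in S513A
(WT_LESS → inconsistent): only the model in which 14-3-3 binding
inactivates Regnase-1 survives.

The scripts in `examples/` walk through each capability — the pulse
signal and time course (the packaged defaults show total Regnase-1
dipping from 0.305 to 0.266 within 30 min of stimulation and
overshooting to 0.529 by 4 h, with the S513A pool at 84% of WT),
closed-form equilibria vs the numeric oracle, the discrimination
argument end to end, and parameter recovery from synthetic data.

A thin CLI mirrors the stages:

```sh
reg1dyn equilibrium --s-input 1 --residual
reg1dyn simulate --t-end 4 --out tc.csv
reg1dyn discriminate --matched-x3 0.4
reg1dyn synth --cv 0.1 --seed 3 --out obs.csv
reg1dyn reproduce-fig4-argument --seed 5 --out report.json
```

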