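# efadose

**First-principles antibody PKPD models for early feasibility assessment of
clinical dosing.**

At the start of a biotherapeutic program there is no PK or PD data — yet
many go/no-go decisions (is this target druggable at a practical dose?
which of two targets is easier? does the lead need affinity maturation or
half-life extension?) hinge on the likely clinical dose.  `efadose` builds
mechanistic target-mediated drug disposition (TMDD) models entirely from
parameters that *are* available early — binding affinity (Kd), valency,
elimination half-life, molecular weight, target baselines, turnover and
compartmental expression — simulates multi-dose pharmacology, and predicts
the minimal dose that satisfies a pharmacology criterion.  It is written
for quantitative pharmacologists and modelers doing early discovery triage.

## The models

Three mass-action model families cover antagonist antibody pharmacology:

* **1-compartment anti-ligand** — drug D binds a soluble ligand L
  (synthesised at rate k_syn, eliminated at k_deg = ln2/t½) and blocks its
  complex with a cognate receptor R.  The criterion is **ID90**: the
  ligand:receptor complex held ≥90% below its pre-treatment level for an
  entire dosing interval,

      ID(%) = 100 · (1 − max_t [L:R](t) / [L:R]₀).

  A hallmark TMDD effect emerges: short-lived ligand accumulates into
  long-lived drug complexes (half-life extension), so the required trough
  is ≫ Kd — roughly C_trough ≈ (Kd/residual)·(k_deg,L/k_el).

* **2-compartment anti-receptor** — membrane receptor synthesised in
  central and peripheral compartments, optionally shedding a soluble decoy;
  receptor-bound drug is internalised with the receptor (target-mediated
  clearance).  The criterion is **TE98**: ≥98% of membrane target bound by
  drug at the steady-state trough in the peripheral compartment,

      TE(%) = 100 · min_t (drug-bound membrane R) / (total membrane R).

* **2-compartment bispecific (receptor × receptor)** — one arm per target
  with independent Kd's; the dual criterion requires TE98 on *both*
  targets, so the later-saturating arm sets the dose.

Binding uses koff = kon·Kd with identical-independent-site statistics;
synthesis and shedding rates are back-calculated in closed form so the
drug-free steady state reproduces the specified baselines exactly.  See
`docs/methods.md` for the full model description, conventions and numerics.

## Worked example

Five literature-parameterised scenarios ship with the package
(`adalimumab`, `infliximab`, `panitumumab`, `emibetuzumab`,
`amivantamab`).  Predicting the adalimumab dose that sustains 90% TNFα
inhibition (SC every 2 weeks, evaluated on the 7th interval):

```python
import efadose as e

model = e.FeasibilityModel(e.load_builtin("adalimumab"))
pred = model.predict_dose()
print(pred.summary())
```

```
predicted effective dose: 40.65 mg (0.5808 mg/kg)
  criterion: ID90 (n_doses)
  metric at dose: 90.016%  [tnfa: 90.02%]
  search: 18 evaluations, final bracket [40.58, 40.73] mg, rel_tol 0.005
```

The model, parameterised only from literature biophysics, lands at 40.65 mg
— essentially the approved 40 mg Q2W dose.  The drug exposure needed is far
above what a potency comparison would suggest:

```python
tc = model.simulate(dose_mg=pred.dose_mg)
print(e.pk_summary(tc))
```

```
Cmax 116.7 nM (17.27 ug/ml); Ctrough 93.74 nM (13.87 ug/ml)
```

A 93.7 nM trough is ~10⁴ × the 8.6 pM Kd: drug binding extends the
half-life of TNFα from 30 minutes to the antibody's 20 days, and the
accumulated total ligand must still be outcompeted at trough — the
mechanistic reason simple exposure/potency reasoning fails for short-lived
soluble targets.

The same analyses run from the shell:

```bash
efadose predict-dose --scenario adalimumab                  # ID90 dose
efadose pk-check --scenario panitumumab --dose-mg-per-kg 6 --n-doses 3
efadose sensitivity --scenario infliximab                   # OAT tornado scan
efadose dose-response --scenario amivantamab --doses 100,300,1000
efadose simulate --scenario emibetuzumab --out-dir out/     # tidy time course
efadose expression --populations cells.csv --volume peripheral=13
```

`sensitivity` re-solves the effective dose with every scenario parameter
varied 3-fold down/up and flags parameters spanning >3-fold in dose — for
the anti-TNF models this singles out binding Kd, ligand half-life,
molecular weight and compartment volume (plus drug half-life for the
8-weekly regimen only), telling an early program which measurements matter.

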