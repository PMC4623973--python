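# protolink

Proton-linkage analysis of titration and pH-dependent ligand binding:
constant-pH Metropolis Monte Carlo with pH replica exchange over discrete
multi-site protonation models, Hill-equation pKa estimation, and Wyman
binding-polynomial computation of pH-dependent binding free energies — with
exact-enumeration and closed-form oracles for every numerical route.

## Who this is for

Enzymes such as aspartyl proteases couple catalysis and inhibitor binding to
the protonation of active-site residues: the catalytic dyad titrates
cooperatively, bound inhibitors shift its pKa by several units, and the
binding free energy consequently varies by many kcal/mol across the
physiological pH range. Production studies of these effects run constant-pH
molecular dynamics with pH replica exchange on GPUs; the *analysis* layer of
such studies — converting sampled protonation states into pKa values, Hill
coefficients, proton-count curves, and pH-dependent binding free energies —
is general and exactly testable at desk scale. `protolink` implements that
layer over a configurable discrete protonation Hamiltonian with a built-in
sampler, so every statistic the pipeline produces can be validated against an
exactly enumerable truth.

## The model and the statistics

A species is a set of two-state titratable sites, discrete conformers, and
pairwise couplings, with microstate energy

    G(x, c, pH) = E_base(c) + Σ_i x_i [kT ln10 (pH − pKa_ref,i) + δ_i(c)]
                + Σ_(a,b) J_ab(c) x_a x_b

Sampling uses Metropolis protonation flips and conformer moves, with replicas
at a ladder of pH values exchanging pH assignments with probability
`min{1, exp[ln10 (N_i − N_j)(pH_i − pH_j)]}`. Per-site deprotonated fractions
s(pH) are fitted to the Hill equation `s = 1/(1 + 10^{n(pKa − pH)})`, and the
Wyman linkage relation turns proton-count differences between complex and
free protein, ΔZ(pH) = Z_PL − Z_P − Z_L, into a binding free-energy profile

    ΔG°(pH) = ΔG°_ref + kT ln10 ∫_{pH_ref}^{pH} ΔZ(pH') dpH'

anchored at a reference measurement (default pH 4.5). See
[docs/methods.md](docs/methods.md) for assumptions, numerics, and diagnostics.

## Worked example

The `bace_like` preset pair emulates an aspartyl-protease active site: ten
titratable residues, an open/closed flap conformer, an anticooperatively
coupled Asp dyad, and a holo variant whose bound inhibitor favours the
protonated dyad and the closed flap.

```sh
protolink preset bace_like -o models
protolink simulate models/bace_like_apo.yaml  -o apo.csv  --seed 1
protolink simulate models/bace_like_holo.yaml -o holo.csv --seed 2
protolink demux apo.csv  -o apo_frac.csv
protolink demux holo.csv -o holo_frac.csv
protolink fit apo.csv  -o apo_pka.csv
protolink fit holo.csv -o holo_pka.csv
protolink dg apo_frac.csv holo_frac.csv --dg-ref -13.0 --ph-ref 4.5 -o profile.csv
```

The apo fit prints (abridged):

```
site        pKa               (Hill n)
Asp228      4.60 ± 0.00  (0.67)
Asp32       4.58 ± 0.00  (0.67)
Glu116      4.37 ± 0.00  (1.03)
Tyr71       9.60 ± 0.00  (1.02)
```

and the holo fit:

```
site        pKa               (Hill n)
Asp228      9.15 ± 0.00  (0.44)
Asp32       9.23 ± 0.00  (0.43)
Glu116      4.40 ± 0.00  (0.99)
Tyr71       9.61 ± 0.00  (1.00)
```

Reading: the uncoupled residues titrate at their model-compound values with
Hill n ≈ 1, while the dyad titrates anticooperatively (n < 1) around pH 4.6
in the free enzyme and is pushed up by ≈ +4.6 pK units by the bound
inhibitor. The profile CSV (`pH,deltaZ,ddG_vs_ref,dG`) then shows binding
weakening as the dyad deprotonates:

```
pH,deltaZ,ddG_vs_ref,dG
4.0,0.6519,-0.551,-13.551
10.0,0.7512,10.655,-2.345
12.0,0.0292,11.515,-1.485
```

i.e. relative to the pH 4.5 reference of −13.0 kcal/mol, binding is ≈ 11.5
kcal/mol weaker at pH 12 — the error a fixed-protonation treatment would make
is the subject of `protolink scenario --fix Asp32=prot --fix Asp228=prot ...`,
which clamps the dyad in both species and reports the deviation per pH.

The same pipeline is available in-process (`run_ph_remd`, `demultiplex`,
`fit_hill`, `pka_table`, `delta_z`, `integrate_profile`, ...), along with the
exact oracles (`enumerate_states`, `exact_profile_from_models`,
`closed_form_single_site`) used throughout the test suite.

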