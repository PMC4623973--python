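# Methods

## The model

`protolink` studies proton-linked conformational and binding equilibria on a
discrete Hamiltonian. A species (a free protein "apo", or a protein-ligand
complex "holo") is a `SystemModel`: a set of two-state titratable sites, a set
of discrete conformers, and pairwise couplings. A microstate is a protonation
bit-vector `x` plus a conformer `c`, with semi-grand free energy

    G(x, c, pH) = E_base(c)
                + Σ_i x_i [ kT ln10 (pH − pKa_ref,i) + δ_i(c) ]
                + Σ_(a,b) J_ab(c) x_a x_b                              (kcal/mol)

The first per-site term is the model-compound transition free energy for
protonating site *i* (deprotonated → protonated); at `pH = pKa_ref` it
vanishes, so an isolated unshifted site titrates along a Henderson–Hasselbalch
curve centered at its reference pKa (defaults: Asp 4.0, Glu 4.4, His 6.5,
Tyr 9.6, Lys 10.4). The intrinsic shift `δ_i(c)` and the both-protonated
coupling `J_ab(c)` are a discrete stand-in for the environment-induced
electrostatic free-energy difference relative to the model compound that a
continuum-electrostatics treatment would supply. This class is deliberately
minimal but reproduces every qualitative behaviour the analysis stack is built
to measure: apparent-pKa shifts (`ΔpKa = −δ/(kT ln10)` for a lone site),
anticooperative coupled titration (Hill n < 1 for a both-protonated penalty),
and pH-dependent conformer switching (conformer-dependent shifts).

Histidine is modeled as a single two-state site at pKa_ref 6.5; the tautomer
pair is not represented — the analyses here never resolve tautomers, so a
three-state site would add state-space without measurable payoff. Ligands are
assumed not to titrate in the pH range of interest, so Z_L ≡ 0.

Constants: k_B = 1.9872041e-3 kcal/(mol·K), default T = 300 K, hence
kT ln10 ≈ 1.37271 kcal/mol (one pH unit of proton chemical potential).
`Z` throughout is the mean count of bound titratable protons, not a net
charge; only differences ΔZ enter the linkage relations, so additive offsets
cancel and acid/base sign conventions are irrelevant.

## Exact oracles

Because the state space is `2^|sites| × |conformers|` (guarded at 2^22),
everything has an exact counterpart by direct enumeration: Boltzmann
probabilities, per-site deprotonated fractions, mean proton counts Z(pH), and
the log binding polynomial `ln Q(pH)` taken relative to the fully deprotonated
state in the lowest-base-energy conformer, which satisfies
`d(lnQ)/dpH = −ln10·Z(pH)`. Every stochastic or numerical route in the
package is tested against these oracles rather than against itself.

## Constant-pH Monte Carlo and pH replica exchange

Each replica holds a microstate and a pH. An attempt is a conformer move with
probability 0.1 (uniform proposal over the other conformers, Metropolis on the
energy difference at fixed protonation) and otherwise a single-site protonation
flip (site uniform, Metropolis on the flip free energy). A protonation-only MC
with discrete conformer moves replaces the "dynamics between titration
attempts" of constant-pH molecular dynamics; the conformer variable is the
surrogate conformational coordinate.

Every 100 attempts, adjacent replicas on the pH ladder attempt to swap pH
assignments with probability `min{1, exp[ln10 (N_i − N_j)(pH_i − pH_j)]}`,
with N the proton counts before the attempt; configurations are untouched by a
swap. Since G is affine in pH with slope `kT ln10 · N`, this acceptance rule
satisfies detailed balance for the joint ensemble. Sweeps alternate between
even- and odd-rooted adjacent pairings so that all neighbour pairs are visited
— the standard ergodic nearest-neighbour scheme.

Defaults (all overridable): ladder pH 1–12 in steps of 1; 6×10^4 attempts per
replica with the first 1/6 discarded as burn-in (5×10^4 recorded); exchange
interval 100; thinning 1. Initial states are deterministic (sites protonated
when `pKa_ref > pH`, lowest-base-energy conformer); the burn-in comfortably
erases them for the enumerable systems studied here (relaxation times are of
order tens of attempts). RNG streams: `default_rng([seed, 0, replica_index])`
per replica and `[seed, 1]` for exchanges, so the replica count never perturbs
existing streams and identical `(model, ladder, schedule, seed)` reproduce
ledgers bit-for-bit.

## Presets (what the synthetic data emulates)

- `single_site(<class>)`: the model compound; exact Henderson–Hasselbalch.
- `coupled_dyad`: two Asp sites with a +2 kT ln10 both-protonated penalty —
  the minimal anticooperative pair (per-site Hill n ≈ 0.66 by enumeration).
- `bace_like` apo/holo: ten sites (5 Asp, 3 Glu, 1 His, 1 Tyr) mirroring a
  titrated active-site neighbourhood of an aspartyl protease, with an
  open/closed conformer pair as the flap surrogate. Apo: closed base energy
  +1.5 kcal/mol, dyad coupling +2 kT ln10, and −3 kcal/mol closed-conformer
  stabilization per protonated dyad site, making the closed flap dominant at
  acidic pH (population ≈ 0.99 at pH ≤ 3) and rare at basic pH (≈ 0.08).
  Holo: additionally −5.5 kcal/mol intrinsic shift per dyad site (raising the
  apparent dyad pKa from ≈ 4.6 to ≈ 9.2, i.e. a binding-induced shift of
  ≈ +4.6 pK units, the scale reported for inhibitor-bound aspartyl proteases)
  and closed base energy −1.5 kcal/mol, representing an inhibitor that locks
  the flap closed at every pH. These parameters are fixed properties of the
  presets, chosen once to place the emulated system in the regimes the
  analyses are designed to detect.

What the generator does *not* emulate: continuous conformational coordinates,
Cartesian structure, explicit electrostatics, tautomers, and the slow
collective relaxations of a real protein. Passing tests therefore demonstrate
the correctness of the sampling and analysis machinery on models whose truth
is exactly computable — not the accuracy of any particular force field or
solvent model on real proteins.

## Titration analysis

Per-pH deprotonated fractions come from counting recorded protonation bits in
the demultiplexed per-pH streams. The Hill equation
`s(pH) = 1/(1 + 10^{n(pKa − pH)})` is fitted by unweighted nonlinear least
squares on s (initial pKa at the half-titration grid point, initial n = 1,
bounds n ∈ (0.05, 5], pKa within the grid ± 5). Curves that never leave one
tail are flagged non-converged instead of raising, so summary tables always
render.

Standard errors: when per-pH counts are available the reported SEs are the
heteroskedasticity-consistent (sandwich) covariance of the unweighted
estimator with per-point binomial variances `p(1−p)/n` evaluated at the fitted
curve — the homoskedastic RSS-based covariance is badly anti-conservative for
binomial noise because the tail points have near-zero variance (measured
coverage of ±3 SE was ~50% with the RSS covariance and ≥ 99% with the
sandwich, over 200 replicates per parameter cell). Without counts, the
RSS-based covariance is used. For MC-derived curves the binomial variances
ignore sample autocorrelation, so those SEs are optimistic by the square root
of the autocorrelation time; the oracle comparisons below use exact variances
instead.

## Oracle comparison statistics

Fractions sampled by MC are compared to enumeration cell-by-cell (site × pH).
The sampling variance of each cell uses the Markov-chain central-limit
variance computed exactly from the fixed-pH attempt kernel (a Poisson-equation
solve over the enumerable state space with rank-one centering) — not an
empirical autocorrelation estimate, which is unreliable exactly where it
matters (extreme pH, where deprotonation events are rare). A cell agrees when
`|s_mc − s_exact| ≤ 3·SE + 3·τ/n`: the second term is a discreteness
allowance, because deprotonation arrives in excursions of mean length ~τ
attempts, so with fewer than ~1 expected excursions per run the sampled
fraction moves in quanta of τ/n and a pure normal band is violated by single
rare excursions even for an unbiased sampler (verified: all such cells
collapse to |z| < 0.5 when runs are extended 10×). In the titrating bulk of
the curve the allowance is negligible compared to the SE. The exchange on/off
comparison (detailed-balance check) uses the same kernel variances in
two-proportion z tests, Bonferroni-corrected at family level α = 0.01, with
the analogous allowance as a minimum practical difference.

## Binding free energy profiles

The Wyman linkage relation `∂lnK_app/∂ln[H+] = ΔZ` with `ln[H+] = −ln10·pH`
and `ΔG = −kT·lnK_app` gives

    dG(pH) = dG_ref + kT ln10 ∫_{pH_ref}^{pH} ΔZ(pH') dpH'

anchored at a reference binding free energy measured at `pH_ref` (default
4.5). The sign is fixed by the single-site closed form (the ratio of two-state
binding polynomials): differentiating it yields `d(dG)/dpH = +kT ln10 ΔZ`, so
binding weakens with rising pH wherever the complex takes up protons on
binding — matching the physical picture of inhibitors that bind most strongly
at acidic pH.

Numerics: ΔZ is interpolated between grid points by a shape-preserving
piecewise cubic (PCHIP) and integrated by composite Simpson on a 10×-refined
grid. Accuracy is interpolation-limited, not quadrature-limited: against the
closed form, the maximum profile error is ≈ 0.03 kcal/mol for knots at 1 pH
unit, 1.3e-5 at 0.125 units. Oracle-equivalence checks therefore evaluate
exact fractions on a 0.125-unit grid; profiles built from simulated 1-unit
ladders inherit the ~0.03 kcal/mol interpolation uncertainty, which is far
below sampling noise in practice. Profiles are never extrapolated beyond the
input grid span. An optional mode integrates fitted Hill curves instead of raw
per-pH means (`dg --mode hill`); raw means are the default since they make no
shape assumption.

Profiles built by the package carry a continuous evaluator over their span;
the Wyman self-consistency residual `max |d(dG)/dpH − kT ln10 ΔZ|` is then a
central finite difference through that evaluator (step 1e-3, error ~1e-7).
Profiles reconstructed from bare arrays are checked by finite differences on
the knot grid, which is what makes a corrupted knot visible.

The fixed-protonation-state scenario clamps named sites to one state in both
species (their ΔZ contribution becomes zero) and reports the per-pH deviation
from the full profile — the error committed by assigning static protonation
states before a binding free-energy calculation. On the `bace_like` pair the
full profile rises by ≈ 9 kcal/mol between pH 4.5 and 10 while the clamped
profile stays flat, so the scenario's error grows to the size of the linkage
effect itself.

## Known limitations

- The Hamiltonian is discrete; nothing here validates continuum-electrostatic
  or force-field accuracy on real structures.
- Exact-kernel comparison statistics require enumerable models; for larger
  systems only empirical (Sokal) autocorrelation estimates are available.
- MC-derived Hill-fit SEs ignore autocorrelation (see above).
- Ligand titration is out of scope (Z_L ≡ 0); a titrating ligand would need
  its own `SystemModel` and a third charge curve.
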