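"""Discrete multi-site protonation models and exact statistical-mechanical oracles.

A :class:`SystemModel` describes a molecule (or complex) as a set of two-state
titratable sites, a set of discrete conformers, and pairwise coupling energies.
The semi-grand-canonical energy of a microstate ``(x, c)`` — protonation
bit-vector ``x`` and conformer ``c`` — at a given pH is

    G(x, c, pH) = E_base(c)
                + sum_i x_i * [ kT ln10 (pH - pKa_ref_i) + delta_i(c) ]
                + sum_{(a,b)} J_ab(c) x_a x_b

where ``delta_i(c)`` is a conformer-dependent intrinsic protonation shift and
``J_ab(c)`` is added when both sites of a coupled pair are protonated.  The
``kT ln10 (pH - pKa_ref)`` term is the model-compound transition free energy
for the deprotonated -> protonated direction, so an isolated unshifted site
titrates along a Henderson-Hasselbalch curve with midpoint ``pKa_ref``.

The intrinsic shifts and couplings stand in for the environment-induced
electrostatic free-energy difference relative to the model compound; a shift
``delta`` moves the apparent pKa by ``-delta / (kT ln10)``.

Everything here is exactly enumerable (up to a guard on the state-space size),
which is what makes this module the oracle for the Monte Carlo engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "BOLTZMANN_KCAL",
    "ThermoParams",
    "SiteSpec",
    "ConformerSpec",
    "CouplingTerm",
    "SystemModel",
    "Microstate",
    "ModelError",
    "DEFAULT_PKA_REF",
    "validate_model",
    "microstate_energy",
    "enumerate_states",
    "ExactDistribution",
    "exact_site_fraction",
    "exact_mean_protons",
    "binding_polynomial_ln",
]

#: Boltzmann constant in kcal/(mol K).
BOLTZMANN_KCAL = 1.9872041e-3

#: Model-compound reference pKa values by residue class.
DEFAULT_PKA_REF = {"Asp": 4.0, "Glu": 4.4, "His": 6.5, "Tyr": 9.6, "Lys": 10.4}

#: Largest enumerable state space: 2^|sites| * |conformers|.
MAX_ENUMERABLE_STATES = 2**22


class ModelError(ValueError):
    """Raised for structurally invalid models or unresolvable references."""


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and derived thermal energies.

    kT and kT_ln10 are in kcal/mol; at the default 300 K,
    kT ln10 ~= 1.37271 kcal/mol (one pH unit of proton chemical potential).
    """

    temperature: float = 300.0
    boltzmann_constant: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ModelError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        return self.boltzmann_constant * self.temperature

    @property
    def kT_ln10(self) -> float:
        return self.kT * math.log(10.0)


@dataclass(frozen=True)
class SiteSpec:
    """One two-state titratable site.

    ``intrinsic_shift`` maps conformer_id -> energy (kcal/mol) added when the
    site is protonated in that conformer; missing conformers mean zero shift.
    ``pKa_ref`` of None is filled from ``residue_class`` during validation.
    """

    site_id: str
    residue_class: str = "custom"
    pKa_ref: float | None = None
    intrinsic_shift: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConformerSpec:
    """A discrete conformer with a protonation-independent base energy."""

    conformer_id: str
    base_energy: float = 0.0


@dataclass(frozen=True)
class CouplingTerm:
    """Pairwise energy added when both named sites are protonated.

    ``conformer_scope`` restricts the term to one conformer, or "all".
    """

    site_a: str
    site_b: str
    energy: float
    conformer_scope: str = "all"


@dataclass(frozen=True)
class Microstate:
    """A protonation bit-vector (1 = protonated, canonical site order) plus a conformer."""

    protonation: tuple[int, ...]
    conformer: str

    @property
    def n_protons(self) -> int:
        return int(sum(self.protonation))


@dataclass(frozen=True)
class SystemModel:
    """A titratable species: sites, conformers, couplings, and thermodynamics."""

    label: str
    sites: tuple[SiteSpec, ...]
    conformers: tuple[ConformerSpec, ...]
    couplings: tuple[CouplingTerm, ...] = ()
    thermo: ThermoParams = field(default_factory=ThermoParams)
    validated: bool = False

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    @property
    def conformer_ids(self) -> tuple[str, ...]:
        return tuple(c.conformer_id for c in self.conformers)

    @property
    def n_states(self) -> int:
        return (2 ** len(self.sites)) * len(self.conformers)

    def site_index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise ModelError(f"unknown site_id {site_id!r} in model {self.label!r}") from None

    def conformer_index(self, conformer_id: str) -> int:
        try:
            return self.conformer_ids.index(conformer_id)
        except ValueError:
            raise ModelError(
                f"unknown conformer_id {conformer_id!r} in model {self.label!r}"
            ) from None


def validate_model(model: SystemModel) -> SystemModel:
    """Check structural invariants, fill defaults, and canonicalize site order.

    Sites are sorted lexicographically by site_id; ``pKa_ref`` defaults are
    filled from ``residue_class``; missing ``intrinsic_shift`` conformer
    entries become 0.  Raises :class:`ModelError` on duplicate ids, dangling
    references, non-finite energies, or an empty conformer list.
    """
    if len(model.conformers) == 0:
        raise ModelError(f"model {model.label!r}: zero conformers")
    conf_ids = [c.conformer_id for c in model.conformers]
    if len(set(conf_ids)) != len(conf_ids):
        raise ModelError(f"model {model.label!r}: duplicate conformer_id")
    for c in model.conformers:
        if not math.isfinite(c.base_energy):
            raise ModelError(f"conformer {c.conformer_id!r}: non-finite base_energy")

    site_ids = [s.site_id for s in model.sites]
    if len(set(site_ids)) != len(site_ids):
        dupes = sorted({i for i in site_ids if site_ids.count(i) > 1})
        raise ModelError(f"model {model.label!r}: duplicate site_id {dupes}")

    new_sites = []
    for s in sorted(model.sites, key=lambda s: s.site_id):
        pka = s.pKa_ref
        if pka is None:
            if s.residue_class not in DEFAULT_PKA_REF:
                raise ModelError(
                    f"site {s.site_id!r}: no pKa_ref and no default for "
                    f"residue_class {s.residue_class!r}"
                )
            pka = DEFAULT_PKA_REF[s.residue_class]
        if not math.isfinite(pka):
            raise ModelError(f"site {s.site_id!r}: non-finite pKa_ref")
        for cid in s.intrinsic_shift:
            if cid not in conf_ids:
                raise ModelError(
                    f"site {s.site_id!r}: intrinsic_shift references unknown conformer {cid!r}"
                )
        shift = {cid: float(s.intrinsic_shift.get(cid, 0.0)) for cid in conf_ids}
        if any(not math.isfinite(v) for v in shift.values()):
            raise ModelError(f"site {s.site_id!r}: non-finite intrinsic_shift")
        new_sites.append(replace(s, pKa_ref=float(pka), intrinsic_shift=shift))

    seen_pairs: set[tuple[str, str, str]] = set()
    for cp in model.couplings:
        if cp.site_a == cp.site_b:
            raise ModelError(f"coupling references the same site twice: {cp.site_a!r}")
        for sid in (cp.site_a, cp.site_b):
            if sid not in site_ids:
                raise ModelError(f"coupling references unknown site {sid!r}")
        if cp.conformer_scope != "all" and cp.conformer_scope not in conf_ids:
            raise ModelError(
                f"coupling {cp.site_a!r}-{cp.site_b!r}: unknown conformer_scope "
                f"{cp.conformer_scope!r}"
            )
        if not math.isfinite(cp.energy):
            raise ModelError(f"coupling {cp.site_a!r}-{cp.site_b!r}: non-finite energy")
        key = (*sorted((cp.site_a, cp.site_b)), cp.conformer_scope)
        if key in seen_pairs:
            raise ModelError(f"duplicate coupling for pair {key[0]!r}-{key[1]!r} ({key[2]})")
        seen_pairs.add(key)

    return replace(model, sites=tuple(new_sites), validated=True)


def _require_validated(model: SystemModel) -> SystemModel:
    return model if model.validated else validate_model(model)


# ---------------------------------------------------------------------------
# Energy evaluation


def _energy_tables(model: SystemModel):
    """Per-conformer arrays: (pKa_ref[s], shift[c][s], coupling list[c], base[c]).

    Couplings are returned per conformer as (idx_a, idx_b, energy) triples with
    "all"-scoped terms included in every conformer.
    """
    n = len(model.sites)
    pka = np.array([s.pKa_ref for s in model.sites], dtype=float)
    shifts = []
    coups = []
    base = []
    for conf in model.conformers:
        cid = conf.conformer_id
        shifts.append(np.array([s.intrinsic_shift.get(cid, 0.0) for s in model.sites]))
        triples = []
        for cp in model.couplings:
            if cp.conformer_scope in ("all", cid):
                triples.append((model.site_index(cp.site_a), model.site_index(cp.site_b), cp.energy))
        coups.append(triples)
        base.append(conf.base_energy)
    return pka, shifts, coups, np.array(base, dtype=float), n


def microstate_energy(model: SystemModel, state: Microstate, pH: float) -> float:
    """Semi-grand free energy G(x, c, pH) in kcal/mol.

    The fully deprotonated state in a zero-base-energy conformer has energy 0;
    the energy change of flipping one site reproduces the model-compound
    transition free energy plus the discrete environment terms.
    """
    model = _require_validated(model)
    if not math.isfinite(pH):
        raise ModelError(f"pH must be finite, got {pH}")
    if len(state.protonation) != len(model.sites):
        raise ModelError(
            f"protonation vector length {len(state.protonation)} != {len(model.sites)} sites"
        )
    ci = model.conformer_index(state.conformer)
    pka, shifts, coups, base, _ = _energy_tables(model)
    x = np.asarray(state.protonation, dtype=float)
    kT_ln10 = model.thermo.kT_ln10
    e = base[ci] + float(x @ (kT_ln10 * (pH - pka) + shifts[ci]))
    for a, b, j in coups[ci]:
        if state.protonation[a] and state.protonation[b]:
            e += j
    return e


# ---------------------------------------------------------------------------
# Exact enumeration


@dataclass(frozen=True)
class ExactDistribution:
    """Exact Boltzmann distribution over every microstate of a model at one pH.

    ``mask`` holds protonation bit-vectors encoded as integers (bit i = site i
    in canonical order), ``conformer`` the conformer index, ``log_weight`` the
    unnormalized -G/kT relative to the reference state (fully deprotonated,
    lowest-base-energy conformer), and ``prob`` the normalized probabilities.
    """

    model: SystemModel
    pH: float
    mask: np.ndarray
    conformer: np.ndarray
    log_weight: np.ndarray
    prob: np.ndarray

    @property
    def ln_Q(self) -> float:
        """Log binding polynomial: ln sum over states of exp(-(G - G_ref)/kT)."""
        return float(logsumexp(self.log_weight))

    def site_fraction_deprotonated(self, site_id: str) -> float:
        i = self.model.site_index(site_id)
        deprot = (self.mask >> i) & 1 == 0
        return float(self.prob[deprot].sum())

    def mean_protons(self) -> float:
        n = len(self.model.sites)
        counts = np.zeros_like(self.prob)
        for i in range(n):
            counts += (self.mask >> i) & 1
        return float(self.prob @ counts)

    def conformer_populations(self) -> dict[str, float]:
        return {
            cid: float(self.prob[self.conformer == k].sum())
            for k, cid in enumerate(self.model.conformer_ids)
        }

    def probability(self, state: Microstate) -> float:
        m = sum(b << i for i, b in enumerate(state.protonation))
        k = self.model.conformer_index(state.conformer)
        sel = (self.mask == m) & (self.conformer == k)
        return float(self.prob[sel].sum())


def enumerate_states(model: SystemModel, pH: float) -> ExactDistribution:
    """Enumerate all 2^|sites| * |conformers| microstates and their exact probabilities.

    Probabilities are proportional to exp(-G/kT) and sum to one to machine
    precision.  Guarded at 2^22 states.
    """
    model = _require_validated(model)
    if model.n_states > MAX_ENUMERABLE_STATES:
        raise ModelError(
            f"state space too large to enumerate: {model.n_states} > {MAX_ENUMERABLE_STATES}"
        )
    pka, shifts, coups, base, n = _energy_tables(model)
    kT = model.thermo.kT
    kT_ln10 = model.thermo.kT_ln10

    masks = np.arange(2**n, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(float)  # (2^n, n)
    site_terms = kT_ln10 * (pH - pka)  # (n,)

    all_masks, all_confs, all_logw = [], [], []
    base_ref = float(np.min(base))
    for k in range(len(model.conformers)):
        g = base[k] - base_ref + bits @ (site_terms + shifts[k])
        for a, b, j in coups[k]:
            g = g + j * bits[:, a] * bits[:, b]
        all_masks.append(masks)
        all_confs.append(np.full(masks.shape, k, dtype=np.int64))
        all_logw.append(-g / kT)
    mask = np.concatenate(all_masks)
    conformer = np.concatenate(all_confs)
    logw = np.concatenate(all_logw)
    logZ = logsumexp(logw)
    prob = np.exp(logw - logZ)
    prob /= prob.sum()  # clean up last-bit normalization
    return ExactDistribution(
        model=model, pH=pH, mask=mask, conformer=conformer, log_weight=logw, prob=prob
    )


def exact_site_fraction(model: SystemModel, pH: float, site_id: str) -> float:
    """Exact fraction of the ensemble with ``site_id`` deprotonated, in [0, 1]."""
    return enumerate_states(model, pH).site_fraction_deprotonated(site_id)


def exact_mean_protons(model: SystemModel, pH: float) -> float:
    """Exact mean number of bound titratable protons Z(pH)."""
    return enumerate_states(model, pH).mean_protons()


def binding_polynomial_ln(model: SystemModel, pH: float) -> float:
    """ln Q(pH): log of the Wyman binding polynomial.

    Q sums exp(-(G - G_ref)/kT) over all microstates with the reference state
    fully deprotonated in the lowest-base-energy conformer, so
    d(ln Q)/d(pH) = -ln10 * Z(pH).
    """
    return enumerate_states(model, pH).ln_Q
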