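"""Constant-pH Metropolis Monte Carlo with pH replica exchange.

Each replica holds a microstate (protonation bit-vector + conformer) and a pH.
An attempt is either a single-site protonation flip (accepted by Metropolis on
the transition free energy of the flip) or, with probability
``conformer_move_prob``, a jump to a uniformly chosen different conformer at
fixed protonation.  Every ``exchange_interval`` attempts, adjacent replicas on
the pH ladder attempt to swap pH assignments with probability

    P(i <-> j) = min{1, exp[ln10 (N_i - N_j)(pH_i - pH_j)]}

where N is the number of titratable protons bound before the attempt; the
configurations themselves are untouched by a swap.  Sweeps alternate between
even- and odd-rooted adjacent pairings so every neighbor pair is visited.

Reproducibility: the root seed keys independent per-replica RNG streams via
``default_rng([seed, 0, replica_index])`` and an exchange stream via
``default_rng([seed, 1])``, so adding replicas never perturbs existing
streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .model import Microstate, ModelError, SystemModel, _energy_tables, _require_validated

__all__ = [
    "MCSchedule",
    "ReplicaState",
    "SampleLedger",
    "ExchangeStats",
    "DEFAULT_LADDER",
    "attempt_protonation_move",
    "attempt_conformer_move",
    "exchange_probability",
    "run_fixed_ph",
    "run_ph_remd",
    "demultiplex",
]

#: Default pH ladder: 1..12 in steps of one pH unit.
DEFAULT_LADDER = tuple(float(p) for p in range(1, 13))

LN10 = math.log(10.0)


@dataclass(frozen=True)
class MCSchedule:
    """Move counts, proposal mix, exchange cadence, burn-in, thinning, seed.

    Defaults: 6e4 attempts per replica with 1/6 burn-in (5e4 recorded),
    exchange sweeps every 100 attempts, 10% conformer moves, no thinning.
    """

    n_attempts: int = 60_000
    conformer_move_prob: float = 0.1
    exchange_interval: int = 100
    burn_in_fraction: float = 1.0 / 6.0
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_attempts < 1:
            raise ValueError("n_attempts must be >= 1")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if not (0.0 <= self.conformer_move_prob <= 1.0):
            raise ValueError("conformer_move_prob must be in [0, 1]")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def burn_in_attempts(self) -> int:
        return int(self.burn_in_fraction * self.n_attempts)

    def to_dict(self) -> dict:
        return {
            "n_attempts": self.n_attempts,
            "conformer_move_prob": self.conformer_move_prob,
            "exchange_interval": self.exchange_interval,
            "burn_in_fraction": self.burn_in_fraction,
            "thin": self.thin,
            "seed": self.seed,
        }


@dataclass
class ReplicaState:
    """One replica of the simulation: its pH assignment and current microstate."""

    replica_id: int
    current_pH: float
    mask: int          # protonation bits, bit i = site i in canonical order
    conformer: int     # index into model.conformer_ids
    n_protons: int

    def microstate(self, model: SystemModel) -> Microstate:
        n = len(model.sites)
        bits = tuple((self.mask >> i) & 1 for i in range(n))
        return Microstate(protonation=bits, conformer=model.conformer_ids[self.conformer])


@dataclass
class SampleLedger:
    """Recorded MC samples: one row per (replica, recorded attempt).

    Columns are parallel numpy arrays; protonation is stored as an integer
    bitmask over the canonical site order and rendered as a 0/1 string only
    on CSV export.  Metadata captures everything needed to reproduce the run.
    """

    replica: np.ndarray
    attempt: np.ndarray
    pH: np.ndarray
    conformer: np.ndarray
    mask: np.ndarray
    n_protons: np.ndarray
    model_label: str
    site_order: tuple[str, ...]
    conformer_order: tuple[str, ...]
    ladder: tuple[float, ...]
    seed: int
    schedule: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.replica)

    def site_bits(self, site_id: str) -> np.ndarray:
        """0/1 protonation array for one site across all rows."""
        try:
            i = self.site_order.index(site_id)
        except ValueError:
            raise ModelError(f"unknown site_id {site_id!r} in ledger") from None
        return ((self.mask >> i) & 1).astype(np.int8)

    def protonation_strings(self) -> list[str]:
        n = len(self.site_order)
        return [format(int(m), f"0{n}b")[::-1] for m in self.mask]

    def select(self, keep: np.ndarray) -> "SampleLedger":
        return SampleLedger(
            replica=self.replica[keep],
            attempt=self.attempt[keep],
            pH=self.pH[keep],
            conformer=self.conformer[keep],
            mask=self.mask[keep],
            n_protons=self.n_protons[keep],
            model_label=self.model_label,
            site_order=self.site_order,
            conformer_order=self.conformer_order,
            ladder=self.ladder,
            seed=self.seed,
            schedule=dict(self.schedule),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replica": self.replica,
                "attempt": self.attempt,
                "pH": self.pH,
                "conformer": [self.conformer_order[k] for k in self.conformer],
                "protonation": self.protonation_strings(),
                "N": self.n_protons,
            }
        )


@dataclass
class ExchangeStats:
    """Attempt/acceptance counts per adjacent pH-ladder pair."""

    pairs: list[tuple[float, float]]
    attempts: np.ndarray
    acceptances: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.attempts > 0, self.acceptances / np.maximum(self.attempts, 1), np.nan)
        return r

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pH_low": [p[0] for p in self.pairs],
                "pH_high": [p[1] for p in self.pairs],
                "attempts": self.attempts,
                "acceptances": self.acceptances,
                "rate": self.rates,
            }
        )


# ---------------------------------------------------------------------------
# Single-move primitives (reference implementations; the run loop below inlines them)


def _flip_delta_g(tables, thermo, mask: int, conf: int, site: int, pH: float) -> float:
    """Transition free energy for flipping one site (sign: current -> proposed)."""
    pka, shifts, coups, base, n = tables
    dg = thermo.kT_ln10 * (pH - pka[site]) + shifts[conf][site]
    for a, b, j in coups[conf]:
        if a == site and (mask >> b) & 1:
            dg += j
        elif b == site and (mask >> a) & 1:
            dg += j
    if (mask >> site) & 1:  # currently protonated: deprotonation move negates
        dg = -dg
    return dg


def _conf_energy(tables, thermo, mask: int, conf: int, pH: float) -> float:
    pka, shifts, coups, base, n = tables
    e = base[conf]
    m = mask
    i = 0
    while m:
        if m & 1:
            e += thermo.kT_ln10 * (pH - pka[i]) + shifts[conf][i]
        m >>= 1
        i += 1
    for a, b, j in coups[conf]:
        if (mask >> a) & 1 and (mask >> b) & 1:
            e += j
    return e


def exchange_probability(N_i: int, N_j: int, pH_i: float, pH_j: float) -> float:
    """Acceptance probability for swapping the pH assignments of two replicas.

    min{1, exp[ln10 (N_i - N_j)(pH_i - pH_j)]} with N the titratable proton
    counts before the attempt; equal proton counts always exchange.
    """
    expo = LN10 * (N_i - N_j) * (pH_i - pH_j)
    return 1.0 if expo >= 0.0 else math.exp(expo)


def attempt_protonation_move(
    model: SystemModel, state: Microstate, pH: float, rng: np.random.Generator
) -> tuple[Microstate, bool]:
    """Metropolis single-site protonation flip; returns (new state, accepted)."""
    model = _require_validated(model)
    tables = _energy_tables(model)
    n = len(model.sites)
    mask = sum(b << i for i, b in enumerate(state.protonation))
    conf = model.conformer_index(state.conformer)
    site = int(rng.integers(n))
    dg = _flip_delta_g(tables, model.thermo, mask, conf, site, pH)
    if dg <= 0.0 or rng.random() < math.exp(-dg / model.thermo.kT):
        bits = list(state.protonation)
        bits[site] ^= 1
        return Microstate(protonation=tuple(bits), conformer=state.conformer), True
    return state, False


def attempt_conformer_move(
    model: SystemModel, state: Microstate, pH: float, rng: np.random.Generator
) -> tuple[Microstate, bool]:
    """Metropolis jump to a uniformly chosen different conformer; no-op if only one."""
    model = _require_validated(model)
    n_conf = len(model.conformers)
    if n_conf < 2:
        return state, False
    tables = _energy_tables(model)
    mask = sum(b << i for i, b in enumerate(state.protonation))
    conf = model.conformer_index(state.conformer)
    prop = int(rng.integers(n_conf - 1))
    if prop >= conf:
        prop += 1
    de = _conf_energy(tables, model.thermo, mask, prop, pH) - _conf_energy(
        tables, model.thermo, mask, conf, pH
    )
    if de <= 0.0 or rng.random() < math.exp(-de / model.thermo.kT):
        return Microstate(protonation=state.protonation, conformer=model.conformer_ids[prop]), True
    return state, False


# ---------------------------------------------------------------------------
# Full runs


def _initial_state(model: SystemModel, tables, pH: float) -> tuple[int, int, int]:
    """Deterministic start: protonate sites with pKa_ref > pH; lowest-base conformer."""
    pka, shifts, coups, base, n = tables
    mask = 0
    for i in range(n):
        if pka[i] > pH:
            mask |= 1 << i
    conf = int(np.argmin(base))
    return mask, conf, bin(mask).count("1")


def _replica_rng(seed: int, replica_id: int) -> np.random.Generator:
    return np.random.default_rng([seed, 0, replica_id])


def _run_replicas(
    model: SystemModel,
    ladder: tuple[float, ...],
    schedule: MCSchedule,
    exchange: bool,
) -> tuple[SampleLedger, ExchangeStats]:
    model = _require_validated(model)
    tables = _energy_tables(model)
    pka, shifts, coups, base, n_sites = tables
    kT = model.thermo.kT
    kT_ln10 = model.thermo.kT_ln10
    n_conf = len(model.conformers)
    n_rep = len(ladder)
    sched = schedule

    # per-replica state and pre-drawn random variates
    masks = [0] * n_rep
    confs = [0] * n_rep
    nprot = [0] * n_rep
    phs = list(ladder)  # phs[r] = current pH of replica r
    at_pos = list(range(n_rep))  # at_pos[k] = replica currently at ladder position k
    rand = []
    for r in range(n_rep):
        masks[r], confs[r], nprot[r] = _initial_state(model, tables, phs[r])
        g = _replica_rng(sched.seed, r)
        rand.append(
            (
                g.random(sched.n_attempts),  # move-type selector
                g.integers(0, n_sites, size=sched.n_attempts),
                g.random(sched.n_attempts),  # acceptance uniforms
                g.integers(0, max(n_conf - 1, 1), size=sched.n_attempts),
            )
        )
    ex_rng = np.random.default_rng([sched.seed, 1])

    burn = sched.burn_in_attempts
    rec_rep, rec_att, rec_ph, rec_conf, rec_mask, rec_n = [], [], [], [], [], []
    pair_attempts = np.zeros(max(n_rep - 1, 0), dtype=np.int64)
    pair_accepts = np.zeros(max(n_rep - 1, 0), dtype=np.int64)
    sweep = 0
    cmp_prob = sched.conformer_move_prob

    shifts_l = [s.tolist() for s in shifts]
    pka_l = pka.tolist()
    base_l = base.tolist()

    for t in range(sched.n_attempts):
        for r in range(n_rep):
            u_move, sites_arr, u_acc, conf_arr = rand[r]
            ph = phs[r]
            mask = masks[r]
            conf = confs[r]
            if n_conf > 1 and u_move[t] < cmp_prob:
                prop = int(conf_arr[t])
                if prop >= conf:
                    prop += 1
                de = base_l[prop] - base_l[conf]
                m = mask
                i = 0
                sh_p = shifts_l[prop]
                sh_c = shifts_l[conf]
                while m:
                    if m & 1:
                        de += sh_p[i] - sh_c[i]
                    m >>= 1
                    i += 1
                for a, b, j in coups[prop]:
                    if (mask >> a) & 1 and (mask >> b) & 1:
                        de += j
                for a, b, j in coups[conf]:
                    if (mask >> a) & 1 and (mask >> b) & 1:
                        de -= j
                if de <= 0.0 or u_acc[t] < math.exp(-de / kT):
                    confs[r] = prop
            else:
                site = int(sites_arr[t])
                dg = kT_ln10 * (ph - pka_l[site]) + shifts_l[conf][site]
                for a, b, j in coups[conf]:
                    if a == site:
                        if (mask >> b) & 1:
                            dg += j
                    elif b == site and (mask >> a) & 1:
                        dg += j
                if (mask >> site) & 1:
                    dg = -dg
                if dg <= 0.0 or u_acc[t] < math.exp(-dg / kT):
                    masks[r] = mask ^ (1 << site)
                    nprot[r] += 1 if not (mask >> site) & 1 else -1

        if exchange and n_rep > 1 and (t + 1) % sched.exchange_interval == 0:
            start = sweep % 2
            sweep += 1
            us = ex_rng.random(n_rep)  # one draw per possible pair position
            for k in range(start, n_rep - 1, 2):
                ri, rj = at_pos[k], at_pos[k + 1]
                pair_attempts[k] += 1
                expo = LN10 * (nprot[ri] - nprot[rj]) * (phs[ri] - phs[rj])
                if expo >= 0.0 or us[k] < math.exp(expo):
                    phs[ri], phs[rj] = phs[rj], phs[ri]
                    at_pos[k], at_pos[k + 1] = rj, ri
                    pair_accepts[k] += 1

        if t >= burn and (t - burn) % sched.thin == 0:
            for r in range(n_rep):
                rec_rep.append(r)
                rec_att.append(t)
                rec_ph.append(phs[r])
                rec_conf.append(confs[r])
                rec_mask.append(masks[r])
                rec_n.append(nprot[r])

    ledger = SampleLedger(
        replica=np.array(rec_rep, dtype=np.int32),
        attempt=np.array(rec_att, dtype=np.int64),
        pH=np.array(rec_ph, dtype=float),
        conformer=np.array(rec_conf, dtype=np.int16),
        mask=np.array(rec_mask, dtype=np.int64),
        n_protons=np.array(rec_n, dtype=np.int16),
        model_label=model.label,
        site_order=model.site_ids,
        conformer_order=model.conformer_ids,
        ladder=tuple(float(p) for p in ladder),
        seed=sched.seed,
        schedule=sched.to_dict(),
    )
    stats = ExchangeStats(
        pairs=[(float(ladder[k]), float(ladder[k + 1])) for k in range(n_rep - 1)],
        attempts=pair_attempts,
        acceptances=pair_accepts,
    )
    return ledger, stats


def run_fixed_ph(model: SystemModel, pH: float, schedule: MCSchedule) -> SampleLedger:
    """Constant-pH MC at a single pH (no replica exchange)."""
    ledger, _ = _run_replicas(model, (float(pH),), schedule, exchange=False)
    return ledger


def run_ph_remd(
    model: SystemModel,
    pH_ladder: tuple[float, ...] = DEFAULT_LADDER,
    schedule: MCSchedule | None = None,
    exchange: bool = True,
) -> tuple[SampleLedger, ExchangeStats]:
    """pH replica exchange MC over an ascending pH ladder.

    ``exchange=False`` runs the same replicas without swaps (for detailed-
    balance diagnostics).
    """
    ladder = tuple(float(p) for p in pH_ladder)
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("pH ladder must be strictly ascending")
    if schedule is None:
        schedule = MCSchedule()
    return _run_replicas(model, ladder, schedule, exchange=exchange)


def demultiplex(ledger: SampleLedger) -> dict[float, SampleLedger]:
    """Regroup ledger rows by pH value (ascending keys); row counts are conserved."""
    streams: dict[float, SampleLedger] = {}
    ladder = set(ledger.ladder)
    for ph in sorted(set(ledger.pH.tolist())):
        if ph not in ladder:
            raise ModelError(f"ledger pH {ph} not present in ladder metadata")
        streams[ph] = ledger.select(ledger.pH == ph)
    return streams
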