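"""Titration curves, Hill-equation pKa fitting, and conformer populations.

The fraction of deprotonated species ``s`` of a titratable group is fitted to
the Hill equation

    s(pH) = 1 / (1 + 10^{n (pKa - pH)})

by unweighted nonlinear least squares; ``pKa`` is the titration midpoint and
``n`` the Hill coefficient (n ~ 1: independent titration; n < 1:
anticooperative, broadened curve, as for coupled aspartyl dyads).  Standard
errors come from the asymptotic covariance of the fit.  A curve that does not
span both tails (s < 0.2 and s > 0.8 somewhere) is flagged non-converged
rather than raising, so summary tables always render.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .mc import SampleLedger

__all__ = [
    "TitrationCurve",
    "HillFit",
    "hill_curve",
    "site_fractions",
    "fit_hill",
    "pka_table",
    "render_pka_table",
    "conformer_populations",
    "synthetic_hill_counts",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Per-pH deprotonated fraction of one site, with underlying counts if known."""

    site_id: str
    pH: np.ndarray
    s: np.ndarray
    n_deprotonated: np.ndarray | None = None
    n_total: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pH) <= 0):
            raise ValueError("pH grid must be strictly ascending")
        if np.any((self.s < 0) | (self.s > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        nd = self.n_deprotonated if self.n_deprotonated is not None else np.full(len(self.pH), -1)
        nt = self.n_total if self.n_total is not None else np.full(len(self.pH), -1)
        return pd.DataFrame(
            {"site": self.site_id, "pH": self.pH, "n_deprot": nd, "n_total": nt, "s": self.s}
        )


@dataclass(frozen=True)
class HillFit:
    """Hill-equation fit result: midpoint pKa, Hill coefficient, and their SEs."""

    site_id: str
    pKa: float
    n: float
    se_pKa: float
    se_n: float
    rss: float
    converged: bool


def hill_curve(pH, pKa: float, n: float = 1.0):
    """Hill-equation deprotonated fraction s(pH) = 1/(1 + 10^{n(pKa - pH)})."""
    pH = np.asarray(pH, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (n * (pKa - pH)))


def site_fractions(streams: dict[float, SampleLedger], site_id: str) -> TitrationCurve:
    """Per-pH deprotonated fractions of one site from demultiplexed sample streams.

    Empty streams at a pH are omitted with a warning.
    """
    if len(streams) < 2:
        raise ValueError("need streams at >= 2 pH values to build a titration curve")
    phs, s, nd, nt = [], [], [], []
    for ph in sorted(streams):
        bits = streams[ph].site_bits(site_id)
        total = len(bits)
        if total == 0:
            warnings.warn(f"no samples at pH {ph}; omitted from titration curve", stacklevel=2)
            continue
        deprot = int(np.sum(bits == 0))
        phs.append(ph)
        nd.append(deprot)
        nt.append(total)
        s.append(deprot / total)
    return TitrationCurve(
        site_id=site_id,
        pH=np.array(phs, dtype=float),
        s=np.array(s, dtype=float),
        n_deprotonated=np.array(nd, dtype=np.int64),
        n_total=np.array(nt, dtype=np.int64),
    )


def fit_hill(curve: TitrationCurve) -> HillFit:
    """Unweighted nonlinear least-squares Hill fit of a titration curve.

    Initial pKa is the grid pH closest to half-titration, initial n = 1;
    bounds n in (0.05, 5], pKa within [grid min - 5, grid max + 5].  Degenerate
    curves (never leaving one tail) return a flagged non-converged result.
    """
    ph = np.asarray(curve.pH, dtype=float)
    s = np.asarray(curve.s, dtype=float)
    spans = bool(np.any(s < 0.2) and np.any(s > 0.8))
    degenerate = bool(np.all(s < 0.05) or np.all(s > 0.95))
    if degenerate or len(ph) < 3:
        pka0 = float(ph[np.argmin(np.abs(s - 0.5))])
        return HillFit(curve.site_id, pka0, 1.0, np.nan, np.nan, np.nan, converged=False)

    p0 = (float(ph[np.argmin(np.abs(s - 0.5))]), 1.0)
    bounds = ([ph.min() - 5.0, 0.05], [ph.max() + 5.0, 5.0])
    try:
        popt, pcov = curve_fit(hill_curve, ph, s, p0=p0, bounds=bounds, maxfev=10_000)
    except RuntimeError:
        return HillFit(curve.site_id, p0[0], p0[1], np.nan, np.nan, np.nan, converged=False)
    fitted = hill_curve(ph, *popt)
    resid = s - fitted
    rss = float(resid @ resid)
    if curve.n_total is not None:
        # counts known: the per-point noise is binomial, which the homoskedastic
        # RSS-based covariance badly miscalibrates (tail points have ~zero
        # variance); use the sandwich covariance of the unweighted estimator
        # with var_i = p_i (1 - p_i) / n_i evaluated at the fitted curve.
        var_i = fitted * (1.0 - fitted) / np.asarray(curve.n_total, dtype=float)
        var_i = np.maximum(var_i, 1e-12)
        sb = np.log(10.0) * fitted * (1.0 - fitted)
        J = np.column_stack([-popt[1] * sb, -(popt[0] - ph) * sb])  # d s / d(pKa, n)
        JtJ_inv = np.linalg.pinv(J.T @ J)
        cov = JtJ_inv @ (J.T * var_i) @ J @ JtJ_inv
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    else:
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return HillFit(
        site_id=curve.site_id,
        pKa=float(popt[0]),
        n=float(popt[1]),
        se_pKa=float(se[0]),
        se_n=float(se[1]),
        rss=rss,
        converged=spans,
    )


def pka_table(streams: dict[float, SampleLedger]) -> pd.DataFrame:
    """Hill fits for every site in a demultiplexed ledger, one row per site."""
    any_stream = next(iter(streams.values()))
    rows = []
    for sid in any_stream.site_order:
        fit = fit_hill(site_fractions(streams, sid))
        rows.append(
            {
                "site": sid,
                "pKa": fit.pKa,
                "se_pKa": fit.se_pKa,
                "hill_n": fit.n,
                "se_n": fit.se_n,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def render_pka_table(table: pd.DataFrame) -> str:
    """Human-readable pKa table: `site  pKa ± se (n)` lines."""
    lines = ["site        pKa               (Hill n)"]
    for _, r in table.iterrows():
        mark = "" if r["converged"] else "  [not converged]"
        se = f" ± {r['se_pKa']:.2f}" if np.isfinite(r["se_pKa"]) else ""
        lines.append(f"{r['site']:<10}  {r['pKa']:.2f}{se}  ({r['hill_n']:.2f}){mark}")
    return "\n".join(lines)


def conformer_populations(streams: dict[float, SampleLedger]) -> pd.DataFrame:
    """Per-pH conformer occupancies (rows: pH; columns: conformer ids; rows sum to 1)."""
    any_stream = next(iter(streams.values()))
    confs = any_stream.conformer_order
    rows = {}
    for ph in sorted(streams):
        led = streams[ph]
        counts = np.bincount(led.conformer, minlength=len(confs)).astype(float)
        rows[ph] = counts / counts.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(confs)).rename_axis("pH")


def synthetic_hill_counts(
    pKa: float,
    n: float,
    pH_grid: np.ndarray,
    n_total: int,
    rng: np.random.Generator,
) -> TitrationCurve:
    """Binomially noised titration counts drawn from an exact Hill curve.

    Emulates per-pH deprotonation counting with ``n_total`` independent
    samples per pH — the idealized (autocorrelation-free) counterpart of an
    MC sample stream.
    """
    pH_grid = np.asarray(pH_grid, dtype=float)
    p = hill_curve(pH_grid, pKa, n)
    k = rng.binomial(n_total, p)
    return TitrationCurve(
        site_id=f"synthetic_pKa{pKa}_n{n}",
        pH=pH_grid,
        s=k / n_total,
        n_deprotonated=k.astype(np.int64),
        n_total=np.full(len(pH_grid), n_total, dtype=np.int64),
    )
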