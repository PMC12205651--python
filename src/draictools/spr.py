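"""1:1 Langmuir binding kinetics: closed-form curves and global fitting.

A single-site (1:1) interaction between an immobilized ligand and an
analyte at concentration C follows

    association:  R(t) = Req * (1 - exp(-(ka*C + kd) * t)),
                  Req  = Rmax * C / (C + KD),   KD = kd / ka
    dissociation: R(t) = R_end * exp(-kd * (t - t0))

with ka in 1/(M*s), kd in 1/s, responses in RU.  ``fit_1to1_global`` fits
(ka, kd, Rmax) jointly across all analyte concentrations of a sensorgram
set by nonlinear least squares in log-parameter space with multi-start
initialization, and reports KD = kd/ka.  Replicate experiments are
summarized as mean +/- sample SD per parameter, with KD averaged over the
per-replicate ratios (the convention used when kinetics tables report a KD
that differs from mean kd / mean ka).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticFitResult",
    "ReplicateSummary",
    "association_curve",
    "dissociation_curve",
    "fit_1to1_global",
    "kd_from_rates",
    "summarize_replicates",
]


@dataclass(frozen=True)
class KineticFitResult:
    """Globally fitted 1:1 parameters and diagnostics."""

    ka: float
    kd: float
    rmax: float
    kD: float
    residual_rms: float
    converged: bool
    warnings: tuple[str, ...] = ()
    replicate: int | None = None


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample SD of kinetic parameters over replicate fits."""

    n: int
    ka_mean: float
    ka_sd: float | None
    kd_mean: float
    kd_sd: float | None
    kD_mean: float
    kD_sd: float | None


def association_curve(
    ka: float, kd: float, rmax: float, conc: float, t
) -> np.ndarray | float:
    """Response during association at analyte concentration ``conc``."""
    if ka <= 0 or kd <= 0 or rmax <= 0 or conc <= 0:
        raise ValueError("ka, kd, rmax and conc must all be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("association time must be >= 0")
    req = rmax * conc / (conc + kd / ka)
    r = req * (1.0 - np.exp(-(ka * conc + kd) * t))
    return float(r) if r.ndim == 0 else r


def dissociation_curve(r0: float, kd: float, elapsed) -> np.ndarray | float:
    """Response ``elapsed`` seconds after the dissociation start."""
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    if kd < 0:
        raise ValueError("kd must be >= 0")
    elapsed = np.asarray(elapsed, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed time must be >= 0")
    r = r0 * np.exp(-kd * elapsed)
    return float(r) if r.ndim == 0 else r


def _model_response(
    log_params: np.ndarray,
    curves: list[dict],
) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        ka, kd, rmax = np.exp(np.clip(log_params, -700.0, 700.0))
        out = []
        for c in curves:
            conc = c["conc"]
            req = rmax * conc / (conc + kd / ka)
            kobs = ka * conc + kd
            r_assoc = req * (1.0 - np.exp(-kobs * c["t_assoc"]))
            r_end = req * (1.0 - np.exp(-kobs * c["t0"]))
            r_dissoc = r_end * np.exp(-kd * (c["t_dissoc"] - c["t0"]))
            out.append(np.concatenate([r_assoc, r_dissoc]))
        return np.nan_to_num(np.concatenate(out), nan=1e6, posinf=1e6)


def _prepare_curves(sensorgrams: pd.DataFrame) -> tuple[list[dict], np.ndarray]:
    required = {"time_s", "response_RU", "conc_M", "phase"}
    missing = required - set(sensorgrams.columns)
    if missing:
        raise ValueError(f"sensorgram table missing columns: {sorted(missing)}")
    curves = []
    responses = []
    for conc, grp in sensorgrams.groupby("conc_M", sort=True):
        if conc <= 0:
            raise ValueError("analyte concentrations must be positive")
        assoc = grp[grp["phase"] == "assoc"].sort_values("time_s")
        dissoc = grp[grp["phase"] == "dissoc"].sort_values("time_s")
        if assoc.empty:
            raise ValueError(f"no association phase for conc {conc}")
        t0 = float(assoc["time_s"].max())
        curves.append(
            {
                "conc": float(conc),
                "t_assoc": assoc["time_s"].to_numpy(float),
                "t_dissoc": dissoc["time_s"].to_numpy(float),
                "t0": t0,
            }
        )
        responses.append(
            np.concatenate(
                [assoc["response_RU"].to_numpy(float),
                 dissoc["response_RU"].to_numpy(float)]
            )
        )
    return curves, np.concatenate(responses)


def fit_1to1_global(
    sensorgrams: pd.DataFrame,
    n_starts: int = 9,
    replicate: int | None = None,
) -> KineticFitResult:
    """Global nonlinear least-squares fit of (ka, kd, Rmax).

    All concentration series in ``sensorgrams`` (tidy columns time_s,
    response_RU, conc_M, phase) are fitted simultaneously with shared
    parameters, in log space.  Initialization is a log-uniform multi-start
    grid over (ka, kd) — the least-squares surface is multi-modal — keeping
    the best of ``n_starts`` solutions.  A single-concentration input is
    allowed but flagged: ka and Rmax are then only weakly identifiable.
    """
    curves, y = _prepare_curves(sensorgrams)
    warn: list[str] = []
    if len(curves) < 2:
        msg = ("single analyte concentration: ka and Rmax are weakly "
               "identifiable")
        warn.append(msg)
        warnings.warn(msg, stacklevel=2)

    rmax0 = max(1.2 * float(np.max(y)), 1e-6)
    ka_grid = np.logspace(3, 7, max(2, int(round(np.sqrt(n_starts)))))
    kd_grid = np.logspace(-5, -2, max(2, int(round(np.sqrt(n_starts)))))
    starts = list(itertools.product(ka_grid, kd_grid))[:n_starts]

    best = None
    for ka0, kd0 in starts:
        x0 = np.log([ka0, kd0, rmax0])
        try:
            res = least_squares(
                lambda lp: _model_response(lp, curves) - y,
                x0,
                method="lm",
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("global 1:1 fit failed from every start")

    ka, kd, rmax = (float(v) for v in np.exp(best.x))
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return KineticFitResult(
        ka=ka,
        kd=kd,
        rmax=rmax,
        kD=kd_from_rates(ka, kd),
        residual_rms=rms,
        converged=bool(best.success),
        warnings=tuple(warn),
        replicate=replicate,
    )


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd / ka (M)."""
    if ka <= 0:
        raise ValueError("ka must be positive")
    if kd < 0:
        raise ValueError("kd must be >= 0")
    return kd / ka


def summarize_replicates(fits: Sequence[KineticFitResult]) -> ReplicateSummary:
    """Mean +/- sample SD of ka, kd and KD over replicate fits.

    KD is summarized as the mean of the per-replicate kd/ka ratios, not the
    ratio of means.  With a single replicate the SDs are reported as None.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    ka = np.array([f.ka for f in fits], dtype=float)
    kd = np.array([f.kd for f in fits], dtype=float)
    kD = np.array([f.kD for f in fits], dtype=float)
    n = len(fits)

    def _sd(x: np.ndarray) -> float | None:
        return float(np.std(x, ddof=1)) if n > 1 else None

    return ReplicateSummary(
        n=n,
        ka_mean=float(ka.mean()),
        ka_sd=_sd(ka),
        kd_mean=float(kd.mean()),
        kd_sd=_sd(kd),
        kD_mean=float(kD.mean()),
        kD_sd=_sd(kD),
    )
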