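"""Four-parameter logistic (4PL) dose-response analysis.

Models intracellular Ca2+ mobilisation responses (% of a reference
maximum) as a function of agonist concentration:

    r(c) = baseline + (emax - baseline) / (1 + (ec50 / c) ** hill)

fitted by bounded least squares on log10 concentration.  Derived
quantities: fold-selectivity of one agonist across two receptors
(EC50 ratio, low-affinity over high-affinity receptor) and the potency
ratio of two agonists at one receptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class DoseResponseError(ValueError):
    pass


@dataclass
class DoseResponseCurve:
    """Replicate-resolved dose-response data.

    ``doses`` in molar (strictly positive, sorted on construction, at
    least 5 distinct values), ``responses`` in % of the reference maximal
    response; repeated dose values carry replicates.
    """

    agonist: str
    receptor: str
    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise DoseResponseError("doses and responses differ in length")
        if np.any(self.doses <= 0):
            raise DoseResponseError("doses must be strictly positive (molar)")
        if np.unique(self.doses).size < 5:
            raise DoseResponseError("need at least 5 distinct doses for fitting")
        order = np.argsort(self.doses, kind="stable")
        self.doses = self.doses[order]
        self.responses = self.responses[order]


@dataclass(frozen=True)
class FitResult:
    ec50: float  # molar
    emax: float  # %, top asymptote
    hill: float
    baseline: float  # %, bottom asymptote
    converged: bool
    residual_sse: float
    agonist: str = ""
    receptor: str = ""


def four_pl(dose: np.ndarray, baseline: float, emax: float, log10_ec50: float, hill: float):
    """4PL evaluated at molar doses with EC50 parameterised on log10 scale."""
    return baseline + (emax - baseline) / (
        1.0 + 10.0 ** (hill * (log10_ec50 - np.log10(dose)))
    )


def fit_4pl(curve: DoseResponseCurve) -> FitResult:
    """Deterministic bounded least-squares 4PL fit.

    Initialiser from data quantiles (baseline = min response, emax = max,
    EC50 = dose nearest the half-range response, hill = 1); EC50 bounded
    to the dose range widened by two decades, hill to [0.1, 10].  Flat
    (unidentifiable) data is flagged unconverged with the initial
    parameters returned.
    """
    x = curve.doses
    y = curve.responses
    lo, hi = float(y.min()), float(y.max())
    span = hi - lo
    logd_lo, logd_hi = np.log10(x.min()), np.log10(x.max())

    if span < 1e-9 * max(1.0, abs(hi)):
        mid = 10 ** ((logd_lo + logd_hi) / 2)
        return FitResult(
            ec50=float(mid), emax=hi, hill=1.0, baseline=lo, converged=False,
            residual_sse=float(np.sum((y - y.mean()) ** 2)),
            agonist=curve.agonist, receptor=curve.receptor,
        )

    half = lo + span / 2.0
    ec50_init = float(x[np.argmin(np.abs(y - half))])
    p0 = [lo, hi, np.log10(ec50_init), 1.0]
    bounds = (
        [lo - span, hi - 0.5 * span, logd_lo - 2.0, 0.1],
        [lo + 0.5 * span, hi + span, logd_hi + 2.0, 10.0],
    )
    try:
        popt, _ = curve_fit(
            four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
        ok = True
    except RuntimeError:
        popt, ok = p0, False
    baseline, emax, log_ec50, hill = (float(v) for v in popt)
    resid = y - four_pl(x, *popt)
    converged = ok and emax > baseline
    return FitResult(
        ec50=float(10**log_ec50), emax=emax, hill=hill, baseline=baseline,
        converged=converged, residual_sse=float(np.sum(resid**2)),
        agonist=curve.agonist, receptor=curve.receptor,
    )


def _check_fit(fit: FitResult) -> None:
    if not fit.converged:
        raise DoseResponseError("fit did not converge")
    if fit.ec50 <= 0:
        raise DoseResponseError("EC50 must be positive")


def fold_selectivity(fit_low_affinity: FitResult, fit_high_affinity: FitResult) -> float:
    """EC50 ratio low-affinity / high-affinity receptor (e.g. OX1R over
    OX2R for an OX2R-selective agonist)."""
    _check_fit(fit_low_affinity)
    _check_fit(fit_high_affinity)
    return fit_low_affinity.ec50 / fit_high_affinity.ec50


def potency_ratio(fit_a: FitResult, fit_b: FitResult) -> float:
    """EC50(a) / EC50(b) at one receptor; > 1 means b is the more potent."""
    _check_fit(fit_a)
    _check_fit(fit_b)
    if fit_a.receptor and fit_b.receptor and fit_a.receptor != fit_b.receptor:
        raise DoseResponseError(
            f"potency ratio requires one receptor, got {fit_a.receptor!r} vs {fit_b.receptor!r}"
        )
    return fit_a.ec50 / fit_b.ec50


def simulate_curve(
    agonist: str,
    receptor: str,
    ec50: float,
    emax: float = 100.0,
    hill: float = 1.0,
    baseline: float = 0.0,
    n_doses: int = 10,
    replicates: int = 1,
    noise_sd_pct: float = 0.0,
    seed: int | None = None,
    decades_around_ec50: float = 3.0,
) -> DoseResponseCurve:
    """Synthetic 4PL data on a log-spaced dose grid centred on the EC50."""
    rng = np.random.default_rng(seed)
    log_c = np.linspace(
        np.log10(ec50) - decades_around_ec50, np.log10(ec50) + decades_around_ec50, n_doses
    )
    doses = np.repeat(10.0**log_c, replicates)
    resp = four_pl(doses, baseline, emax, np.log10(ec50), hill)
    if noise_sd_pct > 0:
        resp = resp + rng.normal(0.0, noise_sd_pct, resp.shape)
    return DoseResponseCurve(agonist=agonist, receptor=receptor, doses=doses, responses=resp)


def fits_frame(fits: list[FitResult]):
    """Fit table for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "agonist": f.agonist,
                "receptor": f.receptor,
                "ec50_M": f.ec50,
                "emax_pct": f.emax,
                "hill": f.hill,
                "baseline_pct": f.baseline,
                "converged": f.converged,
                "residual_sse": f.residual_sse,
            }
            for f in fits
        ]
    )
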