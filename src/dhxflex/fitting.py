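"""Mono- and biexponential fitting of residue DHX curves with Wilks selection.

The exchange assay dilutes an exhaustively deuterated peptide 1:20 into
protonated solvent, so the observable deuteron content of one amide relaxes
from 0.95 to a residual plateau of 0.05:

    mono:  D(t) = 0.95 * exp(-k t) + 0.05
    bi:    D(t) = A * exp(-k_A t) + B * exp(-k_B t) + 0.05,  A + B = 0.95

Rates are fitted in log10 space (bounded to [1e-6, 1e3] 1/min) by weighted
least squares with deterministic multistarts; the biexponential adds one rate
and an amplitude split, i.e. two extra parameters.  The choice between the
nested models uses Wilks' theorem on the Gaussian likelihood-ratio statistic

    Lambda = n * ln(RSS_mono / RSS_bi)  ~  chi2(df=2)

calling an amide biphasic when p < 0.01.  A biexponential solution whose
rates differ by less than a factor 1.5 or whose smaller amplitude is below
0.02 is degenerate at the noise level and is collapsed onto the
monoexponential fit, preventing spurious biphasic calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .fragments import ResidueExchangeCurve

PLATEAU = 0.05   # residual deuteration of the 1:20 dilution
SPAN = 0.95

LOG10_K_MIN = -6.0
LOG10_K_MAX = 3.0

DEGENERATE_RATE_RATIO = 1.5
DEGENERATE_AMPLITUDE = 0.02

WILKS_DF = 2
P_THRESHOLD = 0.01

_LN10 = np.log(10.0)


def model_mono(t: np.ndarray, k: float) -> np.ndarray:
    return SPAN * np.exp(-k * np.asarray(t, float)) + PLATEAU


def model_bi(t: np.ndarray, k_slow: float, k_fast: float, amp_slow: float) -> np.ndarray:
    t = np.asarray(t, float)
    return amp_slow * np.exp(-k_slow * t) + (SPAN - amp_slow) * np.exp(-k_fast * t) + PLATEAU


@dataclass
class KineticFit:
    """Result of fitting one residue exchange curve."""

    model: str                      # "mono" | "bi"
    k_slow: float                   # 1/min; the only rate for mono
    k_fast: float | None            # 1/min; None for mono
    amp_slow: float                 # mono: 0.95
    amp_fast: float                 # mono: 0.0
    se_log10_k_slow: float
    se_log10_k_fast: float | None
    rss: float                      # weighted residual sum of squares
    n_points: int
    p_wilks: float | None = None
    degenerate: bool = False
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def biphasic(self) -> bool:
        return self.model == "bi" and not self.degenerate


class FitFailure(RuntimeError):
    """Raised when a fit cannot converge; the residue becomes n.d."""


def _weights(curve: ResidueExchangeCurve) -> np.ndarray:
    sig = np.asarray(curve.d_sigma, float)
    if sig.size and np.all(sig > 0):
        return 1.0 / sig
    return np.ones_like(np.asarray(curve.d_mean, float))


def _se_from_jac(jac: np.ndarray, rss: float, n: int, n_par: int) -> np.ndarray:
    dof = max(n - n_par, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


def _start_grid(times: np.ndarray, n: int) -> np.ndarray:
    """Deterministic log10-rate starts spanning the observable window."""
    lo = max(-np.log10(times.max()) - 0.5, LOG10_K_MIN)
    hi = min(-np.log10(times.min()) + 0.5, LOG10_K_MAX)
    return np.linspace(lo, hi, n)


def fit_mono(curve: ResidueExchangeCurve) -> KineticFit:
    """Single-rate fit; k is the only free parameter, estimated as log10 k."""
    t = np.asarray(curve.times, float)
    y = np.asarray(curve.d_mean, float)
    if t.size < 3:
        raise FitFailure(f"position {curve.position}: <3 time points")
    w = _weights(curve)

    def resid(p):
        return (model_mono(t, 10.0 ** p[0]) - y) * w

    def jac(p):
        k = 10.0 ** p[0]
        d = SPAN * np.exp(-k * t) * (-t * k * _LN10) * w
        return d[:, None]

    best = None
    for lk0 in _start_grid(t, 6):
        sol = least_squares(
            resid, x0=[lk0], jac=jac, bounds=([LOG10_K_MIN], [LOG10_K_MAX]),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    rss = float(2.0 * best.cost)
    se = _se_from_jac(best.jac, rss, t.size, 1)[0]
    return KineticFit(
        model="mono",
        k_slow=float(10.0 ** best.x[0]),
        k_fast=None,
        amp_slow=SPAN,
        amp_fast=0.0,
        se_log10_k_slow=float(se),
        se_log10_k_fast=None,
        rss=rss,
        n_points=int(t.size),
        converged=bool(best.success),
    )


def fit_bi(curve: ResidueExchangeCurve, mono: KineticFit | None = None) -> KineticFit:
    """Two-rate fit with fixed total amplitude 0.95.

    Free parameters: two log10 rates and the slow-amplitude fraction.  Eight
    deterministic multistarts cover the observable rate window plus starts
    derived from the monoexponential solution; the returned rates satisfy
    k_slow <= k_fast.  Degenerate optima (rate ratio < 1.5 or an amplitude
    < 0.02) are collapsed onto the monoexponential fit.
    """
    t = np.asarray(curve.times, float)
    y = np.asarray(curve.d_mean, float)
    if t.size < 5:
        raise FitFailure(f"position {curve.position}: <5 time points for biexponential")
    w = _weights(curve)
    if mono is None:
        mono = fit_mono(curve)
    lk_mono = np.log10(mono.k_slow)

    def resid(p):
        return (model_bi(t, 10.0 ** p[0], 10.0 ** p[1], SPAN * p[2]) - y) * w

    def jac(p):
        ks, kf, f = 10.0 ** p[0], 10.0 ** p[1], p[2]
        es, ef = np.exp(-ks * t), np.exp(-kf * t)
        d0 = SPAN * f * es * (-t * ks * _LN10) * w
        d1 = SPAN * (1 - f) * ef * (-t * kf * _LN10) * w
        d2 = SPAN * (es - ef) * w
        return np.column_stack([d0, d1, d2])

    g = _start_grid(t, 4)
    starts = [
        (g[0], g[2], 0.5),
        (g[0], g[3], 0.5),
        (g[1], g[3], 0.5),
        (g[0], g[2], 0.2),
        (g[1], g[3], 0.8),
        (np.clip(lk_mono - 1.0, LOG10_K_MIN, LOG10_K_MAX),
         np.clip(lk_mono + 1.0, LOG10_K_MIN, LOG10_K_MAX), 0.5),
        (np.clip(lk_mono - 2.0, LOG10_K_MIN, LOG10_K_MAX),
         np.clip(lk_mono + 0.5, LOG10_K_MIN, LOG10_K_MAX), 0.7),
        (lk_mono, lk_mono, 0.5),  # nested start: guarantees RSS_bi <= RSS_mono
    ]
    best = None
    for lk1, lk2, f0 in starts:
        sol = least_squares(
            resid, x0=[lk1, lk2, f0], jac=jac,
            bounds=([LOG10_K_MIN, LOG10_K_MIN, 0.0], [LOG10_K_MAX, LOG10_K_MAX, 1.0]),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol

    k1, k2 = 10.0 ** best.x[0], 10.0 ** best.x[1]
    f = float(best.x[2])
    se = _se_from_jac(best.jac, float(2 * best.cost), t.size, 3)
    # amplitude fraction se maps to both rates' se columns
    se_k1, se_k2 = float(se[0]), float(se[1])
    if k1 <= k2:
        k_slow, k_fast = k1, k2
        amp_slow, amp_fast = SPAN * f, SPAN * (1 - f)
        se_slow, se_fast = se_k1, se_k2
    else:
        k_slow, k_fast = k2, k1
        amp_slow, amp_fast = SPAN * (1 - f), SPAN * f
        se_slow, se_fast = se_k2, se_k1

    rss_raw = float(2.0 * best.cost)
    degenerate = (k_fast / max(k_slow, 1e-300) < DEGENERATE_RATE_RATIO) or (
        min(amp_slow, amp_fast) < DEGENERATE_AMPLITUDE
    )
    if degenerate:
        # collapse onto the mono solution: the extra phase is not resolved
        return KineticFit(
            model="bi",
            k_slow=mono.k_slow,
            k_fast=mono.k_slow,
            amp_slow=SPAN,
            amp_fast=0.0,
            se_log10_k_slow=mono.se_log10_k_slow,
            se_log10_k_fast=mono.se_log10_k_slow,
            rss=mono.rss,
            n_points=int(t.size),
            degenerate=True,
            converged=bool(best.success),
            flags=[f"degenerate_collapsed(rss_raw={rss_raw:.3e})"],
        )
    return KineticFit(
        model="bi",
        k_slow=float(k_slow),
        k_fast=float(k_fast),
        amp_slow=float(amp_slow),
        amp_fast=float(amp_fast),
        se_log10_k_slow=se_slow,
        se_log10_k_fast=se_fast,
        rss=min(rss_raw, mono.rss),
        n_points=int(t.size),
        converged=bool(best.success),
    )


def select_model(mono: KineticFit, bi: KineticFit) -> KineticFit:
    """Wilks likelihood-ratio choice between the nested fits.

    Lambda = n ln(RSS_mono/RSS_bi) referred to chi2 with 2 df; p < 0.01
    selects the biexponential and sets the biphasic flag.  If the
    biexponential RSS exceeds the monoexponential one (optimizer failure
    despite the nested start) the monoexponential is kept with a warning
    flag.
    """
    n = mono.n_points
    rss_bi = bi.rss
    if rss_bi > mono.rss:
        chosen = mono
        chosen.p_wilks = 1.0
        chosen.flags.append("bi_fit_worse_than_mono")
        return chosen
    lam = n * np.log(max(mono.rss, 1e-300) / max(rss_bi, 1e-300))
    p = float(stats.chi2.sf(lam, WILKS_DF))
    if p < P_THRESHOLD and not bi.degenerate:
        bi.p_wilks = p
        return bi
    mono.p_wilks = p
    return mono


def analyze_curve(curve: ResidueExchangeCurve) -> KineticFit:
    """Fit mono and (when enough points) biexponential models and select."""
    mono = fit_mono(curve)
    if curve.n_points < 5:
        mono.p_wilks = 1.0
        mono.flags.append("too_few_points_for_bi")
        return mono
    bi = fit_bi(curve, mono)
    return select_model(mono, bi)
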