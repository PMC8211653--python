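"""Four-parameter logistic dose-response fitting and derived potency metrics.

The workhorse model is the four-parameter logistic (4PL) on log10
concentration,

    response(x) = bottom + (top - bottom) / (1 + (x / xc50)**hill),

whose midpoint ``xc50`` is reported as an IC50 (biochemical inhibition) or
EC50 (cellular effect) depending on context.  The 4PL carries the exact
reparameterization symmetry (bottom, top, hill) -> (top, bottom, -hill);
fits are canonicalized to ``top >= bottom`` so that a descending inhibition
curve has ``hill > 0`` and its mirrored (activation) curve the same
parameters with ``hill < 0``.

Also here: percent inhibition against on-plate controls, surviving fractions
relative to an untreated reference, and the normalized area under a survival
curve used to summarize drug sensitivity across cell lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .plates import ValidationError

__all__ = [
    "FourPLFit",
    "four_pl",
    "fit_4pl",
    "percent_inhibition",
    "surviving_fraction",
    "auc_survival",
]


def four_pl(x, bottom: float, top: float, xc50: float, hill: float):
    """Evaluate the four-parameter logistic at concentration(s) *x* (> 0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (x / xc50) ** hill)


@dataclass
class FourPLFit:
    """Result of a 4PL least-squares fit.

    ``xc50`` is on the concentration scale of the input (molar throughout the
    package).  ``extrapolated`` flags a midpoint outside the tested span;
    ``indeterminate`` flags data whose dynamic range is indistinguishable from
    residual noise (monotone-flat series), in which case ``xc50`` should not
    be interpreted.  ``ci50`` is an optional bootstrap percentile interval.
    """

    bottom: float
    top: float
    hill: float
    xc50: float
    rss: float
    converged: bool
    extrapolated: bool
    indeterminate: bool
    n_points: int
    ci50: tuple[float, float] | None = field(default=None)

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.xc50, self.hill)


def _resid_factory(lx: np.ndarray, y: np.ndarray):
    def resid(p):
        b, t, l50, h = p
        z = np.clip(h * (lx - l50), -50.0, 50.0)
        return b + (t - b) / (1.0 + 10.0**z) - y

    return resid


def fit_4pl(
    concentrations,
    responses,
    *,
    bounds: tuple | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> FourPLFit:
    """Fit a 4PL to (concentration, response) pairs by least squares on log10(x).

    The optimizer is multi-started: the initial midpoint is placed at each
    distinct measured concentration with initial slope +1 and -1, and the best
    residual sum of squares wins — single-start 4PL fits are notorious for
    local minima when the midpoint initialization is off by orders of
    magnitude.  Parameters are unconstrained by default (``bottom`` may go
    negative); pass ``bounds=(lower, upper)`` as 4-vectors over
    ``(bottom, top, log10_xc50, hill)`` to constrain.

    Requires >= 5 distinct positive concentrations (a 0-dose/vehicle point is
    a normalization reference, not a fittable x).  With ``n_boot > 0`` a
    seeded nonparametric (pairs) bootstrap supplies a 95% percentile interval
    on xc50.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("concentrations and responses must be 1-D arrays of equal length")
    if not np.all(x > 0):
        raise ValidationError("all concentrations must be > 0 (store the vehicle point separately)")
    if not np.all(np.isfinite(y)):
        raise ValidationError("responses must be finite")
    if np.unique(x).size < 5:
        raise ValidationError("need >= 5 distinct concentrations for a 4PL fit")

    lx = np.log10(x)
    resid = _resid_factory(lx, y)
    lo, hi = (-np.inf, np.inf) if bounds is None else bounds
    b0, t0 = float(np.min(y)), float(np.max(y))
    best = None
    for l50 in np.unique(lx):
        for h0 in (1.0, -1.0):
            try:
                sol = least_squares(
                    resid,
                    x0=[b0, t0, l50, h0],
                    bounds=(lo, hi),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                    max_nfev=500,
                )
            except Exception:  # pragma: no cover - pathological start
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        raise ValidationError("4PL fit failed from every start")
    rss, sol = best
    b, t, l50, h = (float(v) for v in sol.x)
    if b > t:  # canonicalize the (b,t,h) <-> (t,b,-h) symmetry
        b, t, h = t, b, -h
    n = y.size
    rmse = np.sqrt(rss / max(n - 4, 1))
    span = abs(t - b)
    indeterminate = bool(np.ptp(y) == 0 or span <= 3.0 * rmse)
    fit = FourPLFit(
        bottom=b,
        top=t,
        hill=h,
        xc50=10.0**l50,
        rss=rss,
        converged=bool(sol.success),
        extrapolated=not (lx.min() <= l50 <= lx.max()),
        indeterminate=indeterminate,
        n_points=n,
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                bsol = least_squares(
                    _resid_factory(lx[idx], y[idx]),
                    x0=sol.x,
                    bounds=(lo, hi),
                    xtol=1e-10,
                    ftol=1e-10,
                    max_nfev=200,
                )
                boot.append(10.0 ** float(bsol.x[2]))
            except Exception:  # pragma: no cover
                continue
        if len(boot) >= max(20, n_boot // 2):
            fit.ci50 = tuple(np.percentile(boot, [2.5, 97.5]))
    return fit


def percent_inhibition(signal, neg_ctrl: float, pos_ctrl: float):
    """Percent inhibition of *signal* between uninhibited and fully inhibited controls.

    ``100 * (neg_ctrl - signal) / (neg_ctrl - pos_ctrl)`` where ``neg_ctrl``
    is the uninhibited (DMSO) reaction and ``pos_ctrl`` the fully inhibited or
    no-enzyme reaction.  0% at the negative control, 100% at the positive;
    affine-invariant to any common rescaling of signal and both controls.
    """
    neg = float(neg_ctrl)
    pos = float(pos_ctrl)
    if neg == pos or not (np.isfinite(neg) and np.isfinite(pos)):
        raise ValidationError("degenerate controls: neg_ctrl and pos_ctrl must differ and be finite")
    out = 100.0 * (neg - np.asarray(signal, dtype=float)) / (neg - pos)
    return float(out) if out.ndim == 0 else out


def surviving_fraction(treated, reference: float):
    """Surviving fraction: colony/viability values relative to the untreated reference.

    ``SF(dose) = value(dose) / value(reference)`` so the 0-dose (or 0 Gy)
    reference maps to exactly 1.0.  *reference* must be positive.
    """
    ref = float(reference)
    if not ref > 0:
        raise ValidationError("reference (0-dose) value must be > 0")
    out = np.asarray(treated, dtype=float) / ref
    return float(out) if out.ndim == 0 else out


def auc_survival(doses, sf) -> float:
    """Normalized area under a survival curve over log10 concentration.

    Trapezoidal area of SF over log10(dose), divided by the log10 span, so a
    completely insensitive line at SF = 1 scores exactly 1.0 and smaller
    values mean greater drug sensitivity.  Requires >= 3 positive doses;
    unordered doses are sorted with a warning.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(sf, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 (dose, SF) pairs")
    if not np.all(x > 0):
        raise ValidationError("doses must be > 0 for a log10 axis")
    if np.any(np.diff(x) < 0):
        warnings.warn("doses were not in ascending order; sorting", RuntimeWarning, stacklevel=2)
        order = np.argsort(x)
        x, y = x[order], y[order]
    lx = np.log10(x)
    span = lx[-1] - lx[0]
    if span <= 0:
        raise ValidationError("doses must span a nonzero log10 range")
    return float(np.trapezoid(y, lx) / span)
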