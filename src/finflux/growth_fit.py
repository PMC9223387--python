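"""Growth-versus-oxygen-saturation curve models and least-squares fitting.

Three model forms relate water oxygen saturation x (fraction of air
saturation) to relative growth rate mu/mu_max:

* ``metabolic`` — a piecewise-linear map from saturation to relative oxygen
  uptake rate r/r_max (zero below x0, linear up to x1, one above), composed
  with a monotone interpolator f of metabolic-model predictions:
  mu/mu_max = f(r/r_max).
* ``logistic`` — 2 / (1 + exp(k (x0 - x))) - 1, with asymptotes -1 and 1,
  so the curve crosses zero at x0.
* ``monod`` — (x - x0) / (Ks + x - x0) for x >= x0 (0 below): a Monod law
  extended with an x-intercept; half-maximal growth at x = x0 + Ks.

Fits are nonlinear least squares with Jacobian-based standard errors and
R-squared; non-convergence is flagged, never silently papered over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model_core import ModelValidationError

__all__ = [
    "SaturationMapping",
    "GrowthCurveFit",
    "eval_saturation",
    "eval_logistic",
    "eval_monod",
    "fit_growth",
]


@dataclass
class SaturationMapping:
    """Piecewise-linear saturation -> relative oxygen uptake map."""

    x0: float
    x1: float

    def validate(self) -> None:
        if not (self.x1 > self.x0 >= 0):
            raise ModelValidationError(
                f"need x1 > x0 >= 0, got x0={self.x0}, x1={self.x1}"
            )


def eval_saturation(x, m: SaturationMapping):
    """Relative oxygen uptake rate r/r_max at saturation ``x`` (vectorized)."""
    m.validate()
    x = np.asarray(x, dtype=float)
    r = (x - m.x0) / (m.x1 - m.x0)
    return np.clip(r, 0.0, 1.0)


def eval_logistic(x, x0: float, k: float):
    """Logistic relative growth with asymptotes -1 and 1, zero at x0."""
    x = np.asarray(x, dtype=float)
    return 2.0 / (1.0 + np.exp(k * (x0 - x))) - 1.0


def eval_monod(x, x0: float, ks: float):
    """Monod relative growth with x-intercept x0; 0.5 at x0 + Ks."""
    x = np.asarray(x, dtype=float)
    s = np.maximum(x - x0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ks + s > 0, s / (ks + s), np.where(s > 0, 1.0, 0.0))
    return out


@dataclass
class GrowthCurveFit:
    model_form: str
    params: dict[str, float]
    std_errors: dict[str, float]
    r_squared: float
    converged: bool
    message: str = ""
    metabolic_curve: list[tuple[float, float]] | None = None

    def predict(self, x):
        if self.model_form == "metabolic":
            mapping = SaturationMapping(self.params["x0"], self.params["x1"])
            return _interp_metabolic(eval_saturation(x, mapping),
                                     self.metabolic_curve)
        if self.model_form == "logistic":
            return eval_logistic(x, self.params["x0"], self.params["k"])
        return eval_monod(x, self.params["x0"], self.params["Ks"])


def _interp_metabolic(r_rel, curve):
    pts = np.asarray(curve, dtype=float)
    order = np.argsort(pts[:, 0])
    xs, ys = pts[order, 0], pts[order, 1]
    # anchor the interpolator at (0, 0): zero oxygen means zero growth
    if xs[0] > 0:
        xs = np.concatenate([[0.0], xs])
        ys = np.concatenate([[0.0], ys])
    return np.interp(r_rel, xs, ys)


def _initial_guess(x, y, form):
    x, y = np.asarray(x), np.asarray(y)
    lo = x[y > 0.05]
    hi = x[y > 0.95]
    x0 = float(lo.min()) if lo.size else float(x.min())
    x1 = float(hi.min()) if hi.size else float(x.max())
    if x1 <= x0:
        x1 = x0 + max(1e-3, float(x.max() - x.min()) / 2 or 1.0)
    if form == "metabolic":
        return {"x0": x0, "x1": x1}
    if form == "logistic":
        return {"x0": x0, "k": 4.0 / (x1 - x0)}
    return {"x0": x0, "Ks": (x1 - x0) / 2.0}


def fit_growth(
    data,
    form: str,
    metabolic_curve=None,
    initial: dict[str, float] | None = None,
) -> GrowthCurveFit:
    """Fit one growth model to (saturation, relative growth) observations.

    ``data`` is a sequence of (x, mu_rel) pairs (>= 3 required); the
    metabolic form additionally needs ``metabolic_curve``, a sequence of
    (r_rel, mu_rel) model predictions interpolated to build f. Standard
    errors come from the Jacobian covariance at the optimum; R-squared is
    1 - SS_res/SS_tot.
    """
    if form not in ("metabolic", "logistic", "monod"):
        raise ValueError(f"unknown model form {form!r}")
    pts = np.asarray(list(data), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ModelValidationError("need at least 3 (x, mu_rel) observations")
    if form == "metabolic" and metabolic_curve is None:
        raise ModelValidationError("metabolic form requires metabolic_curve")
    x, y = pts[:, 0], pts[:, 1]

    guess = dict(_initial_guess(x, y, form))
    if initial:
        guess.update(initial)
    names = list(guess)

    def residuals(theta):
        p = dict(zip(names, theta))
        if form == "metabolic":
            x1 = max(p["x1"], p["x0"] + 1e-9)
            pred = _interp_metabolic(
                eval_saturation(x, SaturationMapping(p["x0"], x1)),
                metabolic_curve,
            )
        elif form == "logistic":
            pred = eval_logistic(x, p["x0"], p["k"])
        else:
            pred = eval_monod(x, p["x0"], max(p["Ks"], 1e-12))
        return pred - y

    res = least_squares(residuals, [guess[n] for n in names],
                        method="lm" if form != "metabolic" else "trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    params = dict(zip(names, map(float, res.x)))
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    dof = max(1, len(x) - len(names))
    sigma2 = ss_res / dof
    try:
        JTJ = res.jac.T @ res.jac
        cov = sigma2 * np.linalg.pinv(JTJ)
        errs = dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None))))
    except Exception:
        errs = {n: float("nan") for n in names}

    return GrowthCurveFit(
        model_form=form,
        params=params,
        std_errors={k: float(v) for k, v in errs.items()},
        r_squared=r2,
        converged=bool(res.success),
        message=res.message if not res.success else "",
        metabolic_curve=(
            [(float(a), float(b)) for a, b in metabolic_curve]
            if metabolic_curve is not None else None
        ),
    )
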