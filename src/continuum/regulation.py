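"""Density-dependent regulation of fecundity and mortality.

Local density enters the vital rates only through the scaled density
``u = n(x) / K``, where n(x) is the kernel-smoothed local density and K is
the carrying-capacity parameter: at u = 1 the per-capita net reproductive
rate

    F(u) = f(u) * (1 - mu(u)) - mu(u)

is zero by construction for every built-in family, and F'(1) < 0, so the
equilibrium density is roughly K.  (Newborns are subject to the same
mortality as everyone else, hence the factor (1 - mu(u)) on fecundity.)

Four families decompose the same net response into different mechanisms:

``bh_mortality``   constant fecundity f; Beverton-Holt feedback on death:
                   survival (1+a) / ((1+f)(1+a*u)), valid for 0 < a <= f.
``bh_fecundity``   constant death probability mu0; fecundity
                   [alpha*(1+a)/(1+a*u) + mu0 - alpha] / (1 - mu0),
                   valid for 0 < alpha <= mu0 < 1.
``bh_compensatory`` fecundity f0/(1+b*u) decaying while survival
                   (1+F(u))/(1+f(u)) *increases* with density
                   (compensation), valid for f0 >= a*alpha, 0 < alpha < 1.
``ricker_fecundity`` constant death probability mu; Ricker feedback on
                   fecundity f(u) = exp(-(u-1)) * mu/(1-mu).

All three Beverton-Holt families share the net form
F(u) = alpha*((1+a)/(1+a*u) - 1) (alpha = 1 for bh_mortality), so with
matched (a, alpha) their F curves are identical even though the underlying
mechanisms — and hence age structure and selection responses — differ.

The discrete logistic F(u) = r*(1-u) is deliberately *not* available:
it is unbounded below, so random density fluctuations eventually produce
negative survival probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "RegulationModel",
    "fecundity",
    "mortality",
    "net_rate",
    "equilibrium",
    "regulation_table",
]

_FAMILIES = ("bh_mortality", "bh_fecundity", "bh_compensatory", "ricker_fecundity")


@dataclass(frozen=True)
class RegulationModel:
    """A paired (fecundity f(u), death probability mu(u)) response to scaled
    density.  Construct via the named classmethods; validity is enforced at
    construction so vital-rate calls never return out-of-range values."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        p = dict(self.params)
        fam = self.family
        if fam == "discrete_logistic":
            raise ValueError(
                "the discrete-logistic family is not supported: F(u) = r(1-u) is "
                "unbounded below, so density fluctuations eventually drive survival "
                "probabilities negative; use a Beverton-Holt or Ricker family instead"
            )
        if fam not in _FAMILIES:
            raise ValueError(f"unknown regulation family {fam!r}")
        if fam == "bh_mortality":
            f, a = p["f"], p["a"]
            if not (f > 0 and 0 < a <= f):
                raise ValueError(
                    f"bh_mortality requires 0 < a <= f (got a={a}, f={f}): "
                    "otherwise low-density survival exceeds 1"
                )
        elif fam == "bh_fecundity":
            mu0, alpha, a = p["mu0"], p["alpha"], p["a"]
            if not (0 < alpha <= mu0 < 1):
                raise ValueError(
                    f"bh_fecundity requires 0 < alpha <= mu0 < 1 "
                    f"(got alpha={alpha}, mu0={mu0}): fecundity must stay nonnegative"
                )
            if not a > 0:
                raise ValueError("bh_fecundity requires a > 0")
        elif fam == "bh_compensatory":
            f0, b, alpha, a = p["f0"], p["b"], p["alpha"], p["a"]
            if not (0 < alpha < 1):
                raise ValueError(f"bh_compensatory requires 0 < alpha < 1 (got {alpha})")
            if not (a > 0 and b > 0):
                raise ValueError("bh_compensatory requires a > 0 and b > 0")
            if not f0 >= a * alpha:
                raise ValueError(
                    f"bh_compensatory requires f0 >= a*alpha (got f0={f0}, a*alpha={a * alpha}): "
                    "otherwise survival probabilities leave [0, 1]"
                )
        elif fam == "ricker_fecundity":
            mu = p["mu"]
            if not (0 < mu < 1):
                raise ValueError(f"ricker_fecundity requires 0 < mu < 1 (got {mu})")
            p.setdefault("shifted", True)
        object.__setattr__(self, "params", p)

    # -- constructors ----------------------------------------------------

    @classmethod
    def beverton_holt_mortality(cls, f: float, a: float | None = None) -> "RegulationModel":
        """Constant fecundity ``f``; density raises mortality.  ``a`` defaults
        to ``f`` (the common choice, giving survival 1/(1 + f*u))."""
        return cls("bh_mortality", {"f": f, "a": f if a is None else a})

    @classmethod
    def beverton_holt_fecundity(cls, mu0: float, alpha: float, a: float) -> "RegulationModel":
        return cls("bh_fecundity", {"mu0": mu0, "alpha": alpha, "a": a})

    @classmethod
    def beverton_holt_compensatory(
        cls, f0: float, b: float, alpha: float, a: float
    ) -> "RegulationModel":
        return cls("bh_compensatory", {"f0": f0, "b": b, "alpha": alpha, "a": a})

    @classmethod
    def ricker(cls, mu: float, shifted: bool = True) -> "RegulationModel":
        """Ricker feedback on fecundity with constant death probability ``mu``.

        ``shifted=True`` (default) uses f(u) = exp(-(u-1)) * mu/(1-mu), which
        satisfies F(1) = 0.  ``shifted=False`` uses the plainer exp(-u)
        variant (the two differ by a factor of e, moving the equilibrium)."""
        return cls("ricker_fecundity", {"mu": mu, "shifted": shifted})

    @classmethod
    def discrete_logistic(cls, r: float):
        return cls("discrete_logistic", {"r": r})

    # -- vital rates -----------------------------------------------------

    def fecundity(self, u):
        """Mean offspring per individual per step at scaled density u >= 0."""
        u = np.asarray(u, dtype=float)
        p = self.params
        if self.family == "bh_mortality":
            out = np.broadcast_to(float(p["f"]), u.shape).copy()
        elif self.family == "bh_fecundity":
            mu0, alpha, a = p["mu0"], p["alpha"], p["a"]
            out = (alpha * (1.0 + a) / (1.0 + a * u) + mu0 - alpha) / (1.0 - mu0)
        elif self.family == "bh_compensatory":
            out = p["f0"] / (1.0 + p["b"] * u)
        else:
            mu = p["mu"]
            arg = -(u - 1.0) if p.get("shifted", True) else -u
            out = np.exp(arg) * mu / (1.0 - mu)
        return out if out.ndim else float(out)

    def mortality(self, u):
        """Death probability per step at scaled density u >= 0; always in [0, 1]."""
        u = np.asarray(u, dtype=float)
        p = self.params
        if self.family == "bh_mortality":
            f, a = p["f"], p["a"]
            out = 1.0 - (1.0 + a) / ((1.0 + f) * (1.0 + a * u))
        elif self.family == "bh_fecundity":
            out = np.broadcast_to(float(p["mu0"]), u.shape).copy()
        elif self.family == "bh_compensatory":
            alpha, a = p["alpha"], p["a"]
            F = alpha * ((1.0 + a) / (1.0 + a * u) - 1.0)
            out = 1.0 - (1.0 + F) / (1.0 + self.fecundity(u))
        else:
            out = np.broadcast_to(float(p["mu"]), u.shape).copy()
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def net_rate(self, u):
        """Per-capita net reproductive rate F(u) = f(u)(1 - mu(u)) - mu(u)."""
        u = np.asarray(u, dtype=float)
        out = self.fecundity(u) * (1.0 - self.mortality(u)) - self.mortality(u)
        return out if np.ndim(out) else float(out)

    @property
    def equilibrium_fecundity(self) -> float:
        """f(1): the mean fecundity at the equilibrium density (the f-bar used
        to convert post-reproduction density to pre-reproduction u)."""
        return float(self.fecundity(1.0))

    def equilibrium(self, u_max: float = 50.0):
        """Numeric root of F on (0, u_max] and its stability (sign of F')."""
        eps = 1e-9
        us = np.linspace(eps, u_max, 2048)
        Fs = np.atleast_1d(self.net_rate(us))
        sign = np.sign(Fs)
        idx = np.flatnonzero(np.diff(sign) != 0)
        root = None
        for i in idx:
            if Fs[i] == 0.0:
                root = us[i]
                break
            try:
                root = optimize.brentq(self.net_rate, us[i], us[i + 1], xtol=1e-12)
                break
            except ValueError:
                continue
        if root is None:
            if np.any(Fs == 0.0):
                root = float(us[np.argmax(Fs == 0.0)])
            else:
                raise ValueError(
                    f"no equilibrium: F(u) has no sign change on (0, {u_max}]"
                )
        h = 1e-6
        slope = (self.net_rate(root + h) - self.net_rate(max(root - h, eps))) / (2 * h)
        return float(root), bool(slope < 0)


# ---------------------------------------------------------------------------
# module-level operation wrappers


def fecundity(model: RegulationModel, u):
    return model.fecundity(u)


def mortality(model: RegulationModel, u):
    return model.mortality(u)


def net_rate(model: RegulationModel, u):
    return model.net_rate(u)


def equilibrium(model: RegulationModel, u_max: float = 50.0):
    return model.equilibrium(u_max=u_max)


def regulation_table(model: RegulationModel, u_max: float = 3.0, n: int = 61):
    """Tabulate f(u), mu(u), F(u) on [0, u_max] (the standard three-panel
    visualization of a regulation family) as a pandas DataFrame."""
    import pandas as pd

    u = np.linspace(0.0, u_max, n)
    return pd.DataFrame(
        {
            "u": u,
            "fecundity": model.fecundity(u),
            "mortality": model.mortality(u),
            "net_rate": model.net_rate(u),
        }
    )
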