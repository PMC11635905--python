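"""Trajectory model families for daily habit-strength series.

Six families describe how self-reported behavioral automaticity (SRBAI,
0-4 scale) evolves over the decay phase: four polynomials in time
(constant, linear, quadratic, cubic), an asymptotic (exponential-approach)
curve, and a four-parameter logistic. The asymptotic curve is

    f(t) = A + (R0 - A) * exp(-exp(lam) * t)

with lower asymptote ``A``, initial value ``R0`` (= f(0)) and log rate
constant ``lam`` (log keeps the rate positive). The logistic is

    f(t) = L + (U - L) / (1 + exp((t - m) / s))

with lower/upper asymptotes ``L``/``U``, midpoint ``m`` and scale
``s > 0``; with ``U > L`` the curve decays from ``U`` toward ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAMILY_ORDER",
    "ModelFamily",
    "FAMILIES",
    "get_family",
    "evaluate",
]

#: Canonical family order; also the tie-break order in BIC selection.
FAMILY_ORDER = ("constant", "linear", "quadratic", "cubic", "asymptotic", "logistic")


@dataclass(frozen=True)
class ModelFamily:
    """One trajectory family: its name, mean-structure parameter count
    and parameter names (in the order the parameter vector uses)."""

    name: str
    k_mean: int
    param_names: tuple[str, ...]

    @property
    def is_polynomial(self) -> bool:
        return self.name in ("constant", "linear", "quadratic", "cubic")

    @property
    def degree(self) -> int:
        """Polynomial degree; raises for non-polynomial families."""
        if not self.is_polynomial:
            raise ValueError(f"{self.name} is not a polynomial family")
        return self.k_mean - 1


FAMILIES: dict[str, ModelFamily] = {
    "constant": ModelFamily("constant", 1, ("b0",)),
    "linear": ModelFamily("linear", 2, ("b0", "b1")),
    "quadratic": ModelFamily("quadratic", 3, ("b0", "b1", "b2")),
    "cubic": ModelFamily("cubic", 4, ("b0", "b1", "b2", "b3")),
    "asymptotic": ModelFamily("asymptotic", 3, ("A", "R0", "lam")),
    "logistic": ModelFamily("logistic", 4, ("L", "U", "m", "s")),
}


def get_family(name: str) -> ModelFamily:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown model family {name!r}; expected one of {FAMILY_ORDER}"
        ) from None


def evaluate(family: str | ModelFamily, theta, t):
    """Evaluate a trajectory family at occasions ``t``.

    Parameters
    ----------
    family : str or ModelFamily
        Family name or object.
    theta : array-like
        Parameter vector; its length must equal the family's ``k_mean``.
    t : array-like
        Occasion(s), in days since the start of the decay phase.

    Returns
    -------
    ndarray or float
        Fitted value(s) ``f(t)``.
    """
    fam = get_family(family) if isinstance(family, str) else family
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (fam.k_mean,):
        raise ValueError(
            f"{fam.name} expects {fam.k_mean} parameters, got shape {theta.shape}"
        )
    t = np.asarray(t, dtype=float)
    if fam.is_polynomial:
        # polyval wants highest degree first
        return np.polyval(theta[::-1], t)
    if fam.name == "asymptotic":
        a, r0, lam = theta
        return a + (r0 - a) * np.exp(-np.exp(lam) * t)
    # logistic; exponent clipped against overflow far outside the window
    low, up, m, s = theta
    z = np.clip((t - m) / s, -700.0, 700.0)
    return low + (up - low) / (1.0 + np.exp(z))
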