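"""Closed-form extension predictions for a worm-like chain confined to a
stripe/channel of width w.

Two classical limits bracket the physics.  In the Gauss–de Gennes (blob)
regime the chain extension is lc*lp/w.  In the Odijk (deflection) regime,
reached when the channel is narrower than the persistence length, the
chain is nearly straight and extends to lc*[1 - A*(lp/w)^(-2/3)] with the
universal prefactor A = 0.17.  The window lp < w < 2*lp is the transition
between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TheoryPrediction",
    "contour_length",
    "degennes_extension",
    "odijk_extension",
    "classify_regime",
    "predict",
]


def contour_length(n_monomers: int, spacing_a: float) -> float:
    """Contour length lc = n*a (nm)."""
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if spacing_a <= 0:
        raise ValueError("spacing_a must be positive")
    return n_monomers * spacing_a


def degennes_extension(lc: float, lp: float, w: float) -> float:
    """Gauss–de Gennes predicted end-to-end distance lc*lp/w (nm)."""
    _check_positive(lc=lc, lp=lp, w=w)
    return lc * lp / w


def odijk_extension(lc: float, lp: float, w: float, A: float = 0.17) -> float:
    """Odijk predicted end-to-end distance lc*[1 - A*(lp/w)^(-2/3)] (nm).

    Raises for parameter combinations where the deflection correction
    A*(w/lp)^(2/3) reaches 1 (the regime does not apply)."""
    _check_positive(lc=lc, lp=lp, w=w)
    correction = A * (lp / w) ** (-2.0 / 3.0)
    if correction >= 1.0:
        raise ValueError(
            f"Odijk correction A*(lp/w)^(-2/3) = {correction:.3g} >= 1: "
            "deflection regime inapplicable"
        )
    return lc * (1.0 - correction)


def classify_regime(lp: float, w: float) -> str:
    """Confinement regime: 'odijk' for w <= lp, 'transition' for
    lp < w < 2*lp, 'degennes' for w >= 2*lp."""
    _check_positive(lp=lp, w=w)
    if w <= lp:
        return "odijk"
    if w < 2.0 * lp:
        return "transition"
    return "degennes"


@dataclass(frozen=True)
class TheoryPrediction:
    """Both confinement-theory extensions and the regime label for a
    chain of contour length lc and persistence length lp in a stripe of
    width w (all nm)."""

    lc: float
    lp: float
    w: float
    prefactor_A: float
    degennes_extension: float
    odijk_extension: float
    regime: str

    def to_dict(self) -> dict:
        return {
            "lc_nm": self.lc,
            "lp_nm": self.lp,
            "w_nm": self.w,
            "prefactor_A": self.prefactor_A,
            "degennes_extension_nm": self.degennes_extension,
            "odijk_extension_nm": self.odijk_extension,
            "regime": self.regime,
        }


def predict(n_monomers: int = 20, spacing_a: float = 0.625,
            lp: float = 1.39, w: float = 1.8, A: float = 0.17) -> TheoryPrediction:
    """Convenience wrapper: both predictions plus the regime label."""
    lc = contour_length(n_monomers, spacing_a)
    return TheoryPrediction(
        lc=lc, lp=lp, w=w, prefactor_A=A,
        degennes_extension=degennes_extension(lc, lp, w),
        odijk_extension=odijk_extension(lc, lp, w, A),
        regime=classify_regime(lp, w),
    )


def _check_positive(**kw: float) -> None:
    for name, val in kw.items():
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
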