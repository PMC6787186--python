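"""Coarse-grained model of a charged discrete worm-like chain adsorbed on a
patterned two-dimensional surface.

The chain is a bead–spring polymer confined to the plane of the surface
(the adsorbed molecule stays flat; out-of-plane motion is not modeled).
The surface is a lateral heterostructure of two materials, A and B, where
B binds every monomer more strongly by ``delta_eps``; the A/B boundary is
smoothed over a van-der-Waals-scale length ``smoothing_delta`` so that the
energy landscape is differentiable everywhere.  An optional in-plane
electric field along +x drives the charged chain.

Internal unit system: lengths in nm, times in ns, energies in kBT at the
convention temperature (300 K by default).  All public energies/forces are
expressed in kBT and kBT/nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "KB_EV_PER_K",
    "UnitsConvention",
    "ChainParams",
    "SurfacePattern",
    "FieldSpec",
    "ChainState",
    "kappa_from_persistence_length",
    "persistence_length_from_kappa",
    "surface_indicator",
    "potential_energy",
    "forces",
]

# Boltzmann constant
KB_KCAL_PER_MOL_K = 1.987204259e-3  # kcal/(mol K)
KB_EV_PER_K = 8.617333262e-5        # eV/K


@dataclass(frozen=True)
class UnitsConvention:
    """Unit conventions: nm / ns / kBT at a fixed temperature.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin.  Default 300 K.
    """

    temperature: float = 300.0

    @property
    def kBT_kcal_per_mol(self) -> float:
        """Thermal energy in kcal/mol (0.59616 at 300 K)."""
        return KB_KCAL_PER_MOL_K * self.temperature

    @property
    def kBT_eV(self) -> float:
        """Thermal energy in eV (0.025852 at 300 K); numerically equal to
        the thermal voltage kBT/e in volts."""
        return KB_EV_PER_K * self.temperature

    def kcal_per_mol_to_kBT(self, energy_kcal: float) -> float:
        return energy_kcal / self.kBT_kcal_per_mol

    def kBT_to_kcal_per_mol(self, energy_kBT: float) -> float:
        return energy_kBT * self.kBT_kcal_per_mol


_DEFAULT_UNITS = UnitsConvention()

# Self-avoidance swells the apparent persistence length: the exponential
# fit to tangent correlations of the default self-avoiding chain returns
# ~20% more than the bare-stiffness value.  The default bending stiffness
# is therefore the exact 2D (Bessel-ratio) mapping rescaled by this
# calibration constant, found by bisection with
# :func:`nanostripe.simulate.calibrate_bend_stiffness` so that the fitted
# lp of a free chain equals target_lp.  Applies only when the excluded
# volume is enabled; an ideal chain uses the bare mapping.
KAPPA_EV_RESCALE = 0.8743


def kappa_from_persistence_length(lp: float, a: float) -> float:
    """Bending stiffness (kBT) of a 2D discrete worm-like chain with target
    persistence length ``lp`` and bond length ``a``.

    For joint energy kappa*(1 - cos(theta)) in two dimensions the bond
    angles are independent with density proportional to exp(beta*kappa*
    cos(theta)) on (-pi, pi], so the tangent correlation per joint is the
    Bessel ratio <cos theta> = I1(beta*kappa)/I0(beta*kappa).  We invert
    <cos theta> = exp(-a/lp) exactly; the familiar small-angle mapping
    kappa = lp/(2a) is the first-order expansion and is noticeably off for
    lp/a of order one.
    """
    if lp <= 0 or a <= 0:
        raise ValueError("lp and a must be positive")
    target = math.exp(-a / lp)

    def f(x: float) -> float:
        # exponentially scaled Bessels avoid overflow for stiff chains
        return i1e(x) / i0e(x) - target

    hi = 4.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("stiffness inversion failed to bracket")
    return float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-14))


def persistence_length_from_kappa(kappa: float, a: float) -> float:
    """Inverse of :func:`kappa_from_persistence_length`."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    c = i1e(kappa) / i0e(kappa)
    return -a / math.log(c)


@dataclass
class ChainParams:
    """Parameters of the discrete worm-like chain standing in for a 20-mer
    ssDNA on the surface.

    ``bond_stiffness``, ``bend_stiffness_kappa`` and ``per_bead_friction``
    default to values derived from the other fields: 100 kBT/a² bonds, the
    calibrated 2D stiffness for ``target_lp`` (Bessel-ratio inversion
    times :data:`KAPPA_EV_RESCALE` when the excluded volume is on), and
    kBT/(n_beads · 0.13 nm²/ns) so that the whole chain diffuses at
    0.13 nm²/ns.

    The excluded volume has two scales.  A soft local term (diameter a/2,
    1 kBT, pairs at least 3 bonds apart) represents the backbone while
    keeping the tangent statistics close to the ideal worm-like chain, so
    that the exponential-fit persistence length of a free chain matches
    ``target_lp``.  An optional wider term for distant pairs
    (``ev_distant_*``: diameter 0.9 nm, pairs at least 8 bonds apart,
    default strength 0) represents the in-plane footprint of whole
    nucleotides; enabling it makes backfolded (hairpin) conformations
    expensive and substantially raises the extension of a stripe-confined
    chain, at the cost of self-avoidance swelling of the free-chain
    tangent correlations (the apparent lp roughly doubles).
    ``per_bead_charge`` is the magnitude of the effective charge per
    monomer, in units of e (default 10.2e/20).
    """

    n_beads: int = 20
    bond_length_a: float = 0.625          # nm
    target_lp: float = 1.39               # nm
    bond_stiffness: Optional[float] = None      # kBT/nm^2
    bend_stiffness_kappa: Optional[float] = None  # kBT
    excluded_volume: bool = True
    ev_diameter: Optional[float] = None   # nm, default = a/2
    ev_strength: float = 1.0              # kBT
    ev_distant_min_sep: int = 8
    ev_distant_diameter: float = 0.9      # nm, in-plane nucleotide footprint
    ev_distant_strength: float = 0.0      # kBT; off by default
    per_bead_charge: float = 10.2 / 20    # e
    per_bead_friction: Optional[float] = None   # kBT ns / nm^2

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if self.bond_length_a <= 0:
            raise ValueError("bond_length_a must be positive")
        if self.bond_stiffness is None:
            self.bond_stiffness = 100.0 / self.bond_length_a**2
        if self.bend_stiffness_kappa is None:
            self.bend_stiffness_kappa = kappa_from_persistence_length(
                self.target_lp, self.bond_length_a
            )
            if self.excluded_volume:
                self.bend_stiffness_kappa *= KAPPA_EV_RESCALE
        if self.bend_stiffness_kappa < 0:
            raise ValueError("bend_stiffness_kappa must be >= 0")
        if self.ev_diameter is None:
            # in-plane overlap footprint: the backbone vdW scale, not the
            # full monomer spacing (a diameter of a would make the 2D
            # chain strongly self-avoiding and inflate the apparent lp
            # far beyond any stiffness calibration)
            self.ev_diameter = self.bond_length_a / 2.0
        if self.per_bead_friction is None:
            self.per_bead_friction = 1.0 / (self.n_beads * 0.13)
        if self.per_bead_friction <= 0:
            raise ValueError("per_bead_friction must be positive")

    @property
    def contour_length(self) -> float:
        """n·a in nm (12.5 nm with defaults)."""
        return self.n_beads * self.bond_length_a

    @property
    def total_charge(self) -> float:
        """Total chain charge in e."""
        return self.n_beads * self.per_bead_charge


_GEOMETRIES = ("uniform", "single_boundary", "stripe")


@dataclass
class SurfacePattern:
    """Two-material adhesive surface: uniform, a single A|B boundary at
    x = 0, or a B stripe of width ``stripe_width_w`` along x centered at
    y = 0.

    ``delta_eps`` is the extra binding energy per bead on material B in
    kBT (negative: B binds more strongly; default −6.1 kcal/mol).
    ``base_eps`` is the uniform adsorption energy on material A, kept as
    metadata only — a uniform offset exerts no lateral force and
    desorption is not modeled.
    """

    geometry: str = "stripe"
    delta_eps: float = _DEFAULT_UNITS.kcal_per_mol_to_kBT(-6.1)   # kBT
    base_eps: float = _DEFAULT_UNITS.kcal_per_mol_to_kBT(-23.2)   # kBT, metadata
    stripe_width_w: float = 1.8      # nm
    smoothing_delta: float = 0.3     # nm

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; expected one of {_GEOMETRIES}"
            )
        if self.delta_eps >= 0:
            raise ValueError("delta_eps must be negative (B binds more strongly)")
        if self.stripe_width_w <= 0:
            raise ValueError("stripe_width_w must be positive")
        if self.smoothing_delta <= 0:
            raise ValueError("smoothing_delta must be positive")


@dataclass(frozen=True)
class FieldSpec:
    """In-plane electric field along +x, in V/nm.

    Either give ``field_E`` directly, or a (voltage, box length) pair from
    which E = V/Lx.  Zero field by default.
    """

    field_E: float = 0.0   # V/nm

    @classmethod
    def from_voltage(cls, voltage_V: float, box_length_Lx: float) -> "FieldSpec":
        if box_length_Lx <= 0:
            raise ValueError("box_length_Lx must be positive")
        return cls(field_E=voltage_V / box_length_Lx)


@dataclass
class ChainState:
    """Bead positions (n, 2) in nm at a time in ns."""

    positions: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_beads, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        d = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if d.size and not np.all(d > 0):
            raise ValueError("consecutive beads must not coincide")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# surface indicator and its gradient

def surface_indicator(position: np.ndarray, pattern: SurfacePattern) -> np.ndarray:
    """Smooth indicator s in [0, 1] of material B at ``position``.

    s = 0 deep inside material A, s = 1 deep inside B.  A single boundary
    uses s(x) = (1 + tanh(x/delta))/2; a stripe of width w centered on
    y = 0 uses s(y) = (tanh((y + w/2)/delta) - tanh((y - w/2)/delta))/2.
    Uniform geometry has s identically 0.
    """
    pos = np.asarray(position, dtype=np.float64)
    scalar = pos.ndim == 1
    pos = np.atleast_2d(pos)
    d = pattern.smoothing_delta
    if pattern.geometry == "uniform":
        s = np.zeros(pos.shape[0])
    elif pattern.geometry == "single_boundary":
        s = 0.5 * (1.0 + np.tanh(pos[:, 0] / d))
    else:  # stripe
        y = pos[:, 1]
        hw = pattern.stripe_width_w / 2.0
        s = 0.5 * (np.tanh((y + hw) / d) - np.tanh((y - hw) / d))
    return float(s[0]) if scalar else s


def _surface_indicator_grad(pos: np.ndarray, pattern: SurfacePattern) -> np.ndarray:
    """Gradient of the indicator, shape (n, 2)."""
    grad = np.zeros_like(pos)
    d = pattern.smoothing_delta
    if pattern.geometry == "single_boundary":
        grad[:, 0] = 0.5 / d / np.cosh(pos[:, 0] / d) ** 2
    elif pattern.geometry == "stripe":
        hw = pattern.stripe_width_w / 2.0
        y = pos[:, 1]
        grad[:, 1] = 0.5 / d * (
            1.0 / np.cosh((y + hw) / d) ** 2 - 1.0 / np.cosh((y - hw) / d) ** 2
        )
    return grad


# ---------------------------------------------------------------------------
# potential energy and forces

def potential_energy(
    state: ChainState,
    params: ChainParams,
    pattern: SurfacePattern,
    field: FieldSpec = FieldSpec(),
    units: UnitsConvention = _DEFAULT_UNITS,
) -> dict:
    """Energy breakdown of a chain configuration, in kBT.

    Terms: harmonic bonds, worm-like-chain bending kappa*(1 - cos theta),
    soft excluded-volume repulsion, adhesive surface term
    delta_eps * sum_i s(r_i) (the uniform base depth is deliberately
    dropped — it exerts no lateral force), and the field term
    -sum_i q_i E x_i converted from eV to kBT.
    """
    if state.n_beads != params.n_beads:
        raise ValueError(
            f"state has {state.n_beads} beads but params expect {params.n_beads}"
        )
    pos = state.positions
    bonds = np.diff(pos, axis=0)
    blen = np.linalg.norm(bonds, axis=1)

    e_bond = 0.5 * params.bond_stiffness * np.sum((blen - params.bond_length_a) ** 2)

    # bending: interior joints between consecutive unit tangents
    u = bonds / blen[:, None]
    cos_t = np.sum(u[:-1] * u[1:], axis=1)
    e_bend = params.bend_stiffness_kappa * np.sum(1.0 - cos_t)

    e_ev = 0.0
    if params.excluded_volume and params.n_beads > 2:
        dr = pos[:, None, :] - pos[None, :, :]
        r = np.linalg.norm(dr, axis=-1)
        # local backbone repulsion.  1-2 and 1-3 pairs are excluded: bonds
        # and the bending potential own that geometry, and a 1-3 repulsion
        # would act as a spurious extra bending stiffness.
        for k_min, sigma, eps in (
            (3, params.ev_diameter, params.ev_strength),
            (params.ev_distant_min_sep, params.ev_distant_diameter,
             params.ev_distant_strength),
        ):
            iu, ju = np.triu_indices(params.n_beads, k=k_min)
            rp = r[iu, ju]
            overlap = rp < sigma
            if np.any(overlap):
                x = rp[overlap] / sigma
                e_ev += eps * float(np.sum((1.0 - x * x) ** 2))

    e_surf = pattern.delta_eps * float(np.sum(surface_indicator(pos, pattern)))

    e_field = 0.0
    if field.field_E != 0.0:
        # q[e] * E[V/nm] * x[nm] -> eV; divide by kBT in eV
        e_field = -params.per_bead_charge * field.field_E * float(np.sum(pos[:, 0]))
        e_field /= units.kBT_eV

    total = e_bond + e_bend + e_ev + e_surf + e_field
    return {
        "bond": float(e_bond),
        "bend": float(e_bend),
        "excluded_volume": float(e_ev),
        "surface": float(e_surf),
        "field": float(e_field),
        "total": float(total),
    }


def forces(
    state: ChainState,
    params: ChainParams,
    pattern: SurfacePattern,
    field: FieldSpec = FieldSpec(),
    units: UnitsConvention = _DEFAULT_UNITS,
) -> np.ndarray:
    """Per-bead force (n, 2) in kBT/nm: the exact negative gradient of
    :func:`potential_energy` (analytic derivatives throughout, including
    the sech² surface-boundary term)."""
    if state.n_beads != params.n_beads:
        raise ValueError(
            f"state has {state.n_beads} beads but params expect {params.n_beads}"
        )
    pos = state.positions
    n = params.n_beads
    f = np.zeros_like(pos)

    bonds = np.diff(pos, axis=0)
    blen = np.linalg.norm(bonds, axis=1)
    u = bonds / blen[:, None]

    # bonds: dU/d|b| = k (|b| - a) along the bond
    fb = params.bond_stiffness * (blen - params.bond_length_a)
    pair = fb[:, None] * u
    f[:-1] += pair
    f[1:] -= pair

    # bending: U = kappa (1 - cos theta); gradient of cos theta w.r.t. the
    # two bond vectors b1, b2 at each interior joint
    if n > 2 and params.bend_stiffness_kappa != 0.0:
        kappa = params.bend_stiffness_kappa
        b1 = bonds[:-1]
        b2 = bonds[1:]
        l1 = blen[:-1, None]
        l2 = blen[1:, None]
        c = np.sum(u[:-1] * u[1:], axis=1)[:, None]
        dc_db1 = b2 / (l1 * l2) - c * b1 / (l1 * l1)
        dc_db2 = b1 / (l1 * l2) - c * b2 / (l2 * l2)
        # dU/db = -kappa * dc/db ; b1 = r_{i+1}-r_i, b2 = r_{i+2}-r_{i+1}
        g1 = -kappa * dc_db1
        g2 = -kappa * dc_db2
        # force = -dU/dr
        f[:-2] += g1
        f[1:-1] -= g1
        f[1:-1] += g2
        f[2:] -= g2

    if params.excluded_volume and n > 2:
        for k_min, sigma, eps in (
            (3, params.ev_diameter, params.ev_strength),
            (params.ev_distant_min_sep, params.ev_distant_diameter,
             params.ev_distant_strength),
        ):
            iu, ju = np.triu_indices(n, k=k_min)
            dr = pos[iu] - pos[ju]
            r = np.linalg.norm(dr, axis=1)
            mask = r < sigma
            if np.any(mask):
                ii, jj = iu[mask], ju[mask]
                rr = r[mask][:, None]
                x = rr / sigma
                # U = eps (1 - x^2)^2, dU/dr = -4 eps x (1 - x^2) / sigma
                mag = 4.0 * eps * (x / sigma) * (1.0 - x * x)  # -dU/dr
                fij = mag * dr[mask] / rr
                np.add.at(f, ii, fij)
                np.add.at(f, jj, -fij)

    f -= pattern.delta_eps * _surface_indicator_grad(pos, pattern)

    if field.field_E != 0.0:
        f[:, 0] += params.per_bead_charge * field.field_E / units.kBT_eV

    return f
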