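"""End-to-end study pipeline: theory numbers, stripe-confinement
extension, and the diffusion/mobility/effective-charge transport chain,
computed from freshly generated Brownian-dynamics trajectories.

Every quantity is produced at run time from the default study conditions
(20 beads, a = 0.625 nm, lp = 1.39 nm, w = 1.8 nm, Δε = −6.1 kcal/mol per
bead, chain diffusion 0.13 nm²/ns, total charge 10.2 e).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import analysis, confinement
from .model import ChainParams, FieldSpec, SurfacePattern
from .simulate import Scenario, run_scenario

__all__ = [
    "theory_numbers",
    "stripe_extension",
    "free_diffusion",
    "driven_mobility",
    "transport_pipeline",
    "persistence_recovery",
    "reproduce",
]

logger = logging.getLogger("nanostripe")


def _subseed(seed: int, k: int) -> int:
    """Derive independent per-run seeds from one base seed."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def theory_numbers(n: int = 20, a: float = 0.625, lp: float = 1.39,
                   w: float = 1.8, A: float = 0.17) -> confinement.TheoryPrediction:
    """Closed-form confinement predictions for the study parameters."""
    return confinement.predict(n, a, lp, w, A)


def stripe_extension(seed: int, n_steps: int = 10_000_000,
                     discard_fraction: float = 1.0 / 3.0) -> dict:
    """Mean end-to-end distance (nm) of the default chain confined on the
    1.8-nm deep-binding stripe, averaged over the production segment of a
    default stripe run (the first ``discard_fraction`` is equilibration)."""
    sc = Scenario.preset(
        "stripe_confinement", seed,
        n_steps=n_steps, equilibration_fraction=discard_fraction,
    )
    traj = run_scenario(sc)
    ee = analysis.end_to_end(traj)
    return {
        "mean_end_to_end_nm": float(np.mean(ee)),
        "std_end_to_end_nm": float(np.std(ee)),
        "n_frames": traj.n_frames,
        "duration_ns": float(traj.times[-1] - traj.times[0]),
    }


def free_diffusion(seed: int, n_steps: int = 10_000_000,
                   sample_every: int = 100) -> dict:
    """Chain COM diffusion constant along the stripe from a zero-field run
    (MSD slope over the default small-lag window, halved)."""
    sc = Scenario.preset(
        "driven_transport", seed, field=FieldSpec(0.0),
        n_steps=n_steps, sample_every=sample_every,
        equilibration_fraction=0.0,
    )
    traj = run_scenario(sc)
    x = analysis.com_series(traj, axis=0)
    lags, curve = analysis.msd(x, max_lag=min(1000, traj.n_frames // 4),
                               dt=traj.dt_between_frames)
    D, window = analysis.fit_diffusion_1d(lags, curve)
    return {
        "D_nm2_per_ns": D,
        "msd_fit_window_ns": window,
        "duration_ns": float(traj.times[-1] - traj.times[0]),
        "lags_ns": lags,
        "msd_nm2": curve,
    }


def driven_mobility(seed: int,
                    fields_V_per_nm: tuple[float, ...] = (0.002, 0.005, 0.01),
                    n_steps: int = 6_000_000) -> dict:
    """Electrophoretic mobility from drift fits at several field
    strengths: through-origin slope of v against E."""
    pairs = []
    for k, E in enumerate(fields_V_per_nm):
        sc = Scenario.preset(
            "driven_transport", _subseed(seed, 100 + k),
            field=FieldSpec(field_E=E), n_steps=n_steps,
            equilibration_fraction=0.05,
        )
        traj = run_scenario(sc)
        x = analysis.com_series(traj, axis=0)
        v = analysis.drift_velocity(traj.times, x)
        logger.info("driven run E=%.4g V/nm: v=%.4g nm/ns", E, v)
        pairs.append((E, v))
    mu = analysis.fit_mobility(pairs)
    return {"mu_nm2_per_ns_V": mu, "velocity_pairs": pairs}


def transport_pipeline(seed: int, n_steps_free: int = 10_000_000,
                       n_steps_driven: int = 6_000_000,
                       temperature: float = 300.0) -> dict:
    """Full Einstein-relation chain: D from a free run, mu from driven
    runs, q_eff = kBT mu / D, screening vs the 19 backbone charges, and
    the Manning prediction for comparison."""
    free = free_diffusion(_subseed(seed, 1), n_steps=n_steps_free)
    driven = driven_mobility(_subseed(seed, 2), n_steps=n_steps_driven)
    D = free["D_nm2_per_ns"]
    mu = driven["mu_nm2_per_ns_V"]
    q_eff = analysis.effective_charge(mu, D, temperature)
    return {
        "D_nm2_per_ns": D,
        "mu_nm2_per_ns_V": mu,
        "q_eff_e": q_eff,
        "screening_fraction": analysis.screening_fraction(q_eff, 19),
        "manning_condensed_fraction": analysis.manning_condensed_fraction(0.625),
        "velocity_pairs": driven["velocity_pairs"],
        "msd_fit_window_ns": free["msd_fit_window_ns"],
    }


def persistence_recovery(seed: int, n_steps: int = 5_000_000,
                         n_runs: int = 4) -> dict:
    """Persistence length recovered from free (uniform-surface) runs via
    the tangent-correlation fit.

    Correlations are pooled over ``n_runs`` independent replicas before
    fitting: a single run of a 20-mer can sit in a long-lived
    conformational excursion that biases the whole curve, and replica
    averaging is what removes it.
    """
    corrs, ses, spacings = [], [], []
    for k in range(n_runs):
        sc = Scenario.preset("free_uniform", _subseed(seed, 300 + k),
                             n_steps=n_steps)
        traj = run_scenario(sc)
        c, se = analysis.tangent_correlation(traj, max_sep=8,
                                             return_stderr=True)
        corrs.append(c)
        ses.append(se)
        spacings.append(analysis.mean_spacing(traj))
    corr = np.mean(corrs, axis=0)
    se = np.sqrt(np.mean(np.square(ses), axis=0) / n_runs)
    a_meas = float(np.mean(spacings))
    fit = analysis.fit_persistence_length(corr, a_meas, fit_range=(1, 6),
                                          stderr=se)
    return {
        "lp_nm": fit.lp,
        "mean_spacing_nm": a_meas,
        "correlations": corr,
        "stderr": se,
        "fit_range": fit.fit_range,
        "n_runs": n_runs,
    }


@dataclass
class ReproRow:
    quantity: str
    units: str
    computed: float
    reference: float


def reproduce(seed: int, fast: bool = False) -> list[ReproRow]:
    """Recompute the study's headline numbers and pair each with its
    reference value.  ``fast`` shortens the simulations ~10x for smoke
    runs (larger statistical error)."""
    scale = 10 if fast else 1
    th = theory_numbers()
    stripe = stripe_extension(_subseed(seed, 10),
                              n_steps=10_000_000 // scale)
    trans = transport_pipeline(_subseed(seed, 20),
                               n_steps_free=10_000_000 // scale,
                               n_steps_driven=6_000_000 // scale)
    lp = persistence_recovery(_subseed(seed, 30),
                              n_steps=2_000_000 // scale)
    return [
        ReproRow("de Gennes extension", "Å", th.degennes_extension * 10, 96.5),
        ReproRow("Odijk extension", "Å", th.odijk_extension * 10, 99.8),
        ReproRow("stripe-confined end-to-end", "Å",
                 stripe["mean_end_to_end_nm"] * 10, 96.8),
        ReproRow("persistence length", "nm", lp["lp_nm"], 1.39),
        ReproRow("diffusion constant D", "nm²/ns", trans["D_nm2_per_ns"], 0.13),
        ReproRow("mobility μ", "nm²/(ns·V)", trans["mu_nm2_per_ns_V"], 51.6),
        ReproRow("effective charge q_eff", "e", trans["q_eff_e"], 10.2),
        ReproRow("screening fraction", "%",
                 trans["screening_fraction"] * 100, 46.0),
        ReproRow("Manning condensed fraction", "%",
                 trans["manning_condensed_fraction"] * 100, 12.0),
    ]
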