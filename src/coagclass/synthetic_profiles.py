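"""Synthetic trajectory cohorts with planted, time-localized group signal.

These generators build artificial "simulation profiles" directly — no ODE
solving — so that selection and importance machinery can be validated
against a known ground truth: which species carries discriminating signal,
and in which time interval.  Each species trajectory is a smooth bump
(scaled Gaussian) plus smooth low-frequency noise; for signal species the
bump amplitude differs between groups only inside a chosen time interval.

They are test/validation fixtures, not models of coagulation chemistry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import FACTORS, Cohort
from .kinetics import SimulationProfile

__all__ = ["planted_profile_cohort"]


def _smooth_noise(rng: np.random.Generator, times: np.ndarray,
                  scale: float, n_modes: int = 6) -> np.ndarray:
    """Band-limited noise: a few random low-frequency cosine modes."""
    t = times / times[-1]
    out = np.zeros_like(t)
    for _ in range(n_modes):
        freq = rng.uniform(0.5, 4.0)
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.normal(0, 1) * np.cos(2 * np.pi * freq * t + phase)
    return scale * out / np.sqrt(n_modes)


def planted_profile_cohort(
    n_per_group: int = 100,
    species: tuple[str, ...] = ("S0", "S1", "S2", "S3", "S4"),
    signal: dict[str, tuple[float, float, float]] | None = None,
    t_end: float = 3600.0,
    n_out: int = 3601,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[Cohort, list[SimulationProfile], np.ndarray]:
    """Two-group profile cohort with signal planted in known time intervals.

    Parameters
    ----------
    signal
        Maps a species name to ``(t_lo, t_hi, effect)``: group "B" samples
        get an extra bump of amplitude ``effect`` supported on
        ``[t_lo, t_hi]`` for that species.  Species not in the map are pure
        noise and identical in distribution between groups.
    noise
        SD scale of the smooth per-sample noise added to every trajectory.

    Returns
    -------
    cohort, profiles, labels
        A :class:`Cohort` (factor percentages are uninformative noise around
        100%), one profile per sample, and the group label array.
    """
    if signal is None:
        signal = {}
    unknown = set(signal) - set(species)
    if unknown:
        raise ValueError(f"signal species not in species list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_out)
    labels = np.array(["A"] * n_per_group + ["B"] * n_per_group)

    profiles = []
    for lab in labels:
        rows = []
        for sp in species:
            # common baseline: broad bump peaking mid-simulation
            centre = 0.4 * t_end
            width = 0.25 * t_end
            amp = rng.lognormal(mean=0.0, sigma=0.15)
            base = amp * np.exp(-0.5 * ((times - centre) / width) ** 2)
            traj = base + _smooth_noise(rng, times, noise)
            if lab == "B" and sp in signal:
                t_lo, t_hi, effect = signal[sp]
                c = 0.5 * (t_lo + t_hi)
                w = (t_hi - t_lo) / 4.0
                bump = np.exp(-0.5 * ((times - c) / w) ** 2)
                bump[(times < t_lo) | (times > t_hi)] = 0.0
                traj = traj + effect * rng.lognormal(0.0, 0.1) * bump
            rows.append(traj)
        profiles.append(SimulationProfile(times, np.vstack(rows), list(species)))

    pct = pd.DataFrame(
        rng.lognormal(np.log(100.0), 0.05, size=(2 * n_per_group, len(FACTORS))),
        columns=list(FACTORS),
    )
    cohort = Cohort(pct, pd.Series(labels, name="group"))
    return cohort, profiles, labels
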