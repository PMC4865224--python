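"""Featurization of simulated clotting trajectories.

Four feature sets are produced from each virtual patient's simulation:

1. **PCHIP coefficients** — each species' normalized profile is fit with a
   shape-preserving piecewise cubic Hermite interpolant on 139 uniform
   pieces (~26 s each); the 4 coefficients per piece, in the layout
   ``C3*(t-t_i)**3 + C2*(t-t_i)**2 + C1*(t-t_i) + C0``, are features.
   34 species x 139 pieces x 4 coefficients = 18 904 features.
2. **Moving averages** — 18 consecutive 200-second window means of each
   normalized profile (34 x 18 = 612 features).  Window k covers
   [200k, 200(k+1)] s and is labelled by its centre, 100 + 200k s.
3. **Conventional thrombin-generation parameters** — 11 scalars summarising
   the raw (molar) thrombin (IIa) and factor Xa profiles: time to 2 nM
   thrombin, AUC, peak level, peak rate, and the times of both peaks.
4. **Initial composition** — the 8 raw factor percentages.

Profiles are normalized per species by a reference peak: the species'
maximum over a single simulation started from the 100% (physiological-mean)
composition, so normalized trajectories are dimensionless and O(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .cohort import DEFAULT_TRIGGER_TF, PHYSIOLOGICAL_MEANS, FACTORS, Cohort
from .kinetics import ReactionNetwork, SimulationProfile, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "reference_peaks",
    "normalize_profile",
    "fit_pchip",
    "moving_averages",
    "conventional_features",
    "assemble_feature_matrix",
    "N_PIECES",
    "N_WINDOWS",
    "WINDOW_LENGTH_S",
    "CONVENTIONAL_NAMES",
]

#: Number of PCHIP pieces over [0, 3600] s (each ~25.9 s long).
N_PIECES = 139
#: Number of 200-s moving-average windows over [0, 3600] s.
N_WINDOWS = 18
WINDOW_LENGTH_S = 200.0
#: Thrombin threshold used for the "time to 2 nM" conventional feature.
THROMBIN_THRESHOLD_M = 2e-9

CONVENTIONAL_NAMES = (
    "IIa|conv|t_2nM",
    "IIa|conv|auc",
    "IIa|conv|max_level",
    "IIa|conv|max_rate",
    "IIa|conv|t_max_level",
    "IIa|conv|t_max_rate",
    "fXa|conv|auc",
    "fXa|conv|max_level",
    "fXa|conv|max_rate",
    "fXa|conv|t_max_level",
    "fXa|conv|t_max_rate",
)


@dataclass
class FeatureMatrix:
    """Samples x features with provenance labels and group labels."""

    values: np.ndarray
    feature_labels: list[str]
    group_labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.feature_labels) != p:
            raise ValueError("feature_labels length must match column count")
        if len(self.group_labels) != n or len(self.sample_ids) != n:
            raise ValueError("row labels must match sample count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select(self, labels: Sequence[str]) -> "FeatureMatrix":
        """Restrict to a named subset of feature columns (order preserved)."""
        index = {lab: j for j, lab in enumerate(self.feature_labels)}
        try:
            cols = [index[lab] for lab in labels]
        except KeyError as exc:
            raise KeyError(f"unknown feature label {exc.args[0]!r}") from None
        return FeatureMatrix(
            self.values[:, cols], list(labels), self.group_labels, self.sample_ids
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_labels)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def reference_peaks(
    network: ReactionNetwork,
    trigger_tf: float = DEFAULT_TRIGGER_TF,
    means: Mapping[str, float] = PHYSIOLOGICAL_MEANS,
    t_end: float = 3600.0,
    n_out: int = 3601,
) -> dict[str, float]:
    """Per-species normalization peaks from the physiological-mean simulation.

    Simulates once with every factor at 100% of its physiological mean and
    the standard trigger, and records each species' maximum concentration.
    Species that are never produced (peak below the solver's absolute
    tolerance) get reference 1.0 so that normalization is a no-op for them;
    a warning is logged.
    """
    from .cohort import to_initial_conditions

    sample = {f: 100.0 for f in FACTORS}
    x0 = to_initial_conditions(sample, network, trigger_tf=trigger_tf, means=means)
    profile = simulate(network, x0, t_end=t_end, n_out=n_out)
    peaks: dict[str, float] = {}
    for name in network.species_names:
        peak = float(profile.trajectory(name).max())
        if peak <= 1e-14:
            logger.warning(
                "species %r never produced at mean composition; reference peak "
                "set to 1.0", name,
            )
            peak = 1.0
        peaks[name] = peak
    return peaks


def normalize_profile(
    profile: SimulationProfile, peaks: Mapping[str, float]
) -> SimulationProfile:
    """Divide each species' trajectory by its reference peak (dimensionless)."""
    scale = np.array([peaks[name] for name in profile.species_names])
    return SimulationProfile(
        profile.times,
        profile.concentrations / scale[:, None],
        list(profile.species_names),
    )


# --- PCHIP coefficients -------------------------------------------------------

def pchip_knots(n_pieces: int = N_PIECES, t_end: float = 3600.0) -> np.ndarray:
    """The ``n_pieces + 1`` uniform knot times over [0, t_end]."""
    return np.linspace(0.0, t_end, n_pieces + 1)


def fit_pchip(
    profile: SimulationProfile,
    n_pieces: int = N_PIECES,
    t_end: float = 3600.0,
) -> dict[str, np.ndarray]:
    """Fit each species with a monotonicity-preserving cubic Hermite spline.

    The profile is sampled at the uniform knots (linear interpolation from
    the stored grid) and interpolated with PCHIP, which is C1 across knots
    and introduces no overshoot on monotone data.  Returns, per species, a
    ``(n_pieces, 4)`` array of coefficients in the order (C3, C2, C1, C0)
    for the local polynomial on piece i starting at knot t_i; C0 equals the
    knot value.
    """
    if profile.times[-1] < t_end:
        raise ValueError(
            f"profile ends at {profile.times[-1]} s but knots extend to {t_end} s"
        )
    knots = pchip_knots(n_pieces, t_end)
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(profile.species_names):
        y = np.interp(knots, profile.times, profile.concentrations[i])
        interp = PchipInterpolator(knots, y, extrapolate=False)
        # interp.c is (4, n_pieces): row 0 multiplies (t-t_i)^3 ... row 3 is C0
        out[name] = interp.c.T.copy()
    return out


def pchip_feature_labels(
    species_names: Sequence[str], n_pieces: int = N_PIECES
) -> list[str]:
    return [
        f"{name}|pchip|p{i:03d}|C{3 - c}"
        for name in species_names
        for i in range(n_pieces)
        for c in range(4)
    ]


# --- moving averages ----------------------------------------------------------

def _window_mean(times: np.ndarray, values: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal mean of values(t) over [a, b] on the stored grid."""
    ta = np.interp(a, times, values)
    tb = np.interp(b, times, values)
    inside = (times > a) & (times < b)
    t = np.concatenate(([a], times[inside], [b]))
    v = np.concatenate(([ta], values[inside], [tb]))
    return float(np.trapezoid(v, t) / (b - a))


def moving_averages(
    profile: SimulationProfile, n_windows: int = N_WINDOWS,
    window_s: float = WINDOW_LENGTH_S,
) -> dict[str, np.ndarray]:
    """Per species, the 18 consecutive 200-s window means (1/200 * integral).

    Window k covers [200k, 200(k+1)] s; the windows partition [0, 3600]
    exactly, so window-sum x 200 equals the trapezoidal AUC of the profile.
    """
    if profile.times[-1] < n_windows * window_s:
        raise ValueError("profile does not cover the moving-average windows")
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(profile.species_names):
        vals = np.array([
            _window_mean(
                profile.times, profile.concentrations[i],
                k * window_s, (k + 1) * window_s,
            )
            for k in range(n_windows)
        ])
        out[name] = vals
    return out


def ma_feature_labels(
    species_names: Sequence[str], n_windows: int = N_WINDOWS
) -> list[str]:
    return [
        f"{name}|ma|w{k:02d}" for name in species_names for k in range(n_windows)
    ]


def ma_window_centre(k: int, window_s: float = WINDOW_LENGTH_S) -> float:
    """Centre time (s) of window k: 100 + 200k for the default windows."""
    return window_s / 2.0 + k * window_s


# --- conventional thrombin-generation parameters ------------------------------

def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float:
    """Time of the first upward crossing of ``level`` (linear interpolation).

    Returns the final time as a right-censoring sentinel when the level is
    never reached (logged), so downstream classifiers see no missing values.
    """
    above = values >= level
    if above[0]:
        return float(times[0])
    idx = np.argmax(above)
    if not above[idx]:
        logger.warning(
            "profile never reaches %.3g M; returning censored time %.0f s",
            level, times[-1],
        )
        return float(times[-1])
    t0, t1 = times[idx - 1], times[idx]
    v0, v1 = values[idx - 1], values[idx]
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def _peak_and_time(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    i = int(np.argmax(values))  # argmax takes the earliest tie
    return float(values[i]), float(times[i])


def conventional_features(
    iia: np.ndarray, fxa: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """The 11 conventional summary parameters of raw IIa and fXa profiles.

    Order matches :data:`CONVENTIONAL_NAMES`: thrombin time-to-2 nM, AUC,
    peak level, peak rate, peak-level time, peak-rate time; then fXa AUC,
    peak level, peak rate, peak-level time, peak-rate time.  Rates are
    estimated by central finite differences on the stored grid; peak times
    take the earliest maximum.
    """
    feats = []
    for name, traj in (("IIa", iia), ("fXa", fxa)):
        traj = np.asarray(traj, dtype=float)
        rate = np.gradient(traj, times)
        auc = float(np.trapezoid(traj, times))
        max_level, t_max_level = _peak_and_time(times, traj)
        max_rate, t_max_rate = _peak_and_time(times, rate)
        if name == "IIa":
            feats.append(_first_crossing(times, traj, THROMBIN_THRESHOLD_M))
        feats.extend([auc, max_level, max_rate, t_max_level, t_max_rate])
    return np.array(feats)


# --- assembly -----------------------------------------------------------------

def assemble_feature_matrix(
    cohort: Cohort,
    profiles: Sequence[SimulationProfile] | None,
    which: str,
    peaks: Mapping[str, float] | None = None,
    n_pieces: int = N_PIECES,
    n_windows: int = N_WINDOWS,
) -> FeatureMatrix:
    """Build the samples-x-features matrix for one of the four feature sets.

    Parameters
    ----------
    which
        ``"pchip"``, ``"ma"``, ``"conventional"`` or ``"initial"``.
        PCHIP and moving-average features are computed on profiles
        normalized by ``peaks``; conventional features use the raw molar
        profiles; ``"initial"`` uses the cohort percentages directly and
        needs no profiles.
    """
    n = len(cohort)
    groups = np.asarray(cohort.labels)
    ids = np.arange(n)
    if which == "initial":
        return FeatureMatrix(
            cohort.samples.to_numpy(),
            [f"{f}|initial|pct" for f in FACTORS],
            groups, ids,
        )
    if profiles is None or len(profiles) != n:
        raise ValueError(
            f"need one profile per cohort sample ({n}), got "
            f"{0 if profiles is None else len(profiles)}"
        )
    if which in ("pchip", "ma") and peaks is None:
        raise ValueError(f"feature set {which!r} requires reference peaks")

    species = profiles[0].species_names
    rows = []
    if which == "pchip":
        labels = pchip_feature_labels(species, n_pieces)
        for prof in profiles:
            coefs = fit_pchip(normalize_profile(prof, peaks),
                              n_pieces=n_pieces, t_end=prof.times[-1])
            rows.append(np.concatenate([coefs[s].ravel() for s in species]))
    elif which == "ma":
        labels = ma_feature_labels(species, n_windows)
        for prof in profiles:
            ma = moving_averages(normalize_profile(prof, peaks),
                                 n_windows=n_windows)
            rows.append(np.concatenate([ma[s] for s in species]))
    elif which == "conventional":
        labels = list(CONVENTIONAL_NAMES)
        for prof in profiles:
            rows.append(
                conventional_features(
                    prof.trajectory("IIa"), prof.trajectory("fXa"), prof.times
                )
            )
    else:
        raise ValueError(
            f"unknown feature set {which!r}; expected pchip/ma/conventional/initial"
        )
    return FeatureMatrix(np.vstack(rows), labels, groups, ids)
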