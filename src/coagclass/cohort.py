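"""Synthetic plasma-factor cohorts for in-silico clotting studies.

Clinical summaries of coagulation-factor levels are typically reported as
percentages of the physiological mean, with per-group arithmetic mean and SD.
This module samples virtual patients from independent lognormal distributions
parameterised by those moments, converts percentage compositions into molar
initial conditions for a :class:`~coagclass.kinetics.ReactionNetwork`, and
reads/writes cohort tables (CSV or XLSX).

The eight varied factors are prothrombin (fII), factor V, factor VII,
factor VIII, factor IX, factor X, tissue factor pathway inhibitor (TFPI) and
antithrombin (AT).  100% corresponds to the physiological mean concentration
of each factor (see :data:`PHYSIOLOGICAL_MEANS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "PHYSIOLOGICAL_MEANS",
    "FactorSpec",
    "CohortSpec",
    "Cohort",
    "lognormal_from_moments",
    "sample_cohort",
    "to_initial_conditions",
    "read_cohort_table",
    "write_cohort_table",
    "default_synthetic_spec",
]

#: The eight plasma factors whose levels vary between virtual patients.
FACTORS: tuple[str, ...] = (
    "fII", "fV", "fVII", "fVIII", "fIX", "fX", "TFPI", "AT",
)

#: Physiological mean plasma concentrations in M; 100% maps to these values.
PHYSIOLOGICAL_MEANS: dict[str, float] = {
    "fII": 1.4e-6,
    "fV": 2.0e-8,
    "fVII": 1.0e-8,
    "fVIII": 7.0e-10,
    "fIX": 9.0e-8,
    "fX": 1.6e-7,
    "TFPI": 2.5e-9,
    "AT": 3.4e-6,
}

#: Default tissue-factor trigger concentration (M): 5 pM.
DEFAULT_TRIGGER_TF = 5e-12


@dataclass(frozen=True)
class FactorSpec:
    """Arithmetic mean/SD (in % of physiological mean) for one factor+group."""

    factor: str
    group: str
    mean_pct: float
    sd_pct: float

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}; expected one of {FACTORS}")
        if self.mean_pct <= 0:
            raise ValueError(f"mean_pct must be > 0, got {self.mean_pct}")
        if self.sd_pct < 0:
            raise ValueError(f"sd_pct must be >= 0, got {self.sd_pct}")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification: 8 factors x all groups, n per group, seed."""

    factor_specs: tuple[FactorSpec, ...]
    n_per_group: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g in self.groups:
            have = {fs.factor for fs in self.factor_specs if fs.group == g}
            missing = set(FACTORS) - have
            if missing:
                raise ValueError(f"group {g!r} missing factor spec(s): {sorted(missing)}")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for fs in self.factor_specs:
            if fs.group not in seen:
                seen.append(fs.group)
        return seen

    def spec_for(self, group: str, factor: str) -> FactorSpec:
        for fs in self.factor_specs:
            if fs.group == group and fs.factor == factor:
                return fs
        raise KeyError((group, factor))


@dataclass
class Cohort:
    """Sampled factor compositions (%) with per-row group labels."""

    samples: pd.DataFrame  # columns = FACTORS, percent units
    labels: pd.Series      # group label per row

    def __post_init__(self) -> None:
        missing = set(FACTORS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"cohort table missing factor column(s): {sorted(missing)}")
        self.samples = self.samples.loc[:, list(FACTORS)].astype(float)
        self.labels = pd.Series(self.labels, index=self.samples.index, name="group")
        bad = self.samples.le(0.0).any(axis=1)
        if bad.any():
            rows = list(self.samples.index[bad][:5])
            raise ValueError(
                f"cohort percentages must be strictly positive; offending row(s) {rows}"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.labels))

    def to_frame(self) -> pd.DataFrame:
        out = self.samples.copy()
        out.insert(0, "group", self.labels.values)
        return out


def lognormal_from_moments(mean_pct: float, sd_pct: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of the lognormal with the given arithmetic moments.

    Method of moments: if X ~ LogNormal(mu, sigma) then E[X] = exp(mu +
    sigma^2/2) and Var[X] = (exp(sigma^2) - 1) E[X]^2, which inverts to

        sigma^2 = ln(1 + (sd/mean)^2),   mu = ln(mean) - sigma^2 / 2.

    ``sd_pct = 0`` yields the degenerate point mass (sigma = 0).
    """
    if mean_pct <= 0:
        raise ValueError(f"mean_pct must be > 0, got {mean_pct}")
    if sd_pct < 0:
        raise ValueError(f"sd_pct must be >= 0, got {sd_pct}")
    sigma2 = math.log1p((sd_pct / mean_pct) ** 2)
    mu = math.log(mean_pct) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from the spec's per-group lognormals.

    Each factor is drawn independently; entries are strictly positive by
    lognormal support.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    labels = []
    for group in spec.groups:
        cols = {}
        for factor in FACTORS:
            fs = spec.spec_for(group, factor)
            mu, sigma = lognormal_from_moments(fs.mean_pct, fs.sd_pct)
            cols[factor] = rng.lognormal(mean=mu, sigma=sigma, size=spec.n_per_group)
        frames.append(pd.DataFrame(cols))
        labels.extend([group] * spec.n_per_group)
    samples = pd.concat(frames, ignore_index=True)
    return Cohort(samples, pd.Series(labels, name="group"))


def to_initial_conditions(
    sample: Mapping[str, float] | pd.Series,
    network,
    trigger_tf: float = DEFAULT_TRIGGER_TF,
    means: Mapping[str, float] = PHYSIOLOGICAL_MEANS,
) -> np.ndarray:
    """Map one percentage composition to per-species initial concentrations.

    Factor species receive ``(pct / 100) * physiological mean``; the
    tissue-factor trigger species ``Tf`` receives ``trigger_tf`` (default
    5 pM); every other species starts at zero.
    """
    idx = network.index
    required = [*FACTORS, "Tf"]
    missing = [name for name in required if name not in idx]
    if missing:
        raise KeyError(
            f"network does not declare required species: {missing}"
        )
    x0 = np.zeros(network.n_species)
    for factor in FACTORS:
        pct = float(sample[factor])
        if pct <= 0:
            raise ValueError(f"percentage for {factor} must be > 0, got {pct}")
        x0[idx[factor]] = pct / 100.0 * means[factor]
    x0[idx["Tf"]] = trigger_tf
    return x0


def write_cohort_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV (columns: group, fII, ..., AT; percent units)."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> Cohort:
    """Read a cohort table (CSV, or XLSX with the same header).

    Expects a ``group`` column plus the 8 factor columns in percent units;
    validates strict positivity row by row.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    missing = {"group", *FACTORS} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return Cohort(df[list(FACTORS)], df["group"])


def default_synthetic_spec(n_per_group: int = 200, seed: int = 0) -> CohortSpec:
    """A synthetic two-group cohort specification for testing and demos.

    These are NOT clinically estimated population parameters; they are a
    synthetic stand-in that places group differences on the four factors
    known to differ between acute coronary syndromes (ACS) and stable
    coronary artery disease (CAD) — prothrombin, factor VIII, TFPI and
    antithrombin — with overlapping distributions so that classification
    accuracy is informative rather than saturated.
    """
    cad = {f: (100.0, 15.0) for f in FACTORS}
    acs = dict(cad)
    acs["fII"] = (110.0, 15.0)
    acs["fVIII"] = (120.0, 25.0)
    acs["TFPI"] = (90.0, 15.0)
    acs["AT"] = (90.0, 15.0)
    specs = [
        FactorSpec(f, "ACS", *acs[f]) for f in FACTORS
    ] + [
        FactorSpec(f, "CAD", *cad[f]) for f in FACTORS
    ]
    return CohortSpec(tuple(specs), n_per_group=n_per_group, seed=seed)
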