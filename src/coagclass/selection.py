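"""Species selection and time-resolved significance from forest importances.

Given MDGini importances from the all-PCHIP-coefficient classifier, species
are selected by three criteria:

1. factor Xa and active thrombin (IIa) are always included — they are the
   classical readouts of thrombin-generation assays;
2. the species with the highest *top-fraction mean* of their PCHIP-coefficient
   MDGini values (the mean of the highest ~10% of a species' values — a
   single maximum is noise-prone, the full mean blurs species apart);
3. the species whose top-fraction mean restricted to late PCHIP pieces
   (knot start time >= 3000 s by default) is highest — species still active
   in the last 600 s of the simulation have an uncertain fate after the end
   time and deserve scrutiny.

The selected species are then resolved in time using importances from the
all-moving-average classifier (18 values per species), ranked windows give
best-k feature subsets, and small species-at-window combinations are
re-classified to find compact assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix, N_PIECES, N_WINDOWS, ma_window_centre
from .forest import ClassifierReport, ForestConfig, ImportanceTable, repeated_accuracy

__all__ = [
    "SpeciesScore",
    "SelectionResult",
    "top_fraction_mean",
    "select_species",
    "time_resolved",
    "best_k_features",
    "combination_report",
]

#: Species always included in the selection (criterion 1).
KNOWN_SIGNIFICANT = ("fXa", "IIa")
#: Default fraction of a species' highest MDGini values that are averaged.
TOP_FRACTION = 0.10
#: Default cutoff (s) for "late" PCHIP pieces (the last 600 s of 3600 s).
LATE_CUTOFF_S = 3000.0


@dataclass(frozen=True)
class SpeciesScore:
    species: str
    score: float
    n_values_used: int


@dataclass
class SelectionResult:
    """Selected species with the criterion that admitted each one."""

    known: list[str]
    global_top: list[SpeciesScore]
    late_window: SpeciesScore | None
    global_ranking: list[SpeciesScore] = field(default_factory=list)
    late_ranking: list[SpeciesScore] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        out = list(self.known)
        for s in self.global_top:
            if s.species not in out:
                out.append(s.species)
        if self.late_window and self.late_window.species not in out:
            out.append(self.late_window.species)
        return out

    def provenance(self) -> dict[str, list[str]]:
        prov: dict[str, list[str]] = {s: [] for s in self.species}
        for s in self.known:
            prov[s].append("known-significance")
        for sc in self.global_top:
            prov[sc.species].append("global-top10pct")
        if self.late_window:
            prov[self.late_window.species].append("late-window")
        return prov

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": s, "criteria": "+".join(c)}
            for s, c in self.provenance().items()
        ]
        return pd.DataFrame(rows)


def top_fraction_mean(values, fraction: float = TOP_FRACTION) -> float:
    """Mean of the ``ceil(fraction * len)`` largest values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * values.size)
    top = np.sort(values)[-k:]
    return float(top.mean())


def _parse_pchip_label(label: str) -> tuple[str, int, str]:
    """Split ``species|pchip|p###|C#`` into (species, piece index, coef)."""
    parts = label.split("|")
    if len(parts) != 4 or parts[1] != "pchip":
        raise ValueError(f"not a PCHIP feature label: {label!r}")
    return parts[0], int(parts[2][1:]), parts[3]


def _parse_ma_label(label: str) -> tuple[str, int]:
    parts = label.split("|")
    if len(parts) != 3 or parts[1] != "ma":
        raise ValueError(f"not a moving-average feature label: {label!r}")
    return parts[0], int(parts[2][1:])


def _rank_species(
    values_by_species: dict[str, list[float]], fraction: float
) -> list[SpeciesScore]:
    scores = [
        SpeciesScore(sp, top_fraction_mean(vals, fraction),
                     math.ceil(fraction * len(vals)))
        for sp, vals in values_by_species.items()
    ]
    return sorted(scores, key=lambda s: (-s.score, s.species))


def select_species(
    pchip_importances: ImportanceTable,
    fraction: float = TOP_FRACTION,
    late_cutoff_s: float = LATE_CUTOFF_S,
    n_global: int = 2,
    n_pieces: int = N_PIECES,
    t_end: float = 3600.0,
) -> SelectionResult:
    """Apply the three selection criteria to run-averaged PCHIP importances.

    ``n_global`` species are taken by criterion 2 (the full ranking is also
    reported so the cut can be inspected); criterion 3 admits the single
    best species over pieces whose knot time is at or beyond
    ``late_cutoff_s``.
    """
    mean_imp = pchip_importances.run_mean
    piece_len = t_end / n_pieces
    all_vals: dict[str, list[float]] = {}
    late_vals: dict[str, list[float]] = {}
    for label, value in zip(pchip_importances.feature_labels, mean_imp):
        species, piece, _coef = _parse_pchip_label(label)
        all_vals.setdefault(species, []).append(float(value))
        if piece * piece_len >= late_cutoff_s - 1e-9:
            late_vals.setdefault(species, []).append(float(value))

    global_ranking = _rank_species(all_vals, fraction)
    late_ranking = _rank_species(late_vals, fraction) if late_vals else []

    known = [s for s in KNOWN_SIGNIFICANT if s in all_vals]
    global_top = [
        sc for sc in global_ranking if sc.species not in known and sc.score > 0
    ][: max(0, n_global)]
    late_window = None
    for sc in late_ranking:
        if sc.score > 0:
            late_window = sc
            break
    return SelectionResult(
        known=known,
        global_top=global_top,
        late_window=late_window,
        global_ranking=global_ranking,
        late_ranking=late_ranking,
    )


def time_resolved(
    ma_importances: ImportanceTable, n_windows: int = N_WINDOWS
) -> pd.DataFrame:
    """Per-species MDGini across the 18 windows (run-averaged).

    Returns a DataFrame with one row per species and one column per window,
    indexed 0..17; column labels carry the window centre time in seconds.
    """
    mean_imp = ma_importances.run_mean
    table: dict[str, np.ndarray] = {}
    for label, value in zip(ma_importances.feature_labels, mean_imp):
        species, window = _parse_ma_label(label)
        table.setdefault(species, np.full(n_windows, np.nan))[window] = value
    df = pd.DataFrame.from_dict(table, orient="index")
    df.columns = [f"w{k:02d}@{ma_window_centre(k):.0f}s" for k in range(n_windows)]
    if df.isna().any().any():
        raise ValueError("moving-average importances do not cover all windows")
    return df


def best_k_features(
    ma_importances: ImportanceTable, species: str, k: int,
    n_windows: int = N_WINDOWS,
) -> list[str]:
    """The species' k windows with highest run-averaged MDGini.

    Ties favour the earlier window (an earlier assay read-out is preferred).
    Returned labels are in window order.
    """
    if not 1 <= k <= n_windows:
        raise ValueError(f"k must be in [1, {n_windows}], got {k}")
    pairs = []
    for label, value in zip(ma_importances.feature_labels,
                            ma_importances.run_mean):
        sp, window = _parse_ma_label(label)
        if sp == species:
            pairs.append((window, float(value)))
    if len(pairs) < n_windows:
        raise KeyError(f"species {species!r} not fully present in importances")
    ranked = sorted(pairs, key=lambda p: (-p[1], p[0]))[:k]
    return [f"{species}|ma|w{w:02d}" for w, _ in sorted(ranked)]


def combination_report(
    combinations: dict[str, list[str]],
    ma_features: FeatureMatrix,
    config: ForestConfig,
) -> dict[str, ClassifierReport]:
    """Classify each named combination of moving-average features.

    ``combinations`` maps a display name to a list of feature labels
    (typically one best window per species).  Unknown labels raise.
    """
    out: dict[str, ClassifierReport] = {}
    for name, labels in combinations.items():
        sub = ma_features.select(labels)
        out[name] = repeated_accuracy(sub, config, feature_set=name)
    return out
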