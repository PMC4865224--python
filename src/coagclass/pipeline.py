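"""End-to-end orchestration: cohort -> simulate -> featurize -> classify -> select.

A :class:`RunConfig` fully determines a run; everything stochastic derives
from its master seed, so re-running the same config reproduces every table
byte for byte.  Stage artifacts (cohort table, simulated profiles, feature
matrices, reports) are written under the output directory, and simulation
results are cached there keyed by a content hash of the model, cohort and
simulation parameters, so repeated runs skip the ODE solves.

The report bundle contains:

* feature-set accuracy table — OOB accuracy mean (SD) for the four feature
  sets (all PCHIP coefficients, initial composition, conventional IIa and
  fXa parameters, all 200 s moving averages);
* species selection with criterion provenance, plus the full rankings;
* time-resolved significance (per-species MDGini across the 18 windows);
* per-species all-18 / best-3 / best-1 window accuracies;
* combination accuracies for triples of best single-window features;
* a manifest recording the config, seeds and library versions.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_TRIGGER_TF,
    Cohort,
    CohortSpec,
    default_synthetic_spec,
    read_cohort_table,
    sample_cohort,
    to_initial_conditions,
    write_cohort_table,
)
from .features import (
    N_PIECES,
    N_WINDOWS,
    assemble_feature_matrix,
    reference_peaks,
)
from .forest import ClassifierReport, ForestConfig, ImportanceTable, repeated_accuracy, repeated_run
from .kinetics import ReactionNetwork, SimulationProfile, parse_model_file, simulate
from .selection import (
    SelectionResult,
    best_k_features,
    combination_report,
    select_species,
    time_resolved,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "make_tables"]

# fixed seed offsets per classification stage, added to the master seed so
# every forest run is re-derivable from the manifest
SEED_OFFSETS = {
    "pchip": 100_000,
    "initial": 200_000,
    "conventional": 300_000,
    "ma": 400_000,
    "per_species": 500_000,
    "combination": 700_000,
}

FEATURE_SET_TITLES = {
    "pchip": "All PCHIP Coefficients",
    "initial": "8 Initial Conditions",
    "conventional_fxa": "Conventional fXa",
    "conventional_iia": "Conventional Active Thrombin",
    "ma": "All 200s-MA",
}


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    model_path: str
    output_dir: str
    master_seed: int = 0
    cohort_table: str | None = None     # read an existing cohort if given
    cohort_spec: CohortSpec | None = None  # else sample from this spec
    n_per_group: int = 200
    trigger_tf: float = DEFAULT_TRIGGER_TF
    t_end: float = 3600.0
    n_out: int = 3601
    clamp_nonnegative: bool = False
    n_pieces: int = N_PIECES
    n_windows: int = N_WINDOWS
    n_trees: int = 501
    n_runs: int = 50
    mtry: int | None = None
    fraction: float = 0.10
    late_cutoff_s: float = 3000.0
    n_global: int = 2
    make_plots: bool = True

    def validate(self) -> None:
        errors = []
        if not Path(self.model_path).is_file():
            errors.append(f"model file not found: {self.model_path}")
        if self.cohort_table is not None and not Path(self.cohort_table).is_file():
            errors.append(f"cohort table not found: {self.cohort_table}")
        for name in ("trigger_tf", "t_end", "n_out", "n_pieces", "n_windows",
                     "n_trees", "n_runs", "fraction", "n_per_group"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    def forest_config(self, stage: str, extra_offset: int = 0) -> ForestConfig:
        base = (self.master_seed + SEED_OFFSETS[stage] + extra_offset) % (2**31)
        return ForestConfig(
            n_trees=self.n_trees, mtry=self.mtry, n_runs=self.n_runs,
            base_seed=base,
        )


@dataclass
class ReportBundle:
    """All run outputs; ``write`` serialises them under the output directory."""

    config: RunConfig
    cohort: Cohort
    feature_set_reports: dict[str, ClassifierReport]
    pchip_importances: ImportanceTable
    ma_importances: ImportanceTable
    selection: SelectionResult
    time_significance: pd.DataFrame
    per_species_reports: dict[str, dict[str, ClassifierReport]]
    combination_reports: dict[str, ClassifierReport]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(self.cohort, outdir / "cohort.csv")
        tables = make_tables(self)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        md = "\n\n".join(
            f"## {name}\n\n{df.to_markdown(index=False)}"
            for name, df in tables.items()
        )
        (outdir / "tables.md").write_text(md + "\n", encoding="utf-8")
        self.pchip_importances.to_frame().to_csv(
            outdir / "importances_pchip.csv", index=False)
        self.ma_importances.to_frame().to_csv(
            outdir / "importances_ma.csv", index=False)
        self.time_significance.to_csv(outdir / "time_resolved_mdgini.csv")
        self.selection.to_frame().to_csv(outdir / "selection.csv", index=False)
        reports = {
            "feature_sets": {k: r.to_dict() for k, r in self.feature_set_reports.items()},
            "per_species": {
                sp: {k: r.to_dict() for k, r in d.items()}
                for sp, d in self.per_species_reports.items()
            },
            "combinations": {k: r.to_dict() for k, r in self.combination_reports.items()},
        }
        (outdir / "reports.json").write_text(
            json.dumps(reports, indent=2, sort_keys=True), encoding="utf-8")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True), encoding="utf-8")


def _config_hash(cfg: RunConfig, model_text: str, cohort_frame: pd.DataFrame) -> str:
    h = hashlib.sha256()
    sim_keys = {
        "trigger_tf": cfg.trigger_tf, "t_end": cfg.t_end, "n_out": cfg.n_out,
        "clamp": cfg.clamp_nonnegative,
    }
    h.update(json.dumps(sim_keys, sort_keys=True).encode())
    h.update(model_text.encode())
    h.update(cohort_frame.to_csv(index=False).encode())
    return h.hexdigest()[:16]


def simulate_cohort(
    network: ReactionNetwork,
    cohort: Cohort,
    cfg: RunConfig,
    cache_dir: Path | None = None,
) -> list[SimulationProfile]:
    """One stiff ODE solve per cohort sample (cached on disk if possible)."""
    model_text = Path(cfg.model_path).read_text(encoding="utf-8")
    key = _config_hash(cfg, model_text, cohort.to_frame())
    cache_file = None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file = cache_dir / f"profiles_{key}.npz"
        if cache_file.is_file():
            logger.info("loading cached simulations from %s", cache_file)
            data = np.load(cache_file)
            return [
                SimulationProfile(data["times"], data[f"y{i}"],
                                  network.species_names)
                for i in range(len(cohort))
            ]
    profiles = []
    for i, (_, row) in enumerate(cohort.samples.iterrows()):
        x0 = to_initial_conditions(row, network, trigger_tf=cfg.trigger_tf)
        prof = simulate(network, x0, t_end=cfg.t_end, n_out=cfg.n_out)
        if cfg.clamp_nonnegative:
            prof = prof.clamp_nonnegative()
        profiles.append(prof)
        if (i + 1) % 50 == 0:
            logger.info("simulated %d/%d samples", i + 1, len(cohort))
    if cache_file is not None:
        np.savez_compressed(
            cache_file, times=profiles[0].times,
            **{f"y{i}": p.concentrations for i, p in enumerate(profiles)},
        )
    return profiles


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    network = parse_model_file(cfg.model_path)
    logger.info("model: %s", network)

    if cfg.cohort_table is not None:
        cohort = read_cohort_table(cfg.cohort_table)
    else:
        spec = cfg.cohort_spec or default_synthetic_spec(
            n_per_group=cfg.n_per_group, seed=cfg.master_seed)
        if spec.seed != cfg.master_seed or spec.n_per_group != cfg.n_per_group:
            spec = CohortSpec(spec.factor_specs, n_per_group=cfg.n_per_group,
                              seed=cfg.master_seed)
        cohort = sample_cohort(spec)
    logger.info("cohort: %d samples, groups %s", len(cohort), cohort.groups)

    peaks = reference_peaks(network, trigger_tf=cfg.trigger_tf,
                            t_end=cfg.t_end, n_out=cfg.n_out)
    profiles = simulate_cohort(network, cohort, cfg, cache_dir=outdir / "cache")

    matrices = {
        "pchip": assemble_feature_matrix(
            cohort, profiles, "pchip", peaks=peaks, n_pieces=cfg.n_pieces),
        "initial": assemble_feature_matrix(cohort, None, "initial"),
        "conventional": assemble_feature_matrix(cohort, profiles, "conventional"),
        "ma": assemble_feature_matrix(
            cohort, profiles, "ma", peaks=peaks, n_windows=cfg.n_windows),
    }

    # feature-set classifiers; conventional is split into its fXa-only and
    # thrombin-only sub-sets, as is traditional for these assays
    reports: dict[str, ClassifierReport] = {}
    reports["pchip"], pchip_imp = repeated_run(
        matrices["pchip"], cfg.forest_config("pchip"),
        feature_set=FEATURE_SET_TITLES["pchip"])
    reports["initial"] = repeated_accuracy(
        matrices["initial"], cfg.forest_config("initial"),
        feature_set=FEATURE_SET_TITLES["initial"])
    conv = matrices["conventional"]
    fxa_cols = [c for c in conv.feature_labels if c.startswith("fXa|")]
    iia_cols = [c for c in conv.feature_labels if c.startswith("IIa|")]
    reports["conventional_fxa"] = repeated_accuracy(
        conv.select(fxa_cols), cfg.forest_config("conventional"),
        feature_set=FEATURE_SET_TITLES["conventional_fxa"])
    reports["conventional_iia"] = repeated_accuracy(
        conv.select(iia_cols), cfg.forest_config("conventional", 1),
        feature_set=FEATURE_SET_TITLES["conventional_iia"])
    reports["ma"], ma_imp = repeated_run(
        matrices["ma"], cfg.forest_config("ma"),
        feature_set=FEATURE_SET_TITLES["ma"])

    selection = select_species(
        pchip_imp, fraction=cfg.fraction, late_cutoff_s=cfg.late_cutoff_s,
        n_global=cfg.n_global, n_pieces=cfg.n_pieces, t_end=cfg.t_end)
    logger.info("selected species: %s", selection.species)

    time_sig = time_resolved(ma_imp, n_windows=cfg.n_windows)
    time_sig = time_sig.loc[[s for s in selection.species if s in time_sig.index]]

    # per-species all-18 / best-3 / best-1 accuracies
    per_species: dict[str, dict[str, ClassifierReport]] = {}
    for j, sp in enumerate(selection.species):
        per_species[sp] = {}
        for tag, k in (("all_18", cfg.n_windows), ("best_3", 3), ("best_1", 1)):
            labels = best_k_features(ma_imp, sp, k, n_windows=cfg.n_windows)
            sub = matrices["ma"].select(labels)
            per_species[sp][tag] = repeated_accuracy(
                sub, cfg.forest_config("per_species", 10 * j), feature_set=f"{sp} {tag}")

    # combinations: triples of best single-window features across species
    best1 = {
        sp: best_k_features(ma_imp, sp, 1, n_windows=cfg.n_windows)[0]
        for sp in selection.species
    }
    combos: dict[str, list[str]] = {}
    for triple in itertools.combinations(selection.species, 3):
        name = " + ".join(triple)
        combos[name] = [best1[sp] for sp in triple]
    combo_reports = {}
    for j, (name, labels) in enumerate(combos.items()):
        combo_reports[name] = combination_report(
            {name: labels}, matrices["ma"],
            cfg.forest_config("combination", 10 * j))[name]

    manifest = {
        "coagclass_version": __version__,
        "config": {k: (v if not isinstance(v, CohortSpec) else "CohortSpec")
                   for k, v in asdict(cfg).items()},
        "master_seed": cfg.master_seed,
        "seed_offsets": SEED_OFFSETS,
        "n_samples": len(cohort),
        "groups": cohort.groups,
        "feature_counts": {k: m.shape[1] for k, m in matrices.items()},
        "combination_features": combos,
        "library_versions": _library_versions(),
    }
    bundle = ReportBundle(
        config=cfg, cohort=cohort, feature_set_reports=reports,
        pchip_importances=pchip_imp, ma_importances=ma_imp,
        selection=selection, time_significance=time_sig,
        per_species_reports=per_species, combination_reports=combo_reports,
        manifest=manifest,
    )
    bundle.write(outdir)
    if cfg.make_plots:
        try:
            from .plots import plot_time_significance, plot_group_bands

            plot_time_significance(time_sig, outdir / "mdgini_vs_time.png")
            for sp in selection.species[:4]:
                if sp in profiles[0].species_names:
                    plot_group_bands(
                        profiles, np.asarray(cohort.labels), sp,
                        outdir / f"profile_bands_{sp.replace('/', '_')}.png")
        except Exception:  # plotting must never sink a run
            logger.exception("plot generation failed; continuing")
    return bundle


def make_tables(bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    """Render the three report tables as DataFrames with 'mean (SD)' cells."""
    order = ["pchip", "initial", "conventional_fxa", "conventional_iia", "ma"]
    t1 = pd.DataFrame([
        {
            "Random Forest Classifier": FEATURE_SET_TITLES[k],
            "n_features": bundle.feature_set_reports[k].n_features,
            "Mean (SD)": bundle.feature_set_reports[k].formatted(),
        }
        for k in order if k in bundle.feature_set_reports
    ])
    t2 = pd.DataFrame([
        {
            "Species": sp,
            "All 18": d["all_18"].formatted(),
            "Best 3": d["best_3"].formatted(),
            "Best 1": d["best_1"].formatted(),
        }
        for sp, d in bundle.per_species_reports.items()
    ])
    combos = sorted(
        bundle.combination_reports.items(), key=lambda kv: -kv[1].mean)
    t3 = pd.DataFrame([
        {"Combination": name, "Features": ", ".join(
            bundle.manifest.get("combination_features", {}).get(name, [])) or "",
         "Mean (SD)": rep.formatted()}
        for name, rep in combos
    ])
    return {"table_feature_sets": t1, "table_per_species": t2,
            "table_combinations": t3}


def _library_versions() -> dict[str, str]:
    import numpy, pandas, scipy, sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
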