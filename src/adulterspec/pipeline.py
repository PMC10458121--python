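"""End-to-end study orchestration.

Reproduces the workflow of the adulteration study on synthetic (or CSV)
data: generate/load the four adulterant sets → compare the 13 preprocessing
methods by full-spectrum SVR and pick the RMSE winner → select feature
wavelengths → fit the per-adulterant model pairing (SVR for soybean, RF for
corn/peanut/rapeseed), tuned and untuned → validate three representative
selected wavelengths (one per UV/Vis/NIR band) by Pearson correlation with
the adulteration content. Every stage is a pure function of (config, seed),
and every derived percentage in the report is stored with its operands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics_core import CorrelationReport, pearson_with_significance
from .feature_selection import (SelectionResult, boss_select, cars_select,
                                ivso_select, selection_summary, spa_select)
from .modeling import PSOConfig, train_and_evaluate
from .preprocessing import PreprocessSpec, preprocess, standard_method_specs
from .spectra_core import (ADULTERANTS, SpectraDataset, WavelengthGrid,
                           default_grid)
from .synthetic_data import MixDesign, generate_full_study

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "compare_preprocessing",
    "improvement_pct",
    "pick_representative_wavelengths",
    "run_selector",
    "run_study",
]

log = logging.getLogger("adulterspec")

_MODEL_PAIRING = {"soybean": "svr", "corn": "rf", "peanut": "rf",
                  "rapeseed": "rf"}


@dataclass(frozen=True)
class PipelineConfig:
    """Study configuration. Unknown keys are rejected on load.

    ``wavelength_step`` thins the grid (every k-th point) before the selector
    and modeling stages; the full-scale defaults (step 1, 1000 bootstrap /
    WBMS samples) are faithful to the study protocol but slow, so drivers
    typically pass a coarser step and smaller sampling counts.
    """

    n_grid_points: int = 2068
    design: MixDesign = field(default_factory=MixDesign)
    preprocess_methods: str = "all"       # "all" -> the 13-method menu
    selector: str = "ivso"
    selectors_compared: tuple = ("cars", "spa", "boss", "ivso")
    wavelength_step: int = 1
    n_mc: int = 100                        # CARS Monte Carlo runs
    n_boot: int = 1000                     # BOSS bootstrap samples
    n_wbms: int = 1000                     # IVSO WBMS samples
    spa_max_vars: int = 40
    max_components: int = 10
    tune_models: bool = True
    pso_swarm: int = 30
    pso_iterations: int = 100
    seed: int = 0
    model_pairing: dict = field(default_factory=lambda: dict(_MODEL_PAIRING))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            dd = d["design"]
            bad = set(dd) - {f.name for f in dataclasses.fields(MixDesign)}
            if bad:
                raise ValueError(f"unknown design keys: {sorted(bad)}")
            if "ratios" in dd:
                dd["ratios"] = tuple(dd["ratios"])
            d["design"] = MixDesign(**dd)
        return cls(**d)


def improvement_pct(old: float, new: float, higher_is_better: bool = False) -> float:
    """Relative change in percent, positive when ``new`` improves on ``old``:
    (old−new)/old·100 for error metrics, (new−old)/old·100 for scores."""
    if old == 0:
        raise ValueError("improvement undefined for old == 0")
    delta = (new - old) if higher_is_better else (old - new)
    return delta / old * 100.0


def compare_preprocessing(ds: SpectraDataset, methods: list = None,
                          model_kind: str = "svr", seed: int = 0,
                          k: int = 10, tune: bool = False) -> pd.DataFrame:
    """Full-spectrum model R²/RMSE (prediction set, Kennard–Stone protocol)
    for each preprocessing method; the argmin-RMSE row is flagged selected,
    ties broken by higher R² then earlier method order."""
    specs = methods if methods is not None else standard_method_specs()
    rows = []
    for spec in specs:
        rep = train_and_evaluate(preprocess(ds, spec), None, model_kind,
                                 tuner_on=tune, seed=seed, k=k)
        rows.append({"method": spec.label, "r2": rep.rp2, "rmse": rep.rmsep})
    df = pd.DataFrame(rows)
    order = np.lexsort((np.arange(len(df)), -df["r2"].to_numpy(),
                        df["rmse"].to_numpy()))
    df["selected"] = False
    df.loc[order[0], "selected"] = True
    return df


def run_selector(method: str, X, y, cfg: PipelineConfig, seed: int) -> SelectionResult:
    common = dict(max_components=cfg.max_components, seed=seed)
    if method == "cars":
        return cars_select(X, y, n_mc=cfg.n_mc, **common)
    if method == "spa":
        max_vars = min(cfg.spa_max_vars, X.shape[0] - 1, X.shape[1])
        return spa_select(X, y, max_vars=max_vars, seed=seed)
    if method == "boss":
        return boss_select(X, y, n_boot=cfg.n_boot, **common)
    if method == "ivso":
        return ivso_select(X, y, n_wbms=cfg.n_wbms, **common)
    raise ValueError(f"unknown selector {method!r}")


def pick_representative_wavelengths(selection: SelectionResult,
                                    grid: WavelengthGrid) -> list:
    """One selected wavelength per band (UV <400 nm, Vis 400-780 nm,
    NIR >780 nm): within each band, the selected wavelength lying in the
    densest cluster of selected wavelengths (count within ±10 nm), ties to
    the lowest wavelength. Bands with no selected wavelength are skipped
    with a warning."""
    lam = grid.values[selection.selected_indices]
    picks = []
    for name, mask in zip(("UV", "Vis", "NIR"),
                          grid.band_masks()):
        in_band = lam[mask[selection.selected_indices]]
        if in_band.size == 0:
            warnings.warn(f"no selected wavelength in the {name} band",
                          stacklevel=2)
            continue
        density = np.array([np.sum(np.abs(in_band - w) <= 10.0)
                            for w in in_band])
        picks.append(float(in_band[int(np.argmax(density))]))
    return picks


@dataclass
class StudyReport:
    config: PipelineConfig
    preprocessing_table: pd.DataFrame
    winning_preprocess: str
    selection_summary_table: pd.DataFrame
    selections: dict                   # adulterant -> SelectionResult
    evaluations: dict                  # adulterant -> {"tuned": .., "untuned": ..}
    improvements: dict                 # adulterant -> operand/percent records
    representative_wavelengths: dict   # adulterant -> [nm, ...]
    correlations: dict                 # adulterant -> [CorrelationReport, ...]

    def to_json_dict(self) -> dict:
        return {
            "preprocessing": self.preprocessing_table.to_dict(orient="records"),
            "winning_preprocess": self.winning_preprocess,
            "selection_summary": self.selection_summary_table.to_dict(
                orient="records"),
            "selections": {a: s.to_dict() for a, s in self.selections.items()},
            "evaluations": {a: {kind: rep.to_dict() for kind, rep in d.items()}
                            for a, d in self.evaluations.items()},
            "improvements": self.improvements,
            "representative_wavelengths": self.representative_wavelengths,
            "correlations": {a: [dataclasses.asdict(c) for c in reports]
                             for a, reports in self.correlations.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _winning_spec(table: pd.DataFrame) -> PreprocessSpec:
    label = table.loc[table["selected"], "method"].iloc[0]
    for spec in standard_method_specs():
        if spec.label == label:
            return spec
    raise RuntimeError(f"no spec for winning method {label!r}")


def run_study(cfg: PipelineConfig) -> StudyReport:
    """The full workflow on synthetic data; deterministic given the config."""
    grid = default_grid(cfg.n_grid_points)
    design = dataclasses.replace(cfg.design, seed=cfg.seed)
    log.info("generating study: %d grid points, seed %d", len(grid), cfg.seed)
    sets = generate_full_study(design, grid)

    # stage 1: preprocessing comparison on the soybean set (full spectrum SVR)
    first = sets["soybean"]
    pp_table = compare_preprocessing(first, seed=cfg.seed)
    win_spec = _winning_spec(pp_table)
    log.info("preprocessing winner: %s", win_spec.label)

    # stage 2: selector comparison on the winner-preprocessed soybean set,
    # then the study selector per adulterant set
    step = max(1, int(cfg.wavelength_step))
    thin = np.arange(0, len(grid), step)
    thin_grid = WavelengthGrid(grid.values[thin])

    def prep_thin(ds):
        return preprocess(ds, win_spec).X[:, thin]

    Xs = prep_thin(first)
    compared = [run_selector(m, Xs, first.y, cfg, cfg.seed)
                for m in cfg.selectors_compared]
    sel_table = selection_summary(compared, thin_grid)

    selections, evaluations, improvements = {}, {}, {}
    rep_wavelengths, correlations = {}, {}
    pso_cfg = PSOConfig(swarm_size=cfg.pso_swarm,
                        max_iterations=cfg.pso_iterations, seed=cfg.seed)
    for name in ADULTERANTS:
        ds = sets[name]
        sel = (compared[list(cfg.selectors_compared).index(cfg.selector)]
               if name == "soybean" and cfg.selector in cfg.selectors_compared
               else run_selector(cfg.selector, prep_thin(ds), ds.y, cfg, cfg.seed))
        selections[name] = sel
        dsp = preprocess(ds, win_spec).subset_wavelengths(thin)
        kind = cfg.model_pairing[name]
        untuned = train_and_evaluate(dsp, sel, kind, tuner_on=False,
                                     seed=cfg.seed, adulterant=name)
        tuned = (train_and_evaluate(dsp, sel, kind, tuner_on=True,
                                    seed=cfg.seed, pso_cfg=pso_cfg,
                                    adulterant=name)
                 if cfg.tune_models else untuned)
        evaluations[name] = {"untuned": untuned, "tuned": tuned}
        improvements[name] = {
            "rp2_untuned": untuned.rp2, "rp2_tuned": tuned.rp2,
            "rp2_improvement_pct": improvement_pct(untuned.rp2, tuned.rp2,
                                                   higher_is_better=True),
            "rmsep_untuned": untuned.rmsep, "rmsep_tuned": tuned.rmsep,
            "rmsep_decrease_pct": improvement_pct(untuned.rmsep, tuned.rmsep),
        }
        log.info("%s %s: RP2 %.4f -> %.4f", name, kind, untuned.rp2, tuned.rp2)

        # stage 3: correlation validation on the raw absorbance
        picks = pick_representative_wavelengths(sel, thin_grid)
        rep_wavelengths[name] = picks
        correlations[name] = [
            pearson_with_significance(ds.X[:, grid.nearest_index(wl)], ds.y,
                                      wavelength=wl)
            for wl in picks]

    return StudyReport(config=cfg, preprocessing_table=pp_table,
                       winning_preprocess=win_spec.label,
                       selection_summary_table=sel_table,
                       selections=selections, evaluations=evaluations,
                       improvements=improvements,
                       representative_wavelengths=rep_wavelengths,
                       correlations=correlations)
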