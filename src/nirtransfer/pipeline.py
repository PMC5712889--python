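"""End-to-end calibration-transfer experiments.

The canonical workflow: preprocess both instruments' spectra, split into
calibration/prediction sets with Kennard-Stone on the master spectra, train
the master regression model, pick the master instrument by Passing-Bablok
agreement with the reference method (when requested), select standardization
samples from the calibration set with Kennard-Stone, build the transfer
mapping, and evaluate master, untransferred, and transferred predictions on
one fixed prediction set.  A sweep over the standardization-set size
supports both protocol variants: standards kept inside the master
calibration set, and standards removed from it with the master model refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .evaluation import EvaluationReport, choose_master, evaluate, passing_bablok
from .preprocess import PreprocessPlan
from .regression import (
    DEFAULT_GAMMA_GRID,
    DEFAULT_SIGMA2_GRID,
    LSSVMModel,
    PLSModel,
    lssvm_fit,
    lssvm_predict,
    lssvm_tune,
    pls_fit,
    pls_predict,
)
from .selection import kennard_stone, select_standardization
from .simulate import generate_paired_dataset
from .spectra import SpectraSet, read_spectra
from .transfer import (
    TransferModel,
    apply_transfer,
    build_common_pds,
    interpolate_to_grid,
    linear_interp_pds,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "SweepResult",
    "run_experiment",
    "compare_methods",
    "sweep_standardization",
]

TRANSFER_METHODS = ("linear_interp_pds", "common_pds", "interp_only", "none")


@dataclass
class ExperimentConfig:
    """Everything needed to re-run an experiment bit-identically."""

    # data: either CSV paths or the built-in simulator
    master_file: str | None = None
    slave_file: str | None = None
    reference_column: str = "reference"
    n_samples: int = 700
    seed: int = 0

    # preprocessing (config form of PreprocessPlan)
    preprocess_master: list = field(
        default_factory=lambda: [{"moving_average": {"window": 3}}, "snv"]
    )
    preprocess_slave: list = field(
        default_factory=lambda: [{"moving_average": {"window": 18}}, "snv"]
    )

    # splitting / standardization
    n_calibration: int = 550
    n_standardization: int = 45

    # regression model
    model: str = "lssvm"  # or "pls"
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    sigma2_grid: tuple = DEFAULT_SIGMA2_GRID
    pls_max_components: int = 15
    pls_cv_folds: int = 10

    # transfer
    transfer_method: str = "linear_interp_pds"
    half_width: int | str = "auto"  # int, or "auto" for an RMSEP search
    half_width_candidates: tuple = tuple(range(1, 21))
    n_window_components: int = 2
    common_tolerance: float = 0.1  # nm, for common-wavelengths matching

    # which instrument's model is kept ("A", "B", or "auto" via Passing-Bablok)
    master_instrument: str = "A"

    # optional pre-loaded (master, slave) SpectraSets, bypassing files/simulator
    data: tuple | None = None

    def __post_init__(self) -> None:
        if self.transfer_method not in TRANSFER_METHODS:
            raise ValueError(f"transfer_method must be one of {TRANSFER_METHODS}")
        if self.model not in ("lssvm", "pls"):
            raise ValueError("model must be 'lssvm' or 'pls'")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class ExperimentResult:
    reports: dict[str, EvaluationReport]
    master_model: Any
    transfer_model: TransferModel | None
    half_width: int | None
    master_label: str
    config: ExperimentConfig


@dataclass
class SweepResult:
    sizes: list[int]
    half_width: int
    keep: list[EvaluationReport]  # standards kept in the calibration set
    remove: list[EvaluationReport]  # standards removed, master model refit
    rmsec_remove: list[float]
    best_size_keep: int
    best_size_remove: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _load_data(config: ExperimentConfig) -> tuple[SpectraSet, SpectraSet]:
    if config.data is not None:
        return config.data
    if config.master_file and config.slave_file:
        m = read_spectra(config.master_file, reference_column=config.reference_column)
        s = read_spectra(config.slave_file, reference_column=config.reference_column)
        return m, s
    return generate_paired_dataset(config.n_samples, seed=config.seed)


def _train(config: ExperimentConfig, X: np.ndarray, y: np.ndarray):
    if config.model == "lssvm":
        gamma, sigma2 = lssvm_tune(X, y, config.gamma_grid, config.sigma2_grid)
        return lssvm_fit(X, y, gamma, sigma2)
    return pls_fit(X, y, config.pls_max_components, config.pls_cv_folds)


def _refit(config: ExperimentConfig, model, X: np.ndarray, y: np.ndarray):
    """Refit on new data keeping the tuned hyperparameters."""
    if isinstance(model, LSSVMModel):
        return lssvm_fit(X, y, model.gamma, model.sigma2)
    coef_model = pls_fit(X, y, model.n_components, config.pls_cv_folds)
    return coef_model


def _predict(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, LSSVMModel):
        return lssvm_predict(model, X)
    return pls_predict(model, X)


@dataclass
class _Prepared:
    master_cal: SpectraSet
    master_pred: SpectraSet
    slave_cal: SpectraSet
    slave_pred: SpectraSet
    master_label: str


def _prepare(config: ExperimentConfig) -> _Prepared:
    a_raw, b_raw = _load_data(config)
    plan_a = PreprocessPlan.from_config(config.preprocess_master)
    plan_b = PreprocessPlan.from_config(config.preprocess_slave)

    label = config.master_instrument
    if label == "auto":
        label = _auto_master(config, plan_a.apply(a_raw), plan_b.apply(b_raw))
    if label == "B":
        a_raw, b_raw = b_raw, a_raw
        plan_a, plan_b = plan_b, plan_a
    elif label != "A":
        raise ValueError("master_instrument must be 'A', 'B' or 'auto'")

    master = plan_a.apply(a_raw)
    slave = plan_b.apply(b_raw)
    if master.reference is None or slave.reference is None:
        raise ValueError("reference values are required for the experiment")
    sel = kennard_stone(master, config.n_calibration)
    return _Prepared(
        master_cal=master.take(sel.selected_indices),
        master_pred=master.take(sel.remaining_indices),
        slave_cal=slave.take(sel.selected_indices),
        slave_pred=slave.take(sel.remaining_indices),
        master_label=label,
    )


def _auto_master(config: ExperimentConfig, a: SpectraSet, b: SpectraSet) -> str:
    """Train one model per instrument on its own spectra and keep the one
    whose prediction-set agreement with the reference passes Passing-Bablok."""
    results = {}
    for label, s in (("A", a), ("B", b)):
        sel = kennard_stone(s, config.n_calibration)
        cal, pred = s.take(sel.selected_indices), s.take(sel.remaining_indices)
        model = _train(config, cal.absorbance, cal.reference)
        yhat = _predict(model, pred.absorbance)
        results[label] = passing_bablok(pred.reference, yhat)
    chosen = choose_master(results)
    return chosen if chosen is not None else "A"


def _build_transfer(
    config: ExperimentConfig,
    prep: _Prepared,
    master_model,
    half_width: int,
) -> TransferModel:
    std = select_standardization(prep.master_cal, config.n_standardization)
    m_std = prep.master_cal.take(std.selected_indices)
    s_std = prep.slave_cal.take(std.selected_indices)
    if config.transfer_method == "common_pds":
        return build_common_pds(
            m_std,
            s_std,
            tolerance=config.common_tolerance,
            half_width=half_width,
            n_window_components=config.n_window_components,
        )
    return linear_interp_pds(
        m_std,
        s_std,
        half_width=half_width,
        n_window_components=config.n_window_components,
    )


def _transfer_and_score(
    config: ExperimentConfig, prep: _Prepared, master_model
) -> tuple[EvaluationReport, TransferModel | None, int | None, Any]:
    """Returns (transferred report, transfer model, half width, scoring model).

    For the common-wavelengths baseline the master model cannot consume the
    reduced grid, so a dedicated model is trained on the matched master
    channels of the calibration set.
    """
    method = config.transfer_method
    if method == "none":
        yhat = _predict(master_model, prep.slave_pred.absorbance)
        return (
            evaluate(yhat, prep.slave_pred.reference, "transferred:none"),
            None,
            None,
            master_model,
        )
    if method == "interp_only":
        moved = interpolate_to_grid(prep.slave_pred, prep.master_cal.wavelengths)
        yhat = _predict(master_model, moved.absorbance)
        return (
            evaluate(yhat, prep.slave_pred.reference, "transferred:interp_only"),
            None,
            None,
            master_model,
        )

    candidates = (
        list(config.half_width_candidates)
        if config.half_width == "auto"
        else [int(config.half_width)]
    )
    if method == "common_pds":
        # the reduced grid needs its own master model (trained, with fresh
        # hyperparameter tuning, on the matched master channels)
        from .transfer import common_wavelengths

        pairs = common_wavelengths(
            prep.master_cal.wavelengths, prep.slave_cal.wavelengths,
            config.common_tolerance,
        )
        cols = np.array([a for a, _ in pairs], dtype=int)
        common_model = _train(
            config, prep.master_cal.absorbance[:, cols], prep.master_cal.reference
        )
    best = None
    for hw in candidates:
        t = _build_transfer(config, prep, master_model, hw)
        model = common_model if method == "common_pds" else master_model
        moved = apply_transfer(t, prep.slave_pred)
        yhat = _predict(model, moved.absorbance)
        rep = evaluate(yhat, prep.slave_pred.reference, f"transferred:{method}")
        if best is None or rep.rmse < best[0].rmse:
            best = (rep, t, hw, model)
    return best


# ---------------------------------------------------------------------------
# public drivers
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Full chain: master-model performance, untransferred slave performance,
    and transferred slave performance on one fixed prediction set."""
    prep = _prepare(config)
    master_model = _train(config, prep.master_cal.absorbance, prep.master_cal.reference)

    reports: dict[str, EvaluationReport] = {}
    yhat_cal = _predict(master_model, prep.master_cal.absorbance)
    reports["master_calibration"] = evaluate(
        yhat_cal, prep.master_cal.reference, "master calibration"
    )
    yhat = _predict(master_model, prep.master_pred.absorbance)
    reports["master"] = evaluate(yhat, prep.master_pred.reference, "master prediction")

    # untransferred baseline: slave spectra pushed through the master model
    # with only the wavelength-grid resampling needed to make shapes match
    if np.array_equal(prep.slave_pred.wavelengths, prep.master_cal.wavelengths):
        raw = prep.slave_pred.absorbance
    else:
        raw = interpolate_to_grid(
            prep.slave_pred, prep.master_cal.wavelengths
        ).absorbance
    yhat_raw = _predict(master_model, raw)
    reports["untransferred"] = evaluate(
        yhat_raw, prep.slave_pred.reference, "untransferred slave"
    )

    transferred, t_model, half_width, _ = _transfer_and_score(config, prep, master_model)
    reports["transferred"] = transferred
    return ExperimentResult(
        reports=reports,
        master_model=master_model,
        transfer_model=t_model,
        half_width=half_width,
        master_label=prep.master_label,
        config=config,
    )


def compare_methods(config: ExperimentConfig) -> dict[str, EvaluationReport]:
    """Evaluate every transfer route on the same data, split, and master
    model: master calibration and prediction, untransferred (interpolation
    only), the common-wavelengths-reserved-PDS baseline, and linear
    interpolation-PDS."""
    from dataclasses import replace

    prep = _prepare(config)
    master_model = _train(config, prep.master_cal.absorbance, prep.master_cal.reference)
    out: dict[str, EvaluationReport] = {}
    yhat_cal = _predict(master_model, prep.master_cal.absorbance)
    out["master_calibration"] = evaluate(
        yhat_cal, prep.master_cal.reference, "master calibration"
    )
    yhat = _predict(master_model, prep.master_pred.absorbance)
    out["master"] = evaluate(yhat, prep.master_pred.reference, "master prediction")
    for method, key in (
        ("interp_only", "untransferred"),
        ("common_pds", "common_pds"),
        ("linear_interp_pds", "linear_interp_pds"),
    ):
        cfg = replace(config, transfer_method=method)
        rep, *_ = _transfer_and_score(cfg, prep, master_model)
        out[key] = rep
    return out


def sweep_standardization(config: ExperimentConfig, sizes) -> SweepResult:
    """Rebuild the transfer at each standardization-set size on a fixed
    split and prediction set, in both protocol variants.

    keep: the master model is trained once on the full calibration set (the
    standards stay inside it).  remove: the standards are dropped from the
    calibration set and the master model is refit with the same
    hyperparameters before scoring.
    """
    sizes = sorted(int(k) for k in sizes)
    if sizes[-1] > config.n_calibration:
        raise ValueError("standardization size exceeds the calibration set")
    prep = _prepare(config)
    master_model = _train(config, prep.master_cal.absorbance, prep.master_cal.reference)

    if config.transfer_method not in ("linear_interp_pds", "common_pds"):
        raise ValueError("sweep requires a PDS-based transfer method")
    if config.half_width == "auto":
        _, _, half_width, _ = _transfer_and_score(config, prep, master_model)
    else:
        half_width = int(config.half_width)

    if config.transfer_method == "common_pds":
        from .transfer import common_wavelengths

        pairs = common_wavelengths(
            prep.master_cal.wavelengths, prep.slave_cal.wavelengths,
            config.common_tolerance,
        )
        cols = np.array([a for a, _ in pairs], dtype=int)
        X_cal = prep.master_cal.absorbance[:, cols]
        model_keep = _train(config, X_cal, prep.master_cal.reference)
    else:
        X_cal = prep.master_cal.absorbance
        model_keep = master_model

    pred_ids = list(prep.slave_pred.sample_ids)
    keep_reports: list[EvaluationReport] = []
    remove_reports: list[EvaluationReport] = []
    rmsec_remove: list[float] = []
    from dataclasses import replace

    cfg_hw = replace(config, half_width=half_width)
    for size in sizes:
        assert list(prep.slave_pred.sample_ids) == pred_ids
        std = select_standardization(prep.master_cal, size)
        cfg_size = replace(cfg_hw, n_standardization=size)
        t = _build_transfer(cfg_size, prep, master_model, half_width)
        moved = apply_transfer(t, prep.slave_pred)
        yhat = _predict(model_keep, moved.absorbance)
        keep_reports.append(
            evaluate(yhat, prep.slave_pred.reference, f"keep n_std={size}")
        )

        rest = std.remaining_indices
        model_rm = _refit(
            config, model_keep, X_cal[rest], prep.master_cal.reference[rest]
        )
        yhat_cal = _predict(model_rm, X_cal[rest])
        rmsec_remove.append(
            evaluate(yhat_cal, prep.master_cal.reference[rest], "rmsec").rmse
        )
        yhat_rm = _predict(model_rm, moved.absorbance)
        remove_reports.append(
            evaluate(yhat_rm, prep.slave_pred.reference, f"remove n_std={size}")
        )

    best_keep = sizes[int(np.argmin([r.rmse for r in keep_reports]))]
    best_remove = sizes[int(np.argmin([r.rmse for r in remove_reports]))]
    return SweepResult(
        sizes=sizes,
        half_width=half_width,
        keep=keep_reports,
        remove=remove_reports,
        rmsec_remove=rmsec_remove,
        best_size_keep=best_keep,
        best_size_remove=best_remove,
    )
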