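"""Study orchestration: 7:3 calibration/prediction splits, repeated-split
evaluation, the orientation x pretreatment x model grid, and fixture IO.

Leakage discipline: pretreatments are parameter-free row operations and may
be applied to the full matrix up front; wavelength selection and
latent-variable choice are always refit on the calibration rows of each
split only.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import larsselect, plsr
from .preprocess import PretreatmentSpec, apply_pretreatment
from .scanproc import (
    AggregationParams,
    BackgroundSpectrum,
    MultiPointScan,
    WavelengthGrid,
    aggregate_scan,
)

logger = logging.getLogger(__name__)

MODEL_VARIANTS = ("full", "lars-l1", "lars-l2")


class PipelineStageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class SplitPlan:
    calibration: np.ndarray
    prediction: np.ndarray
    seed: int


@dataclass(frozen=True)
class SelectionSpec:
    """How to pick wavelengths inside one repeat.

    ``lam`` may be a number or the string ``"cv"`` (L1 only), in which
    case the penalty weight is chosen by k-fold lasso RMSECV on the
    calibration rows.
    """

    penalty: str = "L1"
    lam: float | str = "cv"
    lambda_grid: tuple | None = None
    max_steps: int | None = None
    max_active: int | None = None


@dataclass
class SingleRunResult:
    calibration: plsr.EvaluationMetrics
    prediction: plsr.EvaluationMetrics
    n_lv: int
    n_variables: int
    lam: float | None = None


@dataclass
class RepeatSummary:
    results: list[SingleRunResult]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.results)

    def metric(self, name: str) -> np.ndarray:
        pick = {
            "Rc": lambda r: r.calibration.r,
            "RMSEC": lambda r: r.calibration.rmse,
            "Rp": lambda r: r.prediction.r,
            "RMSEP": lambda r: r.prediction.rmse,
            "LVs": lambda r: r.n_lv,
            "n_variables": lambda r: r.n_variables,
        }[name]
        return np.array([pick(r) for r in self.results])

    def mean(self, name: str) -> float:
        return float(self.metric(name).mean())

    def sd(self, name: str) -> float:
        return float(self.metric(name).std(ddof=1))

    @property
    def complete(self) -> bool:
        return not self.failures


def split_dataset(n: int, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Random 7:3-style partition; calibration gets floor(ratio * n)."""
    n_cal = int(np.floor(ratio * n))
    if n < 4 or n_cal < 2 or n - n_cal < 2:
        raise ValueError(f"n={n} too small to populate both sets at ratio {ratio}")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitPlan(calibration=np.sort(perm[:n_cal]),
                     prediction=np.sort(perm[n_cal:]), seed=seed)


def run_single(
    dataset: plsr.Dataset,
    pretreatment: PretreatmentSpec,
    selection: SelectionSpec | None,
    split: SplitPlan,
    max_lv: int = 20,
    cv_seed: int | None = None,
    r_mode: str = "paper",
    pretreated_X: np.ndarray | None = None,
) -> SingleRunResult:
    """One split: pretreat -> (select) -> choose LVs -> fit -> evaluate.

    ``pretreated_X`` lets callers amortize the row-wise pretreatment over
    many splits (it is split-independent, so this leaks nothing).
    """
    cv_seed = split.seed if cv_seed is None else cv_seed
    try:
        X = pretreated_X if pretreated_X is not None else apply_pretreatment(
            dataset.X, pretreatment, dataset.sample_ids)
    except Exception as exc:
        raise PipelineStageError("pretreatment", exc) from exc
    y = dataset.y
    X_cal, y_cal = X[split.calibration], y[split.calibration]
    X_pred, y_pred = X[split.prediction], y[split.prediction]

    lam_used = None
    if selection is not None:
        try:
            lam = selection.lam
            if lam == "cv":
                if selection.penalty != "L1":
                    raise ValueError("lam='cv' is only supported for the L1 penalty")
                lam = larsselect.choose_lambda_l1_cv(
                    X_cal, y_cal, lambdas=selection.lambda_grid, seed=cv_seed)
            sel = larsselect.select_wavelengths(
                X_cal, y_cal, float(lam), penalty=selection.penalty,
                cv_seed=cv_seed, wavelengths=dataset.wavelengths,
                max_steps=selection.max_steps, max_active=selection.max_active)
            lam_used = float(lam)
            cols = sel.indices
        except Exception as exc:
            raise PipelineStageError("selection", exc) from exc
        X_cal, X_pred = X_cal[:, cols], X_pred[:, cols]
        n_vars = cols.size
    else:
        n_vars = X.shape[1]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_lv, _ = plsr.select_lvs_cv(
                X_cal, y_cal, max_lv=min(max_lv, X_cal.shape[1]), seed=cv_seed)
            model = plsr.fit_plsr(X_cal, y_cal, n_lv)
    except Exception as exc:
        raise PipelineStageError("plsr-fit", exc) from exc
    m_cal = plsr.compute_metrics(y_cal, plsr.predict(model, X_cal), mode=r_mode)
    m_pred = plsr.compute_metrics(y_pred, plsr.predict(model, X_pred), mode=r_mode)
    return SingleRunResult(calibration=m_cal, prediction=m_pred,
                           n_lv=model.n_lv, n_variables=n_vars, lam=lam_used)


def run_repeats(
    dataset: plsr.Dataset,
    pretreatment: PretreatmentSpec,
    selection: SelectionSpec | None = None,
    n_repeats: int = 100,
    base_seed: int = 0,
    ratio: float = 0.7,
    max_lv: int = 20,
    r_mode: str = "paper",
) -> RepeatSummary:
    """Repeat the random split + full modeling procedure n_repeats times.

    Repeat i uses seed ``base_seed + i`` for its split and downstream CV,
    so the whole summary is deterministic in ``base_seed``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    pre_X = apply_pretreatment(dataset.X, pretreatment, dataset.sample_ids)
    results, failures = [], []
    for i in range(n_repeats):
        seed = base_seed + i
        split = split_dataset(dataset.n, ratio=ratio, seed=seed)
        try:
            results.append(run_single(dataset, pretreatment, selection, split,
                                      max_lv=max_lv, r_mode=r_mode,
                                      pretreated_X=pre_X))
        except PipelineStageError as exc:
            logger.warning("repeat %d failed: %s", i, exc)
            failures.append((i, str(exc)))
    if not results:
        raise PipelineStageError("repeats", RuntimeError("every repeat failed"))
    return RepeatSummary(results=results, failures=failures)


def run_grid(
    datasets: dict[str, plsr.Dataset],
    pretreatments=("RAW", "SG", "SNV"),
    variants=MODEL_VARIANTS,
    n_repeats: int = 100,
    base_seed: int = 0,
    variety: str = "",
    selection_specs: dict[str, SelectionSpec] | None = None,
    max_lv: int = 20,
    r_mode: str = "paper",
) -> pd.DataFrame:
    """Evaluate every (orientation x pretreatment x model-variant) cell.

    Returns a tidy DataFrame with mean and SD columns per metric; cell
    failures are recorded in an ``error`` column and do not abort the grid.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    sel_defaults = {
        "full": None,
        "lars-l1": SelectionSpec(penalty="L1", lam="cv"),
        "lars-l2": SelectionSpec(penalty="L2", lam=0.1, max_steps=40),
    }
    if selection_specs:
        sel_defaults.update(selection_specs)
    rows = []
    for orientation, dataset in datasets.items():
        for method in pretreatments:
            pre = PretreatmentSpec(method=method)
            for variant in variants:
                if variant not in sel_defaults:
                    raise ValueError(f"unknown model variant {variant!r}")
                t0 = time.perf_counter()
                row = {"variety": variety, "orientation": orientation,
                       "pretreatment": method, "model": variant}
                try:
                    summary = run_repeats(dataset, pre, sel_defaults[variant],
                                          n_repeats=n_repeats, base_seed=base_seed,
                                          max_lv=max_lv, r_mode=r_mode)
                    row.update({
                        "LVs": summary.mean("LVs"),
                        "n_variables": summary.mean("n_variables"),
                        "Rc": summary.mean("Rc"), "Rc_sd": summary.sd("Rc"),
                        "RMSEC": summary.mean("RMSEC"), "RMSEC_sd": summary.sd("RMSEC"),
                        "Rp": summary.mean("Rp"), "Rp_sd": summary.sd("Rp"),
                        "RMSEP": summary.mean("RMSEP"), "RMSEP_sd": summary.sd("RMSEP"),
                        "n_repeats": summary.n_repeats,
                        "error": "",
                    })
                except Exception as exc:  # cell failure must not kill the grid
                    logger.error("grid cell %s/%s/%s failed: %s",
                                 orientation, method, variant, exc)
                    row["error"] = str(exc)
                row["seconds"] = round(time.perf_counter() - t0, 2)
                rows.append(row)
                logger.info("grid cell %s/%s/%s done in %.1fs",
                            orientation, method, variant, row["seconds"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture IO


def load_manifest(fixture_dir: str | Path):
    """Load a generated fixture set (manifest + scans + background).

    Returns ``(scans, background, manifest)``.
    """
    root = Path(fixture_dir)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"sample_id", "variety", "orientation", "ssc_brix", "scan_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(manifest["ssc_brix"]):
        bad = manifest[pd.to_numeric(manifest["ssc_brix"], errors="coerce").isna()]
        raise ValueError(
            f"{manifest_path}: non-numeric ssc_brix in rows {bad.index.tolist()}")

    bg_path = root / "background.csv"
    if not bg_path.exists():
        raise FileNotFoundError(f"background not found: {bg_path}")
    bg_df = pd.read_csv(bg_path)
    grid = WavelengthGrid(np.array([float(c) for c in bg_df.columns]))

    noise_sd = 0.0
    gt_path = root / "ground_truth.json"
    if gt_path.exists():
        import json
        noise_sd = float(json.loads(gt_path.read_text()).get("background_noise_sd", 0.0))
    background = BackgroundSpectrum(bg_df.to_numpy()[0], noise_sd=noise_sd)

    scans = []
    for _, rec in manifest.iterrows():
        scan_path = root / rec["scan_path"]
        if not scan_path.exists():
            raise FileNotFoundError(
                f"manifest row {rec['sample_id']}: scan file missing: {scan_path}")
        pts = pd.read_csv(scan_path)
        if pts.shape[1] != len(grid):
            raise ValueError(f"{scan_path}: {pts.shape[1]} channels, grid has {len(grid)}")
        scans.append(MultiPointScan(sample_id=str(rec["sample_id"]),
                                    orientation=str(rec["orientation"]),
                                    points=pts.to_numpy(), grid=grid))
    return scans, background, manifest


def aggregate_to_dataset(
    scans: list[MultiPointScan],
    background: BackgroundSpectrum,
    ssc: np.ndarray,
    params: AggregationParams = AggregationParams(),
) -> plsr.Dataset:
    """Reduce every multi-point scan to its effective spectrum."""
    spectra = [aggregate_scan(s, background, params) for s in scans]
    grid = scans[0].grid
    return plsr.Dataset(
        X=np.vstack([sp.intensity for sp in spectra]),
        y=np.asarray(ssc, dtype=float),
        wavelengths=grid.values,
        sample_ids=[s.sample_id for s in scans],
    )


def load_fixture_dataset(fixture_dir: str | Path,
                         params: AggregationParams = AggregationParams()) -> plsr.Dataset:
    scans, background, manifest = load_manifest(fixture_dir)
    return aggregate_to_dataset(scans, background,
                                manifest["ssc_brix"].to_numpy(), params)


def write_spectra_csv(dataset: plsr.Dataset, path: str | Path) -> None:
    cols = [f"{w:.4f}" for w in dataset.wavelengths]
    df = pd.DataFrame(dataset.X, columns=cols)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.insert(1, "ssc_brix", dataset.y)
    df.to_csv(path, index=False, float_format="%.10g")


def read_spectra_csv(path: str | Path) -> plsr.Dataset:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "ssc_brix" not in df.columns:
        raise ValueError(f"{path}: expected sample_id and ssc_brix columns")
    wl_cols = [c for c in df.columns if c not in ("sample_id", "ssc_brix")]
    return plsr.Dataset(
        X=df[wl_cols].to_numpy(float),
        y=df["ssc_brix"].to_numpy(float),
        wavelengths=np.array([float(c) for c in wl_cols]),
        sample_ids=[str(s) for s in df["sample_id"]],
    )


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False, float_format="%.10g")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
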