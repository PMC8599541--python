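"""Elastic-net epigenetic clocks: training, prediction, and LOOCV evaluation.

A clock is a sparse linear predictor over CpG beta values whose response is
a transformed chronological age (identity, relative, or log-linear; see
:mod:`swineclock.transforms`). Training uses elastic-net penalized least
squares with the mixing parameter fixed at alpha = 0.5 and the penalty
strength lambda chosen by internal ten-fold cross-validation over a
descending log-spaced grid (100 values from lambda_max, the smallest
penalty producing the all-zero model, down to 1e-3 * lambda_max), taking
the lambda minimizing mean CV squared error; ties break toward the larger
(sparser) lambda.

Features are standardized internally for fitting; stored coefficients are
on the original beta scale. The coordinate-descent solver is
scikit-learn's (glmnet-equivalent parameterization: the objective is
(1/2n)||y - Xb||^2 + lambda * [alpha ||b||_1 + (1-alpha)/2 ||b||_2^2]
on standardized features).
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path

from .core_io import MethylationDataset
from .transforms import AgeTransform

__all__ = [
    "ClockConfig",
    "ClockModel",
    "ClockEvaluation",
    "fit_clock",
    "predict_age",
    "loocv",
    "fit_dual_species_clock",
    "write_clock",
    "read_clock",
]


@dataclass(frozen=True)
class ClockConfig:
    """Training configuration for an elastic-net clock."""

    alpha: float = 0.5
    lambda_grid: tuple[float, ...] | None = None
    n_folds_internal: int = 10
    transform: AgeTransform = field(default_factory=AgeTransform)
    standardize_features: bool = True
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    tol: float = 1e-3
    max_iter: int = 1000
    dtype: type = np.float32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.n_folds_internal < 2:
            raise ValueError("n_folds_internal must be >= 2")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, float)
            if len(g) and not (np.all(g > 0) and np.all(np.diff(g) < 0)):
                raise ValueError("lambda_grid must be positive and strictly decreasing")


@dataclass
class ClockModel:
    """Sparse linear age predictor: intercept + per-probe coefficients."""

    intercept: float
    coefficients: pd.Series  # indexed by probe_id, nonzero entries only
    transform: AgeTransform
    training_meta: dict = field(default_factory=dict)

    @property
    def n_cpgs(self) -> int:
        return int((self.coefficients != 0).sum())


@dataclass
class ClockEvaluation:
    """Held-out (LOOCV) predictions and accuracy summaries."""

    predictions: pd.DataFrame  # sample_id-indexed: age_years, pred_transformed, pred_age_years, ...
    r: float  # Pearson R, predicted vs actual on the clock's natural scale
    mae: float  # median absolute error on the clock's natural scale
    per_tissue: pd.DataFrame
    per_species: pd.DataFrame


# ---------------------------------------------------------------------------
# fitting internals
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray, scale: bool = True):
    """Center columns (intercept stays unpenalized) and optionally scale to
    unit variance; zero-variance columns keep scale 1."""
    mu = X.mean(axis=0)
    if not scale:
        return X - mu, mu, np.ones(X.shape[1])
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, cfg: ClockConfig) -> np.ndarray:
    n = Xs.shape[0]
    l1 = max(cfg.alpha, 1e-3)  # pure-ridge limit still needs a finite grid top
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * l1)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, cfg.lambda_min_ratio * lam_max, cfg.n_lambdas)


def _fold_assignments(n: int, k: int, rng: np.random.Generator, strata=None) -> np.ndarray:
    """Seeded fold labels in 0..k-1, optionally stratified by group labels."""
    folds = np.empty(n, int)
    if strata is None:
        strata = np.zeros(n, int)
    strata = np.asarray(strata)
    for g in np.unique(strata):
        idx = np.flatnonzero(strata == g)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _cv_choose_lambda(X, y, lambdas, cfg: ClockConfig, rng, strata=None) -> int:
    n = X.shape[0]
    folds = _fold_assignments(n, cfg.n_folds_internal, rng, strata)
    sse = np.zeros(len(lambdas))
    cnt = 0
    for f in range(cfg.n_folds_internal):
        test = folds == f
        train = ~test
        if test.sum() == 0 or train.sum() < 2:
            continue
        Xt, yt = X[train], y[train]
        Xs, mu, sd = _standardize(Xt, scale=cfg.standardize_features)
        ym = yt.mean()
        coefs = _path(Xs, yt - ym, lambdas, cfg)
        # back to original scale: b = coef/sd; a = ym - mu @ b
        b = coefs / sd[:, None]
        a = ym - mu @ b
        pred = X[test] @ b + a  # (n_test, n_lambdas)
        sse += ((pred - y[test][:, None]) ** 2).sum(axis=0)
        cnt += int(test.sum())
    mse = sse / max(cnt, 1)
    # grid is descending, so argmin of the first minimal value is the sparser model
    return int(np.argmin(mse))


def _path(Xs, yc, lambdas, cfg: ClockConfig) -> np.ndarray:
    """Elastic-net coefficient path over a descending lambda grid.

    Solved in ``cfg.dtype`` at ``cfg.tol``; the default single-precision /
    1e-3 setting is ample for CV model selection on beta matrices, and
    exact-arithmetic callers (small-instance checks) pass float64 with a
    tighter tol.
    """
    Xf = np.asfortranarray(Xs, dtype=cfg.dtype)
    yf = np.ascontiguousarray(yc, dtype=cfg.dtype)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(
            Xf,
            yf,
            l1_ratio=cfg.alpha,
            alphas=np.asarray(lambdas, float),
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            check_input=True,
        )
    return coefs.astype(float)


def _fit_enet(X, y, lam, cfg: ClockConfig):
    Xs, mu, sd = _standardize(X, scale=cfg.standardize_features)
    ym = y.mean()
    coefs = _path(Xs, y - ym, np.array([lam]), cfg)
    b = coefs[:, 0] / sd
    a = float(ym - mu @ b)
    return a, b


def _response(ds: MethylationDataset, transform: AgeTransform) -> np.ndarray:
    return np.asarray(
        transform.forward(
            ds.samples["age_years"].to_numpy(float), ds.samples["species"].to_numpy(object)
        ),
        float,
    )


def _fit_core(X, y, cfg: ClockConfig, strata=None):
    n = X.shape[0]
    if np.std(y) == 0:
        raise ValueError("degenerate response: zero variance in transformed age")
    rng = np.random.default_rng(cfg.seed)
    if cfg.lambda_grid is not None:
        lambdas = np.asarray(cfg.lambda_grid, float)
    else:
        Xs, _, _ = _standardize(X, scale=cfg.standardize_features)
        lambdas = _lambda_grid(Xs, y - y.mean(), cfg)
    if len(lambdas) == 1:
        best = 0  # fixed penalty: no internal CV needed
    else:
        if n < 2 * cfg.n_folds_internal:
            raise ValueError(f"need at least {2 * cfg.n_folds_internal} samples, got {n}")
        best = _cv_choose_lambda(X, y, lambdas, cfg, rng, strata)
    lam = float(lambdas[best])
    a, b = _fit_enet(X, y, lam, cfg)
    return a, b, lam, lambdas


def fit_clock(ds: MethylationDataset, cfg: ClockConfig) -> ClockModel:
    """Train an elastic-net clock on a methylation dataset.

    The response is ``cfg.transform`` applied to chronological age. Training
    probes must be complete (no missing betas). Only nonzero coefficients
    are stored in the returned model.
    """
    X = ds.betas.to_numpy(float).T  # samples x probes
    if np.isnan(X).any():
        raise ValueError("missing betas in training probes; clock training requires complete rows")
    y = _response(ds, cfg.transform)
    strata = (
        ds.samples["species"].to_numpy(object)
        if ds.samples["species"].nunique() > 1
        else None
    )
    a, b, lam, lambdas = _fit_core(X, y, cfg, strata)
    nz = np.flatnonzero(b)
    coef = pd.Series(b[nz], index=ds.betas.index[nz], name="coefficient")
    meta = {
        "alpha": cfg.alpha,
        "lambda": lam,
        "n_lambdas": len(lambdas),
        "n_samples": X.shape[0],
        "n_probes": X.shape[1],
        "species": sorted(ds.samples["species"].unique().tolist()),
    }
    return ClockModel(float(a), coef, cfg.transform, meta)


def predict_age(model: ClockModel, ds: MethylationDataset) -> pd.DataFrame:
    """Predict DNAm age for every sample.

    Returns a DataFrame indexed by sample id with ``pred_transformed`` (the
    linear predictor) and ``pred_age_years`` (inverse-transformed). For a
    relative-age clock the transformed value is the predicted relative age
    and years are recovered via each sample's species max lifespan.
    """
    missing = model.coefficients.index.difference(ds.betas.index)
    if len(missing):
        raise ValueError(f"model probes missing from dataset: {list(missing[:10])}")
    X = ds.betas.loc[model.coefficients.index].to_numpy(float).T
    yhat = X @ model.coefficients.to_numpy() + model.intercept
    species = ds.samples["species"].to_numpy(object)
    ages = np.asarray(model.transform.inverse(yhat, species), float)
    if not np.all(np.isfinite(ages)):
        raise FloatingPointError("non-finite inverse-transformed prediction")
    return pd.DataFrame(
        {"pred_transformed": yhat, "pred_age_years": ages}, index=ds.betas.columns
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _natural_scale(transform: AgeTransform, preds: pd.DataFrame, samples: pd.DataFrame):
    """(predicted, actual) on the clock's natural reporting scale.

    Years for identity/log-linear clocks; relative-age units for the
    relative clock (matching how such clocks are plotted and their mae read).
    """
    age = samples["age_years"].to_numpy(float)
    sp = samples["species"].to_numpy(object)
    if transform.kind == "relative":
        actual = np.asarray(transform.forward(age, sp), float)
        return preds["pred_transformed"].to_numpy(), actual
    return preds["pred_age_years"].to_numpy(), age


def _evaluate(transform, preds: pd.DataFrame, samples: pd.DataFrame) -> ClockEvaluation:
    yhat, y = _natural_scale(transform, preds, samples)
    out = preds.copy()
    out["age_years"] = samples["age_years"].to_numpy(float)
    out["tissue"] = samples["tissue"].to_numpy(object)
    out["species"] = samples["species"].to_numpy(object)
    err = np.abs(yhat - y)
    per_tissue = []
    for t, grp in out.groupby("tissue"):
        gh, gy = _natural_scale(transform, grp, grp)
        per_tissue.append(
            {"tissue": t, "n": len(grp), "r": _pearson(gh, gy), "mae": float(np.median(np.abs(gh - gy)))}
        )
    per_species = []
    for s, grp in out.groupby("species"):
        gh, gy = _natural_scale(transform, grp, grp)
        per_species.append(
            {"species": s, "n": len(grp), "r": _pearson(gh, gy), "mae": float(np.median(np.abs(gh - gy)))}
        )
    return ClockEvaluation(
        predictions=out,
        r=_pearson(yhat, y),
        mae=float(np.median(err)),
        per_tissue=pd.DataFrame(per_tissue).set_index("tissue"),
        per_species=pd.DataFrame(per_species).set_index("species"),
    )


def loocv(ds: MethylationDataset, cfg: ClockConfig, verbose: bool = False) -> ClockEvaluation:
    """Leave-one-sample-out evaluation with a full refit (including the
    internal lambda search) for every held-out sample.

    Accuracy is reported on held-out predictions only: Pearson R between
    predicted and actual (transformed-scale for the relative clock, years
    otherwise) and the median absolute error on the same scale.
    """
    X = ds.betas.to_numpy(float).T
    if np.isnan(X).any():
        raise ValueError("missing betas; clock training requires complete rows")
    y = _response(ds, cfg.transform)
    species = ds.samples["species"].to_numpy(object)
    strata_all = species if len(np.unique(species)) > 1 else None
    n = X.shape[0]
    yhat_t = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        sub_cfg = dataclasses.replace(
            cfg, seed=int(np.random.default_rng([cfg.seed, i]).integers(2**31 - 1))
        )
        strata = strata_all[mask] if strata_all is not None else None
        a, b, _, _ = _fit_core(X[mask], y[mask], sub_cfg, strata)
        yhat_t[i] = X[i] @ b + a
        if verbose and (i + 1) % 25 == 0:
            print(f"loocv {i + 1}/{n}", flush=True)
    ages = np.asarray(cfg.transform.inverse(yhat_t, species), float)
    preds = pd.DataFrame(
        {"pred_transformed": yhat_t, "pred_age_years": ages}, index=ds.betas.columns
    )
    return _evaluate(cfg.transform, preds, ds.samples)


def fit_dual_species_clock(
    ds_pig: MethylationDataset, ds_human: MethylationDataset | None, cfg: ClockConfig
) -> ClockModel:
    """Train one clock jointly on two species over their shared probes.

    The cohorts are column-concatenated on the probe intersection and the
    species-aware transform (relative or log-linear) is applied per sample.
    With ``ds_human=None`` this degenerates to :func:`fit_clock` on pigs.
    """
    if ds_human is None:
        return fit_clock(ds_pig, cfg)
    if cfg.transform.kind not in ("relative", "loglinear"):
        raise ValueError("dual-species clock requires a relative or loglinear transform")
    ds = concat_cohorts(ds_pig, ds_human)
    return fit_clock(ds, cfg)


def concat_cohorts(a: MethylationDataset, b: MethylationDataset) -> MethylationDataset:
    """Join two cohorts on their shared probes (columns concatenated)."""
    shared = a.betas.index.intersection(b.betas.index)
    if len(shared) == 0:
        raise ValueError("empty probe intersection between cohorts")
    betas = pd.concat([a.betas.loc[shared], b.betas.loc[shared]], axis=1)
    cols = sorted(set(a.samples.columns) & set(b.samples.columns), key=list(a.samples.columns).index)
    samples = pd.concat([a.samples[cols], b.samples[cols]], axis=0)
    return MethylationDataset(betas, samples, a.probes.loc[shared])


# ---------------------------------------------------------------------------
# clock (de)serialization: CSV with '#'-prefixed header block
# ---------------------------------------------------------------------------

def write_clock(model: ClockModel, path) -> Path:
    """Write a clock as CSV: a '#' header block (intercept, transform
    parameters, training meta) followed by probe_id,coefficient rows."""
    path = Path(path)
    tp = model.transform.to_params()
    lines = [
        f"# intercept={model.intercept!r}",
        f"# transform={tp['kind']}",
        f"# offset={tp['offset']!r}",
    ]
    for sp, v in sorted(tp["max_lifespan_by_species"].items()):
        lines.append(f"# max_lifespan.{sp}={v!r}")
    for sp, v in sorted(tp["maturity_by_species"].items()):
        lines.append(f"# maturity.{sp}={v!r}")
    for k, v in sorted(model.training_meta.items()):
        lines.append(f"# meta.{k}={v!r}")
    lines.append("probe_id,coefficient")
    for pid, c in model.coefficients.items():
        lines.append(f"{pid},{c!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_clock(path) -> ClockModel:
    """Read a clock written by :func:`write_clock`; exact round-trip."""
    import ast

    header: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                header[k.strip()] = v
            elif line != "probe_id,coefficient":
                pid, _, c = line.partition(",")
                rows.append((pid, float(c)))
    kind = header.get("transform", "")
    from .transforms import TRANSFORM_KINDS

    if kind not in TRANSFORM_KINDS:
        raise ValueError(f"unknown transform name {kind!r} in clock file")
    lifespans = {
        k.split(".", 1)[1]: float(v)
        for k, v in header.items()
        if k.startswith("max_lifespan.")
    }
    maturities = {
        k.split(".", 1)[1]: float(v) for k, v in header.items() if k.startswith("maturity.")
    }
    meta = {}
    for k, v in header.items():
        if k.startswith("meta."):
            try:
                meta[k.split(".", 1)[1]] = ast.literal_eval(v)
            except (ValueError, SyntaxError):
                meta[k.split(".", 1)[1]] = v
    transform = AgeTransform(
        kind=kind,
        max_lifespan_by_species=lifespans,
        maturity_by_species=maturities,
        offset=float(header.get("offset", 1.0)),
    )
    coef = pd.Series(
        dict(rows), name="coefficient", dtype=float
    ) if rows else pd.Series([], name="coefficient", dtype=float)
    if rows:
        coef = coef.loc[[r[0] for r in rows]]  # preserve file order
    return ClockModel(float(header["intercept"]), coef, transform, meta)
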