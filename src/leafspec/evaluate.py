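"""Repeated random-split calibration/validation protocol and model grid.

The protocol: a spectra/trait dataset is split at random into a calibration
part (default 80%) and a validation part (default 20%), a PLSR model is
built on the calibration part only -- including any wavelength selection and
the LOO choice of component count -- and scored on both parts; this is
repeated ``n_rep`` times (the reference protocol uses 200) to yield a
distribution of R2/RMSE statistics rather than a single split's luck.

Reproducibility contract: repetition ``r`` of a run with master seed ``s``
uses ``numpy.random.SeedSequence(s, spawn_key=(r,))`` for everything random
in that repetition (the split, fold assignments, selector seeds), so any
single repetition can be re-run in isolation and a grid of preprocessing x
selector cells sharing ``s`` shares the identical split sequence -- the grid
comparison is paired by construction.

Row-wise pre-treatments (SNV, derivatives) need no training-set fitting, so
spectra are preprocessed once per cell before the repetition loop; selection
and rank choice always happen inside the loop, on calibration rows only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectraMatrix
from .errors import DegenerateDataError, InvalidParameterError, SchemaError
from .pls import PLSRModel, fit_plsr, fit_stats, loo_select_ncomp, predict
from .preprocess import METHODS, preprocess
from .select import SELECTORS

__all__ = [
    "FittedPipeline",
    "EvaluationDistribution",
    "evaluate_pipeline",
    "summarize",
    "grid_search",
    "ensemble_predict",
    "residual_table",
]

_STATS = ("r2_cal", "rmse_cal", "r2_val", "rmse_val")


@dataclass
class FittedPipeline:
    """One repetition's fitted model: preprocessing, band mask, PLSR fit."""

    method: str
    window: int
    polyorder: int
    mask: np.ndarray
    model: PLSRModel

    def predict(self, spectra: SpectraMatrix) -> np.ndarray:
        Xp = preprocess(spectra, self.method, self.window, self.polyorder)
        if Xp.n_bands != self.mask.size:
            raise SchemaError(
                f"band count {Xp.n_bands} does not match pipeline mask "
                f"length {self.mask.size}"
            )
        return predict(self.model, Xp.values[:, self.mask])


@dataclass
class EvaluationDistribution:
    """Per-repetition records of one preprocessing x selector cell."""

    records: pd.DataFrame
    masks: np.ndarray                  # (n_rep, n_bands) bool
    pipelines: list                    # FittedPipeline per successful rep
    wavelengths: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def selection_frequency(self) -> np.ndarray:
        """Per-band fraction of repetitions that selected the band."""
        ok = np.asarray(self.records["failed"] == False)  # noqa: E712
        if not ok.any():
            raise DegenerateDataError("no successful repetition")
        return self.masks[ok].mean(axis=0)


def _rep_rng(master_seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(rep,)))


def _split(n: int, frac_cal: float, rng: np.random.Generator):
    n_cal = int(round(frac_cal * n))
    perm = rng.permutation(n)
    return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])


def _split_hash(val_idx: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(val_idx, dtype=np.int64).tobytes()).hexdigest()[:10]


def evaluate_pipeline(
    spectra: SpectraMatrix,
    y,
    method: str = "raw",
    selector: str = "none",
    n_rep: int = 200,
    frac_cal: float = 0.8,
    seed: int = 0,
    max_ncomp: int = 10,
    window: int = 15,
    polyorder: int = 2,
    selector_params: dict | None = None,
) -> EvaluationDistribution:
    """Run the repeated-split protocol for one preprocessing x selector cell.

    Failed repetitions (degenerate splits) are recorded with their reason,
    never silently dropped.
    """
    if method not in METHODS:
        raise InvalidParameterError(f"unknown preprocessing method '{method}'")
    if selector != "none" and selector not in SELECTORS:
        raise InvalidParameterError(
            f"unknown selector '{selector}'; choose none or one of "
            f"{tuple(SELECTORS)}"
        )
    if not (0.0 < frac_cal < 1.0):
        raise InvalidParameterError("frac_cal must be in (0, 1)")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != spectra.n_samples:
        raise SchemaError("y length does not match spectra rows")
    n = y.size
    n_cal = int(round(frac_cal * n))
    if min(n_cal, n - n_cal) < 5:
        raise InvalidParameterError(
            "both partitions need at least 5 samples; "
            f"n={n}, frac_cal={frac_cal}"
        )
    selector_params = dict(selector_params or {})

    Xp = preprocess(spectra, method, window, polyorder)
    p = Xp.n_bands
    masks = np.zeros((n_rep, p), dtype=bool)
    pipelines: list[FittedPipeline | None] = []
    rows = []
    for rep in range(n_rep):
        rng = _rep_rng(seed, rep)
        cal, val = _split(n, frac_cal, rng)
        row = {
            "rep": rep,
            "seed": seed,
            "split_hash": _split_hash(val),
            "failed": False,
            "reason": "",
        }
        try:
            Xc, yc = Xp.values[cal], y[cal]
            if selector == "none":
                mask = np.ones(p, dtype=bool)
            else:
                params = dict(selector_params)
                if selector in ("ga", "rep"):
                    params.setdefault("seed", int(rng.integers(2**31)))
                params.setdefault("max_ncomp", max_ncomp)
                mask = SELECTORS[selector](Xc, yc, **params).selected
            best_k, _ = loo_select_ncomp(Xc[:, mask], yc, max_ncomp)
            k = max(1, best_k)
            model = fit_plsr(Xc[:, mask], yc, k)
            r2c, rmsec = fit_stats(yc, predict(model, Xc[:, mask]))
            r2v, rmsev = fit_stats(
                y[val], predict(model, Xp.values[np.ix_(val, np.where(mask)[0])])
            )
            masks[rep] = mask
            pipelines.append(
                FittedPipeline(method, window, polyorder, mask, model)
            )
            row.update(
                n_components=model.n_components,
                n_selected=int(mask.sum()),
                r2_cal=r2c,
                rmse_cal=rmsec,
                r2_val=r2v,
                rmse_val=rmsev,
            )
        except (DegenerateDataError, InvalidParameterError) as exc:
            row.update(
                failed=True, reason=str(exc), n_components=0, n_selected=0,
                r2_cal=np.nan, rmse_cal=np.nan, r2_val=np.nan, rmse_val=np.nan,
            )
            pipelines.append(None)
        rows.append(row)
    return EvaluationDistribution(
        records=pd.DataFrame(rows),
        masks=masks,
        pipelines=[pl for pl in pipelines if pl is not None],
        wavelengths=Xp.wavelengths.copy(),
        config={
            "method": method,
            "selector": selector,
            "n_rep": n_rep,
            "frac_cal": frac_cal,
            "seed": seed,
            "max_ncomp": max_ncomp,
            "window": window,
            "polyorder": polyorder,
            "selector_params": selector_params,
        },
    )


def summarize(dist: EvaluationDistribution) -> dict:
    """Mean / min / max / 2.5th / 97.5th percentile of each fit statistic."""
    ok = dist.records[dist.records["failed"] == False]  # noqa: E712
    if len(ok) == 0:
        raise DegenerateDataError("all repetitions failed; nothing to summarize")
    out = {
        "method": dist.config.get("method"),
        "selector": dist.config.get("selector"),
        "n_rep": len(dist.records),
        "n_failed": int(dist.records["failed"].sum()),
        "mean_n_components": float(ok["n_components"].mean()),
        "mean_n_selected": float(ok["n_selected"].mean()),
    }
    for stat in _STATS:
        v = np.asarray(ok[stat], dtype=float)
        out[f"{stat}_mean"] = float(v.mean())
        out[f"{stat}_min"] = float(v.min())
        out[f"{stat}_max"] = float(v.max())
        out[f"{stat}_p2.5"] = float(np.percentile(v, 2.5))
        out[f"{stat}_p97.5"] = float(np.percentile(v, 97.5))
    return out


def grid_search(
    spectra: SpectraMatrix,
    y,
    methods=METHODS,
    selectors=("none",),
    n_rep: int = 200,
    seed: int = 0,
    frac_cal: float = 0.8,
    max_ncomp: int = 10,
    window: int = 15,
    polyorder: int = 2,
    selector_params: dict | None = None,
):
    """Evaluate every preprocessing x selector cell on shared splits.

    Returns ``(summary_table, best_config, distributions)``. The best cell
    maximizes mean validation R2; ties break toward lower mean validation
    RMSE, then toward the earlier method/selector in the given lists.
    """
    methods = list(methods)
    selectors = list(selectors)
    if not methods or not selectors:
        raise InvalidParameterError("methods and selectors must be non-empty")
    dists = {}
    rows = []
    for method in methods:
        for selector in selectors:
            dist = evaluate_pipeline(
                spectra, y, method, selector, n_rep, frac_cal, seed,
                max_ncomp, window, polyorder,
                (selector_params or {}).get(selector),
            )
            dists[(method, selector)] = dist
            rows.append(summarize(dist))
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(rows)),
        key=lambda i: (
            -rows[i]["r2_val_mean"],
            rows[i]["rmse_val_mean"],
            methods.index(rows[i]["method"]),
            selectors.index(rows[i]["selector"]),
        ),
    )
    best = (rows[order[0]]["method"], rows[order[0]]["selector"])
    return table, best, dists


def ensemble_predict(pipelines, spectra_new: SpectraMatrix):
    """Per-sample mean and SD of predictions over a model ensemble."""
    if len(pipelines) < 2:
        raise InvalidParameterError("ensemble needs at least 2 models")
    preds = np.stack([pl.predict(spectra_new) for pl in pipelines])
    return preds.mean(axis=0), preds.std(axis=0, ddof=1)


def residual_table(y, yhat_mean, yhat_sd=None) -> pd.DataFrame:
    """Measured-minus-predicted residuals with ensemble SD carried through."""
    y = np.asarray(y, dtype=float).ravel()
    yhat_mean = np.asarray(yhat_mean, dtype=float).ravel()
    if y.size != yhat_mean.size:
        raise InvalidParameterError("y and predictions must have equal length")
    out = pd.DataFrame(
        {
            "measured": y,
            "predicted": yhat_mean,
            "residual": y - yhat_mean,
        }
    )
    if yhat_sd is not None:
        out["predicted_sd"] = np.asarray(yhat_sd, dtype=float).ravel()
    return out
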