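"""CSV/JSON readers and writers, pipeline configuration, and ``run_all``.

File dialects
-------------
* spectra: wide CSV, header ``tree_id,w1100,w1106,...``; each ``w<nm>`` column
  holds the signal at that wavelength. Wavelengths must parse and increase.
* design / trait tables: plain CSV with ``tree_id, family_id,
  replication_id`` and, for traits, one column per trait.
* configuration: YAML with ``seed``, ``simulate``, ``evaluate`` and
  ``genetics`` blocks; any omitted key falls back to the documented default
  (see :data:`DEFAULT_CONFIG`).

``run_all`` chains the whole analysis: simulate the trial, its traits and
spectra; evaluate the preprocessing grid per trait on the lab-measured
subset; refine the winning method with the sMC selector; ensemble-predict
the unmeasured trees; run the genetic analysis on the combined trait table;
select families; and write every artifact plus a manifest under one output
directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import SpectraMatrix
from .errors import InvalidParameterError, SchemaError
from .evaluate import (
    ensemble_predict,
    evaluate_pipeline,
    grid_search,
    residual_table,
    summarize,
)
from .genetics import select_families, summarize_genetics
from .preprocess import METHODS
from .select import SELECTORS
from .simulate import (
    SpectraParams,
    TraitParams,
    make_design,
    simulate_spectra,
    simulate_traits,
    subsample_measured,
)

__all__ = [
    "DEFAULT_CONFIG",
    "read_spectra",
    "write_spectra",
    "load_config",
    "run_all",
]

log = logging.getLogger("leafspec")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "n_families": 50,
        "n_reps": 5,
        "trees_per_rep": 6,
        "n_measured": 500,
        "traits": {},   # TraitParams overrides (mu, cov_f, cov_e)
        "spectra": {},  # SpectraParams overrides
    },
    "evaluate": {
        "methods": list(METHODS),
        "selectors": ["none"],
        "refine_selector": "smc",
        "n_rep": 200,
        "frac_cal": 0.8,
        "max_ncomp": 8,
        "window": 15,
        "polyorder": 2,
    },
    "genetics": {
        "coefficient": 2.5,
        "gain_fractions": [0.1, 0.2, 0.3],
        "jackknife": True,
        "selection_rules": [["anth", "flav"], ["anth", "flav", "nbi"]],
    },
}


def write_spectra(spectra: SpectraMatrix, path) -> None:
    """Write a spectra matrix as wide CSV (``tree_id, w<nm>, ...``)."""
    cols = [f"w{int(round(w))}" for w in spectra.wavelengths]
    df = pd.DataFrame(spectra.values, columns=cols)
    df.insert(0, "tree_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_spectra(path) -> SpectraMatrix:
    """Read a wide-CSV spectra file, validating layout and values."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.columns[0] != "tree_id":
        raise SchemaError(
            f"{path}: expected header 'tree_id,w<nm>,...', got "
            f"{list(df.columns[:3])}..."
        )
    wl = []
    for c in df.columns[1:]:
        if not c.startswith("w"):
            raise SchemaError(f"{path}: band column '{c}' does not match 'w<nm>'")
        try:
            wl.append(float(c[1:]))
        except ValueError as exc:
            raise SchemaError(f"{path}: cannot parse wavelength from '{c}'") from exc
    wl = np.asarray(wl)
    if np.any(np.diff(wl) <= 0):
        raise SchemaError(f"{path}: wavelengths are not strictly increasing")
    raw = df.iloc[:, 1:].to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        blank = np.char.strip(col.astype(str)) == ""
        if blank.any():
            i = int(np.argmax(blank))
            raise SchemaError(
                f"{path}: blank cell at row {i + 2}, column '{df.columns[j + 1]}'"
            )
        try:
            values[:, j] = col.astype(float)
        except ValueError:
            for i, v in enumerate(col):
                try:
                    float(v)
                except ValueError:
                    raise SchemaError(
                        f"{path}: non-numeric value '{v}' at row {i + 2}, "
                        f"column '{df.columns[j + 1]}'"
                    ) from None
    return SpectraMatrix(
        values=values, wavelengths=wl, sample_ids=list(df["tree_id"])
    )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a pipeline configuration: defaults <- YAML file <- overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise InvalidParameterError(f"{path}: config must be a YAML mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    for m in cfg["evaluate"]["methods"]:
        if m not in METHODS:
            raise InvalidParameterError(f"config: unknown preprocessing method '{m}'")
    for s in cfg["evaluate"]["selectors"]:
        if s != "none" and s not in SELECTORS:
            raise InvalidParameterError(f"config: unknown selector '{s}'")
    if "seed" not in cfg or cfg["seed"] is None:
        raise InvalidParameterError("config: master seed is required")
    return cfg


def _trait_params(block: dict) -> TraitParams:
    kwargs = {}
    if block.get("mu") is not None:
        kwargs["mu"] = np.asarray(block["mu"], dtype=float)
    for key in ("cov_f", "cov_e"):
        if block.get(key) is not None:
            kwargs[key] = np.asarray(block[key], dtype=float)
    return TraitParams(**kwargs)


def _spectra_params(block: dict) -> SpectraParams:
    known = {
        "wavelength_start", "wavelength_step", "n_bands", "peak_centers",
        "peak_widths", "peak_amplitudes", "baseline_coeffs", "scatter_sd",
        "noise_sd", "n_scans",
    }
    bad = set(block) - known
    if bad:
        raise InvalidParameterError(f"config: unknown spectra parameters {sorted(bad)}")
    return SpectraParams(**block)


def run_all(config: dict, outdir) -> dict:
    """Execute the full simulate -> evaluate -> predict -> genetics chain.

    Returns the manifest (also written as ``manifest.json``). Artifacts of
    completed stages persist even if a later stage fails; the failure is
    re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {
        "package": "leafspec",
        "version": __version__,
        "config": config,
        "derived_seeds": {},
        "outputs": [],
        "stages": [],
    }

    def _save_manifest():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def _record(path: Path):
        manifest["outputs"].append(str(path.relative_to(outdir)))

    stage = "simulate"
    try:
        sim = config["simulate"]
        tp = _trait_params(sim.get("traits") or {})
        sp = _spectra_params(sim.get("spectra") or {})
        ss = np.random.SeedSequence(seed)
        seeds = {
            name: int(s.generate_state(1)[0] % (2**31))
            for name, s in zip(
                ("traits", "spectra", "measured"), ss.spawn(3)
            )
        }
        manifest["derived_seeds"] = seeds
        log.info("simulating design, traits and spectra (seed=%d)", seed)
        design = make_design(sim["n_families"], sim["n_reps"], sim["trees_per_rep"])
        traits = simulate_traits(design, tp, seeds["traits"])
        spectra = simulate_spectra(traits, sp, seeds["spectra"])
        measured = subsample_measured(design, sim["n_measured"], seeds["measured"])

        design.to_csv(outdir / "design.csv", index=False)
        _record(outdir / "design.csv")
        traits.assign(measured=measured).to_csv(outdir / "traits_true.csv", index=False)
        _record(outdir / "traits_true.csv")
        lab = traits.loc[measured, ["tree_id", "family_id", "replication_id",
                                    "anth", "flav", "nbi"]]
        lab.to_csv(outdir / "traits_measured.csv", index=False)
        _record(outdir / "traits_measured.csv")
        write_spectra(spectra, outdir / "spectra.csv")
        _record(outdir / "spectra.csv")
        manifest["stages"].append(stage)
        _save_manifest()

        ev = config["evaluate"]
        midx = np.where(measured)[0]
        sm = spectra.take(midx)
        combined = traits[["tree_id", "family_id", "replication_id"]].copy()
        best_models = {}
        for t_i, trait in enumerate(("anth", "flav", "nbi")):
            stage = f"evaluate:{trait}"
            log.info("grid search for %s", trait)
            y = np.asarray(lab[trait], dtype=float)
            table, best, dists = grid_search(
                sm, y,
                methods=ev["methods"], selectors=ev["selectors"],
                n_rep=ev["n_rep"], seed=seed + 101 + t_i,
                frac_cal=ev["frac_cal"], max_ncomp=ev["max_ncomp"],
                window=ev["window"], polyorder=ev["polyorder"],
            )
            refine = ev.get("refine_selector")
            if refine and refine not in ev["selectors"]:
                log.info("refining %s (%s) with selector %s", trait, best[0], refine)
                dist = evaluate_pipeline(
                    sm, y, best[0], refine, ev["n_rep"], ev["frac_cal"],
                    seed + 101 + t_i, ev["max_ncomp"], ev["window"],
                    ev["polyorder"],
                )
                row = summarize(dist)
                table = pd.concat([table, pd.DataFrame([row])], ignore_index=True)
                if row["r2_val_mean"] >= table["r2_val_mean"].max() - 1e-12 or (
                    row["r2_val_mean"] >= summarize(dists[best])["r2_val_mean"]
                ):
                    best, dists[(best[0], refine)] = (best[0], refine), dist
                else:
                    dists[(best[0], refine)] = dist
            best_dist = dists[best]
            table.to_csv(outdir / f"grid_summary_{trait}.csv", index=False)
            _record(outdir / f"grid_summary_{trait}.csv")
            best_dist.records.to_csv(outdir / f"records_{trait}.csv", index=False)
            _record(outdir / f"records_{trait}.csv")
            stab = pd.DataFrame(
                best_dist.masks.astype(int),
                columns=[f"w{int(round(w))}" for w in best_dist.wavelengths],
            )
            stab.insert(0, "rep", np.arange(len(stab)))
            stab.to_csv(outdir / f"stability_{trait}.csv", index=False)
            _record(outdir / f"stability_{trait}.csv")

            mean_pred, sd_pred = ensemble_predict(best_dist.pipelines, spectra)
            pred = pd.DataFrame(
                {
                    "tree_id": spectra.sample_ids,
                    "measured": measured,
                    f"pred_{trait}": mean_pred,
                    f"pred_sd_{trait}": sd_pred,
                }
            )
            pred.to_csv(outdir / f"ensemble_predictions_{trait}.csv", index=False)
            _record(outdir / f"ensemble_predictions_{trait}.csv")
            resid = residual_table(y, mean_pred[midx], sd_pred[midx])
            resid.insert(0, "tree_id", lab["tree_id"].to_numpy())
            resid.to_csv(outdir / f"residuals_{trait}.csv", index=False)
            _record(outdir / f"residuals_{trait}.csv")

            best_models[trait] = {
                "method": best[0],
                "selector": best[1],
                "r2_val_mean": float(
                    table.set_index(["method", "selector"]).loc[
                        best, "r2_val_mean"
                    ]
                ),
            }
            combined[trait] = np.where(measured, traits[trait], mean_pred)
            manifest["stages"].append(stage)
            _save_manifest()

        stage = "genetics"
        log.info("genetic analysis on the combined trait table")
        combined.to_csv(outdir / "traits_combined.csv", index=False)
        _record(outdir / "traits_combined.csv")
        gn = config["genetics"]
        summary = summarize_genetics(
            combined,
            k=gn["coefficient"],
            gain_fractions=gn["gain_fractions"],
            jackknife=gn.get("jackknife", True),
        )
        gd = summary.to_dict()
        gd["best_models"] = best_models
        with open(outdir / "genetics_summary.json", "w") as fh:
            json.dump(gd, fh, indent=2)
        _record(outdir / "genetics_summary.json")
        summary.breeding_values.to_csv(outdir / "breeding_values.csv", index=False)
        _record(outdir / "breeding_values.csv")

        stage = "select"
        selection = {
            "+".join(rule): select_families(summary.breeding_values, rule)
            for rule in gn["selection_rules"]
        }
        report = {
            rule: {"n_families": len(fams), "families": [int(f) for f in fams]}
            for rule, fams in selection.items()
        }
        with open(outdir / "selection_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        _record(outdir / "selection_report.json")
        manifest["stages"] += ["genetics", "select"]
        _save_manifest()
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _save_manifest()
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc
    return manifest
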