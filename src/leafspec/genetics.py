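"""Variance components, heritability, correlations, breeding values and gain
for balanced (or near-balanced) half-sib family trials.

Model: ``y = grand mean + replication (fixed) + family (random) + residual``.
The family variance sigma2_f and residual variance sigma2_e are estimated by
REML; because the model has a single random effect whose incidence matrix is
a family indicator, the REML log-likelihood is profiled down to a
one-dimensional search over the variance ratio gamma = sigma2_f/sigma2_e,
with all linear algebra collapsing to family counts (Z'Z is diagonal). On a
balanced design this reproduces the classical expected-mean-squares ANOVA
estimator; on unbalanced data (e.g. the lab-measured subset) it remains the
proper REML fit. Negative family variance solutions are truncated at zero
and flagged.

Derived quantities follow half-sib progeny-trial practice:

* narrow-sense heritability ``h2 = k * sigma2_f / (sigma2_f + sigma2_e)``
  with the multiplier ``k`` defaulting to 2.5 (a conservative choice between
  the classic half-sib 4 and full-sib 2, guarding against part-sib
  assembly and inbreeding in open-pollinated families);
* genetic correlation ``r_g = cov_f / sqrt(sigma2_f_i * sigma2_f_j)`` and
  phenotypic correlation
  ``r_p = (cov_f + cov_e) / sqrt(total_i * total_j)``, with the bivariate
  covariances obtained from univariate fits of the two traits and their sum
  (``cov = (var(i+j) - var(i) - var(j)) / 2``, exact for shared designs);
* family breeding values as BLUPs of the family effect,
  ``BV_f = shrink * (family mean - grand mean)`` with
  ``shrink = sigma2_f / (sigma2_f + sigma2_e / n_f)``;
* realized genetic gain ``dG_R`` = mean BV of the selected top fraction
  minus the mean BV of all families (the BV scale; the phenotype scale adds
  the grand mean to both terms and cancels);
* delete-one-family jackknife standard errors for h2, r_g and r_p (families
  are the independent genetic units).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DegenerateDataError, InvalidParameterError

__all__ = [
    "VarianceComponents",
    "PairCovariance",
    "GeneticSummary",
    "fit_univariate_reml",
    "fit_pair_covariance",
    "heritability",
    "genetic_correlation",
    "phenotypic_correlation",
    "jackknife_se",
    "breeding_values",
    "realized_gain",
    "select_families",
    "summarize_genetics",
]


@dataclass
class VarianceComponents:
    trait: str
    sigma2_f: float
    sigma2_e: float
    n_families: int
    n_per_family: float
    loglik: float
    truncated: bool = False


@dataclass
class PairCovariance:
    trait_i: str
    trait_j: str
    cov_f: float
    cov_e: float


@dataclass
class GeneticSummary:
    traits: list
    variance_components: dict          # trait -> VarianceComponents
    heritability: dict                 # trait -> h2
    heritability_se: dict              # trait -> jackknife SE
    genetic_correlation: dict          # (i, j) -> r_g
    genetic_correlation_se: dict
    phenotypic_correlation: dict       # (i, j) -> r_p
    phenotypic_correlation_se: dict
    heritability_coefficient: float
    breeding_values: pd.DataFrame
    realized_gain: dict = field(default_factory=dict)  # (trait, frac) -> dG_R

    def to_dict(self) -> dict:
        pair_key = lambda k: f"{k[0]}__{k[1]}"
        return {
            "traits": list(self.traits),
            "heritability_coefficient": self.heritability_coefficient,
            "variance_components": {
                t: {
                    "sigma2_f": vc.sigma2_f,
                    "sigma2_e": vc.sigma2_e,
                    "n_families": vc.n_families,
                    "n_per_family": vc.n_per_family,
                    "loglik": vc.loglik,
                    "truncated": vc.truncated,
                }
                for t, vc in self.variance_components.items()
            },
            "heritability": dict(self.heritability),
            "heritability_se": dict(self.heritability_se),
            "genetic_correlation": {
                pair_key(k): v for k, v in self.genetic_correlation.items()
            },
            "genetic_correlation_se": {
                pair_key(k): v for k, v in self.genetic_correlation_se.items()
            },
            "phenotypic_correlation": {
                pair_key(k): v for k, v in self.phenotypic_correlation.items()
            },
            "phenotypic_correlation_se": {
                pair_key(k): v for k, v in self.phenotypic_correlation_se.items()
            },
            "realized_gain": {
                f"{t}__top{frac:g}": v
                for (t, frac), v in self.realized_gain.items()
            },
        }


def _design_arrays(y, family, replication):
    y = np.asarray(y, dtype=float).ravel()
    family = np.asarray(family)
    if family.size != y.size:
        raise InvalidParameterError("family labels must match y length")
    fams, fam_idx = np.unique(family, return_inverse=True)
    if fams.size < 2:
        raise InvalidParameterError(
            "singular design: need at least 2 families for a family variance"
        )
    n = y.size
    if replication is None:
        X = np.ones((n, 1))
    else:
        replication = np.asarray(replication)
        if replication.size != n:
            raise InvalidParameterError("replication labels must match y length")
        reps = np.unique(replication)
        X = np.ones((n, len(reps)))
        for j, r in enumerate(reps[1:], start=1):
            X[:, j] = (replication == r).astype(float)
    return y, fams, fam_idx, X


def fit_univariate_reml(
    y, family, replication=None, trait: str = "y"
) -> VarianceComponents:
    """REML variance components for one trait.

    ``replication`` labels enter as fixed block effects; pass ``None`` for a
    mean-only fixed part. The profiled criterion is searched over
    log(sigma2_f / sigma2_e) and compared against the sigma2_f = 0 boundary.
    """
    y, fams, fam_idx, X = _design_arrays(y, family, replication)
    n, p = X.shape
    F = fams.size
    n_f = np.bincount(fam_idx, minlength=F).astype(float)
    if n_f.max() < 2:
        raise InvalidParameterError(
            "need at least 2 trees in some family to separate the variances"
        )

    # sufficient statistics; Z'Z is diag(n_f) for the family indicator
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ZtX = np.zeros((F, p))
    np.add.at(ZtX, fam_idx, X)
    Zty = np.bincount(fam_idx, weights=y, minlength=F)

    def criterion(log_gamma: float) -> float:
        gamma = math.exp(log_gamma)
        c = gamma / (1.0 + gamma * n_f)            # = (1/gamma + n_f)^-1
        A = XtX - ZtX.T @ (c[:, None] * ZtX)       # X' V0^-1 X
        rhs = Xty - ZtX.T @ (c * Zty)
        try:
            beta = np.linalg.solve(A, rhs)
            sign, logdetA = np.linalg.slogdet(A)
        except np.linalg.LinAlgError:
            return np.inf
        if sign <= 0:
            return np.inf
        ypy = yty - float(Zty @ (c * Zty)) - float(rhs @ beta)
        if ypy <= 0:
            return np.inf
        logdetV0 = float(np.log1p(gamma * n_f).sum())
        return (n - p) * math.log(ypy) + logdetV0 + logdetA

    res = minimize_scalar(
        criterion, bounds=(-18.0, 10.0), method="bounded",
        options={"xatol": 1e-8},
    )
    # sigma2_f = 0 boundary (OLS residual variance)
    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    ypy0 = float(np.sum((y - X @ beta0) ** 2))
    sign0, logdet0 = np.linalg.slogdet(XtX)
    c_bound = (n - p) * math.log(ypy0) + logdet0 if ypy0 > 0 else np.inf

    if res.fun < c_bound - 1e-10:
        gamma = math.exp(res.x)
        # recompute profiled sigma2_e at the optimum
        c = gamma / (1.0 + gamma * n_f)
        A = XtX - ZtX.T @ (c[:, None] * ZtX)
        rhs = Xty - ZtX.T @ (c * Zty)
        beta = np.linalg.solve(A, rhs)
        ypy = yty - float(Zty @ (c * Zty)) - float(rhs @ beta)
        s2e = ypy / (n - p)
        s2f = gamma * s2e
        crit = res.fun
        truncated = False
    else:
        s2e = ypy0 / (n - p)
        s2f = 0.0
        crit = c_bound
        truncated = True
    loglik = -0.5 * (crit + (n - p) * (1.0 + math.log(2.0 * math.pi) - math.log(n - p)))
    return VarianceComponents(
        trait=trait,
        sigma2_f=float(s2f),
        sigma2_e=float(s2e),
        n_families=F,
        n_per_family=float(n_f.mean()),
        loglik=float(loglik),
        truncated=truncated,
    )


def fit_pair_covariance(
    y_i, y_j, family, replication=None, trait_i: str = "i", trait_j: str = "j"
) -> PairCovariance:
    """Family and residual covariance between two traits on shared samples.

    Uses the sum-trait identity cov(i, j) = (var(i+j) - var(i) - var(j)) / 2
    applied to three univariate REML fits, exact when both traits share the
    design.
    """
    y_i = np.asarray(y_i, dtype=float).ravel()
    y_j = np.asarray(y_j, dtype=float).ravel()
    if y_i.size != y_j.size:
        raise InvalidParameterError("paired traits must share samples")
    vc_i = fit_univariate_reml(y_i, family, replication, trait_i)
    vc_j = fit_univariate_reml(y_j, family, replication, trait_j)
    vc_s = fit_univariate_reml(y_i + y_j, family, replication, "sum")
    return PairCovariance(
        trait_i=trait_i,
        trait_j=trait_j,
        cov_f=0.5 * (vc_s.sigma2_f - vc_i.sigma2_f - vc_j.sigma2_f),
        cov_e=0.5 * (vc_s.sigma2_e - vc_i.sigma2_e - vc_j.sigma2_e),
    )


def heritability(vc: VarianceComponents, k: float = 2.5) -> float:
    """Narrow-sense heritability ``k * sigma2_f / (sigma2_f + sigma2_e)``."""
    total = vc.sigma2_f + vc.sigma2_e
    if total <= 0:
        raise DegenerateDataError("zero total variance: heritability undefined")
    return k * vc.sigma2_f / total


def genetic_correlation(
    pc: PairCovariance, vc_i: VarianceComponents, vc_j: VarianceComponents
) -> float:
    """Family-level correlation cov_f / sqrt(sigma2_f_i * sigma2_f_j)."""
    if vc_i.sigma2_f <= 0 or vc_j.sigma2_f <= 0:
        raise DegenerateDataError(
            "zero family variance: genetic correlation undefined"
        )
    return pc.cov_f / math.sqrt(vc_i.sigma2_f * vc_j.sigma2_f)


def phenotypic_correlation(
    pc: PairCovariance, vc_i: VarianceComponents, vc_j: VarianceComponents
) -> float:
    """Total-phenotype correlation
    (cov_f + cov_e) / sqrt((sigma2_f_i + sigma2_e_i)(sigma2_f_j + sigma2_e_j))."""
    tot_i = vc_i.sigma2_f + vc_i.sigma2_e
    tot_j = vc_j.sigma2_f + vc_j.sigma2_e
    if tot_i <= 0 or tot_j <= 0:
        raise DegenerateDataError(
            "zero total variance: phenotypic correlation undefined"
        )
    return (pc.cov_f + pc.cov_e) / math.sqrt(tot_i * tot_j)


def _stat_from_table(table: pd.DataFrame, statistic, k: float):
    """Evaluate a named or callable statistic on a trait table."""
    if callable(statistic):
        return statistic(table)
    kind, *traits = statistic
    fam = table["family_id"]
    rep = table["replication_id"] if "replication_id" in table.columns else None
    if kind == "h2":
        vc = fit_univariate_reml(table[traits[0]], fam, rep, traits[0])
        return heritability(vc, k)
    vc_i = fit_univariate_reml(table[traits[0]], fam, rep, traits[0])
    vc_j = fit_univariate_reml(table[traits[1]], fam, rep, traits[1])
    pc = fit_pair_covariance(
        table[traits[0]], table[traits[1]], fam, rep, traits[0], traits[1]
    )
    if kind == "r_g":
        return genetic_correlation(pc, vc_i, vc_j)
    if kind == "r_p":
        return phenotypic_correlation(pc, vc_i, vc_j)
    raise InvalidParameterError(f"unknown statistic {statistic!r}")


def jackknife_se(table: pd.DataFrame, statistic, k: float = 2.5) -> float:
    """Delete-one-family jackknife SE of a genetic statistic.

    ``statistic`` is either a callable mapping a trait table to a float, or a
    tuple ``("h2", trait)`` / ``("r_g", ti, tj)`` / ``("r_p", ti, tj)``.
    Leave-one-out subsets on which the statistic is undefined are skipped
    with a warning.
    """
    fams = np.unique(table["family_id"])
    if fams.size < 3:
        raise InvalidParameterError("jackknife needs at least 3 families")
    values = []
    skipped = 0
    for f in fams:
        sub = table[table["family_id"] != f]
        try:
            values.append(_stat_from_table(sub, statistic, k))
        except (DegenerateDataError, InvalidParameterError):
            skipped += 1
    if skipped:
        warnings.warn(
            f"jackknife: statistic undefined on {skipped} leave-one-family "
            "subsets; SE based on the remainder", stacklevel=2,
        )
    values = np.asarray(values, dtype=float)
    g = values.size
    if g < 2:
        raise DegenerateDataError("too few jackknife subsets with a defined value")
    return float(np.sqrt((g - 1) / g * np.sum((values - values.mean()) ** 2)))


def breeding_values(y, family, vc: VarianceComponents) -> pd.DataFrame:
    """BLUP family breeding values for one trait.

    BV_f = shrink_f * (family mean - grand mean), with per-family shrinkage
    sigma2_f / (sigma2_f + sigma2_e / n_f). Returns a DataFrame with
    ``family_id`` and ``bv`` columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    family = np.asarray(family)
    fams, fam_idx = np.unique(family, return_inverse=True)
    n_f = np.bincount(fam_idx).astype(float)
    means = np.bincount(fam_idx, weights=y) / n_f
    grand = float(y.mean())
    if vc.sigma2_f <= 0:
        shrink = np.zeros_like(n_f)
    else:
        shrink = vc.sigma2_f / (vc.sigma2_f + vc.sigma2_e / n_f)
    return pd.DataFrame({"family_id": fams, "bv": shrink * (means - grand)})


def realized_gain(bv: pd.DataFrame, trait: str, top_fraction: float) -> float:
    """Realized genetic gain from selecting the top fraction of families.

    dG_R = mean BV of the top ``ceil(top_fraction * F)`` families ranked by
    ``bv_<trait>`` (or ``bv``) minus the mean BV of all families.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise InvalidParameterError(
            f"top_fraction must be in (0, 1], got {top_fraction}"
        )
    col = f"bv_{trait}" if f"bv_{trait}" in bv.columns else "bv"
    if col not in bv.columns:
        raise InvalidParameterError(f"no breeding-value column for trait '{trait}'")
    vals = np.sort(np.asarray(bv[col], dtype=float))[::-1]
    n_top = max(1, math.ceil(top_fraction * vals.size))
    return float(vals[:n_top].mean() - vals.mean())


def select_families(bv: pd.DataFrame, traits) -> list:
    """Families whose breeding value is above the mean BV for every listed
    trait (intersection of the per-trait above-mean rules)."""
    keep = np.ones(len(bv), dtype=bool)
    for trait in traits:
        col = f"bv_{trait}" if f"bv_{trait}" in bv.columns else trait
        if col not in bv.columns:
            raise InvalidParameterError(f"no breeding-value column for '{trait}'")
        vals = np.asarray(bv[col], dtype=float)
        keep &= vals > vals.mean()
    return sorted(bv.loc[keep, "family_id"].tolist())


def summarize_genetics(
    table: pd.DataFrame,
    traits=("anth", "flav", "nbi"),
    k: float = 2.5,
    gain_fractions=(0.1, 0.2, 0.3),
    jackknife: bool = True,
) -> GeneticSummary:
    """Full genetic analysis of a trait table.

    ``table`` needs ``family_id`` (and optionally ``replication_id``) plus
    one column per trait. Computes variance components, h2 with optional
    jackknife SEs, all pairwise genetic/phenotypic correlations, BLUP
    breeding values per family, and realized gains at the requested selected
    fractions.
    """
    fam = table["family_id"]
    rep = table["replication_id"] if "replication_id" in table.columns else None
    vcs = {t: fit_univariate_reml(table[t], fam, rep, t) for t in traits}
    h2 = {t: heritability(vcs[t], k) for t in traits}
    h2_se = {}
    rg, rp, rg_se, rp_se = {}, {}, {}, {}
    for a in range(len(traits)):
        for b in range(a + 1, len(traits)):
            ti, tj = traits[a], traits[b]
            pc = fit_pair_covariance(table[ti], table[tj], fam, rep, ti, tj)
            try:
                rg[(ti, tj)] = genetic_correlation(pc, vcs[ti], vcs[tj])
            except DegenerateDataError:
                rg[(ti, tj)] = float("nan")
            rp[(ti, tj)] = phenotypic_correlation(pc, vcs[ti], vcs[tj])
    if jackknife:
        for t in traits:
            h2_se[t] = jackknife_se(table, ("h2", t), k)
        for (ti, tj) in rg:
            rg_se[(ti, tj)] = jackknife_se(table, ("r_g", ti, tj), k)
            rp_se[(ti, tj)] = jackknife_se(table, ("r_p", ti, tj), k)

    bv = None
    for t in traits:
        part = breeding_values(table[t], fam, vcs[t]).rename(columns={"bv": f"bv_{t}"})
        bv = part if bv is None else bv.merge(part, on="family_id")
    for t in traits:
        bv[f"rank_{t}"] = (
            bv[f"bv_{t}"].rank(ascending=False, method="min").astype(int)
        )
    gains = {
        (t, float(frac)): realized_gain(bv, t, frac)
        for t in traits
        for frac in gain_fractions
    }
    return GeneticSummary(
        traits=list(traits),
        variance_components=vcs,
        heritability=h2,
        heritability_se=h2_se,
        genetic_correlation=rg,
        genetic_correlation_se=rg_se,
        phenotypic_correlation=rp,
        phenotypic_correlation_se=rp_se,
        heritability_coefficient=k,
        breeding_values=bv,
        realized_gain=gains,
    )
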