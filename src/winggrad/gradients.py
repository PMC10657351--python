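"""Regression-discontinuity inference on spanwise profiles, plus robustness
scans (clade splits, taxon rarefaction, posterior-tree iteration).

The headline question is whether a per-slice statistic (evolutionary rate
sigma2 or morphological disparity) steps discontinuously at the wrist joint
or follows a smooth spanwise gradient.  :class:`RegressionDiscontinuity`
fits the standard sharp-design two-segment linear model

    y = b0 + b1 (x - c) + delta D + b2 D (x - c),   D = 1[x >= c]

by OLS; ``delta`` is the intercept discontinuity at the cutoff ``c`` and its
two-sided t-test p-value is the reported effect p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import phylo as _phylo
from .modularity import disparity_profile

__all__ = [
    "RegressionDiscontinuity",
    "RDDResults",
    "rda",
    "clade_split",
    "rarefaction",
    "posterior_tree_scan",
    "RobustnessScan",
    "report_table",
]


@dataclass
class RDDResults:
    """Fitted regression-discontinuity model."""

    delta: float
    p_delta: float
    se_delta: float
    slope_below: float
    slope_above: float
    p_slope_change: float
    intercept: float
    cutoff: float
    n_below: int
    n_above: int

    def summary(self) -> str:
        return (
            "Regression discontinuity (sharp design, linear)\n"
            f"  cutoff                : {self.cutoff:g}\n"
            f"  n (below | above)     : {self.n_below} | {self.n_above}\n"
            f"  intercept at cutoff-  : {self.intercept:.6g}\n"
            f"  slope (below | above) : {self.slope_below:.6g} | {self.slope_above:.6g}\n"
            f"  delta (step at cutoff): {self.delta:.6g}  (SE {self.se_delta:.3g})\n"
            f"  p(delta)              : {self.p_delta:.4g}\n"
            f"  p(slope change)       : {self.p_slope_change:.4g}"
        )


class RegressionDiscontinuity:
    """Sharp-design RD model for a spanwise profile.

    Parameters
    ----------
    y : per-slice statistic values.
    x : slice positions (same length); default slice index 1..len(y).
    cutoff : position of the wrist; must lie strictly inside the x range
        with >= 3 points on each side.
    bandwidth : optional half-width restricting the fit to
        ``|x - cutoff| <= bandwidth`` (local-linear variant); default uses
        all points (global parametric fit).
    """

    def __init__(self, y, x=None, cutoff: float = 10.5, bandwidth: float | None = None):
        y = np.asarray(y, dtype=float)
        x = np.arange(1, y.size + 1, dtype=float) if x is None else np.asarray(x, float)
        if x.size != y.size:
            raise ValueError("x and y lengths differ")
        ok = np.isfinite(y) & np.isfinite(x)
        if bandwidth is not None:
            ok &= np.abs(x - cutoff) <= bandwidth
        x, y = x[ok], y[ok]
        above = x >= cutoff
        if above.sum() < 3 or (~above).sum() < 3:
            raise ValueError("need >= 3 points on each side of the cutoff")
        self.x, self.y, self.cutoff = x, y, cutoff
        self._above = above

    def fit(self) -> RDDResults:
        xc = self.x - self.cutoff
        D = self._above.astype(float)
        X = sm.add_constant(np.column_stack([xc, D, D * xc]))
        model = sm.OLS(self.y, X)
        res = model.fit()
        b0, b1, delta, b2 = res.params
        # perfect piecewise-linear fits leave ~0 residual variance; the
        # t-test p is then 0/0 — report p=0 for a nonzero step, 1 otherwise
        se = res.bse[2]
        if not np.isfinite(se) or se == 0:
            p_delta = 0.0 if abs(delta) > 1e-12 else 1.0
            p_b2 = 0.0 if abs(b2) > 1e-12 else 1.0
        else:
            p_delta = float(res.pvalues[2])
            p_b2 = float(res.pvalues[3])
        return RDDResults(delta=float(delta), p_delta=p_delta, se_delta=float(se),
                          slope_below=float(b1), slope_above=float(b1 + b2),
                          p_slope_change=p_b2, intercept=float(b0),
                          cutoff=self.cutoff, n_below=int((~self._above).sum()),
                          n_above=int(self._above.sum()))


def rda(y, x=None, cutoff: float = 10.5, bandwidth: float | None = None) -> RDDResults:
    """Functional wrapper over :class:`RegressionDiscontinuity`."""
    return RegressionDiscontinuity(y, x=x, cutoff=cutoff, bandwidth=bandwidth).fit()


def clade_split(values: pd.DataFrame, tree: _phylo.Phylogeny, clades: dict,
                model_policy: str = "best-aicc", disparity_metric: str = "variance"):
    """Per-clade sigma2 and disparity profiles.

    ``clades`` maps clade name -> list of species labels (a partition of the
    rows of ``values``).  Returns {clade: {"sigma2": df, "disparity": df}}.
    """
    all_species = set(values.index)
    seen: set = set()
    for name, labels in clades.items():
        labels = list(labels)
        if not labels:
            raise ValueError(f"clade {name!r} is empty")
        extra = set(labels) - all_species
        if extra:
            raise ValueError(f"clade {name!r} lists unknown species: {sorted(extra)}")
        if seen & set(labels):
            raise ValueError("clade labels overlap")
        seen |= set(labels)
        if len(labels) < 10:
            warnings.warn(f"clade {name!r} has only {len(labels)} species")
    out = {}
    for name, labels in clades.items():
        sub_vals = values.loc[list(labels)]
        sub_tree = tree.prune(list(labels))
        out[name] = {
            "sigma2": _phylo.sigma2_profile(sub_vals, sub_tree, model_policy=model_policy),
            "disparity": disparity_profile(sub_vals, metric=disparity_metric),
        }
    return out


@dataclass
class RobustnessScan:
    """Replicate profiles with per-slice median and MAD summaries."""

    profiles: pd.DataFrame       # columns: replicate, slice, value (+ descriptor)
    summary: pd.DataFrame        # columns: slice, median, mad
    kind: str

    @staticmethod
    def summarize(profiles: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
        def _agg(g):
            v = g[value_col].to_numpy(float)
            med = np.median(v)
            return pd.Series({"median": med, "mad": np.median(np.abs(v - med))})
        out = profiles.groupby("slice", sort=False).apply(_agg, include_groups=False)
        return out.reset_index()


def rarefaction(values: pd.DataFrame, tree: _phylo.Phylogeny, removals,
                n_reps: int = 10, seed: int | None = None,
                model_policy: str = "best-aicc", disparity_metric: str = "variance",
                statistic: str = "sigma2") -> RobustnessScan:
    """Taxon-rarefaction scan: remove k taxa at random (with replacement of
    the pool between draws), recompute the per-slice statistic, and
    summarize replicates by median and MAD per slice.

    ``removals`` lists taxon-removal counts; each must leave >= 3 species
    (the analysis floor used in practice is 6).
    """
    rng = np.random.default_rng(seed)
    n = len(values.index)
    rows = []
    for k in removals:
        if n - k < 3:
            raise ValueError(f"removing {k} of {n} taxa leaves fewer than 3 species")
        for rep in range(n_reps):
            if k == 0:
                keep = list(values.index)
            else:
                keep = list(rng.choice(values.index.to_numpy(), size=n - k,
                                       replace=False))
            sub_vals = values.loc[keep]
            if statistic == "sigma2":
                prof = _phylo.sigma2_profile(sub_vals, tree.prune(keep),
                                             model_policy=model_policy)
                prof = prof.rename(columns={"sigma2": "value"})[["slice", "value"]]
            else:
                prof = disparity_profile(sub_vals, metric=disparity_metric)
                prof = prof.rename(columns={"disparity": "value"})[["slice", "value"]]
            prof["replicate"] = rep
            prof["n_removed"] = k
            rows.append(prof)
    profiles = pd.concat(rows, ignore_index=True)
    return RobustnessScan(profiles=profiles,
                          summary=RobustnessScan.summarize(profiles),
                          kind=f"rarefaction:{statistic}")


def posterior_tree_scan(values: pd.DataFrame, trees, model_policy: str = "best-aicc") -> RobustnessScan:
    """Iterate the sigma2 profile across a sample of trees (e.g. posterior
    draws); summarize per slice by median and MAD.  Trees missing sampled
    taxa are skipped with a warning.  (Disparity needs no scan: it does not
    depend on the tree.)
    """
    rows = []
    kept = 0
    for i, tree in enumerate(trees):
        missing = set(values.index) - set(tree.tip_labels)
        if missing:
            warnings.warn(f"tree {i} missing taxa {sorted(missing)[:3]}...; skipped")
            continue
        prof = _phylo.sigma2_profile(values, tree, model_policy=model_policy)
        prof = prof.rename(columns={"sigma2": "value"})[["slice", "value"]]
        prof["replicate"] = i
        rows.append(prof)
        kept += 1
    if not rows:
        raise ValueError("no usable trees")
    profiles = pd.concat(rows, ignore_index=True)
    return RobustnessScan(profiles=profiles,
                          summary=RobustnessScan.summarize(profiles),
                          kind="posterior-trees")


def report_table(profiles: dict, tree: _phylo.Phylogeny, regions: dict,
                 cutoff: float = 10.5, model_policy: str = "best-aicc",
                 disparity_metric: str = "variance", cr_log10: bool = True,
                 n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Per-trait summary table: mean K/lambda by region, mean disparity and
    sigma2 by region, CR with p, and the RDA effect p for disparity and
    sigma2 profiles.

    Parameters
    ----------
    profiles : {trait_name: species × slice DataFrame} (wrist excluded,
        10 AW + 25 HW columns, base-to-tip order).
    regions : {column: "AW"|"HW"} for the profile columns.
    """
    from .modularity import cr_permutation_test

    rows = []
    for trait, vals in profiles.items():
        cols = list(vals.columns)
        reg = np.array([regions[c] for c in cols])
        hw, aw = reg == "HW", reg == "AW"
        sig = _phylo.sigma2_profile(vals, tree, model_policy=model_policy)
        disp = disparity_profile(vals, metric=disparity_metric)
        signal = _phylo.signal_profile(vals, tree)
        s2 = sig.set_index("slice").loc[cols, "sigma2"].to_numpy(float)
        dv = disp.set_index("slice").loc[cols, "disparity"].to_numpy(float)
        kv = signal.set_index("slice").loc[cols, "blomberg_k"].to_numpy(float)
        lv = signal.set_index("slice").loc[cols, "pagel_lambda"].to_numpy(float)
        x = np.arange(1, len(cols) + 1, dtype=float)
        rd_disp = rda(dv, x=x, cutoff=cutoff)
        rd_s2 = rda(s2, x=x, cutoff=cutoff)
        cr = cr_permutation_test(vals.to_numpy(float), hw, n_perm=n_perm,
                                 seed=seed, log10=cr_log10)
        rows.append({
            "trait": trait,
            "lambda_hw": float(np.nanmean(lv[hw])), "k_hw": float(np.nanmean(kv[hw])),
            "lambda_aw": float(np.nanmean(lv[aw])), "k_aw": float(np.nanmean(kv[aw])),
            "disparity_hw": float(np.nanmean(dv[hw])),
            "disparity_aw": float(np.nanmean(dv[aw])),
            "sigma2_hw": float(np.nanmean(s2[hw])), "sigma2_aw": float(np.nanmean(s2[aw])),
            "cr": cr.cr, "cr_p": cr.p_value,
            "disparity_rda_p": rd_disp.p_delta, "sigma2_rda_p": rd_s2.p_delta,
        })
    return pd.DataFrame(rows)
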