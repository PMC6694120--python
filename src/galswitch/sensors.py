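"""Sensor-dependency analysis across GAL4-GAL80 backgrounds.

Given replicate-level growth/expression records for each GAL4 x GAL80
allele pair across four genetic arms — the intact network, a GAL3
deletion, a GAL1::GALK sensor swap (heterologous galactokinase without
galactose-sensing activity), and the double sensorless arm — this module

* contrasts each arm against the intact reference (Welch t-tests with
  Benjamini-Hochberg FDR and a minimum-effect filter),
* fits a logistic "leakiness null" to the sensorless arm: with no sensor,
  growth in galactose is driven purely by how leaky the pathway already
  is in glucose,
* tests which backgrounds grow significantly above that null (one-sided),
* and calls a per-sensor verdict (essential / contributing / dispensable /
  deleterious) plus a harmonious-switch flag per pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "contrast_backgrounds",
    "LogisticGrowthNull",
    "fit_leakiness_null",
    "test_above_null",
    "call_dependencies",
    "DependencyConfig",
    "bh_adjust",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def contrast_backgrounds(records: pd.DataFrame, reference_arm: str = "intact",
                         alpha: float = 0.05, min_effect: float = 0.03,
                         value: str = "mu") -> pd.DataFrame:
    """Per-pair Welch t-tests of each arm against the reference arm.

    ``records`` is replicate-level with columns pair_id, arm, and the
    tested ``value`` (growth rate by default).  Within each non-reference
    arm (one BH family per contrast type), all pairs with >= 2 replicates
    in both arms are tested two-sided with unequal variances; significance
    requires q < alpha AND |mean effect| >= min_effect (effect filter
    applied after FDR control).  Single-replicate arms are excluded and
    reported with ``tested = False``.
    """
    rows = []
    for (pair, arm), grp in records.groupby(["pair_id", "arm"], sort=True):
        if arm == reference_arm:
            continue
        ref = records[(records["pair_id"] == pair)
                      & (records["arm"] == reference_arm)][value]
        x, y = grp[value].dropna(), ref.dropna()
        tested = len(x) >= 2 and len(y) >= 2
        effect = float(x.mean() - y.mean()) if len(x) and len(y) else np.nan
        if tested:
            if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
                p = 1.0 if x.mean() == y.mean() else 0.0
            else:
                p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append(dict(pair_id=pair, arm=arm, reference=reference_arm,
                         mean=float(x.mean()) if len(x) else np.nan,
                         mean_reference=float(y.mean()) if len(y) else np.nan,
                         effect=effect, n=len(x), n_reference=len(y),
                         p=p, tested=tested))
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=pd.Series(dtype=float),
                          significant=pd.Series(dtype=bool))
    out["q"] = np.nan
    for arm, idx in out.groupby("arm").groups.items():
        sub = out.loc[idx]
        mask = sub["tested"]
        if mask.any():
            out.loc[sub.index[mask], "q"] = bh_adjust(
                sub.loc[mask, "p"].to_numpy())
    out["significant"] = (out["tested"] & (out["q"] < alpha)
                          & (out["effect"].abs() >= min_effect))
    return out


# ---------------------------------------------------------------------------
# leakiness null
# ---------------------------------------------------------------------------

def _logistic(x, asym, xmid, scal):
    z = np.clip((xmid - x) / scal, -700, 700)  # avoid overflow in exp
    return asym / (1.0 + np.exp(z))


class LogisticGrowthNull(BaseEstimator, RegressorMixin):
    """Three-parameter logistic fit of growth vs glucose leakiness.

    Model: mu = Asym / (1 + exp((xmid - x)/scal)), x the pseudo-log mean
    glucose expression of the sensorless background.  Initialization is
    self-starting (scaled-logit linearization, as R's SSlogis): Asym from
    1.05 x max(y), xmid/scal from a logit-linear regression; on
    non-convergence a coarse grid of restarts is tried.  A fit whose
    residual sum of squares does not beat the constant-mean null is
    flagged (``converged_ = False``).
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def _self_start(self, x, y):
        asym0 = 1.05 * float(np.max(y))
        z = np.clip(y / asym0, 1e-6, 1 - 1e-6)
        logit = np.log(z / (1 - z))
        if np.ptp(x) == 0:
            return asym0, float(np.mean(x)), 1.0
        b, a = np.polyfit(x, logit, 1)
        if b <= 0:
            b = 1.0
        return asym0, -a / b, 1.0 / b

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 6:
            raise ValueError("need >= 6 points to fit the leakiness null")
        self.converged_ = False
        starts = [self._self_start(x, y)]
        for xm in np.quantile(x, [0.25, 0.5, 0.75]):
            for sc in (0.1, 0.3, 1.0):
                starts.append((1.05 * float(np.max(y)), float(xm), sc))
        best = None
        for p0 in starts:
            try:
                popt, _ = optimize.curve_fit(
                    _logistic, x, y, p0=p0, maxfev=self.maxfev,
                    bounds=([1e-9, -np.inf, 1e-6], [np.inf, np.inf, np.inf]))
            except (RuntimeError, ValueError):
                continue
            ss = float(np.sum((y - _logistic(x, *popt)) ** 2))
            if best is None or ss < best[0]:
                best = (ss, popt)
        if best is None:
            raise RuntimeError("logistic fit failed from every start")
        ss, popt = best
        self.asym_, self.xmid_, self.scal_ = map(float, popt)
        self.rss_ = ss
        self.null_ss_ = float(np.sum((y - y.mean()) ** 2))
        self.converged_ = ss < self.null_ss_
        return self

    def predict(self, x) -> np.ndarray:
        return _logistic(np.asarray(x, dtype=float), self.asym_, self.xmid_,
                         self.scal_)


def fit_leakiness_null(sensorless: pd.DataFrame, group: str = "galk_panel",
                       x: str = "leakiness", y: str = "mu"
                       ) -> dict[str, LogisticGrowthNull]:
    """Fit the logistic null per galactokinase-ortholog group.

    ``sensorless`` holds the double-sensorless arm's records (one or more
    rows per pair); per group, the fit uses per-pair means of leakiness
    and growth.  Groups whose fit cannot beat a constant mean are kept but
    flagged via ``converged_``.
    """
    fits = {}
    for g, grp in sensorless.groupby(group):
        per_pair = grp.groupby("pair_id")[[x, y]].mean()
        fits[g] = LogisticGrowthNull().fit(per_pair[x], per_pair[y])
    return fits


def test_above_null(records: pd.DataFrame,
                    nulls: dict[str, LogisticGrowthNull],
                    alpha: float = 0.05, group: str = "galk_panel",
                    leakiness: str = "leakiness", value: str = "mu"
                    ) -> pd.DataFrame:
    """One-sided tests of growth above the leakiness-null expectation.

    For each pair x arm, the replicate growth values are compared against
    the matching ortholog group's null prediction at the pair's glucose
    leakiness (one-sample t-test, alternative "greater"), BH-adjusted
    across all tested pair-arms.  Rows lacking a leakiness value or a
    fitted group are skipped.
    """
    rows = []
    for (pair, arm, g), grp in records.groupby(["pair_id", "arm", group]):
        if g not in nulls:
            continue
        leak = grp[leakiness].mean()
        if not np.isfinite(leak):
            continue
        expected = float(nulls[g].predict([leak])[0])
        vals = grp[value].dropna().to_numpy()
        if len(vals) < 2:
            continue
        if np.std(vals, ddof=1) == 0:
            p = 1.0 if vals.mean() <= expected else 0.0
        else:
            p = float(stats.ttest_1samp(vals, expected,
                                        alternative="greater").pvalue)
        rows.append(dict(pair_id=pair, arm=arm, galk_panel=g,
                         leakiness=float(leak), expected=expected,
                         mean=float(vals.mean()), n=len(vals), p=p))
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


# ---------------------------------------------------------------------------
# dependency calls
# ---------------------------------------------------------------------------

@dataclass
class DependencyConfig:
    alpha: float = 0.05
    min_effect: float = 0.03          # 1/h, matches the contrast filter
    background_mu: float = 0.02       # growth with no GAL regulation
    essential_margin: float = 0.02    # "non-growing" = below bg + margin
    growth_floor: float = 0.15        # "grows" means at least this
    harmonious_mu_fraction: float = 0.75  # of WT galactose growth
    repression_drop: float = 0.5      # pseudo-log glucose signal drop


SENSOR_ARM = {"GAL3": "dGAL3", "GAL1": "GALK"}


def _verdict(intact_mu: float, arm_mu: float, significant: bool,
             effect: float, glu_drop: float, class_flip: bool,
             cfg: DependencyConfig) -> str:
    dead = arm_mu < cfg.background_mu + cfg.essential_margin
    grows = intact_mu >= cfg.growth_floor
    if dead and grows:
        return "essential"
    if significant and effect < 0:
        return "contributing"
    if (significant and effect > 0) or (glu_drop >= cfg.repression_drop
                                        and class_flip):
        # removing the sensor helps growth, or restores glucose repression
        return "deleterious"
    return "dispensable"


def call_dependencies(records: pd.DataFrame, contrasts: pd.DataFrame,
                      classes: pd.DataFrame | None = None,
                      wt_mu: float | None = None,
                      config: DependencyConfig | None = None) -> pd.DataFrame:
    """Per-pair sensor verdicts and the harmonious-switch flag.

    ``records``: replicate-level with pair_id, arm, mu, mean_yfp_glu and a
    per-arm class column (``true_class`` or ``class_intermediate``).
    ``contrasts``: output of :func:`contrast_backgrounds`.  A sensor is
    essential where its removal arm stops growing while the intact arm
    grows; deleterious where removal significantly increases growth or
    restores glucose repression (large glucose-signal drop with a class
    flip to Inducible/Leaky); contributing where removal significantly
    reduces growth without abolishing it; dispensable otherwise.  Pairs
    missing any arm are "indeterminate".  The harmonious flag marks pairs
    whose intact double is Inducible or Leaky with galactose growth at
    least ``harmonious_mu_fraction`` of WT.
    """
    cfg = config or DependencyConfig()
    cls_col = ("class_intermediate" if classes is not None
               else "true_class" if "true_class" in records.columns
               else None)
    cls_lookup = None
    if classes is not None:
        cls_lookup = classes.set_index(["pair_id", "arm"])[
            "class_intermediate"]

    arm_means = records.groupby(["pair_id", "arm"]).agg(
        mu=("mu", "mean"), yfp_glu=("mean_yfp_glu", "mean")).reset_index()
    if wt_mu is None:
        if "pair_type" in records.columns:
            wt_rows = records[(records["pair_type"] == "wt_like")
                              & (records["arm"] == "intact")]
        else:
            wt_rows = records.iloc[0:0]
        wt_mu = (float(wt_rows["mu"].mean()) if len(wt_rows)
                 else float(arm_means[arm_means["arm"] == "intact"]
                            ["mu"].max()))

    csub = contrasts.set_index(["pair_id", "arm"]) if len(contrasts) else None
    rows = []
    for pair, grp in arm_means.groupby("pair_id"):
        arms = dict(zip(grp["arm"], grp.itertuples()))
        row = dict(pair_id=pair)
        if not {"intact", "dGAL3", "GALK"}.issubset(arms):
            row.update(gal3_verdict="indeterminate",
                       gal1_verdict="indeterminate", harmonious=False)
            rows.append(row)
            continue
        intact = arms["intact"]
        for sensor, arm_name in SENSOR_ARM.items():
            arm = arms[arm_name]
            sig, eff = False, float(arm.mu - intact.mu)
            if csub is not None and (pair, arm_name) in csub.index:
                c = csub.loc[(pair, arm_name)]
                sig, eff = bool(c["significant"]), float(c["effect"])
            glu_drop = float(intact.yfp_glu - arm.yfp_glu)
            flip = False
            if cls_lookup is not None and (pair, arm_name) in cls_lookup.index:
                flip = cls_lookup.loc[(pair, arm_name)] in ("Inducible",
                                                            "Leaky")
            elif cls_col and cls_col in records.columns:
                sub = records[(records["pair_id"] == pair)
                              & (records["arm"] == arm_name)]
                flip = (sub[cls_col].iloc[0] in ("Inducible", "Leaky")
                        if len(sub) else False)
            row[f"{sensor.lower()}_verdict"] = _verdict(
                float(intact.mu), float(arm.mu), sig, eff, glu_drop, flip,
                cfg)
        intact_cls = None
        singles_non_inducible = True
        sub = records[(records["pair_id"] == pair)
                      & (records["arm"] == "intact")]
        if cls_col and cls_col in records.columns and len(sub):
            intact_cls = sub[cls_col].iloc[0]
        if {"gal80_class", "gal4_class"}.issubset(records.columns) and len(sub):
            c80 = sub["gal80_class"].iloc[0]
            c4 = sub["gal4_class"].iloc[0]
            # harmonious = individually broken parts forming a working switch
            singles_non_inducible = (c80 != "Inducible" and c4 != "Inducible")
        row["intact_class"] = intact_cls
        row["harmonious"] = bool(
            singles_non_inducible
            and intact_cls in ("Inducible", "Leaky")
            and intact.mu >= cfg.harmonious_mu_fraction * wt_mu)
        row["intact_mu"] = float(intact.mu)
        rows.append(row)
    return pd.DataFrame(rows)
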