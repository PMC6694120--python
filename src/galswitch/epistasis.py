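"""Growth-rate prediction for double mutants from single-mutant data.

Two model families:

* the multiplicative null — the standard independence assumption of
  quantitative genetics, ``mu_MUT = mu_mut1 * mu_mut2 / mu_WT`` on
  background-subtracted growth rates, with propagated standard errors;
* expression-class-mean models — the prediction for a double mutant is the
  mean observed growth of all double mutants whose single mutants fall in
  the same expression-class combination, either locus-aware (each class is
  tagged with the gene carrying it) or locus-blinded (an unordered class
  pair).

Both are sklearn-style estimators; module-level functions mirror them for
one-off use.  ``design_accounting`` enumerates which class combinations a
pairwise design can realize, and ``downsample_cv`` measures how few
alleles per class suffice to train the class-mean model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .synthetic import ADMISSIBLE_CLASSES, BROAD_CLASSES, broaden_class

__all__ = [
    "multiplicative_expectation",
    "propagate_se",
    "MultiplicativeNullModel",
    "ClassMeanGrowthModel",
    "fit_class_model",
    "predict_and_score",
    "variance_explained",
    "downsample_cv",
    "design_accounting",
    "class_key",
]


# ---------------------------------------------------------------------------
# multiplicative null
# ---------------------------------------------------------------------------

def propagate_se(mu_mut: float, mu1: float, se1: float, mu2: float,
                 se2: float, mu_wt: float, se_wt: float, n_rep: int,
                 mode: str = "corrected") -> float:
    """Standard error of the multiplicative expectation.

    ``corrected`` (default) is first-order error propagation for a
    product/quotient: |mu_mut| * sqrt((se1/mu1)^2 + (se2/mu2)^2 +
    (se_wt/mu_wt)^2).  ``as_printed`` reproduces an alternative published
    reading verbatim — |mu_mut| * |(N-1)*(se_wt/mu_wt) + se1/mu1 +
    se2/mu1| — whose (N-1) weighting and repeated mu1 denominator do not
    follow from standard propagation; it is provided for comparability
    only.
    """
    denoms = {"mu1": mu1, "mu2": mu2, "mu_wt": mu_wt}
    if any(d == 0 for d in denoms.values()):
        return np.nan
    if mode == "corrected":
        return abs(mu_mut) * float(np.sqrt(
            (se1 / mu1) ** 2 + (se2 / mu2) ** 2 + (se_wt / mu_wt) ** 2))
    if mode == "as_printed":
        inner = (n_rep - 1) * (se_wt / mu_wt) + se1 / mu1 + se2 / mu1
        return abs(mu_mut) * float(np.sqrt(inner ** 2))
    raise ValueError(f"unknown se mode: {mode!r}")


def multiplicative_expectation(mu1: float, se1: float, mu2: float,
                               se2: float, mu_wt: float, se_wt: float,
                               background: float = 0.0, n_rep: int = 2,
                               se_mode: str = "corrected") -> dict:
    """Expected double-mutant growth under independent single effects.

    All rates are background-subtracted first (the background is the
    growth observed with no functional GAL regulation), combined as
    ``mu_MUT = mu_mut1 * mu_mut2 / mu_WT``, then the background is
    re-added for reporting.  Symmetric in the two mutants.
    """
    m1, m2, mw = mu1 - background, mu2 - background, mu_wt - background
    if mw == 0:
        return dict(mu_pred=np.nan, se=np.nan, flagged=True)
    mu_mut = m1 * m2 / mw
    se = propagate_se(mu_mut, m1, se1, m2, se2, mw, se_wt, n_rep, se_mode)
    return dict(mu_pred=mu_mut + background, se=se, flagged=False)


class MultiplicativeNullModel(BaseEstimator, RegressorMixin):
    """Multiplicative single-mutant null as an estimator.

    ``fit`` ingests single-mutant and WT replicate statistics; ``predict``
    takes a doubles table with ``allele1``/``allele2`` columns and returns
    expected growth per genotype.

    Parameters
    ----------
    background : growth rate with no GAL regulators, subtracted before the
        multiplicative combination (per hour).
    se_mode : "corrected" or "as_printed" (see :func:`propagate_se`).
    """

    def __init__(self, background: float = 0.0, se_mode: str = "corrected"):
        self.background = background
        self.se_mode = se_mode

    def fit(self, singles: pd.DataFrame, y=None):
        """``singles``: one row per single-mutant allele with columns
        allele, mu, se_mu, n_rep — plus one row with allele == "WT"."""
        req = {"allele", "mu", "se_mu"}
        if not req.issubset(singles.columns):
            raise ValueError(f"singles table needs columns {sorted(req)}")
        self.singles_ = singles.set_index("allele")
        if "WT" not in self.singles_.index:
            raise ValueError("singles table must include a WT row")
        wt = self.singles_.loc["WT"]
        self.mu_wt_, self.se_wt_ = float(wt["mu"]), float(wt["se_mu"])
        if self.mu_wt_ - self.background == 0:
            raise ValueError("WT growth equals the background rate; "
                             "multiplicative null undefined")
        return self

    def predict_df(self, doubles: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for _, d in doubles.iterrows():
            s1 = self.singles_.loc[d["allele1"]]
            s2 = self.singles_.loc[d["allele2"]]
            n = int(d.get("n_rep", s1.get("n_rep", 2)))
            res = multiplicative_expectation(
                float(s1["mu"]), float(s1["se_mu"]),
                float(s2["mu"]), float(s2["se_mu"]),
                self.mu_wt_, self.se_wt_, self.background, n, self.se_mode)
            rows.append(dict(genotype_id=d.get("genotype_id", ""),
                             mu_pred=res["mu_pred"], se=res["se"],
                             flagged=res["flagged"]))
        return pd.DataFrame(rows)

    def predict(self, doubles: pd.DataFrame) -> np.ndarray:
        return self.predict_df(doubles)["mu_pred"].to_numpy()


# ---------------------------------------------------------------------------
# class-mean models
# ---------------------------------------------------------------------------

def class_key(locus1: str, cls1: str, locus2: str, cls2: str,
              locus_aware: bool = True) -> tuple:
    """Canonical class-combination key for a double mutant.

    The locus-aware key is the per-locus class triple (GAL3, GAL80, GAL4)
    with the unmutated locus carrying Inducible — so a double whose GAL3
    single is phenotypically Inducible shares its key with the
    corresponding GAL80 x GAL4 combinations, exactly as the combinatorial
    accounting counts them.  Blinded keys are unordered class pairs,
    discarding gene identity.
    """
    if locus_aware:
        triple = {"GAL3": "Inducible", "GAL80": "Inducible",
                  "GAL4": "Inducible"}
        for locus, cls in ((locus1, cls1), (locus2, cls2)):
            if locus not in triple:
                raise ValueError(f"unknown locus: {locus!r}")
            triple[locus] = cls
        return (triple["GAL3"], triple["GAL80"], triple["GAL4"])
    return tuple(sorted([cls1, cls2]))


class ClassMeanGrowthModel(BaseEstimator, RegressorMixin):
    """Predict double-mutant growth by expression-class-combination means.

    ``fit`` groups observed double-mutant growth rates by the class
    combination of their single mutants and stores each group's mean as
    that combination's parameter; ``predict`` looks the parameter up.
    Combinations unseen in training fall back to the training grand mean
    and are flagged.

    Parameters
    ----------
    scheme : "intermediate5" (five classes) or "broad3" (three classes,
        Leaky/WeakExpression coarsened).
    locus_aware : key combinations by (gene, class) pairs (True) or by the
        unordered class pair alone (False).
    """

    def __init__(self, scheme: str = "intermediate5",
                 locus_aware: bool = True):
        self.scheme = scheme
        self.locus_aware = locus_aware

    def _classes(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.scheme not in ("intermediate5", "broad3"):
            raise ValueError(f"unknown scheme: {self.scheme!r}")
        out = df.copy()
        if self.scheme == "broad3":
            out["class1"] = out["class1"].map(broaden_class)
            out["class2"] = out["class2"].map(broaden_class)
        return out

    def _keys(self, df: pd.DataFrame) -> list[tuple]:
        df = self._classes(df)
        return [class_key(r["locus1"], r["class1"], r["locus2"], r["class2"],
                          self.locus_aware) for _, r in df.iterrows()]

    def fit(self, doubles: pd.DataFrame, y=None):
        """``doubles`` needs columns locus1, class1, locus2, class2, mu;
        rows with a missing class are excluded (and counted)."""
        req = {"locus1", "class1", "locus2", "class2", "mu"}
        if not req.issubset(doubles.columns):
            raise ValueError(f"doubles table needs columns {sorted(req)}")
        ok = doubles[["class1", "class2", "mu"]].notna().all(axis=1)
        self.n_excluded_ = int((~ok).sum())
        kept = doubles[ok]
        keys = self._keys(kept)
        df = pd.DataFrame({"key": keys, "mu": kept["mu"].to_numpy(float)})
        means = df.groupby("key", sort=True)["mu"].mean()
        self.parameters_ = dict(means.items())
        self.n_parameters_ = len(self.parameters_)
        self.grand_mean_ = float(kept["mu"].mean())
        return self

    def predict_df(self, doubles: pd.DataFrame) -> pd.DataFrame:
        keys = self._keys(doubles)
        pred = [self.parameters_.get(k, self.grand_mean_) for k in keys]
        covered = [k in self.parameters_ for k in keys]
        return pd.DataFrame({
            "genotype_id": doubles.get("genotype_id", ""),
            "key": [repr(k) for k in keys],
            "mu_pred": pred, "covered": covered})

    def predict(self, doubles: pd.DataFrame) -> np.ndarray:
        return self.predict_df(doubles)["mu_pred"].to_numpy()


def fit_class_model(doubles: pd.DataFrame, scheme: str = "intermediate5",
                    locus_aware: bool = True) -> ClassMeanGrowthModel:
    """Fit a :class:`ClassMeanGrowthModel` on a doubles table."""
    return ClassMeanGrowthModel(scheme=scheme, locus_aware=locus_aware).fit(
        doubles)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def variance_explained(observed, predicted) -> float:
    """1 - SSR/SST with SST about the grand mean of the observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    if obs.size == 0:
        raise ValueError("no finite observation/prediction pairs")
    sst = float(((obs - obs.mean()) ** 2).sum())
    ssr = float(((obs - pred) ** 2).sum())
    return 1.0 - ssr / sst if sst > 0 else 1.0


@dataclass
class VarianceReport:
    model: str
    variance_explained: float
    n_predicted: int
    per_locus_pair: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(model=self.model, locus_pair="all",
                     variance_explained=self.variance_explained,
                     n=self.n_predicted)]
        for pair, (ve, n) in self.per_locus_pair.items():
            rows.append(dict(model=self.model, locus_pair=pair,
                             variance_explained=ve, n=n))
        return pd.DataFrame(rows)


def predict_and_score(model, doubles: pd.DataFrame,
                      name: str | None = None) -> VarianceReport:
    """Score a fitted model on a doubles table (columns mu, locus1, locus2).

    Variance explained is reported overall and per locus pair, computed on
    the per-genotype (within-genotype mean) growth values in ``doubles``.
    """
    if len(doubles) == 0:
        raise ValueError("empty doubles table")
    pred = model.predict(doubles)
    obs = doubles["mu"].to_numpy(float)
    ve = variance_explained(obs, pred)
    per_pair = {}
    if {"locus1", "locus2"}.issubset(doubles.columns):
        pair_label = doubles.apply(
            lambda r: "-".join(sorted([r["locus1"], r["locus2"]])), axis=1)
        for pair, idx in doubles.groupby(pair_label).groups.items():
            sub = doubles.loc[idx]
            per_pair[pair] = (variance_explained(sub["mu"],
                                                 model.predict(sub)),
                              len(sub))
    return VarianceReport(model=name or type(model).__name__,
                          variance_explained=ve, n_predicted=len(doubles),
                          per_locus_pair=per_pair)


# ---------------------------------------------------------------------------
# downsampled cross-validation
# ---------------------------------------------------------------------------

def downsample_cv(doubles: pd.DataFrame, k_alleles_per_class: int = 1,
                  iterations: int = 1000, seed: int = 0,
                  scheme: str = "intermediate5",
                  locus_aware: bool = True) -> dict:
    """Class-mean model trained on k alleles per (locus, class) group.

    Per iteration, k alleles are sampled from every single-mutant class
    group; training doubles are those whose two alleles were both
    sampled, and the fitted model predicts the held-out remainder.
    Returns the distribution of held-out variance explained (median, IQR).
    With k covering every allele the training set is the full fit and the
    result is defined as the full-fit variance explained.
    """
    req = {"locus1", "allele1", "class1", "locus2", "allele2", "class2",
           "mu"}
    if not req.issubset(doubles.columns):
        raise ValueError(f"doubles table needs columns {sorted(req)}")
    use_cls = ((lambda c: c) if scheme == "intermediate5" else broaden_class)
    groups: dict[tuple, set] = {}
    for _, r in doubles.iterrows():
        for side in ("1", "2"):
            groups.setdefault(
                (r[f"locus{side}"], use_cls(r[f"class{side}"])),
                set()).add(r[f"allele{side}"])
    groups = {g: sorted(a) for g, a in groups.items()}
    for g, alleles in groups.items():
        if len(alleles) < k_alleles_per_class:
            raise ValueError(
                f"class group {g} has only {len(alleles)} alleles, "
                f"fewer than k={k_alleles_per_class}")

    if all(len(a) <= k_alleles_per_class for a in groups.values()):
        model = fit_class_model(doubles, scheme, locus_aware)
        ve = predict_and_score(model, doubles).variance_explained
        scores = np.full(iterations, ve)
    else:
        rng = np.random.default_rng(seed)
        scores = np.empty(iterations)
        for it in range(iterations):
            chosen: set = set()
            for g, alleles in groups.items():
                take = min(k_alleles_per_class, len(alleles))
                chosen.update(rng.choice(alleles, size=take, replace=False))
            in_train = (doubles["allele1"].isin(chosen)
                        & doubles["allele2"].isin(chosen))
            train, test = doubles[in_train], doubles[~in_train]
            if len(test) == 0:
                model = fit_class_model(doubles, scheme, locus_aware)
                scores[it] = predict_and_score(
                    model, doubles).variance_explained
                continue
            model = fit_class_model(train, scheme, locus_aware)
            scores[it] = predict_and_score(model, test).variance_explained
    q25, med, q75 = np.quantile(scores, [0.25, 0.5, 0.75])
    return {"scores": scores, "median": float(med),
            "iqr": (float(q25), float(q75)), "k": k_alleles_per_class,
            "iterations": iterations}


# ---------------------------------------------------------------------------
# design accounting
# ---------------------------------------------------------------------------

SCHEME_CLASS_SETS = {
    "intermediate5": {loc: tuple(ADMISSIBLE_CLASSES[loc])
                      for loc in ADMISSIBLE_CLASSES},
    "broad3": {"GAL3": ("Inducible", "Uninducible"),
               "GAL80": BROAD_CLASSES, "GAL4": BROAD_CLASSES},
}


def design_accounting(scheme: str = "intermediate5",
                      class_sets: dict | None = None) -> dict:
    """Combinatorial accounting of class combinations a pairwise design
    can realize.

    Enumerates all (GAL3, GAL80, GAL4) class triples; ``possible`` is
    their count, ``excluded`` those unreachable in a pairwise design —
    an Uninducible GAL3 class combined with non-Inducible classes at both
    other loci would require a triple mutant (the unmutated locus always
    carries Inducible) — and ``realizable = possible - excluded``.
    """
    sets = class_sets or SCHEME_CLASS_SETS[scheme]
    for locus, classes in sets.items():
        if not classes:
            raise ValueError(f"empty class set for {locus}")
    possible = excluded = 0
    for c3 in sets["GAL3"]:
        for c80 in sets["GAL80"]:
            for c4 in sets["GAL4"]:
                possible += 1
                if (c3 == "Uninducible" and c80 != "Inducible"
                        and c4 != "Inducible"):
                    excluded += 1
    return {"possible": possible, "excluded": excluded,
            "realizable": possible - excluded}


def blinded_parameter_count(scheme: str = "broad3") -> int:
    """Number of unordered class-pair parameters of the blinded model."""
    classes = (BROAD_CLASSES if scheme == "broad3"
               else tuple(dict.fromkeys(
                   c for cs in ADMISSIBLE_CLASSES.values() for c in cs)))
    n = len(classes)
    return n * (n + 1) // 2
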