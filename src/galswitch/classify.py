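"""Expression-distribution classification.

Each genotype is represented by its paired glucose/galactose expression
histograms (60 pseudo-log bins per condition, 120 dimensions), variance-
stabilized with ``V = log10(round(v, 3) + 0.001)`` and z-scaled per bin.
Profiles are clustered with HDBSCAN*; cluster labelings are scored by how
much total phenotypic variance they explain; clusters are mapped to named
classes by nearest archetype; per-genotype curation rules then fix the
boundary cases, and an anchored re-clustering rescues everything HDBSCAN*
called noise, so every genotype ends with a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN

from . import synthetic
from .cytometry import default_bin_edges

__all__ = [
    "FeatureMatrix",
    "build_features",
    "v_transform",
    "ExpressionProfileClusterer",
    "cluster_profiles",
    "evaluate_clusters",
    "class_archetypes",
    "curate_classes",
    "rescue_unclustered",
    "assign_classes",
    "PHENOTYPE_COLUMNS",
]

PHENOTYPE_COLUMNS = ("fracON_glu", "fracON_gal", "mean_yfp_glu",
                     "mean_yfp_gal", "mu")

INTERMEDIATE_CLASSES = synthetic.CLASSES
BROAD_MAP = {"Inducible": "Inducible", "Constitutive": "Constitutive",
             "Uninducible": "Uninducible", "Leaky": "Inducible"}


def v_transform(v):
    """Variance-stabilizing transform of bin densities.

    ``V = log10(round(v, 3) + 0.001)`` — densities are rounded to the
    nearest 1/1000 (round-half-to-even, numpy's rule) before the offset
    log, so v = 0 maps to -3 and anything below 0.0005 collapses there
    too.  Monotone (non-strictly) in v.
    """
    v = np.asarray(v, dtype=float)
    return np.log10(np.round(v, 3) + 0.001)


@dataclass
class FeatureMatrix:
    """Z-scaled V-transformed profile matrix plus its scaling stats.

    ``X`` has one row per genotype and 120 columns (60 glucose bins then
    60 galactose bins).  ``col_mean_``/``col_sd_`` are the pre-scaling
    column statistics, kept so external raw profiles (archetypes, anchors)
    can be projected into the same space with :meth:`transform_raw`.
    """

    X: pd.DataFrame
    col_mean_: np.ndarray
    col_sd_: np.ndarray

    @property
    def genotype_ids(self) -> pd.Index:
        return self.X.index

    def transform_raw(self, raw: pd.DataFrame | np.ndarray) -> np.ndarray:
        V = v_transform(np.asarray(raw, dtype=float))
        return (V - self.col_mean_) / self.col_sd_


def build_features(profiles: pd.DataFrame) -> FeatureMatrix:
    """Build the 120-dimensional feature matrix from mean profiles.

    ``profiles`` holds per-genotype replicate-mean raw bin densities
    (glucose 60 columns then galactose 60 columns).  Applies the V
    transform then a per-column z-score; constant columns are set to 0.
    """
    if profiles.shape[1] != 120:
        raise ValueError(
            f"expected 120 profile columns, got {profiles.shape[1]}")
    V = v_transform(profiles.to_numpy(float))
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=0)
    constant = sd <= 1e-12  # numerically constant columns
    sd_safe = np.where(constant, 1.0, sd)
    Z = (V - mean) / sd_safe
    Z[:, constant] = 0.0
    X = pd.DataFrame(Z, index=profiles.index, columns=profiles.columns)
    return FeatureMatrix(X=X, col_mean_=mean, col_sd_=sd_safe)


def _scale_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    scaled = {}
    for col in phenotypes.columns:
        x = phenotypes[col].to_numpy(float)
        sd = np.nanstd(x)
        scaled[col] = (x - np.nanmean(x)) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(scaled, index=phenotypes.index)


def evaluate_clusters(labels, phenotypes: pd.DataFrame) -> dict:
    """Phenotypic variance explained by a cluster labeling.

    Stacks the five per-genotype mean phenotypes (each z-scaled across
    genotypes) in long format and fits the saturated interaction model
    value ~ cluster * phenotype.  For a full categorical interaction model
    the least-squares fit is exactly the per-(cluster, phenotype) cell
    mean, so variance explained = 1 - SSR/SST with SSR the within-cell sum
    of squares and SST about the grand mean.  Noise labels (-1) enter as
    singleton clusters so the quantity is defined for any labeling.
    """
    labels = np.asarray(labels)
    if len(labels) != len(phenotypes):
        raise ValueError("labels and phenotypes must align")
    lab = labels.astype(object).copy()
    noise = labels == -1
    lab[noise] = [f"noise_{i}" for i in np.flatnonzero(noise)]

    scaled = _scale_phenotypes(phenotypes[list(PHENOTYPE_COLUMNS)])
    long = scaled.melt(ignore_index=False, var_name="phenotype_id",
                       value_name="value").reset_index(drop=True)
    long["cluster"] = np.tile(lab, len(PHENOTYPE_COLUMNS))
    long = long.dropna(subset=["value"])

    grand = long["value"].mean()
    sst = float(((long["value"] - grand) ** 2).sum())
    cell_mean = long.groupby(["cluster", "phenotype_id"], sort=False)[
        "value"].transform("mean")
    ssr = float(((long["value"] - cell_mean) ** 2).sum())
    ve = 1.0 - ssr / sst if sst > 0 else 1.0
    n_clusters = int(len(set(labels)) - (1 if noise.any() else 0))
    return {"variance_explained": ve, "n_clusters": n_clusters,
            "n_noise": int(noise.sum())}


class ExpressionProfileClusterer(BaseEstimator, ClusterMixin):
    """HDBSCAN* over a minPts grid, selected by phenotypic variance.

    Runs hierarchical density-based clustering once per candidate
    ``min_cluster_size`` (minPts), scores every labeling with
    :func:`evaluate_clusters`, and keeps the labeling that maximizes
    variance explained; labelings within ``tie_margin`` of the best are
    resolved toward fewer clusters (parsimony), then toward smaller
    minPts.

    Parameters
    ----------
    min_cluster_size_grid : candidate minPts values.
    tie_margin : absolute variance-explained slack treated as a tie
        (default 0.005, i.e. half a percentage point).

    Attributes (after ``fit``)
    --------------------------
    labels_ : chosen cluster labels, noise = -1.
    best_min_cluster_size_ : the selected minPts.
    evaluations_ : per-minPts DataFrame (n_clusters, variance_explained).
    """

    def __init__(self, min_cluster_size_grid=(5, 10, 15, 25),
                 tie_margin: float = 0.005):
        self.min_cluster_size_grid = min_cluster_size_grid
        self.tie_margin = tie_margin

    def fit(self, X, y=None, phenotypes: pd.DataFrame | None = None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 genotypes to cluster")
        if phenotypes is None:
            raise ValueError("phenotypes are required to score labelings")
        rows, labelings = [], {}
        for m in self.min_cluster_size_grid:
            m_eff = int(min(m, X.shape[0]))
            if m_eff < 2:
                m_eff = 2
            labels = HDBSCAN(min_cluster_size=m_eff, copy=True).fit_predict(X)
            if (labels == -1).all():
                # fully degenerate geometry (e.g. all rows identical)
                labels = np.zeros(len(labels), dtype=int)
            ev = evaluate_clusters(labels, phenotypes)
            rows.append({"minPts": m, **ev})
            labelings[m] = labels
        self.evaluations_ = pd.DataFrame(rows)
        if (self.evaluations_["n_clusters"] == 0).all():
            raise RuntimeError(
                "every minPts produced an all-noise labeling; "
                "profiles may be degenerate: "
                + self.evaluations_.to_string())
        best_ve = self.evaluations_["variance_explained"].max()
        cand = self.evaluations_[
            self.evaluations_["variance_explained"] >= best_ve
            - self.tie_margin]
        cand = cand.sort_values(
            ["n_clusters", "variance_explained", "minPts"],
            ascending=[True, False, True])
        chosen = cand.iloc[0]
        self.best_min_cluster_size_ = int(chosen["minPts"])
        self.labels_ = labelings[self.best_min_cluster_size_]
        self.variance_explained_ = float(chosen["variance_explained"])
        return self

    def fit_predict(self, X, y=None, phenotypes=None):
        return self.fit(X, phenotypes=phenotypes).labels_


def cluster_profiles(features: FeatureMatrix, phenotypes: pd.DataFrame,
                     min_cluster_size_grid=(5, 10, 15, 25)
                     ) -> ExpressionProfileClusterer:
    """Functional wrapper over :class:`ExpressionProfileClusterer`."""
    est = ExpressionProfileClusterer(
        min_cluster_size_grid=min_cluster_size_grid)
    return est.fit(features.X.to_numpy(), phenotypes=phenotypes)


def _expected_histogram(frac_on: float, on_mean: float, bin_edges: np.ndarray,
                        params: synthetic.SimulationParams) -> np.ndarray:
    """Expected normalized histogram of the OFF/ON pseudo-log mixture."""
    from scipy.stats import norm
    off = norm.cdf(bin_edges, params.off_mean, params.off_sd)
    on = norm.cdf(bin_edges, on_mean, params.on_sd)
    mass = (1 - frac_on) * np.diff(off) + frac_on * np.diff(on)
    width = bin_edges[1] - bin_edges[0]
    total = mass.sum()
    return mass / (total * width) if total > 0 else mass


def class_archetypes(bin_edges: np.ndarray | None = None,
                     params: synthetic.SimulationParams | None = None
                     ) -> pd.DataFrame:
    """Reference 120-bin raw profiles, one per expression class.

    Built from the class-conditional mixture at its central parameters —
    the same information a deletion experiment plus curated exemplars
    provides: an Inducible, Constitutive and Uninducible archetype (the
    three deletion-panel classes) plus Leaky and WeakExpression exemplars.
    """
    params = params or synthetic.SimulationParams()
    if bin_edges is None:
        bin_edges = default_bin_edges()
    rows = {}
    for cls in INTERMEDIATE_CLASSES:
        cp = params.class_params[cls]
        f_glu = float(np.mean(cp["fracON_glu"]))
        f_gal = float(np.mean(cp["fracON_gal"]))
        on_gal = cp["on_mean"][0]
        on_glu = cp.get("on_mean_glu", cp["on_mean"])[0]
        h_glu = _expected_histogram(f_glu, on_glu, bin_edges, params)
        h_gal = _expected_histogram(f_gal, on_gal, bin_edges, params)
        rows[cls] = np.concatenate([h_glu, h_gal])
    return pd.DataFrame(rows).T


def _correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 1.0
    return 1.0 - float(a @ b) / denom


@dataclass
class CurationConfig:
    induction_high: float = 3.0   # mean-signal gal/glu ratio: clearly induced
    induction_low: float = 1.5    # below this an "Inducible" call is not
    fracON_gal_min: float = 0.40  # rescue threshold for mislabeled Uninducible
    high_mode_cutoff: float = 1.0  # pseudo-log mode that counts as "high"
    leaky_glu_min: float = 0.05   # detectable ON fraction in glucose
    archetype_ceiling: float = 0.75  # max correlation distance to accept


def _induction_ratio(rec: pd.Series) -> float:
    # ratio of mean signals; means are kept on the pseudo-log scale, so the
    # ratio of raw-scale geometric means is 10**(difference)
    return float(10.0 ** (rec["mean_yfp_gal"] - rec["mean_yfp_glu"]))


def _gal_mode(profile_row: np.ndarray, bin_edges: np.ndarray) -> float:
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    gal = profile_row[len(centers):]
    return float(centers[int(np.argmax(gal))])


def _apply_overrides(cls: str, rec: pd.Series, gal_mode: float,
                     config: CurationConfig) -> tuple[str, bool]:
    """Summary-statistic overrides for boundary calls.

    Returns (possibly changed class, whether an override fired).  A
    "Constitutive" call that strongly induces becomes Leaky (detectable
    glucose ON fraction) or Inducible; an "Inducible"/"Leaky" call with no
    real induction becomes Constitutive (if broadly ON in glucose) or
    Uninducible; an "Uninducible" call with >40% galactose cells ON at a
    high mode becomes Inducible.
    """
    ratio = _induction_ratio(rec)
    f_glu = float(rec["fracON_glu"])
    f_gal = float(rec["fracON_gal"])
    if cls == "Constitutive" and ratio >= config.induction_high:
        return (("Leaky" if f_glu >= config.leaky_glu_min else "Inducible"),
                True)
    if cls in ("Inducible", "Leaky") and ratio <= config.induction_low:
        return (("Constitutive" if f_glu >= 0.40 else "Uninducible"), True)
    if (cls == "Uninducible" and f_gal > config.fracON_gal_min
            and gal_mode > config.high_mode_cutoff):
        return "Inducible", True
    return cls, False


def curate_classes(labels, features: FeatureMatrix, records: pd.DataFrame,
                   profiles: pd.DataFrame,
                   archetypes: pd.DataFrame | None = None,
                   config: CurationConfig | None = None,
                   bin_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Map clusters to named classes and apply per-genotype overrides.

    Each cluster centroid is matched to its nearest class archetype in
    feature space (correlation distance); clusters beyond the distance
    ceiling, and noise points, are left unassigned for rescue.  Overrides:
    a "Constitutive" genotype that actually induces strongly becomes Leaky
    (detectable glucose ON fraction) or Inducible; an "Inducible" genotype
    with no real induction becomes Uninducible; an "Uninducible" genotype
    with >40% of galactose cells ON at a high mode becomes Inducible.
    """
    config = config or CurationConfig()
    if bin_edges is None:
        bin_edges = default_bin_edges()
    if archetypes is None:
        archetypes = class_archetypes(bin_edges)
    arch_f = features.transform_raw(archetypes.to_numpy(float))
    arch_names = list(archetypes.index)

    labels = np.asarray(labels)
    Xa = features.X.to_numpy(float)
    cluster_class: dict[int, str | None] = {}
    for cl in sorted(set(labels) - {-1}):
        centroid = Xa[labels == cl].mean(axis=0)
        dists = [_correlation_distance(centroid, arch_f[j])
                 for j in range(len(arch_names))]
        j = int(np.argmin(dists))
        cluster_class[cl] = (arch_names[j]
                             if dists[j] <= config.archetype_ceiling else None)

    rows = []
    prof = profiles.to_numpy(float)
    for i, gid in enumerate(features.genotype_ids):
        cl = int(labels[i])
        cls = cluster_class.get(cl) if cl != -1 else None
        provenance = "primary_cluster"
        ratio = _induction_ratio(records.loc[gid])
        if cls is not None:
            cls, overridden = _apply_overrides(
                cls, records.loc[gid], _gal_mode(prof[i], bin_edges), config)
            if overridden:
                provenance = "curated"
        rows.append(dict(genotype_id=gid, cluster=cl,
                         class_intermediate=cls, induction_ratio=ratio,
                         provenance=provenance if cls is not None else None))
    return pd.DataFrame(rows).set_index("genotype_id", drop=False)


def rescue_unclustered(features: FeatureMatrix, assignment: pd.DataFrame,
                       archetypes: pd.DataFrame | None = None,
                       min_cluster_size: int = 3,
                       bin_edges: np.ndarray | None = None,
                       ceiling: float = 0.75) -> pd.DataFrame:
    """Give every unassigned genotype a class; never leaves residue.

    Stage 1 re-clusters the unassigned profiles together with the
    WeakExpression anchor; stage 2 repeats with the three archetypal
    deletion-panel profiles (Inducible, Constitutive, Uninducible); any
    cluster containing an anchor adopts the anchor's class, provided the
    member profile is within the correlation-distance ``ceiling`` of that
    anchor (small re-clustering runs would otherwise glue unrelated
    profiles to an anchor).  Whatever is still unassigned is given its
    nearest anchor class outright.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    if archetypes is None:
        archetypes = class_archetypes(bin_edges)
    arch_f = features.transform_raw(archetypes.to_numpy(float))
    arch_names = list(archetypes.index)
    out = assignment.copy()
    Xa = features.X.to_numpy(float)

    stages = [[n for n in ("WeakExpression", "Leaky") if n in arch_names],
              [n for n in ("Inducible", "Constitutive", "Uninducible")
               if n in arch_names]]
    for stage_names in stages:
        pending = out.index[out["class_intermediate"].isna()]
        if len(pending) == 0 or not stage_names:
            continue
        idx = [features.genotype_ids.get_loc(g) for g in pending]
        anchor_rows = np.stack([arch_f[arch_names.index(n)]
                                for n in stage_names])
        Xs = np.vstack([Xa[idx], anchor_rows])
        m = int(min(max(min_cluster_size, 2), Xs.shape[0]))
        try:
            labels = HDBSCAN(min_cluster_size=m, copy=True).fit_predict(Xs)
        except ValueError:
            continue
        anchor_labels = labels[len(idx):]
        label_class = {}
        for name, lab in zip(stage_names, anchor_labels):
            if lab != -1:
                label_class.setdefault(lab, name)
        for row_pos, g in enumerate(pending):
            lab = labels[row_pos]
            if lab in label_class:
                name = label_class[lab]
                anchor_vec = arch_f[arch_names.index(name)]
                if _correlation_distance(Xa[idx[row_pos]],
                                         anchor_vec) <= ceiling:
                    out.loc[g, "class_intermediate"] = name
                    out.loc[g, "provenance"] = "rescued"

    pending = out.index[out["class_intermediate"].isna()]
    for g in pending:
        x = Xa[features.genotype_ids.get_loc(g)]
        dists = [_correlation_distance(x, arch_f[j])
                 for j in range(len(arch_names))]
        out.loc[g, "class_intermediate"] = arch_names[int(np.argmin(dists))]
        out.loc[g, "provenance"] = "rescued"
    return out


def _broaden(assignment: pd.DataFrame, records: pd.DataFrame,
             config: CurationConfig) -> pd.Series:
    """Deterministic coarsening to the three-class scheme.

    Leaky -> Inducible; a WeakExpression genotype goes to whichever broad
    class its summary statistics support (induced, constitutively on, or
    neither).
    """
    broad = []
    for gid, rec in assignment.iterrows():
        cls = rec["class_intermediate"]
        if cls in BROAD_MAP:
            broad.append(BROAD_MAP[cls])
        else:  # WeakExpression
            if rec["induction_ratio"] >= config.induction_high:
                broad.append("Inducible")
            elif float(records.loc[gid, "fracON_glu"]) >= 0.40:
                broad.append("Constitutive")
            else:
                broad.append("Uninducible")
    return pd.Series(broad, index=assignment.index)


def assign_classes(profiles: pd.DataFrame, records: pd.DataFrame,
                   min_cluster_size_grid=(5, 10, 15, 25),
                   config: CurationConfig | None = None,
                   params: synthetic.SimulationParams | None = None,
                   bin_edges: np.ndarray | None = None
                   ) -> tuple[pd.DataFrame, ExpressionProfileClusterer]:
    """Full classification: features -> cluster -> curate -> rescue.

    ``profiles``: per-genotype 120-column raw mean bin densities.
    ``records``: per-genotype summaries with the five phenotype columns.
    Returns the total ClassAssignment table (every genotype classified)
    and the fitted clusterer (evaluations per minPts).
    """
    config = config or CurationConfig()
    if bin_edges is None:
        bin_edges = default_bin_edges()
    records = records.loc[profiles.index]
    features = build_features(profiles)
    phen = records[list(PHENOTYPE_COLUMNS)]
    est = cluster_profiles(features, phen, min_cluster_size_grid)
    archetypes = class_archetypes(bin_edges, params)
    assignment = curate_classes(est.labels_, features, records, profiles,
                                archetypes, config, bin_edges)
    assignment = rescue_unclustered(features, assignment, archetypes,
                                    bin_edges=bin_edges)
    assert not assignment["class_intermediate"].isna().any(), \
        "rescue must leave no genotype unclassified"
    # rescued genotypes went through distance matching only; give their
    # calls the same summary-statistic curation pass
    prof = profiles.to_numpy(float)
    rescued = assignment.index[assignment["provenance"] == "rescued"]
    for gid in rescued:
        i = profiles.index.get_loc(gid)
        cls, _ = _apply_overrides(
            assignment.loc[gid, "class_intermediate"], records.loc[gid],
            _gal_mode(prof[i], bin_edges), config)
        assignment.loc[gid, "class_intermediate"] = cls
    assignment["class_broad"] = _broaden(assignment, records, config)
    return assignment, est
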