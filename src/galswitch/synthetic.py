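"""Seeded synthetic data with the statistical structure of a combinatorial
GAL-regulatory mutant experiment.

The generator emulates the design of a pairwise combinatorially complete
library over the three regulatory loci of the yeast galactose switch:
GAL4 (activator), GAL80 (repressor) and GAL3 (sensor).  Each allele belongs
to an expression class; classes of allele pairs combine through a
deterministic rule cascade that encodes the known regulatory logic
(e.g. a dead activator is epistatic to everything; loss of the repressor
gives constitutive expression regardless of the sensor).  Per-genotype
"truth" — fraction of cells ON in glucose and in galactose, ON-component
location, growth rate — is drawn from class-conditional distributions, and
flow-cytometry event streams are synthesized from OFF/ON fluorescence
mixtures with event-rate-encoded cell density.

Randomness is keyed: every genotype/sample derives its own generator from
(master seed, CRC32 of its identifier), so adding genotypes or reordering
the design never perturbs other samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cytometry import EventTable, pseudolog_inverse

__all__ = [
    "LOCI",
    "CLASSES",
    "ADMISSIBLE_CLASSES",
    "AlleleSpec",
    "GenotypeDesign",
    "TruthTable",
    "SimulationParams",
    "generate_allele_library",
    "generate_design",
    "generate_deletion_design",
    "combine_classes",
    "build_truth_table",
    "simulate_events",
    "simulate_growth",
    "simulate_autofluorescence",
    "simulate_sensor_panel",
]

LOCI = ("GAL3", "GAL80", "GAL4")
CLASSES = ("Inducible", "Constitutive", "Uninducible", "Leaky",
           "WeakExpression")
BROAD_CLASSES = ("Inducible", "Constitutive", "Uninducible")

#: Expression classes each locus can produce as a single mutant.  GAL3
#: variants only modulate sensing, so they are Inducible or Uninducible;
#: GAL80 alleles add Constitutive (dead repressor) and Leaky (weak
#: repressor); GAL4 alleles add Constitutive (repressor-blind) and
#: WeakExpression (low-output activator).
ADMISSIBLE_CLASSES: dict[str, tuple[str, ...]] = {
    "GAL3": ("Inducible", "Uninducible"),
    "GAL80": ("Inducible", "Constitutive", "Uninducible", "Leaky"),
    "GAL4": ("Inducible", "Constitutive", "Uninducible", "WeakExpression"),
}

#: Allele counts per class per locus for the default library (46/39/43).
DEFAULT_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "GAL3": {"Inducible": 28, "Uninducible": 18},
    "GAL80": {"Inducible": 17, "Constitutive": 8, "Uninducible": 7,
              "Leaky": 7},
    "GAL4": {"Inducible": 22, "Constitutive": 8, "Uninducible": 10,
             "WeakExpression": 3},
}

#: Class-conditional truth distributions.  fracON ranges are uniform
#: supports; on_mean is (mean, sd) of the ON-component location on the
#: pseudo-log scale; on_mean_glu overrides the glucose-condition ON
#: location where the class expresses at reduced level in glucose.
CLASS_PARAMS: dict[str, dict] = {
    "Inducible": dict(fracON_glu=(0.0, 0.02), fracON_gal=(0.95, 1.0),
                      on_mean=(2.0, 0.08)),
    "Constitutive": dict(fracON_glu=(0.88, 1.0), fracON_gal=(0.88, 1.0),
                         on_mean=(2.0, 0.08)),
    "Uninducible": dict(fracON_glu=(0.0, 0.02), fracON_gal=(0.0, 0.04),
                        on_mean=(2.0, 0.08)),
    "Leaky": dict(fracON_glu=(0.06, 0.30), fracON_gal=(0.90, 1.0),
                  on_mean=(2.0, 0.08), on_mean_glu=(1.15, 0.05)),
    "WeakExpression": dict(fracON_glu=(0.0, 0.05), fracON_gal=(0.70, 0.92),
                           on_mean=(1.15, 0.05)),
}


@dataclass
class SimulationParams:
    """All tunable generator settings with study-design defaults."""

    # fluorescence mixture, pseudo-log scale
    off_mean: float = 0.05
    off_sd: float = 0.12
    on_sd: float = 0.15
    saturation_fraction: float = 0.02   # extra-bright ON subpopulation
    saturation_mean: float = 2.60       # above the pseudo-log ceiling
    saturation_sd: float = 0.08
    ceiling: float = 2 ** 18 - 1        # detector max, raw A.U.
    pe_scale: float = 0.5               # PE-A ~ pe_scale*(FITC+1000)*lognoise
    pe_noise_sd: float = 0.04
    # scatter cloud
    scatter_mean: float = 5e4
    scatter_sd: float = 8e3
    scatter_corr: float = 0.5
    scatter_outlier_fraction: float = 0.03
    # growth model: mu = b0 + b_gal*fracON_gal + b_glu*fracON_glu + noise
    beta0: float = 0.02
    beta_gal: float = 0.28
    beta_glu: float = -0.02
    mu_noise_sd: float = 0.008
    # densities and acquisition
    density_glu: float = 2000.0         # saturated glucose culture, cells/ul
    density_jitter_sd: float = 0.04     # per-culture lognormal jitter
    dilution: float = 150.0 / 9.0
    hours: float = 12.0
    rate_fast: float = 0.5              # ul/s for dense samples
    rate_slow: float = 2.0              # ul/s for sparse samples
    rate_threshold: float = 500.0       # cells/ul
    # design
    replicate_count: int = 2
    dropout_rate: float = 0.02
    n_events: int = 5000
    class_counts: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_CLASS_COUNTS.items()})
    class_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in CLASS_PARAMS.items()})

    @property
    def mu_background(self) -> float:
        """Growth with no functional GAL regulation (fracON ~ 0)."""
        return self.beta0


@dataclass
class AlleleSpec:
    locus: str
    allele_id: str
    true_class: str
    fracON_glu: float
    fracON_gal: float
    on_mean_log10: float
    on_sd_log10: float


@dataclass
class GenotypeDesign:
    genotype_id: str
    alleles: dict  # locus -> allele_id or "WT"
    n_mutant_loci: int
    replicate_count: int = 2
    dropout: bool = False


@dataclass
class TruthTable:
    """Ground truth per genotype plus the generating growth model."""

    table: pd.DataFrame  # indexed by genotype_id
    beta0: float
    beta_gal: float
    beta_glu: float
    mu_noise_sd: float
    mu_background: float

    def row(self, genotype_id: str) -> pd.Series:
        try:
            return self.table.loc[genotype_id]
        except KeyError as exc:
            raise KeyError(f"unknown genotype_id: {genotype_id!r}") from exc


def _rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Generator keyed by master seed plus stable string/int keys."""
    entropy = [int(seed)]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()))
        else:
            entropy.append(int(k))
    return np.random.default_rng(entropy)


def generate_allele_library(
        counts: Mapping[str, Mapping[str, int]] | None = None,
        seed: int = 0,
        params: SimulationParams | None = None) -> list[AlleleSpec]:
    """Draw a class-parameterized allele library.

    ``counts`` maps locus -> class -> number of alleles (defaults give the
    46/39/43 split).  Each allele's fracON values are drawn uniformly from
    its class support and its ON-component location from the class normal.
    Deterministic under ``seed``; classes inadmissible for a locus are
    rejected.
    """
    params = params or SimulationParams()
    counts = counts if counts is not None else params.class_counts
    library: list[AlleleSpec] = []
    for locus in LOCI:
        locus_counts = counts.get(locus, {})
        for cls, n in locus_counts.items():
            if n < 0:
                raise ValueError(f"negative allele count for {locus}/{cls}")
            if n > 0 and cls not in ADMISSIBLE_CLASSES[locus]:
                raise ValueError(
                    f"class {cls!r} is not admissible for locus {locus}; "
                    f"allowed: {ADMISSIBLE_CLASSES[locus]}")
        i = 0
        for cls in ADMISSIBLE_CLASSES[locus]:
            n = int(locus_counts.get(cls, 0))
            cp = params.class_params[cls]
            for _ in range(n):
                i += 1
                allele_id = f"{locus}.a{i:02d}"
                rng = _rng(seed, "allele", allele_id)
                lo, hi = cp["fracON_glu"]
                f_glu = float(rng.uniform(lo, hi))
                lo, hi = cp["fracON_gal"]
                f_gal = float(rng.uniform(lo, hi))
                m, s = cp["on_mean"]
                on_mean = float(rng.normal(m, s))
                library.append(AlleleSpec(
                    locus=locus, allele_id=allele_id, true_class=cls,
                    fracON_glu=f_glu, fracON_gal=f_gal,
                    on_mean_log10=on_mean,
                    on_sd_log10=params.on_sd))
    return library


def _genotype_id(alleles: Mapping[str, str]) -> str:
    parts = [alleles[locus] for locus in LOCI if alleles.get(locus, "WT") != "WT"]
    return "+".join(parts) if parts else "WT"


def generate_design(library: list[AlleleSpec],
                    dropout_rate: float = 0.0,
                    seed: int = 0,
                    replicate_count: int = 2) -> list[GenotypeDesign]:
    """Pairwise combinatorially complete design.

    Returns WT, every single mutant, and every cross-locus allele pair;
    a ``dropout_rate`` fraction of the pairs is marked dropped (never two
    alleles at the same locus).  Deterministic under ``seed``.
    """
    if not library:
        raise ValueError("allele library is empty")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    by_locus: dict[str, list[AlleleSpec]] = {locus: [] for locus in LOCI}
    for a in library:
        by_locus[a.locus].append(a)

    designs = [GenotypeDesign("WT", {l: "WT" for l in LOCI}, 0,
                              replicate_count)]
    for locus in LOCI:
        for a in by_locus[locus]:
            alleles = {l: "WT" for l in LOCI}
            alleles[locus] = a.allele_id
            designs.append(GenotypeDesign(_genotype_id(alleles), alleles, 1,
                                          replicate_count))
    for i, l1 in enumerate(LOCI):
        for l2 in LOCI[i + 1:]:
            for a1 in by_locus[l1]:
                for a2 in by_locus[l2]:
                    alleles = {l: "WT" for l in LOCI}
                    alleles[l1] = a1.allele_id
                    alleles[l2] = a2.allele_id
                    gid = _genotype_id(alleles)
                    dropped = bool(
                        dropout_rate > 0
                        and _rng(seed, "dropout", gid).random() < dropout_rate)
                    designs.append(GenotypeDesign(gid, alleles, 2,
                                                  replicate_count, dropped))
    return designs


def generate_deletion_design(replicate_count: int = 2) -> list[GenotypeDesign]:
    """The 2^3 = 8 full-factorial deletion design (WT or null per locus)."""
    designs = []
    for m3 in (False, True):
        for m80 in (False, True):
            for m4 in (False, True):
                alleles = {"GAL3": "GAL3.del" if m3 else "WT",
                           "GAL80": "GAL80.del" if m80 else "WT",
                           "GAL4": "GAL4.del" if m4 else "WT"}
                designs.append(GenotypeDesign(
                    _genotype_id(alleles), alleles, m3 + m80 + m4,
                    replicate_count))
    return designs


def deletion_library(params: SimulationParams | None = None) -> list[AlleleSpec]:
    """One null allele per locus, classed by its single-mutant phenotype."""
    params = params or SimulationParams()
    specs = []
    for locus, cls in (("GAL3", "Uninducible"), ("GAL80", "Constitutive"),
                       ("GAL4", "Uninducible")):
        cp = params.class_params[cls]
        specs.append(AlleleSpec(
            locus=locus, allele_id=f"{locus}.del", true_class=cls,
            fracON_glu=float(np.mean(cp["fracON_glu"])),
            fracON_gal=float(np.mean(cp["fracON_gal"])),
            on_mean_log10=cp["on_mean"][0], on_sd_log10=params.on_sd))
    return specs


def combine_classes(c3: str, c80: str, c4: str) -> str:
    """Expression class of a genotype from its per-locus allele classes.

    The unmutated (WT) state of a locus carries the Inducible class.  The
    cascade encodes the regulatory logic of the switch: a dead activator
    masks everything; a dead repressor gives constitutive output; a
    constitutively active GAL4 escapes repression; a super-repressor GAL80
    silences any remaining activator; a weak repressor leaks; without a
    functional sensor a WT-like switch cannot induce.  A weak-output GAL4
    caps any expressing outcome at the WeakExpression class.
    """
    if c4 == "Uninducible":
        return "Uninducible"
    if c80 == "Constitutive":
        base = "Constitutive"
    elif c4 == "Constitutive":
        base = "Constitutive"
    elif c80 == "Uninducible":
        return "Uninducible"
    elif c80 == "Leaky":
        base = "Leaky"
    elif c3 == "Uninducible":
        return "Uninducible"
    else:
        base = "Inducible"
    if c4 == "WeakExpression":
        return "WeakExpression"
    return base


def broaden_class(cls: str) -> str:
    """Coarsen an intermediate class to the three-class scheme.

    Leaky profiles are near-Inducible; the WeakExpression truth class
    (induces to a low ON level) also coarsens to Inducible.
    """
    return {"Leaky": "Inducible", "WeakExpression": "Inducible"}.get(cls, cls)


def build_truth_table(library: list[AlleleSpec],
                      designs: list[GenotypeDesign],
                      seed: int = 0,
                      params: SimulationParams | None = None) -> TruthTable:
    """Ground-truth phenotypes for every non-dropout design.

    Single mutants inherit their allele's drawn fracON/ON-location values;
    multi-mutant genotypes get the class from :func:`combine_classes` and
    class-conditional draws keyed by their genotype_id.  Growth is the
    linear model ``mu = b0 + b_gal*fracON_gal + b_glu*fracON_glu + noise``
    clipped at zero.
    """
    params = params or SimulationParams()
    by_id = {a.allele_id: a for a in library}
    rows = []
    for d in designs:
        if d.dropout:
            continue
        cls_per_locus = {}
        for locus in LOCI:
            aid = d.alleles[locus]
            cls_per_locus[locus] = ("Inducible" if aid == "WT"
                                    else by_id[aid].true_class)
        cls = combine_classes(cls_per_locus["GAL3"], cls_per_locus["GAL80"],
                              cls_per_locus["GAL4"])
        cp = params.class_params[cls]
        rng = _rng(seed, "truth", d.genotype_id)
        if d.n_mutant_loci == 1:
            allele = by_id[[a for a in d.alleles.values() if a != "WT"][0]]
            f_glu, f_gal = allele.fracON_glu, allele.fracON_gal
            on_gal = allele.on_mean_log10
        else:
            f_glu = float(rng.uniform(*cp["fracON_glu"]))
            f_gal = float(rng.uniform(*cp["fracON_gal"]))
            on_gal = float(rng.normal(*cp["on_mean"]))
        if "on_mean_glu" in cp:
            on_glu = float(rng.normal(*cp["on_mean_glu"]))
        else:
            on_glu = on_gal
        mu = (params.beta0 + params.beta_gal * f_gal
              + params.beta_glu * f_glu
              + float(rng.normal(0.0, params.mu_noise_sd)))
        mu = max(mu, 0.0)
        rows.append(dict(
            genotype_id=d.genotype_id,
            gal3_allele=d.alleles["GAL3"], gal80_allele=d.alleles["GAL80"],
            gal4_allele=d.alleles["GAL4"],
            gal3_class=cls_per_locus["GAL3"],
            gal80_class=cls_per_locus["GAL80"],
            gal4_class=cls_per_locus["GAL4"],
            n_mutant_loci=d.n_mutant_loci, replicate_count=d.replicate_count,
            true_class=cls, true_class_broad=broaden_class(cls),
            fracON_glu=f_glu, fracON_gal=f_gal,
            on_mean_glu=on_glu, on_mean_gal=on_gal,
            mu_true=mu, density_glu=params.density_glu))
    table = pd.DataFrame(rows).set_index("genotype_id", drop=False)
    return TruthTable(table=table, beta0=params.beta0,
                      beta_gal=params.beta_gal, beta_glu=params.beta_glu,
                      mu_noise_sd=params.mu_noise_sd,
                      mu_background=params.mu_background)


def simulate_growth(truth: TruthTable, genotype_id: str,
                    params: SimulationParams | None = None
                    ) -> tuple[float, float]:
    """Noise-free density pair (glucose culture, 12 h galactose culture).

    The galactose culture starts at the post-dilution inoculum density
    (glucose density / dilution, dilution = 150/9) and grows exponentially
    at mu_true for ``hours``.
    """
    params = params or SimulationParams()
    row = truth.row(genotype_id)
    d_glu = float(row["density_glu"])
    if d_glu <= 0:
        raise ValueError("nonpositive inoculum density")
    mu = float(row["mu_true"])
    if not np.isfinite(mu):
        raise ValueError("mu_true must be finite")
    d_gal = (d_glu / params.dilution) * float(np.exp(mu * params.hours))
    return d_glu, d_gal


def replicate_densities(truth: TruthTable, genotype_id: str, replicate: int,
                        seed: int, params: SimulationParams | None = None
                        ) -> tuple[float, float]:
    """Per-replicate realized densities with culture-level lognormal jitter.

    The galactose culture inherits its replicate's glucose-culture density
    (it was inoculated from it), then gets its own jitter.
    """
    params = params or SimulationParams()
    d_glu, _ = simulate_growth(truth, genotype_id, params)
    mu = float(truth.row(genotype_id)["mu_true"])
    j_glu = _rng(seed, "culture", genotype_id, replicate, "glu").normal(
        0.0, params.density_jitter_sd)
    j_gal = _rng(seed, "culture", genotype_id, replicate, "gal").normal(
        0.0, params.density_jitter_sd)
    d_glu_rep = d_glu * float(np.exp(j_glu))
    d_gal_rep = (d_glu_rep / params.dilution
                 * float(np.exp(mu * params.hours + j_gal)))
    return d_glu_rep, d_gal_rep


def _mixture_pseudolog(rng: np.random.Generator, n: int, frac_on: float,
                       on_mean: float, params: SimulationParams) -> np.ndarray:
    n_on = int(rng.binomial(n, min(max(frac_on, 0.0), 1.0)))
    p_off = rng.normal(params.off_mean, params.off_sd, n - n_on)
    p_on = rng.normal(on_mean, params.on_sd, n_on)
    if n_on and params.saturation_fraction > 0:
        bright = rng.random(n_on) < params.saturation_fraction
        p_on[bright] = rng.normal(params.saturation_mean,
                                  params.saturation_sd, int(bright.sum()))
    p = np.concatenate([p_off, p_on])
    return rng.permutation(p)


def simulate_events(genotype_id: str, condition: str, truth: TruthTable,
                    n_events: int = 5000, seed: int = 0, replicate: int = 0,
                    params: SimulationParams | None = None) -> EventTable:
    """Synthesize one sample's event stream.

    FITC-A is a two-component mixture (autofluorescent OFF cells plus the
    genotype's ON component at its condition-specific fraction and
    location); a configurable bright subfraction of ON events exceeds the
    detector ceiling and is clipped, with PE-A carrying the uncensored
    correlated signal.  Event timestamps are a Poisson stream whose rate
    encodes the replicate's true cell density at the sample's aspiration
    rate.
    """
    if condition not in ("glucose", "galactose"):
        raise ValueError("condition must be 'glucose' or 'galactose'")
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    params = params or SimulationParams()
    row = truth.row(genotype_id)
    rng = _rng(seed, "events", genotype_id, replicate, condition)

    if condition == "glucose":
        frac_on = float(row["fracON_glu"])
        on_mean = float(row["on_mean_glu"])
    else:
        frac_on = float(row["fracON_gal"])
        on_mean = float(row["on_mean_gal"])

    p = _mixture_pseudolog(rng, n_events, frac_on, on_mean, params)
    raw_true = pseudolog_inverse(p)
    pe = params.pe_scale * (raw_true + 1000.0) * np.exp(
        rng.normal(0.0, params.pe_noise_sd, n_events))
    fitc = np.minimum(raw_true, params.ceiling)

    z1 = rng.standard_normal(n_events)
    z2 = rng.standard_normal(n_events)
    rho = params.scatter_corr
    fsc = params.scatter_mean + params.scatter_sd * z1
    ssc = params.scatter_mean + params.scatter_sd * (
        rho * z1 + np.sqrt(1 - rho ** 2) * z2)
    out = rng.random(n_events) < params.scatter_outlier_fraction
    n_out = int(out.sum())
    if n_out:
        fsc[out] = rng.uniform(0, 4 * params.scatter_mean, n_out)
        ssc[out] = rng.uniform(0, 4 * params.scatter_mean, n_out)

    d_glu, d_gal = replicate_densities(truth, genotype_id, replicate, seed,
                                       params)
    density = d_glu if condition == "glucose" else d_gal
    rate = (params.rate_fast if density >= params.rate_threshold
            else params.rate_slow)
    events_per_ms = density * rate / 1000.0
    gaps = rng.exponential(1.0 / events_per_ms, n_events)
    time_ms = np.cumsum(gaps)

    df = pd.DataFrame({"FSC-A": fsc, "SSC-A": ssc, "FITC-A": fitc,
                       "PE-A": pe, "time_ms": time_ms})
    sid = f"{genotype_id}|{condition}|r{replicate}"
    return EventTable(data=df, sample_id=sid, sampling_rate=rate)


def simulate_autofluorescence(n_events: int = 5000, seed: int = 0,
                              replicate: int = 0,
                              params: SimulationParams | None = None
                              ) -> np.ndarray:
    """Pseudo-log FITC-A draws from an autofluorescent (all-OFF) control."""
    params = params or SimulationParams()
    rng = _rng(seed, "autofluor", replicate)
    return rng.normal(params.off_mean, params.off_sd, n_events)


# ---------------------------------------------------------------------------
# sensor-dependency panel
# ---------------------------------------------------------------------------

SENSOR_ARMS = ("intact", "dGAL3", "GALK", "dGAL3+GALK")
GALK_ORTHOLOGS = ("ecoli", "calbicans")

#: Logistic growth-vs-leakiness parameters of the sensorless null per
#: heterologous galactokinase (Asym 1/h, xmid pseudo-log A.U., scal).
SENSORLESS_LOGISTIC = {"ecoli": (0.26, 0.90, 0.25),
                       "calbicans": (0.30, 0.90, 0.25)}

#: Pair archetypes: (GAL80 class, GAL4 class, leakiness range) with the
#: sensing dependencies resolved by :func:`_sensor_arm_truth`.
SENSOR_PAIR_TYPES = {
    "wt_like": ("Inducible", "Inducible", (0.03, 0.15)),
    "leaky80": ("Leaky", "Inducible", (0.45, 1.20)),
    "mid_leak": ("Leaky", "Inducible", (0.60, 1.40)),
    "gal4c": ("Inducible", "Constitutive", (0.90, 1.60)),
    "constitutive80": ("Constitutive", "Inducible", (1.80, 2.20)),
    "gal80s": ("Uninducible", "Inducible", (0.02, 0.10)),
    "gal80s_gal4c": ("Uninducible", "Constitutive", (0.08, 0.30)),
}

DEFAULT_SENSOR_COMPOSITION = {
    "wt_like": 6, "leaky80": 4, "mid_leak": 6, "gal4c": 3,
    "constitutive80": 2, "gal80s": 1, "gal80s_gal4c": 2,
}


def _logistic(x: float, asym: float, xmid: float, scal: float) -> float:
    return asym / (1.0 + np.exp((xmid - x) / scal))


def _sensor_arm_truth(pair_type: str, leak: float, mu_on: float,
                      gal3: bool, gal1_sensing: bool, galk: str,
                      params: SimulationParams) -> dict:
    """True class, growth and glucose expression for one pair x arm.

    Encodes the four canonical rewiring patterns: a WT-like switch needs
    GAL3 and ignores GAL1 sensing; a leaky-GAL80 switch induces through
    either sensor; GAL4C is constitutive through GAL1 positive feedback and
    reverts to Leaky when GAL1 sensing is removed; the GAL80S+GAL4C
    harmonious switch depends on GAL1 instead of GAL3.
    """
    c80, c4, _ = SENSOR_PAIR_TYPES[pair_type]
    asym, xmid, scal = SENSORLESS_LOGISTIC.get(galk,
                                               SENSORLESS_LOGISTIC["ecoli"])
    mu_leak = _logistic(leak, asym, xmid, scal)

    if c80 == "Constitutive":
        # no repressor: constitutively expressed regardless of sensors;
        # with no sensor at all, growth is pure leakiness-driven (the pair
        # sits at the saturated end of the logistic)
        mu = mu_on if (gal3 or gal1_sensing) else mu_leak
        return dict(cls="Constitutive", mu=mu, yfp_glu=leak)
    if c4 == "Constitutive" and c80 == "Uninducible":
        # harmonious GAL80S + GAL4C: induction rides on GAL1 sensing
        if gal1_sensing:
            return dict(cls="Inducible", mu=mu_on, yfp_glu=leak)
        return dict(cls="Uninducible", mu=mu_leak, yfp_glu=leak)
    if c4 == "Constitutive":
        if gal1_sensing:
            # GAL1 positive feedback locks the pathway on in glucose
            return dict(cls="Constitutive", mu=mu_on, yfp_glu=2.0)
        if gal3:
            # removing GAL1 sensing restores repression; GAL3 still induces
            return dict(cls="Leaky", mu=mu_on, yfp_glu=leak)
        return dict(cls="Uninducible", mu=mu_leak, yfp_glu=leak)
    if c80 == "Uninducible":
        return dict(cls="Uninducible", mu=mu_leak, yfp_glu=leak)
    if c80 == "Leaky":
        if gal3 or gal1_sensing:
            return dict(cls="Leaky", mu=mu_on, yfp_glu=leak)
        return dict(cls="Leaky", mu=mu_leak, yfp_glu=leak)
    # WT-like pair: induction strictly GAL3-dependent
    if gal3:
        return dict(cls="Inducible", mu=mu_on, yfp_glu=leak)
    return dict(cls="Uninducible", mu=mu_leak, yfp_glu=leak)


def simulate_sensor_panel(seed: int = 0,
                          composition: Mapping[str, int] | None = None,
                          n_replicates: int = 8,
                          mu_rep_sd: float = 0.010,
                          yfp_rep_sd: float = 0.05,
                          params: SimulationParams | None = None
                          ) -> pd.DataFrame:
    """Replicate-level records for the sensor-dependency experiment.

    For each GAL80 x GAL4 allele pair, measures growth and glucose
    expression across four arms (intact, delta-GAL3, GAL1::GALK, and the
    double sensorless arm) for each heterologous galactokinase.  The
    sensorless arms place growth on a logistic function of glucose
    leakiness, the null that :mod:`galswitch.sensors` re-estimates.
    """
    params = params or SimulationParams()
    composition = dict(composition or DEFAULT_SENSOR_COMPOSITION)
    rows = []
    pair_idx = 0
    for ptype, n_pairs in composition.items():
        if ptype not in SENSOR_PAIR_TYPES:
            raise ValueError(f"unknown sensor pair type: {ptype!r}")
        for k in range(int(n_pairs)):
            pair_idx += 1
            pair_id = f"pair{pair_idx:02d}.{ptype}"
            prng = _rng(seed, "sensorpair", pair_id)
            lo, hi = SENSOR_PAIR_TYPES[ptype][2]
            leak = float(prng.uniform(lo, hi))
            mu_on = float(prng.uniform(0.27, 0.32))
            for galk in GALK_ORTHOLOGS:
                for arm in SENSOR_ARMS:
                    gal3 = arm in ("intact", "GALK")
                    gal1 = arm in ("intact", "dGAL3")
                    source = "native" if gal1 else galk
                    truth = _sensor_arm_truth(ptype, leak, mu_on, gal3,
                                              gal1, galk, params)
                    arng = _rng(seed, "sensorarm", pair_id, galk, arm)
                    c80_cls, c4_cls, _ = SENSOR_PAIR_TYPES[ptype]
                    for rep in range(n_replicates):
                        rows.append(dict(
                            pair_id=pair_id, pair_type=ptype,
                            gal80_class=c80_cls, gal4_class=c4_cls,
                            galk_panel=galk, galk_source=source,
                            gal3_status="intact" if gal3 else "delta",
                            arm=arm, replicate=rep,
                            mu=truth["mu"] + float(arng.normal(0, mu_rep_sd)),
                            mean_yfp_glu=truth["yfp_glu"]
                            + float(arng.normal(0, yfp_rep_sd)),
                            true_class=truth["cls"],
                            mu_true=truth["mu"], leakiness=leak))
    return pd.DataFrame(rows)


def library_to_frame(library: Iterable[AlleleSpec]) -> pd.DataFrame:
    return pd.DataFrame([asdict(a) for a in library])


def design_to_frame(designs: Iterable[GenotypeDesign]) -> pd.DataFrame:
    rows = []
    for d in designs:
        row = dict(genotype_id=d.genotype_id, n_mutant_loci=d.n_mutant_loci,
                   replicate_count=d.replicate_count, dropout=d.dropout)
        for locus in LOCI:
            row[f"{locus.lower()}_allele"] = d.alleles[locus]
        rows.append(row)
    return pd.DataFrame(rows)
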