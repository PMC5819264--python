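"""Seeded generator of CalMorph-like morphological profiling datasets.

The generator emulates the statistical structure the analysis assumes: a
panel of wild-type replicates plus single-replicate deletion mutants scored
on hundreds of traits of three kinds —

* **mean** traits: positive, gamma-distributed summary statistics;
* **cv** traits: coefficients of variation paired one-to-one with mean
  traits, with log(CV) linear in log(mean) plus Gaussian noise (the
  mean-dependence that the noise-trait transform removes);
* **ratio** traits: cell-count proportions, beta-binomially overdispersed
  with a per-strain denominator.

Traits are correlated through a small number of shared latent Gaussian
factors: every trait value is produced by the probability-integral
transform of a standard-normal latent variable whose correlation structure
comes from the factor model.  Planted effects are additive shifts of the
latent variable, i.e. effect sizes are expressed in wild-type standard
deviations on the normalized (Z) scale.

Each mutant belongs to one of three planted classes: ``null`` (no shift),
``specific`` (1–5 perturbed traits) or ``holistic`` (a large random subset
of traits, ≥20%, perturbed with independent random signs).  The truth table
returned alongside the matrix carries the class, the perturbed traits and
their signed effect sizes, for parameter-recovery and error-rate audits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import TraitMatrix, read_trait_matrix, write_trait_matrix

WT_PREFIX = "wt"
MUT_PREFIX = "mut"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset.

    Defaults mirror the screen the pipeline is built for: 501 traits
    (220 mean + 220 CV + 61 ratio) and 109 wild-type replicates.
    """

    n_traits_mean: int = 220
    n_traits_cv: int = 220
    n_traits_ratio: int = 61
    n_wt: int = 109
    n_mutants: int = 1000
    n_latent_factors: int = 57
    frac_holistic: float = 0.1
    frac_specific: float = 0.2
    holistic_effect_sd: float = 3.0
    specific_effect_sd: float = 3.0
    #: fraction of all traits perturbed in a holistic mutant (≥ 0.2)
    holistic_trait_frac: float = 0.3
    ratio_cells_per_strain: int = 200
    #: slope of log(CV) on log(mean) across strains
    cv_mean_slope: float = -0.3
    #: residual sd of log(CV) around the trend (the "noise" scale)
    cv_noise_sd: float = 0.2
    #: communality: fraction of each latent variable's variance shared
    #: through the factors
    factor_strength: float = 0.8
    #: beta-binomial overdispersion of ratio traits
    ratio_overdispersion: float = 0.05
    #: number of shared "abnormality modes" holistic effects draw from
    n_effect_modes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_traits_mean", "n_traits_cv", "n_traits_ratio",
                     "n_wt", "ratio_cells_per_strain"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_mutants < 0 or self.n_latent_factors < 0:
            raise ValidationError("counts must be non-negative")
        for name in ("frac_holistic", "frac_specific"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.frac_holistic + self.frac_specific > 1.0:
            raise ValidationError("frac_holistic + frac_specific must be ≤ 1")
        if self.n_traits_cv > self.n_traits_mean:
            raise ValidationError("each cv trait needs a paired mean trait: "
                                  "n_traits_cv must be ≤ n_traits_mean")
        if not 0.2 <= self.holistic_trait_frac <= 1.0:
            raise ValidationError("holistic_trait_frac must be in [0.2, 1]")
        if not 0.0 < self.ratio_overdispersion < 1.0:
            raise ValidationError("ratio_overdispersion must be in (0, 1)")
        if self.n_effect_modes <= 0:
            raise ValidationError("n_effect_modes must be > 0")

    @property
    def n_traits(self) -> int:
        return self.n_traits_mean + self.n_traits_cv + self.n_traits_ratio

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trait_names(config: SynthConfig) -> tuple[list, list, list]:
    mean = [f"t{i:03d}_mean" for i in range(config.n_traits_mean)]
    cv = [f"t{i:03d}_cv" for i in range(config.n_traits_cv)]
    ratio = [f"r{i:03d}_ratio" for i in range(config.n_traits_ratio)]
    return mean, cv, ratio


def _factor_loadings(rng: np.random.Generator, n_traits: int,
                     config: SynthConfig) -> np.ndarray | None:
    """Unit-norm rows of the trait × factor loading matrix (None if no
    factor structure is configured)."""
    k = config.n_latent_factors
    if k == 0 or config.factor_strength == 0.0:
        return None
    w = rng.standard_normal((n_traits, k))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return w


def _latent_field(rng: np.random.Generator, n_strains: int, n_traits: int,
                  config: SynthConfig,
                  loadings: np.ndarray | None) -> np.ndarray:
    """Standard-normal latent matrix with factor-induced correlation.

    Each latent column is marginally N(0, 1) with cross-trait correlation
    h · W Wᵀ where rows of W are unit norm.
    """
    eps = rng.standard_normal((n_strains, n_traits))
    if loadings is None:
        return eps
    h = config.factor_strength
    f = rng.standard_normal((n_strains, loadings.shape[1]))
    return np.sqrt(h) * (f @ loadings.T) + np.sqrt(1.0 - h) * eps


def _plant_effects(rng: np.random.Generator, config: SynthConfig,
                   trait_names: list,
                   loadings: np.ndarray | None) -> pd.DataFrame:
    """Assign planted classes and signed latent shifts per mutant.

    Holistic effects are drawn from a dictionary of ``n_effect_modes``
    shared abnormality modes — fixed signed ±``holistic_effect_sd``
    patterns over a random ``holistic_trait_frac`` subset of traits — and
    each holistic mutant applies one mode with a random overall sign.
    Mode sign patterns follow the trait covariance structure (the sign of
    a random factor-space direction), so correlated traits deviate
    coherently: gross abnormalities perturb many traits each while staying
    low-rank across mutants and aligned with the natural trait modules,
    mirroring the strong mutual similarity of grossly abnormal mutants in
    real screens.  Specific effects are independent signed shifts of 1–5
    random traits.
    """
    n = config.n_mutants
    n_h = int(round(config.frac_holistic * n))
    n_s = int(round(config.frac_specific * n))
    classes = np.array(["holistic"] * n_h + ["specific"] * n_s
                       + ["null"] * (n - n_h - n_s), dtype=object)
    classes = classes[rng.permutation(n)]
    d = config.n_traits
    n_h_traits = max(int(round(config.holistic_trait_frac * d)),
                     int(np.ceil(0.2 * d)))
    modes = []
    for _ in range(config.n_effect_modes):
        support = rng.choice(d, size=n_h_traits, replace=False)
        if loadings is None:
            signs = rng.choice([-1.0, 1.0], size=n_h_traits)
        else:
            direction = loadings[support] @ rng.standard_normal(
                loadings.shape[1])
            signs = np.where(direction >= 0.0, 1.0, -1.0)
        modes.append((support, signs))
    rows = []
    for i, cls in enumerate(classes):
        if cls == "holistic":
            idx, signs = modes[int(rng.integers(config.n_effect_modes))]
            signs = signs * rng.choice([-1.0, 1.0])
            mag = config.holistic_effect_sd
        elif cls == "specific":
            idx = rng.choice(d, size=int(rng.integers(1, 6)), replace=False)
            signs = rng.choice([-1.0, 1.0], size=len(idx))
            mag = config.specific_effect_sd
        else:
            idx, signs, mag = np.array([], dtype=int), np.array([]), 0.0
        rows.append({
            "strain_id": f"{MUT_PREFIX}{i:05d}",
            "planted_class": cls,
            "perturbed_traits": ";".join(trait_names[j] for j in idx),
            "effect_sizes": ";".join(f"{s * mag:g}" for s in signs),
        })
    return pd.DataFrame(rows,
                        columns=["strain_id", "planted_class",
                                 "perturbed_traits", "effect_sizes"])


def _shift_matrix(truth: pd.DataFrame, trait_names: list) -> np.ndarray:
    pos = {t: j for j, t in enumerate(trait_names)}
    delta = np.zeros((len(truth), len(trait_names)))
    for i, row in enumerate(truth.itertuples(index=False)):
        if not row.perturbed_traits:
            continue
        for t, e in zip(row.perturbed_traits.split(";"),
                        row.effect_sizes.split(";")):
            delta[i, pos[t]] = float(e)
    return delta


def generate_dataset(config: SynthConfig) -> tuple[TraitMatrix, pd.DataFrame]:
    """Generate a seeded dataset and its ground-truth table.

    Returns
    -------
    (TraitMatrix, DataFrame)
        The matrix holds ``n_wt`` wild-type rows followed by ``n_mutants``
        mutant rows; the truth table has one row per mutant with columns
        ``strain_id``, ``planted_class``, ``perturbed_traits`` and
        ``effect_sizes`` (semicolon-joined, in latent/Z sd units).
    """
    rng = np.random.default_rng(config.seed)
    mean_names, cv_names, ratio_names = _trait_names(config)
    trait_names = mean_names + cv_names + ratio_names
    d = config.n_traits

    # per-trait null parameters
    gamma_shape = rng.uniform(2.0, 10.0, size=config.n_traits_mean)
    gamma_scale = rng.uniform(0.5, 20.0, size=config.n_traits_mean)
    cv_intercept = rng.uniform(-1.5, -0.5, size=config.n_traits_cv)
    ratio_pi = rng.uniform(0.05, 0.95, size=config.n_traits_ratio)
    rho = config.ratio_overdispersion
    ratio_conc = (1.0 - rho) / rho  # beta concentration a+b

    loadings = _factor_loadings(rng, d, config)
    truth = _plant_effects(rng, config, trait_names, loadings)
    n_strains = config.n_wt + config.n_mutants
    z = _latent_field(rng, n_strains, d, config, loadings)
    if config.n_mutants:
        z[config.n_wt:] += _shift_matrix(truth, trait_names)
    u = stats.norm.cdf(z)

    values = np.empty((n_strains, d))
    s = 0
    for j in range(config.n_traits_mean):
        values[:, s + j] = stats.gamma.ppf(u[:, s + j], gamma_shape[j],
                                           scale=gamma_scale[j])
    s += config.n_traits_mean
    # cv traits depend on the paired mean trait's realized value
    for j in range(config.n_traits_cv):
        log_mean = np.log(values[:, j])
        eps = stats.norm.ppf(u[:, s + j]) * config.cv_noise_sd
        values[:, s + j] = np.exp(cv_intercept[j]
                                  + config.cv_mean_slope * log_mean + eps)
    s += config.n_traits_cv
    n_cells = config.ratio_cells_per_strain
    denom = np.full((n_strains, config.n_traits_ratio), n_cells, dtype=int)
    for j in range(config.n_traits_ratio):
        a = ratio_pi[j] * ratio_conc
        b = (1.0 - ratio_pi[j]) * ratio_conc
        p_strain = stats.beta.ppf(u[:, s + j], a, b)
        counts = rng.binomial(n_cells, p_strain)
        values[:, s + j] = counts / n_cells

    strain_ids = ([f"{WT_PREFIX}{i:03d}" for i in range(config.n_wt)]
                  + truth["strain_id"].tolist())
    df = pd.DataFrame(values, index=pd.Index(strain_ids, name="strain"),
                      columns=trait_names)
    trait_types = pd.Series(
        ["mean"] * config.n_traits_mean + ["cv"] * config.n_traits_cv
        + ["ratio"] * config.n_traits_ratio, index=trait_names)
    is_wt = pd.Series([True] * config.n_wt + [False] * config.n_mutants,
                      index=df.index)
    denominators = pd.DataFrame(denom, index=df.index, columns=ratio_names)
    matrix = TraitMatrix(df, trait_types, is_wt, denominators)
    return matrix, truth


def cv_mean_pairs(matrix: TraitMatrix) -> dict:
    """Map each generated cv trait to its paired mean trait by name."""
    return {t: t.replace("_cv", "_mean") for t in matrix.traits_of_type("cv")}


def generate_fitness(truth: pd.DataFrame, seed: int,
                     null_mean: float = 0.0, null_sd: float = 1.0,
                     slow_frac: dict | None = None,
                     effect_sd: float = 6.0) -> pd.DataFrame:
    """Synthetic per-gene fitness table aligned with a truth table.

    A seeded fraction of each planted class (``slow_frac``, defaults
    holistic 0.5 / specific 0.2 / null 0.05) receives a downward fitness
    shift of ``effect_sd`` null standard deviations; all other strains draw
    from the null.
    """
    slow_frac = slow_frac or {"holistic": 0.5, "specific": 0.2, "null": 0.05}
    rng = np.random.default_rng(seed)
    fitness = rng.normal(null_mean, null_sd, size=len(truth))
    slow = rng.random(len(truth)) < truth["planted_class"].map(slow_frac) \
        .to_numpy(float)
    fitness[slow] -= effect_sd * null_sd
    return pd.DataFrame({"gene_id": truth["strain_id"], "fitness": fitness,
                         "null_mean": null_mean, "null_sd": null_sd,
                         "planted_slow": slow})


def write_fixture(matrix: TraitMatrix, truth: pd.DataFrame, directory,
                  config: SynthConfig | None = None) -> dict:
    """Write the dataset, truth table and a JSON manifest to a directory.

    Returns the mapping of artifact name → file path.  The manifest records
    the full config (including the seed) so a fixture is reproducible from
    the manifest alone.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "trait_types": directory / "trait_types.tsv",
        "denominators": directory / "denominators.tsv",
        "truth": directory / "truth.tsv",
        "manifest": directory / "manifest.json",
    }
    write_trait_matrix(matrix, paths["matrix"], paths["trait_types"],
                       paths["denominators"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    manifest = {"config": config.to_dict() if config else None,
                "seed": config.seed if config else None,
                "n_strains": len(matrix.strain_ids),
                "n_traits": len(matrix.trait_names)}
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return {k: str(v) for k, v in paths.items()}


def read_fixture(directory) -> tuple[TraitMatrix, pd.DataFrame]:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    matrix = read_trait_matrix(directory / "matrix.tsv",
                               directory / "trait_types.tsv",
                               denominators_path=directory
                               / "denominators.tsv")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t",
                        keep_default_na=False)
    return matrix, truth
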