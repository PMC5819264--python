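"""Stage orchestration: noise traits → nulls → Z → PCA → holistic calls.

:func:`detect_effectors` is the library entry point covering the whole
morphology arm; :func:`run_pipeline` drives it (plus the optional fitness /
classification / similarity / enrichment stages) from a :class:`RunConfig`,
writing every stage's tables into an output directory with a manifest that
records a hash of the configuration.  Rerunning with an identical config
skips stages whose manifest hash already matches, so deleting an
intermediate regenerates only the downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import classify as ca
from . import io as mio
from . import syndata
from .errors import ValidationError
from .holistic import HolisticDetector, classify_morphology
from .trait_stats import WaldZNormalizer, compute_noise_traits, \
    specific_abnormality

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    matrix_path: str | None = None
    trait_types_path: str | None = None
    denominators_path: str | None = None
    fitness_path: str | None = None
    annotations_path: str | None = None
    ccr_target_holistic: float = 0.80
    ccr_target_similarity: float = 0.99
    fdr_level: float = 0.01
    seed: int = 0
    family_overrides: dict | None = None
    simulate: dict | None = None  # SynthConfig fields; replaces matrix_path

    def __post_init__(self) -> None:
        for name in ("ccr_target_holistic", "ccr_target_similarity"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1]")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValidationError("fdr_level must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DetectionResult:
    """All tables produced by the morphology detection arm."""

    matrix: "mio.TraitMatrix"          # after the noise-trait transform
    trends: pd.DataFrame               # fitted CV–mean trends
    normalizer: WaldZNormalizer
    z: pd.DataFrame                    # all strains × traits
    detector: HolisticDetector
    distance_table: pd.DataFrame       # per mutant
    specific_summary: pd.DataFrame     # per mutant
    p_matrix: pd.DataFrame
    q_matrix: pd.DataFrame
    morph_class: pd.Series


def detect_effectors(matrix: "mio.TraitMatrix",
                     ccr_target: float = 0.80,
                     fdr_level: float = 0.01,
                     family_overrides: dict | None = None,
                     cv_pairs: dict | None = None) -> DetectionResult:
    """Run the full morphology arm on a trait matrix.

    Noise-trait construction, wild-type null fits, Wald-Z normalization,
    mutant-fitted PCA at ``ccr_target``, wild-type-standardized Euclidean
    distances, gamma-null holistic calls and per-trait specific calls at
    ``fdr_level``, and the three-way morphology classification.
    """
    matrix = matrix.drop_incomplete_strains()
    if len(matrix.traits_of_type("cv")):
        matrix, trends = compute_noise_traits(matrix, cv_pairs)
    else:
        trends = pd.DataFrame(columns=["mean_trait", "intercept",
                                       "slope", "n"])
    normalizer = WaldZNormalizer(family_overrides=family_overrides)
    normalizer.fit(matrix)
    z = normalizer.transform(matrix)
    detector = HolisticDetector(ccr_target=ccr_target, fdr_level=fdr_level)
    detector.fit(z, matrix.is_wildtype)
    summary, p, q = specific_abnormality(matrix, normalizer.models_,
                                         fdr_level=fdr_level)
    morph = classify_morphology(detector.distance_table_, summary,
                                fdr_level=fdr_level)
    return DetectionResult(matrix, trends, normalizer, z, detector,
                           detector.distance_table_, summary, p, q, morph)


# ---------------------------------------------------------------------------
# staged runner
# ---------------------------------------------------------------------------

def _manifest_path(stage_dir: Path) -> Path:
    return stage_dir / "manifest.json"


def _stage_current(stage_dir: Path, config_hash: str) -> bool:
    mf = _manifest_path(stage_dir)
    if not mf.exists():
        return False
    try:
        return json.loads(mf.read_text()).get("config_hash") == config_hash
    except json.JSONDecodeError:
        return False


def _write_manifest(stage_dir: Path, stage: str, config: RunConfig,
                    config_hash: str, elapsed: float,
                    extra: dict | None = None) -> None:
    payload = {"stage": stage, "config_hash": config_hash,
               "config": config.to_dict(), "elapsed_s": round(elapsed, 3)}
    payload.update(extra or {})
    _manifest_path(stage_dir).write_text(json.dumps(payload, indent=1))


def _write_z(z: pd.DataFrame, is_wildtype: pd.Series, path: Path) -> None:
    out = z.copy()
    out.insert(0, "is_wildtype", is_wildtype.astype(int))
    out.rename_axis("strain").reset_index().to_csv(path, sep="\t",
                                                   index=False)


def read_z_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t").set_index("strain")
    is_wt = df.pop("is_wildtype").astype(bool)
    return df, is_wt


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every configured stage, reusing up-to-date outputs.

    Returns the output directory.  Stage failures propagate with the stage
    named; outputs of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash()

    # -- simulate --------------------------------------------------------
    if config.simulate is not None:
        sim_dir = outdir / "simulate"
        if not _stage_current(sim_dir, h):
            t0 = time.perf_counter()
            cfg = syndata.SynthConfig(**{**config.simulate,
                                         "seed": config.simulate.get(
                                             "seed", config.seed)})
            matrix, truth = syndata.generate_dataset(cfg)
            syndata.write_fixture(matrix, truth, sim_dir, cfg)
            _write_manifest(sim_dir, "simulate", config, h,
                            time.perf_counter() - t0)
            logger.info("simulate: %d strains × %d traits",
                        len(matrix.strain_ids), len(matrix.trait_names))
        config = dataclasses.replace(
            config,
            matrix_path=str(sim_dir / "matrix.tsv"),
            trait_types_path=str(sim_dir / "trait_types.tsv"),
            denominators_path=str(sim_dir / "denominators.tsv"))

    if config.matrix_path is None:
        raise ValidationError("no input: set matrix_path or simulate")

    # -- detect ----------------------------------------------------------
    det_dir = outdir / "detect"
    if not _stage_current(det_dir, h):
        t0 = time.perf_counter()
        det_dir.mkdir(exist_ok=True)
        matrix = mio.read_trait_matrix(
            config.matrix_path, config.trait_types_path,
            denominators_path=config.denominators_path,
            require_wildtype=True)
        res = detect_effectors(matrix,
                               ccr_target=config.ccr_target_holistic,
                               fdr_level=config.fdr_level,
                               family_overrides=config.family_overrides)
        _write_z(res.z, res.matrix.is_wildtype, det_dir / "z_matrix.tsv")
        res.distance_table.rename_axis("strain").reset_index().to_csv(
            det_dir / "distances.tsv", sep="\t", index=False)
        joined = res.specific_summary.join(res.morph_class)
        joined.rename_axis("strain").reset_index().to_csv(
            det_dir / "specific.tsv", sep="\t", index=False)
        pd.DataFrame({
            "contribution": res.detector.embedding_.contribution,
            "ccr": res.detector.embedding_.ccr,
        }, index=res.detector.embedding_.pc_names).rename_axis("pc") \
            .reset_index().to_csv(det_dir / "contribution.tsv", sep="\t",
                                  index=False)
        res.trends.reset_index().to_csv(det_dir / "trends.tsv", sep="\t",
                                        index=False)
        _write_manifest(det_dir, "detect", config, h,
                        time.perf_counter() - t0,
                        {"retained_pcs": int(res.detector.embedding_
                                             .retained),
                         "gamma_null": dataclasses.asdict(
                             res.detector.null_)})
        logger.info("detect: %d holistic / %d mutants",
                    int(res.distance_table["is_holistic"].sum()),
                    len(res.distance_table))

    # -- classify --------------------------------------------------------
    if config.fitness_path is not None:
        cls_dir = outdir / "classify"
        if not _stage_current(cls_dir, h):
            t0 = time.perf_counter()
            cls_dir.mkdir(exist_ok=True)
            fitness = mio.read_fitness(config.fitness_path)
            fit = ca.fitness_significance(fitness,
                                          fdr_level=config.fdr_level)
            spec = pd.read_csv(det_dir / "specific.tsv", sep="\t") \
                .set_index("strain")
            groups = ca.assign_groups(spec["morph_class"],
                                      fit["slow_growth"])
            fit.reset_index().to_csv(cls_dir / "fitness.tsv", sep="\t",
                                     index=False)
            groups.rename_axis("gene_id").reset_index().to_csv(
                cls_dir / "groups.tsv", sep="\t", index=False)
            _write_manifest(cls_dir, "classify", config, h,
                            time.perf_counter() - t0,
                            {"group_sizes": groups["group"]
                             .value_counts().to_dict()})

        # -- enrich ------------------------------------------------------
        if config.annotations_path is not None:
            enr_dir = outdir / "enrich"
            if not _stage_current(enr_dir, h):
                t0 = time.perf_counter()
                enr_dir.mkdir(exist_ok=True)
                groups = pd.read_csv(cls_dir / "groups.tsv", sep="\t") \
                    .set_index("gene_id")
                ann = mio.read_annotations(config.annotations_path)
                enr = ca.fisher_enrichment(groups, ann,
                                           fdr_level=config.fdr_level)
                enr.to_csv(enr_dir / "enrichment.tsv", sep="\t",
                           index=False)
                _write_manifest(enr_dir, "enrich", config, h,
                                time.perf_counter() - t0)

    # -- similarity ------------------------------------------------------
    sim_dir = outdir / "similarity"
    if not _stage_current(sim_dir, h):
        t0 = time.perf_counter()
        sim_dir.mkdir(exist_ok=True)
        z, is_wt = read_z_matrix(det_dir / "z_matrix.tsv")
        edges = ca.morphological_similarity(
            z, is_wt, ccr_target=config.ccr_target_similarity)
        mio.write_edge_list(edges, sim_dir / "edges.tsv")
        _write_manifest(sim_dir, "similarity", config, h,
                        time.perf_counter() - t0,
                        {"n_edges": int(len(edges))})

    return outdir
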