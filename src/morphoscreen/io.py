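"""Tabular input/output with validation.

All files are tab-separated UTF-8 text with a header row and ``.`` as the
decimal mark (CSV is accepted via ``sep=","``).  The central container is
:class:`TraitMatrix`: a strains × traits value table plus per-trait type
metadata (``mean`` / ``cv`` / ``noise`` / ``ratio``), a wild-type flag per
strain, and optional per-strain cell counts serving as denominators of the
ratio traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("mean", "cv", "noise", "ratio")

#: fraction of missing trait values above which a strain is dropped
MAX_MISSING_FRACTION = 0.10


@dataclass
class TraitMatrix:
    """Strains × traits morphological profile matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Trait values; index = strain ids, columns = trait names.  Missing
        measurements are NaN (never silently zero).
    trait_types : pandas.Series
        Per-trait type, one of ``mean``, ``cv``, ``noise``, ``ratio``.
        ``noise`` marks real-line residual traits produced by
        :func:`morphoscreen.trait_stats.compute_noise_traits`.
    is_wildtype : pandas.Series
        Boolean flag per strain; wild-type replicates calibrate all nulls.
    ratio_denominators : pandas.DataFrame, optional
        Per-strain cell counts for each ratio trait (same index as
        ``values``, columns ⊆ ratio traits).
    """

    values: pd.DataFrame
    trait_types: pd.Series
    is_wildtype: pd.Series
    ratio_denominators: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def strain_ids(self) -> pd.Index:
        return self.values.index

    @property
    def trait_names(self) -> pd.Index:
        return self.values.columns

    @property
    def n_wildtype(self) -> int:
        return int(self.is_wildtype.sum())

    def wildtype(self) -> pd.DataFrame:
        return self.values.loc[self.is_wildtype]

    def mutants(self) -> pd.DataFrame:
        return self.values.loc[~self.is_wildtype]

    def traits_of_type(self, kind: str) -> pd.Index:
        return self.trait_types.index[self.trait_types == kind]

    def with_values(self, values: pd.DataFrame,
                    trait_types: pd.Series | None = None) -> "TraitMatrix":
        return replace(self, values=values,
                       trait_types=self.trait_types if trait_types is None
                       else trait_types)

    # -- validation ------------------------------------------------------
    def validate(self, require_wildtype: bool = False) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate strain id(s): {dup}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate trait name(s): {dup}")
        missing = cols.difference(self.trait_types.index)
        if len(missing):
            raise ValidationError(f"traits without a declared type: "
                                  f"{missing.tolist()[:5]}")
        self.trait_types = self.trait_types.reindex(cols)
        bad = self.trait_types[~self.trait_types.isin(TRAIT_TYPES)]
        if len(bad):
            raise ValidationError(
                f"unknown trait type(s): {sorted(set(bad))} "
                f"(expected one of {TRAIT_TYPES})")
        self.is_wildtype = self.is_wildtype.reindex(idx).astype(bool)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ratio = self.traits_of_type("ratio")
            if len(ratio):
                v = self.values[ratio].to_numpy(float)
                ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
                if not ok.all():
                    raise ValidationError("ratio trait values outside [0, 1]")
            for kind in ("mean", "cv"):
                tr = self.traits_of_type(kind)
                if len(tr):
                    v = self.values[tr].to_numpy(float)
                    if not (np.isnan(v) | (v >= 0.0)).all():
                        raise ValidationError(
                            f"negative values in {kind} trait(s)")
        n_wt = self.n_wildtype
        if n_wt < 2:
            msg = (f"only {n_wt} wild-type replicate(s); ≥2 are required to "
                   f"fit the per-trait nulls")
            if require_wildtype:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)

    # -- quality control -------------------------------------------------
    def drop_incomplete_strains(self,
                                max_missing: float = MAX_MISSING_FRACTION
                                ) -> "TraitMatrix":
        """Drop strains missing more than ``max_missing`` of their traits."""
        frac = self.values.isna().mean(axis=1)
        bad = frac.index[frac > max_missing]
        if len(bad):
            logger.warning("dropping %d strain(s) with >%.0f%% missing "
                           "traits: %s", len(bad), 100 * max_missing,
                           bad.tolist()[:10])
        keep = frac.index.difference(bad, sort=False)
        denom = (None if self.ratio_denominators is None
                 else self.ratio_denominators.loc[keep])
        return TraitMatrix(self.values.loc[keep], self.trait_types,
                           self.is_wildtype.loc[keep], denom)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_trait_matrix(path, trait_types, wildtype_label: str = "wild-type",
                      denominators_path=None, sep: str = "\t",
                      require_wildtype: bool = False) -> TraitMatrix:
    """Read a strains × traits TSV into a validated :class:`TraitMatrix`.

    The file must carry a ``strain`` column and either an ``is_wildtype``
    column (0/1) or strain ids beginning with ``wildtype_label``.
    ``trait_types`` is a ``{trait: type}`` mapping, a Series, or the path of
    a two-column TSV (``trait``, ``type``).  Strain order is preserved as
    read.  Missing cells stay missing (NaN); they are never coerced to zero.
    """
    df = pd.read_csv(path, sep=sep)
    if "strain" not in df.columns:
        raise ValidationError(f"{path}: no 'strain' column")
    if df["strain"].duplicated().any():
        dup = df["strain"][df["strain"].duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate strain id(s): {dup}")
    df = df.set_index("strain")
    if "is_wildtype" in df.columns:
        is_wt = df.pop("is_wildtype").astype(bool)
    else:
        is_wt = df.index.to_series().str.startswith(wildtype_label)
    if isinstance(trait_types, (str,)) or hasattr(trait_types, "__fspath__"):
        tt = pd.read_csv(trait_types, sep=sep)
        trait_types = tt.set_index("trait")["type"]
    trait_types = pd.Series(trait_types)
    denom = None
    if denominators_path is not None:
        denom = pd.read_csv(denominators_path, sep=sep).set_index("strain")
        denom = denom.reindex(df.index)
    m = TraitMatrix(df.astype(float), trait_types, is_wt, denom)
    if require_wildtype:
        m.validate(require_wildtype=True)
    return m


def write_trait_matrix(matrix: TraitMatrix, matrix_path, types_path,
                       denominators_path=None) -> None:
    out = matrix.values.copy()
    out.insert(0, "is_wildtype", matrix.is_wildtype.astype(int))
    out.rename_axis("strain").reset_index().to_csv(matrix_path, sep="\t",
                                                   index=False)
    (matrix.trait_types.rename("type").rename_axis("trait").reset_index()
        .to_csv(types_path, sep="\t", index=False))
    if denominators_path is not None and matrix.ratio_denominators is not None:
        (matrix.ratio_denominators.rename_axis("strain").reset_index()
            .to_csv(denominators_path, sep="\t", index=False))


def read_fitness(path, sep: str = "\t") -> pd.DataFrame:
    """Read a per-gene fitness table: gene_id, fitness, null_mean, null_sd.

    ``fitness`` is a growth-rate coefficient (LSC-style); ``null_mean`` and
    ``null_sd`` parameterize the wild-type (no-effect) normal distribution
    against which slow growth is tested.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"gene_id", "fitness", "null_mean", "null_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id rows")
    bad = df.index[df["null_sd"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{path}: null_sd must be > 0 (line(s) {(bad + 2).tolist()[:5]})")
    return df


def read_annotations(path, sep: str = "\t") -> pd.DataFrame:
    """Read gene → term annotations.

    Accepts either a headed TSV with columns ``gene_id``, ``term_id``
    (optionally ``term_name``), or a GAF-style headerless file whose lines
    have ≥15 tab-separated fields (``!`` comment lines skipped); there the
    gene symbol is column 3 and the GO id column 5 (1-based).  Duplicate
    (gene, term) pairs are collapsed.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if not line.startswith("!") and line.strip():
                first = line
                break
    if not first:
        return pd.DataFrame(columns=["gene_id", "term_id", "term_name"])
    if len(first.rstrip("\n").split("\t")) >= 15:
        df = pd.read_csv(path, sep="\t", header=None, comment="!",
                         dtype=str, low_memory=False)
        out = pd.DataFrame({"gene_id": df[2], "term_id": df[4],
                            "term_name": ""})
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)
        missing = {"gene_id", "term_id"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"{path}: missing column(s) {sorted(missing)}")
        if "term_name" not in df.columns:
            df["term_name"] = ""
        out = df[["gene_id", "term_id", "term_name"]]
    return out.drop_duplicates(["gene_id", "term_id"]).reset_index(drop=True)


def read_interactions(path, sep: str = "\t") -> pd.DataFrame:
    """Read pairwise genetic-interaction records.

    Columns: gene_a, gene_b, score (ε), p, experiment_id.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"gene_a", "gene_b", "score", "p", "experiment_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df.index[(df["p"] < 0) | (df["p"] > 1) | df["p"].isna()]
    if len(bad):
        raise ValidationError(
            f"{path}: p outside [0,1] (line(s) {(bad + 2).tolist()[:5]})")
    return df


def count_interactions(interactions: pd.DataFrame,
                       p_cut: float = 0.05) -> pd.Series:
    """Standardized genetic-interaction count per gene.

    For each gene: the number of pairs with p < ``p_cut`` involving the
    gene, divided by the number of distinct experiments in which the gene
    was assayed (significant or not).  Genes assayed in zero experiments do
    not appear.
    """
    long = pd.concat([
        interactions.rename(columns={"gene_a": "gene"})[
            ["gene", "p", "experiment_id"]],
        interactions.rename(columns={"gene_b": "gene"})[
            ["gene", "p", "experiment_id"]],
    ], ignore_index=True)
    n_exp = long.groupby("gene")["experiment_id"].nunique()
    n_sig = (long["p"] < p_cut).groupby(long["gene"]).sum()
    return (n_sig / n_exp).rename("interaction_count")


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Write a similarity edge list (source, target, r, sign, strength)."""
    cols = ["gene_a", "gene_b", "r", "sign", "strength"]
    edges[cols].rename(columns={"gene_a": "source", "gene_b": "target"}) \
        .to_csv(path, sep="\t", index=False)
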