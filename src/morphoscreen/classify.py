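"""Fitness significance, six-group gene classification and associations.

Genes are cross-classified by their morphology class (holistic / specific /
other) and their growth phenotype (slow / normal, from a one-tailed test of
the fitness coefficient against its wild-type null):

===========  ==========  ==========
morphology   slow        normal
===========  ==========  ==========
holistic     I           IV
specific     II          V
other        III         VI
===========  ==========  ==========

Downstream association analyses: one-sided Fisher exact enrichment of
annotation terms per group, pairwise morphological similarity (Pearson
correlation of PC score profiles in a wild-type-fitted PCA space),
(partial) feature correlations, and Mann–Whitney group comparisons with
Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .embedding import fit_pca, project
from .errors import ValidationError
from .trait_stats import qvalues

logger = logging.getLogger(__name__)

GROUP_LABELS = {
    ("holistic", True): "I",
    ("specific", True): "II",
    ("other", True): "III",
    ("holistic", False): "IV",
    ("specific", False): "V",
    ("other", False): "VI",
}

#: |r| bin edges of similarity edge strengths
STRENGTH_BINS = ((0.6, "strong"), (0.4, "moderate"), (0.2, "weak"))


# ---------------------------------------------------------------------------
# fitness and groups
# ---------------------------------------------------------------------------

def fitness_significance(fitness: pd.DataFrame,
                         fdr_level: float = 0.01) -> pd.DataFrame:
    """One-tailed significance of slow growth per gene.

    p is the lower-tail normal probability of the observed fitness under
    the gene's (null_mean, null_sd); q-values via Storey; ``slow_growth``
    flags q ≤ ``fdr_level``.
    """
    if (fitness["null_sd"] <= 0).any():
        raise ValidationError("null_sd must be > 0 for every gene")
    z = (fitness["fitness"] - fitness["null_mean"]) / fitness["null_sd"]
    p = stats.norm.cdf(z.to_numpy(float))
    q = qvalues(p)
    return pd.DataFrame({
        "gene_id": fitness["gene_id"],
        "fitness": fitness["fitness"],
        "fitness_p": p,
        "fitness_q": q,
        "slow_growth": q <= fdr_level,
    }).set_index("gene_id")


def assign_groups(morph_class: pd.Series,
                  slow_growth: pd.Series) -> pd.DataFrame:
    """Six-way functional group per gene from the 3×2 cross.

    Genes present in only one of the two inputs are excluded with a logged
    note (no fitness data → no group).
    """
    common = morph_class.index.intersection(slow_growth.index)
    dropped = len(morph_class.index.union(slow_growth.index)) - len(common)
    if dropped:
        logger.info("excluding %d gene(s) lacking morphology or fitness "
                    "calls", dropped)
    mc = morph_class.loc[common]
    sg = slow_growth.loc[common].astype(bool)
    bad = mc[~mc.isin(["holistic", "specific", "other"])]
    if len(bad):
        raise ValidationError(f"unknown morphology class(es): "
                              f"{sorted(set(bad))}")
    group = [GROUP_LABELS[(m, s)] for m, s in zip(mc, sg)]
    return pd.DataFrame({"morph_class": mc, "slow_growth": sg,
                         "group": group}, index=common)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(groups: pd.DataFrame, annotations: pd.DataFrame,
                      background: pd.Index | None = None,
                      fdr_level: float = 0.01,
                      alternative: str = "greater",
                      min_annotated: int = 3) -> pd.DataFrame:
    """Per-(term, group) Fisher exact enrichment.

    The 2×2 table for term T and group G over background N is
    (k_in, K−k_in; n−k_in, N−K−n+k_in) with K annotated genes, n the group
    size and k_in their overlap.  Default background: all genes with a
    group assignment.  q-values are computed over all tested pairs; terms
    annotating fewer than ``min_annotated`` background genes are skipped.
    """
    if background is None:
        background = groups.index
    background = pd.Index(background).unique()
    g = groups.loc[groups.index.intersection(background), "group"]
    ann = annotations[annotations["gene_id"].isin(background)]
    term_names = (ann.drop_duplicates("term_id")
                  .set_index("term_id")["term_name"])
    n_bg = len(background)
    rows = []
    for term_id, sub in ann.groupby("term_id"):
        annotated = pd.Index(sub["gene_id"]).unique()
        K = len(annotated)
        if K < min_annotated:
            continue
        for grp, members in g.groupby(g):
            n = len(members)
            k_in = len(members.index.intersection(annotated))
            table = [[k_in, K - k_in], [n - k_in, n_bg - K - n + k_in]]
            odds, p = stats.fisher_exact(table, alternative=alternative)
            rows.append({"term_id": term_id,
                         "term_name": term_names.get(term_id, ""),
                         "group": grp, "k_in": k_in, "K": K, "n": n,
                         "N": n_bg, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "group",
                                      "k_in", "K", "n", "N", "odds_ratio",
                                      "p"])
    out["q"] = qvalues(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] <= fdr_level if len(out) else []
    return out.sort_values(["p", "term_id", "group"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# similarity network
# ---------------------------------------------------------------------------

def _strength(abs_r: float) -> str:
    for cut, name in STRENGTH_BINS:
        if abs_r > cut:
            return name
    return "none"


def morphological_similarity(z: pd.DataFrame, is_wildtype,
                             ccr_target: float = 0.99,
                             min_abs_r: float = 0.2,
                             genes: pd.Index | None = None) -> pd.DataFrame:
    """Pairwise morphological similarity edges between mutants.

    The PCA is fitted on the wild-type Z rows; mutants are projected, and
    the Pearson correlation of two mutants' retained-PC score vectors
    (CCR ≥ ``ccr_target``) is their similarity.  Edges with |r| ≤
    ``min_abs_r`` are omitted (they fall in the "none" strength bin);
    |r| > 0.8 maps to "strong".  ``genes`` restricts the mutants compared.
    """
    is_wt = np.asarray(is_wildtype, bool)
    z_wt, z_mut = z.loc[is_wt], z.loc[~is_wt]
    if genes is not None:
        z_mut = z_mut.loc[z_mut.index.intersection(pd.Index(genes))]
    if len(z_mut) < 2:
        raise ValidationError("need ≥2 mutants to compute similarities")
    emb = fit_pca(z_wt, ccr_target=ccr_target)
    scores = project(emb, z_mut).iloc[:, : emb.retained].to_numpy(float)
    sd = scores.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        warnings.warn(f"omitting {int(constant.sum())} mutant(s) with a "
                      f"constant PC score vector (undefined correlation)",
                      stacklevel=2)
    ids = z_mut.index[~constant]
    r = np.corrcoef(scores[~constant])
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        rij = float(r[i, j])
        if abs(rij) <= min_abs_r:
            continue
        rows.append({"gene_a": ids[i], "gene_b": ids[j], "r": rij,
                     "sign": "positive" if rij >= 0 else "negative",
                     "strength": _strength(abs(rij))})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign",
                                       "strength"])


# ---------------------------------------------------------------------------
# feature correlations and group comparisons
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), controls])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def correlate_features(values_a, values_b, method: str = "pearson",
                       controls=None) -> dict:
    """(Partial) correlation between two gene features.

    Spearman rank-transforms both variables first; partial correlation
    residualizes both on the controls (double residualization).  The 95% CI
    uses the Fisher z transform with n − 3 − (#controls) effective degrees
    of freedom.  Pairs with missing values are dropped.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    c = None
    if controls is not None:
        c = np.asarray(controls, float)
        if c.ndim == 1:
            c = c[:, None]
    ok = np.isfinite(a) & np.isfinite(b)
    if c is not None:
        ok &= np.isfinite(c).all(axis=1)
    a, b = a[ok], b[ok]
    c = c[ok] if c is not None else None
    n = a.size
    n_ctrl = 0 if c is None else c.shape[1]
    if n < 4 + n_ctrl:
        raise ValidationError(f"need ≥{4 + n_ctrl} complete pairs, got {n}")
    if method == "spearman":
        a = stats.rankdata(a)
        b = stats.rankdata(b)
        if c is not None:
            c = np.apply_along_axis(stats.rankdata, 0, c)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    if c is not None:
        a = _residualize(a, c)
        b = _residualize(b, c)
    r, p = stats.pearsonr(a, b)
    zf = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3 - n_ctrl)
    lo, hi = np.tanh(zf - 1.959964 * se), np.tanh(zf + 1.959964 * se)
    return {"r": float(r), "p": float(p), "ci_low": float(lo),
            "ci_high": float(hi), "n": int(n), "method": method,
            "n_controls": n_ctrl}


def compare_groups(values_by_group: dict,
                   correction: str = "bonferroni") -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney U tests between groups.

    scipy chooses the exact distribution for small tie-free samples and the
    normal approximation otherwise.  Bonferroni multiplies each p by the
    number of tested pairs (capped at 1).  Empty groups are skipped with a
    warning; group medians are reported alongside.
    """
    groups = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    empty = [k for k, v in groups.items() if v.size == 0]
    if empty:
        warnings.warn(f"skipping empty group(s): {empty}", stacklevel=2)
        groups = {k: v for k, v in groups.items() if v.size}
    if len(groups) < 2:
        raise ValidationError("need ≥2 non-empty groups")
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for ga, gb in pairs:
        u, p = stats.mannwhitneyu(groups[ga], groups[gb],
                                  alternative="two-sided")
        rows.append({"group_a": ga, "group_b": gb,
                     "median_a": float(np.median(groups[ga])),
                     "median_b": float(np.median(groups[gb])),
                     "U": float(u), "p": float(p)})
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(pairs), 1.0)
    elif correction in (None, "none"):
        out["p_adj"] = out["p"]
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return out
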