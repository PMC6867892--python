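"""Functional-investment statistics: LOX/GH DEG shifts, enrichment, GH:LOX
expression ratios, family-level PCA and Z-score scaling.

Brown-rot fungi oxidatively pretreat wood at the hyphal front before
deploying glycoside hydrolases; white-rot fungi degrade lignin and
carbohydrates enzymatically throughout.  These routines quantify that
contrast: counts of early- vs late-upregulated DEGs per CAZY family and
functional class (LOX = lignocellulose-oxidising, GH = glycoside
hydrolase), a Fisher exact test for the rot-type difference in LOX stage
skew, per-family paired t-tests, hypergeometric term enrichment, and the
GH:LOX summed-RPKM "transcriptional investment" ratio per decay stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rotstage.express import bh_fdr
from rotstage.synthdata import SECTIONS


def family_deg_counts(
    early_sets: dict[str, set[str]],
    late_sets: dict[str, set[str]],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Early/late DEG counts per (species, family) with the class label and
    the early-late difference.

    DEG genes missing from the annotation are counted as class "other"
    (family "unannotated") with a warning.
    """
    rows = []
    for sp in sorted(set(early_sets) | set(late_sets)):
        tallies: dict[tuple[str, str], list[int]] = {}
        for stage_idx, genes in ((0, early_sets.get(sp, set())), (1, late_sets.get(sp, set()))):
            for g in genes:
                if g in annotation.index:
                    fam = annotation.at[g, "family"]
                    cls = annotation.at[g, "func_class"]
                else:
                    warnings.warn(f"DEG {g} missing annotation; counted as 'other'")
                    fam, cls = "unannotated", "other"
                tallies.setdefault((fam, cls), [0, 0])[stage_idx] += 1
        for (fam, cls), (n_early, n_late) in sorted(tallies.items()):
            rows.append(
                {
                    "species": sp,
                    "family": fam,
                    "func_class": cls,
                    "n_early": n_early,
                    "n_late": n_late,
                    "delta_early_minus_late": n_early - n_late,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species", "family", "func_class", "n_early", "n_late", "delta_early_minus_late"],
    )


def class_deg_counts(family_counts: pd.DataFrame, rot_type: dict[str, str]) -> pd.DataFrame:
    """Pool family counts to (rot type, functional class) totals."""
    df = family_counts.copy()
    df["rot_type"] = df["species"].map(rot_type)
    pooled = (
        df.groupby(["rot_type", "func_class"])[["n_early", "n_late"]].sum().reset_index()
    )
    return pooled


@dataclass
class ShiftTestResult:
    fisher_table: np.ndarray  # rows: brown/white; cols: early/late LOX DEGs
    fisher_odds: float
    fisher_p: float
    degenerate: bool
    paired_t: dict[str, tuple[float, float]]  # class -> (t, p) brown vs white per-family deltas


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = np.asarray(x, float) - np.asarray(y, float)
    if len(d) < 2:
        raise ValueError("paired t-test needs >= 2 pairs")
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return 0.0, 1.0  # identical vectors: no shift, no evidence
    t, p = stats.ttest_rel(np.asarray(x, float), np.asarray(y, float))
    return float(t), float(p)


def lox_shift_tests(
    family_counts: pd.DataFrame,
    rot_type: dict[str, str],
) -> ShiftTestResult:
    """Test the LOX early-shift contrast between rot types.

    (a) Fisher's exact test on the 2x2 table of pooled LOX DEG counts,
    rot type x (early, late).  A table with a zero margin is flagged
    degenerate and reported with p = 1.

    (b) Two-tailed paired t-tests on per-family early-minus-late DEG
    differences, pairing each CAZY family's difference in brown rot against
    the same family in white rot (species of a type are pooled), separately
    for the LOX and GH classes.
    """
    pooled = class_deg_counts(family_counts, rot_type)
    lox = pooled[pooled["func_class"] == "LOX"].set_index("rot_type")
    table = np.zeros((2, 2), dtype=int)
    for i, rt in enumerate(("brown", "white")):
        if rt in lox.index:
            table[i] = (lox.at[rt, "n_early"], lox.at[rt, "n_late"])
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        odds, p = math.nan, 1.0
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")

    df = family_counts.copy()
    df["rot_type"] = df["species"].map(rot_type)
    per_family = (
        df.groupby(["rot_type", "func_class", "family"])["delta_early_minus_late"].sum()
    )
    paired: dict[str, tuple[float, float]] = {}
    for cls in ("LOX", "GH"):
        fams = sorted(
            set(per_family.get(("brown", cls), pd.Series(dtype=float)).index)
            | set(per_family.get(("white", cls), pd.Series(dtype=float)).index)
        )
        if len(fams) < 2:
            continue
        brown = np.array([per_family.get(("brown", cls, f), 0) for f in fams], float)
        white = np.array([per_family.get(("white", cls, f), 0) for f in fams], float)
        paired[cls] = _paired_t(brown, white)
    return ShiftTestResult(
        fisher_table=table,
        fisher_odds=float(odds) if not degenerate else math.nan,
        fisher_p=float(p),
        degenerate=degenerate,
        paired_t=paired,
    )


def fisher_enrichment(
    target: set[str],
    universe: set[str],
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided (over-representation) term enrichment with BH correction.

    For each term, the p-value is the hypergeometric upper tail of drawing
    at least the observed number of term genes when sampling |target| genes
    from the universe.  Terms with no gene in the universe are skipped with
    a warning.
    """
    if not target <= universe:
        raise ValueError("target set must be a subset of the universe")
    n_universe = len(universe)
    n_target = len(target)
    rows = []
    for term, genes in sorted(term_map.items()):
        in_universe = genes & universe
        if not in_universe:
            warnings.warn(f"term {term} has no genes in the universe; skipped")
            continue
        k = len(in_universe & target)
        big_k = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_target))
        rows.append(
            {"term": term, "n_target_term": k, "n_term": big_k,
             "n_target": n_target, "n_universe": n_universe, "pvalue": min(p, 1.0)}
        )
    out = pd.DataFrame(
        rows, columns=["term", "n_target_term", "n_term", "n_target", "n_universe", "pvalue"]
    )
    if len(out):
        out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def investment_ratio(
    section_rpkm: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """GH:LOX transcriptional-investment summary per species and section.

    Sums section-mean RPKM over all GH genes and all LOX genes; the ratio
    of the sums measures how much transcription a fungus devotes to
    saccharification relative to oxidative chemistry.  A zero LOX sum
    leaves the ratio undefined (NaN), never infinite.
    """
    rows = []
    for sp, table in sorted(section_rpkm.items()):
        cls = annotation.loc[annotation.index.intersection(table.index), "func_class"]
        gh_genes = cls.index[cls == "GH"]
        lox_genes = cls.index[cls == "LOX"]
        for sec in SECTIONS:
            gh_sum = float(table.loc[gh_genes, sec].sum())
            lox_sum = float(table.loc[lox_genes, sec].sum())
            rows.append(
                {
                    "species": sp,
                    "section": sec,
                    "gh_rpkm": gh_sum,
                    "lox_rpkm": lox_sum,
                    "gh_lox_ratio": gh_sum / lox_sum if lox_sum > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows)


def family_expression_matrix(
    section_rpkm: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    classes: tuple[str, ...] = ("LOX", "GH"),
    log: bool = True,
) -> pd.DataFrame:
    """Family-summed RPKM per (species, section) observation.

    Rows are species_section observations, columns CAZY families restricted
    to the given classes; values are log2(x+1) of the summed section-mean
    RPKM (expression spans orders of magnitude).  Input matrix for the
    family-expression PCA.
    """
    rows = {}
    for sp, table in sorted(section_rpkm.items()):
        ann = annotation.loc[annotation.index.intersection(table.index)]
        keep = ann.index[ann["func_class"].isin(classes)]
        fams = ann.loc[keep, "family"]
        for sec in SECTIONS:
            summed = table.loc[keep, sec].groupby(fams).sum()
            rows[f"{sp}_{sec}"] = summed
    mat = pd.DataFrame(rows).T.fillna(0.0)
    if log:
        mat = np.log2(mat + 1.0)
    return mat


def pca(
    matrix: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-component analysis by SVD of the centred data.

    Returns (scores, loadings, explained-variance fractions).  Loadings are
    orthonormal columns; component variances are non-increasing and sum to
    the total variance of the centred data.  A constant matrix yields zero
    components.  Signs are fixed so each loading's largest-magnitude entry
    is positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two observations")
    centred = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s**2 / (x.shape[0] - 1)
    total = var.sum()
    keep = var > 1e-12 * max(total, 1.0)
    if n_components is not None:
        keep = keep & (np.arange(len(var)) < n_components)
    u, s, vt, var = u[:, keep], s[keep], vt[keep], var[keep]
    # deterministic sign convention
    signs = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)]) if len(s) else np.array([])
    vt = vt * signs[:, None] if len(s) else vt
    scores = (u * s) * signs if len(s) else np.zeros((x.shape[0], 0))
    explained = var / total if total > 0 else var
    return scores, vt.T, explained


def zscore_scale(matrix: pd.DataFrame, axis: int = 1) -> pd.DataFrame:
    """Z-score scaling with the sample standard deviation (ddof=1).

    axis=1 scales each row, axis=0 each column; constant vectors map to
    zeros (not NaN).
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    if axis == 1:
        centred = matrix.sub(matrix.mean(axis=1), axis=0)
        sd = matrix.std(axis=1, ddof=1)
        out = centred.div(sd.replace(0.0, np.nan), axis=0)
    else:
        centred = matrix.sub(matrix.mean(axis=0), axis=1)
        sd = matrix.std(axis=0, ddof=1)
        out = centred.div(sd.replace(0.0, np.nan), axis=1)
    return out.fillna(0.0)
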