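"""RPKM normalisation, expression evidence, and NB exact-test DEG calling.

Differential expression between wafer sections is tested with a
negative-binomial exact test with a common dispersion (the Robinson-Smyth
construction): replicate counts are scaled to a common library depth, the
per-gene test conditions on the total count across both groups, and the
two-sided p-value sums the probabilities of all splits no more likely than
the observed one.  The common dispersion phi (var = mu + phi*mu^2) is
estimated by maximising the conditional log-likelihood of within-group
counts given the group totals.  Genes are DEGs for a contrast when the
BH-adjusted FDR is < 0.05 and the fold change exceeds 4 (|log2FC| > 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from rotstage.synthdata import SECTIONS

#: the three section contrasts, oriented later minus earlier
CONTRASTS = (
    (SECTIONS[0], SECTIONS[1]),
    (SECTIONS[0], SECTIONS[2]),
    (SECTIONS[1], SECTIONS[2]),
)

LOG2FC_PSEUDOCOUNT = 0.5  # added to each scaled group mean


def contrast_name(earlier: str, later: str) -> str:
    return f"{later}_vs_{earlier}"


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM[g, s] = counts[g, s] * 1e9 / (length[g] * libsize[s]).  Library
    sizes default to column sums.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts.mul(1e9, axis=0).div(lengths, axis=0).div(library_sizes, axis=1)


def section_mean_rpkm(rpkm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean RPKM per section (columns ordered early -> late), averaging
    replicates.  ``design`` rows must cover every RPKM column."""
    missing = [c for c in rpkm.columns if c not in design.index]
    if missing:
        raise ValueError(f"samples absent from design: {missing[:3]}")
    section_of = design.loc[list(rpkm.columns), "section"]
    out = rpkm.T.groupby(section_of.values).mean().T
    absent = [s for s in SECTIONS if s not in out.columns]
    if absent:
        raise ValueError(f"no samples for section(s): {absent}")
    return out[list(SECTIONS)]


def expression_evidence(section_means: pd.DataFrame, threshold: float = 5.0) -> pd.Series:
    """Per-gene expression-evidence label.

    ``full`` if the section-mean RPKM exceeds the threshold in all three
    sections, ``partial`` if in one or two, ``none`` otherwise.
    """
    absent = [s for s in SECTIONS if s not in section_means.columns]
    if absent:
        raise ValueError(f"missing section(s): {absent}")
    n_above = (section_means[list(SECTIONS)] > threshold).sum(axis=1)
    return n_above.map(lambda k: "full" if k == 3 else ("none" if k == 0 else "partial"))


def scale_to_common_depth(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale columns to the geometric-mean library depth and round to
    integers (the conditional test requires integer counts)."""
    libsizes = counts.sum(axis=0).astype(float)
    if (libsizes <= 0).any():
        raise ValueError("cannot scale samples with zero total count")
    target = float(np.exp(np.log(libsizes).mean()))
    scaled = counts * (target / libsizes)
    return scaled.round().astype(np.int64)


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str
    n_genes: int
    n_groups: int


def _conditional_loglik(phi: float, counts: np.ndarray) -> float:
    """Summed conditional log-likelihood of replicate counts given their
    totals, for one group of n exchangeable NB samples per gene.

    counts: genes x n array (equal library depths assumed).
    """
    n = counts.shape[1]
    z = counts.sum(axis=1)
    r = 1.0 / phi
    ll = (
        gammaln(counts + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: list[list[str]],
    max_phi: float = 5.0,
) -> DispersionEstimate:
    """Common-dispersion estimate by conditional maximum likelihood.

    ``groups`` lists replicate sample ids per experimental group; groups
    with fewer than two replicates are ignored.  Counts are scaled to a
    common depth first so the conditional likelihood (which assumes equal
    depths) applies.  The estimate is clipped at zero: if the likelihood is
    maximised at the lower boundary the data show no overdispersion.
    """
    replicated = [g for g in groups if len(g) >= 2]
    if not replicated:
        raise ValueError("need at least one group with >= 2 replicates")
    scaled = scale_to_common_depth(counts)
    blocks = []
    for g in replicated:
        block = scaled[g].to_numpy(dtype=np.float64)
        block = block[block.sum(axis=1) > 0]  # all-zero genes carry no signal
        if len(block):
            blocks.append(block)
    if not blocks:
        raise ValueError("all genes have zero counts in every replicated group")

    def neg_ll(log_phi: float) -> float:
        phi = math.exp(log_phi)
        return -sum(_conditional_loglik(phi, b) for b in blocks)

    res = minimize_scalar(
        neg_ll, bounds=(math.log(1e-6), math.log(max_phi)), method="bounded",
        options={"xatol": 1e-6},
    )
    phi_hat = math.exp(res.x)
    # boundary check: Poisson-consistent data push the optimum to the floor
    if phi_hat < 5e-4 or neg_ll(math.log(1e-6)) <= res.fun:
        phi_hat = 0.0
    n_genes = int(sum(len(b) for b in blocks))
    return DispersionEstimate(phi=phi_hat, method="conditional-ml", n_genes=n_genes, n_groups=len(blocks))


def nb_exact_test(
    y1: np.ndarray,
    y2: np.ndarray,
    phi: float,
) -> tuple[float, float]:
    """Exact two-group NB test for one gene on depth-scaled integer counts.

    Conditions on the total t = sum(y1) + sum(y2): the group-1 total follows
    a (negative-)hypergeometric-type distribution over splits of t, free of
    the mean parameter.  The two-sided p-value sums the probabilities of all
    splits whose probability does not exceed that of the observed split.
    phi = 0 reduces to the binomial (Poisson-limit) split.  Returns
    (p-value, log2FC) with log2FC oriented group 2 over group 1 and
    pseudocounted group means.
    """
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    if (y1 < 0).any() or (y2 < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    s1, s2 = int(y1.sum()), int(y2.sum())
    m1 = s1 / len(y1)
    m2 = s2 / len(y2)
    log2fc = math.log2((m2 + LOG2FC_PSEUDOCOUNT) / (m1 + LOG2FC_PSEUDOCOUNT))
    t = s1 + s2
    if t == 0:
        return 1.0, 0.0

    y = np.arange(t + 1)
    if phi == 0:
        frac = len(y1) / (len(y1) + len(y2))
        logp = (
            gammaln(t + 1) - gammaln(y + 1) - gammaln(t - y + 1)
            + y * math.log(frac) + (t - y) * math.log1p(-frac)
        )
    else:
        r1 = len(y1) / phi
        r2 = len(y2) / phi
        logp = (
            gammaln(y + r1) - gammaln(y + 1)
            + gammaln(t - y + r2) - gammaln(t - y + 1)
        )
        logp -= logsumexp(logp)
    p = float(np.exp(logsumexp(logp[logp <= logp[s1] + 1e-10])))
    return min(p, 1.0), log2fc


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(
    de: pd.DataFrame,
    fc_threshold: float = 4.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Attach DEG directions: '+' / '-' by sign of log2FC when the gene
    passes FDR < threshold and |log2FC| > log2(fc_threshold), else '0'."""
    log2_cut = math.log2(fc_threshold)
    out = de.copy()
    sig = (out["fdr"] < fdr_threshold) & (out["log2fc"].abs() > log2_cut)
    out["direction"] = "0"
    out.loc[sig & (out["log2fc"] > 0), "direction"] = "+"
    out.loc[sig & (out["log2fc"] < 0), "direction"] = "-"
    return out


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    phi: float | None = None,
    fc_threshold: float = 4.0,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, DispersionEstimate | None]:
    """Full DE analysis for one species' count matrix.

    Tests the three section contrasts (later vs earlier), with counts scaled
    to a common depth, BH correction per contrast, and DEG direction calls.
    If ``phi`` is None the common dispersion is estimated from the section
    replicate groups first.
    """
    design = design.loc[list(counts.columns)]
    groups = {s: list(design.index[design["section"] == s]) for s in SECTIONS}
    empty = [s for s, g in groups.items() if not g]
    if empty:
        raise ValueError(f"no samples for section(s): {empty}")

    estimate = None
    if phi is None:
        estimate = estimate_common_dispersion(counts, list(groups.values()))
        phi = estimate.phi

    scaled = scale_to_common_depth(counts)
    frames = []
    for earlier, later in CONTRASTS:
        a = scaled[groups[earlier]].to_numpy()
        b = scaled[groups[later]].to_numpy()
        pvals = np.empty(len(scaled))
        lfcs = np.empty(len(scaled))
        for i in range(len(scaled)):
            pvals[i], lfcs[i] = nb_exact_test(a[i], b[i], phi)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": scaled.index,
                    "contrast": contrast_name(earlier, later),
                    "log2fc": lfcs,
                    "pvalue": pvals,
                    "fdr": bh_fdr(pvals),
                }
            )
        )
    de = pd.concat(frames, ignore_index=True)
    return call_degs(de, fc_threshold, fdr_threshold), estimate
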