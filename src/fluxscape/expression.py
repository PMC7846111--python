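"""Downstream RNA-seq statistics, starting from a counts matrix.

Implements the post-alignment stages: TPM normalization with the log2(TPM+1)
transform, replicate quality control, phenotype-correlated gene selection
(correlated with acetate secretion and biomass yield but not with growth
rate), exact one-sided binomial gene-set enrichment, and average-linkage
hierarchical clustering on correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import InputError

__all__ = [
    "ExpressionMatrix",
    "GeneSetAnnotation",
    "counts_to_logtpm",
    "replicate_qc",
    "select_phenotype_genes",
    "binomial_enrichment",
    "hierarchical_cluster",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with per-gene effective lengths and per-sample
    phenotype annotations (mu, Y, q_glc, q_o2, q_ac)."""

    counts: pd.DataFrame  # genes x samples, non-negative
    lengths: pd.Series  # per-gene effective length, bp
    annotations: pd.DataFrame  # samples x phenotype columns

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        if (self.lengths <= 0).any():
            raise InputError("gene lengths must be positive")
        if not self.counts.index.equals(self.lengths.index):
            raise InputError("counts and lengths must share the gene index")


@dataclass
class GeneSetAnnotation:
    """Pathway label -> set of gene ids, drawn from the matrix universe."""

    sets: dict[str, set[str]]

    def validate_against(self, universe) -> None:
        u = set(universe)
        for label, genes in self.sets.items():
            missing = genes - u
            if missing:
                raise InputError(
                    f"gene set {label!r} references genes outside the "
                    f"matrix universe: {sorted(missing)[:5]}"
                )


def counts_to_logtpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million normalization followed by log2(TPM + 1).

    TPM_g = 1e6 * (count_g / length_g) / sum_g' (count_g' / length_g').
    """
    if not counts.index.equals(lengths.index):
        lengths = lengths.reindex(counts.index)
        if lengths.isna().any():
            raise InputError("missing gene length for some genes")
    zero_samples = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero_samples):
        raise InputError(f"all-zero sample(s): {list(zero_samples)}")
    rate = counts.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return np.log2(tpm + 1.0)


def replicate_qc(logtpm: pd.DataFrame, pairs) -> pd.Series:
    """Squared Pearson correlation of log-TPM profiles per replicate pair."""
    out = {}
    for a, b in pairs:
        if a not in logtpm.columns or b not in logtpm.columns:
            raise InputError(f"replicate pair ({a}, {b}) references unknown samples")
        x, y = logtpm[a].to_numpy(), logtpm[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise InputError(f"constant profile in pair ({a}, {b})")
        r = stats.pearsonr(x, y).statistic
        out[f"{a}|{b}"] = float(r * r)
    return pd.Series(out, name="R2")


def select_phenotype_genes(
    logtpm: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha: float = 0.01,
) -> tuple[set[str], pd.DataFrame]:
    """Select aero-type-representative genes.

    A gene is selected when its log-TPM profile correlates with both the
    acetate production rate and the biomass yield (Pearson p < alpha) but not
    with the growth rate (p >= alpha).  Returns the gene set and a per-gene
    report of the three correlations.
    """
    samples = [s for s in logtpm.columns if s in annotations.index]
    if len(samples) < 4:
        raise InputError("need >= 4 annotated samples for gene selection")
    ann = annotations.loc[samples]
    X = logtpm[samples]
    rows = []
    selected = set()
    targets = {
        "q_ac": ann["q_ac"].to_numpy(float),
        "Y": ann["Y"].to_numpy(float),
        "mu": ann["mu"].to_numpy(float),
    }
    for gene, profile in X.iterrows():
        x = profile.to_numpy(float)
        rec = {"gene": gene}
        if np.std(x) == 0:
            rec.update({f"p_{k}": 1.0 for k in targets})
            rec.update({f"r_{k}": 0.0 for k in targets})
        else:
            for k, t in targets.items():
                r, p = stats.pearsonr(x, t)
                rec[f"r_{k}"] = float(r)
                rec[f"p_{k}"] = float(p)
        ok = (
            rec["p_q_ac"] < alpha
            and rec["p_Y"] < alpha
            and rec["p_mu"] >= alpha
        )
        rec["selected"] = ok
        if ok:
            selected.add(gene)
        rows.append(rec)
    return selected, pd.DataFrame(rows).set_index("gene")


def binomial_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Exact one-sided (upper tail) binomial enrichment p-value.

    P(X >= k) with X ~ Binomial(n, K/N): ``k`` selected genes inside a set of
    size ``n``, given ``K`` selected among ``N`` profiled genes.
    """
    if not (0 <= k <= n):
        raise InputError("need 0 <= k <= n")
    if not (0 < K <= N):
        raise InputError("need 0 < K <= N")
    return float(stats.binom.sf(k - 1, n, K / N))


def hierarchical_cluster(
    logtpm: pd.DataFrame,
    genes=None,
    n_clusters: int | None = None,
):
    """Average-linkage clustering of samples on 1 - Pearson distance over a
    gene subset.  Returns (linkage matrix, sample order, flat labels or None).

    Samples are taken in sorted-id order before linkage so that ties in the
    distance matrix resolve deterministically.
    """
    sub = logtpm.loc[list(genes)] if genes is not None else logtpm
    samples = sorted(sub.columns)
    sub = sub[samples]
    if len(samples) < 1:
        raise InputError("no samples to cluster")
    X = sub.to_numpy(float).T
    if len(samples) == 1:
        return np.empty((0, 4)), samples, (np.array([1]) if n_clusters else None)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [samples[i] for i in np.flatnonzero(sd == 0)]
        raise InputError(f"constant sample profile(s): {bad}")
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, samples, labels
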