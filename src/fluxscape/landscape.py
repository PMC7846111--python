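"""Landscape statistics: mixture fitting of f_ATPS, aero-type assignment,
stepwise variance decomposition, flux PCA, proteome-complexity metrics and
the feasibility envelope of the rate-yield plane."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .model import FluxSolution, InputError, ModelSpec

__all__ = [
    "MixtureFit",
    "ComplexityMetrics",
    "RegressionReport",
    "FitError",
    "AEROTYPE_LABELS",
    "NITROTYPE_LABELS",
    "fit_fatps_mixture",
    "mixture_bic_table",
    "preferred_component_count",
    "assign_aerotype",
    "annotate_aerotypes",
    "stepwise_regression",
    "proteome_complexity",
    "flux_pca",
    "feasibility_envelope",
]

ZERO_PEAK_THRESHOLD = 0.02  # f_ATPS below this counts as the fermentative point mass

AEROTYPE_LABELS = ("i", "ii", "iii", "iv", "v")
#: under nitrate: the fermentative point mass plus three nitrate-respiring modes
NITROTYPE_LABELS = ("ferm", "i", "ii", "iii")


class FitError(RuntimeError):
    """Mixture fit impossible (too few values or no converged restart)."""


@dataclass
class MixtureFit:
    """A zero point mass plus a Gaussian mixture over the non-zero values,
    components sorted by ascending mean."""

    zero_peak_weight: float
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]  # scaled so zero peak + components sum to 1
    loglik: float
    converged: bool
    n_used: int
    zero_threshold: float = ZERO_PEAK_THRESHOLD

    @property
    def n_components(self) -> int:
        return len(self.means)

    def to_dict(self) -> dict:
        return {
            "zero_peak_weight": self.zero_peak_weight,
            "components": [
                {"mean": m, "sd": s, "weight": w}
                for m, s, w in zip(self.means, self.sds, self.weights)
            ],
            "loglik": self.loglik,
            "converged": self.converged,
            "n_used": self.n_used,
            "zero_threshold": self.zero_threshold,
        }


@dataclass(frozen=True)
class ComplexityMetrics:
    """Proteome complexity of one optimal solution."""

    n_genes_expressed: int
    avg_subunits: float


@dataclass
class RegressionReport:
    """Forward-selection summary: predictors in selection order with the
    cumulative fraction of variance explained after each addition."""

    selected: list[str]
    cumulative_r2: list[float]
    final_r2: float
    warnings: list[str] = field(default_factory=list)


def fit_fatps_mixture(
    values,
    n_components: int = 4,
    zero_threshold: float = ZERO_PEAK_THRESHOLD,
    n_restarts: int = 50,
    min_nonzero: int = 50,
) -> MixtureFit:
    """Fit the multimodal f_ATPS distribution.

    Values below ``zero_threshold`` are assigned to the fermentative point
    mass; the remainder is fitted with ``n_components`` Gaussians by EM with
    k-means-seeded deterministic restarts, keeping the best log-likelihood.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise InputError("expected a non-empty 1-D sequence of fractions")
    if np.any((v < -1e-9) | (v > 1 + 1e-9)):
        raise InputError("f_ATPS values must lie in [0, 1]")
    zero_mask = v < zero_threshold
    zw = float(np.mean(zero_mask))
    rest = v[~zero_mask]
    if len(rest) == 0:
        return MixtureFit(1.0, (), (), (), 0.0, True, 0, zero_threshold)
    if len(rest) < min_nonzero:
        raise FitError(
            f"{len(rest)} non-zero-peak values; need >= {min_nonzero} for a "
            f"{n_components}-component fit"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=n_restarts,
        init_params="kmeans",
        random_state=0,
        reg_covar=1e-8,
        max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(rest.reshape(-1, 1))
    if not gm.converged_:
        raise FitError("no EM restart converged")
    order = np.argsort(gm.means_.ravel(), kind="stable")
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(c)) for c in gm.covariances_.ravel()[order])
    comp_w = gm.weights_[order] * (1.0 - zw)
    return MixtureFit(
        zero_peak_weight=zw,
        means=means,
        sds=sds,
        weights=tuple(float(w) for w in comp_w),
        loglik=float(gm.score(rest.reshape(-1, 1)) * len(rest)),
        converged=bool(gm.converged_),
        n_used=len(rest),
        zero_threshold=zero_threshold,
    )


def mixture_bic_table(
    values, max_components: int = 5, zero_threshold: float = ZERO_PEAK_THRESHOLD
) -> dict[int, float]:
    """BIC of k-component Gaussian fits (k = 1..max) over the non-zero part."""
    v = np.asarray(values, dtype=float)
    rest = v[v >= zero_threshold].reshape(-1, 1)
    out: dict[int, float] = {}
    for k in range(1, max_components + 1):
        if len(rest) < max(10, 5 * k):
            break
        gm = GaussianMixture(
            n_components=k, n_init=10, init_params="kmeans", random_state=0,
            reg_covar=1e-8, max_iter=500,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(rest)
        out[k] = float(gm.bic(rest))
    return out


def preferred_component_count(values, max_components: int = 5) -> int:
    """Number of non-zero Gaussian components preferred by BIC."""
    table = mixture_bic_table(values, max_components)
    if not table:
        return 0
    return min(table, key=table.get)


def component_silhouette(values, fit: MixtureFit) -> float:
    """Silhouette of the hard (maximum-posterior) component assignment over
    the non-zero values; quantifies how separated the fitted modes are."""
    from sklearn.metrics import silhouette_score

    v = np.asarray(values, dtype=float)
    v = v[v >= fit.zero_threshold]
    if fit.n_components < 2 or len(v) < 3:
        raise InputError("need >= 2 components and >= 3 values")
    post = np.array(
        [
            w * stats.norm.pdf(v, m, s)
            for m, s, w in zip(fit.means, fit.sds, fit.weights)
        ]
    )
    labels = np.argmax(post, axis=0)
    if len(np.unique(labels)) < 2:
        return 0.0
    return float(silhouette_score(v.reshape(-1, 1), labels))


def assign_aerotype(
    f_atps: float, fit: MixtureFit, labels: tuple[str, ...] = AEROTYPE_LABELS
) -> str:
    """Label a solution by its f_ATPS mode.

    Zero-peak values take the first label; otherwise the maximum-posterior
    Gaussian component, mapped in mean order to the remaining labels, with
    posterior ties broken toward the lower label.
    """
    if not (0.0 <= f_atps <= 1.0):
        raise InputError(f"f_ATPS {f_atps} outside [0, 1]")
    if len(labels) != fit.n_components + 1:
        raise InputError(
            f"{len(labels)} labels for {fit.n_components} components + zero peak"
        )
    if f_atps < fit.zero_threshold or fit.n_components == 0:
        return labels[0]
    post = np.array(
        [
            w * stats.norm.pdf(f_atps, m, s)
            for m, s, w in zip(fit.means, fit.sds, fit.weights)
        ]
    )
    best = int(np.argmax(post))  # argmax returns the first (lowest) maximum
    return labels[best + 1]


def annotate_aerotypes(
    table: pd.DataFrame,
    fit: MixtureFit | None = None,
    labels: tuple[str, ...] = AEROTYPE_LABELS,
) -> tuple[pd.DataFrame, MixtureFit]:
    """Fit (unless given) and write the aero-type column of a sample table."""
    feas = table[table["feasible"].astype(bool)]
    if fit is None:
        fit = fit_fatps_mixture(feas["f_ATPS"].to_numpy(), n_components=len(labels) - 1)
    out = table.copy()
    out["aerotype"] = [
        assign_aerotype(f, fit, labels) if ok else ""
        for f, ok in zip(out["f_ATPS"], out["feasible"].astype(bool))
    ]
    return out, fit


def stepwise_regression(
    predictors: pd.DataFrame, response, alpha: float = 0.05
) -> RegressionReport:
    """Forward stepwise linear regression on the ATP-production fractions.

    At each step the candidate with the smallest partial-F p-value below
    ``alpha`` enters; selection stops when no candidate qualifies.
    """
    X = predictors.astype(float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n < 30:
        raise InputError("need >= 30 rows for the stepwise regression")
    if X.shape[0] != n:
        raise InputError("predictors and response length mismatch")
    tss = float(np.sum((y - y.mean()) ** 2))
    selected: list[str] = []
    warnings_: list[str] = []
    cum_r2: list[float] = []

    def rss_of(cols: list[str]) -> float:
        A = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])
        coef, residuals, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ coef
        return float(np.sum((y - fitted) ** 2))

    rss_cur = tss
    remaining = list(X.columns)
    while remaining:
        best = None
        for c in remaining:
            cols = selected + [c]
            A = np.column_stack([np.ones(n)] + [X[k].to_numpy() for k in cols])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                warnings_.append(f"{c}: rank-deficient design, skipped")
                continue
            rss_new = rss_of(cols)
            df2 = n - len(cols) - 1
            if df2 <= 0:
                continue
            f_stat = max(0.0, (rss_cur - rss_new)) / max(rss_new / df2, 1e-300)
            p = float(stats.f.sf(f_stat, 1, df2))
            if best is None or p < best[0]:
                best = (p, c, rss_new)
        if best is None or best[0] >= alpha:
            break
        _, chosen, rss_cur = best
        selected.append(chosen)
        remaining.remove(chosen)
        cum_r2.append(1.0 - rss_cur / tss if tss > 0 else 0.0)
    final = cum_r2[-1] if cum_r2 else 0.0
    return RegressionReport(selected, cum_r2, final, warnings_)


EXPRESSION_PHI_THRESHOLD = 1e-6


def proteome_complexity(solution: FluxSolution, model: ModelSpec) -> ComplexityMetrics:
    """Count the genes behind expressed enzymes and their mean subunit number.

    An enzyme is expressed when its proteome mass fraction exceeds 1e-6;
    with nothing expressed both metrics report 0.
    """
    expressed = [
        model.enzyme(eid)
        for eid, phi in solution.enzyme_phi.items()
        if phi > EXPRESSION_PHI_THRESHOLD
    ]
    if not expressed:
        return ComplexityMetrics(0, 0.0)
    genes = set()
    for e in expressed:
        genes.update(e.gene_ids)
    avg = float(np.mean([e.n_subunits for e in expressed]))
    return ComplexityMetrics(len(genes), avg)


#: central-metabolism reactions used for the flux PCA
CENTRAL_REACTIONS = [
    "GLCpts", "GLYCU", "GAPD", "PGK", "ENO", "PYK", "OXPPP", "TKT", "PDH",
    "CITICD", "AKGDH", "SUCOAS", "SUCD", "FUMMDH", "PPC", "PTA", "ACKr",
    "NADH_NUO", "NADH_NDH", "CYO", "CYD", "ATPS4rpp",
]


def flux_pca(flux_table: pd.DataFrame, reactions: list[str] | None = None):
    """PCA on column-standardized fluxes of the central-metabolism reactions.

    Zero-variance columns are dropped with a warning.  Returns (loadings
    DataFrame indexed by reaction, explained-variance fractions, scores).
    """
    cols = reactions if reactions is not None else [
        c for c in CENTRAL_REACTIONS if c in flux_table.columns
    ]
    X = flux_table[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise InputError("need >= 3 samples for PCA")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"zero-variance columns dropped: {dropped}")
    cols = [c for c, k in zip(cols, keep) if k]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=cols,
        columns=[f"PC{i + 1}" for i in range(pca.components_.shape[0])],
    )
    return loadings, pca.explained_variance_ratio_, scores


FATPS_RANGE_FOR_ENVELOPE = (0.0, 0.83)


def feasibility_envelope(
    tables: dict[float, pd.DataFrame],
    f_range: tuple[float, float] = FATPS_RANGE_FOR_ENVELOPE,
    min_points: int = 5,
) -> pd.DataFrame:
    """Estimate the feasible rate-yield region from fixed-growth-rate samples.

    Per growth-rate isocline, Y and q_glc are regressed linearly on f_ATPS
    and evaluated at the minimum and maximum attainable fractions, giving
    four corner points; isoclines with fewer than ``min_points`` feasible
    samples are skipped with a warning.
    """
    if len(tables) < 2:
        raise InputError("need fixed-rate tables at >= 2 growth rates")
    rows = []
    for mu, df in sorted(tables.items()):
        feas = df[df["feasible"].astype(bool)]
        if len(feas) < min_points:
            warnings.warn(f"isocline mu={mu}: only {len(feas)} points, skipped")
            continue
        f = feas["f_ATPS"].to_numpy()
        slope_y, icpt_y = np.polyfit(f, feas["Y"].to_numpy(), 1)
        slope_q, icpt_q = np.polyfit(f, feas["q_glc"].to_numpy(), 1)
        f0, f1 = f_range
        rows.append(
            {
                "mu": mu,
                "slope_Y": slope_y,
                "slope_q": slope_q,
                "Y_at_fmin": icpt_y + slope_y * f0,
                "Y_at_fmax": icpt_y + slope_y * f1,
                "q_at_fmin": icpt_q + slope_q * f0,
                "q_at_fmax": icpt_q + slope_q * f1,
            }
        )
    return pd.DataFrame(rows)
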