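"""Count models: ZINB marginals coupled by a Gaussian copula.

Each gene in each cell type is fitted with a zero-inflated negative binomial
(ZINB) distribution parameterized by the structural-zero probability pi, the
mean count m, and the overdispersion r (variance = m + m^2 / r).  When a
component is unidentifiable the fit falls back along ZINB -> NB -> ZIP ->
Poisson, choosing the best-supported family by BIC among the identifiable
candidates.

Gene-gene dependence is modeled with a Gaussian copula: latent scores
Z_i ~ N(0, Sigma) are mapped through U = Phi(Z) and the per-gene quantile
function Y_g = F_g^{-1}(U_g), which preserves each marginal exactly while
inducing the latent correlation.  Fitting inverts this map with the
randomized distributional transform (a seeded uniform draw spreads each
discrete count across its CDF step), giving unbiased latent correlations for
heavily tied count data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp, ndtr, ndtri
from statsmodels.stats.correlation_tools import corr_nearest

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE_CAP = 2500

_DISP_CAP = 1e6  # dispersion above this is numerically Poisson
_EPS = 1e-12


@dataclass(frozen=True)
class GeneMarginal:
    """ZINB family marginal for one gene: P(0) inflated NB(mean, dispersion).

    ``family`` records which components were identifiable: "zinb", "nb"
    (pi = 0), "zip" (no overdispersion), or "poisson".
    """

    pi: float
    mean: float
    dispersion: float
    family: str = "zinb"

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.mean < 0 or self.dispersion <= 0:
            raise ValueError("mean must be >= 0 and dispersion > 0")

    # -- negative binomial component ------------------------------------
    def _nb(self, mean: float | None = None):
        m = self.mean if mean is None else mean
        r = self.dispersion
        if not np.isfinite(r) or r >= _DISP_CAP:
            return stats.poisson(max(m, _EPS))
        return stats.nbinom(r, r / (r + max(m, _EPS)))

    def cdf(self, y, depth_factor: float = 1.0):
        comp = self._nb(self.mean * depth_factor)
        y = np.asarray(y, dtype=float)
        out = self.pi * (y >= 0) + (1 - self.pi) * comp.cdf(y)
        return out

    def pmf(self, y, depth_factor: float = 1.0):
        comp = self._nb(self.mean * depth_factor)
        y = np.asarray(y, dtype=float)
        return np.where(y == 0, self.pi, 0.0) + (1 - self.pi) * comp.pmf(y)

    def ppf(self, u, depth_factor: float = 1.0):
        """Quantile function; u below the zero-inflation mass maps to 0."""
        comp = self._nb(self.mean * depth_factor)
        u = np.asarray(u, dtype=float)
        if self.pi >= 1.0:
            return np.zeros_like(u)
        q = np.clip((u - self.pi) / (1.0 - self.pi), 0.0, 1.0 - _EPS)
        # discrete ppf(0) is -1 by convention; the zero-inflation mass maps to 0
        return np.maximum(comp.ppf(q), 0.0)

    def theoretical_moments(self, depth_factor: float = 1.0) -> dict:
        """Mean, variance, and zero fraction implied by the parameters."""
        m = self.mean * depth_factor
        r = self.dispersion
        nb_var = m + (0.0 if not np.isfinite(r) or r >= _DISP_CAP else m * m / r)
        mean = (1 - self.pi) * m
        var = (1 - self.pi) * (nb_var + m * m) - mean * mean
        zero = self.pi + (1 - self.pi) * float(self._nb(m).pmf(0))
        return {"mean": mean, "var": var, "zero_fraction": zero}


def _zinb_nll(theta: np.ndarray, y: np.ndarray, zero_inflated: bool, overdispersed: bool) -> float:
    """Negative log-likelihood over the (logit pi, log mean, log r) chart."""
    k = 0
    if zero_inflated:
        pi = 1.0 / (1.0 + np.exp(-theta[k]))
        k += 1
    else:
        pi = 0.0
    m = np.exp(theta[k])
    k += 1
    if overdispersed:
        r = np.exp(theta[k])
        comp_log0 = stats.nbinom.logpmf(0, r, r / (r + m))
        comp_logpmf = stats.nbinom.logpmf(y, r, r / (r + m))
    else:
        comp_log0 = stats.poisson.logpmf(0, m)
        comp_logpmf = stats.poisson.logpmf(y, m)
    log1mpi = np.log1p(-min(pi, 1 - _EPS))
    ll_pos = log1mpi + comp_logpmf
    if zero_inflated:
        log_pi = np.log(max(pi, _EPS))
        ll_zero = np.logaddexp(log_pi, log1mpi + comp_log0)
    else:
        ll_zero = ll_pos  # comp_logpmf already handles zeros
    ll = np.where(y == 0, ll_zero, ll_pos)
    return -float(np.sum(ll))


def _fit_family(y: np.ndarray, zero_inflated: bool, overdispersed: bool):
    """MLE for one family; returns (pi, mean, dispersion, nll, n_params)."""
    m0 = max(y.mean(), 0.05)
    v0 = max(y.var(), m0 * 1.01)
    r0 = np.clip(m0 * m0 / max(v0 - m0, m0 / 10), 1e-2, 1e3)
    zero_frac = float(np.mean(y == 0))
    theta0 = []
    if zero_inflated:
        pi0 = np.clip(zero_frac * 0.5 + 0.05, 0.02, 0.9)
        theta0.append(np.log(pi0 / (1 - pi0)))
        m0 = max(y.mean() / max(1 - pi0, 0.1), 0.05)
    theta0.append(np.log(m0))
    if overdispersed:
        theta0.append(np.log(r0))
    res = optimize.minimize(
        _zinb_nll,
        np.array(theta0),
        args=(y, zero_inflated, overdispersed),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    theta = res.x
    k = 0
    if zero_inflated:
        pi = float(1.0 / (1.0 + np.exp(-theta[k])))
        k += 1
    else:
        pi = 0.0
    mean = float(np.exp(theta[k]))
    k += 1
    disp = float(np.exp(theta[k])) if overdispersed else np.inf
    return pi, mean, disp, float(res.fun), len(theta0)


def fit_marginal(counts: np.ndarray) -> GeneMarginal:
    """Maximum-likelihood ZINB fit for one gene with a fallback ladder.

    All-zero genes collapse to a degenerate distribution (pi = 1).  Genes
    without zeros cannot identify pi, so only NB and Poisson are considered;
    otherwise ZINB, NB, ZIP, and Poisson are fitted and compared by BIC.
    Dispersion estimates at the Poisson boundary are reported as the
    zero-inflation-only family.
    """
    y = np.asarray(counts, dtype=float)
    if y.size == 0:
        raise ValueError("empty count vector")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if np.all(y == 0):
        return GeneMarginal(pi=1.0, mean=_EPS, dispersion=1.0, family="zinb")
    has_zeros = bool(np.any(y == 0))
    candidates = {}
    fams = [("nb", False, True), ("poisson", False, False)]
    if has_zeros:
        fams = [("zinb", True, True), ("zip", True, False)] + fams
    for name, zi, od in fams:
        try:
            pi, mean, disp, nll, k = _fit_family(y, zi, od)
        except Exception as exc:  # pragma: no cover - optimizer failure
            logger.warning("fit of %s family failed: %s", name, exc)
            continue
        if not np.isfinite(nll):
            continue
        bic = 2 * nll + k * np.log(y.size)
        candidates[name] = (bic, pi, mean, disp)
    if not candidates:
        raise RuntimeError("no marginal family could be fitted")
    name, (bic, pi, mean, disp) = min(candidates.items(), key=lambda kv: kv[1][0])
    if name in ("zinb", "zip") and pi < 1e-4:
        name = "nb" if name == "zinb" else "poisson"
        pi = 0.0
    if name in ("zinb", "nb") and disp >= _DISP_CAP:
        name = "zip" if name == "zinb" else "poisson"
        disp = np.inf
    return GeneMarginal(pi=pi, mean=mean, dispersion=disp if np.isfinite(disp) else _DISP_CAP * 10, family=name)


def _conditional_mean_scores(marg: GeneMarginal, y: np.ndarray) -> tuple[np.ndarray, float]:
    """E[z | y] under the fitted marginal and its theoretical variance.

    For a latent z ~ N(0, 1) mapped to the count y through the copula,
    E[z | y] = (phi(l) - phi(u)) / (F(y) - F(y-1)) with l, u the normal
    quantiles of the CDF interval of y.  Its variance
    lambda^2 = sum_y P(y) E[z|y]^2 < 1 quantifies how much of the latent
    scale the discrete counts retain.
    """
    from scipy.stats import norm

    lo = np.clip(marg.cdf(y - 1), _EPS, 1 - _EPS)
    hi = np.clip(marg.cdf(y), _EPS, 1 - _EPS)
    p = np.maximum(hi - lo, 1e-300)
    m = (norm.pdf(ndtri(lo)) - norm.pdf(ndtri(hi))) / p
    support = np.arange(0, int(marg.ppf(1 - 1e-8)) + 2)
    lo_t = np.clip(marg.cdf(support - 1), _EPS, 1 - _EPS)
    hi_t = np.clip(marg.cdf(support), _EPS, 1 - _EPS)
    p_t = np.maximum(hi_t - lo_t, 1e-300)
    m_t = (norm.pdf(ndtri(lo_t)) - norm.pdf(ndtri(hi_t))) / p_t
    lam2 = float(np.sum(p_t * m_t**2))
    return m, lam2


def fit_copula_correlation(
    counts: np.ndarray,
    marginals: list[GeneMarginal],
    seed: int | None = None,
    method: str = "conditional_mean",
) -> np.ndarray:
    """Latent Gaussian correlation behind the observed counts.

    The default estimator uses conditional-mean scores: each count is
    replaced by E[z | y] under its fitted marginal and the pairwise latent
    correlation is estimated as E[m_g m_h] / (lambda_g^2 lambda_h^2), which
    corrects the attenuation that discreteness (ties, zero inflation) would
    otherwise introduce.  ``method="randomized"`` instead applies the seeded
    randomized distributional transform (u = F(y-1) + V * pmf(y),
    z = Phi^{-1}(u)) and returns the plain score correlation; it is simpler
    but biased toward zero for coarse counts.  Constant genes get an
    identity row/column; an indefinite estimate is projected to the nearest
    correlation matrix.
    """
    counts = np.asarray(counts, dtype=float)
    G, n = counts.shape
    if G < 2 or n < 3:
        raise ValueError("need >= 2 genes and >= 3 cells")
    if len(marginals) != G:
        raise ValueError("one marginal per gene required")
    constant = np.array([np.all(counts[g] == counts[g][0]) for g in range(G)])
    if constant.any():
        logger.warning("%d constant gene(s); correlation rows set to identity", int(constant.sum()))
    if method == "randomized":
        rng = np.random.default_rng(seed)
        Z = np.zeros((G, n))
        for g, marg in enumerate(marginals):
            if constant[g]:
                continue
            V = rng.random(n)
            u = np.clip(marg.cdf(counts[g] - 1) + V * marg.pmf(counts[g]), _EPS, 1 - _EPS)
            Z[g] = ndtri(u)
        R = np.corrcoef(Z)
    elif method == "conditional_mean":
        M = np.zeros((G, n))
        lam2 = np.ones(G)
        for g, marg in enumerate(marginals):
            if constant[g]:
                continue
            M[g], lam2[g] = _conditional_mean_scores(marg, counts[g])
        cross = (M - M.mean(axis=1, keepdims=True)) @ (M - M.mean(axis=1, keepdims=True)).T / n
        R = cross / np.outer(lam2, lam2)
        R = np.clip(R, -0.999, 0.999)
    else:
        raise ValueError(f"unknown copula estimator {method!r}")
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R).min() < -1e-10:
        logger.warning("indefinite score correlation; projecting to nearest PSD correlation")
        R = np.asarray(corr_nearest(R, threshold=1e-12))
        np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def subsample_cells(
    cells,
    cap: int = DEFAULT_SUBSAMPLE_CAP,
    seed: int | None = None,
) -> np.ndarray:
    """Representative subset for model fitting: per (cell type, region)
    stratum a uniform sample of at most ``cap`` cells.  Returns positional
    indices into ``cells`` (a DataFrame with a cell_type column and an
    optional region column)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    ct = np.asarray(cells["cell_type"])
    reg = np.asarray(cells["region"]) if "region" in cells else np.zeros(len(ct))
    keys = np.array([f"{a}\x00{b}" for a, b in zip(ct, reg)])
    keep = []
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(np.sort(idx))
    return np.sort(np.concatenate(keep))


@dataclass
class CellTypeExpressionModel:
    """Per-cell-type (optionally per-region) count model for all genes."""

    cell_type: str
    gene_names: list
    marginals: list
    sigma: np.ndarray | None = None
    region: object | None = None

    def __post_init__(self):
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != (len(self.marginals), len(self.marginals)):
                raise ValueError("sigma must be G x G")
            if not np.allclose(np.diag(self.sigma), 1.0, atol=1e-8):
                raise ValueError("sigma must have a unit diagonal")

    def save(self, path) -> None:
        import pathlib

        p = pathlib.Path(path)
        p.mkdir(parents=True, exist_ok=True)
        meta = {
            "cell_type": self.cell_type,
            "region": None if self.region is None else str(self.region),
            "gene_names": list(map(str, self.gene_names)),
            "marginals": [asdict(m) for m in self.marginals],
            "has_sigma": self.sigma is not None,
        }
        (p / "model.json").write_text(json.dumps(meta))
        if self.sigma is not None:
            np.savetxt(p / "sigma.tsv", self.sigma, delimiter="\t")

    @classmethod
    def load(cls, path) -> "CellTypeExpressionModel":
        import pathlib

        p = pathlib.Path(path)
        meta = json.loads((p / "model.json").read_text())
        sigma = np.loadtxt(p / "sigma.tsv", delimiter="\t") if meta["has_sigma"] else None
        return cls(
            cell_type=meta["cell_type"],
            region=meta["region"],
            gene_names=meta["gene_names"],
            marginals=[GeneMarginal(**m) for m in meta["marginals"]],
            sigma=sigma,
        )


def fit_expression_model(
    counts: np.ndarray,
    gene_names: list,
    cell_type: str = "",
    region: object | None = None,
    use_correlation: bool = True,
    seed: int | None = None,
) -> CellTypeExpressionModel:
    """Fit marginals (and, optionally, the copula correlation) for one stratum."""
    counts = np.asarray(counts)
    marginals = [fit_marginal(counts[g]) for g in range(counts.shape[0])]
    sigma = None
    if use_correlation and counts.shape[0] >= 2 and counts.shape[1] >= 3:
        sigma = fit_copula_correlation(counts, marginals, seed=seed)
    return CellTypeExpressionModel(
        cell_type=cell_type, region=region, gene_names=list(gene_names),
        marginals=marginals, sigma=sigma,
    )


def draw_counts(
    model: CellTypeExpressionModel,
    n_cells: int,
    depth_factor: float = 1.0,
    use_correlation: bool = True,
    seed: int | None = None,
) -> np.ndarray:
    """Draw a gene x cell integer matrix from the fitted model.

    Latent scores are multivariate normal with the fitted correlation (or
    independent), mapped through the Gaussian copula to per-gene ZINB
    quantiles.  ``depth_factor`` rescales every NB mean (zero inflation
    untouched), emulating a shallower or deeper sequencing run.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if depth_factor <= 0:
        raise ValueError("depth_factor must be > 0")
    G = len(model.marginals)
    if n_cells == 0:
        return np.zeros((G, 0), dtype=int)
    rng = np.random.default_rng(seed)
    if use_correlation and model.sigma is not None:
        sig = model.sigma
        try:
            L = np.linalg.cholesky(sig)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(sig)
            L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        Z = L @ rng.standard_normal((G, n_cells))
    else:
        Z = rng.standard_normal((G, n_cells))
    U = ndtr(Z)
    out = np.empty((G, n_cells), dtype=np.int64)
    for g, marg in enumerate(model.marginals):
        out[g] = marg.ppf(U[g], depth_factor=depth_factor).astype(np.int64)
    return out
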