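"""Confounder-corrected linear mixed model association scan.

For transcript *k* and CpG *j* the model is

    y_k = mu_k + M_j * a_jk + X * b_jk + u_k + e_jk,
    u_k ~ N(0, sigma2_g * H),   e_jk ~ N(0, sigma2_e * I),

where ``H`` is the intersample correlation matrix estimated from the
standardized expression matrix itself (``H = Z'Z / m``). ``H`` absorbs
inter-individual correlation induced by unmeasured confounders such as
cellular heterogeneity. The variance ratio ``delta = sigma2_e / sigma2_g`` is
profiled by maximum likelihood on a log grid with local refinement, after a
one-off spectral rotation of all vectors by the eigenvectors of ``H``
(EMMA-style), so each additional (transcript, CpG) fit is a weighted least
squares problem.

Wald statistics use a t reference distribution with ``n - rank(design)``
degrees of freedom; with ``H = I`` the fit collapses exactly to ordinary
least squares, which the tests use as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Null median of a chi-square(1) statistic; denominator of the genomic
#: inflation factor, GIF = median(T^2) / 0.4549.
GIF_DENOM = 0.4549

#: Significance tiers for the scan.
SUGGESTIVE_P = 1e-5
SIGNIFICANT_P = 1e-11

#: Per-transcript GIF threshold: transcripts with GIF > 2 are dropped.
GIF_MAX = 2.0

_DELTA_GRID = np.logspace(-5.0, 5.0, 100)


class AlignmentError(ValueError):
    """Sample IDs of the input matrices do not match."""


class DegenerateFitError(RuntimeError):
    """The rotated design is singular and no fit is possible."""


@dataclass(frozen=True)
class IntersampleCorrelation:
    """Expression-derived sample covariance ``H`` with cached eigensystem.

    ``eigenvalues`` are in descending order and clamped below at
    ``1e-6 * max(eigenvalue)`` for numerical stability when ``H`` is
    rank-deficient (n > m).
    """

    H: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns match eigenvalues
    sample_ids: tuple = ()


@dataclass(frozen=True)
class LmmFit:
    effect: float
    se: float
    sigma2_g: float
    sigma2_e: float
    delta: float
    T: float
    p: float
    loglik: float
    df: int


@dataclass(frozen=True)
class TranscriptGIF:
    transcript_id: str
    gif: float
    passed: bool


def standardize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a transcripts × samples log-expression matrix.

    Each row is centered and scaled to unit standard deviation (n−1
    denominator). Zero-variance transcripts cannot be standardized; they are
    dropped with a warning.
    """
    values = expr.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least two samples to standardize")
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] <= 0.0
    if degenerate.any():
        bad = list(expr.index[degenerate])
        warnings.warn(
            f"excluding {len(bad)} zero-variance transcript(s): {bad[:5]}...",
            RuntimeWarning,
            stacklevel=2,
        )
        values, mu, sd = values[~degenerate], mu[~degenerate], sd[~degenerate]
        expr = expr.loc[~degenerate]
    z = (values - mu) / sd
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def estimate_intersample_correlation(Z: pd.DataFrame) -> IntersampleCorrelation:
    """``H = Z'Z / m`` over the m standardized transcript rows, with cached,
    clamped eigendecomposition."""
    zv = Z.to_numpy(dtype=float)
    m, n = zv.shape
    if m < 2:
        raise ValueError("need at least two transcripts to estimate H")
    if n > m:
        warnings.warn(
            f"H is rank-deficient (n={n} samples > m={m} transcripts); "
            "eigenvalues are clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    H = zv.T @ zv / m
    H = (H + H.T) / 2.0
    evals, evecs = np.linalg.eigh(H)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    eps = 1e-6 * max(evals[0], 1e-300)
    evals = np.maximum(evals, eps)
    return IntersampleCorrelation(
        H=H, eigenvalues=evals, eigenvectors=evecs,
        sample_ids=tuple(Z.columns),
    )


def _as_eigensystem(H) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(H, IntersampleCorrelation):
        return H.eigenvalues, H.eigenvectors
    H = np.asarray(H, dtype=float)
    evals, evecs = np.linalg.eigh((H + H.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 1e-6 * max(evals[0], 1e-300))
    return evals, evecs


def _ll_terms(S, delta, X0r, yr, Mr):
    """Profile-likelihood pieces for all CpG columns at one or many deltas.

    ``delta`` is scalar (shared across columns) or a vector of length p
    (one per column). Returns (a, mwm, rss, loglik) each of shape (p,).
    """
    n, q0 = X0r.shape
    p = Mr.shape[1]
    if np.ndim(delta) == 0:
        w = 1.0 / (S + float(delta))                      # (n,)
        logdet = float(np.log(S + float(delta)).sum())
        Xw = X0r * w[:, None]
        G = X0r.T @ Xw                                    # (q0, q0)
        try:
            Gi = np.linalg.inv(G)
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError("singular rotated design") from exc
        ey = yr - X0r @ (Gi @ (Xw.T @ yr))                # (n,)
        EM = Mr - X0r @ (Gi @ (Xw.T @ Mr))                # (n, p)
        wey = w * ey
        mwm = np.einsum("ij,ij->j", EM * w[:, None], EM)
        mwy = EM.T @ wey
        ywy = float(ey @ wey)
        logdet = np.full(p, logdet)
    else:
        delta = np.asarray(delta, dtype=float)            # (p,)
        w = 1.0 / (S[:, None] + delta[None, :])           # (n, p)
        logdet = np.log(S[:, None] + delta[None, :]).sum(axis=0)
        G = np.einsum("ia,ij,ib->jab", X0r, w, X0r)       # (p, q0, q0)
        rhs_y = np.einsum("ia,ij,i->ja", X0r, w, yr)      # (p, q0)
        rhs_m = np.einsum("ia,ij,ij->ja", X0r, w, Mr)     # (p, q0)
        try:
            by = np.linalg.solve(G, rhs_y[..., None])[..., 0]   # (p, q0)
            bm = np.linalg.solve(G, rhs_m[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError("singular rotated design") from exc
        ey = yr[:, None] - X0r @ by.T                     # (n, p)
        EM = Mr - X0r @ bm.T
        mwm = (w * EM * EM).sum(axis=0)
        mwy = (w * EM * ey).sum(axis=0)
        ywy = (w * ey * ey).sum(axis=0)
    safe = mwm > 1e-12 * max(float(np.max(mwm, initial=0.0)), 1e-300)
    a = np.where(safe, mwy / np.where(safe, mwm, 1.0), 0.0)
    rss = np.maximum(ywy - a * mwy, 0.0)
    with np.errstate(divide="ignore"):
        log_s2 = np.where(rss > 0, np.log(np.maximum(rss, 1e-300) / n), -np.inf)
    ll = -0.5 * (n * np.log(2.0 * np.pi) + n * log_s2 + logdet + n)
    # a zero-RSS fit has unbounded likelihood; keep it finite but dominant
    ll = np.where(np.isfinite(ll), ll, 1e300)
    return a, mwm, rss, ll


def _fit_columns(S, U, y, Mmat, X0, grid=_DELTA_GRID):
    """Vectorized profile-ML fits of one transcript against many CpG columns.

    Returns a dict of arrays (effect, se, T, p, sigma2_g, sigma2_e, delta,
    loglik) of length p, plus the scalar df.
    """
    n = len(y)
    yr = U.T @ y
    X0r = U.T @ X0
    Mr = U.T @ Mmat
    p = Mr.shape[1]
    q = X0.shape[1] + 1
    df = n - q
    if df <= 0:
        raise DegenerateFitError(f"no residual degrees of freedom (n={n}, q={q})")

    lls = np.empty((len(grid), p))
    for gi, d in enumerate(grid):
        lls[gi] = _ll_terms(S, d, X0r, yr, Mr)[3]
    best = np.argmax(lls, axis=0)
    log_grid = np.log10(grid)

    # parabolic refinement in log10(delta) around the grid optimum
    inner = np.clip(best, 1, len(grid) - 2)
    l0 = lls[inner - 1, np.arange(p)]
    l1 = lls[inner, np.arange(p)]
    l2 = lls[inner + 1, np.arange(p)]
    denom = l0 - 2.0 * l1 + l2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(denom < -1e-12, 0.5 * (l0 - l2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    h = log_grid[1] - log_grid[0]
    refined = 10.0 ** (log_grid[inner] + shift * h)

    a_r, mwm_r, rss_r, ll_r = _ll_terms(S, refined, X0r, yr, Mr)
    ll_g = lls[best, np.arange(p)]
    use_ref = ll_r > ll_g
    delta = np.where(use_ref, refined, grid[best])
    # final statistics at the chosen per-column delta
    a, mwm, rss, ll = _ll_terms(S, delta, X0r, yr, Mr)

    sigma2_g = rss / n
    sigma2_e = delta * sigma2_g
    with np.errstate(divide="ignore", invalid="ignore"):
        resid_var = rss / df
        se = np.sqrt(np.where(mwm > 0, resid_var / np.where(mwm > 0, mwm, 1.0), np.inf))
        T = np.where(se > 0, a / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(T), df)
    # zero residual variance: effect fits exactly; floor p at machine tiny
    exact = (rss <= 1e-12 * np.maximum(np.abs(a) * mwm, 1e-300)) & (np.abs(a) > 0)
    pvals = np.where(exact, np.finfo(float).tiny, np.maximum(pvals, np.finfo(float).tiny))
    return {
        "effect": a, "se": se, "T": T, "p": pvals,
        "sigma2_g": sigma2_g, "sigma2_e": sigma2_e,
        "delta": delta, "loglik": ll, "df": df,
    }


def fit_lmm(y, M, X, H) -> LmmFit:
    """Fit the mixed model for a single (transcript, CpG) pair.

    Parameters
    ----------
    y : (n,) expression vector.
    M : (n,) methylation β vector.
    X : (n, q0) fixed-effect design **including** the intercept column.
    H : IntersampleCorrelation or an (n, n) symmetric matrix (``np.eye(n)``
        collapses the fit to OLS).
    """
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float).reshape(-1, 1)
    X = np.asarray(X, dtype=float)
    if not (len(y) == M.shape[0] == X.shape[0]):
        raise ValueError("y, M and X must share the sample dimension")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateFitError("covariate design is rank deficient")
    S, U = _as_eigensystem(H)
    r = _fit_columns(S, U, y, M, X)
    return LmmFit(
        effect=float(r["effect"][0]), se=float(r["se"][0]),
        sigma2_g=float(r["sigma2_g"][0]), sigma2_e=float(r["sigma2_e"][0]),
        delta=float(r["delta"][0]), T=float(r["T"][0]), p=float(r["p"][0]),
        loglik=float(r["loglik"][0]), df=int(r["df"]),
    )


def tier_of(p: float, suggestive: float = SUGGESTIVE_P,
            significant: float = SIGNIFICANT_P) -> str:
    if p < significant:
        return "significant"
    if p < suggestive:
        return "suggestive"
    return "none"


def scan(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    suggestive: float = SUGGESTIVE_P,
    significant: float = SIGNIFICANT_P,
    H: IntersampleCorrelation | np.ndarray | None = None,
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """Association scan of every (CpG, transcript) combination.

    Parameters
    ----------
    meth : samples × CpGs β-value matrix.
    expr : transcripts × samples log-expression matrix.
    covars : samples × covariates (age, sex, ...); an intercept is added.
    H : optional pre-computed intersample correlation; by default ``Z'Z/m``
        is estimated once from ``expr`` and reused for every fit.
    leave_one_out : when ``H`` is estimated internally, the tested
        transcript's own rank-one contribution ``z_k z_k'/m`` is removed from
        ``H`` before fitting transcript k. The tested expression vector lies
        exactly in the row space of ``Z``, so with few transcripts its own
        contribution lets the random effect absorb the phenotype and deflates
        every test statistic; the downdate removes this proximal
        contamination while keeping the shared (confounder) structure.
        Negligible when m >> n, the regime the estimator assumes.

    Returns a tidy DataFrame with one row per pair, ordered by
    (transcript_id, cpg_id), with columns cpg_id, transcript_id, effect, se,
    T, p, delta, tier.
    """
    meth_samples = set(meth.index)
    expr_samples = set(expr.columns)
    if meth_samples != expr_samples:
        offenders = sorted(meth_samples ^ expr_samples)
        raise AlignmentError(
            f"methylation/expression sample IDs differ: {offenders[:10]}"
        )
    sample_ids = sorted(meth_samples)
    if covars is not None:
        if set(covars.index) != meth_samples:
            offenders = sorted(set(covars.index) ^ meth_samples)
            raise AlignmentError(f"covariate sample IDs differ: {offenders[:10]}")
        covars = covars.loc[sample_ids]

    meth = meth.loc[sample_ids].sort_index(axis=1)
    expr = expr.loc[:, sample_ids].sort_index(axis=0)
    n = len(sample_ids)
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")

    bad = (meth.to_numpy() < 0).any() or (meth.to_numpy() > 1).any()
    if bad:
        raise ValueError("β-values must lie in [0, 1]")

    Z = standardize_expression(expr)
    expr = expr.loc[Z.index]  # drop zero-variance transcripts consistently
    m = Z.shape[0]
    loo = False
    if H is None:
        ice = estimate_intersample_correlation(Z)
        S, U = ice.eigenvalues, ice.eigenvectors
        loo = leave_one_out and m >= 3
    else:
        S, U = _as_eigensystem(H)

    X0 = np.ones((n, 1))
    if covars is not None and covars.shape[1] > 0:
        X0 = np.column_stack([X0, covars.to_numpy(dtype=float)])

    Mmat = meth.to_numpy(dtype=float)
    cpg_ids = np.asarray(meth.columns)
    zmat = Z.to_numpy(dtype=float)
    frames = []
    for k, (tx_id, row) in enumerate(zip(expr.index, expr.to_numpy(dtype=float))):
        if loo:
            Hk = (m * ice.H - np.outer(zmat[k], zmat[k])) / (m - 1)
            S, U = _as_eigensystem(Hk)
        r = _fit_columns(S, U, row, Mmat, X0)
        frames.append(pd.DataFrame({
            "cpg_id": cpg_ids,
            "transcript_id": tx_id,
            "effect": r["effect"], "se": r["se"], "T": r["T"], "p": r["p"],
            "delta": r["delta"],
        }))
    out = pd.concat(frames, ignore_index=True)
    out["tier"] = [tier_of(p, suggestive, significant) for p in out["p"]]
    out = out.sort_values(["transcript_id", "cpg_id"], kind="mergesort")
    return out.reset_index(drop=True)


def compute_gif(t_stats, transcript_id: str = "", gif_max: float = GIF_MAX) -> TranscriptGIF:
    """GIF = median(T²) / 0.4549; transcripts with GIF > ``gif_max`` fail."""
    t = np.asarray(t_stats, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one statistic")
    gif = float(np.median(t ** 2) / GIF_DENOM)
    return TranscriptGIF(transcript_id=transcript_id, gif=gif, passed=gif <= gif_max)


def gif_table(results: pd.DataFrame, gif_max: float = GIF_MAX) -> pd.DataFrame:
    """Per-transcript GIF summary from a scan results frame."""
    rows = []
    for tx, sub in results.groupby("transcript_id", sort=True):
        g = compute_gif(sub["T"].to_numpy(), tx, gif_max)
        rows.append((tx, g.gif, g.passed))
    return pd.DataFrame(rows, columns=["transcript_id", "gif", "passed"])


def filter_by_gif(results: pd.DataFrame, gif_max: float = GIF_MAX) -> pd.DataFrame:
    """Drop all records of transcripts whose GIF exceeds ``gif_max``.

    Applied after the scan and before classification.
    """
    gifs = gif_table(results, gif_max)
    keep = set(gifs.loc[gifs["passed"], "transcript_id"])
    return results[results["transcript_id"].isin(keep)].reset_index(drop=True)
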