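"""Correlation diagnostics and the confirmatory three-component model.

The measurement model is a principal component analysis of the 20 adjusted
performance variables with the number of components fixed a priori at
three (one per emotion domain), varimax rotation with Kaiser
normalization, and Anderson-Rubin factor scores (mean 0, SD 1, mutually
uncorrelated by construction).

Diagnostics: element-wise Olkin-Pratt-corrected mean correlations within
vs. between the domain blocks (with bootstrap CIs and a Fisher r-to-z
contrast), the Kaiser-Meyer-Olkin sampling-adequacy index, and Bartlett's
test of sphericity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.special import hyp2f1


class SingularCorrelationError(ValueError):
    """The correlation matrix is singular; Bartlett's statistic is undefined."""


class RotationConvergenceError(RuntimeError):
    """Varimax rotation failed to converge within the iteration budget."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# Correlation diagnostics
# ---------------------------------------------------------------------------


def _hyp2f1_half_half(c: float, z) -> np.ndarray:
    """Gauss series for 2F1(1/2, 1/2; c; z), term-wise to convergence.

    scipy's hyp2f1 loses accuracy (returns NaN) for z -> 1 with large c,
    exactly the regime of near-zero correlations at large n, so the series
    is summed directly; successive term ratios are < z, so it converges
    for |z| < 1 and the tail is bounded geometrically.
    """
    z = np.asarray(z, dtype=float)
    total = np.ones_like(z)
    term = np.ones_like(z)
    for k in range(10_000):
        term = term * ((0.5 + k) ** 2) / ((c + k) * (k + 1.0)) * z
        total += term
        if np.all(np.abs(term) < 1e-14 * np.abs(total)):
            break
    return total


def olkin_pratt(r, n: int):
    """Approximately unbiased estimate of a correlation coefficient.

    The standard series in closed form: G(r) = r * 2F1(1/2, 1/2;
    (n-2)/2; 1 - r^2).  Converges to r as n grows.
    """
    r = np.asarray(r, dtype=float)
    if n < 5:
        raise ValueError("Olkin-Pratt correction requires n >= 5")
    z = 1.0 - r**2
    c = (n - 2) / 2.0
    if c >= 100.0:
        # large-c regime: the direct series converges in a few terms and
        # avoids scipy's slow/inaccurate z -> 1 branch
        return r * _hyp2f1_half_half(c, z)
    with np.errstate(all="ignore"):
        g = np.asarray(hyp2f1(0.5, 0.5, c, z), dtype=float)
    bad = ~np.isfinite(g)
    if np.any(bad):
        g = np.where(bad, _hyp2f1_half_half(c, z), g)
    return r * g


def _block_masks(columns, domain_partition) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (within, between) over the upper triangle of pairs."""
    cols = list(columns)
    domain_of = {}
    for domain, block in domain_partition.items():
        for c in block:
            domain_of[c] = domain
    p = len(cols)
    within = np.zeros((p, p), dtype=bool)
    between = np.zeros((p, p), dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            same = domain_of[cols[i]] == domain_of[cols[j]]
            within[i, j] = same
            between[i, j] = not same
    return within, between


def _mean_block_r(corr: np.ndarray, mask: np.ndarray, n: int) -> float:
    return float(np.mean(olkin_pratt(corr[mask], n)))


def kmo(corr: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin index, overall and per variable.

    Compares squared correlations with squared partial correlations
    obtained from the (pseudo-)inverse of the correlation matrix.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    try:
        s = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular correlation matrix: KMO computed with a pseudo-inverse",
            stacklevel=2,
        )
        s = np.linalg.pinv(corr)
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    partial = -s / d
    off = ~np.eye(p, dtype=bool)
    r2 = corr[off] ** 2
    p2 = partial[off] ** 2
    overall = r2.sum() / (r2.sum() + p2.sum())
    per_var = np.array(
        [
            (corr[i, :][off[i]] ** 2).sum()
            / ((corr[i, :][off[i]] ** 2).sum() + (partial[i, :][off[i]] ** 2).sum())
            for i in range(p)
        ]
    )
    return float(overall), per_var


def bartlett_sphericity(corr: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: chi2, df = p(p-1)/2, p-value."""
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or not np.isfinite(logdet):
        raise SingularCorrelationError(
            "correlation matrix is singular: Bartlett's statistic undefined"
        )
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


@dataclass
class CorrDiagnostics:
    corr_matrix: pd.DataFrame
    n: int
    mean_r_within: float
    mean_r_within_ci: tuple[float, float]
    mean_r_between: float
    mean_r_between_ci: tuple[float, float]
    fisher_z: float
    fisher_p: float
    kmo_overall: float
    kmo_per_variable: pd.Series
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_r_within": self.mean_r_within,
            "mean_r_within_ci": list(self.mean_r_within_ci),
            "mean_r_between": self.mean_r_between,
            "mean_r_between_ci": list(self.mean_r_between_ci),
            "fisher_z": self.fisher_z,
            "fisher_p": self.fisher_p,
            "kmo_overall": self.kmo_overall,
            "kmo_per_variable": self.kmo_per_variable.to_dict(),
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
        }


def corr_diagnostics(
    z: pd.DataFrame,
    domain_partition: dict,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> CorrDiagnostics:
    """Correlation-structure diagnostics of the adjusted score table.

    Pearson correlations; the Olkin-Pratt correction is applied per
    element before averaging within/between the domain blocks; CIs by
    percentile bootstrap over participants; the within-vs-between contrast
    is a Fisher r-to-z two-sample-style z statistic on the two means.
    """
    for domain, block in domain_partition.items():
        if len(block) < 3:
            raise ValueError(f"domain {domain!r} must contribute >= 3 variables")
    n, p = z.shape
    if n <= p:
        warnings.warn(
            f"n = {n} <= p = {p}: correlation diagnostics will be unstable",
            stacklevel=2,
        )
    x = z.to_numpy(dtype=float)
    corr = np.corrcoef(x, rowvar=False)
    within, between = _block_masks(z.columns, domain_partition)
    mean_w = _mean_block_r(corr, within, n)
    mean_b = _mean_block_r(corr, between, n)

    if rng is None:
        rng = np.random.default_rng()
    boots_w = np.empty(n_boot)
    boots_b = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        cb = np.corrcoef(x[idx], rowvar=False)
        boots_w[b] = _mean_block_r(cb, within, n)
        boots_b[b] = _mean_block_r(cb, between, n)
    ci_w = tuple(np.percentile(boots_w, [2.5, 97.5]))
    ci_b = tuple(np.percentile(boots_b, [2.5, 97.5]))

    # Fisher r-to-z contrast of the two mean correlations
    zdiff = np.arctanh(mean_w) - np.arctanh(mean_b)
    fisher = float(zdiff / np.sqrt(2.0 / (n - 3)))
    fisher_p = float(2 * stats.norm.sf(abs(fisher)))

    kmo_overall, kmo_per = kmo(corr)
    chi2, df, pval = bartlett_sphericity(corr, n)
    return CorrDiagnostics(
        corr_matrix=pd.DataFrame(corr, index=z.columns, columns=z.columns),
        n=n,
        mean_r_within=mean_w,
        mean_r_within_ci=ci_w,
        mean_r_between=mean_b,
        mean_r_between_ci=ci_b,
        fisher_z=fisher,
        fisher_p=fisher_p,
        kmo_overall=kmo_overall,
        kmo_per_variable=pd.Series(kmo_per, index=z.columns),
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
    )


# ---------------------------------------------------------------------------
# PCA with varimax rotation
# ---------------------------------------------------------------------------


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: summed column variance of squared loadings."""
    lam2 = loadings**2
    p = loadings.shape[0]
    return float(np.sum(lam2**2) / p - np.sum((lam2.sum(axis=0) / p) ** 2))


def varimax(
    loadings: np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by pairwise planar rotations.

    With ``kaiser=True`` rows are normalized by their communalities before
    rotation and de-normalized after.  Returns (rotated loadings, rotation
    matrix).  Raises :class:`RotationConvergenceError` if the criterion has
    not stabilized after ``max_iter`` sweeps.
    """
    lam = np.asarray(loadings, dtype=float).copy()
    p, k = lam.shape
    h = np.sqrt((lam**2).sum(axis=1))
    if kaiser:
        lam = lam / h[:, None]
    rot = np.eye(k)
    trajectory = [varimax_criterion(lam)]
    converged = k < 2
    for _ in range(max_iter):
        max_phi = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = lam[:, i], lam[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                a, b = u.sum(), v.sum()
                c = (u**2 - v**2).sum()
                d = 2 * (u * v).sum()
                num = d - 2 * a * b / p
                den = c - (a**2 - b**2) / p
                phi = 0.25 * np.arctan2(num, den)
                max_phi = max(max_phi, abs(phi))
                if abs(phi) < 1e-15:
                    continue
                cs, sn = np.cos(phi), np.sin(phi)
                g = np.array([[cs, -sn], [sn, cs]])
                lam[:, [i, j]] = lam[:, [i, j]] @ g
                rot[:, [i, j]] = rot[:, [i, j]] @ g
        trajectory.append(varimax_criterion(lam))
        # the criterion is flat (quadratic) at the optimum, so convergence is
        # declared on the rotation angles as well as the criterion change
        if abs(trajectory[-1] - trajectory[-2]) < tol and max_phi < 1e-9:
            converged = True
            break
    if not converged:
        raise RotationConvergenceError(
            f"varimax did not converge in {max_iter} sweeps", trajectory
        )
    if kaiser:
        lam = lam * h[:, None]
    return lam, rot


@dataclass
class FactorSolution:
    """Rotated k-component solution on the 20-variable battery."""

    loadings: pd.DataFrame  # variables x components (rotated, de-normalized)
    eigenvalues: np.ndarray  # rotated sums of squared loadings, per component
    variance_explained: np.ndarray  # proportions of total variance (p)
    total_variance_explained: float
    domain_assignment: dict  # component name -> domain
    unrotated_loadings: pd.DataFrame = field(repr=False, default=None)
    corr_matrix: pd.DataFrame = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def display_loadings(self, threshold: float = 0.30) -> pd.DataFrame:
        """Presentation view with small loadings blanked (storage keeps all)."""
        shown = self.loadings.round(3).astype(object)
        shown[self.loadings.abs() < threshold] = ""
        return shown


def _assign_domains(
    loadings: pd.DataFrame, domain_partition: dict
) -> dict[str, str]:
    """Map each component to the domain whose block loads it most strongly.

    Uses mean absolute loadings (sign-agnostic) and solves the bijective
    assignment maximizing total block loading.
    """
    domains = list(domain_partition)
    comps = list(loadings.columns)
    cost = np.zeros((len(comps), len(domains)))
    for ci, comp in enumerate(comps):
        for di, dom in enumerate(domains):
            block = list(domain_partition[dom])
            cost[ci, di] = loadings.loc[block, comp].abs().mean()
    rows, cols = linear_sum_assignment(-cost)
    return {comps[r]: domains[c] for r, c in zip(rows, cols)}


def fit_pca_varimax(
    z: pd.DataFrame,
    k: int = 3,
    domain_partition: dict | None = None,
    salient_threshold: float = 0.30,
) -> FactorSolution:
    """Confirmatory PCA: retain k components, varimax-rotate, label domains.

    Eigendecomposition of the correlation matrix; the first k components
    are retained regardless of the eigenvalue-greater-than-one rule (the
    number of factors is fixed a priori).  Column signs are oriented so
    each component's salient loadings are majority-positive; reported
    eigenvalues are post-rotation column sums of squared loadings, sorted
    descending.
    """
    p = z.shape[1]
    if k > p:
        raise ValueError("cannot retain more components than variables")
    corr = np.corrcoef(z.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:k]
    lam_unrot = eigvec[:, order] * np.sqrt(eigval[order])[None, :]
    lam_rot, _ = varimax(lam_unrot, kaiser=True)

    # majority-positive salient loadings per component (ties broken so the
    # salient sum is positive)
    for j in range(k):
        col = lam_rot[:, j]
        salient = col[np.abs(col) >= salient_threshold]
        ref = salient if salient.size else col
        n_pos, n_neg = (ref > 0).sum(), (ref < 0).sum()
        if n_pos < n_neg or (n_pos == n_neg and ref.sum() < 0):
            lam_rot[:, j] = -col

    ssl = (lam_rot**2).sum(axis=0)
    order2 = np.argsort(ssl)[::-1]
    lam_rot = lam_rot[:, order2]
    ssl = ssl[order2]

    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(lam_rot, index=z.columns, columns=comp_names)
    assignment = (
        _assign_domains(loadings, domain_partition) if domain_partition else {}
    )
    return FactorSolution(
        loadings=loadings,
        eigenvalues=ssl,
        variance_explained=ssl / p,
        total_variance_explained=float(ssl.sum() / p),
        unrotated_loadings=pd.DataFrame(
            lam_unrot, index=z.columns, columns=comp_names
        ),
        corr_matrix=pd.DataFrame(corr, index=z.columns, columns=z.columns),
        domain_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# Anderson-Rubin factor scores
# ---------------------------------------------------------------------------


def _inv_sqrt_sym(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    if np.any(w <= 1e-12):
        raise np.linalg.LinAlgError("matrix not positive-definite")
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def anderson_rubin_scores(z: pd.DataFrame, solution: FactorSolution) -> pd.DataFrame:
    """Anderson-Rubin factor scores: M = 0, SD = 1, pairwise correlation 0.

    Computed as the regression-method transform ``Z R^{-1} L`` followed by
    orthonormalization with the symmetric inverse square root of its
    sample covariance, which enforces unit variance and zero inter-score
    correlation exactly.
    """
    if list(solution.loadings.index) != list(z.columns):
        raise ValueError("solution was fitted on a different variable set")
    x = z.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    r = solution.corr_matrix.to_numpy()
    lam = solution.loadings.to_numpy()
    try:
        f = x @ np.linalg.solve(r, lam)
        cov = f.T @ f / x.shape[0]
        scores = f @ _inv_sqrt_sym(cov)
    except np.linalg.LinAlgError as exc:
        raise SingularCorrelationError(
            f"Anderson-Rubin transform hit a singular matrix: {exc}"
        ) from exc
    return pd.DataFrame(scores, index=z.index, columns=solution.loadings.columns)


def orient_for_performance(
    scores: pd.DataFrame,
    solution: FactorSolution,
    error_keyed_columns=None,
) -> pd.DataFrame:
    """Flip score columns so that higher = better performance.

    Every battery variable is an error score, so a component whose salient
    loadings point in the error direction increases with errors; its score
    is negated so that "bottom of the distribution" means "worst
    performers", the direction the normative deficit cutoff assumes.
    Negation preserves the Anderson-Rubin moments.  Columns are renamed to
    their assigned domains.
    """
    if error_keyed_columns is None:
        error_keyed_columns = list(solution.loadings.index)
    out = scores.copy()
    for comp in scores.columns:
        keyed = solution.loadings.loc[list(error_keyed_columns), comp]
        salient = keyed[keyed.abs() >= 0.30]
        ref = salient if len(salient) else keyed
        if ref.sum() > 0:  # score rises with errors -> flip to performance
            out[comp] = -out[comp]
    return out.rename(columns=solution.domain_assignment)
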